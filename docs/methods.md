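# Methods

This note documents the models, conventions and numerical choices behind
`radscan`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Data model and conventions

The central container is a sites × accessions diploid genotype matrix with
alleles coded A/C/G/T and a dedicated missing sentinel (never an ambiguity
code). Coordinates are 0-based half-open internally and 1-based in all
human-readable reports, matching VCF display convention. Multiallelic sites
(more than two alleles across all accessions) are retained in the matrix but
excluded from every pattern-counting and association operation, which are
defined only for biallelic sites; this is the conservative reading of
biallelic-pattern methods.

Two quality presets follow common transcriptome practice: HQ (per-genotype
depth ≥ 3, mapping quality ≥ 30) for distance and window work, and HD
(depth ≥ 10, MQ ≥ 30) for heterozygosity, where undercalled heterozygotes
bias H downward. Genotypes failing a threshold become missing; sites below a
minimum number of covered accessions are dropped.

**Heterozygote resolution.** All haploid analyses (D-statistics,
D_FOIL, PhyloGWAS, distances) consume a haploid matrix obtained by picking
one allele of each heterozygous genotype uniformly at random. One global
seeded RNG stream is consumed in site-major, accession-minor order, so a run
is reproducible and order-stable; homozygous genotypes map to their allele
unchanged and the operation is idempotent on its own output. Whether the
draw should be fixed once per site or redrawn per analysis is genuinely
open; a single global stream per seed was chosen so that all analyses in one
run see the same resolution.

**Codon classification.** A substitution is classified by translating the
two codons that differ only at the focal site (standard genetic code,
biopython); a change of amino acid — stop included — is nonsynonymous.
Minus-strand gene models complement the alleles before substitution into the
mRNA-sense CDS. Codons containing missing bases raise a
classification-unavailable signal rather than guessing. The classification
is symmetric in the two alleles.

## Synthetic-data generator

The generator emulates the structure of a multi-accession transcriptome
variant matrix from a rapid radiation under the multispecies coalescent
(MSC), using msprime:

- A rooted ultrametric species tree carries node ages in **years**; ages
  convert to coalescent units as `years × gens_per_year / (2 N_e)`. Defaults
  are N_e = 10⁵ diploids and 2.5 generations/year. Branch lengths are
  converted to generations before building the msprime demography, and the
  model ploidy is always 2 so one coalescent unit is 2·N_e generations
  regardless of how many lineages per accession are sampled (sample-set
  ploidy controls that instead).
- The bundled default tree has 13 ingroup species in four subclades plus a
  two-accession outgroup (29 accessions, 27 ingroup). Backbone internodes
  are ~1 coalescent unit so ILS is extensive, while subclade stems are long,
  mirroring radiations whose major groups are solid but whose backbone is
  not.
- Each gene is an independent non-recombining genealogy. Each diploid
  accession contributes two sampled lineages of its species' population, so
  heterozygosity arises naturally from within-population coalescence.
- Variable sites are placed per gene at distinct CDS offsets; the mutated
  branch is drawn with probability proportional to branch length
  (infinite-sites: derived carriers are exactly the leaves below the branch,
  no back-mutation). Genes sit 10 kb apart on one synthetic chromosome
  (300-codon single-exon CDS per gene) so window machinery is exercised.
- **Introgression** is a per-gene pulse: with probability γ (recorded per
  gene in the truth table) a gene's genealogy reroutes the recipient's
  lineages through the donor population at the event time (mass migration
  with proportion 1 for that gene). This matches a "fraction of the genome
  exchanged" framing rather than continuous migration, and gives an exact
  truth table for recovery tests.
- **Environment-sorted alleles** are injected as outcomes, not simulated
  under selection: at second codon positions (every second-position change
  is nonsynonymous under the standard code, asserted at runtime), group-1
  accessions are fixed for the ancestral base and group-2 for a derived
  base; uncontrasted accessions carry the ancestral base. Partitions
  congruent with a clade of the species tree are refused, since they would
  not emulate environment-driven sorting. A linked-block injector also
  writes synonymous sites at four-fold-degenerate third positions in one
  gene to emulate an introgressed haplotype block.

What the generator does **not** model: sequencing error, RNA-seq coverage
structure, indels, selection dynamics, recombination within genes, or
population structure within species. Passing recovery tests therefore shows
the estimators are correct under the MSC with clean genotypes; it does not
certify behavior under mapping artifacts or coverage-driven missingness.

## Introgression statistics

**Trio roles** are fixed by the species tree: for each 3-subset, the sister
pair is the pair whose smallest containing clade excludes the third member.
The accession-level tree resolves within-species trios by expanding each
species into a shallow ladder.

**Pattern counting.** Only sites where all four (five for D_FOIL) taxa have
data, at most two alleles segregate across the matrix, and the outgroup
carries one allele are counted; the outgroup allele defines the ancestral
state. D = (nABBA − nBABA)/(nABBA + nBABA); swapping P1 and P2 negates D
exactly.

**Window significance** uses a two-sided exact binomial test of nABBA in
nABBA + nBABA trials at ½. The binomial test on pattern counts is the
standard small-window choice; a χ² goodness-of-fit alternative is available
behind a flag. The test treats informative sites as independent, which is
exact when genes contribute one site each and approximate otherwise (sites
within one gene share a genealogy); the null-control simulation in the test
suite uses one variable site per gene for this reason.

**Block bootstrap**: windows are resampled with replacement (default 10,000
replicates) and D recomputed from the pooled counts of each replicate; the
95% CI is the percentile interval, and the headline flag is whether it
excludes 0. Replicates with no informative sites are excluded (NaN).

**D_FOIL.** On a symmetric quintet ((P1,P2),(P3,P4)),O with the first pair
younger, four left/right pattern contrasts are computed per window; left and
right sets are images of each other under the exchange symmetry each
statistic tests (P3↔P4 for D_FO/D_IL, P1↔P2 for D_FI/D_OL), so all four
have expectation 0 under ILS. A component's sign is scored only when its
exact binomial p-value is below α (default 0.001, per-component); the joint
sign vector is matched against the shipped signature table. The signature
table was determined by directed-pulse simulation across all eight
donor→recipient pairs plus ancestral events, is internally consistent under
both exchange symmetries, and is guarded by tests (all-concordant input
gives all-zero statistics; directed pulses recover the injected direction;
pulse-free runs make no calls). The zero component falls in the D_FO/D_IL
pair when the recipient is P1 or P2, and in the D_FI/D_OL pair when the
recipient is P3 or P4; ancestral flow zeroes both D_FI and D_OL and is
direction-ambiguous.

**Introgressed fraction.** The difference of the two discordant
rooted-triplet proportions estimates the introgressed gene fraction. The
estimator's premise is that introgressed genes nearly always display the
donor–recipient sister pair; it is biased low by the donor's failure to
capture the recipient lineage before the next speciation (roughly a factor
1 − e^(−Δ) for a donor interval of Δ coalescent units). Recovery
demonstrations therefore use a recent pulse with a long donor interval;
with short donor intervals the estimate should be read as a lower bound.

**Clade-wide summary** reports, at fixed thresholds (defaults |D| ≥ 0.2,
p < 10⁻⁴, |ABBA − BABA| ≥ 10), the number of windows significant for at
least one trio, the fraction of windows, and the per-branch fraction
n_sig/(n_windows × n_branches). The branch list is user-supplied (taxon
exclusions change it), and raw components are always reported so either
denominator convention can be checked. It accepts either the long-format
windowed table or bare counts.

## Lineage-specific substitutions

A site is clade-diagnostic when the allele set sampled from the target clade
and the allele set from all other accessions (outgroup pooled with the
nontarget side) are completely nonoverlapping; polymorphism within a side is
allowed as long as the sets stay disjoint. Sites qualify only when every
ingroup species has at least one allele and at least one outgroup accession
is covered. This counting needs no ancestral-state reconstruction, which is
the point: under rampant ILS, tree-based placement of substitutions is
unreliable.

Synonymous/nonsynonymous calls use the nontarget codon context with the
target allele substituted; if any target/nontarget base pair changes the
amino acid the site is nonsynonymous. Representative sequences (one
accession per species, the one with most aligned codons; ties to the
lexicographically first id) and per-gene monophyly of the target clade in
the gene tree (rooted by the outgroup) gate which genes are testable. The
likelihood branch-site test itself is external: the module emits codon
alignments and eligibility flags and ingests per-gene p-values; a built-in
exact binomial count test (observed nonsynonymous fraction against a 3/4
opportunity fraction) is provided as a clearly-labelled fallback, not a
substitute for the codon-model LRT.

The significance summary reports the proportion of tested genes significant
at α (default 0.01) and FDR = (α × n_tested)/n_significant, undefined when
nothing is significant. Proportions are reported unrounded.

## PhyloGWAS

A partition is scan-eligible only when both sides are non-empty, at least
one species has accessions on both sides (otherwise environment is
confounded with phylogeny), and neither side coincides with a clade of the
species tree. A site is *examined* when every contrasted accession has data
and it is biallelic and of the requested class (nonsynonymous by default);
it is a *hit* when the two groups' allele sets are disjoint. Missing data
remove a site from both numerator and denominator: a perfect association
requires complete observation.

The null asks how often ILS alone would sort one variant perfectly with the
partition. One haploid lineage per contrasted accession is simulated over
the species tree (N_e = 10⁵, 2.5 generations/year by default) and one
mutation is dropped on a branch chosen proportional to branch length —
because only contrasted lineages are simulated and the root branch is
excluded, every simulated site is variable among the contrasted accessions,
matching the "examined" conditioning. q is the fraction of genes whose
carrier set equals either side (label-swap invariant), with its binomial
standard error. The dataset p-value is P[Binomial(n_examined, q) ≥ m], the
standard Monte-Carlo exceedance convention (m = 0 gives p = 1); a
strictly-greater variant sits behind a flag. A full-resimulation mode draws
datasets from a freshly simulated pool of per-gene outcomes instead and
agrees with the binomial method within Monte-Carlo error under per-gene
independence; it is retained as a cross-check. The default Monte-Carlo size
is 10⁶ single-site genes; desk-scale runs pass smaller M and should quote
the reported standard error with q.

The linked-synonymous check counts, for each gene with a nonsynonymous hit,
the synonymous sites in the same gene that are also perfectly associated.
Isolated nonsynonymous hits are the standing-variation expectation; a block
of associated synonymous + nonsynonymous variants is the introgression
signature, and such genes are flagged ambiguous rather than excluded.

## Discordance metrics

Distinct-topology counting compares trees as unrooted topologies on an
identical taxon set (equal nontrivial bipartition sets, i.e.
Robinson–Foulds distance 0). Bipartition support for a reference branch is
the fraction of trees containing that exact bipartition (hard support;
polytomies do not count as compatible), with input trees pruned to the
reference's taxa when they carry extras. The three-taxon support anchor,
1 − (2/3)e^(−t) for an internode of t coalescent units, is verified by
simulation in the test suite. Branch length vs support uses Spearman rank
correlation over internal branches (≥ 3 required; constant vectors return
NaN with a tie flag).

The per-taxon instability score is a stand-in for published leaf-stability
indices, whose exact formula is not reproduced here: for each tree the
taxon's profile of nodal (edge-count) distances to all other taxa is taken,
and the score is the mean over tree pairs of the mean absolute change in
that profile. Its contract is the *ranking* (rogue taxa rank first;
identical trees score zero everywhere), not the absolute value; it is
quadratic in the number of trees and intended for moderate tree sets.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the CLI manifest records
the package version, a config hash and the seeds, and reruns are
bit-identical. The bundled demonstrations and the acceptance script run at
desk scale by design: topology-count recovery uses 5,000 genes per γ, the
analytic discordance check 10,000 genes, coalescent-null q estimates
30,000–40,000 single-site genes (with their Monte-Carlo standard errors
reported), and windowed-scan demonstrations use ~10–20 genes per 100-kb
window with enough sites per window (hundreds) that per-window exact tests
have power, comparable in spirit to the aligned-site densities of
transcriptome windows. All of these sizes are configurable upward.

## Known limitations

- The D_FOIL direction table assumes the symmetric quintet with the first
  pair younger; other shapes are refused rather than mis-called.
- The introgressed-fraction estimator is a lower bound when the donor
  interval is short (see above).
- The PhyloGWAS null samples one lineage per accession; heterozygous
  resolution noise in the observed scan is not propagated into the null.
- Window tests assume independent informative sites; with many sites per
  gene and few genes per window the exact binomial is anti-conservative.
- The instability score is rank-calibrated only; absolute values are not
  comparable across taxon sets of different size.
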
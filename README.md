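# radscan

Phylogenomic dissection of adaptive variation in rapid radiations.

When a clade radiates quickly, speciation events are so closely spaced that
ancestral polymorphism fails to sort between them (incomplete lineage
sorting, ILS) and post-speciation hybridization adds further reticulation.
`radscan` takes a clade sampled as a multisample variant matrix (many
accessions from many closely related species, e.g. transcriptome variant
calls from a wild plant radiation) plus species/gene trees and quantifies
three distinct sources of adaptive variation against that noisy background:

1. **Introgression** — ABBA–BABA *D*-statistics per trio of accessions over
   genomic windows, with a block bootstrap over windows, five-taxon
   *D*<sub>FOIL</sub> statistics to infer the *direction* of gene flow, and
   gene-tree topology counting to estimate the fraction of the genome
   exchanged.
2. **Lineage-specific de novo substitution** — conservative counting of
   substitutions diagnostic for a clade: a site counts only when the target
   clade's allele set and the allele set of *all* other taxa (outgroup
   included) are completely disjoint, with monophyly eligibility checked per
   gene tree and FDR arithmetic for downstream branch-site test p-values.
3. **Environment-sorted ancestral variation ("PhyloGWAS")** — a scan for
   nonsynonymous variants perfectly associated with a binary environmental
   classification that is incongruent with the phylogeny, with significance
   from a multispecies-coalescent null (how often would ILS alone sort a
   variant perfectly with the environment?).

A seeded multispecies-coalescent simulator (`radscan.synthetic_data`, built
on msprime) generates diploid variant matrices over a labelled species tree,
with optional introgression pulses and injected environment-sorted alleles,
and returns truth tables so every scan can be validated end to end.

## The statistics, briefly

For an ordered trio (P1, P2 sisters relative to P3) polarized by an outgroup
O, with biallelic site patterns written in (P1, P2, P3, O) order:

    D = (n_ABBA − n_BABA) / (n_ABBA + n_BABA)

Under ILS alone E[D] = 0; gene flow between P3 and P2 (or P1) inflates ABBA
(or BABA). Window significance uses a two-sided exact binomial test of
n_ABBA against Binomial(n_ABBA + n_BABA, ½). On a symmetric five-taxon tree
((P1,P2),(P3,P4)),O, the four D<sub>FOIL</sub> statistics (D_FO, D_IL, D_FI,
D_OL) are analogous left/right pattern contrasts whose joint sign signature
identifies donor and recipient.

The gene-tree estimate of the introgressed fraction is the difference of the
two discordant rooted-triplet proportions, |p(disc₁) − p(disc₂)|, since ILS
alone produces both discordant topologies equally often.

The PhyloGWAS dataset p-value is P[Binomial(n, q) ≥ m] where m of n examined
nonsynonymous variants are perfectly associated and q is the Monte-Carlo
probability (from single-variable-site coalescent genes over the species
tree, N_e = 10⁵, 2.5 generations/year) that one variant sorts perfectly with
the partition by ILS alone.

## Worked example

End-to-end demonstration on synthetic data (a 29-accession, 14-species
radiation with a γ = 0.3 introgression pulse from `per1` into `esc3` and 5
injected environment-sorted sites):

```
$ radscan run-all --out-dir demo --seed 1 --n-genes 80
simulated 485 sites x 29 accessions
mean H = 0.0061
1 trios x 8 windows
concordant=53 disc(esc3_1,per1_1)=27 disc(esc1_1,per1_1)=0 unresolved=0 skipped=0
introgressed fraction estimate = 0.3375 pair=('esc3_1', 'per1_1')
m=5 of 109 examined; q=0; p=0
69 distinct topologies among 80 trees; rho=0.686
checks: {'env_sites_recovered': True, 'introgression_detected': True}
```

Reading the output: per-accession heterozygosity averages 0.61% of sites;
the trio (esc3_1, esc1_1 | per1_1) shows a discordant-topology excess of
0.3375 — recovering the simulated pulse fraction γ = 0.3 and implicating the
correct pair; the PhyloGWAS scan returns exactly the 5 injected
environment-associated variants (m = 5) among 109 examined nonsynonymous
variants, with a coalescent-null sorting probability q ≈ 0 and dataset
p ≈ 0; and 69 of 80 gene trees are topologically unique with bipartition
support positively rank-correlated with branch length (ρ = 0.69), the ILS
signature. The run directory contains per-stage TSV/JSON reports and a
manifest with the config hash and seeds; reruns with the same seed are
bit-identical.

Each stage is also a standalone subcommand (`simulate`, `diversity`,
`dstat`, `dfoil`, `topo`, `clade-sub`, `phylogwas`, `discordance`) operating
on declared files (VCF / MVF-like TSV matrices, newick tree lists, TSV
metadata and partitions), and everything is importable as a library.

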
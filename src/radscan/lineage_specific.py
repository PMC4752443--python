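"""Unambiguous clade-diagnostic substitution counting and selection summaries.

In a radiation with rampant gene-tree discordance, ancestral-state
reconstruction misplaces substitutions, so lineage-specific changes are
counted conservatively: a site is diagnostic for a target clade only when
the allele set sampled from the clade and the allele set sampled from all
other taxa (outgroup included) are completely nonoverlapping.  Polymorphism
within either side is allowed as long as the two sets stay disjoint.

The likelihood branch-site test itself is external: this module prepares its
inputs (representative codon alignments, monophyly eligibility of the target
branch in each gene tree) and summarises its per-gene p-values; a simple
binomial count test is provided as a built-in fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .variant_core import (
    BASES,
    MISSING,
    GeneModel,
    HaploidMatrix,
    SubstitutionClass,
)

__all__ = [
    "GeneUntestable",
    "RepresentativeSet",
    "CladeSubstitutionRecord",
    "SignificanceSummary",
    "select_representatives",
    "clade_diagnostic_sites",
    "alignment_from_matrix",
    "monophyly_eligibility",
    "significance_summary",
    "binomial_selection_test",
]

_GAPS = set("-N?")


class GeneUntestable(ValueError):
    """A gene failing an eligibility rule (missing species, broken frame)."""


@dataclass
class RepresentativeSet:
    """One accession per ingroup species (max aligned codons) + one outgroup."""

    chosen: dict[str, tuple[str, int]]  # species -> (accession, n_codons)
    outgroup: tuple[str, int]

    @property
    def accessions(self) -> list[str]:
        return [a for a, _ in self.chosen.values()] + [self.outgroup[0]]


@dataclass
class CladeSubstitutionRecord:
    """Per-gene tally of unambiguous clade-diagnostic substitutions."""

    gene_id: str
    target_clade: str
    n_nonsyn: int
    n_syn: int
    sites: list[dict] = field(default_factory=list)


@dataclass
class SignificanceSummary:
    """Positive-selection proportion and its FDR for one target clade.

    FDR = (alpha * n_tested) / n_significant: the expected false positives at
    level alpha over the genes tested, relative to the number called.
    Undefined (None) when nothing is significant.
    """

    target_clade: str
    n_tested: int
    n_significant: int
    alpha: float = 0.01

    @property
    def proportion_significant(self) -> float:
        return self.n_significant / self.n_tested

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.proportion_significant

    @property
    def fdr(self) -> float | None:
        if self.n_significant == 0:
            return None
        return (self.alpha * self.n_tested) / self.n_significant

    @property
    def fdr_pct(self) -> float | None:
        return None if self.fdr is None else 100.0 * self.fdr


def _aligned_codons(seq: str) -> int:
    return sum(
        1
        for i in range(0, len(seq) - 2, 3)
        if not (set(seq[i : i + 3].upper()) & _GAPS)
    )


def select_representatives(
    alignment: dict[str, str],
    species_map: dict[str, str],
    outgroup_species: str,
    exclude: set[str] | None = None,
) -> RepresentativeSet:
    """Pick, per species, the accession with the most aligned codons.

    Ties break to the lexicographically first accession id.  A gene lacking
    any covered accession for some ingroup species (or the outgroup) is
    untestable.  *exclude* drops accessions (e.g. domesticated lines with
    intentional wild-allele introgression) before selection.
    """
    exclude = exclude or set()
    by_species: dict[str, list[tuple[str, int]]] = {}
    for acc, seq in alignment.items():
        if acc in exclude or acc not in species_map:
            continue
        n = _aligned_codons(seq)
        if n > 0:
            by_species.setdefault(species_map[acc], []).append((acc, n))
    species = {sp for a, sp in species_map.items() if a in alignment and a not in exclude}
    chosen: dict[str, tuple[str, int]] = {}
    outgroup: tuple[str, int] | None = None
    for sp in sorted(species):
        cands = by_species.get(sp)
        if not cands:
            if sp == outgroup_species:
                continue
            raise GeneUntestable(f"no covered accession for species {sp!r}")
        best = sorted(cands, key=lambda t: (-t[1], t[0]))[0]
        if sp == outgroup_species:
            outgroup = best
        else:
            chosen[sp] = best
    if outgroup is None:
        raise GeneUntestable("no covered outgroup accession")
    return RepresentativeSet(chosen=chosen, outgroup=outgroup)


def clade_diagnostic_sites(
    alignment: dict[str, str],
    target_clade: set[str],
    species_map: dict[str, str],
    outgroup_accessions: set[str],
    gene_id: str = "gene",
    clade_label: str = "target",
) -> CladeSubstitutionRecord:
    """Count clade-diagnostic substitutions in one haploid codon alignment.

    A site qualifies for consideration only when at least one allele is
    available for each ingroup species and for at least one outgroup
    accession.  It is counted when the target clade's alleles and all other
    taxa's alleles (outgroup pooled with the nontarget side) are completely
    nonoverlapping sets.  Each counted site is classified synonymous or
    nonsynonymous by translating the two codons (nontarget context with the
    target allele substituted); any target/nontarget base pair that changes
    the amino acid makes the site nonsynonymous.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
        raise GeneUntestable(f"broken or ragged codon frame in {gene_id}")
    length = next(iter(lengths))
    accs = list(alignment)
    target = [a for a in accs if a in target_clade]
    nontarget = [a for a in accs if a not in target_clade]
    ingroup_species = {
        species_map[a] for a in accs if a not in outgroup_accessions and a in species_map
    }
    n_nonsyn = n_syn = 0
    sites: list[dict] = []
    for pos in range(length):
        col = {a: alignment[a][pos].upper() for a in accs}
        covered = {a for a, b in col.items() if b not in _GAPS}
        cov_species = {species_map[a] for a in covered if a in species_map and a not in outgroup_accessions}
        if cov_species != ingroup_species or not (covered & outgroup_accessions):
            continue
        t_alleles = {col[a] for a in target if a in covered}
        nt_alleles = {col[a] for a in nontarget if a in covered}
        if not t_alleles or not nt_alleles or (t_alleles & nt_alleles):
            continue
        cls, aa_change = _classify_column(alignment, covered, target, nontarget, pos)
        if cls is None:
            continue
        if cls is SubstitutionClass.NONSYNONYMOUS:
            n_nonsyn += 1
        else:
            n_syn += 1
        sites.append(
            {
                "position": pos,
                "class": cls.value,
                "target_alleles": "".join(sorted(t_alleles)),
                "other_alleles": "".join(sorted(nt_alleles)),
                "aa_change": aa_change,
            }
        )
    return CladeSubstitutionRecord(
        gene_id=gene_id,
        target_clade=clade_label,
        n_nonsyn=n_nonsyn,
        n_syn=n_syn,
        sites=sites,
    )


def _classify_column(alignment, covered, target, nontarget, pos):
    """Synonymous/nonsynonymous call for a diagnostic alignment column."""
    start = (pos // 3) * 3
    within = pos - start
    nt_codons = {
        alignment[a][start : start + 3].upper()
        for a in nontarget
        if a in covered and not (set(alignment[a][start : start + 3].upper()) & _GAPS)
    }
    t_alleles = sorted({alignment[a][pos].upper() for a in target if a in covered})
    if not nt_codons:
        return None, None
    nonsyn_change = None
    for codon in sorted(nt_codons):
        aa_nt = str(Seq(codon).translate())
        for allele in t_alleles:
            swapped = codon[:within] + allele + codon[within + 1 :]
            aa_t = str(Seq(swapped).translate())
            if aa_t != aa_nt:
                nonsyn_change = f"{aa_nt}{pos // 3 + 1}{aa_t}"
    if nonsyn_change is not None:
        return SubstitutionClass.NONSYNONYMOUS, nonsyn_change
    aa = str(Seq(sorted(nt_codons)[0]).translate())
    return SubstitutionClass.SYNONYMOUS, f"{aa}{pos // 3 + 1}{aa}"


def alignment_from_matrix(
    h: HaploidMatrix,
    model: GeneModel,
    cds: str,
    accessions: list[str] | None = None,
) -> dict[str, str]:
    """Reconstruct a per-gene haploid codon alignment from a variant matrix.

    Invariant positions take the reference CDS base; accessions missing at a
    variant site get ``N`` there (only that position is masked).
    """
    accessions = accessions or list(h.accessions)
    length = model.coding_length
    cols = {a: list(cds.upper()) for a in accessions}
    in_gene = (h.chrom == model.chromosome) & np.array(
        [model.cds_index(int(p)) is not None for p in h.pos]
    )
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in np.nonzero(in_gene)[0]:
        idx = model.cds_index(int(h.pos[i]))
        for a in accessions:
            code = h.alleles[i, h.acc_index(a)]
            if code == MISSING:
                cols[a][idx] = "N"
            else:
                base = BASES[code]
                cols[a][idx] = comp[base] if model.strand == "-" else base
    return {a: "".join(c[:length]) for a, c in cols.items()}


def monophyly_eligibility(
    gene_tree: str | dendropy.Tree,
    target_members: set[str],
    outgroup: str | None = None,
) -> tuple[bool, str]:
    """Is the target clade monophyletic in this gene tree?

    The tree is rooted by *outgroup* when given.  Returns (eligible, reason);
    a gene whose tree lacks the ancestral branch of the target group is not
    tested for that group.
    """
    tree = (
        gene_tree
        if isinstance(gene_tree, dendropy.Tree)
        else dendropy.Tree.get(data=gene_tree, schema="newick", preserve_underscores=True)
    )
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = set(target_members) - labels
    if missing:
        return False, f"taxa absent from gene tree: {sorted(missing)}"
    if outgroup is not None:
        if outgroup not in labels:
            return False, f"outgroup {outgroup!r} absent from gene tree"
        og = tree.find_node_with_taxon_label(outgroup)
        tree.reroot_at_edge(og.edge, update_bipartitions=False)
    mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in target_members])
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    if clade == set(target_members):
        return True, "monophyletic"
    return False, f"clade contaminated by {sorted(clade - set(target_members))[:3]}"


def significance_summary(
    pvalues: dict[str, float] | pd.Series,
    alpha: float = 0.01,
    target_clade: str = "target",
) -> SignificanceSummary:
    """Summarise external branch-site test p-values for one target clade."""
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return SignificanceSummary(
        target_clade=target_clade,
        n_tested=int(p.notna().sum()),
        n_significant=int((p < alpha).sum()),
        alpha=alpha,
    )


def binomial_selection_test(
    record: CladeSubstitutionRecord,
    nonsyn_opportunity: float = 0.75,
) -> float:
    """Built-in fallback selection test (not the external branch-site LRT).

    One-sided exact binomial p-value for observing ``n_nonsyn`` of
    ``n_nonsyn + n_syn`` diagnostic substitutions when the per-substitution
    nonsynonymous opportunity fraction is *nonsyn_opportunity* (~3/4 of
    random coding changes are nonsynonymous under the standard code).
    """
    from scipy import stats

    n = record.n_nonsyn + record.n_syn
    if n == 0:
        return math.nan
    return float(
        stats.binomtest(record.n_nonsyn, n, nonsyn_opportunity, alternative="greater").pvalue
    )
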
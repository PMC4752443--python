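"""PhyloGWAS: environment-association scanning with a coalescent null.

Accessions from many species are pooled and scanned for nonsynonymous
variants *perfectly* associated with a binary environmental classification:
at a hit site the two environmental groups carry completely disjoint allele
sets with no missing contrasted accession.  Because incomplete lineage
sorting alone can produce such hemiplasious associations, significance comes
from a multispecies-coalescent null: single-variable-site genes are
simulated over the species phylogeny and the probability q that one variant
sorts perfectly with the partition is estimated; the dataset p-value is the
probability of seeing more than the observed number of hits among the
variants examined.

The scan is only informative for partitions that are incongruent with the
phylogeny (accessions of one species or group on both sides), which
:func:`validate_partition` enforces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .synthetic_data import SimSpeciesTree, partition_congruent_with_clade
from .variant_core import (
    BASES,
    MISSING,
    GeneModel,
    HaploidMatrix,
    SubstitutionClass,
    classify_substitution,
)

__all__ = [
    "EnvPartition",
    "AssociationHit",
    "AssociationScan",
    "NullSimConfig",
    "NullEstimate",
    "validate_partition",
    "scan_perfect_association",
    "estimate_null_probability",
    "simulate_match_pool",
    "dataset_pvalue",
    "linked_synonymous_check",
]


@dataclass(frozen=True)
class EnvPartition:
    """A binary environmental classification of (a subset of) accessions."""

    factor: str
    groups: dict[str, int]  # accession -> 1 or 2
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.groups.values()) - {1, 2}:
            raise ValueError("groups must map accessions to 1 or 2")

    def side(self, which: int) -> frozenset[str]:
        return frozenset(a for a, g in self.groups.items() if g == which)

    @property
    def accessions(self) -> list[str]:
        return list(self.groups)

    def swapped(self) -> "EnvPartition":
        return EnvPartition(
            self.factor, {a: 3 - g for a, g in self.groups.items()}, self.provenance
        )


@dataclass
class AssociationHit:
    gene_id: str
    position: int
    substitution_class: str
    allele_group1: str
    allele_group2: str
    aa_change: str | None = None


@dataclass
class AssociationScan:
    """Result of a perfect-association scan for one environmental factor."""

    factor: str
    n_variants_examined: int
    hits: list[AssociationHit]
    q: float | None = None
    q_se: float | None = None
    p_dataset: float | None = None

    @property
    def m(self) -> int:
        return len(self.hits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": h.gene_id,
                    "position": h.position + 1,  # 1-based for reports
                    "class": h.substitution_class,
                    "allele_group1": h.allele_group1,
                    "allele_group2": h.allele_group2,
                    "aa_change": h.aa_change,
                }
                for h in self.hits
            ],
            columns=["gene", "position", "class", "allele_group1", "allele_group2", "aa_change"],
        )


@dataclass
class NullSimConfig:
    """Coalescent-null configuration: the species tree supplies N_e and
    generations/year; ``n_genes`` single-variable-site genes are simulated."""

    species_tree: SimSpeciesTree
    n_genes: int = 1_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")


@dataclass
class NullEstimate:
    q: float
    se: float
    n_genes: int
    seed: int


# ---------------------------------------------------------------------------


def validate_partition(
    partition: EnvPartition,
    species_map: dict[str, str],
    species_tree: SimSpeciesTree | None = None,
) -> list[str]:
    """Check a partition is usable for association scanning.

    Returns the list of violations (empty = valid): both sides non-empty; at
    least one species with accessions on both sides (phylogenetic
    incongruence); and, when the species tree is given, neither side exactly
    matching a clade's accession set.
    """
    violations: list[str] = []
    unknown = [a for a in partition.accessions if a not in species_map]
    if unknown:
        raise KeyError(f"accessions missing from metadata: {unknown}")
    g1, g2 = partition.side(1), partition.side(2)
    if not g1 or not g2:
        violations.append("both groups must be non-empty")
        return violations
    split_species = {
        sp
        for sp in set(species_map.values())
        if {a for a in g1 if species_map[a] == sp}
        and {a for a in g2 if species_map[a] == sp}
    }
    if not split_species:
        violations.append(
            "no species occurs in both ecological categories (partition is "
            "confounded with phylogeny)"
        )
    if species_tree is not None:
        for side in (g1, g2):
            if partition_congruent_with_clade(species_tree, side):
                violations.append(
                    f"group {sorted(side)} is congruent with a clade of the species tree"
                )
    return violations


def _aa_change(model: GeneModel, cds: str, pos: int, a1: str, a2: str) -> str | None:
    idx = model.cds_index(pos)
    if idx is None:
        return None
    c = idx - model.frame_offset
    start = model.frame_offset + (c // 3) * 3
    within = c % 3
    codon = cds[start : start + 3].upper()
    if len(codon) < 3 or any(b not in "ACGT" for b in codon):
        return None
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if model.strand == "-":
        a1, a2 = comp[a1], comp[a2]
    aa1 = str(Seq(codon[:within] + a1 + codon[within + 1 :]).translate())
    aa2 = str(Seq(codon[:within] + a2 + codon[within + 1 :]).translate())
    return f"{aa1}{c // 3 + 1}{aa2}"


def scan_perfect_association(
    h: HaploidMatrix,
    partition: EnvPartition,
    gene_models: list[GeneModel],
    cds: dict[str, str],
    substitution_class: SubstitutionClass = SubstitutionClass.NONSYNONYMOUS,
) -> AssociationScan:
    """Scan for variants perfectly associated with the partition.

    A site is *examined* when every contrasted accession has data, it is
    biallelic among the contrasted accessions (and across the matrix), and
    its reference->alternate change classifies to the requested class.  It is
    a *hit* when the two groups' allele sets are disjoint.
    """
    idx1 = [h.acc_index(a) for a in sorted(partition.side(1))]
    idx2 = [h.acc_index(a) for a in sorted(partition.side(2))]
    models = sorted(gene_models, key=lambda m: (m.chromosome, m.coding_intervals[0][0]))
    n_alleles_total = np.zeros(h.n_sites, dtype=np.int8)
    for code in range(4):
        n_alleles_total += (h.alleles == code).any(axis=1)
    examined = 0
    hits: list[AssociationHit] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for i in range(h.n_sites):
        a1 = h.alleles[i, idx1]
        a2 = h.alleles[i, idx2]
        if (a1 == MISSING).any() or (a2 == MISSING).any():
            continue
        contrasted = set(a1.tolist()) | set(a2.tolist())
        if len(contrasted) != 2 or n_alleles_total[i] > 2:
            continue  # invariant among contrasted, or multiallelic
        model = _model_at(by_chrom.get(str(h.chrom[i]), []), int(h.pos[i]))
        if model is None:
            continue
        x, y = sorted(contrasted)
        cls = classify_substitution(
            model, cds[model.gene_id], int(h.pos[i]), BASES[x], BASES[y]
        )
        if cls is not substitution_class:
            continue
        examined += 1
        s1, s2 = set(a1.tolist()), set(a2.tolist())
        if s1 & s2:
            continue
        al1 = "".join(sorted(BASES[c] for c in s1))
        al2 = "".join(sorted(BASES[c] for c in s2))
        hits.append(
            AssociationHit(
                gene_id=model.gene_id,
                position=int(h.pos[i]),
                substitution_class=cls.value,
                allele_group1=al1,
                allele_group2=al2,
                aa_change=_aa_change(
                    model, cds[model.gene_id], int(h.pos[i]), al1[0], al2[0]
                ),
            )
        )
    return AssociationScan(
        factor=partition.factor, n_variants_examined=examined, hits=hits
    )


def _model_at(models: list[GeneModel], pos: int) -> GeneModel | None:
    for m in models:
        if any(s <= pos < e for s, e in m.coding_intervals):
            return m
    return None


# ---------------------------------------------------------------------------
# coalescent null
# ---------------------------------------------------------------------------


def _simulate_sorting_matches(
    cfg: NullSimConfig, partition: EnvPartition
) -> np.ndarray:
    """Boolean per simulated gene: does its single variable site sort with
    the partition?

    One haploid lineage is sampled per contrasted accession; each gene's
    genealogy receives one mutation on a branch drawn proportional to branch
    length (so every simulated site is variable among the contrasted
    accessions); a gene matches when the derived-allele carriers equal one
    side of the partition exactly (either polarity).
    """
    tree = cfg.species_tree
    contrasted = [a for a in tree.accession_order if a in partition.groups]
    absent = set(partition.accessions) - set(contrasted)
    if absent:
        raise KeyError(f"partition accessions not in species tree: {sorted(absent)}")
    counts: dict[str, int] = {}
    for acc in contrasted:
        sp = tree.accessions[acc]
        counts[sp] = counts.get(sp, 0) + 1
    # sample order is grouped by species, mirroring the accession order
    ordered = [a for sp in counts for a in contrasted if tree.accessions[a] == sp]
    side1 = frozenset(i for i, a in enumerate(ordered) if partition.groups[a] == 1)
    side2 = frozenset(range(len(ordered))) - side1
    rng = np.random.default_rng(cfg.seed)
    # one haploid lineage per contrasted accession; model ploidy stays 2 so
    # the time scale remains 2*N_e generations per coalescent unit
    reps = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n, population=sp, ploidy=1) for sp, n in counts.items()
        ],
        demography=tree.demography(),
        ploidy=2,
        sequence_length=1,
        num_replicates=cfg.n_genes,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    u = rng.random(cfg.n_genes)
    matches = np.zeros(cfg.n_genes, dtype=bool)
    for g, ts in enumerate(reps):
        t = ts.first()
        nodes, lens = [], []
        for node in t.nodes():
            parent = t.parent(node)
            if parent != -1:
                nodes.append(node)
                lens.append(t.time(parent) - t.time(node))
        lens = np.asarray(lens)
        cum = np.cumsum(lens)
        branch = nodes[int(np.searchsorted(cum, u[g] * cum[-1], side="right"))]
        carriers = frozenset(int(x) for x in t.leaves(branch))
        matches[g] = carriers == side1 or carriers == side2
    return matches


def estimate_null_probability(
    cfg: NullSimConfig, partition: EnvPartition
) -> NullEstimate:
    """Monte-Carlo estimate of q, the per-variant perfect-sorting probability.

    q is the fraction of simulated single-variable-site genes whose
    derived-allele carrier set matches the partition (either polarity), with
    its binomial standard error.  Invariant under swapping the group labels.
    """
    matches = _simulate_sorting_matches(cfg, partition)
    m = int(cfg.n_genes)
    q = float(matches.mean())
    se = math.sqrt(max(q * (1 - q), 1e-300) / m)
    return NullEstimate(q=q, se=se, n_genes=m, seed=cfg.seed)


def simulate_match_pool(
    cfg: NullSimConfig, partition: EnvPartition
) -> np.ndarray:
    """Freshly simulated pool of per-gene sorting outcomes (for resimulation)."""
    return _simulate_sorting_matches(cfg, partition)


def dataset_pvalue(
    m: int,
    n_variants_examined: int,
    q: float | None = None,
    method: str = "binomial",
    pool: np.ndarray | None = None,
    n_datasets: int = 10_000,
    seed: int = 0,
    strict: bool = False,
) -> float:
    """Dataset-level p-value: chance of at least *m* perfect associations.

    ``binomial``: p = P[Binomial(n, q) >= m], the standard Monte-Carlo
    exceedance p-value (so m = 0 gives p = 1); ``strict=True`` uses the
    strictly-greater reading instead.  ``resimulation``: *n_datasets*
    datasets of ``n_variants_examined`` genes are drawn with replacement from
    a simulated pool of per-gene sorting outcomes and the exceedance
    proportion is returned; the two methods agree within Monte-Carlo error
    under per-gene independence.
    """
    if method == "binomial":
        if q is None:
            raise ValueError("binomial method requires q")
        if not 0 <= q <= 1:
            raise ValueError("q must be in [0, 1]")
        k = m if strict else m - 1
        return float(stats.binom.sf(k, n_variants_examined, q))
    if method == "resimulation":
        if pool is None:
            raise ValueError("resimulation requires a simulated pool")
        rng = np.random.default_rng(seed)
        counts = np.empty(n_datasets, dtype=np.int64)
        for r in range(n_datasets):
            counts[r] = pool[
                rng.integers(0, len(pool), size=n_variants_examined)
            ].sum()
        exceed = (counts > m) if strict else (counts >= m)
        return float(exceed.mean())
    raise ValueError(f"unknown method {method!r}")


def linked_synonymous_check(
    scan: AssociationScan,
    h: HaploidMatrix,
    partition: EnvPartition,
    gene_models: list[GeneModel],
    cds: dict[str, str],
) -> pd.DataFrame:
    """Count associated synonymous variants in each hit gene.

    Selection on standing single-site variation predicts isolated
    nonsynonymous hits; introgression of a haplotype block predicts linked
    synonymous variants tracking the same partition.  Genes with >= 1
    associated synonymous site are flagged introgression-ambiguous.
    """
    syn_scan = scan_perfect_association(
        h, partition, gene_models, cds, substitution_class=SubstitutionClass.SYNONYMOUS
    )
    syn_by_gene: dict[str, int] = {}
    for hit in syn_scan.hits:
        syn_by_gene[hit.gene_id] = syn_by_gene.get(hit.gene_id, 0) + 1
    genes = sorted({hit.gene_id for hit in scan.hits})
    return pd.DataFrame(
        {
            "gene": genes,
            "n_assoc_synonymous": [syn_by_gene.get(g, 0) for g in genes],
            "introgression_ambiguous": [syn_by_gene.get(g, 0) >= 1 for g in genes],
        }
    )
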
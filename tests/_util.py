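"""Hand-built fixtures and small independent oracles shared across tests."""

from __future__ import annotations

import numpy as np

from radscan.variant_core import BASE_TO_CODE, MISSING, HaploidMatrix, VariantMatrix

# In pattern strings, 'A' is the ancestral base (A) and 'B' the derived (G).
_PATTERN_BASE = {"A": BASE_TO_CODE["A"], "B": BASE_TO_CODE["G"], ".": MISSING}


def haploid_from_patterns(accessions: list[str], patterns: list[str]) -> HaploidMatrix:
    """One row per site; each pattern string has one A/B/. per accession."""
    alleles = np.array(
        [[_PATTERN_BASE[c] for c in row] for row in patterns], dtype=np.int8
    )
    n = len(patterns)
    return HaploidMatrix(
        accessions=list(accessions),
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(n, dtype=np.int64),
        ref=np.zeros(n, dtype=np.int8),
        alleles=alleles,
    )


def variant_from_pairs(
    accessions: list[str],
    rows: list[list[str]],
    chrom: str = "chr1",
    depth: int | np.ndarray = 30,
    mq: int | np.ndarray = 60,
) -> VariantMatrix:
    """rows[i][j] is a two-letter genotype like 'AG', or '..' for missing."""
    n, k = len(rows), len(accessions)
    geno = np.full((n, k, 2), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j, g in enumerate(row):
            if g != "..":
                geno[i, j] = (BASE_TO_CODE[g[0]], BASE_TO_CODE[g[1]])
    depth = np.full((n, k), depth, dtype=np.int32) if np.isscalar(depth) else depth
    mq = np.full((n, k), mq, dtype=np.int32) if np.isscalar(mq) else mq
    return VariantMatrix(
        accessions=list(accessions),
        chrom=np.array([chrom] * n, dtype=object),
        pos=np.arange(n, dtype=np.int64),
        ref=np.zeros(n, dtype=np.int8),
        geno=geno,
        depth=depth,
        mq=mq,
    )


def msc_trio_discordance(t_coal: float) -> float:
    """Analytic MSC: P(discordant gene-tree topology) for a 3-taxon species
    tree with an internal branch of *t_coal* coalescent units."""
    return (2.0 / 3.0) * np.exp(-t_coal)


class BruteForceMSC:
    """Minimal structured-coalescent simulator, independent of msprime.

    Simulates one haploid lineage per species over an arbitrary ultrametric
    species tree given as nested tuples ``(label, age_coal_units, children)``
    (ages in coalescent units of 2N_e generations; leaves have age 0), then
    drops a single mutation on a branch chosen proportional to branch length
    and reports the derived-allele carrier set.  Used as the oracle for the
    coalescent-null sorting probability.
    """

    def __init__(self, tree, rng: np.random.Generator):
        self.tree = tree
        self.rng = rng

    def _sim_node(self, node):
        """Returns list of (lineage_set, birth_time) active at node's age."""
        label, age, children = node
        if not children:
            return [(frozenset([label]), 0.0)], age
        active = []
        for ch in children:
            lins, _ = self._sim_node(ch)
            ch_age = ch[1]
            lins = self._coalesce(lins, ch_age, age)
            active.extend(lins)
        return active, age

    def _coalesce(self, lineages, t_from, t_to):
        lineages = list(lineages)
        t = t_from
        while len(lineages) > 1:
            k = len(lineages)
            wait = self.rng.exponential(1.0 / (k * (k - 1) / 2.0))
            if t + wait >= t_to:
                return lineages
            t += wait
            i, j = self.rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            merged = (a[0] | b[0], t)
            self._events.append((a[0], a[1], t))
            self._events.append((b[0], b[1], t))
            lineages = [l for r, l in enumerate(lineages) if r not in (i, j)]
            lineages.append(merged)
        return lineages

    def one_gene_carriers(self) -> frozenset[str]:
        """Simulate one genealogy + one branch-proportional mutation."""
        self._events = []  # (carrier_set, birth, death) closed branches
        active, root_age = self._sim_node(self.tree)
        # continue in the root population until full coalescence
        t = root_age
        lineages = list(active)
        while len(lineages) > 1:
            k = len(lineages)
            t += self.rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = self.rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            self._events.append((a[0], a[1], t))
            self._events.append((b[0], b[1], t))
            lineages = [l for r, l in enumerate(lineages) if r not in (i, j)]
            lineages.append((a[0] | b[0], t))
        branches = [(c, death - birth) for c, birth, death in self._events]
        total = sum(l for _, l in branches)
        u = self.rng.random() * total
        acc = 0.0
        for carriers, length in branches:
            acc += length
            if u <= acc:
                return carriers
        return branches[-1][0]

    def sorting_probability(self, side1: set[str], side2: set[str], n: int) -> tuple[float, float]:
        s1, s2 = frozenset(side1), frozenset(side2)
        hits = 0
        for _ in range(n):
            carriers = self.one_gene_carriers()
            restricted = carriers & (s1 | s2)
            if restricted == s1 or restricted == s2:
                hits += 1
        q = hits / n
        se = np.sqrt(max(q * (1 - q), 1e-12) / n)
        return q, se
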
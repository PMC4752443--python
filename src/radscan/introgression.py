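"""Introgression detection: ABBA-BABA D-statistics over genomic windows,
block bootstrap, five-taxon D_FOIL direction tests, gene-tree topology
counting, and the clade-wide per-branch summary.

The D-statistic for an ordered trio (P1, P2 sisters relative to P3) plus an
outgroup O is D = (nABBA - nBABA) / (nABBA + nBABA), where ABBA and BABA are
the two discordant biallelic site patterns polarized by the outgroup.  Under
incomplete lineage sorting alone the two patterns are equally likely and
D = 0; an excess of one pattern indicates gene flow between P3 and one of
the sister taxa.  The D_FOIL system extends this to a symmetric five-taxon
tree ((P1,P2),(P3,P4),O): four D-like statistics whose joint sign signature
identifies the donor and recipient of the flow.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .variant_core import MISSING, GenomeWindow, HaploidMatrix

__all__ = [
    "TrioAssignment",
    "TrioPatternCounts",
    "BootstrapResult",
    "DfoilResult",
    "TopologyCountResult",
    "IntrogressionFractionEstimate",
    "CladewideSummary",
    "enumerate_trios",
    "count_patterns",
    "d_statistic",
    "windowed_d",
    "bootstrap_d",
    "dfoil",
    "DFOIL_PATTERNS",
    "DFOIL_SIGNATURES",
    "count_topologies",
    "introgressed_fraction",
    "cladewide_summary",
]


# ---------------------------------------------------------------------------
# trio enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrioAssignment:
    """An ordered trio: P1 and P2 are sisters relative to P3 on the species tree."""

    p1: str
    p2: str
    p3: str
    outgroup: str


class _CladeIndex:
    """Pairwise smallest-clade lookup on a rooted tree (for trio roles)."""

    def __init__(self, tree: dendropy.Tree):
        self._clades: list[frozenset[str]] = []
        for node in tree.preorder_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(leaves) > 1:
                self._clades.append(leaves)
        self.taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())

    def mrca_clade(self, a: str, b: str) -> frozenset[str]:
        best = None
        for clade in self._clades:
            if a in clade and b in clade and (best is None or len(clade) < len(best)):
                best = clade
        if best is None:
            raise KeyError(f"accessions {a!r}/{b!r} absent from tree")
        return best


def enumerate_trios(
    ingroup: list[str],
    species_tree: dendropy.Tree,
    outgroup: str,
) -> list[TrioAssignment]:
    """All C(n, 3) trios of *ingroup* with roles fixed by the species tree.

    For each unordered 3-subset {a, b, c} the sister pair is the pair whose
    most recent common ancestor excludes the third member; the excluded
    member becomes P3.  Raises if an accession is absent or a trio is not
    resolved by the tree.
    """
    index = _CladeIndex(species_tree)
    for acc in ingroup:
        if acc not in index.taxa:
            raise KeyError(f"accession {acc!r} absent from species tree")
    trios = []
    for a, b, c in itertools.combinations(sorted(ingroup), 3):
        assignment = None
        for p1, p2, p3 in ((a, b, c), (a, c, b), (b, c, a)):
            if p3 not in index.mrca_clade(p1, p2):
                assignment = TrioAssignment(p1, p2, p3, outgroup)
                break
        if assignment is None:
            raise ValueError(f"species tree does not resolve trio {(a, b, c)}")
        trios.append(assignment)
    return trios


# ---------------------------------------------------------------------------
# pattern counting and D
# ---------------------------------------------------------------------------


@dataclass
class TrioPatternCounts:
    """ABBA/BABA counts for one trio over one region."""

    trio: TrioAssignment
    region: str
    n_abba: int
    n_baba: int

    @property
    def n_informative(self) -> int:
        return self.n_abba + self.n_baba

    @property
    def d(self) -> float:
        if self.n_informative == 0:
            return math.nan
        return (self.n_abba - self.n_baba) / self.n_informative


def _region_mask(h: HaploidMatrix, region) -> np.ndarray:
    if region is None:
        return np.ones(h.n_sites, dtype=bool)
    if isinstance(region, GenomeWindow):
        c, s, e = region.chromosome, region.start, region.end
    else:
        c, s, e = region
    return (h.chrom == c) & (h.pos >= s) & (h.pos < e)


def count_patterns(
    h: HaploidMatrix,
    trio: TrioAssignment,
    region=None,
) -> TrioPatternCounts:
    """Count ABBA and BABA site patterns for a trio + outgroup.

    Only sites where all four taxa have data, at most two alleles are present
    across *all* accessions, and the outgroup carries a single (ancestral)
    allele are counted.  ABBA = (P1=A, P2=B, P3=B, O=A); BABA = (P1=B, P2=A,
    P3=B, O=A); every other pattern is ignored.
    """
    idx = [h.acc_index(x) for x in (trio.p1, trio.p2, trio.p3, trio.outgroup)]
    sub = h.alleles[:, idx]
    mask = _region_mask(h, region) & (sub != MISSING).all(axis=1)
    biallelic = _n_alleles_total(h) <= 2
    mask &= biallelic
    sub = sub[mask]
    anc = sub[:, 3]
    b = sub[:, :3] != anc[:, None]
    abba = int((~b[:, 0] & b[:, 1] & b[:, 2]).sum())
    baba = int((b[:, 0] & ~b[:, 1] & b[:, 2]).sum())
    label = _region_label(region)
    return TrioPatternCounts(trio=trio, region=label, n_abba=abba, n_baba=baba)


def _region_label(region) -> str:
    if region is None:
        return "all"
    if isinstance(region, GenomeWindow):
        return f"{region.chromosome}:{region.start + 1}-{region.end}"
    c, s, e = region
    return f"{c}:{s + 1}-{e}"


def _n_alleles_total(h: HaploidMatrix) -> np.ndarray:
    out = np.zeros(h.n_sites, dtype=np.int8)
    for code in range(4):
        out += (h.alleles == code).any(axis=1)
    return out


def d_statistic(counts: TrioPatternCounts, method: str = "binomial") -> tuple[float, float]:
    """D and its two-sided significance for one set of pattern counts.

    The default test is an exact binomial test of nABBA successes in
    nABBA + nBABA trials against 0.5 (the ILS-only expectation); a chi-square
    goodness-of-fit alternative is available with ``method="chi2"``.  With no
    informative sites both values are NaN (undefined, not 0).
    """
    n = counts.n_informative
    if n == 0:
        return math.nan, math.nan
    if method == "binomial":
        p = stats.binomtest(counts.n_abba, n, 0.5).pvalue
    elif method == "chi2":
        p = float(stats.chisquare([counts.n_abba, counts.n_baba]).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return counts.d, float(p)


def windowed_d(
    h: HaploidMatrix,
    trios: list[TrioAssignment],
    windows: list[GenomeWindow],
    method: str = "binomial",
    include_excluded: bool = False,
) -> pd.DataFrame:
    """Long-format per-window, per-trio D table.

    Columns: trio (P1,P2,P3 joined), window, n_abba, n_baba, D, p.  Windows
    flagged excluded (too few aligned sites) are skipped unless requested.
    """
    rows = []
    for w in windows:
        if w.excluded and not include_excluded:
            continue
        for trio in trios:
            c = count_patterns(h, trio, region=w)
            d, p = d_statistic(c, method=method)
            rows.append(
                {
                    "trio": f"{trio.p1},{trio.p2},{trio.p3}",
                    "window": c.region,
                    "n_abba": c.n_abba,
                    "n_baba": c.n_baba,
                    "D": d,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["trio", "window", "n_abba", "n_baba", "D", "p"])


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    n_replicates: int
    d_point: float
    ci_low: float
    ci_high: float
    excludes_zero: bool
    n_windows: int


def bootstrap_d(
    window_counts: list[TrioPatternCounts],
    n_replicates: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Block bootstrap of the pooled D over windows.

    Windows are resampled with replacement; each replicate's D is recomputed
    from the pooled ABBA/BABA counts of the resampled windows.  The 95% CI is
    the percentile interval of the replicate distribution, and the flag
    reports whether it excludes D = 0.
    """
    abba = np.array([c.n_abba for c in window_counts], dtype=np.int64)
    baba = np.array([c.n_baba for c in window_counts], dtype=np.int64)
    if (abba + baba).sum() == 0:
        raise ValueError("no informative sites in any window")
    w = len(window_counts)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_replicates)
    chunk = max(1, min(n_replicates, 50_000_000 // max(w, 1) // 8))
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        idx = rng.integers(0, w, size=(m, w))
        a = abba[idx].sum(axis=1)
        b = baba[idx].sum(axis=1)
        tot = a + b
        with np.errstate(invalid="ignore"):
            reps[done : done + m] = np.where(tot > 0, (a - b) / np.maximum(tot, 1), np.nan)
        done += m
    d_point = (abba.sum() - baba.sum()) / (abba.sum() + baba.sum())
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return BootstrapResult(
        n_replicates=n_replicates,
        d_point=float(d_point),
        ci_low=float(lo),
        ci_high=float(hi),
        excludes_zero=bool(lo > 0 or hi < 0),
        n_windows=w,
    )


# ---------------------------------------------------------------------------
# D_FOIL
# ---------------------------------------------------------------------------

# Site-pattern memberships of the four statistics.  Patterns are written over
# (P1, P2, P3, P4) with the outgroup ancestral ('A'); each statistic is
# (sum(left) - sum(right)) / (sum(left) + sum(right)).  Left/right sets are
# images of each other under the exchange symmetry the statistic tests
# (P3<->P4 for DFO/DIL, P1<->P2 for DFI/DOL), so all four have expectation 0
# under ILS alone.
DFOIL_PATTERNS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "DFO": (("BABA", "BBBA", "ABAB", "AAAB"), ("BAAB", "BBAB", "ABBA", "AABA")),
    "DIL": (("ABBA", "BBBA", "BAAB", "AAAB"), ("ABAB", "BBAB", "BABA", "AABA")),
    "DFI": (("BABA", "BABB", "ABAB", "ABAA"), ("ABBA", "ABBB", "BAAB", "BAAA")),
    "DOL": (("BAAB", "BABB", "ABBA", "ABAA"), ("ABAB", "ABBB", "BABA", "BAAA")),
}

# Joint sign signatures (DFO, DIL, DFI, DOL) -> (donor, recipient); 0 means
# "not significantly different from zero".  The zero falls in the DFO/DIL
# pair when the recipient is P1 or P2 and in the DFI/DOL pair when the
# recipient is P3 or P4 (the recipient's captured lineage cancels that
# statistic's gains and losses); ancestral events (gene flow between the
# P1P2 ancestor and P3 or P4, in either direction) zero both DFI and DOL and
# are direction-ambiguous.  The table is validated by the directed-pulse
# simulation tests and respects both exchange symmetries (P1<->P2 swaps
# DFO<->DIL and negates DFI/DOL; P3<->P4 negates DFO/DIL and swaps
# DFI<->DOL).
DFOIL_SIGNATURES: dict[tuple[int, int, int, int], tuple[str, str]] = {
    (1, 0, 1, 1): ("P3", "P1"),
    (1, 1, 1, 0): ("P1", "P3"),
    (-1, 0, 1, 1): ("P4", "P1"),
    (-1, -1, 0, 1): ("P1", "P4"),
    (0, 1, -1, -1): ("P3", "P2"),
    (1, 1, -1, 0): ("P2", "P3"),
    (0, -1, -1, -1): ("P4", "P2"),
    (-1, -1, 0, -1): ("P2", "P4"),
    (1, 1, 0, 0): ("ancestral(P1,P2)", "P3"),
    (-1, -1, 0, 0): ("ancestral(P1,P2)", "P4"),
}


@dataclass
class DfoilResult:
    """Per-window D_FOIL statistics and the inferred direction category."""

    quintet: tuple[str, str, str, str, str]
    table: pd.DataFrame
    alpha: float


def _check_symmetric_quintet(
    tree: dendropy.Tree, p1: str, p2: str, p3: str, p4: str
) -> None:
    index = _CladeIndex(tree)
    first = index.mrca_clade(p1, p2)
    second = index.mrca_clade(p3, p4)
    if first & {p3, p4} or second & {p1, p2}:
        raise ValueError(
            "quintet is not the symmetric topology ((P1,P2),(P3,P4)) on the species tree"
        )


def dfoil(
    h: HaploidMatrix,
    quintet: tuple[str, str, str, str, str],
    windows: list[GenomeWindow] | None = None,
    alpha: float = 0.001,
    species_tree: dendropy.Tree | None = None,
    include_excluded: bool = False,
) -> DfoilResult:
    """Windowed D_FOIL scan on a symmetric five-taxon tree.

    For each window the biallelic site patterns over (P1, P2, P3, P4),
    polarized by the outgroup, are tallied and the four statistics computed
    with an exact binomial test each.  A component's sign is scored +1/-1
    only when its p-value is below *alpha*, otherwise 0; the joint signature
    is matched against the canonical donor->recipient table.  Passing the
    species tree enables the symmetric-topology precondition check.
    """
    p1, p2, p3, p4, og = quintet
    if species_tree is not None:
        _check_symmetric_quintet(species_tree, p1, p2, p3, p4)
    idx = [h.acc_index(x) for x in quintet]
    sub_all = h.alleles[:, idx]
    base_mask = (sub_all != MISSING).all(axis=1) & (_n_alleles_total(h) <= 2)
    regions = windows if windows is not None else [None]
    rows = []
    for w in regions:
        if isinstance(w, GenomeWindow) and w.excluded and not include_excluded:
            continue
        mask = base_mask & _region_mask(h, w)
        sub = sub_all[mask]
        anc = sub[:, 4]
        derived = sub[:, :4] != anc[:, None]
        counts: dict[str, int] = {}
        for key, n in zip(*np.unique(derived, axis=0, return_counts=True)):
            pattern = "".join("B" if x else "A" for x in key)
            counts[pattern] = int(n)
        row: dict = {"window": _region_label(w), "n_sites": int(mask.sum())}
        signs = []
        for name, (left, right) in DFOIL_PATTERNS.items():
            nl = sum(counts.get(p, 0) for p in left)
            nr = sum(counts.get(p, 0) for p in right)
            tot = nl + nr
            if tot == 0:
                stat, p = 0.0, 1.0
            else:
                stat = (nl - nr) / tot
                p = stats.binomtest(nl, tot, 0.5).pvalue
            row[name] = stat
            row[f"p_{name}"] = float(p)
            signs.append(0 if p >= alpha else (1 if stat > 0 else -1))
        donor, recipient = DFOIL_SIGNATURES.get(tuple(signs), (None, None))
        role = {"P1": p1, "P2": p2, "P3": p3, "P4": p4}
        row["signature"] = "".join({1: "+", -1: "-", 0: "0"}[s] for s in signs)
        row["donor"] = role.get(donor, donor)
        row["recipient"] = role.get(recipient, recipient)
        row["introgression"] = donor is not None
        rows.append(row)
    cols = ["window", "n_sites"]
    for name in DFOIL_PATTERNS:
        cols += [name, f"p_{name}"]
    cols += ["signature", "donor", "recipient", "introgression"]
    return DfoilResult(quintet=quintet, table=pd.DataFrame(rows, columns=cols), alpha=alpha)


# ---------------------------------------------------------------------------
# gene-tree topology counting
# ---------------------------------------------------------------------------


@dataclass
class TopologyCountResult:
    """Rooted-triplet topology tallies for (trio + outgroup) gene trees."""

    trio: TrioAssignment
    n_concordant: int  # (P1,P2) sister — the species-tree topology
    n_disc_p1p3: int
    n_disc_p2p3: int
    n_unresolved: int = 0
    n_skipped: int = 0

    @property
    def n_resolved(self) -> int:
        return self.n_concordant + self.n_disc_p1p3 + self.n_disc_p2p3

    @property
    def proportions(self) -> tuple[float, float, float]:
        n = self.n_resolved
        if n == 0:
            return (math.nan,) * 3
        return (self.n_concordant / n, self.n_disc_p1p3 / n, self.n_disc_p2p3 / n)


def _triplet_class(tree: dendropy.Tree, trio: TrioAssignment) -> str | None:
    """Classify one gene tree by its rooted triplet; None when unresolved."""
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    four = {trio.p1, trio.p2, trio.p3, trio.outgroup}
    if not four.issubset(labels):
        raise KeyError("missing taxon")
    og = tree.find_node_with_taxon_label(trio.outgroup)
    tree.reroot_at_edge(og.edge, update_bipartitions=False)
    index = _CladeIndex(tree)
    pairs = {
        "concordant": (trio.p1, trio.p2),
        "disc_p1p3": (trio.p1, trio.p3),
        "disc_p2p3": (trio.p2, trio.p3),
    }
    third = {"concordant": trio.p3, "disc_p1p3": trio.p2, "disc_p2p3": trio.p1}
    for cls, (a, b) in pairs.items():
        clade = index.mrca_clade(a, b)
        if third[cls] not in clade and trio.outgroup not in clade:
            return cls
    return None


def count_topologies(
    gene_trees: list[str],
    trio: TrioAssignment,
) -> TopologyCountResult:
    """Classify rooted gene trees into the three possible triplet topologies.

    Trees are rooted by the outgroup and reduced to the trio; trees missing a
    taxon are skipped (tallied), unresolved triplets are excluded and
    reported.
    """
    res = TopologyCountResult(trio, 0, 0, 0)
    for nwk in gene_trees:
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        try:
            cls = _triplet_class(tree, trio)
        except KeyError:
            res.n_skipped += 1
            continue
        if cls is None:
            res.n_unresolved += 1
        elif cls == "concordant":
            res.n_concordant += 1
        elif cls == "disc_p1p3":
            res.n_disc_p1p3 += 1
        else:
            res.n_disc_p2p3 += 1
    return res


@dataclass
class IntrogressionFractionEstimate:
    """|p(disc1) - p(disc2)|: the excess of one discordant class over the other."""

    estimate: float
    implicated_pair: tuple[str, str] | None


def introgressed_fraction(t: TopologyCountResult) -> IntrogressionFractionEstimate:
    """Estimate the introgressed gene fraction from discordant-tree imbalance.

    Under ILS alone the two discordant triplet classes are equally frequent;
    introgression inflates the class joining the exchanging pair, so the
    difference of the two discordant proportions estimates the introgressed
    fraction.
    """
    if t.n_resolved == 0:
        raise ValueError("no resolved gene trees")
    _, d1, d2 = t.proportions
    pair = None
    if d1 > d2:
        pair = (t.trio.p1, t.trio.p3)
    elif d2 > d1:
        pair = (t.trio.p2, t.trio.p3)
    return IntrogressionFractionEstimate(estimate=abs(d1 - d2), implicated_pair=pair)


# ---------------------------------------------------------------------------
# clade-wide summary
# ---------------------------------------------------------------------------


@dataclass
class CladewideSummary:
    """Clade-wide windowed-introgression tallies at fixed thresholds."""

    n_windows: int
    n_significant_windows: int
    n_branches: int
    d_min: float = 0.2
    p_max: float = 1e-4
    min_pattern_diff: int = 10

    @property
    def fraction_any(self) -> float:
        return self.n_significant_windows / self.n_windows

    @property
    def per_branch_fraction(self) -> float:
        return self.n_significant_windows / (self.n_windows * self.n_branches)

    @property
    def pct_any(self) -> float:
        return 100.0 * self.fraction_any

    @property
    def pct_per_branch(self) -> float:
        return 100.0 * self.per_branch_fraction


def cladewide_summary(
    windowed: pd.DataFrame | None = None,
    *,
    n_branches: int,
    n_windows: int | None = None,
    n_significant: int | None = None,
    d_min: float = 0.2,
    p_max: float = 1e-4,
    min_pattern_diff: int = 10,
    exclude_trios_with: set[str] | None = None,
) -> CladewideSummary:
    """Summarise windowed trio D results clade-wide.

    Either pass the long-format table from :func:`windowed_d` (a window is
    significant when >= 1 trio meets |D| >= d_min, p < p_max and
    |ABBA - BABA| >= min_pattern_diff), or pass bare counts directly.
    ``exclude_trios_with`` drops trios containing any named accession
    (e.g. known admixed taxa) before summarising.
    """
    if windowed is not None:
        df = windowed
        if exclude_trios_with:
            keep = ~df["trio"].map(
                lambda t: bool(set(t.split(",")) & exclude_trios_with)
            )
            df = df[keep]
        sig = (
            (df["D"].abs() >= d_min)
            & (df["p"] < p_max)
            & ((df["n_abba"] - df["n_baba"]).abs() >= min_pattern_diff)
        )
        n_significant = int(df.loc[sig, "window"].nunique())
        if n_windows is None:
            n_windows = int(df["window"].nunique())
    if n_windows is None or n_significant is None:
        raise ValueError("need a windowed table or explicit counts")
    return CladewideSummary(
        n_windows=n_windows,
        n_significant_windows=n_significant,
        n_branches=n_branches,
        d_min=d_min,
        p_max=p_max,
        min_pattern_diff=min_pattern_diff,
    )
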
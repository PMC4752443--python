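import math

import dendropy
import numpy as np
import pytest

from _util import haploid_from_patterns
from radscan import introgression as intro
from radscan import synthetic_data as sd
from radscan.variant_core import GenomeWindow, partition_windows, resolve_heterozygotes


# ---------------------------------------------------------------------------
# trio enumeration
# ---------------------------------------------------------------------------


def _tree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)


def test_three_accessions_give_one_resolved_trio():
    t = _tree("((a,b),(c,o));")
    (trio,) = intro.enumerate_trios(["a", "b", "c"], t, "o")
    assert {trio.p1, trio.p2} == {"a", "b"} and trio.p3 == "c"


def test_five_accessions_give_ten_trios():
    t = _tree("((((a,b),c),(d,e)),o);")
    trios = intro.enumerate_trios(list("abcde"), t, "o")
    assert len(trios) == 10


def test_27_ingroup_accessions_give_2925_trios(default_tree):
    at = default_tree.accession_tree()
    trios = intro.enumerate_trios(
        default_tree.ingroup_accessions, at, default_tree.outgroup_accessions[0]
    )
    assert len(trios) == 2925


def test_unknown_accession_is_an_error():
    t = _tree("((a,b),(c,o));")
    with pytest.raises(KeyError):
        intro.enumerate_trios(["a", "b", "zz"], t, "o")


# ---------------------------------------------------------------------------
# pattern counting and D
# ---------------------------------------------------------------------------

QUARTET = ["p1", "p2", "p3", "o"]
TRIO = intro.TrioAssignment("p1", "p2", "p3", "o")


def test_toy_pattern_counts():
    h = haploid_from_patterns(QUARTET, ["ABBA", "ABBA", "BABA", "BBBA", "AABA"])
    c = intro.count_patterns(h, TRIO)
    assert (c.n_abba, c.n_baba) == (2, 1)


def test_site_missing_in_outgroup_is_excluded():
    h = haploid_from_patterns(QUARTET, ["ABB.", "ABBA"])
    c = intro.count_patterns(h, TRIO)
    assert (c.n_abba, c.n_baba) == (1, 0)


def test_multiallelic_sites_are_excluded():
    import numpy as np
    h = haploid_from_patterns(QUARTET, ["ABBA", "ABBA"])
    h.alleles[0, 0] = 3  # third allele at site 0 across accessions
    c = intro.count_patterns(h, TRIO)
    assert (c.n_abba, c.n_baba) == (1, 0)


@pytest.mark.parametrize(
    "abba,baba,d", [(30, 10, 0.5), (15, 15, 0.0)]
)
def test_d_statistic_values(abba, baba, d):
    c = intro.TrioPatternCounts(TRIO, "all", abba, baba)
    dd, p = intro.d_statistic(c)
    assert dd == pytest.approx(d)
    assert 0 <= p <= 1


def test_d_undefined_with_no_informative_sites():
    c = intro.TrioPatternCounts(TRIO, "all", 0, 0)
    d, p = intro.d_statistic(c)
    assert math.isnan(d) and math.isnan(p)


def test_swapping_p1_p2_negates_d():
    rng = np.random.default_rng(0)
    pats = rng.choice(["ABBA", "BABA", "AABA", "BBBA"], size=200)
    h = haploid_from_patterns(QUARTET, list(pats))
    swapped = intro.TrioAssignment("p2", "p1", "p3", "o")
    d1 = intro.count_patterns(h, TRIO).d
    d2 = intro.count_patterns(h, swapped).d
    assert d1 == pytest.approx(-d2)


def test_pure_ils_has_balanced_patterns(three_species_tree):
    gts = sd.simulate_gene_trees(three_species_tree, 3000, seed=17, lineages_per_accession=2)
    m, _, _ = sd.simulate_variants(gts, 4, seed=18)
    h = resolve_heterozygotes(m, seed=1)
    trio = intro.TrioAssignment("A_1", "B_1", "C_1", "O_1")
    c = intro.count_patterns(h, trio)
    _, p = intro.d_statistic(c)
    assert c.n_informative > 50
    assert p > 0.01


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------


def test_identical_windows_give_degenerate_ci():
    counts = [intro.TrioPatternCounts(TRIO, str(i), 13, 7) for i in range(30)]
    bs = intro.bootstrap_d(counts, n_replicates=500, seed=1)
    assert bs.ci_low == bs.ci_high == pytest.approx(0.3)


def test_single_window_ci_is_degenerate():
    counts = [intro.TrioPatternCounts(TRIO, "w", 12, 4)]
    bs = intro.bootstrap_d(counts, n_replicates=200, seed=1)
    assert bs.ci_low == bs.ci_high == pytest.approx(0.5)


def test_bootstrap_ci_covers_zero_under_null():
    # coverage experiment on exact binomial nulls: ABBA ~ Bin(n, 1/2)
    rng = np.random.default_rng(12)
    covered = 0
    for run in range(20):
        counts = []
        for w in range(40):
            n = 20
            a = rng.binomial(n, 0.5)
            counts.append(intro.TrioPatternCounts(TRIO, str(w), int(a), int(n - a)))
        bs = intro.bootstrap_d(counts, n_replicates=2_000, seed=run)
        covered += not bs.excludes_zero
    assert covered >= 17


def test_all_empty_windows_is_an_error():
    counts = [intro.TrioPatternCounts(TRIO, "w", 0, 0)]
    with pytest.raises(ValueError):
        intro.bootstrap_d(counts)


# ---------------------------------------------------------------------------
# D_FOIL
# ---------------------------------------------------------------------------

QUINTET = ("p1", "p2", "p3", "p4", "o")
FIVE = list(QUINTET)


def test_concordant_sites_give_all_zero_statistics():
    # patterns concordant with ((P1,P2),(P3,P4)): BBAA / AABB and singleton-free
    h = haploid_from_patterns(FIVE, ["BBAAA"] * 30 + ["AABBA"] * 30)
    res = intro.dfoil(h, QUINTET)
    row = res.table.iloc[0]
    for name in intro.DFOIL_PATTERNS:
        assert row[name] == 0.0
    assert not row["introgression"]


def test_dfoil_statistics_negate_under_their_exchange_symmetry():
    rng = np.random.default_rng(4)
    pats = rng.choice(
        ["BABAA", "BAABA", "ABBAA", "ABABA", "BBBAA", "BBABA", "AABAA", "AAABA",
         "BABBA", "ABBBA", "BAAAA", "ABAAA"],
        size=400,
    )
    h = haploid_from_patterns(FIVE, list(pats))
    base = intro.dfoil(h, QUINTET).table.iloc[0]
    # swapping P3<->P4 negates DFO and DIL; swapping P1<->P2 negates DFI, DOL
    swap34 = intro.dfoil(h, ("p1", "p2", "p4", "p3", "o")).table.iloc[0]
    assert swap34["DFO"] == pytest.approx(-base["DFO"])
    assert swap34["DIL"] == pytest.approx(-base["DIL"])
    swap12 = intro.dfoil(h, ("p2", "p1", "p3", "p4", "o")).table.iloc[0]
    assert swap12["DFI"] == pytest.approx(-base["DFI"])
    assert swap12["DOL"] == pytest.approx(-base["DOL"])


def test_asymmetric_quintet_is_refused():
    t = _tree("((((p1,p2),p3),p4),o);")
    h = haploid_from_patterns(FIVE, ["BBAAA"])
    with pytest.raises(ValueError, match="symmetric"):
        intro.dfoil(h, QUINTET, species_tree=t)


def _simulate_quintet_matrix(quintet_tree, event=None, seed=23, n_genes=600):
    tree = quintet_tree
    if event is not None:
        tree = sd.inject_introgression(tree, event)
    gts = sd.simulate_gene_trees(tree, n_genes, seed=seed, lineages_per_accession=2)
    m, _, _ = sd.simulate_variants(gts, 6, seed=seed + 1)
    return resolve_heterozygotes(m, seed=1)


def test_dfoil_recovers_injected_direction(quintet_tree):
    # pulse P3 -> P1 (donor P3, recipient P1) at gamma = 0.3
    ev = sd.SimIntrogressionEvent("P3", "P1", time_years=50_000, proportion=0.3)
    h = _simulate_quintet_matrix(quintet_tree, ev)
    res = intro.dfoil(h, ("P1_1", "P2_1", "P3_1", "P4_1", "O_1"))
    row = res.table.iloc[0]
    assert row["introgression"]
    assert row["donor"] == "P3_1" and row["recipient"] == "P1_1"


def test_dfoil_quiet_without_introgression(quintet_tree):
    h = _simulate_quintet_matrix(quintet_tree, None, seed=31)
    res = intro.dfoil(h, ("P1_1", "P2_1", "P3_1", "P4_1", "O_1"))
    assert not res.table["introgression"].any()


# ---------------------------------------------------------------------------
# topology counting
# ---------------------------------------------------------------------------


def test_identical_concordant_trees():
    trees = ["((p1,p2),(p3,o));"] * 100
    res = intro.count_topologies(trees, TRIO)
    assert (res.n_concordant, res.n_disc_p1p3, res.n_disc_p2p3) == (100, 0, 0)


def test_rotated_newick_is_same_topology():
    res = intro.count_topologies(["((p2,p1),(o,p3));"], TRIO)
    assert res.n_concordant == 1


def test_tree_missing_taxon_is_skipped():
    res = intro.count_topologies(["((p1,p2),(p3,o));", "((p1,p2),o);"], TRIO)
    assert res.n_skipped == 1 and res.n_concordant == 1


def test_pure_ils_discordant_classes_balanced(three_species_tree):
    gts = sd.simulate_gene_trees(three_species_tree, 3000, seed=19)
    trio = intro.TrioAssignment("A_1", "B_1", "C_1", "O_1")
    res = intro.count_topologies(gts.newicks(), trio)
    from scipy import stats

    p = stats.binomtest(res.n_disc_p1p3, res.n_disc_p1p3 + res.n_disc_p2p3, 0.5).pvalue
    assert p > 0.01


@pytest.mark.parametrize(
    "props,expected",
    [((60, 30, 10), 0.2), ((50, 25, 25), 0.0)],
)
def test_introgressed_fraction_arithmetic(props, expected):
    res = intro.TopologyCountResult(TRIO, *props)
    est = intro.introgressed_fraction(res)
    assert est.estimate == pytest.approx(expected)


def test_introgressed_fraction_recovers_gamma(three_species_tree):
    ev = sd.SimIntrogressionEvent("C", "B", time_years=50_000, proportion=0.1)
    tree = sd.inject_introgression(three_species_tree, ev)
    gts = sd.simulate_gene_trees(tree, 5000, seed=29)
    trio = intro.TrioAssignment("A_1", "B_1", "C_1", "O_1")
    res = intro.count_topologies(gts.newicks(), trio)
    est = intro.introgressed_fraction(res)
    assert est.implicated_pair == ("B_1", "C_1")
    assert abs(est.estimate - 0.1) <= 0.03


# ---------------------------------------------------------------------------
# clade-wide summary
# ---------------------------------------------------------------------------


def test_worked_per_branch_fraction():
    s = intro.cladewide_summary(n_windows=2596, n_significant=672, n_branches=20)
    assert s.pct_per_branch == pytest.approx(1.29, abs=0.005)


def test_worked_any_branch_fraction():
    s = intro.cladewide_summary(n_windows=2596, n_significant=1147, n_branches=26)
    assert s.pct_any == pytest.approx(44.0, abs=0.5)


def test_zero_significant_windows():
    s = intro.cladewide_summary(n_windows=100, n_significant=0, n_branches=5)
    assert s.pct_any == 0.0 and s.pct_per_branch == 0.0


def test_summary_from_table_and_order_invariance():
    import pandas as pd

    df = pd.DataFrame(
        {
            "trio": ["a,b,c", "a,b,c", "a,b,d", "x,y,z"],
            "window": ["w1", "w2", "w1", "w2"],
            "n_abba": [30, 11, 8, 5],
            "n_baba": [5, 9, 30, 5],
            "D": [25 / 35, 0.1, -22 / 38, 0.0],
            "p": [1e-6, 0.5, 1e-6, 1.0],
        }
    )
    s = intro.cladewide_summary(df, n_branches=3)
    assert s.n_windows == 2 and s.n_significant_windows == 1
    shuffled = intro.cladewide_summary(df.sample(frac=1, random_state=0), n_branches=3)
    assert shuffled.n_significant_windows == s.n_significant_windows
    # excluding the admixed taxon drops its trio before summarising
    s2 = intro.cladewide_summary(df, n_branches=3, exclude_trios_with={"d"})
    assert s2.n_significant_windows == 1
    s3 = intro.cladewide_summary(df, n_branches=3, exclude_trios_with={"c"})
    assert s3.n_significant_windows == 1
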
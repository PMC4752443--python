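import numpy as np
import pytest

from _util import BruteForceMSC, haploid_from_patterns
from radscan import phylogwas as pg
from radscan import synthetic_data as sd
from radscan.variant_core import (
    GeneModel,
    SubstitutionClass,
    resolve_heterozygotes,
)


# ---------------------------------------------------------------------------
# partition validation
# ---------------------------------------------------------------------------


def test_partition_equal_to_a_clade_is_rejected(default_tree):
    esc_accs = [
        a for a, s in default_tree.accessions.items() if s.startswith("esc")
    ]
    others = [a for a in default_tree.accession_order if a not in esc_accs]
    part = pg.EnvPartition("f", {a: 1 for a in esc_accs} | {a: 2 for a in others})
    v = pg.validate_partition(part, dict(default_tree.accessions), default_tree)
    assert any("congruent" in msg for msg in v)


def test_partition_splitting_species_is_accepted(default_tree):
    groups = {}
    for sp in ("esc1", "arc1"):
        a = default_tree.accessions_for(sp)
        groups[a[0]] = 1
        groups[a[1]] = 2
    part = pg.EnvPartition("f", groups)
    assert pg.validate_partition(part, dict(default_tree.accessions), default_tree) == []


def test_empty_group_is_rejected(default_tree):
    part = pg.EnvPartition("f", {a: 1 for a in list(default_tree.accessions)[:4]})
    v = pg.validate_partition(part, dict(default_tree.accessions), default_tree)
    assert any("non-empty" in msg for msg in v)


def test_confounded_partition_is_flagged(default_tree):
    # groups follow species boundaries (no species split across sides) but
    # are not a clade either
    part = pg.EnvPartition(
        "f",
        {a: 1 for a in default_tree.accessions_for("esc1")}
        | {a: 1 for a in default_tree.accessions_for("per1")}
        | {a: 2 for a in default_tree.accessions_for("arc1")},
    )
    v = pg.validate_partition(part, dict(default_tree.accessions), default_tree)
    assert any("confounded" in msg for msg in v)


# ---------------------------------------------------------------------------
# perfect-association scan
# ---------------------------------------------------------------------------

ACCS = ["w", "x", "y", "z"]
PART = pg.EnvPartition("f", {"w": 1, "x": 1, "y": 2, "z": 2})
# one gene covering positions 0..8; CDS chosen so positions are classifiable
MODEL = GeneModel("g1", "chr1", "+", ((0, 9),))
CDS = {"g1": "GAACGTTGG"}


def test_single_disjoint_site_is_one_hit():
    # position 1 (2nd codon position): G/G vs A/A
    h = haploid_from_patterns(ACCS, ["ABBA"])  # pos 0: w=A x=G y=G z=A -> mixed
    h = haploid_from_patterns(ACCS, ["AABB"])
    h.pos = np.array([1])
    scan = pg.scan_perfect_association(h, PART, [MODEL], CDS)
    assert scan.n_variants_examined == 1 and scan.m == 1
    assert scan.hits[0].substitution_class == "nonsynonymous"


def test_overlapping_allele_sets_are_not_hits():
    h = haploid_from_patterns(ACCS, ["ABBB"])  # x carries the group-2 allele
    h.pos = np.array([1])
    scan = pg.scan_perfect_association(h, PART, [MODEL], CDS)
    assert scan.n_variants_examined == 1 and scan.m == 0


def test_missing_contrasted_accession_excludes_site():
    h = haploid_from_patterns(ACCS, ["AAB."])
    h.pos = np.array([1])
    scan = pg.scan_perfect_association(h, PART, [MODEL], CDS)
    assert scan.n_variants_examined == 0


def test_class_filter_selects_synonymous_when_asked():
    # position 2 is the 3rd base of codon GAA: A<->G is synonymous (E/E)
    h = haploid_from_patterns(ACCS, ["AABB"])
    h.pos = np.array([2])
    nonsyn = pg.scan_perfect_association(h, PART, [MODEL], CDS)
    syn = pg.scan_perfect_association(
        h, PART, [MODEL], CDS, substitution_class=SubstitutionClass.SYNONYMOUS
    )
    assert nonsyn.n_variants_examined == 0
    assert syn.m == 1


def test_adding_accessions_can_only_shrink_hits():
    h = haploid_from_patterns(["w", "x", "y", "z", "v"], ["AABBA", "AABBB"])
    h.pos = np.array([1, 4])
    base = pg.scan_perfect_association(h, PART, [MODEL], CDS)
    wider = pg.EnvPartition("f", dict(PART.groups) | {"v": 2})
    out = pg.scan_perfect_association(h, wider, [MODEL], CDS)
    assert out.m <= base.m


# ---------------------------------------------------------------------------
# coalescent null
# ---------------------------------------------------------------------------


def test_q_is_one_for_two_accession_tree():
    nwk = "(A:100000,B:100000)r;"
    tree = sd.SimSpeciesTree(newick=nwk, accessions={"A_1": "A", "B_1": "B"})
    part = pg.EnvPartition("f", {"A_1": 1, "B_1": 2})
    est = pg.estimate_null_probability(pg.NullSimConfig(tree, 500, seed=4), part)
    assert est.q == 1.0


def test_q_near_zero_for_partition_crossing_long_internodes():
    nwk = "(((A:100000,B:100000)ab:900000,(C:100000,D:100000)cd:900000)r:0,O:1000000)root;"
    tree = sd.SimSpeciesTree(
        newick=nwk, accessions={f"{s}_1": s for s in "ABCD"}
    )
    part = pg.EnvPartition("f", {"A_1": 1, "C_1": 1, "B_1": 2, "D_1": 2})
    est = pg.estimate_null_probability(pg.NullSimConfig(tree, 3000, seed=4), part)
    assert est.q < 0.01


def test_q_invariant_under_label_swap(three_species_tree):
    part = pg.EnvPartition("f", {"A_1": 1, "C_1": 1, "B_1": 2})
    cfg = pg.NullSimConfig(three_species_tree, 2000, seed=7)
    q1 = pg.estimate_null_probability(cfg, part).q
    q2 = pg.estimate_null_probability(cfg, part.swapped()).q
    assert q1 == q2


def test_q_matches_brute_force_enumeration_oracle():
    # 4-taxon tree ((A,B),(C,D)); partition = the two non-sister pairs.
    # Oracle: an independent hand-rolled structured-coalescent simulator
    # (tests/_util.py) with branch-proportional mutation placement.
    nwk = "((A:80000,B:80000)ab:80000,(C:80000,D:80000)cd:80000)r;"
    tree = sd.SimSpeciesTree(newick=nwk, accessions={f"{s}_1": s for s in "ABCD"})
    part = pg.EnvPartition(
        "f", {"A_1": 1, "C_1": 1, "B_1": 2, "D_1": 2}
    )
    n = 30_000
    est = pg.estimate_null_probability(pg.NullSimConfig(tree, n, seed=11), part)
    # same tree in coalescent units (2 N_e generations = 80 ky here)
    oracle_tree = (
        "r",
        2.0,
        [
            ("ab", 1.0, [("A", 0.0, []), ("B", 0.0, [])]),
            ("cd", 1.0, [("C", 0.0, []), ("D", 0.0, [])]),
        ],
    )
    bf = BruteForceMSC(oracle_tree, np.random.default_rng(13))
    q_bf, se_bf = bf.sorting_probability({"A", "C"}, {"B", "D"}, 30_000)
    tol = 3 * np.sqrt(est.se**2 + se_bf**2)
    assert abs(est.q - q_bf) <= tol


# ---------------------------------------------------------------------------
# dataset p-value
# ---------------------------------------------------------------------------


def test_p_is_one_when_nothing_can_exceed_zero():
    assert pg.dataset_pvalue(0, 1000, q=0.0) == 1.0


def test_p_is_zero_for_hits_impossible_under_null():
    assert pg.dataset_pvalue(10, 1000, q=0.0) == 0.0


def test_binomial_and_resimulation_agree(three_species_tree):
    part = pg.EnvPartition("f", {"A_1": 1, "C_1": 1, "B_1": 2})
    q = pg.estimate_null_probability(
        pg.NullSimConfig(three_species_tree, 20_000, seed=3), part
    ).q
    pool = pg.simulate_match_pool(
        pg.NullSimConfig(three_species_tree, 20_000, seed=4), part
    )
    n, m = 200, 30
    p_bin = pg.dataset_pvalue(m, n, q=q)
    n_datasets = 10_000
    p_res = pg.dataset_pvalue(
        m, n, method="resimulation", pool=pool, n_datasets=n_datasets, seed=5
    )
    se = np.sqrt(max(p_bin * (1 - p_bin), 1e-9) / n_datasets) + 0.01
    assert abs(p_bin - p_res) <= 2 * se


# ---------------------------------------------------------------------------
# truth recovery and the linked-synonymous check
# ---------------------------------------------------------------------------


def _env_setup(default_tree, seed=15, n_env=5):
    groups = {}
    for sp in ("esc1", "arc1", "per1"):
        a = default_tree.accessions_for(sp)
        groups[a[0]] = 1
        groups[a[1]] = 2
    out = sd.simulate_dataset(
        default_tree, n_genes=40, sites_per_gene=5, seed=seed,
        env_groups=groups, n_env_sites=n_env,
    )
    part = pg.EnvPartition("env", groups)
    h = resolve_heterozygotes(out.matrix, seed=1)
    return out, part, h


def test_injected_sites_are_all_recovered(default_tree):
    out, part, h = _env_setup(default_tree)
    scan = pg.scan_perfect_association(h, part, out.gene_models, out.cds)
    found = {(hit.gene_id, hit.position) for hit in scan.hits}
    truth = set(zip(out.env_truth["gene"], out.env_truth["position"]))
    assert truth <= found


def test_isolated_hits_are_not_flagged_ambiguous(default_tree):
    out, part, h = _env_setup(default_tree)
    scan = pg.scan_perfect_association(h, part, out.gene_models, out.cds)
    linked = pg.linked_synonymous_check(scan, h, part, out.gene_models, out.cds)
    truth_genes = set(out.env_truth["gene"])
    flagged = set(linked.loc[linked["introgression_ambiguous"], "gene"])
    assert not (truth_genes & flagged)


def test_injected_linked_block_is_flagged(default_tree):
    out, part, h = _env_setup(default_tree, n_env=2)
    gene = out.gene_models[7].gene_id
    assert gene not in set(out.env_truth["gene"])
    matrix, block = sd.inject_linked_block(
        out.matrix, part.groups, gene, n_nonsyn=2, n_syn=3,
        gene_models=out.gene_models, cds=out.cds, seed=77,
    )
    h2 = resolve_heterozygotes(matrix, seed=1)
    scan = pg.scan_perfect_association(h2, part, out.gene_models, out.cds)
    linked = pg.linked_synonymous_check(scan, h2, part, out.gene_models, out.cds)
    row = linked.set_index("gene").loc[gene]
    assert row["introgression_ambiguous"]
    assert row["n_assoc_synonymous"] >= 3
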
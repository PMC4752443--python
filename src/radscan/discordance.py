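"""Gene-tree/window-tree discordance metrics.

Rapid radiations produce forests of window or gene trees that almost never
agree: this module counts distinct unrooted topologies, measures per-branch
bipartition support against a reference tree, relates internal branch length
to concordance (short internodes sort less), and scores per-taxon positional
instability to flag rogue (e.g. admixed) lineages.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "count_distinct_topologies",
    "bipartition_support",
    "branchlen_vs_concordance",
    "taxon_instability",
]


def _parse_trees(newicks: list[str], tns: dendropy.TaxonNamespace | None = None):
    tns = tns or dendropy.TaxonNamespace()
    trees = []
    for nwk in newicks:
        t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns, preserve_underscores=True)
        trees.append(t)
    return trees, tns


def _check_common_taxa(trees) -> frozenset[str]:
    taxa_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    if len(set(taxa_sets)) != 1:
        raise ValueError("trees must share an identical taxon set")
    return taxa_sets[0]


def _topology_key(tree: dendropy.Tree) -> frozenset[int]:
    tree.is_rooted = False
    tree.encode_bipartitions()
    return frozenset(
        b.split_bitmask for b in tree.bipartition_encoding if not b.is_trivial()
    )


def count_distinct_topologies(newicks: list[str]) -> int:
    """Number of distinct unrooted topologies among the trees.

    Two trees are the same class iff their nontrivial bipartition sets are
    equal (Robinson-Foulds distance 0); child order and branch lengths are
    ignored.  All trees must be on the same taxon set.
    """
    trees, _ = _parse_trees(newicks)
    _check_common_taxa(trees)
    return len({_topology_key(t) for t in trees})


def bipartition_support(newicks: list[str], reference: str) -> pd.DataFrame:
    """Per reference branch: fraction of trees containing the bipartition.

    Trees with extra taxa are pruned to the reference's taxon set; a tree
    missing reference taxa is an error.  Polytomies count a branch as
    supported only when the exact bipartition is present (hard support).
    Returns one row per internal (nontrivial) reference branch with the
    smaller bipartition side, the branch length, and the support fraction.
    """
    tns = dendropy.TaxonNamespace()
    ref = dendropy.Tree.get(data=reference, schema="newick", taxon_namespace=tns, preserve_underscores=True)
    ref_taxa = frozenset(l.taxon.label for l in ref.leaf_node_iter())
    trees, _ = _parse_trees(newicks, tns)
    keys = []
    for t in trees:
        taxa = frozenset(l.taxon.label for l in t.leaf_node_iter())
        if not ref_taxa.issubset(taxa):
            raise ValueError("a tree lacks taxa present in the reference")
        if taxa != ref_taxa:
            t.retain_taxa_with_labels(sorted(ref_taxa))
        keys.append(_topology_key(t))
    ref.is_rooted = False
    ref.encode_bipartitions()
    rows = []
    for edge in ref.preorder_edge_iter():
        b = edge.bipartition
        if b is None or b.is_trivial() or edge.head_node.parent_node is None:
            continue
        side = {l.taxon.label for l in edge.head_node.leaf_iter()}
        if len(side) > len(ref_taxa) / 2:
            side = ref_taxa - side
        support = sum(b.split_bitmask in k for k in keys) / len(keys)
        rows.append(
            {
                "bipartition": "|".join(sorted(side)),
                "n_taxa_side": len(side),
                "branch_length": edge.length,
                "support": support,
            }
        )
    return pd.DataFrame(rows, columns=["bipartition", "n_taxa_side", "branch_length", "support"])


@dataclass
class ConcordanceCorrelation:
    rho: float
    pvalue: float
    n_branches: int
    tied: bool = False


def branchlen_vs_concordance(support: pd.DataFrame) -> ConcordanceCorrelation:
    """Spearman rank correlation of internal branch length vs support.

    A positive correlation is the ILS expectation: shorter internodes leave
    less time for lineage sorting and are recovered by fewer trees.  With
    fewer than 3 branches the statistic is undefined; constant supports or
    lengths return NaN with the tie flag set.
    """
    df = support.dropna(subset=["branch_length", "support"])
    if len(df) < 3:
        raise ValueError("need at least 3 internal branches")
    if df["support"].nunique() == 1 or df["branch_length"].nunique() == 1:
        return ConcordanceCorrelation(math.nan, math.nan, len(df), tied=True)
    rho, p = stats.spearmanr(df["branch_length"], df["support"])
    return ConcordanceCorrelation(float(rho), float(p), len(df))


def taxon_instability(newicks: list[str]) -> pd.Series:
    """Per-taxon positional-instability score across a set of trees.

    For each tree the taxon's profile of nodal (edge-count) distances to all
    other taxa is computed; the score is the mean, over all tree pairs, of
    the mean absolute change of that profile.  Identical trees score 0
    everywhere; a taxon regrafted between clades ranks first.  The contract
    is the ranking, not the absolute value.
    """
    trees, tns = _parse_trees(newicks)
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    labels = sorted(_check_common_taxa(trees))
    k = len(labels)
    pos = {l: i for i, l in enumerate(labels)}
    mats = []
    for t in trees:
        pdm = t.phylogenetic_distance_matrix()
        m = np.zeros((k, k))
        for t1, t2 in itertools.combinations(tns, 2):
            if t1.label in pos and t2.label in pos:
                d = pdm.path_edge_count(t1, t2)
                m[pos[t1.label], pos[t2.label]] = d
                m[pos[t2.label], pos[t1.label]] = d
        mats.append(m)
    scores = np.zeros(k)
    n_pairs = 0
    for a, b in itertools.combinations(range(len(mats)), 2):
        diff = np.abs(mats[a] - mats[b])
        scores += diff.sum(axis=1) / (k - 1)
        n_pairs += 1
    return pd.Series(scores / n_pairs, index=labels).sort_values(ascending=False)
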
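"""Per-accession heterozygosity, ancestral-allele sorting, and pairwise distance.

These summaries describe how ancestral polymorphism is distributed in a
radiation: the fraction of heterozygous sites per accession, the proportion
of those heterozygous sites whose allele pair is still segregating outside
the accession's own species (pervasive under incomplete lineage sorting),
group-specific allele sharing (a diagnostic for recent hybrids), and the
pairwise proportion of differing sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variant_core import MISSING, HaploidMatrix, VariantMatrix

__all__ = [
    "heterozygosity",
    "shared_het_profile",
    "group_specific_allele_share",
    "pairwise_distance",
]


def heterozygosity(matrix: VariantMatrix) -> pd.DataFrame:
    """Per-accession heterozygosity H = n_het / n_assayed.

    Sites where the accession is missing are excluded from its denominator;
    an accession with zero assayed sites gets H = NaN (undefined, not 0).
    A high-depth-filtered matrix is the recommended input.
    """
    assayed = (~matrix.missing_mask()).sum(axis=0)
    het = matrix.het_mask().sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(assayed > 0, het / np.maximum(assayed, 1), np.nan)
    return pd.DataFrame(
        {
            "accession": matrix.accessions,
            "n_assayed": assayed.astype(int),
            "n_heterozygous": het.astype(int),
            "H": h,
        }
    )


def _allele_presence(matrix: VariantMatrix) -> np.ndarray:
    """(n_sites, n_accessions, 4) booleans: accession carries allele code."""
    return np.stack(
        [(matrix.geno == code).any(axis=2) for code in range(4)], axis=2
    )


def shared_het_profile(
    matrix: VariantMatrix,
    grouping: dict[str, str],
    strict_single_group: bool = False,
) -> pd.DataFrame:
    """Fraction of each accession's het sites whose alleles sort elsewhere.

    A het site (alleles x/y) counts as *shared* when both x and y are also
    observed among accessions outside the focal accession's own group
    (polymorphic there or as fixed differences).  With
    ``strict_single_group=True`` both alleles must be observed within a
    single other group.  The denominator is het sites with at least one
    non-focal-group observation.
    """
    if len(set(grouping.values())) < 2:
        raise ValueError("at least two groups are required")
    presence = _allele_presence(matrix)
    het = matrix.het_mask()
    groups = np.array([grouping[a] for a in matrix.accessions])
    rows = []
    for j, acc in enumerate(matrix.accessions):
        outside = groups != grouping[acc]
        out_presence = presence[:, outside, :]  # (n_sites, n_out, 4)
        has_out_data = (~matrix.missing_mask()[:, outside]).any(axis=1)
        sites = np.nonzero(het[:, j] & has_out_data)[0]
        n_shared = 0
        for i in sites:
            x, y = int(matrix.geno[i, j, 0]), int(matrix.geno[i, j, 1])
            if strict_single_group:
                out_groups = groups[outside]
                ok = False
                for g in set(out_groups):
                    sel = out_presence[i, out_groups == g, :]
                    if sel[:, x].any() and sel[:, y].any():
                        ok = True
                        break
                n_shared += ok
            else:
                n_shared += bool(
                    out_presence[i, :, x].any() and out_presence[i, :, y].any()
                )
        denom = len(sites)
        rows.append(
            {
                "accession": acc,
                "n_het_considered": denom,
                "n_shared": n_shared,
                "shared_proportion": (n_shared / denom) if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def group_specific_allele_share(
    matrix: VariantMatrix,
    focal: str,
    grouping: dict[str, str],
) -> pd.Series:
    """Per group: fraction of focal het sites carrying an otherwise
    group-specific allele.

    An allele is *group-specific* when, among all accessions other than the
    focal one, it is observed only within that group.  Values near 1 for two
    groups diagnose a recent hybrid between them.  Returns NaN when the focal
    accession has no heterozygous sites.
    """
    jf = matrix.acc_index(focal)
    presence = _allele_presence(matrix)
    others = np.array([a != focal for a in matrix.accessions])
    groups = np.array([grouping[a] for a in matrix.accessions])
    het_sites = np.nonzero(matrix.het_mask()[:, jf])[0]
    labels = sorted(set(groups[others]))
    counts = {g: 0 for g in labels}
    for i in het_sites:
        pair = {int(matrix.geno[i, jf, 0]), int(matrix.geno[i, jf, 1])}
        for g in labels:
            in_g = others & (groups == g)
            out_g = others & (groups != g)
            for allele in pair:
                if presence[i, in_g, allele].any() and not presence[i, out_g, allele].any():
                    counts[g] += 1
                    break
    denom = len(het_sites)
    vals = {g: (counts[g] / denom if denom else np.nan) for g in labels}
    return pd.Series(vals, name=focal)


def pairwise_distance(h: HaploidMatrix) -> pd.DataFrame:
    """Accession x accession proportion of differing sites.

    d(i, j) = mismatches / jointly non-missing sites; symmetric with zero
    diagonal; NaN for pairs with no joint coverage.
    """
    k = h.n_accessions
    d = np.zeros((k, k))
    present = h.alleles != MISSING
    for i in range(k):
        for j in range(i + 1, k):
            joint = present[:, i] & present[:, j]
            n = int(joint.sum())
            if n == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                mism = int((h.alleles[joint, i] != h.alleles[joint, j]).sum())
                d[i, j] = d[j, i] = mism / n
    return pd.DataFrame(d, index=h.accessions, columns=h.accessions)
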
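"""Multisample variant data model, filtering, and codon-level classification.

The central container is :class:`VariantMatrix`, a sites x accessions table of
unphased diploid genotypes backed by numpy integer codes.  All coordinates are
0-based half-open internally; file dialects that are conventionally 1-based
(VCF, the MVF-like TSV) are converted on read/write.

Alleles are encoded as ``A=0, C=1, G=2, T=3`` with ``-1`` as the missing
sentinel.  Ambiguity codes are never used: a genotype is either a concrete
(unordered) allele pair or missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
MISSING = -1

__all__ = [
    "BASES",
    "BASE_TO_CODE",
    "MISSING",
    "FilterProfile",
    "HQ_PROFILE",
    "HD_PROFILE",
    "VariantMatrix",
    "HaploidMatrix",
    "GeneModel",
    "GenomeWindow",
    "SubstitutionClass",
    "ClassificationUnavailable",
    "read_vcf",
    "resolve_heterozygotes",
    "classify_substitution",
    "partition_windows",
    "write_matrix",
    "read_matrix",
]


class VcfParseError(ValueError):
    """A malformed record or metadata mismatch while reading variant input."""


@dataclass(frozen=True)
class FilterProfile:
    """Per-genotype quality filter.

    A genotype is retained only if its sequencing depth is at least
    ``min_depth`` and its mapping quality at least ``min_mq``; a site is kept
    only if at least ``min_accessions_with_data`` accessions survive.
    """

    name: str
    min_depth: int
    min_mq: int
    min_accessions_with_data: int = 1


#: High-quality preset (depth >= 3, MQ >= 30).
HQ_PROFILE = FilterProfile("HQ", 3, 30)
#: High-depth preset (depth >= 10, MQ >= 30), used for heterozygosity work.
HD_PROFILE = FilterProfile("HD", 10, 30)


def _as_code(allele: str) -> int:
    try:
        return BASE_TO_CODE[allele.upper()]
    except KeyError:
        raise ValueError(f"allele must be one of {BASES!r}, got {allele!r}")


@dataclass
class VariantMatrix:
    """Sites x accessions diploid genotype matrix.

    Attributes
    ----------
    accessions:
        Ordered accession identifiers (column order of all arrays).
    chrom:
        Chromosome identifier per site (object array).
    pos:
        0-based site position, strictly increasing within a chromosome.
    ref:
        Reference allele code per site.
    geno:
        ``(n_sites, n_accessions, 2)`` int8 array of allele codes; genotypes
        are unordered and stored with the pair sorted; missing is
        ``(-1, -1)``.
    depth, mq:
        Optional per-genotype read depth and mapping quality.
    """

    accessions: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    geno: np.ndarray
    depth: np.ndarray | None = None
    mq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 3 or self.geno.shape[2] != 2:
            raise ValueError("geno must have shape (n_sites, n_accessions, 2)")
        if self.geno.shape[1] != len(self.accessions):
            raise ValueError("one genotype slot per accession is required")
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        # normalise unordered pairs and validate ordering
        self.geno = np.sort(self.geno, axis=2)
        half_missing = (self.geno[:, :, 0] == MISSING) ^ (self.geno[:, :, 1] == MISSING)
        if half_missing.any():
            raise ValueError("genotypes must be a full allele pair or fully missing")
        for c in dict.fromkeys(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c!r}")

    # -- basic introspection ------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.geno.shape[0]

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def acc_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_accessions): True where genotype is missing."""
        return self.geno[:, :, 0] == MISSING

    def het_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_accessions): True at heterozygous genotypes."""
        return (self.geno[:, :, 0] != self.geno[:, :, 1]) & ~self.missing_mask()

    def n_alleles(self) -> np.ndarray:
        """Number of distinct observed alleles per site (missing excluded)."""
        out = np.zeros(self.n_sites, dtype=np.int8)
        for code in range(4):
            out += (self.geno == code).any(axis=(1, 2))
        return out

    def site_alleles(self, i: int) -> set[int]:
        codes = self.geno[i].ravel()
        return set(int(c) for c in codes if c != MISSING)

    def take_sites(self, idx: np.ndarray) -> "VariantMatrix":
        return VariantMatrix(
            accessions=list(self.accessions),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            geno=self.geno[idx],
            depth=None if self.depth is None else self.depth[idx],
            mq=None if self.mq is None else self.mq[idx],
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, VariantMatrix):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.geno, other.geno)
        )


@dataclass
class HaploidMatrix:
    """One allele per accession per site, from random heterozygote resolution."""

    accessions: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alleles: np.ndarray  # (n_sites, n_accessions) int8
    seed: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def acc_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def as_variant_matrix(self) -> VariantMatrix:
        """View the haploid calls as an all-homozygous diploid matrix."""
        geno = np.stack([self.alleles, self.alleles], axis=2)
        return VariantMatrix(
            accessions=list(self.accessions),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            geno=geno,
        )


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene model: ordered coding intervals, 0-based half-open."""

    gene_id: str
    chromosome: str
    strand: str
    coding_intervals: tuple[tuple[int, int], ...]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ivs = tuple((int(s), int(e)) for s, e in self.coding_intervals)
        object.__setattr__(self, "coding_intervals", ivs)
        for s, e in ivs:
            if e <= s:
                raise ValueError("empty coding interval")
        if (self.coding_length - self.frame_offset) % 3 != 0:
            raise ValueError("coding length (after frame adjustment) not divisible by 3")

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)

    def cds_index(self, genomic_pos: int) -> int | None:
        """Map a genomic position to a 0-based index in the mRNA-sense CDS.

        Returns None for positions outside the coding intervals.
        """
        fwd = 0
        hit = None
        for s, e in sorted(self.coding_intervals):
            if s <= genomic_pos < e:
                hit = fwd + (genomic_pos - s)
                break
            fwd += e - s
        if hit is None:
            return None
        if self.strand == "-":
            hit = self.coding_length - 1 - hit
        return hit


@dataclass(frozen=True)
class GenomeWindow:
    """Nonoverlapping genomic window with its aligned-site tally."""

    chromosome: str
    start: int
    end: int
    n_aligned_sites: int
    excluded: bool = False


class SubstitutionClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NONCODING = "noncoding"


class ClassificationUnavailable(ValueError):
    """Raised when the codon context contains missing/ambiguous bases."""


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_vcf(
    path: str,
    profile: FilterProfile,
    accessions: list[str] | None = None,
) -> VariantMatrix:
    """Read a multisample VCF into a filtered :class:`VariantMatrix`.

    Genotypes failing the per-sample depth/MQ thresholds of *profile* become
    missing; sites with fewer than ``profile.min_accessions_with_data``
    surviving accessions are dropped.  Only biallelic-or-more SNP records
    with single-base ACGT alleles are retained (indels are skipped).

    Mapping quality is taken from the per-sample ``MQ`` FORMAT field when
    present, otherwise from the site-level ``INFO/MQ`` applied to all samples.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(path)
    samples = list(vcf.samples)
    if accessions is not None:
        unknown = set(samples) ^ set(accessions)
        if unknown:
            raise VcfParseError(f"sample set mismatch with metadata: {sorted(unknown)}")
    k = len(samples)
    chroms, poss, refs, genos, depths, mqs = [], [], [], [], [], []
    for lineno, v in enumerate(vcf, start=1):
        alleles = [v.REF] + list(v.ALT)
        if any(len(a) != 1 or a.upper() not in BASE_TO_CODE for a in alleles):
            continue  # not a simple SNP
        codes = np.array([BASE_TO_CODE[a.upper()] for a in alleles], dtype=np.int8)
        try:
            gts = np.asarray(v.genotype.array())[:, :2]
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"malformed record at VCF body line {lineno}") from exc
        pair = np.full((k, 2), MISSING, dtype=np.int8)
        called = (gts >= 0).all(axis=1)
        pair[called] = codes[gts[called]]

        dp = v.format("DP")
        dp = np.full(k, 0, dtype=np.int32) if dp is None else dp.reshape(k).astype(np.int32)
        mq = v.format("MQ")
        if mq is None:
            site_mq = v.INFO.get("MQ")
            mq = np.full(k, -1 if site_mq is None else int(site_mq), dtype=np.int32)
        else:
            mq = mq.reshape(k).astype(np.int32)
        dp = np.where(dp < 0, 0, dp)
        fail = (dp < profile.min_depth) | ((mq >= 0) & (mq < profile.min_mq))
        pair[fail] = MISSING
        if int((pair[:, 0] != MISSING).sum()) < profile.min_accessions_with_data:
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # to 0-based
        refs.append(BASE_TO_CODE[v.REF.upper()])
        genos.append(pair)
        depths.append(dp)
        mqs.append(mq)
    n = len(poss)
    return VariantMatrix(
        accessions=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=np.int8),
        geno=(np.stack(genos) if n else np.empty((0, k, 2), dtype=np.int8)),
        depth=(np.stack(depths) if n else np.empty((0, k), dtype=np.int32)),
        mq=(np.stack(mqs) if n else np.empty((0, k), dtype=np.int32)),
    )


def resolve_heterozygotes(
    matrix: VariantMatrix | HaploidMatrix, seed: int
) -> HaploidMatrix:
    """Resolve heterozygous genotypes by a seeded random allele draw.

    One global RNG stream is consumed in site-major, accession-minor order so
    the result is reproducible and stable under site/accession subsetting of
    the *output*.  Homozygous genotypes map to their single allele; a haploid
    input is returned unchanged (idempotence).
    """
    if isinstance(matrix, HaploidMatrix):
        matrix = matrix.as_variant_matrix()
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, size=(matrix.n_sites, matrix.n_accessions))
    alleles = np.take_along_axis(matrix.geno, pick[:, :, None], axis=2)[:, :, 0]
    alleles = np.where(matrix.missing_mask(), MISSING, alleles).astype(np.int8)
    return HaploidMatrix(
        accessions=list(matrix.accessions),
        chrom=matrix.chrom,
        pos=matrix.pos,
        ref=matrix.ref,
        alleles=alleles,
        seed=seed,
    )


def classify_substitution(
    model: GeneModel,
    cds_sequence: str,
    site_offset: int,
    allele_a: str,
    allele_b: str,
) -> SubstitutionClass:
    """Classify an ``allele_a -> allele_b`` change at a genomic position.

    *cds_sequence* is the spliced coding sequence in mRNA sense (already
    reverse-complemented for minus-strand genes).  *site_offset* is the
    0-based genomic position of the site.  The two codons differing only at
    that site are translated with the standard genetic code; a change of
    amino acid (stop included) is nonsynonymous.  Positions outside the
    coding intervals are noncoding.  The classification is symmetric in the
    two alleles.
    """
    idx = model.cds_index(site_offset)
    if idx is None:
        return SubstitutionClass.NONCODING
    c = idx - model.frame_offset
    if c < 0:
        return SubstitutionClass.NONCODING
    start = model.frame_offset + (c // 3) * 3
    within = c % 3
    codon = cds_sequence[start : start + 3].upper()
    if len(codon) < 3 or any(b not in BASE_TO_CODE for b in codon):
        raise ClassificationUnavailable(
            f"codon context unavailable at CDS index {idx} of {model.gene_id}"
        )
    a, b = allele_a.upper(), allele_b.upper()
    if model.strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        a, b = comp[a], comp[b]
    if a not in BASE_TO_CODE or b not in BASE_TO_CODE:
        raise ClassificationUnavailable("allele is not an unambiguous base")
    ca = codon[:within] + a + codon[within + 1 :]
    cb = codon[:within] + b + codon[within + 1 :]
    if str(Seq(ca).translate()) == str(Seq(cb).translate()):
        return SubstitutionClass.SYNONYMOUS
    return SubstitutionClass.NONSYNONYMOUS


def partition_windows(
    matrix: VariantMatrix | HaploidMatrix,
    size: int,
    min_sites: int = 100,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomeWindow]:
    """Tile each chromosome with nonoverlapping windows starting at 0.

    Windows with fewer than *min_sites* aligned sites are flagged excluded.
    The terminal window of a chromosome is truncated at the chromosome length
    (taken from *chrom_lengths* when given, otherwise one past the last site).
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows: list[GenomeWindow] = []
    for c in dict.fromkeys(matrix.chrom.tolist()):
        p = matrix.pos[matrix.chrom == c]
        length = (chrom_lengths or {}).get(c, int(p.max()) + 1)
        for start in range(0, length, size):
            end = min(start + size, length)
            n = int(((p >= start) & (p < end)).sum())
            windows.append(GenomeWindow(c, start, end, n, excluded=n < min_sites))
    return windows


# ---------------------------------------------------------------------------
# I/O: MVF-like TSV and VCF dialects
# ---------------------------------------------------------------------------

_MISS_PAIR = ".."


def _geno_str(pair: np.ndarray) -> str:
    if pair[0] == MISSING:
        return _MISS_PAIR
    return BASES[pair[0]] + BASES[pair[1]]


def write_matrix(matrix: VariantMatrix, path: str, dialect: str = "tsv_mvf_like") -> None:
    """Write a matrix as an MVF-like TSV or a minimal VCF 4.2 file.

    The TSV dialect stores chromosome, 1-based position, reference allele and
    one two-character allele-pair column per accession (missing = ``..``);
    depth/MQ are carried only by the VCF dialect.
    """
    if dialect == "tsv_mvf_like":
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\t" + "\t".join(matrix.accessions) + "\n")
            for i in range(matrix.n_sites):
                cols = [
                    str(matrix.chrom[i]),
                    str(int(matrix.pos[i]) + 1),
                    BASES[matrix.ref[i]],
                ]
                cols += [_geno_str(matrix.geno[i, j]) for j in range(matrix.n_accessions)]
                fh.write("\t".join(cols) + "\n")
    elif dialect == "vcf":
        _write_vcf(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_vcf(matrix: VariantMatrix, path: str) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=radscan",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=MQ,Number=1,Type=Integer,Description="Mapping quality">',
    ]
    for c in dict.fromkeys(matrix.chrom.tolist()):
        last = matrix.pos[matrix.chrom == c].max() if matrix.n_sites else 0
        lines.append(f"##contig=<ID={c},length={int(last) + 1}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.accessions)
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(matrix.n_sites):
            ref = int(matrix.ref[i])
            alts = sorted(matrix.site_alleles(i) - {ref})
            allele_order = [ref] + alts
            index = {code: j for j, code in enumerate(allele_order)}
            alt_str = ",".join(BASES[a] for a in alts) if alts else "."
            fields = []
            for j in range(matrix.n_accessions):
                pair = matrix.geno[i, j]
                if pair[0] == MISSING:
                    gt = "./."
                else:
                    gt = f"{index[int(pair[0])]}/{index[int(pair[1])]}"
                dp = 99 if matrix.depth is None else int(matrix.depth[i, j])
                mq = 60 if matrix.mq is None else int(matrix.mq[i, j])
                fields.append(f"{gt}:{dp}:{mq}")
            fh.write(
                f"{matrix.chrom[i]}\t{int(matrix.pos[i]) + 1}\t.\t{BASES[ref]}\t"
                f"{alt_str}\t.\tPASS\t.\tGT:DP:MQ\t" + "\t".join(fields) + "\n"
            )


def read_matrix(path: str, dialect: str | None = None) -> VariantMatrix:
    """Read a matrix written by :func:`write_matrix` (dialect sniffed if None)."""
    if dialect is None:
        with open(path) as fh:
            first = fh.readline()
        dialect = "vcf" if first.startswith("##fileformat=VCF") else "tsv_mvf_like"
    if dialect == "vcf":
        return read_vcf(path, FilterProfile("passthrough", 0, 0, 0))
    if dialect != "tsv_mvf_like":
        raise ValueError(f"unknown dialect {dialect!r}")
    chroms, poss, refs, genos = [], [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or header[0] != "#chrom":
            raise VcfParseError("malformed MVF-like header")
        accessions = header[3:]
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3 + len(accessions):
                raise VcfParseError(f"malformed record at line {lineno}")
            chroms.append(cols[0])
            poss.append(int(cols[1]) - 1)
            refs.append(_as_code(cols[2]))
            pairs = []
            for g in cols[3:]:
                if g == _MISS_PAIR:
                    pairs.append((MISSING, MISSING))
                else:
                    pairs.append((_as_code(g[0]), _as_code(g[1])))
            genos.append(pairs)
    k = len(accessions)
    n = len(poss)
    return VariantMatrix(
        accessions=accessions,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=np.int8),
        geno=(np.array(genos, dtype=np.int8) if n else np.empty((0, k, 2), dtype=np.int8)),
    )
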
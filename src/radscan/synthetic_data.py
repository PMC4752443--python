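"""Multispecies-coalescent synthetic data: gene trees, diploid variant
matrices, introgression pulses, and injected environment-sorted alleles.

The generator emulates a rapid plant radiation sampled as a multi-accession,
multi-species diploid variant matrix: a labelled ultrametric species tree
(node ages in years) is converted to an msprime demography (ages x
generations/year, one panmictic population of effective size ``N_e`` per
branch), each gene is an independent non-recombining coalescent genealogy,
and variable sites are placed on genealogy branches in proportion to branch
length under an infinite-sites model (no back-mutation, so the derived
allele is unambiguous).  Introgression is realised as a per-gene pulse: a
recorded fraction of genes reroute the recipient's lineages through the
donor population at the event time.

Every operation is deterministic given its seed; truth tables (which genes
are introgressed, which sites were injected) are returned alongside the data
so downstream recovery can be tested.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace

import dendropy
import msprime
import numpy as np
import pandas as pd

from .variant_core import (
    BASES,
    GeneModel,
    SubstitutionClass,
    VariantMatrix,
    classify_substitution,
)

__all__ = [
    "SimSpeciesTree",
    "SimIntrogressionEvent",
    "SimGeneTrees",
    "SimOutput",
    "default_species_tree",
    "simulate_gene_trees",
    "simulate_variants",
    "inject_introgression",
    "inject_environment_alleles",
    "inject_linked_block",
    "simulate_dataset",
    "clade_accession_sets",
    "partition_congruent_with_clade",
]

_STOPS = {"TAA", "TAG", "TGA"}
# codon prefixes whose third position is four-fold degenerate
_FOURFOLD_PREFIXES = {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}


@dataclass(frozen=True)
class SimIntrogressionEvent:
    """A post-speciation gene-flow pulse from *donor* into *recipient*.

    ``proportion`` is the fraction of the recipient's genes replaced; it is
    realised per gene (Bernoulli draw, recorded in the truth table) rather
    than as continuous migration.
    """

    donor: str
    recipient: str
    time_years: float
    proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must be in [0, 1]")
        if self.time_years < 0:
            raise ValueError("time must be non-negative")


@dataclass
class SimSpeciesTree:
    """Rooted ultrametric species tree with demographic parameters.

    ``newick`` carries node ages in *years* (ultrametric); internal nodes may
    be labelled so they can serve as introgression donors/recipients.  Ages
    convert to coalescent units as ``years * gens_per_year / (2 N_e)``.
    ``accessions`` maps accession id -> species label (>= 1 per species);
    each diploid accession is simulated as two sampled lineages of its
    species' population.
    """

    newick: str
    accessions: dict[str, str]
    ne: float = 1e5
    gens_per_year: float = 2.5
    events: tuple[SimIntrogressionEvent, ...] = ()
    outgroup_species: str | None = None

    def __post_init__(self) -> None:
        t = self._dendropy_tree()
        ages = {}
        for leaf in t.leaf_node_iter():
            ages[leaf.taxon.label] = leaf.distance_from_root()
        depths = np.array(list(ages.values()))
        if np.ptp(depths) > 1e-6 * max(depths.max(), 1.0):
            raise ValueError("species tree must be ultrametric")
        species = set(ages)
        missing = set(self.accessions.values()) - species
        if missing:
            raise ValueError(f"accession species not in tree: {sorted(missing)}")

    # -- structure ----------------------------------------------------------

    def _dendropy_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick", suppress_internal_node_taxa=False
        )

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.accessions.values()))

    def accessions_for(self, species: str) -> list[str]:
        return [a for a, s in self.accessions.items() if s == species]

    @property
    def accession_order(self) -> list[str]:
        """Accessions grouped by species (simulation sample order)."""
        return [a for sp in self.species for a in self.accessions_for(sp)]

    @property
    def ingroup_accessions(self) -> list[str]:
        return [
            a
            for a in self.accession_order
            if self.accessions[a] != self.outgroup_species
        ]

    @property
    def outgroup_accessions(self) -> list[str]:
        return [
            a
            for a in self.accession_order
            if self.accessions[a] == self.outgroup_species
        ]

    def coalescent_units(self, years: float) -> float:
        return years * self.gens_per_year / (2.0 * self.ne)

    # -- msprime ------------------------------------------------------------

    def demography(
        self, events: tuple[SimIntrogressionEvent, ...] | None = None
    ) -> msprime.Demography:
        """Convert to an msprime demography (branch lengths in generations).

        When *events* is given, each pulse is added as a complete lineage
        rerouting (mass migration, backwards in time, recipient -> donor) at
        the event time; callers draw per-gene whether a gene uses the pulsed
        or the base demography.
        """
        t = self._dendropy_tree()
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * self.gens_per_year
        sio = _io.StringIO()
        t.write(
            file=sio,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        dem = msprime.Demography.from_species_tree(sio.getvalue(), initial_size=self.ne)
        pop_names = {p.name for p in dem.populations}
        for ev in events or ():
            for lineage in (ev.donor, ev.recipient):
                if lineage not in pop_names:
                    raise ValueError(f"unknown lineage {lineage!r} in event")
            dem.add_mass_migration(
                time=ev.time_years * self.gens_per_year,
                source=ev.recipient,
                dest=ev.donor,
                proportion=1.0,
            )
        dem.sort_events()
        return dem

    def accession_tree(self, within_species_age: float = 5e3) -> dendropy.Tree:
        """Accession-level tree: each species expanded into a resolved ladder.

        Within-species splits are placed at *within_species_age* years, so
        every trio of accessions is resolved.
        """
        t = self._dendropy_tree()
        tns = dendropy.TaxonNamespace()
        for leaf in list(t.leaf_node_iter()):
            accs = self.accessions_for(leaf.taxon.label)
            if not accs:
                raise ValueError(f"species {leaf.taxon.label!r} has no accessions")
            node = leaf
            node.taxon = None
            remaining = list(accs)
            age = within_species_age
            while len(remaining) > 1:
                tip = dendropy.Node()
                tip.taxon = dendropy.Taxon(label=remaining.pop(0))
                tip.edge.length = age
                inner = dendropy.Node()
                inner.edge.length = 0.0
                node.add_child(tip)
                node.add_child(inner)
                node = inner
                age *= 0.5
            tip = dendropy.Node()
            tip.taxon = dendropy.Taxon(label=remaining[0])
            tip.edge.length = age
            node.add_child(tip)
        out = dendropy.Tree.get(
            data=t.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=tns,
        )
        return out


def inject_introgression(
    tree: SimSpeciesTree, event: SimIntrogressionEvent
) -> SimSpeciesTree:
    """Return a copy of *tree* carrying an additional introgression pulse."""
    # the event must postdate (be younger than) the donor/recipient split
    t = tree._dendropy_tree()
    labels = {}
    for node in t.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label:
            labels[label] = node
    for name in (event.donor, event.recipient):
        if name not in labels:
            raise ValueError(f"lineage {name!r} not found in species tree")
    mrca_age = None
    a, b = labels[event.donor], labels[event.recipient]
    anc_a = {id(n): n for n in a.ancestor_iter(inclusive=True)}
    for n in b.ancestor_iter(inclusive=True):
        if id(n) in anc_a:
            mrca_age = n.distance_from_tip()
            break
    if mrca_age is not None and event.time_years >= mrca_age:
        raise ValueError(
            "introgression time must be younger than the donor/recipient divergence"
        )
    return replace(tree, events=tree.events + (event,))


# ---------------------------------------------------------------------------
# default study-like tree
# ---------------------------------------------------------------------------


def _newick_from_ages(node) -> str:
    """node = (label, age, [children]) with ages in years; leaves have age 0."""

    def rec(n, parent_age):
        label, age, children = n
        if not children:
            return f"{label}:{parent_age - age:.6f}"
        inner = ",".join(rec(c, age) for c in children)
        return f"({inner}){label}:{parent_age - age:.6f}"

    label, age, children = node
    inner = ",".join(rec(c, age) for c in children)
    return f"({inner}){label};"


def default_species_tree() -> SimSpeciesTree:
    """A 14-species, 29-accession tree emulating a rapid radiation.

    Four ingroup subclades (6 accessions each except the first, which has 9)
    plus a two-accession outgroup; the backbone internodes are ~1 coalescent
    unit (80 ky at N_e = 1e5, 2.5 generations/year) so incomplete lineage
    sorting is extensive, while subclade stems are long enough that the
    groups themselves are well supported.
    """
    leaf = lambda name: (name, 0.0, [])
    tree = (
        "anc_all",
        4.0e6,
        [
            leaf("out1"),
            (
                "anc_ingroup",
                2.48e6,
                [
                    ("anc_hir", 1.3e6, [leaf("hir1"), ("anc_hir23", 0.8e6, [leaf("hir2"), leaf("hir3")])]),
                    (
                        "anc_epa",
                        2.40e6,
                        [
                            ("anc_per", 2.35e6, [leaf("per1"), ("anc_per23", 1.2e6, [leaf("per2"), leaf("per3")])]),
                            (
                                "anc_ea",
                                2.32e6,
                                [
                                    ("anc_arc", 0.9e6, [leaf("arc1"), ("anc_arc23", 0.5e6, [leaf("arc2"), leaf("arc3")])]),
                                    (
                                        "anc_esc",
                                        0.30e6,
                                        [
                                            ("anc_esc12", 0.22e6, [leaf("esc1"), leaf("esc2")]),
                                            ("anc_esc34", 0.26e6, [leaf("esc3"), leaf("esc4")]),
                                        ],
                                    ),
                                ],
                            ),
                        ],
                    ),
                ],
            ),
        ],
    )
    species = [
        "esc1", "esc2", "esc3", "esc4",
        "arc1", "arc2", "arc3",
        "per1", "per2", "per3",
        "hir1", "hir2", "hir3",
        "out1",
    ]
    accessions: dict[str, str] = {}
    for sp in species:
        n = 3 if sp == "esc1" else 2
        for i in range(1, n + 1):
            accessions[f"{sp}_{i}"] = sp
    return SimSpeciesTree(
        newick=_newick_from_ages(tree),
        accessions=accessions,
        outgroup_species="out1",
    )


def species_group(accession: str) -> str:
    """Major-group label for accessions of :func:`default_species_tree`."""
    return {"e": "Esculentum", "a": "Arcanum", "p": "Peruvianum", "h": "Hirsutum", "o": "Outgroup"}[accession[0]]


# ---------------------------------------------------------------------------
# gene-tree simulation
# ---------------------------------------------------------------------------


@dataclass
class SimGeneTrees:
    """Batch of per-gene coalescent genealogies.

    ``tree_sequences[g]`` is the tskit tree sequence of gene *g*;
    ``sample_labels`` names each sample node (``acc`` for haploid sampling,
    ``acc|0`` / ``acc|1`` for diploid).  ``introgressed`` flags the genes
    that were rerouted through the donor (the truth table).
    """

    species_tree: SimSpeciesTree
    tree_sequences: list
    accession_order: list[str]
    lineages_per_accession: int
    introgressed: np.ndarray
    seed: int

    @property
    def n_genes(self) -> int:
        return len(self.tree_sequences)

    def sample_labels(self) -> list[str]:
        if self.lineages_per_accession == 1:
            return list(self.accession_order)
        return [
            f"{acc}|{i}"
            for acc in self.accession_order
            for i in range(self.lineages_per_accession)
        ]

    def newick(self, gene: int, haploid: bool = False) -> str:
        """Newick string of one gene tree, tips labelled by accession.

        With ``haploid=True`` a diploid simulation is reduced to one lineage
        per accession (the first of the pair) so tip labels are accession
        ids; this is the form consumed by topology counting.
        """
        ts = self.tree_sequences[gene]
        labels = self.sample_labels()
        if haploid and self.lineages_per_accession == 2:
            keep = [2 * i for i in range(len(self.accession_order))]
            ts = ts.simplify(samples=[ts.samples()[j] for j in keep])
            labels = list(self.accession_order)
        t = ts.first()
        node_labels = {ts.samples()[j]: labels[j] for j in range(len(labels))}
        return t.as_newick(node_labels=node_labels)

    def newicks(self, haploid: bool = False) -> list[str]:
        return [self.newick(g, haploid=haploid) for g in range(self.n_genes)]


def simulate_gene_trees(
    tree: SimSpeciesTree,
    n_genes: int,
    seed: int,
    lineages_per_accession: int = 1,
    introgressed_genes: np.ndarray | None = None,
) -> SimGeneTrees:
    """Simulate independent per-gene genealogies under the MSC.

    Each gene tree samples ``lineages_per_accession`` lineages per accession
    (1 for gene-tree topology work, 2 for diploid variant simulation),
    constrained by the species tree: lineages from different species cannot
    coalesce more recently than the species divergence.

    Introgression pulses attached to *tree* are applied per gene: gene *g*
    is introgressed with probability ``event.proportion`` (or exactly when
    listed in *introgressed_genes*), in which case its genealogy is simulated
    with the recipient's lineages rerouted through the donor at the event
    time.  The flags are returned as the truth table.
    """
    rng = np.random.default_rng(seed)
    order = tree.accession_order
    counts: dict[str, int] = {}
    for acc in order:
        counts[tree.accessions[acc]] = counts.get(tree.accessions[acc], 0) + 1
    if tree.events:
        gamma = max(ev.proportion for ev in tree.events)
        if introgressed_genes is not None:
            flags = np.zeros(n_genes, dtype=bool)
            flags[np.asarray(list(introgressed_genes), dtype=int)] = True
        else:
            flags = rng.random(n_genes) < gamma
    else:
        flags = np.zeros(n_genes, dtype=bool)

    out: list = [None] * n_genes
    for use_pulse in (False, True):
        idx = np.nonzero(flags == use_pulse)[0]
        if len(idx) == 0:
            continue
        dem = tree.demography(tree.events if use_pulse else None)
        # model ploidy stays 2 so time scales in 2*N_e generations; the
        # per-set ploidy controls how many lineages each accession contributes
        sample_sets = [
            msprime.SampleSet(n, population=sp, ploidy=lineages_per_accession)
            for sp, n in counts.items()
        ]
        reps = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            ploidy=2,
            sequence_length=1,
            num_replicates=len(idx),
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        for g, ts in zip(idx, reps):
            out[int(g)] = ts
    return SimGeneTrees(
        species_tree=tree,
        tree_sequences=out,
        accession_order=order,
        lineages_per_accession=lineages_per_accession,
        introgressed=flags,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def make_gene_models(
    n_genes: int,
    seed: int,
    chromosome: str = "chr1",
    gene_spacing: int = 10_000,
    cds_offset: int = 100,
    n_codons: int = 300,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Lay synthetic single-exon genes on one chromosome, 10 kb apart."""
    rng = np.random.default_rng(seed)
    models, cds = [], {}
    for g in range(n_genes):
        start = g * gene_spacing + cds_offset
        gid = f"gene{g:05d}"
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=chromosome,
                strand="+",
                coding_intervals=((start, start + 3 * n_codons),),
            )
        )
        cds[gid] = _random_cds(rng, n_codons)
    return models, cds


def simulate_variants(
    gene_trees: SimGeneTrees,
    sites_per_gene: int,
    seed: int,
    gene_spacing: int = 10_000,
    cds_offset: int = 100,
    n_codons: int = 300,
    chromosome: str = "chr1",
) -> tuple[VariantMatrix, list[GeneModel], dict[str, str]]:
    """Place biallelic variable sites on the simulated genealogies.

    Each gene contributes *sites_per_gene* sites at distinct CDS offsets; a
    site's mutated branch is drawn with probability proportional to branch
    length (infinite sites: the derived-allele carriers are exactly the
    leaves below that branch).  The reference/ancestral base is the gene's
    reference CDS base at that offset.  Diploid genotypes pair the two
    sampled lineages of each accession, so heterozygosity arises naturally.
    """
    if gene_trees.lineages_per_accession != 2:
        raise ValueError("variant simulation requires diploid gene trees")
    if sites_per_gene > 3 * n_codons:
        raise ValueError("sites_per_gene exceeds CDS length")
    rng = np.random.default_rng(seed)
    models, cds = make_gene_models(
        gene_trees.n_genes,
        seed=int(rng.integers(1, 2**31 - 1)),
        chromosome=chromosome,
        gene_spacing=gene_spacing,
        cds_offset=cds_offset,
        n_codons=n_codons,
    )
    order = gene_trees.accession_order
    k = len(order)
    chroms, poss, refs, genos = [], [], [], []
    for g, ts in enumerate(gene_trees.tree_sequences):
        t = ts.first()
        samples = list(ts.samples())
        nodes, lens = [], []
        for u in t.nodes():
            parent = t.parent(u)
            if parent != -1:
                nodes.append(u)
                lens.append(t.time(parent) - t.time(u))
        lens = np.asarray(lens, dtype=float)
        p = lens / lens.sum()
        branch_draws = rng.choice(len(nodes), size=sites_per_gene, p=p)
        offsets = np.sort(rng.choice(3 * n_codons, size=sites_per_gene, replace=False))
        gene_start = models[g].coding_intervals[0][0]
        seq = cds[models[g].gene_id]
        sample_pos = {s: j for j, s in enumerate(samples)}
        for off, bi in zip(offsets, branch_draws):
            anc = seq[off]
            derived = BASES[
                rng.choice([c for c in range(4) if BASES[c] != anc])
            ]
            carriers = np.zeros(len(samples), dtype=bool)
            for leaf in t.leaves(nodes[bi]):
                carriers[sample_pos[leaf]] = True
            if carriers.all() or not carriers.any():
                continue  # mutation above the root of the sample set
            alleles = np.where(carriers, BASES.index(derived), BASES.index(anc))
            pair = alleles.reshape(k, 2).astype(np.int8)
            chroms.append(chromosome)
            poss.append(gene_start + int(off))
            refs.append(BASES.index(anc))
            genos.append(np.sort(pair, axis=1))
    n = len(poss)
    matrix = VariantMatrix(
        accessions=list(order),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=np.int8),
        geno=(np.stack(genos) if n else np.empty((0, k, 2), dtype=np.int8)),
        depth=np.full((n, k), 30, dtype=np.int32),
        mq=np.full((n, k), 60, dtype=np.int32),
    )
    return matrix, models, cds


# ---------------------------------------------------------------------------
# truth injection
# ---------------------------------------------------------------------------


def clade_accession_sets(tree: SimSpeciesTree) -> list[frozenset[str]]:
    """Accession sets of every clade of the species tree (species included)."""
    t = tree._dendropy_tree()
    sets = []
    for node in t.preorder_node_iter():
        species = [
            leaf.taxon.label for leaf in node.leaf_iter()
        ]
        accs = frozenset(a for sp in species for a in tree.accessions_for(sp))
        sets.append(accs)
    return sets


def partition_congruent_with_clade(
    tree: SimSpeciesTree, group: frozenset[str] | set[str]
) -> bool:
    """True when *group* exactly matches some clade's accession set."""
    g = frozenset(group)
    return any(g == s for s in clade_accession_sets(tree))


def _insert_sites(matrix: VariantMatrix, rows: list[dict]) -> VariantMatrix:
    """Insert/overwrite site rows (dicts with chrom,pos,ref,geno) keeping order."""
    chrom = list(matrix.chrom)
    pos = list(matrix.pos)
    ref = list(matrix.ref)
    geno = list(matrix.geno)
    for row in rows:
        key = (row["chrom"], row["pos"])
        existing = [
            i for i, (c, p) in enumerate(zip(chrom, pos)) if (c, p) == key
        ]
        if existing:
            i = existing[0]
            ref[i], geno[i] = row["ref"], row["geno"]
        else:
            i = int(np.searchsorted(np.array(pos), row["pos"]))
            chrom.insert(i, row["chrom"])
            pos.insert(i, row["pos"])
            ref.insert(i, row["ref"])
            geno.insert(i, row["geno"])
    n, k = len(pos), matrix.n_accessions
    return VariantMatrix(
        accessions=list(matrix.accessions),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=np.int8),
        geno=np.stack(geno) if n else np.empty((0, k, 2), dtype=np.int8),
        depth=np.full((n, k), 30, dtype=np.int32),
        mq=np.full((n, k), 60, dtype=np.int32),
    )


def _make_diagnostic_site(
    matrix: VariantMatrix,
    model: GeneModel,
    seq: str,
    offset: int,
    groups: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict, int, int]:
    """Build a site row fixed for allele X in group 1 and Y in group 2."""
    gene_start = model.coding_intervals[0][0]
    posn = gene_start + offset
    anc_code = BASES.index(seq[offset])
    derived_code = int(rng.choice([c for c in range(4) if c != anc_code]))
    k = matrix.n_accessions
    geno = np.zeros((k, 2), dtype=np.int8)
    for j, acc in enumerate(matrix.accessions):
        code = derived_code if groups.get(acc) == 2 else anc_code
        geno[j] = (code, code)
    row = {
        "chrom": model.chromosome,
        "pos": posn,
        "ref": np.int8(anc_code),
        "geno": geno,
    }
    return row, anc_code, derived_code


def inject_environment_alleles(
    matrix: VariantMatrix,
    groups: dict[str, int],
    n_sites: int,
    gene_models: list[GeneModel],
    cds: dict[str, str],
    seed: int,
    species_tree: SimSpeciesTree | None = None,
    factor: str = "factor",
    genes: list[str] | None = None,
) -> tuple[VariantMatrix, pd.DataFrame]:
    """Inject *n_sites* environment-sorted nonsynonymous sites.

    *groups* maps contrasted accessions to group 1 or 2.  Each injected site
    sits at a second codon position (every second-position change is
    nonsynonymous under the standard code, asserted at runtime); group-1
    accessions are fixed for the ancestral base, group-2 for a derived base,
    and uncontrasted accessions carry the ancestral base.  One site is placed
    per gene (distinct genes).  Refuses a partition congruent with a species
    clade, which would not emulate environment-driven sorting.
    """
    if species_tree is not None:
        for side in (1, 2):
            members = frozenset(a for a, g in groups.items() if g == side)
            if partition_congruent_with_clade(species_tree, members):
                raise ValueError(
                    "partition is congruent with a clade of the species tree"
                )
    rng = np.random.default_rng(seed)
    by_id = {m.gene_id: m for m in gene_models}
    if genes is None:
        pool = [m.gene_id for m in gene_models]
        genes = list(rng.choice(pool, size=n_sites, replace=False)) if n_sites else []
    used = {(c, int(p)) for c, p in zip(matrix.chrom, matrix.pos)}
    rows, records = [], []
    for gid in genes[:n_sites]:
        model = by_id[gid]
        seq = cds[gid]
        gene_start = model.coding_intervals[0][0]
        offs = [
            off
            for off in range(1, len(seq), 3)  # second codon positions
            if (model.chromosome, gene_start + off) not in used
        ]
        offset = int(rng.choice(offs))
        row, anc, der = _make_diagnostic_site(matrix, model, seq, offset, groups, rng)
        cls = classify_substitution(model, seq, row["pos"], BASES[anc], BASES[der])
        assert cls is SubstitutionClass.NONSYNONYMOUS
        used.add((model.chromosome, row["pos"]))
        rows.append(row)
        records.append(
            {
                "gene": gid,
                "position": row["pos"],
                "factor": factor,
                "allele_group1": BASES[anc],
                "allele_group2": BASES[der],
                "class": "nonsynonymous",
            }
        )
    truth = pd.DataFrame(
        records,
        columns=["gene", "position", "factor", "allele_group1", "allele_group2", "class"],
    )
    if not rows:
        return matrix, truth
    return _insert_sites(matrix, rows), truth


def inject_linked_block(
    matrix: VariantMatrix,
    groups: dict[str, int],
    gene: str,
    n_nonsyn: int,
    n_syn: int,
    gene_models: list[GeneModel],
    cds: dict[str, str],
    seed: int,
    factor: str = "factor",
) -> tuple[VariantMatrix, pd.DataFrame]:
    """Inject a linked haplotype block tracking the partition in one gene.

    Emulates an introgressed segment: *n_nonsyn* second-position sites plus
    *n_syn* four-fold-degenerate third-position (synonymous) sites, all
    perfectly associated with the partition.  Such a block is what the
    linked-synonymous check flags as introgression-ambiguous.
    """
    rng = np.random.default_rng(seed)
    model = {m.gene_id: m for m in gene_models}[gene]
    seq = cds[gene]
    gene_start = model.coding_intervals[0][0]
    used = {(c, int(p)) for c, p in zip(matrix.chrom, matrix.pos)}
    nonsyn_offs = [
        off
        for off in range(1, len(seq), 3)
        if (model.chromosome, gene_start + off) not in used
    ]
    syn_offs = [
        off
        for off in range(2, len(seq), 3)
        if seq[off - 2 : off] in _FOURFOLD_PREFIXES
        and (model.chromosome, gene_start + off) not in used
    ]
    if len(nonsyn_offs) < n_nonsyn or len(syn_offs) < n_syn:
        raise ValueError("gene too short for requested block")
    chosen = [
        (int(o), "nonsynonymous")
        for o in rng.choice(nonsyn_offs, size=n_nonsyn, replace=False)
    ] + [(int(o), "synonymous") for o in rng.choice(syn_offs, size=n_syn, replace=False)]
    rows, records = [], []
    for offset, cls_name in chosen:
        row, anc, der = _make_diagnostic_site(matrix, model, seq, offset, groups, rng)
        cls = classify_substitution(model, seq, row["pos"], BASES[anc], BASES[der])
        assert cls.value == cls_name, (cls, cls_name, offset)
        rows.append(row)
        records.append(
            {
                "gene": gene,
                "position": row["pos"],
                "factor": factor,
                "allele_group1": BASES[anc],
                "allele_group2": BASES[der],
                "class": cls_name,
            }
        )
    truth = pd.DataFrame(records)
    return _insert_sites(matrix, rows), truth


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class SimOutput:
    """Bundle of simulated data plus the truth tables used by recovery tests."""

    species_tree: SimSpeciesTree
    matrix: VariantMatrix
    gene_models: list[GeneModel]
    cds: dict[str, str]
    gene_trees: SimGeneTrees
    introgression_truth: pd.DataFrame
    env_truth: pd.DataFrame
    seed: int


def simulate_dataset(
    tree: SimSpeciesTree | None = None,
    n_genes: int = 200,
    sites_per_gene: int = 6,
    seed: int = 1,
    introgressed_genes: np.ndarray | None = None,
    env_groups: dict[str, int] | None = None,
    n_env_sites: int = 0,
    gene_spacing: int = 10_000,
) -> SimOutput:
    """Simulate a full synthetic dataset with truth tables.

    Defaults reproduce the study-like conditions of
    :func:`default_species_tree` (29 diploid accessions, N_e = 1e5,
    2.5 generations/year) at a desk-scale number of genes.
    """
    tree = tree or default_species_tree()
    ss = np.random.SeedSequence(seed)
    s_trees, s_vars, s_env = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(3))
    gts = simulate_gene_trees(
        tree, n_genes, seed=s_trees, lineages_per_accession=2,
        introgressed_genes=introgressed_genes,
    )
    matrix, models, cds = simulate_variants(
        gts, sites_per_gene, seed=s_vars, gene_spacing=gene_spacing
    )
    intro_truth = pd.DataFrame(
        {
            "gene": [m.gene_id for m in models],
            "start": [m.coding_intervals[0][0] for m in models],
            "introgressed": gts.introgressed,
        }
    )
    env_truth = pd.DataFrame(
        columns=["gene", "position", "factor", "allele_group1", "allele_group2", "class"]
    )
    if env_groups and n_env_sites:
        matrix, env_truth = inject_environment_alleles(
            matrix, env_groups, n_env_sites, models, cds,
            seed=s_env, species_tree=tree,
        )
    return SimOutput(
        species_tree=tree,
        matrix=matrix,
        gene_models=models,
        cds=cds,
        gene_trees=gts,
        introgression_truth=intro_truth,
        env_truth=env_truth,
        seed=seed,
    )
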
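"""Small text-format helpers shared by the CLI: gene models, CDS FASTA,
metadata/partition tables, species-tree configs, and gene-tree lists."""

from __future__ import annotations

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import SimIntrogressionEvent, SimSpeciesTree
from .variant_core import GeneModel

__all__ = [
    "write_gene_models",
    "read_gene_models",
    "write_cds_fasta",
    "read_cds_fasta",
    "write_metadata",
    "read_metadata",
    "read_partition_table",
    "write_tree_config",
    "read_tree_config",
    "write_tree_list",
    "read_tree_list",
]


def write_gene_models(models: list[GeneModel], path: str) -> None:
    """BED-like TSV: gene, chrom, strand, frame, and 0-based half-open intervals."""
    with open(path, "w") as fh:
        fh.write("#gene\tchrom\tstrand\tframe\tintervals\n")
        for m in models:
            ivs = ",".join(f"{s}-{e}" for s, e in m.coding_intervals)
            fh.write(f"{m.gene_id}\t{m.chromosome}\t{m.strand}\t{m.frame_offset}\t{ivs}\n")


def read_gene_models(path: str) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gene, chrom, strand, frame, ivs = line.rstrip("\n").split("\t")
            intervals = tuple(
                (int(s), int(e)) for s, e in (p.split("-") for p in ivs.split(","))
            )
            models.append(GeneModel(gene, chrom, strand, intervals, int(frame)))
    return models


def write_cds_fasta(cds: dict[str, str], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=g, description="") for g, s in cds.items()), path, "fasta"
    )


def read_cds_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_metadata(rows: list[dict], path: str) -> None:
    """accession / species / group table."""
    with open(path, "w") as fh:
        fh.write("accession\tspecies\tgroup\n")
        for r in rows:
            fh.write(f"{r['accession']}\t{r['species']}\t{r.get('group', '')}\n")


def read_metadata(path: str) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def read_partition_table(path: str, factor: str | None = None) -> dict[str, dict[str, int]]:
    """TSV (accession, factor, group in {1,2}) -> factor -> accession -> group."""
    out: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            if factor is not None and row["factor"] != factor:
                continue
            out.setdefault(row["factor"], {})[row["accession"]] = int(row["group"])
    return out


def write_tree_config(tree: SimSpeciesTree, path: str) -> None:
    cfg = {
        "newick": tree.newick,
        "ne": tree.ne,
        "gens_per_year": tree.gens_per_year,
        "accessions": dict(tree.accessions),
        "outgroup_species": tree.outgroup_species,
        "events": [
            {
                "donor": e.donor,
                "recipient": e.recipient,
                "time_years": e.time_years,
                "proportion": e.proportion,
            }
            for e in tree.events
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_tree_config(path: str) -> SimSpeciesTree:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    events = tuple(
        SimIntrogressionEvent(
            donor=e["donor"],
            recipient=e["recipient"],
            time_years=float(e["time_years"]),
            proportion=float(e["proportion"]),
        )
        for e in cfg.get("events", [])
    )
    return SimSpeciesTree(
        newick=cfg["newick"],
        accessions=cfg["accessions"],
        ne=float(cfg.get("ne", 1e5)),
        gens_per_year=float(cfg.get("gens_per_year", 2.5)),
        events=events,
        outgroup_species=cfg.get("outgroup_species"),
    )


def write_tree_list(newicks: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for nwk in newicks:
            fh.write(nwk.rstrip("\n;") + ";\n")


def read_tree_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
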
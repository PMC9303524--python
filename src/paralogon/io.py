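"""Readers and writers for the package's plain-text exchange formats.

All tabular formats are tab-separated with ``#`` comment lines.  Locus
tables carry columns ``family_id  genome_id  chromosome_id  [position]``;
alignment blocks travel as FASTA plus a two-column TSV sidecar
(``seq_id  subfamily``); gene models use a small documented YAML schema;
trees are newick.  Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignmentBlock,
    Exon,
    GeneLocus,
    GeneModel,
    Isoform,
    LinkageGroup,
    OrthologTable,
    ParalogTree,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_loci",
    "write_loci",
    "read_linkage_group",
    "write_linkage_group",
    "read_gene_models",
    "write_gene_models",
    "read_alignment",
    "write_alignment",
    "read_tree",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _data_lines(path: PathLike):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_loci(path: PathLike, genomes: Optional[list[str]] = None) -> OrthologTable:
    """Read a TSV locus table into an :class:`OrthologTable`.

    Rows have 3 or 4 tab-separated fields: family, genome, chromosome and an
    optional 0-based ordinal position.  Multiple rows per (family, genome)
    are multiple gene copies.
    """
    data: dict[str, dict[str, list[GeneLocus]]] = {}
    copy_counter: dict[tuple[str, str], int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise ParseError(f"{path}:{lineno}: expected 3-4 tab-separated fields, got {len(fields)}")
        family, genome, chrom = (f.strip() for f in fields[:3])
        if not family or not genome or not chrom:
            raise ParseError(f"{path}:{lineno}: empty field")
        position: Optional[int] = None
        if len(fields) == 4 and fields[3].strip() not in ("", "."):
            try:
                position = int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: position {fields[3]!r} is not an integer") from exc
        n = copy_counter.get((family, genome), 0)
        copy_counter[(family, genome)] = n + 1
        gene_id = family if n == 0 else f"{family}.{n + 1}"
        try:
            locus = GeneLocus(gene_id, genome, chrom, position)
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        data.setdefault(family, {}).setdefault(genome, []).append(locus)
    return OrthologTable(data, genomes=genomes)


def write_loci(table: OrthologTable, path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# family_id\tgenome_id\tchromosome_id\tposition\n")
        for family in table.families:
            for genome in table.genomes:
                for locus in table.loci(family, genome):
                    pos = "." if locus.position is None else str(locus.position)
                    fh.write(f"{family}\t{genome}\t{locus.chromosome_id}\t{pos}\n")


def read_linkage_group(path: PathLike, name: Optional[str] = None) -> LinkageGroup:
    """One family id per line; '#' comments; the first comment may name the group."""
    members: list[str] = []
    for _, line in _data_lines(path):
        members.append(line.strip())
    return LinkageGroup(name or Path(path).stem, members)


def write_linkage_group(group: LinkageGroup, path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# linkage group: {group.name}\n")
        for member in group.members:
            fh.write(member + "\n")


# ---------------------------------------------------------------------------
# Gene-model YAML schema
#
# genes:
#   - gene_id: TCF7
#     exons:
#       - {label: I, motifs: [BCBD]}
#       - {label: III}
#     alt_tss: [III]
#     isoforms:
#       - {name: E, path: [I, III], start_exon: I, start_offset_codon: 0}
#     flags: {met33: true}
#     unknown_features: [DELTA_N_ISOFORM]
# ---------------------------------------------------------------------------


def _gene_model_from_mapping(entry: dict) -> GeneModel:
    try:
        gene_id = entry["gene_id"]
        exons = tuple(
            Exon(str(e["label"]), frozenset(str(m).upper() for m in e.get("motifs", ())))
            for e in entry["exons"]
        )
        isoforms = tuple(
            Isoform(
                name=str(i["name"]),
                splice_path=tuple(str(x) for x in i["path"]),
                start_exon=str(i.get("start_exon", i["path"][0])),
                start_offset_codon=i.get("start_offset_codon"),
            )
            for i in entry.get("isoforms", ())
        )
    except KeyError as exc:
        raise ParseError(f"gene-model entry missing required key {exc}") from exc
    return GeneModel(
        gene_id=gene_id,
        exons=exons,
        isoforms=isoforms,
        alt_tss=frozenset(str(x) for x in entry.get("alt_tss", ())),
        flags=dict(entry.get("flags", {})),
        unknown_features=tuple(entry.get("unknown_features", ())),
    )


def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read the documented YAML gene-model schema; invalid models raise."""
    with open(path, "rt", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "genes" not in doc:
        raise ParseError(f"{path}: expected a mapping with a top-level 'genes' list")
    models = [_gene_model_from_mapping(entry) for entry in doc["genes"]]
    seen: set[str] = set()
    for m in models:
        if m.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {m.gene_id}")
        seen.add(m.gene_id)
    return models


def write_gene_models(models: list[GeneModel], path: PathLike) -> None:
    doc = {
        "genes": [
            {
                "gene_id": m.gene_id,
                "exons": [
                    {"label": e.label, **({"motifs": sorted(e.motifs)} if e.motifs else {})}
                    for e in m.exons
                ],
                "alt_tss": sorted(m.alt_tss),
                "isoforms": [
                    {
                        "name": i.name,
                        "path": list(i.splice_path),
                        "start_exon": i.start_exon,
                        **(
                            {"start_offset_codon": i.start_offset_codon}
                            if i.start_offset_codon is not None
                            else {}
                        ),
                    }
                    for i in m.isoforms
                ],
                **({"flags": dict(m.flags)} if m.flags else {}),
                **({"unknown_features": list(m.unknown_features)} if m.unknown_features else {}),
            }
            for m in models
        ]
    }
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_alignment(fasta_path: PathLike, labels_path: PathLike, name: Optional[str] = None) -> AlignmentBlock:
    """Read an aligned FASTA plus its ``seq_id<TAB>subfamily`` sidecar."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records")
    sequences = {rec.id: str(rec.seq).upper() for rec in records}
    labels: dict[str, str] = {}
    for lineno, line in _data_lines(labels_path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{labels_path}:{lineno}: expected 'seq_id<TAB>subfamily'")
        labels[fields[0].strip()] = fields[1].strip()
    missing = set(sequences) - set(labels)
    if missing:
        raise ValidationError(f"missing subfamily label for: {sorted(missing)}")
    return AlignmentBlock(name or Path(fasta_path).stem, sequences, {s: labels[s] for s in sequences})


def write_alignment(block: AlignmentBlock, fasta_path: PathLike, labels_path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in block.sequences.items()
    ]
    with open(fasta_path, "wt", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(labels_path, "wt", encoding="utf-8") as fh:
        fh.write("# seq_id\tsubfamily\n")
        for sid in block.sequences:
            fh.write(f"{sid}\t{block.subfamily[sid]}\n")


def read_tree(path: PathLike) -> ParalogTree:
    with open(path, "rt", encoding="utf-8") as fh:
        return ParalogTree.from_newick(fh.read())
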
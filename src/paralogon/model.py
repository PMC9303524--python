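"""Core domain types for post-WGD paralogy analysis.

The objects here are deliberately small and validated on construction:
gene placements on chromosomes (:class:`GeneLocus`, :class:`OrthologTable`),
ancestral linkage-group membership (:class:`LinkageGroup`), exon/motif/isoform
gene architectures (:class:`GeneModel`), labelled protein alignment blocks
(:class:`AlignmentBlock`) and a rooted paralog tree (:class:`ParalogTree`).

Chromosome coordinates are ordinal gene ranks, not base pairs: every rule in
the synteny analysis depends only on co-chromosome membership and flanking
order, never on physical distance, and strand is ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "ValidationError",
    "GeneLocus",
    "LinkageGroup",
    "OrthologTable",
    "Exon",
    "Isoform",
    "GeneModel",
    "AlignmentBlock",
    "ParalogTree",
    "MOTIF_VOCABULARY",
]


class ValidationError(ValueError):
    """An object violated one of its structural invariants."""


#: Motifs/domains a gene-model exon may carry.  BCBD = beta-catenin binding
#: domain; HELPER/COREPRESSOR = the two halves of the co-repressor region;
#: HMG = High Mobility Group box; NLS = nuclear localisation signal;
#: CRARF/CRALF = the two C-clamp motifs; CTBP = CtBP-interaction motif.
MOTIF_VOCABULARY = frozenset(
    {
        "BCBD",
        "LVPQ",
        "SXXSS",
        "HELPER",
        "COREPRESSOR",
        "HMG",
        "NLS",
        "CRARF",
        "CRALF",
        "CTBP",
    }
)


@dataclass(frozen=True)
class GeneLocus:
    """A gene copy placed on a chromosome of one genome.

    ``position`` is the 0-based ordinal rank of the gene along its
    chromosome, or ``None`` when order information is unavailable.
    """

    gene_id: str
    genome_id: str
    chromosome_id: str
    position: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("gene_id", "genome_id", "chromosome_id"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value or any(c.isspace() for c in value):
                raise ValidationError(f"{name} must be a non-empty whitespace-free token, got {value!r}")
        if self.position is not None:
            if not isinstance(self.position, int) or isinstance(self.position, bool) or self.position < 0:
                raise ValidationError(f"position must be a non-negative integer or None, got {self.position!r}")


@dataclass(frozen=True)
class LinkageGroup:
    """An ancestral linkage group: a named, ordered set of gene-family ids."""

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members: Iterable[str]):
        members = tuple(members)
        if not members:
            raise ValidationError("linkage group must have at least one member")
        if len(set(members)) != len(members):
            raise ValidationError("linkage group members must be unique")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", members)

    def __contains__(self, family_id: str) -> bool:
        return family_id in set(self.members)

    def __len__(self) -> int:
        return len(self.members)


class OrthologTable:
    """Per-family, per-genome lists of gene loci.

    An empty locus list means "ortholog searched for but absent"; a genome
    missing from :attr:`genomes` means "genome not surveyed".  The two are
    deliberately distinct.
    """

    def __init__(
        self,
        data: Mapping[str, Mapping[str, Sequence[GeneLocus]]],
        genomes: Optional[Sequence[str]] = None,
    ):
        self._data: dict[str, dict[str, tuple[GeneLocus, ...]]] = {}
        seen_genomes: list[str] = []
        for family, per_genome in data.items():
            self._data[family] = {}
            for genome, loci in per_genome.items():
                loci = tuple(loci)
                for locus in loci:
                    if locus.genome_id != genome:
                        raise ValidationError(
                            f"locus {locus.gene_id} filed under genome {genome} "
                            f"but carries genome_id {locus.genome_id}"
                        )
                self._data[family][genome] = loci
                if genome not in seen_genomes:
                    seen_genomes.append(genome)
        if genomes is None:
            self.genomes: tuple[str, ...] = tuple(seen_genomes)
        else:
            self.genomes = tuple(genomes)
            missing = set(seen_genomes) - set(self.genomes)
            if missing:
                raise ValidationError(f"loci reference undeclared genomes: {sorted(missing)}")
        self._validate()

    def _validate(self) -> None:
        seen_gene: set[tuple[str, str]] = set()
        seen_pos: set[tuple[str, str, int]] = set()
        for family, per_genome in self._data.items():
            for genome, loci in per_genome.items():
                for locus in loci:
                    key = (locus.gene_id, genome)
                    if key in seen_gene:
                        raise ValidationError(f"duplicate gene {locus.gene_id} in genome {genome}")
                    seen_gene.add(key)
                    if locus.position is not None:
                        pkey = (genome, locus.chromosome_id, locus.position)
                        if pkey in seen_pos:
                            raise ValidationError(
                                f"duplicate position {locus.position} on "
                                f"{genome}:{locus.chromosome_id}"
                            )
                        seen_pos.add(pkey)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self._data)

    def loci(self, family_id: str, genome_id: str) -> tuple[GeneLocus, ...]:
        """Loci of ``family_id`` in ``genome_id`` (empty tuple = absent)."""
        return self._data.get(family_id, {}).get(genome_id, ())

    def per_genome(self, family_id: str) -> dict[str, tuple[GeneLocus, ...]]:
        return dict(self._data.get(family_id, {}))

    def all_loci(self, genome_id: str) -> list[GeneLocus]:
        out: list[GeneLocus] = []
        for family in self._data:
            out.extend(self._data[family].get(genome_id, ()))
        return out

    def present_families(self, genome_id: str) -> tuple[str, ...]:
        """Families with at least one locus in ``genome_id``."""
        return tuple(f for f in self._data if self._data[f].get(genome_id))

    def chromosomes(self, genome_id: str) -> tuple[str, ...]:
        seen: list[str] = []
        for locus in self.all_loci(genome_id):
            if locus.chromosome_id not in seen:
                seen.append(locus.chromosome_id)
        return tuple(seen)

    def merged_with(self, other: "OrthologTable") -> "OrthologTable":
        """Union of two tables (used to append a query genome)."""
        data: dict[str, dict[str, list[GeneLocus]]] = {}
        for table in (self, other):
            for family in table.families:
                for genome, loci in table.per_genome(family).items():
                    data.setdefault(family, {}).setdefault(genome, []).extend(loci)
        return OrthologTable(data, genomes=tuple(dict.fromkeys(self.genomes + other.genomes)))

    def __len__(self) -> int:
        return len(self._data)

    def _shape(self) -> dict:
        # gene ids are dataset-local names, not part of table identity
        # an explicitly empty locus list equals an absent key: both mean
        # "surveyed, not found" once the genome is declared in the header
        shape = {
            family: {
                genome: sorted((l.chromosome_id, l.position if l.position is not None else -1) for l in loci)
                for genome, loci in per_genome.items()
                if loci
            }
            for family, per_genome in self._data.items()
        }
        return {family: per for family, per in shape.items() if per}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologTable):
            return NotImplemented
        return self._shape() == other._shape() and set(self.genomes) == set(other.genomes)


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII", "XIII", "XIV"]
_BASE_LABELS = set(_ROMAN) | {"XII'"} | set("abcde")


def _label_ok(label: str) -> bool:
    # Accepts the unified Roman-numeral scheme, the primed duplicate exon
    # (XII'), species-specific lower-case exons (a-e), and fused exons of
    # invertebrate lineages written as hyphenated compounds (e.g. X-XI).
    if label in _BASE_LABELS:
        return True
    parts = label.split("-")
    return len(parts) > 1 and all(p in _BASE_LABELS for p in parts)


@dataclass(frozen=True)
class Exon:
    label: str
    motifs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not _label_ok(self.label):
            raise ValidationError(f"unrecognised exon label {self.label!r}")
        bad = set(self.motifs) - MOTIF_VOCABULARY
        if bad:
            raise ValidationError(f"unknown motif name(s) {sorted(bad)}")


@dataclass(frozen=True)
class Isoform:
    """One transcript: an ordered splice path through the gene's exons."""

    name: str
    splice_path: tuple[str, ...]
    start_exon: str
    start_offset_codon: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.splice_path:
            raise ValidationError(f"isoform {self.name} has an empty splice path")
        if self.start_exon not in self.splice_path:
            raise ValidationError(f"isoform {self.name}: start exon {self.start_exon} not on its splice path")


@dataclass
class GeneModel:
    """Exon/motif/isoform architecture of one gene.

    ``flags`` carries per-gene boolean annotations that are not structural
    (currently ``met33``: presence of the conserved exon III methionine).
    ``unknown_features`` lists feature-matrix characters for which the
    underlying data are too partial to call (used for cyclostome genes).
    """

    gene_id: str
    exons: tuple[Exon, ...]
    isoforms: tuple[Isoform, ...]
    alt_tss: frozenset[str] = frozenset()
    flags: dict = field(default_factory=dict)
    unknown_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        self.isoforms = tuple(self.isoforms)
        self.alt_tss = frozenset(self.alt_tss)
        labels = [e.label for e in self.exons]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"{self.gene_id}: exon labels must be unique")
        order = {lab: i for i, lab in enumerate(labels)}
        for iso in self.isoforms:
            unknown = [x for x in iso.splice_path if x not in order]
            if unknown:
                raise ValidationError(f"{self.gene_id}/{iso.name}: path uses undeclared exon(s) {unknown}")
            idx = [order[x] for x in iso.splice_path]
            if idx != sorted(idx):
                raise ValidationError(f"{self.gene_id}/{iso.name}: splice path violates exon order")
        for tss in self.alt_tss:
            if tss not in order:
                raise ValidationError(f"{self.gene_id}: alt TSS on undeclared exon {tss}")

    @property
    def exon_labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.exons)

    def motifs(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.exons:
            out |= e.motifs
        return frozenset(out)

    def exon(self, label: str) -> Exon:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(label)


_AA = set("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}


class AlignmentBlock:
    """A labelled slice of a protein multiple alignment.

    All sequences are gap-padded to equal length and every sequence carries a
    subfamily label.  Columns are addressed 1-based, matching how positions
    inside domain alignments are conventionally quoted.
    """

    def __init__(self, name: str, sequences: Mapping[str, str], subfamily: Mapping[str, str]):
        self.name = name
        self.sequences = dict(sequences)
        self.subfamily = dict(subfamily)
        if not self.sequences:
            raise ValidationError("alignment block has no sequences")
        widths = {len(s) for s in self.sequences.values()}
        if len(widths) != 1:
            raise ValidationError(f"ragged alignment: sequence lengths {sorted(widths)}")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - _AA
            if bad:
                raise ValidationError(f"{sid}: non-amino-acid symbols {sorted(bad)}")
        missing = set(self.sequences) - set(self.subfamily)
        if missing:
            raise ValidationError(f"sequences without a subfamily label: {sorted(missing)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def subfamilies(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.subfamily[s] for s in self.sequences))

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(s for s in self.sequences if self.subfamily[s] == label)

    def column(self, position: int) -> dict[str, str]:
        """Residues at a 1-based column."""
        if not 1 <= position <= self.width:
            raise ValidationError(f"column {position} outside block of width {self.width}")
        return {sid: seq[position - 1].upper() for sid, seq in self.sequences.items()}

    def restricted_to(self, labels: Iterable[str]) -> "AlignmentBlock":
        keep = set(labels)
        seqs = {s: q for s, q in self.sequences.items() if self.subfamily[s] in keep}
        return AlignmentBlock(self.name, seqs, {s: self.subfamily[s] for s in seqs})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentBlock):
            return NotImplemented
        return (
            self.name == other.name
            and self.sequences == other.sequences
            and self.subfamily == other.subfamily
        )


class ParalogTree:
    """A rooted tree over gene families / subfamilies (polytomies allowed).

    Thin wrapper over :class:`dendropy.Tree` that enforces unique leaf labels
    and gives deterministic names to unnamed internal nodes.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValidationError("leaf labels must be unique")
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"node{counter}"
            counter += 1

    @classmethod
    def from_newick(cls, newick: str) -> "ParalogTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        tree.is_rooted = True
        return cls(tree)

    def clone(self) -> "ParalogTree":
        return ParalogTree(self.tree.clone(depth=1))

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def node(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon.label == label:
                    return node
            elif node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    def attach_polytomy(self, leaf_labels: Sequence[str], at: str, on_stem: bool = False) -> "ParalogTree":
        """Return a new tree with ``leaf_labels`` attached as direct children.

        ``at`` names an existing node.  With ``on_stem=True`` a new node is
        inserted on the edge above ``at`` and the leaves attach there instead
        (the "stem" placement).
        """
        out = self.clone()
        target = out.node(at)
        if on_stem:
            parent = target.parent_node
            if parent is None:
                raise ValidationError(f"node {at} has no stem edge (it is the root)")
            stem = dendropy.Node(label=f"{at}_stem")
            parent.remove_child(target)
            parent.add_child(stem)
            stem.add_child(target)
            target = stem
        ns = out.tree.taxon_namespace
        for label in leaf_labels:
            taxon = ns.get_taxon(label) or ns.new_taxon(label)
            target.add_child(dendropy.Node(taxon=taxon))
        return ParalogTree(out.tree)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()
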
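"""Neighborhood definition, query classification and contingency building.

The synteny logic mirrors how paralogons are recognised after whole-genome
duplication: a linkage-group family belongs to the neighborhood of a given
paralog (anchor gene) if, in at least one reference genome, one of its loci
lies on the same chromosome as that anchor.  A query-genome family is then
labelled by the neighborhoods containing it: exactly one -> that paralog's
label, two or more -> ``SHARED``, none -> ``OTHER``.  Families absent from
the query genome are excluded from the classification denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import GeneLocus, LinkageGroup, OrthologTable, ValidationError

__all__ = [
    "SHARED",
    "OTHER",
    "NeighborhoodSet",
    "NeighborhoodAssignment",
    "ContingencyTable2x2",
    "define_neighborhoods",
    "classify_query",
    "build_contingency",
    "shared_flank_orthology",
    "FlankAssignment",
]

SHARED = "SHARED"
OTHER = "OTHER"


@dataclass(frozen=True)
class NeighborhoodSet:
    """Per-paralog sets of linkage-group families co-located with its anchor."""

    members: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", {p: frozenset(v) for p, v in self.members.items()})

    @property
    def paralogs(self) -> tuple[str, ...]:
        return tuple(self.members)

    def of(self, paralog: str) -> frozenset[str]:
        return self.members[paralog]

    def labels_for(self, family_id: str) -> tuple[str, ...]:
        return tuple(p for p in self.members if family_id in self.members[p])


@dataclass(frozen=True)
class NeighborhoodAssignment:
    """Classification of query-genome families into neighborhood categories.

    ``label`` maps each classified family to a paralog neighborhood name, to
    ``SHARED`` or to ``OTHER``; ``query_chromosomes`` records the query
    chromosome(s) carrying each family's loci.
    """

    label: Mapping[str, str]
    query_chromosomes: Mapping[str, frozenset[str]]
    query_genome: str
    paralogs: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", dict(self.label))
        object.__setattr__(
            self, "query_chromosomes", {f: frozenset(v) for f, v in self.query_chromosomes.items()}
        )
        valid = set(self.paralogs) | {SHARED, OTHER}
        bad = {l for l in self.label.values() if l not in valid}
        if bad:
            raise ValidationError(f"labels outside the category set: {sorted(bad)}")
        if set(self.label) != set(self.query_chromosomes):
            raise ValidationError("label and query_chromosomes must cover the same families")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self.label)

    def count(self, label: str) -> int:
        return sum(1 for v in self.label.values() if v == label)

    def category_counts(self) -> dict[str, int]:
        out = {p: 0 for p in self.paralogs}
        out[SHARED] = 0
        out[OTHER] = 0
        for v in self.label.values():
            out[v] += 1
        return out

    def on_chromosome(self, family_id: str, chromosome_id: str) -> bool:
        return chromosome_id in self.query_chromosomes[family_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": f,
                "label": self.label[f],
                "query_chromosomes": ",".join(sorted(self.query_chromosomes[f])),
            }
            for f in self.label
        ]
        return pd.DataFrame(rows, columns=["family_id", "label", "query_chromosomes"])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts feeding the exact tests.

    Rows: family carries the focal neighborhood label / does not.
    Columns: family has a locus on the focal chromosome / does not.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def on_chromosome_margin(self) -> int:
        return self.a + self.c

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def define_neighborhoods(
    table: OrthologTable,
    ref_genomes: Sequence[str],
    anchor_loci: Mapping[str, Mapping[str, GeneLocus]],
    clgq: LinkageGroup,
    single_copy_only: bool = False,
) -> NeighborhoodSet:
    """Assign linkage-group families to paralog neighborhoods.

    A family joins the neighborhood of paralog ``P`` if in at least one
    reference genome some (or, with ``single_copy_only``, its only) locus
    shares a chromosome with P's anchor locus in that genome.
    """
    for paralog, per_genome in anchor_loci.items():
        missing = [g for g in ref_genomes if g not in per_genome]
        if missing:
            raise ValidationError(f"anchor for {paralog} missing from genome(s) {missing}")
    clg_members = set(clgq.members)
    members: dict[str, set[str]] = {p: set() for p in anchor_loci}
    for family in table.families:
        if family not in clg_members:
            continue
        for genome in ref_genomes:
            loci = table.loci(family, genome)
            if single_copy_only and len(loci) > 1:
                continue
            chroms = {l.chromosome_id for l in loci}
            for paralog, per_genome in anchor_loci.items():
                if per_genome[genome].chromosome_id in chroms:
                    members[paralog].add(family)
    return NeighborhoodSet({p: frozenset(v) for p, v in members.items()})


def classify_query(
    neighborhoods: NeighborhoodSet,
    table: OrthologTable,
    query_genome: str,
    clgq: Optional[LinkageGroup] = None,
) -> NeighborhoodAssignment:
    """Label every linkage-group family present in the query genome."""
    if query_genome not in table.genomes:
        raise ValidationError(f"query genome {query_genome!r} not in table")
    families = table.present_families(query_genome)
    if clgq is not None:
        keep = set(clgq.members)
        families = tuple(f for f in families if f in keep)
    label: dict[str, str] = {}
    chroms: dict[str, frozenset[str]] = {}
    for family in families:
        hits = neighborhoods.labels_for(family)
        if len(hits) == 1:
            label[family] = hits[0]
        elif len(hits) >= 2:
            label[family] = SHARED
        else:
            label[family] = OTHER
        chroms[family] = frozenset(l.chromosome_id for l in table.loci(family, query_genome))
    return NeighborhoodAssignment(label, chroms, query_genome, neighborhoods.paralogs)


def build_contingency(
    assignment: NeighborhoodAssignment,
    label: str,
    chromosome: str,
) -> ContingencyTable2x2:
    """Cross-classify families by focal label and focal-chromosome presence.

    ``SHARED`` and ``OTHER`` families count toward the no-label row: the
    test asks whether *this* neighborhood is over-represented on the
    chromosome relative to everything else that was classified.
    """
    if label in (SHARED, OTHER):
        raise ValidationError("contingency label must be a paralog neighborhood")
    if label not in assignment.paralogs:
        raise ValidationError(f"unknown neighborhood label {label!r}")
    if not any(chromosome in v for v in assignment.query_chromosomes.values()):
        raise ValidationError(f"chromosome {chromosome!r} carries no classified family in the query genome")
    a = b = c = d = 0
    for family in assignment.families:
        has_label = assignment.label[family] == label
        on_chrom = assignment.on_chromosome(family, chromosome)
        if has_label and on_chrom:
            a += 1
        elif has_label:
            b += 1
        elif on_chrom:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


@dataclass(frozen=True)
class FlankAssignment:
    """Result of flanking-gene orthology disambiguation."""

    assigned: Mapping[str, str]
    shared_counts: Mapping[str, Mapping[str, int]]
    ties: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assigned", dict(self.assigned))
        object.__setattr__(self, "shared_counts", {q: dict(v) for q, v in self.shared_counts.items()})


def shared_flank_orthology(
    query_paralogs: Mapping[str, Sequence[str]],
    ref_paralogs: Mapping[str, Sequence[str]],
) -> FlankAssignment:
    """Name duplicate query paralogs after the reference paralog whose
    flanking gene families they share most.

    ``query_paralogs`` / ``ref_paralogs`` map paralog ids to the family ids
    flanking them (a window of neighbours each side).  Ties leave the query
    paralog unassigned and are reported.
    """
    if not ref_paralogs:
        raise ValidationError("at least one reference paralog is required")
    for pid, flanks in {**query_paralogs, **ref_paralogs}.items():
        if not flanks:
            raise ValidationError(f"paralog {pid} has an empty flanking set")
    assigned: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    ties: list[str] = []
    for q, qflanks in query_paralogs.items():
        qset = set(qflanks)
        counts[q] = {r: len(qset & set(rflanks)) for r, rflanks in ref_paralogs.items()}
        best = max(counts[q].values())
        winners = [r for r, v in counts[q].items() if v == best]
        if len(winners) == 1:
            assigned[q] = winners[0]
        else:
            ties.append(q)
    return FlankAssignment(assigned, counts, tuple(ties))
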
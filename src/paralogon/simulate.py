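"""Synthetic WGD genomes and alignment blocks with known ground truth.

The genome generator emulates the situation the synteny analysis assumes:
an ancestral linkage group whose genes were duplicated by one or two rounds
of whole-genome duplication into paralogons, then differentially lost
("fractionated") and occasionally translocated in each descendant genome.
One designated anchor family (the "TCF" family) is always retained in every
paralogon of every genome; its copies are the anchor paralogs that define
neighborhoods downstream.

Randomness contract: every operation builds its own generators from
``numpy.random.SeedSequence(seed).spawn(...)`` in a documented order
(retention, translocation, placement), and draws fixed-shape arrays
regardless of earlier outcomes, so any stage can be re-derived
independently by consuming the same streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import GeneLocus, LinkageGroup, OrthologTable, ValidationError
from .synteny import OTHER, SHARED

__all__ = [
    "WgdSimConfig",
    "SimTruth",
    "simulate_wgd_genomes",
    "simulate_query_lineage",
    "simulate_alignment_block",
    "reference_anchor_loci",
]

LOST = "lost"
TCF_FAMILY = "TCF"

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class WgdSimConfig:
    """Parameters of the fractionated-linkage-group simulation.

    ``retention_prob`` is the per-paralogon probability that a family's
    copy survives rediploidization in the common ancestor of the reference
    genomes (drawn once per family x paralogon); ``genome_loss_prob`` then
    removes each surviving copy independently per descendant genome - the
    differential loss that makes the "in at least one genome" neighborhood
    rule meaningful.  ``translocation_rate`` is the probability a retained
    copy moves to a uniformly chosen non-home chromosome.  ``fuse`` names
    two paralogon indices (0-based) that share one chromosome in the first
    reference genome, emulating shared neighborhoods that arise from real
    genomic history rather than noise.
    """

    n_families: int
    n_rounds: int = 2
    retention_prob: float = 0.3
    translocation_rate: float = 0.0
    n_ref_genomes: int = 4
    n_extra_chromosomes: int = 2
    seed: int = 0
    genome_loss_prob: float = 0.0
    fuse: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be positive")
        if self.n_rounds not in (1, 2):
            raise ValidationError("n_rounds must be 1 or 2")
        for name in ("retention_prob", "translocation_rate", "genome_loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_ref_genomes < 1:
            raise ValidationError("n_ref_genomes must be positive")
        if self.n_extra_chromosomes < 0:
            raise ValidationError("n_extra_chromosomes must be non-negative")
        if self.fuse is not None:
            n_par = 2**self.n_rounds
            a, b = self.fuse
            if a == b or not (0 <= a < n_par and 0 <= b < n_par):
                raise ValidationError(f"fuse must name two distinct paralogon indices < {n_par}")

    @property
    def n_paralogons(self) -> int:
        return 2**self.n_rounds

    @property
    def paralogons(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.n_paralogons))

    @property
    def family_ids(self) -> tuple[str, ...]:
        # family index 0 is the always-retained anchor family
        return (TCF_FAMILY,) + tuple(f"fam{i:04d}" for i in range(1, self.n_families))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for every downstream stage of the pipeline."""

    config: WgdSimConfig
    family_labels: dict  # family -> paralogon label, SHARED, or "lost"
    paralogon_chromosomes: dict  # genome -> {paralogon -> chromosome}
    retained: dict  # genome -> {paralogon -> frozenset(families)}
    linkage_group: LinkageGroup
    query_genome: Optional[str] = None
    query_mode: Optional[str] = None
    query_paralogon_chromosomes: dict = field(default_factory=dict)
    expected_query_labels: dict = field(default_factory=dict)
    enriched_chromosomes: frozenset = frozenset()

    @property
    def paralogons(self) -> tuple[str, ...]:
        return self.config.paralogons


def _genome_chromosomes(genome: str, config: WgdSimConfig) -> tuple[dict, list]:
    """Home chromosome per paralogon plus full chromosome list for a genome."""
    homes: dict[str, str] = {}
    for i, paralogon in enumerate(config.paralogons):
        j = i
        if config.fuse is not None and genome.endswith("1") and i == config.fuse[1]:
            j = config.fuse[0]  # second fused paralogon rides on the first's chromosome
        homes[paralogon] = f"{genome}_chr{j + 1}"
    all_chroms = sorted(set(homes.values())) + [
        f"{genome}_chrE{k + 1}" for k in range(config.n_extra_chromosomes)
    ]
    return homes, all_chroms


def _place(
    copies: list[tuple[str, str, str]],  # (family, paralogon, chromosome)
    genome: str,
    rng: np.random.Generator,
) -> dict[str, dict[str, list[GeneLocus]]]:
    """Assign ordinal positions by shuffling gene order within chromosomes."""
    per_chrom: dict[str, list[tuple[str, str]]] = {}
    for family, paralogon, chrom in copies:
        per_chrom.setdefault(chrom, []).append((family, paralogon))
    data: dict[str, dict[str, list[GeneLocus]]] = {}
    for chrom in sorted(per_chrom):
        genes = per_chrom[chrom]
        order = rng.permutation(len(genes))
        for pos, idx in enumerate(order):
            family, paralogon = genes[idx]
            locus = GeneLocus(f"{family}|{paralogon}", genome, chrom, int(pos))
            data.setdefault(family, {}).setdefault(genome, []).append(locus)
    return data


def simulate_wgd_genomes(config: WgdSimConfig) -> tuple[OrthologTable, SimTruth]:
    """Fractionate a duplicated linkage group across reference genomes.

    Deterministic under a fixed config (byte-identical outputs).
    """
    families = config.family_ids
    paralogons = config.paralogons
    genomes = tuple(f"ref{i + 1}" for i in range(config.n_ref_genomes))
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_ret = np.random.default_rng(streams[0])
    rng_tr = np.random.default_rng(streams[1])
    rng_place = np.random.default_rng(streams[2])

    shape = (config.n_ref_genomes, config.n_families, config.n_paralogons)
    # rediploidization happens once in the common ancestor, then each
    # descendant genome loses surviving copies independently
    ancestral = rng_ret.random((config.n_families, config.n_paralogons)) < config.retention_prob
    survive = rng_ret.random(shape) >= config.genome_loss_prob
    retained = ancestral[None, :, :] & survive
    retained[:, 0, :] = True  # the anchor family survives everywhere
    move = rng_tr.random(shape) < config.translocation_rate
    move[:, 0, :] = False  # anchors stay put: they define the neighborhoods
    dest_draw = rng_tr.integers(0, 2**31, size=shape)

    data: dict[str, dict[str, list[GeneLocus]]] = {f: {g: [] for g in genomes} for f in families}
    paralogon_chromosomes: dict[str, dict[str, str]] = {}
    retained_sets: dict[str, dict[str, frozenset]] = {}
    for gi, genome in enumerate(genomes):
        homes, all_chroms = _genome_chromosomes(genome, config)
        paralogon_chromosomes[genome] = dict(homes)
        copies: list[tuple[str, str, str]] = []
        per_par: dict[str, set[str]] = {p: set() for p in paralogons}
        for fi, family in enumerate(families):
            for pi, paralogon in enumerate(paralogons):
                if not retained[gi, fi, pi]:
                    continue
                per_par[paralogon].add(family)
                chrom = homes[paralogon]
                if move[gi, fi, pi]:
                    others = [c for c in all_chroms if c != chrom]
                    chrom = others[dest_draw[gi, fi, pi] % len(others)]
                copies.append((family, paralogon, chrom))
        retained_sets[genome] = {p: frozenset(v) for p, v in per_par.items()}
        placed = _place(copies, genome, rng_place)
        for family, per_genome in placed.items():
            data[family][genome].extend(per_genome[genome])

    table = OrthologTable(
        {f: {g: tuple(data[f][g]) for g in genomes} for f in families}, genomes=genomes
    )
    labels: dict[str, str] = {}
    for fi, family in enumerate(families):
        survived = {paralogons[pi] for pi in range(config.n_paralogons) if retained[:, fi, pi].any()}
        if not survived:
            labels[family] = LOST
        elif len(survived) == 1:
            labels[family] = next(iter(survived))
        else:
            labels[family] = SHARED
    truth = SimTruth(
        config=config,
        family_labels=labels,
        paralogon_chromosomes=paralogon_chromosomes,
        retained=retained_sets,
        linkage_group=LinkageGroup("CLG_sim", families),
    )
    return table, truth


def reference_anchor_loci(table: OrthologTable, truth: SimTruth) -> dict:
    """Anchor loci per paralogon, from the always-retained anchor family.

    Returns ``paralogon -> {genome -> GeneLocus}`` suitable for
    :func:`paralogon.synteny.define_neighborhoods`.
    """
    anchors: dict[str, dict[str, GeneLocus]] = {p: {} for p in truth.paralogons}
    for genome, homes in truth.paralogon_chromosomes.items():
        for locus in table.loci(TCF_FAMILY, genome):
            if "|" in locus.gene_id:
                paralogon = locus.gene_id.split("|", 1)[1]
            else:  # round-tripped table: anchors never translocate, match by home chromosome
                matches = [p for p, chrom in homes.items() if chrom == locus.chromosome_id]
                if len(matches) != 1:
                    continue
                paralogon = matches[0]
            anchors[paralogon][genome] = locus
    return anchors


def simulate_query_lineage(
    table: OrthologTable,
    truth: SimTruth,
    mode: str,
    loss_prob: float,
    seed: int,
    translocation_rate: float = 0.0,
    intact_paralogons: Optional[Sequence[str]] = None,
) -> tuple[OrthologTable, SimTruth]:
    """Append a query genome that either shares the reference WGD or not.

    ``shared_2R``: the query inherits the reference paralogon structure - a
    family's copy in paralogon P exists iff P retained it in at least one
    reference genome and the copy additionally survives loss in the query
    lineage (probability ``1 - loss_prob``).

    ``independent_dup``: the query's chromosomes descend from the pre-WGD
    state via its own duplications - each family's copy on each query
    chromosome is retained with probability ``1 - loss_prob`` independently
    of the reference paralogon sorting, scrambling any correspondence.

    ``translocation_rate`` scatters retained query copies to random other
    chromosomes; paralogons listed in ``intact_paralogons`` are exempt
    (an intact enriched paralogon among scattered ones).
    """
    if mode not in ("shared_2R", "independent_dup"):
        raise ValidationError(f"unknown query mode {mode!r}")
    if not 0.0 <= loss_prob <= 1.0:
        raise ValidationError("loss_prob must be in [0, 1]")
    config = truth.config
    genome = "query"
    paralogons = truth.paralogons
    intact = set(intact_paralogons or ())
    unknown = intact - set(paralogons)
    if unknown:
        raise ValidationError(f"unknown paralogon(s) in intact set: {sorted(unknown)}")

    homes = {p: f"{genome}_chr{i + 1}" for i, p in enumerate(paralogons)}
    all_chroms = [homes[p] for p in paralogons] + [
        f"{genome}_chrE{k + 1}" for k in range(config.n_extra_chromosomes)
    ]
    in_reference = {
        p: frozenset().union(*(truth.retained[g][p] for g in truth.retained))
        for p in paralogons
    }

    streams = np.random.SeedSequence(seed).spawn(3)
    rng_keep = np.random.default_rng(streams[0])
    rng_tr = np.random.default_rng(streams[1])
    rng_place = np.random.default_rng(streams[2])
    families = config.family_ids
    shape = (config.n_families, config.n_paralogons)
    keep = rng_keep.random(shape) < (1.0 - loss_prob)
    keep[0, :] = True  # anchor family survives in the query too
    move = rng_tr.random(shape) < translocation_rate
    move[0, :] = False
    dest_draw = rng_tr.integers(0, 2**31, size=shape)

    copies: list[tuple[str, str, str]] = []
    for fi, family in enumerate(families):
        for pi, paralogon in enumerate(paralogons):
            if mode == "shared_2R" and fi > 0 and family not in in_reference[paralogon]:
                continue
            if not keep[fi, pi]:
                continue
            chrom = homes[paralogon]
            if move[fi, pi] and paralogon not in intact:
                others = [c for c in all_chroms if c != chrom]
                chrom = others[dest_draw[fi, pi] % len(others)]
            copies.append((family, paralogon, chrom))
    placed = _place(copies, genome, rng_place)
    query_table = OrthologTable(
        {f: {genome: tuple(loci[genome])} for f, loci in placed.items()}, genomes=(genome,)
    )
    merged = table.merged_with(query_table)

    expected = {
        f: (OTHER if truth.family_labels[f] == LOST else truth.family_labels[f])
        for f in merged.present_families(genome)
    }
    enriched = (
        frozenset(homes[p] for p in (intact or paralogons)) if mode == "shared_2R" else frozenset()
    )
    new_truth = replace(
        truth,
        query_genome=genome,
        query_mode=mode,
        query_paralogon_chromosomes=dict(homes),
        expected_query_labels=expected,
        enriched_chromosomes=enriched,
    )
    return merged, new_truth


def simulate_alignment_block(
    n_per_subfamily: dict,
    width: int,
    planted: Sequence[tuple[str, int, Sequence[str]]],
    noise_rate: float,
    seed: int,
    name: str = "simulated",
):
    """Build an alignment block with planted subfamily-diagnostic columns.

    Background columns share a random consensus with ``noise_rate``
    point substitutions.  At a planted (subfamily, column, residues) the
    subfamily's members carry the listed residues (round-robin, so every
    listed residue appears when the subfamily is large enough) and no other
    sequence ever does; planted columns receive no background noise.
    """
    from .model import AlignmentBlock  # local import avoids cycle at module load

    if not 0.0 <= noise_rate <= 1.0:
        raise ValidationError("noise_rate must be in [0, 1]")
    plant_cols: dict[int, dict[str, tuple[str, ...]]] = {}
    for subfamily, column, residues in planted:
        if not 1 <= column <= width:
            raise ValidationError(f"planted column {column} outside width {width}")
        residues = tuple(str(r).upper() for r in residues)
        if not residues:
            raise ValidationError("planted residue set is empty")
        at = plant_cols.setdefault(column, {})
        if subfamily in at:
            raise ValidationError(f"conflicting plants for {subfamily} at column {column}")
        for other, other_res in at.items():
            if set(other_res) & set(residues):
                raise ValidationError(
                    f"column {column}: residue overlap between plants for {other} and {subfamily}"
                )
        at[subfamily] = residues

    rng = np.random.default_rng(seed)
    consensus = rng.choice(_AMINO_ACIDS, size=width)
    for column, at in plant_cols.items():
        forbidden = {r for residues in at.values() for r in residues}
        allowed = [a for a in _AMINO_ACIDS if a not in forbidden]
        consensus[column - 1] = allowed[int(rng.integers(len(allowed)))]

    sequences: dict[str, str] = {}
    subfamily_of: dict[str, str] = {}
    for subfamily in n_per_subfamily:
        n = int(n_per_subfamily[subfamily])
        if n < 1:
            raise ValidationError(f"subfamily {subfamily} must have at least one member")
        for i in range(n):
            sid = f"{subfamily}_{i + 1}"
            seq = consensus.copy()
            noise = rng.random(width) < noise_rate
            for j in np.nonzero(noise)[0]:
                if (j + 1) in plant_cols:
                    continue
                alt = [a for a in _AMINO_ACIDS if a != seq[j]]
                seq[j] = alt[int(rng.integers(len(alt)))]
            for column, at in plant_cols.items():
                if subfamily in at:
                    residues = at[subfamily]
                    seq[column - 1] = residues[i % len(residues)]
            sequences[sid] = "".join(seq)
            subfamily_of[sid] = subfamily
    return AlignmentBlock(name, sequences, subfamily_of)
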
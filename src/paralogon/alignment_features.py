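"""Subfamily-diagnostic columns and start-codon conservation in alignments.

A column is diagnostic for a subfamily when (almost) all of its members
carry a small residue set there while (almost) no sequence outside the
subfamily does.  Positions are 1-based within the supplied block - the
block boundaries (e.g. the HMG-box slice, or the exon III slice) must be
chosen by the caller; the scanner does not locate domains itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import AlignmentBlock, ValidationError

__all__ = ["DiagnosticResidue", "StartCodonReport", "scan_diagnostics", "methionine_conservation"]


@dataclass(frozen=True)
class DiagnosticResidue:
    """A subfamily-specific residue set at one alignment column."""

    subfamily: str
    column: int  # 1-based
    residues: frozenset[str]
    support: float  # fraction of subfamily members carrying a listed residue
    leakage: float  # fraction of non-members carrying a listed residue

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(self.residues))


@dataclass(frozen=True)
class StartCodonReport:
    """Presence of methionine at a fixed column, per sequence and aggregated."""

    column: int
    per_sequence: dict
    conservation: float
    per_subfamily: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_sequence", dict(self.per_sequence))
        object.__setattr__(self, "per_subfamily", dict(self.per_subfamily))


def _minimal_cover(counts: dict[str, int], n: int, required: int, max_set: int) -> Optional[tuple[str, ...]]:
    """Smallest residue set (by member frequency) covering >= required members."""
    ranked = sorted(counts, key=lambda r: (-counts[r], r))
    chosen: list[str] = []
    covered = 0
    for residue in ranked:
        if covered >= required:
            break
        if len(chosen) == max_set:
            return None
        chosen.append(residue)
        covered += counts[residue]
    if covered >= required and chosen:
        return tuple(sorted(chosen))
    return None


def scan_diagnostics(
    block: AlignmentBlock,
    min_support: float = 1.0,
    max_leakage: float = 0.0,
    max_set: int = 2,
    allowed_exceptions: int = 1,
) -> list[DiagnosticResidue]:
    """Find every (subfamily, column, residue set) diagnostic in the block.

    A residue set of size <= ``max_set`` qualifies when it covers at least
    ``min(ceil(min_support * n), n - allowed_exceptions)`` of the
    subfamily's ``n`` members (so one divergent sequence is tolerated by
    default) and the fraction of non-members carrying any listed residue is
    <= ``max_leakage``.  Gaps never count as diagnostic residues and
    gap-majority columns are skipped.
    """
    subfamilies = block.subfamilies
    if len(subfamilies) < 2:
        raise ValidationError("need at least two subfamilies to scan for diagnostics")
    members = {s: block.members(s) for s in subfamilies}
    for s, mem in members.items():
        if len(mem) < 2:
            raise ValidationError(f"subfamily {s!r} has fewer than two members")
    if not 0.0 <= min_support <= 1.0 or not 0.0 <= max_leakage <= 1.0:
        raise ValidationError("min_support and max_leakage must be fractions in [0, 1]")
    if max_set < 1 or allowed_exceptions < 0:
        raise ValidationError("max_set must be >= 1 and allowed_exceptions >= 0")

    import math

    found: list[DiagnosticResidue] = []
    n_total = len(block.sequences)
    for column in range(1, block.width + 1):
        residues_at = block.column(column)
        if sum(1 for r in residues_at.values() if r == "-") * 2 > n_total:
            continue  # gap-majority column
        for subfamily in subfamilies:
            mem = members[subfamily]
            n = len(mem)
            counts: dict[str, int] = {}
            for sid in mem:
                r = residues_at[sid]
                if r != "-":
                    counts[r] = counts.get(r, 0) + 1
            if not counts:
                continue
            required = min(math.ceil(min_support * n), n - allowed_exceptions)
            required = max(required, 1)
            chosen = _minimal_cover(counts, n, required, max_set)
            if chosen is None:
                continue
            outside = [residues_at[sid] for sid in block.sequences if sid not in set(mem)]
            leak = sum(1 for r in outside if r in set(chosen)) / len(outside)
            if leak > max_leakage + 1e-12:
                continue
            support = sum(counts.get(r, 0) for r in chosen) / n
            found.append(
                DiagnosticResidue(
                    subfamily=subfamily,
                    column=column,
                    residues=frozenset(chosen),
                    support=support,
                    leakage=leak,
                )
            )
    found.sort(key=lambda d: (d.column, d.subfamily))
    return found


def methionine_conservation(block: AlignmentBlock, column: int) -> StartCodonReport:
    """Report which sequences carry methionine at a 1-based column.

    Used to trace conservation of an internal translation-start methionine
    (such as the exon III position used by truncated-isoform starts).
    """
    residues_at = block.column(column)  # raises on out-of-range
    per_sequence = {sid: residues_at[sid] == "M" for sid in block.sequences}
    conservation = sum(per_sequence.values()) / len(per_sequence)
    per_subfamily: dict[str, float] = {}
    for subfamily in block.subfamilies:
        mem = block.members(subfamily)
        per_subfamily[subfamily] = sum(per_sequence[s] for s in mem) / len(mem)
    return StartCodonReport(
        column=column,
        per_sequence=per_sequence,
        conservation=conservation,
        per_subfamily=per_subfamily,
    )
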
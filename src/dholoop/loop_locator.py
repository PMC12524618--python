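"""Locating the flexible active-site loop within a chain.

The loop is found either by its author-numbered residue range (checked
against the expected motif, tolerating up to two substitutions so that
point mutants of loop residues still locate) or, when no range is packaged,
by exact motif search over the chain sequence.  Location is sequence-only,
so it is invariant under rigid-body motion of the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations import LoopDefinition
from .structure_io import (
    Residue,
    StructureModel,
    extract_chain_sequence,
    one_letter_code,
)

__all__ = ["LoopSegment", "LoopLocateError", "locate_loop", "loop_completeness"]

#: Mismatches tolerated when a residue range is checked against the motif.
MISMATCH_TOLERANCE = 2


class LoopLocateError(ValueError):
    """Loop motif absent, ambiguous, or inconsistent with the stated range."""


@dataclass
class LoopSegment:
    """The located loop of one chain: resolved residues plus missing numbers."""

    chain_id: str
    residue_range: tuple[int, int]
    resolved_residues: list[Residue]
    missing_numbers: list[int]
    definition: LoopDefinition

    def __post_init__(self) -> None:
        lo, hi = self.residue_range
        width = hi - lo + 1
        if width != self.definition.loop_length:
            raise LoopLocateError(
                f"range {lo}-{hi} width {width} != loop length {self.definition.loop_length}"
            )
        if len(self.resolved_residues) + len(self.missing_numbers) != width:
            raise LoopLocateError("resolved + missing residues do not cover the range")


def locate_loop(model: StructureModel, chain: str, definition: LoopDefinition) -> LoopSegment:
    """Locate the loop defined by ``definition`` in ``chain`` of ``model``."""
    motif = definition.motif
    by_number = {r.author_number: r for r in model.polymer_residues(chain)}
    if definition.residue_range is not None:
        # Range-based location works even when part (or all) of the loop is
        # unresolved; the motif check only covers resolved positions.
        lo, hi = definition.residue_range
        mismatches = sum(
            1
            for k, n in enumerate(range(lo, hi + 1))
            if n in by_number and one_letter_code(by_number[n].name) != motif[k]
        )
        if mismatches > MISMATCH_TOLERANCE:
            raise LoopLocateError(
                f"{model.pdb_id}/{chain}: sequence at {lo}-{hi} has "
                f"{mismatches} mismatches to motif {motif}"
            )
    else:
        seq, first = extract_chain_sequence(model, chain)
        hits = [
            i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
        ]
        if not hits:
            raise LoopLocateError(f"{model.pdb_id}/{chain}: motif {motif} not found")
        if len(hits) > 1:
            raise LoopLocateError(
                f"{model.pdb_id}/{chain}: motif {motif} found at {len(hits)} positions "
                "and no residue range disambiguates"
            )
        lo = first + hits[0]
        hi = lo + len(motif) - 1
    resolved = [by_number[n] for n in range(lo, hi + 1) if n in by_number]
    missing = [n for n in range(lo, hi + 1) if n not in by_number]
    return LoopSegment(
        chain_id=chain,
        residue_range=(lo, hi),
        resolved_residues=resolved,
        missing_numbers=missing,
        definition=definition,
    )


def loop_completeness(segment: LoopSegment) -> float:
    """Fraction of loop residues resolved in the coordinates, in [0, 1]."""
    return len(segment.resolved_residues) / segment.definition.loop_length
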
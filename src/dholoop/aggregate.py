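"""Aggregation of per-monomer annotations into survey summaries.

Produces the three views the survey reports: counts by species, by DHOase
type (split by ligand-bound status), and by bound ligand (split by type).
Ligand-bound means the monomer's assigned ligand is not NONE.  UNDETERMINED
monomers are tallied separately and never folded into in/out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotations import MonomerAnnotation, StructureRecord, expand_monomers

__all__ = [
    "SpeciesCounts",
    "TypeCounts",
    "LigandCounts",
    "SurveySummary",
    "summarize",
    "ligand_state_fractions",
    "ph_consistency_query",
    "write_report",
]


@dataclass
class SpeciesCounts:
    loop_in: int = 0
    loop_out: int = 0
    undetermined: int = 0
    monomers: int = 0
    structures: int = 0


@dataclass
class TypeCounts:
    in_total: int = 0
    in_with_ligand: int = 0
    out_total: int = 0
    out_with_ligand: int = 0
    undetermined: int = 0


@dataclass
class LigandCounts:
    loop_in: int = 0
    loop_out: int = 0
    by_type: dict[str, list[int]] = field(default_factory=dict)  # type -> [in, out]


@dataclass
class SurveySummary:
    by_species: dict[str, SpeciesCounts] = field(default_factory=dict)
    by_type: dict[str, TypeCounts] = field(default_factory=dict)
    by_ligand: dict[str, LigandCounts] = field(default_factory=dict)
    total_in: int = 0
    total_out: int = 0
    total_undetermined: int = 0
    total_monomers: int = 0
    total_structures: int = 0
    ligand_bound_total: int = 0


def summarize(annotations: Iterable[MonomerAnnotation]) -> SurveySummary:
    """Deterministic counts over expanded monomer annotations (keys sorted)."""
    annotations = list(annotations)
    summary = SurveySummary()
    pdb_ids: set[str] = set()
    species_pdb: dict[str, set[str]] = {}
    for ann in annotations:
        pdb_ids.add(ann.pdb_id)
        sp = summary.by_species.setdefault(ann.species, SpeciesCounts())
        species_pdb.setdefault(ann.species, set()).add(ann.pdb_id)
        ty = summary.by_type.setdefault(ann.dhoase_type, TypeCounts())
        bound = ann.ligand != "NONE"
        sp.monomers += 1
        if ann.loop_state == "LOOP_IN":
            sp.loop_in += 1
            summary.total_in += 1
            ty.in_total += 1
            ty.in_with_ligand += int(bound)
        elif ann.loop_state == "LOOP_OUT":
            sp.loop_out += 1
            summary.total_out += 1
            ty.out_total += 1
            ty.out_with_ligand += int(bound)
        else:
            sp.undetermined += 1
            summary.total_undetermined += 1
            ty.undetermined += 1
        if bound:
            summary.ligand_bound_total += 1
            lig = summary.by_ligand.setdefault(ann.ligand, LigandCounts())
            per_type = lig.by_type.setdefault(ann.dhoase_type, [0, 0])
            if ann.loop_state == "LOOP_IN":
                lig.loop_in += 1
                per_type[0] += 1
            elif ann.loop_state == "LOOP_OUT":
                lig.loop_out += 1
                per_type[1] += 1
    for species, ids in species_pdb.items():
        summary.by_species[species].structures = len(ids)
    summary.total_monomers = len(annotations)
    summary.total_structures = len(pdb_ids)
    summary.by_species = dict(sorted(summary.by_species.items()))
    summary.by_type = dict(sorted(summary.by_type.items()))
    summary.by_ligand = dict(sorted(summary.by_ligand.items()))
    return summary


def ligand_state_fractions(summary: SurveySummary, ligand: str) -> tuple[float, float]:
    """(% loop-in, % loop-out) among the bound monomers of one ligand."""
    if ligand not in summary.by_ligand:
        raise KeyError(f"no monomers bound to {ligand!r} in this summary")
    counts = summary.by_ligand[ligand]
    n = counts.loop_in + counts.loop_out
    if n == 0:
        raise KeyError(f"ligand {ligand!r} has zero classified bound monomers")
    return 100.0 * counts.loop_in / n, 100.0 * counts.loop_out / n


def ph_consistency_query(
    records: Sequence[StructureRecord], group: Sequence[str]
) -> bool:
    """True iff every monomer across the listed entries shares one loop state.

    Used for the pH-series check: structures of the same complex solved at
    different pH values should classify identically if pH does not drive the
    loop conformation.
    """
    by_id = {r.pdb_id: r for r in records}
    missing = [pdb_id for pdb_id in group if pdb_id not in by_id]
    if missing:
        raise KeyError(f"unknown PDB ids in group: {missing}")
    states = {
        m.loop_state
        for m in expand_monomers([by_id[pdb_id] for pdb_id in group])
    }
    return len(states) == 1


def _species_rows(summary: SurveySummary) -> list[str]:
    rows = ["species\tloop_in\tloop_out\tundetermined\tmonomers\tstructures"]
    for species, c in summary.by_species.items():
        rows.append(
            f"{species}\t{c.loop_in}\t{c.loop_out}\t{c.undetermined}\t{c.monomers}\t{c.structures}"
        )
    return rows


def _type_rows(summary: SurveySummary) -> list[str]:
    rows = ["type\tin_total\tin_with_ligand\tout_total\tout_with_ligand\tundetermined"]
    for t, c in summary.by_type.items():
        rows.append(
            f"{t}\t{c.in_total}\t{c.in_with_ligand}\t{c.out_total}\t{c.out_with_ligand}\t{c.undetermined}"
        )
    return rows


def _ligand_rows(summary: SurveySummary) -> list[str]:
    rows = ["ligand\tloop_in\tloop_out\tby_type"]
    for name, c in summary.by_ligand.items():
        per_type = ";".join(
            f"{t}:{io[0]}/{io[1]}" for t, io in sorted(c.by_type.items())
        )
        rows.append(f"{name}\t{c.loop_in}\t{c.loop_out}\t{per_type}")
    return rows


def write_report(summary: SurveySummary, out_dir: str | Path, format: str = "TSV") -> list[Path]:
    """Write byte-stable TSV tables (species/type/ligand) and a JSON bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format.upper() not in ("TSV", "JSON"):
        raise ValueError(f"unknown report format {format!r}")
    if format.upper() == "TSV":
        for name, rows in (
            ("by_species.tsv", _species_rows(summary)),
            ("by_type.tsv", _type_rows(summary)),
            ("by_ligand.tsv", _ligand_rows(summary)),
        ):
            path = out_dir / name
            path.write_text("\n".join(rows) + "\n", encoding="utf-8")
            written.append(path)
    bundle = {
        "totals": {
            "loop_in": summary.total_in,
            "loop_out": summary.total_out,
            "undetermined": summary.total_undetermined,
            "monomers": summary.total_monomers,
            "structures": summary.total_structures,
            "ligand_bound": summary.ligand_bound_total,
        },
        "by_species": {
            s: vars(c).copy() for s, c in summary.by_species.items()
        },
        "by_type": {t: vars(c).copy() for t, c in summary.by_type.items()},
        "by_ligand": {
            l: {"loop_in": c.loop_in, "loop_out": c.loop_out, "by_type": c.by_type}
            for l, c in summary.by_ligand.items()
        },
    }
    path = out_dir / "summary.json"
    path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(path)
    return written
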
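"""Synthetic coordinate files with known ground-truth loop states.

The generator emulates the structural situations the survey classifies,
without pretending to physics: a compact helical C-alpha/O core, a
contiguous surface loop whose sequence is one of the packaged loop motifs,
a catalytic Zn placed at the pocket center, and a rigid planar 9-heavy-atom
ligand fragment (orotate-sized) whose minimum heavy-atom distance to the
loop is placed at a requested target.  Loop-in monomers bulge toward the
pocket, loop-out monomers away from it; the ligand is slid along the pocket
axis until the realized loop-ligand minimum distance matches the target
(within 0.05 A), so the brute-force distance oracle and the recorded ground
truth agree by construction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import LoopDefinition, load_loop_definitions
from .structure_io import Atom, Residue, StructureModel, write_structure

__all__ = [
    "SyntheticSpec",
    "ChainTruth",
    "GroundTruth",
    "GeometryError",
    "make_monomer",
    "make_corpus",
    "motif_for_length",
]

STERIC_FLOOR = 2.5  # A; requesting a contact below this is unrealizable
_PLACEMENT_TOL = 0.05  # A; ligand placement convergence
LIGAND_NAME = "LIG"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


class GeometryError(ValueError):
    """Requested geometry cannot be realized (e.g. below the steric floor)."""


@dataclass
class SyntheticSpec:
    n_core_residues: int = 60
    loop_length: int = 16
    loop_state: str = "in"  # "in" or "out"
    target_contact_distance: float = 3.0  # A, loop<->ligand heavy-atom minimum
    include_ligand: bool = True
    include_metal: bool = True
    missing_loop_residues: tuple[int, ...] = ()  # 0-based positions within the loop
    n_chains: int = 1
    seed: int = 0
    as_reference: bool = False  # permit a ligand-free loop-in pose (apo-rule references/tests)

    def __post_init__(self) -> None:
        if self.loop_state not in ("in", "out"):
            raise ValueError("loop_state must be 'in' or 'out'")
        if self.target_contact_distance <= 0:
            raise ValueError("target contact distance must be positive")
        if self.loop_state == "in" and not (self.include_ligand or self.as_reference):
            raise ValueError("a loop-in pose needs a ligand or the as_reference flag")
        if self.include_ligand and self.target_contact_distance < STERIC_FLOOR:
            raise GeometryError(
                f"contact distance {self.target_contact_distance} below steric floor {STERIC_FLOOR}"
            )


@dataclass
class ChainTruth:
    chain_id: str
    loop_state: str
    residue_range: tuple[int, int]
    min_contact_distance: float | None
    ligand: str


@dataclass
class GroundTruth:
    chains: list[ChainTruth] = field(default_factory=list)


def motif_for_length(loop_length: int) -> LoopDefinition:
    """A packaged loop definition with the requested length (first match).

    The author-numbering anchors (residue range, key residue) are stripped:
    they refer to the definition's native structures, not to synthetic or
    arbitrary numbering, so location falls back to motif search.
    """
    for definition in load_loop_definitions():
        if definition.loop_length == loop_length:
            return replace(definition, residue_range=None, key_residue=None)
    lengths = sorted({d.loop_length for d in load_loop_definitions()})
    raise ValueError(f"no packaged loop motif of length {loop_length}; available: {lengths}")


def _helix_ca(n: int, start_index: int = 0) -> np.ndarray:
    """Idealized helical C-alpha trace along z."""
    i = np.arange(start_index, start_index + n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _bezier(s: np.ndarray, apex: np.ndarray, e: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Quadratic Bezier through apex at t=0.5."""
    c = 2.0 * apex - 0.5 * (s + e)
    ts = ts[:, None]
    return (1 - ts) ** 2 * s + 2 * ts * (1 - ts) * c + ts**2 * e


def _loop_ca(core_end: np.ndarray, loop_length: int, bulge: float) -> np.ndarray:
    """Loop C-alpha arc appended after the core, bulging along +/-x."""
    s = core_end + np.array([0.0, 0.0, 2.0])
    e = s + np.array([0.0, 3.0, 1.5 * max(loop_length, 4) * 0.5])
    apex = 0.5 * (s + e) + np.array([bulge, 0.0, 0.0])
    ts = np.linspace(0.0, 1.0, loop_length + 2)[1:-1]
    if loop_length >= 3:
        ts = ts.copy()
        ts[loop_length // 2] = 0.5  # guarantee a sample exactly at the apex
    return _bezier(s, apex, e, ts)


def _ligand_atoms(center: np.ndarray) -> list[Atom]:
    """Rigid planar 9-heavy-atom fragment (6-ring + 3 substituents), orotate-sized."""
    ring_elems = ["C", "N", "C", "N", "C", "C"]
    atoms = []
    for k in range(6):
        ang = np.pi / 3.0 * k
        pos = center + 1.4 * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms.append(Atom(name=f"{ring_elems[k]}{k + 1}", element=ring_elems[k], coords=pos, is_hetero=True))
    for k, ang in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3)):
        pos = center + 2.6 * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms.append(Atom(name=f"O{k + 1}", element="O", coords=pos, is_hetero=True))
    return atoms


def _place_ligand(
    protein_coords: np.ndarray,
    loop_coords: np.ndarray,
    target: float,
    direction: np.ndarray,
    start: np.ndarray,
) -> np.ndarray:
    """Slide the ligand center along ``direction`` until min(loop, ligand) == target."""
    center = start.astype(float)
    for _ in range(60):
        lig = np.array([a.coords for a in _ligand_atoms(center)])
        d = np.linalg.norm(loop_coords[:, None, :] - lig[None, :, :], axis=2)
        m = float(d.min())
        if abs(m - target) <= _PLACEMENT_TOL:
            break
        center = center + (target - m) * direction
    else:
        raise GeometryError("ligand placement did not converge")
    lig = np.array([a.coords for a in _ligand_atoms(center)])
    d_all = np.linalg.norm(protein_coords[:, None, :] - lig[None, :, :], axis=2)
    if float(d_all.min()) < STERIC_FLOOR - 1e-9:
        raise GeometryError(
            f"ligand placement collides with the protein (min {float(d_all.min()):.2f} A)"
        )
    return center


def _build_chain(
    spec: SyntheticSpec, chain_id: str, offset: np.ndarray
) -> tuple[list[Residue], ChainTruth]:
    definition = motif_for_length(spec.loop_length)
    core = _helix_ca(spec.n_core_residues)
    bulge = 6.0 if spec.loop_state == "in" else -6.0
    loop = _loop_ca(core[-1], spec.loop_length, bulge)

    residues: list[Residue] = []
    number = 0
    for k, ca in enumerate(core):
        number = k + 1
        o_dir = ca - np.array([0.0, 0.0, ca[2]])
        o_dir = o_dir / np.linalg.norm(o_dir)
        residues.append(
            Residue(
                author_number=number,
                name="ALA",
                atoms=[
                    Atom(name="CA", element="C", coords=ca + offset),
                    Atom(name="O", element="O", coords=ca + 1.23 * o_dir + offset),
                ],
            )
        )
    loop_start = number + 1
    loop_residues: list[Residue] = []
    away = np.array([-1.0, 0.0, 0.0])  # -x: opposite the pocket side
    for k, ca in enumerate(loop):
        loop_residues.append(
            Residue(
                author_number=loop_start + k,
                name=_ONE_TO_THREE[definition.motif[k]],
                # carbonyl O on the side facing away from the pocket, so the
                # C-alpha apex carries the minimum contact distance
                atoms=[
                    Atom(name="CA", element="C", coords=ca + offset),
                    Atom(name="O", element="O", coords=ca + 1.23 * away + offset),
                ],
            )
        )
    loop_range = (loop_start, loop_start + spec.loop_length - 1)

    min_contact: float | None = None
    het: list[Residue] = []
    if spec.include_ligand:
        resolved_loop = [
            r for k, r in enumerate(loop_residues) if k not in set(spec.missing_loop_residues)
        ]
        contact_set = resolved_loop if resolved_loop else loop_residues
        loop_coords = np.array(
            [a.coords - offset for r in contact_set for a in r.atoms]
        )
        protein_coords = np.array(
            [a.coords - offset for r in residues + loop_residues for a in r.atoms]
        )
        apex = loop[len(loop) // 2]
        start = apex + np.array([spec.target_contact_distance + 4.0, 0.0, 0.0])
        if spec.loop_state == "out":
            start = np.array([max(loop[:, 0].max(), core[:, 0].max()), 0.0, apex[2]]) + np.array(
                [spec.target_contact_distance + 4.0, 0.0, 0.0]
            )
        center = _place_ligand(
            protein_coords, loop_coords, spec.target_contact_distance, np.array([1.0, 0.0, 0.0]), start
        )
        lig_atoms = [
            Atom(name=a.name, element=a.element, coords=a.coords + offset, is_hetero=True)
            for a in _ligand_atoms(center)
        ]
        het.append(
            Residue(
                author_number=loop_range[1] + 10,
                name=LIGAND_NAME,
                atoms=lig_atoms,
                is_polymer=False,
            )
        )
        lig_coords = np.array([a.coords - offset for a in lig_atoms])
        if resolved_loop:
            d = np.linalg.norm(loop_coords[:, None, :] - lig_coords[None, :, :], axis=2)
            min_contact = float(d.min())
        if spec.include_metal:
            zn = center + np.array([0.0, 0.0, 2.2])
            het.append(
                Residue(
                    author_number=loop_range[1] + 11,
                    name="ZN",
                    atoms=[Atom(name="ZN", element="ZN", coords=zn + offset, is_hetero=True)],
                    is_polymer=False,
                )
            )
    elif spec.include_metal:
        apex = loop[len(loop) // 2]
        zn = apex + np.array([6.0, 0.0, 0.0])
        het.append(
            Residue(
                author_number=loop_range[1] + 11,
                name="ZN",
                atoms=[Atom(name="ZN", element="ZN", coords=zn + offset, is_hetero=True)],
                is_polymer=False,
            )
        )

    kept_loop = [
        r for k, r in enumerate(loop_residues) if k not in set(spec.missing_loop_residues)
    ]
    truth = ChainTruth(
        chain_id=chain_id,
        loop_state=spec.loop_state,
        residue_range=loop_range,
        min_contact_distance=min_contact,
        ligand=LIGAND_NAME if spec.include_ligand else "NONE",
    )
    return residues + kept_loop + het, truth


def make_monomer(spec: SyntheticSpec, tag: str = "SYN1") -> tuple[StructureModel, GroundTruth]:
    """Build a synthetic structure (one or more chains) with ground truth."""
    model = StructureModel(pdb_id=tag, source_format="synthetic")
    truth = GroundTruth()
    labels = [chr(ord("A") + k) for k in range(spec.n_chains)]
    for k, label in enumerate(labels):
        offset = np.array([0.0, 60.0 * k, 0.0])
        residues, chain_truth = _build_chain(spec, label, offset)
        model.chains[label] = residues
        truth.chains.append(chain_truth)
    return model, truth


def make_corpus(
    n: int,
    in_fraction: float,
    out_dir: str | Path,
    seed: int = 0,
    cutoff: float = 4.0,
    in_margin: float = 1.0,
    out_margin: float = 2.0,
    loop_length: int = 16,
) -> tuple[list[Path], Path]:
    """Generate ``n`` single-chain files with an exact in/out allocation.

    Loop-in targets are drawn uniformly from [steric floor, cutoff - in_margin]
    and loop-out targets from [cutoff + out_margin, cutoff + out_margin + 4],
    i.e. well inside/outside the classification margin.  The truth table TSV
    lists every chain's state and realized contact distance.  Identical seeds
    give byte-identical output.
    """
    if not (0.0 <= in_fraction <= 1.0):
        raise ValueError("in_fraction must be within [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_in = round(n * in_fraction)
    states = ["in"] * n_in + ["out"] * (n - n_in)
    files: list[Path] = []
    rows = []
    for idx, state in enumerate(states):
        if state == "in":
            target = float(rng.uniform(STERIC_FLOOR + 0.1, cutoff - in_margin))
        else:
            target = float(rng.uniform(cutoff + out_margin, cutoff + out_margin + 4.0))
        tag = f"S{idx:04d}"
        spec = SyntheticSpec(
            loop_length=loop_length,
            loop_state=state,
            target_contact_distance=round(target, 2),
            seed=seed + idx,
        )
        model, truth = make_monomer(spec, tag=tag)
        path = out_dir / f"{tag.lower()}.pdb"
        write_structure(model, path)
        files.append(path)
        ct = truth.chains[0]
        rows.append(
            {
                "file": path.name,
                "tag": tag,
                "chain": ct.chain_id,
                "state": ct.loop_state,
                "loop_start": ct.residue_range[0],
                "loop_end": ct.residue_range[1],
                "min_contact": f"{ct.min_contact_distance:.3f}",
                "ligand": ct.ligand,
            }
        )
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["file", "tag", "chain", "state", "loop_start", "loop_end", "min_contact", "ligand"],
            delimiter="\t",
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(rows)
    return files, truth_path
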
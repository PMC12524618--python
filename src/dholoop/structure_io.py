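"""Reading and writing macromolecular coordinates.

A thin, uniform in-memory model (``StructureModel`` -> chains -> ``Residue``
-> ``Atom``) over gemmi's PDB and mmCIF readers.  Author residue numbering is
authoritative throughout the package, matching how residues are referred to
in the structural literature this pipeline serves.

Policies:

* only the first model of multi-model files is read;
* alternate locations are resolved per atom name by highest occupancy,
  ties broken by lexicographically smallest altloc label;
* waters (HOH/WAT/DOD) are flagged and excluded from ligand logic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "StructureIOError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "extract_chain_sequence",
    "GAP_CHAR",
]

GAP_CHAR = "-"
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureIOError(ValueError):
    """Unreadable, malformed, or unwritable coordinate data."""


class EmptyStructureError(StructureIOError):
    """File contains no polymer residues."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureIOError(f"atom {self.name}: bad coordinates {self.coords}")
        if not self.element:
            raise StructureIOError(f"atom {self.name}: empty element")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    author_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_water: bool = False
    is_polymer: bool = True

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class StructureModel:
    pdb_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = "synthetic"  # PDB / mmCIF / synthetic

    def chain(self, label: str) -> list[Residue]:
        try:
            return self.chains[label]
        except KeyError:
            raise KeyError(f"{self.pdb_id}: no chain {label!r}") from None

    def polymer_residues(self, label: str) -> list[Residue]:
        return [r for r in self.chain(label) if r.is_polymer]

    def hetero_residues(self, label: str) -> list[Residue]:
        return [r for r in self.chain(label) if not r.is_polymer and not r.is_water]

    def validate(self) -> None:
        for label, residues in self.chains.items():
            nums = [r.author_number for r in residues if r.is_polymer]
            if any(b < a for a, b in zip(nums, nums[1:])):
                raise StructureIOError(f"chain {label}: polymer residues out of order")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties -> smallest altloc."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
        else:
            best = by_name[atom.name]
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                best.occupancy,
                _altloc_rank(best.altloc),
            ):
                by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> float:
    # Higher is better: blank beats any label; otherwise 'A' beats 'B'.
    if not altloc:
        return math.inf
    return -ord(altloc)


def read_structure(path: str | Path, format_hint: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format_hint`` may be ``"pdb"`` or ``"mmcif"``; by default the format is
    detected from the file contents/extension.  Only the first model of a
    multi-model file is kept.
    """
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"no such file: {path}")
    try:
        if format_hint is None:
            st = gemmi.read_structure(str(path))
        else:
            fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[
                format_hint.lower()
            ]
            st = gemmi.read_structure(str(path), format=fmt)
    except KeyError:
        raise StructureIOError(f"unknown format hint {format_hint!r}") from None
    except Exception as exc:  # gemmi raises RuntimeError subclasses
        raise StructureIOError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    source = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    model = StructureModel(pdb_id=(st.name or path.stem).strip().upper(), source_format=source)
    gmodel = st[0]
    n_polymer = 0
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            is_water = gres.name in _WATER_NAMES
            is_het = gres.het_flag == "H"
            info = gemmi.find_tabulated_residue(gres.name)
            is_amino = bool(info and info.is_amino_acid())
            is_polymer = is_amino and not is_water
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name or "X",
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    is_hetero=is_het or is_water,
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                    occupancy=ga.occ,
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    author_number=gres.seqid.num,
                    name=gres.name,
                    atoms=_resolve_altlocs(atoms),
                    insertion_code=(gres.seqid.icode or "").strip(),
                    is_water=is_water,
                    is_polymer=is_polymer,
                )
            )
            n_polymer += int(is_polymer)
        if gchain.name in model.chains:
            model.chains[gchain.name].extend(residues)
        else:
            model.chains[gchain.name] = residues
    if n_polymer == 0:
        raise EmptyStructureError(f"{path}: no polymer residues")
    model.validate()
    return model


def write_structure(model: StructureModel, path: str | Path, format: str = "PDB") -> None:
    """Write the model as a fixed-column PDB file (re-parses to an equal model)."""
    if format.upper() != "PDB":
        raise StructureIOError(f"unsupported output format {format!r}")
    st = gemmi.Structure()
    st.name = model.pdb_id
    gmodel = gemmi.Model("1")
    for label, residues in model.chains.items():
        if len(label) > 2:
            raise StructureIOError(f"chain label {label!r} too long for PDB output")
        gchain = gemmi.Chain(label)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            gres.het_flag = "H" if (not res.is_polymer or res.is_water) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


_THREE_TO_ONE_EXTRA = {"MSE": "M", "SEC": "U", "PYL": "O"}


def one_letter_code(name: str) -> str:
    """Three-letter residue name to one-letter code (nonstandard -> X, MSE -> M)."""
    return _one_letter(name)


def _one_letter(name: str) -> str:
    if name in _THREE_TO_ONE_EXTRA:
        return _THREE_TO_ONE_EXTRA[name]
    info = gemmi.find_tabulated_residue(name)
    if info and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def extract_chain_sequence(model: StructureModel, chain: str) -> tuple[str, int]:
    """One-letter sequence of a chain with ``-`` marking unresolved numbers.

    Returns ``(sequence, first_author_number)``; position ``i`` of the
    sequence corresponds to author number ``first_author_number + i``.
    Nonstandard residues map to ``X`` (selenomethionine to ``M``).
    """
    residues = model.polymer_residues(chain)
    if not residues:
        raise KeyError(f"{model.pdb_id}: chain {chain!r} has no polymer residues")
    by_number = {r.author_number: r for r in residues}
    lo = min(by_number)
    hi = max(by_number)
    seq = "".join(
        _one_letter(by_number[i].name) if i in by_number else GAP_CHAR
        for i in range(lo, hi + 1)
    )
    return seq, lo
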
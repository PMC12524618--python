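"""Catalytic metal sites, active-site ligands, and the conserved arginine.

DHOase is a Zn metalloenzyme; its catalytic center carries one to three metal
ions (the alpha/beta/gamma sites).  A bound small molecule is treated as an
active-site ligand when at least one of its heavy atoms lies within a radius
(default 8 A) of a metal of the same chain; waters, metals themselves, and
common crystallization-buffer components are never ligands.  When a chain has
no metal, the caller may supply the loop centroid as the site anchor.

``check_conserved_arg`` supports the bona fide DHOase check: a true DHOase
carries a conserved substrate-binding arginine near a known position, and a
protein where it is substituted (e.g. by tryptophan) is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .structure_io import Atom, Residue, StructureModel

__all__ = [
    "METAL_ELEMENTS",
    "MetalSite",
    "BoundLigand",
    "find_metals",
    "find_active_site_ligands",
    "check_conserved_arg",
    "DEFAULT_SITE_RADIUS",
]

#: Elements accepted as catalytic/structural metals.
METAL_ELEMENTS = frozenset({"ZN", "CO", "NI", "MN", "MG", "CD"})

DEFAULT_SITE_RADIUS = 8.0  # Angstrom

_SITE_LABELS = ("alpha", "beta", "gamma")


@dataclass
class MetalSite:
    chain_id: str
    element: str
    coords: np.ndarray
    site_label: str = "unassigned"


@dataclass
class BoundLigand:
    chain_id: str
    het_name: str
    normalized_name: str
    heavy_atoms: list[Atom]
    min_dist_to_metal: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms])


def _load_tsv_column(filename: str) -> list[str]:
    text = (resources.files("dholoop.data") / filename).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return lines[1:]  # drop header


def _buffer_blocklist() -> frozenset[str]:
    return frozenset(_load_tsv_column("buffer_blocklist.tsv"))


def _het_map() -> dict[str, str]:
    out = {}
    for line in _load_tsv_column("het_name_map.tsv"):
        code, name = line.split("\t")
        out[code] = name
    return out


_BLOCKLIST = _buffer_blocklist()
_HET_MAP = _het_map()


def normalize_het_name(het: str) -> str:
    return _HET_MAP.get(het.upper(), het.upper())


def find_metals(model: StructureModel, chain: str) -> list[MetalSite]:
    """All mono-/di-atomic hetero groups made of metal atoms in a chain.

    Zn sites are listed first; within an element, sites are ordered by
    distance to the chain centroid.  The first three sites get the
    alpha/beta/gamma labels (reporting only; classification never uses them).
    """
    residues = model.chain(chain)
    poly_coords = [
        a.coords for r in residues if r.is_polymer for a in r.atoms if not a.is_hydrogen
    ]
    centroid = (
        np.mean(poly_coords, axis=0) if poly_coords else np.zeros(3)
    )
    sites: list[MetalSite] = []
    for res in residues:
        if res.is_polymer or res.is_water:
            continue
        atoms = res.heavy_atoms()
        if 1 <= len(atoms) <= 2 and all(a.element.upper() in METAL_ELEMENTS for a in atoms):
            for a in atoms:
                sites.append(MetalSite(chain_id=chain, element=a.element.upper(), coords=a.coords))
    sites.sort(
        key=lambda s: (s.element != "ZN", float(np.linalg.norm(s.coords - centroid)))
    )
    for i, site in enumerate(sites):
        site.site_label = _SITE_LABELS[i] if i < len(_SITE_LABELS) else "unassigned"
    return sites


def find_active_site_ligands(
    model: StructureModel,
    chain: str,
    metals: list[MetalSite],
    radius: float = DEFAULT_SITE_RADIUS,
    anchor: np.ndarray | None = None,
) -> list[BoundLigand]:
    """Hetero groups with a heavy atom within ``radius`` of the site.

    The site is the set of metal positions of the chain; with no metals the
    optional ``anchor`` point (e.g. the loop centroid) is used instead.
    Waters, metals, and blocklisted buffer components are excluded.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    anchors = [m.coords for m in metals]
    if not anchors:
        if anchor is None:
            return []
        anchors = [np.asarray(anchor, dtype=float)]
    anchors_arr = np.array(anchors)
    ligands: list[BoundLigand] = []
    for res in model.chain(chain):
        if res.is_polymer or res.is_water:
            continue
        if res.name.upper() in _BLOCKLIST:
            continue
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        if all(a.element.upper() in METAL_ELEMENTS for a in heavy) and len(heavy) <= 2:
            continue  # a metal site, not a ligand
        coords = np.array([a.coords for a in heavy])
        dmin = float(
            np.min(np.linalg.norm(coords[:, None, :] - anchors_arr[None, :, :], axis=2))
        )
        if dmin <= radius:
            ligands.append(
                BoundLigand(
                    chain_id=chain,
                    het_name=res.name,
                    normalized_name=normalize_het_name(res.name),
                    heavy_atoms=heavy,
                    min_dist_to_metal=dmin,
                )
            )
    ligands.sort(key=lambda l: l.min_dist_to_metal)
    return ligands


def check_conserved_arg(
    model: StructureModel,
    chain: str,
    expected_position: int,
    window: int = 2,
) -> tuple[bool | None, Residue | None]:
    """Is there an arginine within ``window`` residues of the expected position?

    Returns ``(True, residue)`` when found, ``(False, nearest_residue)`` when
    the window is resolved but has no Arg, and ``(None, None)`` when the whole
    window is unresolved (undetermined, deliberately distinct from False).
    """
    by_number = {r.author_number: r for r in model.polymer_residues(chain)}
    in_window = [
        by_number[n]
        for n in range(expected_position - window, expected_position + window + 1)
        if n in by_number
    ]
    if not in_window:
        return None, None
    for res in sorted(in_window, key=lambda r: abs(r.author_number - expected_position)):
        if res.name.upper() == "ARG":
            return True, res
    nearest = min(in_window, key=lambda r: abs(r.author_number - expected_position))
    return False, nearest
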
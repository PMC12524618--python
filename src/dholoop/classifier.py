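"""Loop-in / loop-out classification of a monomer from its coordinates.

Two rules, mirroring how the survey labels were assigned:

* **Contact rule** (ligand-bound monomers): the loop is *in* when the minimum
  heavy-atom distance between resolved loop residues and the bound ligand is
  at or below a cutoff (default 4.0 A, covering hydrogen bonds and van der
  Waals contacts), otherwise *out*.  A loop that is mostly unresolved
  (completeness < 0.7) and not in contact is *out* with a disordered flag.

* **Apo reference rule** (ligand-free monomers): after superposing the apo
  chain onto a ligand-bound loop-in reference with both loops excluded from
  the fit (core superposition), the loop's key-residue backbone carbonyl
  oxygen is compared with its reference counterpart.  Displacement at or
  below 2.0 A means loop-in; distance of at least 5.0 A from the reference
  ligand's nearest heavy atom means loop-out; the gap between the thresholds
  is deliberately left undetermined rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .active_site import (
    DEFAULT_SITE_RADIUS,
    BoundLigand,
    find_active_site_ligands,
    find_metals,
)
from .annotations import LoopDefinition, MonomerAnnotation
from .loop_locator import LoopLocateError, LoopSegment, locate_loop, loop_completeness
from .structure_io import Residue, StructureModel
from .superposition import SuperpositionError, superpose_chains

__all__ = [
    "DEFAULT_CONTACT_CUTOFF",
    "COMPLETENESS_THRESHOLD",
    "DEFAULT_APO_IN_THRESHOLD",
    "DEFAULT_APO_OUT_THRESHOLD",
    "ContactReport",
    "ApoReferenceReport",
    "LoopClassification",
    "ReferenceEntry",
    "classify_by_contact",
    "classify_apo_by_reference",
    "classify_monomer",
]

DEFAULT_CONTACT_CUTOFF = 4.0  # A, heavy-atom minimum distance
COMPLETENESS_THRESHOLD = 0.7  # below this, a non-contacting loop is flagged disordered
DEFAULT_APO_IN_THRESHOLD = 2.0  # A, key-atom displacement vs reference
DEFAULT_APO_OUT_THRESHOLD = 5.0  # A, key atom to reference ligand


@dataclass
class ContactReport:
    """Minimum loop-ligand heavy-atom distances, per residue and overall."""

    min_distance: float
    closest_pair: tuple[str, str]  # ("resname number/atom", "ligand atom")
    per_residue_min: dict[int, float]


@dataclass
class ApoReferenceReport:
    """Key-atom geometry after core superposition onto the reference."""

    key_displacement: float | None  # apo key O vs reference key O, A
    key_to_ligand: float | None  # apo key O vs nearest reference ligand heavy atom, A
    reference_pdb_id: str
    core_rmsd: float
    reason: str = ""


@dataclass
class LoopClassification:
    state: str  # LOOP_IN / LOOP_OUT / UNDETERMINED
    rule: str  # "contact" or "apo_reference"
    evidence: ContactReport | ApoReferenceReport | None
    cutoff_used: float
    disordered_loop: bool = False


@dataclass
class ReferenceEntry:
    """A curated ligand-bound loop-in exemplar used by the apo rule."""

    model: StructureModel
    chain: str
    definition: LoopDefinition
    segment: LoopSegment = field(init=False)
    ligand: BoundLigand = field(init=False)

    def __post_init__(self) -> None:
        self.segment = locate_loop(self.model, self.chain, self.definition)
        metals = find_metals(self.model, self.chain)
        ligands = find_active_site_ligands(self.model, self.chain, metals)
        if not ligands:
            raise ValueError(
                f"reference {self.model.pdb_id}/{self.chain} has no active-site ligand"
            )
        self.ligand = ligands[0]


def _contact_report(segment: LoopSegment, ligand: BoundLigand) -> ContactReport:
    lig_coords = ligand.coords
    per_residue: dict[int, float] = {}
    best = np.inf
    best_pair = ("", "")
    for res in segment.resolved_residues:
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        coords = np.array([a.coords for a in heavy])
        dmat = np.linalg.norm(coords[:, None, :] - lig_coords[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
        dmin = float(dmat[i, j])
        per_residue[res.author_number] = dmin
        if dmin < best:
            best = dmin
            best_pair = (
                f"{res.name} {res.author_number}/{heavy[i].name}",
                ligand.heavy_atoms[j].name,
            )
    return ContactReport(
        min_distance=float(best), closest_pair=best_pair, per_residue_min=per_residue
    )


def classify_by_contact(
    segment: LoopSegment,
    ligand: BoundLigand,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> LoopClassification:
    """Contact rule: loop-in iff the loop touches the ligand within ``cutoff``."""
    if not ligand.heavy_atoms:
        raise ValueError("ligand has no heavy atoms")
    completeness = loop_completeness(segment)
    if not segment.resolved_residues:
        return LoopClassification(
            state="UNDETERMINED",
            rule="contact",
            evidence=None,
            cutoff_used=cutoff,
            disordered_loop=True,
        )
    report = _contact_report(segment, ligand)
    if report.min_distance <= cutoff:
        state, disordered = "LOOP_IN", False
    else:
        state = "LOOP_OUT"
        disordered = completeness < COMPLETENESS_THRESHOLD
    return LoopClassification(
        state=state,
        rule="contact",
        evidence=report,
        cutoff_used=cutoff,
        disordered_loop=disordered,
    )


def _key_residue(segment: LoopSegment) -> Residue | None:
    """The loop's key residue: the one named in the definition, else the middle one."""
    definition = segment.definition
    if definition.key_residue is not None:
        _, number = definition.key_residue
        for res in segment.resolved_residues:
            if res.author_number == number:
                return res
        return None
    lo, hi = segment.residue_range
    mid = (lo + hi) // 2
    for res in segment.resolved_residues:
        if res.author_number == mid:
            return res
    return None  # the key (middle) residue itself is unresolved


def classify_apo_by_reference(
    apo_model: StructureModel,
    apo_chain: str,
    apo_segment: LoopSegment,
    reference: ReferenceEntry,
    in_threshold: float = DEFAULT_APO_IN_THRESHOLD,
    out_threshold: float = DEFAULT_APO_OUT_THRESHOLD,
) -> LoopClassification:
    """Apo rule: compare the key-residue carbonyl oxygen with a loop-in reference."""
    key = _key_residue(apo_segment)
    key_o = key.atom("O") if key is not None else None
    if key_o is None:
        return LoopClassification(
            state="UNDETERMINED",
            rule="apo_reference",
            evidence=ApoReferenceReport(
                key_displacement=None,
                key_to_ligand=None,
                reference_pdb_id=reference.model.pdb_id,
                core_rmsd=float("nan"),
                reason="key residue (or its carbonyl oxygen) unresolved in apo chain",
            ),
            cutoff_used=in_threshold,
        )
    # Core superposition: apo (mobile) onto reference (fixed), both loops excluded.
    fit = superpose_chains(
        reference.model,
        reference.chain,
        apo_model,
        apo_chain,
        exclude_loop=[reference.segment, apo_segment],
    )
    apo_o_in_ref = fit.transform(key_o.coords)
    ref_key = _key_residue(reference.segment)
    ref_o = ref_key.atom("O") if ref_key is not None else None
    displacement = (
        float(np.linalg.norm(apo_o_in_ref - ref_o.coords)) if ref_o is not None else None
    )
    key_to_ligand = float(
        np.min(np.linalg.norm(reference.ligand.coords - apo_o_in_ref, axis=1))
    )
    report = ApoReferenceReport(
        key_displacement=displacement,
        key_to_ligand=key_to_ligand,
        reference_pdb_id=reference.model.pdb_id,
        core_rmsd=fit.rmsd,
    )
    if displacement is not None and displacement <= in_threshold:
        state = "LOOP_IN"
    elif key_to_ligand >= out_threshold:
        state = "LOOP_OUT"
    else:
        state = "UNDETERMINED"
    return LoopClassification(
        state=state, rule="apo_reference", evidence=report, cutoff_used=in_threshold
    )


def classify_monomer(
    model: StructureModel,
    chain: str,
    definition: LoopDefinition,
    references: dict[str, ReferenceEntry] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    site_radius: float = DEFAULT_SITE_RADIUS,
    in_threshold: float = DEFAULT_APO_IN_THRESHOLD,
    out_threshold: float = DEFAULT_APO_OUT_THRESHOLD,
) -> tuple[MonomerAnnotation, LoopClassification]:
    """Classify one chain: contact rule if a ligand is bound, else apo rule.

    ``references`` maps DHOase type ("I"/"II"/"III") to a curated loop-in
    exemplar.  With no ligand and no same-type reference the result is
    UNDETERMINED.
    """
    segment = locate_loop(model, chain, definition)
    metals = find_metals(model, chain)
    anchor = None
    if segment.resolved_residues:
        anchor = np.mean(
            [a.coords for r in segment.resolved_residues for a in r.heavy_atoms()], axis=0
        )
    ligands = find_active_site_ligands(model, chain, metals, radius=site_radius, anchor=anchor)
    if ligands:
        classification = classify_by_contact(segment, ligands[0], cutoff=cutoff)
        provenance = "contact_rule"
        ligand_name = ligands[0].normalized_name
    elif references and definition.dhoase_type in references:
        classification = classify_apo_by_reference(
            model,
            chain,
            segment,
            references[definition.dhoase_type],
            in_threshold=in_threshold,
            out_threshold=out_threshold,
        )
        provenance = "apo_reference_rule"
        ligand_name = "NONE"
    else:
        classification = LoopClassification(
            state="UNDETERMINED", rule="contact", evidence=None, cutoff_used=cutoff
        )
        provenance = "contact_rule"
        ligand_name = "NONE"
    annotation = MonomerAnnotation(
        pdb_id=model.pdb_id,
        chain_id=chain,
        species=definition.species,
        dhoase_type=definition.dhoase_type,
        loop_state=classification.state,
        state_provenance=provenance,
        ligand=ligand_name,
        disordered_loop=classification.disordered_loop,
    )
    return annotation, classification
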
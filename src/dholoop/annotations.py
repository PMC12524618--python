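"""Curated per-structure annotations and loop definitions.

The packaged annotation corpus transcribes, structure by structure, the
published survey of dihydroorotase (DHOase) crystal structures: one row per
PDB entry with its bound ligands, similarity to the *E. coli* reference fold
(sequence identity, TM-score, RMSD), DHOase type (I/II/III), and the curated
loop state of every chain.  Two entries are excluded from analysis: a protein
that is likely not a bona fide DHOase (it lacks the conserved substrate-binding
arginine) and an enzymatically inactive DHOase-like domain.

Structure-level rows are expanded into per-monomer records under two
documented conventions:

* a raw ``in/out`` chain state (mixed substrate/product occupancy) counts as
  loop-in for all summaries;
* a raw ``out a`` state (loop partially unresolved) counts as loop-out with
  ``disordered_loop=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "LIGAND_VOCABULARY",
    "RAW_STATE_TOKENS",
    "StructureRecord",
    "LoopDefinition",
    "MonomerAnnotation",
    "AnnotationError",
    "load_annotation_table",
    "load_loop_definitions",
    "write_annotation_table",
    "expand_monomers",
    "infer_species",
    "packaged_annotation_path",
    "packaged_loop_definition_path",
]

#: Controlled vocabulary for normalized ligand names.
LIGAND_VOCABULARY = frozenset(
    {
        "NCA",
        "DHO",
        "DHO_NCA_MIX",
        "FOA",
        "OROTIC_ACID",
        "OROTIC_NCA_MIX",
        "HDDP",
        "ACY",
        "MALIC_ACID",
        "5FU",
        "5AU",
        "PLUMBAGIN",
        "CITRATE",
        "CACODYLATE",
        "IMIDAZOLE",
        "NONE",
    }
)

#: Raw chain-state tokens as transcribed from the survey table.
#: ``in_out`` is the mixed-occupancy "in/out" state; ``out_d`` is "out a"
#: (loop-out with some loop residues unresolved).
RAW_STATE_TOKENS = frozenset({"in", "out", "in_out", "out_d"})

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

# Ordered so that e.g. "Human ... obtained recombinantly from E. coli"
# resolves to Human.  Patterns are matched case-insensitively.
_SPECIES_PATTERNS: tuple[tuple[str, str], ...] = (
    ("human", "Human"),
    ("chaetomium thermophilum", "C. thermophilum"),
    ("saccharomyces cerevisiae", "S. cerevisiae"),
    ("escherichia coli", "E. coli"),
    ("e. coli", "E. coli"),
    ("aquifex aeolicus", "A. aeolicus"),
    ("porphyromonas gingivalis", "P. gingivalis"),
    ("agrobacterium fabrum", "A. fabrum"),
    ("thermus thermophilus", "T. thermophilus"),
    ("staphylococcus aureus", "S. aureus"),
    ("salmonella enterica", "S. enterica"),
    ("bacillus anthracis", "B. anthracis"),
    ("campylobacter jejuni", "C. jejuni"),
    ("burkholderia cenocepacia", "B. cenocepacia"),
    ("vibrio cholerae", "V. cholerae"),
    ("yersinia pestis", "Y. pestis"),
    ("methanococcus jannaschii", "M. jannaschii"),
)

_FIXTURE_COLUMNS = [
    "pdb_id",
    "description",
    "ligands",
    "metal",
    "per_chain_ligands",
    "residue_range",
    "seq_id_pct",
    "tm_score",
    "rmsd",
    "type",
    "chain_states",
    "flags",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation data."""


@dataclass
class StructureRecord:
    """One survey row: a PDB entry with curated per-chain loop states."""

    pdb_id: str
    description: str
    ligand_labels: frozenset[str]
    metal_annotation: str
    per_chain_ligands: dict[str, str]
    residue_range: tuple[int, int] | None
    seq_identity_pct: float | None
    tm_score: float
    rmsd_ang: float
    dhoase_type: str  # "I", "II", "III" or "UNDETERMINED"
    chain_states: dict[str, str]
    excluded: bool = False
    exclusion_reason: str = ""
    apo_reference_in: bool = False  # footnote-b rows: apo, classified in by superposition

    def __post_init__(self) -> None:
        if not _PDB_ID_RE.match(self.pdb_id):
            raise AnnotationError(f"invalid PDB id {self.pdb_id!r}")
        if not (0.0 < self.tm_score <= 1.0):
            raise AnnotationError(f"{self.pdb_id}: TM-score {self.tm_score} outside (0, 1]")
        if self.rmsd_ang < 0:
            raise AnnotationError(f"{self.pdb_id}: negative RMSD")
        if self.seq_identity_pct is not None and not (0.0 < self.seq_identity_pct <= 100.0):
            raise AnnotationError(f"{self.pdb_id}: sequence identity outside (0, 100]")
        if self.excluded != bool(self.exclusion_reason):
            raise AnnotationError(f"{self.pdb_id}: excluded flag and reason disagree")
        if not self.excluded and not self.chain_states:
            raise AnnotationError(f"{self.pdb_id}: non-excluded row without chain states")
        for chain, token in self.chain_states.items():
            if token not in RAW_STATE_TOKENS:
                raise AnnotationError(f"{self.pdb_id}: unknown state token {token!r} for chain {chain}")
        for name in self.ligand_labels:
            if name not in LIGAND_VOCABULARY:
                raise AnnotationError(f"{self.pdb_id}: unknown ligand token {name!r}")
        for chain, name in self.per_chain_ligands.items():
            if name not in LIGAND_VOCABULARY:
                raise AnnotationError(f"{self.pdb_id}: unknown per-chain ligand {name!r}")

    @property
    def species(self) -> str:
        return infer_species(self.description)


@dataclass(frozen=True)
class LoopDefinition:
    """Species-specific definition of the flexible active-site loop.

    ``motif`` is the one-letter loop sequence; ``residue_range`` (author
    numbering, inclusive) is given where the literature states one whose
    width matches the loop length; ``key_residue`` names the residue whose
    backbone carbonyl oxygen anchors the apo-state classification rule.
    """

    species: str
    dhoase_type: str
    motif: str
    residue_range: tuple[int, int] | None = None
    key_residue: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.motif:
            raise AnnotationError("empty loop motif")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if hi - lo + 1 != self.loop_length:
                raise AnnotationError(
                    f"{self.species}: residue range {lo}-{hi} width does not "
                    f"match loop length {self.loop_length}"
                )

    @property
    def loop_length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class MonomerAnnotation:
    """Loop state of one chain of one structure."""

    pdb_id: str
    chain_id: str
    species: str
    dhoase_type: str
    loop_state: str  # LOOP_IN / LOOP_OUT / UNDETERMINED
    state_provenance: str  # curated / contact_rule / apo_reference_rule / mixed_in_out_convention
    ligand: str = "NONE"
    disordered_loop: bool = False


def infer_species(description: str) -> str:
    """Map a structure description to its short species label."""
    low = description.lower()
    for pattern, label in _SPECIES_PATTERNS:
        if pattern in low:
            return label
    return "unknown"


def _parse_range(text: str) -> tuple[int, int] | None:
    if text in ("-", "", "ND"):
        return None
    lo, _, hi = text.partition("-")
    try:
        return int(lo), int(hi)
    except ValueError as exc:
        raise AnnotationError(f"bad residue range {text!r}") from exc


def _parse_chain_map(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if text in ("-", ""):
        return out
    for item in text.split(","):
        chain, sep, value = item.partition(":")
        if not sep or not chain or not value:
            raise AnnotationError(f"bad chain map entry {item!r}")
        out[chain] = value
    return out


def load_annotation_table(path: str | Path | None = None) -> list[StructureRecord]:
    """Parse the tab-separated annotation corpus into validated records.

    Row order is preserved.  Raises :class:`AnnotationError` naming the
    offending row for malformed input.
    """
    if path is None:
        path = packaged_annotation_path()
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise AnnotationError(f"{path}: empty annotation table")
    header = lines[0].split("\t")
    if header != _FIXTURE_COLUMNS:
        raise AnnotationError(f"{path}: unexpected header {header}")
    records: list[StructureRecord] = []
    for row_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(_FIXTURE_COLUMNS):
            raise AnnotationError(f"{path}: row {row_no}: expected {len(_FIXTURE_COLUMNS)} columns, got {len(fields)}")
        row = dict(zip(_FIXTURE_COLUMNS, fields))
        flags = [] if row["flags"] in ("-", "") else row["flags"].split(";")
        excluded_reason = ""
        apo_ref = False
        for flag in flags:
            if flag.startswith("excluded:"):
                excluded_reason = flag.split(":", 1)[1]
            elif flag == "b":
                apo_ref = True
            else:
                raise AnnotationError(f"{path}: row {row_no}: unknown flag {flag!r}")
        ligands = (
            frozenset()
            if row["ligands"] in ("-", "NONE", "")
            else frozenset(row["ligands"].split(","))
        )
        try:
            record = StructureRecord(
                pdb_id=row["pdb_id"],
                description=row["description"],
                ligand_labels=ligands,
                metal_annotation=row["metal"],
                per_chain_ligands=_parse_chain_map(row["per_chain_ligands"]),
                residue_range=_parse_range(row["residue_range"]),
                seq_identity_pct=None if row["seq_id_pct"] == "ND" else float(row["seq_id_pct"]),
                tm_score=float(row["tm_score"]),
                rmsd_ang=float(row["rmsd"]),
                dhoase_type="UNDETERMINED" if row["type"] == "ND" else row["type"],
                chain_states=_parse_chain_map(row["chain_states"]),
                excluded=bool(excluded_reason),
                exclusion_reason=excluded_reason,
                apo_reference_in=apo_ref,
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{path}: row {row_no}: {exc}") from exc
        except ValueError as exc:
            raise AnnotationError(f"{path}: row {row_no}: {exc}") from exc
        records.append(record)
    return records


def write_annotation_table(records: Iterable[StructureRecord], path: str | Path) -> None:
    """Serialize records back to the fixture format (round-trip inverse)."""

    def fmt_num(x: float) -> str:
        # Preserve table formatting: integers print without a decimal point.
        return f"{x:g}"

    rows = ["\t".join(_FIXTURE_COLUMNS)]
    for r in records:
        flags = []
        if r.apo_reference_in:
            flags.append("b")
        if r.excluded:
            flags.append(f"excluded:{r.exclusion_reason}")
        rows.append(
            "\t".join(
                [
                    r.pdb_id,
                    r.description,
                    ",".join(sorted(r.ligand_labels)) if r.ligand_labels else "NONE",
                    r.metal_annotation,
                    ",".join(f"{c}:{l}" for c, l in sorted(r.per_chain_ligands.items())) or "-",
                    f"{r.residue_range[0]}-{r.residue_range[1]}" if r.residue_range else "ND",
                    "ND" if r.seq_identity_pct is None else fmt_num(r.seq_identity_pct),
                    fmt_num(r.tm_score),
                    fmt_num(r.rmsd_ang),
                    "ND" if r.dhoase_type == "UNDETERMINED" else r.dhoase_type,
                    ",".join(f"{c}:{s}" for c, s in sorted(r.chain_states.items())) or "-",
                    ";".join(flags) or "-",
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def load_loop_definitions(path: str | Path | None = None) -> list[LoopDefinition]:
    """Parse the loop-definition table (species, type, motif, range, key residue)."""
    if path is None:
        path = packaged_loop_definition_path()
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    defs: list[LoopDefinition] = []
    for row_no, line in enumerate(lines[1:], start=2):
        row = dict(zip(header, line.split("\t")))
        stated_length = int(row["loop_length"])
        if stated_length != len(row["motif"]):
            raise AnnotationError(f"loop definitions row {row_no}: length/motif mismatch")
        key = None
        if row["key_residue"] not in ("-", ""):
            name, _, num = row["key_residue"].partition(":")
            key = (name, int(num))
        defs.append(
            LoopDefinition(
                species=row["species"],
                dhoase_type=row["dhoase_type"],
                motif=row["motif"],
                residue_range=_parse_range(row["residue_range"]),
                key_residue=key,
            )
        )
    return defs


def expand_monomers(records: Iterable[StructureRecord]) -> list[MonomerAnnotation]:
    """Expand structure-level rows into one annotation per chain.

    Excluded records contribute nothing.  Raw ``in_out`` maps to LOOP_IN with
    ``state_provenance="mixed_in_out_convention"``; footnote-b rows (apo,
    classified by superposition onto a ligand-bound reference) carry
    ``state_provenance="apo_reference_rule"``; everything else is ``curated``.
    """
    monomers: list[MonomerAnnotation] = []
    for record in records:
        if record.excluded:
            continue
        if not record.chain_states:
            raise AnnotationError(f"{record.pdb_id}: no chain states on a non-excluded record")
        for chain, token in record.chain_states.items():
            if token == "in_out":
                state, provenance, disordered = "LOOP_IN", "mixed_in_out_convention", False
            elif token == "in":
                provenance = "apo_reference_rule" if record.apo_reference_in else "curated"
                state, disordered = "LOOP_IN", False
            elif token == "out":
                state, provenance, disordered = "LOOP_OUT", "curated", False
            else:  # out_d
                state, provenance, disordered = "LOOP_OUT", "curated", True
            monomers.append(
                MonomerAnnotation(
                    pdb_id=record.pdb_id,
                    chain_id=chain,
                    species=record.species,
                    dhoase_type=record.dhoase_type,
                    loop_state=state,
                    state_provenance=provenance,
                    ligand=record.per_chain_ligands.get(chain, "NONE"),
                    disordered_loop=disordered,
                )
            )
    return monomers


def packaged_annotation_path() -> Path:
    return Path(str(resources.files("dholoop.data") / "survey_annotations.tsv"))


def packaged_loop_definition_path() -> Path:
    return Path(str(resources.files("dholoop.data") / "loop_definitions.tsv"))


def packaged_path(name: str) -> Path:
    return Path(str(resources.files("dholoop.data") / name))
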
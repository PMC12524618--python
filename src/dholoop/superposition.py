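"""Rigid-body superposition, RMSD, and TM-score between chains.

Chains are paired by global sequence alignment (match +1, mismatch 0,
gap -1), fitted on C-alpha atoms by the closed-form least-squares rotation
(reflections excluded), and scored with the length-normalized TM-score

    TM = (1 / L_ref) * sum_i 1 / (1 + (d_i / d0)^2),

where L_ref is the reference (first) chain's residue count and
d0 = 1.24 * (L_ref - 15)^(1/3) - 1.8, floored at 0.5 A.  The score is
maximized by iterative subset refinement: fit on all pairs, refit on pairs
closer than 2*d0, repeat until the subset is stable (capped at 20 rounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .loop_locator import LoopSegment
from .structure_io import GAP_CHAR, StructureModel, extract_chain_sequence

__all__ = [
    "AlignedPairs",
    "SuperpositionResult",
    "SuperpositionError",
    "align_sequences",
    "kabsch_fit",
    "tm_score",
    "tm_d0",
    "superpose_chains",
]


class SuperpositionError(ValueError):
    """Alignment or fitting failed (no pairs, degenerate geometry)."""


@dataclass
class AlignedPairs:
    """Index pairs (into the two gap-free sequences) from global alignment."""

    pairs: list[tuple[int, int]]
    reference_length: int


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector; x_B -> R x_B + t lands on frame A
    rmsd: float
    n_pairs: int
    tm_score: float | None = None
    d0: float | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates from the mobile (B) frame into the reference (A) frame."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_sequences(seq_a: str, seq_b: str) -> AlignedPairs:
    """Global alignment returning matched index pairs.

    Input sequences must be gap-free (strip unresolved-position marks first).
    The first alignment with optimal score is used; ties are resolved
    deterministically by the aligner.
    """
    if not seq_a or not seq_b:
        raise SuperpositionError("empty sequence")
    if GAP_CHAR in seq_a or GAP_CHAR in seq_b:
        raise SuperpositionError("sequences must be gap-free for alignment")
    alignment = _aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        pairs.extend((a_start + k, b_start + k) for k in range(a_end - a_start))
    if not pairs:
        raise SuperpositionError("no alignable residue pairs")
    return AlignedPairs(pairs=pairs, reference_length=len(seq_a))


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid-body fit of B onto A (rotation + translation).

    Solves for the proper rotation R and translation t minimizing
    ``|| (R b_i + t) - a_i ||`` over the paired points; reflections are
    excluded by construction.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError("coordinate arrays must both be n x 3")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 pairs for a rigid fit")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    # Collinear input leaves the rotation about the line undetermined.
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise SuperpositionError("degenerate (collinear) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (B @ R.T + t) - A
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def tm_d0(reference_length: int) -> float:
    """TM-score distance scale for a reference of the given length (floored at 0.5 A)."""
    if reference_length > 15:
        d0 = 1.24 * (reference_length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def tm_score(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    reference_length: int,
    max_rounds: int = 20,
) -> SuperpositionResult:
    """TM-score of paired coordinates, maximized by iterative subset fitting.

    Starts from the all-pair fit; each round refits on the pairs currently
    closer than 2*d0 (never fewer than 3) and rescores *all* pairs.  Stops
    when the subset is stable or after ``max_rounds``; reports the best score
    seen together with the fit that produced it.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    d0 = tm_d0(reference_length)
    subset = np.arange(A.shape[0])
    best: SuperpositionResult | None = None
    seen: set[tuple[int, ...]] = set()
    for _ in range(max_rounds):
        fit = kabsch_fit(A[subset], B[subset])
        d = np.linalg.norm(fit.transform(B) - A, axis=1)
        score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / reference_length)
        full = kabsch_fit(A, B) if len(subset) == A.shape[0] else fit
        candidate = SuperpositionResult(
            rotation=fit.rotation,
            translation=fit.translation,
            rmsd=full.rmsd,
            n_pairs=A.shape[0],
            tm_score=score,
            d0=d0,
        )
        if best is None or score > best.tm_score:
            best = candidate
        new_subset = np.nonzero(d < 2.0 * d0)[0]
        if len(new_subset) < 3:
            break
        key = tuple(new_subset.tolist())
        if key in seen:
            break
        seen.add(key)
        subset = new_subset
    assert best is not None
    # rmsd reported over all fitted pairs of the plain all-pair fit
    all_fit = kabsch_fit(A, B)
    best.rmsd = all_fit.rmsd
    return best


def _ca_map(model: StructureModel, chain: str):
    """(gap-free sequence, residues-with-CA list) for a chain."""
    seq, first = extract_chain_sequence(model, chain)
    residues = {r.author_number: r for r in model.polymer_residues(chain)}
    letters: list[str] = []
    with_ca = []
    for i, ch in enumerate(seq):
        if ch == GAP_CHAR:
            continue
        res = residues[first + i]
        ca = res.atom("CA")
        if ca is None:
            continue
        letters.append(ch)
        with_ca.append(res)
    if not with_ca:
        raise SuperpositionError(f"{model.pdb_id}/{chain}: no C-alpha atoms")
    return "".join(letters), with_ca


def superpose_chains(
    model_a: StructureModel,
    chain_a: str,
    model_b: StructureModel,
    chain_b: str,
    exclude_loop: LoopSegment | list[LoopSegment] | None = None,
) -> SuperpositionResult:
    """Align, fit, and TM-score two chains on C-alpha atoms.

    ``exclude_loop`` removes loop residues from the fitted set (core
    superposition), so that the loop's own displacement can be measured in
    the resulting frame.  Segments are matched to either chain by their
    residue-number range.
    """
    seq_a, res_a = _ca_map(model_a, chain_a)
    seq_b, res_b = _ca_map(model_b, chain_b)
    aligned = align_sequences(seq_a, seq_b)

    excluded = []
    if exclude_loop is not None:
        excluded = [exclude_loop] if isinstance(exclude_loop, LoopSegment) else list(exclude_loop)

    def in_excluded(residue, chain_id: str) -> bool:
        for seg in excluded:
            lo, hi = seg.residue_range
            if seg.chain_id == chain_id and lo <= residue.author_number <= hi:
                return True
        return False

    pair_idx = [
        (i, j)
        for i, j in aligned.pairs
        if not in_excluded(res_a[i], chain_a) and not in_excluded(res_b[j], chain_b)
    ]
    if len(pair_idx) < 3:
        raise SuperpositionError("fewer than 3 fittable pairs after exclusions")
    coords_a = np.array([res_a[i].atom("CA").coords for i, _ in pair_idx])
    coords_b = np.array([res_b[j].atom("CA").coords for _, j in pair_idx])
    return tm_score(coords_a, coords_b, reference_length=len(res_a))
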
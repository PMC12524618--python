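"""Superposition: alignment, Kabsch vs a rotation-grid oracle, TM-score."""

import itertools

import numpy as np
import pytest

from dholoop.superposition import (
    SuperpositionError,
    align_sequences,
    kabsch_fit,
    superpose_chains,
    tm_d0,
    tm_score,
)

from conftest import random_rotation, rigid_copy


def euler(a, b, c):
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


def grid_search_rmsd(A, B, levels=5, initial_step=np.deg2rad(15.0)):
    """Independent oracle: hierarchically refined Euler-angle grid search.

    For a fixed rotation the optimal translation matches the centroids, so
    only the rotation is searched.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def rmsd_for(R):
        diff = Bc @ R.T - Ac
        return float(np.sqrt((diff**2).sum() / len(A)))

    best_angles = (0.0, 0.0, 0.0)
    best = rmsd_for(euler(*best_angles))
    step = initial_step
    span = np.pi
    for _ in range(levels):
        a0, b0, c0 = best_angles
        grid = np.arange(-span, span + 1e-12, step)
        for da, db, dc in itertools.product(grid, repeat=3):
            r = rmsd_for(euler(a0 + da, b0 + db, c0 + dc))
            if r < best:
                best = r
                best_angles = (a0 + da, b0 + db, c0 + dc)
        span = 2.0 * step
        step = step / 4.0
    return best


class TestAlignSequences:
    def test_identical_sequences_pair_everything(self):
        pairs = align_sequences("ACDEFGHIKL", "ACDEFGHIKL")
        assert pairs.pairs == [(i, i) for i in range(10)]
        assert pairs.reference_length == 10

    def test_interior_deletion_places_gap(self):
        seq_a = "ACDEFGHIKL"
        seq_b = "ACDEHIKL"  # F,G deleted
        pairs = align_sequences(seq_a, seq_b)
        assert len(pairs.pairs) == 8
        matched_a = [i for i, _ in pairs.pairs]
        assert matched_a == [0, 1, 2, 3, 6, 7, 8, 9]
        # oracle: enumerate all 8-subsets preserving order, best score is exact match
        assert all(seq_a[i] == seq_b[j] for i, j in pairs.pairs)

    def test_disjoint_alphabets_still_return_defined_result(self):
        # documented policy: global alignment yields mismatch pairs (score 0),
        # not an error, as long as at least one pair exists
        pairs = align_sequences("AAAA", "GGGG")
        assert len(pairs.pairs) == 4


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 3))
        fit = kabsch_fit(A, A)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(fit.rotation) - 1.0) < 1e-6

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(12, 3))
        R = euler(np.pi / 2, 0.0, 0.0)  # 90 degrees about z
        B = (A - A.mean(axis=0)) @ R.T + A.mean(axis=0) + np.array([5.0, 0.0, 0.0])
        fit = kabsch_fit(A, B)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        # recovered rotation maps B back onto A
        assert np.allclose(fit.rotation @ R, np.eye(3), atol=1e-6)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 3)) * 3.0
        B = rng.normal(size=(4, 3)) * 3.0
        fit = kabsch_fit(A, B)
        oracle = grid_search_rmsd(A, B)
        assert fit.rmsd <= oracle + 1e-9  # closed form is optimal
        assert fit.rmsd == pytest.approx(oracle, abs=1e-3)

    def test_rmsd_symmetry(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(20, 3))
        B = rng.normal(size=(20, 3))
        assert kabsch_fit(A, B).rmsd == pytest.approx(kabsch_fit(B, A).rmsd, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(SuperpositionError):
            kabsch_fit(line, line + 1.0)
        with pytest.raises(SuperpositionError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTmScore:
    def test_self_score_is_exactly_one(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(50, 3)) * 10.0
        result = tm_score(A, A, reference_length=50)
        assert result.tm_score == 1.0

    def test_all_pairs_at_d0_give_half(self):
        # Construct a case whose optimal fit is exactly the identity while
        # every pair sits exactly d0 apart: duplicate each point and displace
        # the two copies by +d0 and -d0 along x.  The displacement field then
        # contributes nothing to the cross-covariance, so the least-squares
        # rotation is the identity and each residual is exactly d0.
        base = np.random.default_rng(8).normal(size=(20, 3)) * 20.0
        A = np.vstack([base, base])
        n = len(A)
        d0 = tm_d0(n)
        shift = np.array([d0, 0.0, 0.0])
        B = np.vstack([base + shift, base - shift])
        result = tm_score(A, B, reference_length=n)
        assert result.tm_score == pytest.approx(0.5, rel=1e-9)

    def test_d0_formula_and_floor(self):
        assert tm_d0(348) == pytest.approx(1.24 * (348 - 15) ** (1 / 3) - 1.8)
        assert tm_d0(16) == 0.5  # formula gives negative value; floored
        assert tm_d0(10) == 0.5

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(30, 3)) * 8.0
        B = A + rng.normal(scale=0.5, size=(30, 3))
        base = tm_score(A, B, reference_length=30)
        R = random_rotation(rng)
        t = rng.normal(scale=15, size=3)
        moved = tm_score(A, B @ R.T + t, reference_length=30)
        assert moved.tm_score == pytest.approx(base.tm_score, abs=1e-6)
        assert moved.rmsd == pytest.approx(base.rmsd, abs=1e-6)


class TestSuperposeChains:
    def test_identical_chains(self, holo_in):
        model, _ = holo_in
        result = superpose_chains(model, "A", model, "A")
        assert result.tm_score == 1.0
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_superposes_exactly(self, holo_in):
        model, _ = holo_in
        rng = np.random.default_rng(10)
        moved = rigid_copy(model, random_rotation(rng), rng.normal(scale=25, size=3))
        result = superpose_chains(model, "A", moved, "A")
        assert result.tm_score == pytest.approx(1.0, abs=1e-9)
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_core_superposition_isolates_loop_motion(self, holo_in, holo_out, defn16):
        """Same core, loop swung away: core fit is tight, loop apex moves far."""
        from dholoop.loop_locator import locate_loop

        model_in, _ = holo_in
        model_out, _ = holo_out
        seg_in = locate_loop(model_in, "A", defn16)
        seg_out = locate_loop(model_out, "A", defn16)
        fit = superpose_chains(model_in, "A", model_out, "A", exclude_loop=[seg_in, seg_out])
        assert fit.rmsd == pytest.approx(0.0, abs=1e-6)  # cores are identical
        apex_in = seg_in.resolved_residues[8].atom("CA").coords
        apex_out = fit.transform(seg_out.resolved_residues[8].atom("CA").coords)
        assert np.linalg.norm(apex_in - apex_out) > 5.0
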
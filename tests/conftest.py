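"""Shared fixtures: the packaged annotation corpus and synthetic structures."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from dholoop import annotations, synthetic


@pytest.fixture(scope="session")
def records():
    return annotations.load_annotation_table()


@pytest.fixture(scope="session")
def monomers(records):
    return annotations.expand_monomers(records)


@pytest.fixture(scope="session")
def loop_definitions():
    return annotations.load_loop_definitions()


@pytest.fixture(scope="session")
def defn16():
    return synthetic.motif_for_length(16)


@pytest.fixture(scope="session")
def holo_in():
    """Synthetic loop-in monomer with ligand at 3.0 A."""
    return synthetic.make_monomer(
        synthetic.SyntheticSpec(loop_state="in", target_contact_distance=3.0)
    )


@pytest.fixture(scope="session")
def holo_out():
    """Synthetic loop-out monomer with ligand at 9.0 A."""
    return synthetic.make_monomer(
        synthetic.SyntheticSpec(loop_state="out", target_contact_distance=9.0)
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR decomposition."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rigid_copy(model, rotation: np.ndarray, translation: np.ndarray):
    """Deep copy of a StructureModel with every atom rigidly transformed."""
    moved = copy.deepcopy(model)
    for residues in moved.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.coords = rotation @ atom.coords + translation
    return moved


def brute_force_min_contact(segment, ligand) -> float:
    """Independent all-pairs heavy-atom minimum distance oracle."""
    best = np.inf
    for res in segment.resolved_residues:
        for atom in res.heavy_atoms():
            for latom in ligand.heavy_atoms:
                d = float(np.linalg.norm(atom.coords - latom.coords))
                best = min(best, d)
    return best
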
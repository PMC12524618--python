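"""Loop-state classification: contact rule, apo reference rule, pipeline."""

import numpy as np
import pytest

from dholoop import synthetic
from dholoop.classifier import (
    ReferenceEntry,
    classify_apo_by_reference,
    classify_by_contact,
    classify_monomer,
)
from dholoop.loop_locator import locate_loop
from dholoop.active_site import find_active_site_ligands, find_metals

from conftest import brute_force_min_contact, random_rotation, rigid_copy


def _segment_and_ligand(model, defn):
    seg = locate_loop(model, "A", defn)
    metals = find_metals(model, "A")
    ligands = find_active_site_ligands(model, "A", metals)
    return seg, ligands[0]


class TestContactRule:
    def test_loop_at_3A_is_in_at_cutoff_4(self, holo_in, defn16):
        model, truth = holo_in
        seg, ligand = _segment_and_ligand(model, defn16)
        cls = classify_by_contact(seg, ligand, cutoff=4.0)
        assert cls.state == "LOOP_IN"
        assert cls.evidence.min_distance == pytest.approx(
            truth.chains[0].min_contact_distance, abs=1e-9
        )

    def test_loop_at_9A_is_out_at_cutoff_4(self, holo_out, defn16):
        model, _ = holo_out
        seg, ligand = _segment_and_ligand(model, defn16)
        cls = classify_by_contact(seg, ligand, cutoff=4.0)
        assert cls.state == "LOOP_OUT"
        assert not cls.disordered_loop

    @pytest.mark.parametrize("target", [2.8, 3.5, 5.2, 7.0, 9.5])
    def test_agrees_with_brute_force_oracle(self, target, defn16):
        state = "in" if target <= 4.0 else "out"
        model, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(loop_state=state, target_contact_distance=target)
        )
        seg, ligand = _segment_and_ligand(model, defn16)
        cls = classify_by_contact(seg, ligand, cutoff=4.0)
        oracle = brute_force_min_contact(seg, ligand)
        assert cls.evidence.min_distance == pytest.approx(oracle, abs=1e-9)
        assert cls.state == ("LOOP_IN" if oracle <= 4.0 else "LOOP_OUT")
        assert cls.evidence.min_distance == min(cls.evidence.per_residue_min.values())

    def test_cutoff_monotonicity(self, defn16):
        """The loop-in set never shrinks as the cutoff grows."""
        models = [
            synthetic.make_monomer(
                synthetic.SyntheticSpec(
                    loop_state="in" if t < 5.0 else "out",
                    target_contact_distance=t,
                )
            )[0]
            for t in (2.6, 3.2, 3.8, 4.4, 5.1, 6.5)
        ]
        previous: set[int] = set()
        for cutoff in (3.0, 3.5, 4.0, 4.5, 5.0):
            in_set = set()
            for k, model in enumerate(models):
                seg, ligand = _segment_and_ligand(model, defn16)
                if classify_by_contact(seg, ligand, cutoff=cutoff).state == "LOOP_IN":
                    in_set.add(k)
            assert previous <= in_set
            previous = in_set

    def test_mostly_unresolved_loop_out_is_flagged_disordered(self, defn16):
        model, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="out",
                target_contact_distance=9.0,
                missing_loop_residues=tuple(range(8)),  # 8/16 resolved = 0.5 < 0.7
            )
        )
        lo = 61
        from dholoop.annotations import LoopDefinition

        ranged = LoopDefinition("syn", "II", defn16.motif, residue_range=(lo, lo + 15))
        seg = locate_loop(model, "A", ranged)
        metals = find_metals(model, "A")
        ligand = find_active_site_ligands(model, "A", metals)[0]
        cls = classify_by_contact(seg, ligand, cutoff=4.0)
        assert cls.state == "LOOP_OUT"
        assert cls.disordered_loop

    def test_rigid_motion_invariance(self, holo_in, defn16):
        model, _ = holo_in
        rng = np.random.default_rng(21)
        moved = rigid_copy(model, random_rotation(rng), rng.normal(scale=40, size=3))
        seg_a, lig_a = _segment_and_ligand(model, defn16)
        seg_b, lig_b = _segment_and_ligand(moved, defn16)
        cls_a = classify_by_contact(seg_a, lig_a)
        cls_b = classify_by_contact(seg_b, lig_b)
        assert cls_a.state == cls_b.state
        assert cls_a.evidence.min_distance == pytest.approx(
            cls_b.evidence.min_distance, abs=1e-9
        )


@pytest.fixture(scope="module")
def reference(defn16):
    model, _ = synthetic.make_monomer(
        synthetic.SyntheticSpec(loop_state="in", target_contact_distance=3.0), tag="REF0"
    )
    return ReferenceEntry(model=model, chain="A", definition=defn16)


class TestApoReferenceRule:
    def test_apo_copy_of_loop_in_classifies_in(self, reference, defn16):
        apo, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="in",
                target_contact_distance=3.0,
                include_ligand=False,
                include_metal=False,
                as_reference=True,
            ),
            tag="APO0",
        )
        rng = np.random.default_rng(22)
        apo = rigid_copy(apo, random_rotation(rng), rng.normal(scale=30, size=3))
        seg = locate_loop(apo, "A", defn16)
        cls = classify_apo_by_reference(apo, "A", seg, reference)
        assert cls.state == "LOOP_IN"
        assert cls.evidence.key_displacement == pytest.approx(0.0, abs=1e-6)

    def test_apo_posed_out_classifies_out(self, reference, defn16):
        apo, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="out",
                target_contact_distance=9.0,
                include_ligand=False,
                include_metal=False,
            ),
            tag="APO1",
        )
        seg = locate_loop(apo, "A", defn16)
        cls = classify_apo_by_reference(apo, "A", seg, reference)
        assert cls.state == "LOOP_OUT"
        assert cls.evidence.key_to_ligand >= 5.0

    def test_unresolved_key_residue_is_undetermined(self, reference, defn16):
        apo, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="in",
                target_contact_distance=3.0,
                include_ligand=False,
                include_metal=False,
                as_reference=True,
                missing_loop_residues=(6, 7, 8, 9),  # covers the apex/key residue
            ),
            tag="APO2",
        )
        from dholoop.annotations import LoopDefinition

        ranged = LoopDefinition("syn", "II", defn16.motif, residue_range=(61, 76))
        seg = locate_loop(apo, "A", ranged)
        cls = classify_apo_by_reference(apo, "A", seg, reference)
        assert cls.state == "UNDETERMINED"
        assert "unresolved" in cls.evidence.reason


class TestClassifyMonomer:
    def test_holo_in_via_contact(self, holo_in, defn16):
        model, _ = holo_in
        ann, cls = classify_monomer(model, "A", defn16)
        assert (ann.loop_state, cls.rule) == ("LOOP_IN", "contact")
        assert ann.state_provenance == "contact_rule"
        assert ann.ligand == "LIG"

    def test_apo_out_via_reference(self, reference, defn16):
        apo, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="out",
                target_contact_distance=9.0,
                include_ligand=False,
                include_metal=False,
            ),
            tag="APO3",
        )
        ann, cls = classify_monomer(apo, "A", defn16, references={"II": reference})
        assert (ann.loop_state, cls.rule) == ("LOOP_OUT", "apo_reference")
        assert ann.state_provenance == "apo_reference_rule"

    def test_no_ligand_no_reference_is_undetermined(self, defn16):
        apo, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="out",
                target_contact_distance=9.0,
                include_ligand=False,
                include_metal=False,
            ),
            tag="APO4",
        )
        ann, _ = classify_monomer(apo, "A", defn16)
        assert ann.loop_state == "UNDETERMINED"

    def test_ligand_with_fully_unresolved_loop_is_undetermined(self):
        from dholoop.annotations import LoopDefinition

        model, _ = synthetic.make_monomer(
            synthetic.SyntheticSpec(
                loop_state="out",
                target_contact_distance=8.0,
                missing_loop_residues=tuple(range(16)),
            )
        )
        ranged = LoopDefinition("syn", "II", "PAGVTTNSAAGVDPND", residue_range=(61, 76))
        ann, cls = classify_monomer(model, "A", ranged)
        assert ann.loop_state == "UNDETERMINED"
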
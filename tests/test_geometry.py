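"""Hydrophobic-contact angles and Hausdorff-distance comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import directed_hausdorff

from memtol.geometry import (
    AngleVectorSet,
    AnnealingSchedule,
    GeometryError,
    angle_at,
    compare_cohort,
    hausdorff_distance,
    hydrophobic_contact_angles,
    min_hausdorff,
    representative_point,
    vector_distance,
)
from memtol.structure_contacts import build_contact_map
from memtol.synthetic_data import make_globular_decoy, make_ideal_helix


class TestAngles:
    def test_right_angle(self):
        assert angle_at(np.zeros(3), np.array([1, 0, 0]), np.array([0, 2, 0])) == pytest.approx(90.0)

    def test_collinear_opposite(self):
        assert angle_at(np.zeros(3), np.array([1, 0, 0]), np.array([-3, 0, 0])) == pytest.approx(180.0)

    @given(st.data())
    def test_matches_arccos_dot_product_oracle(self, data):
        coords = st.floats(-10, 10, allow_nan=False)
        pts = [
            np.array([data.draw(coords) for _ in range(3)]) for _ in range(3)
        ]
        c, a, b = pts
        if np.allclose(a, c) or np.allclose(b, c):
            return
        u, v = a - c, b - c
        expect = np.degrees(
            np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        )
        assert angle_at(c, a, b) == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_representative_point_is_sidechain_centroid(self):
        atoms = {
            "N": np.zeros(3),
            "CA": np.array([1.0, 0, 0]),
            "CB": np.array([2.0, 0, 0]),
            "CG": np.array([4.0, 0, 0]),
        }
        assert representative_point(atoms) == pytest.approx([3.0, 0, 0])
        assert representative_point({"CA": np.ones(3)}) == pytest.approx([1.0, 1.0, 1.0])


class TestHausdorff:
    def test_identity(self):
        A = [np.array([10.0, 5.0])]
        assert hausdorff_distance(A, A) == 0.0

    def test_single_element_sets(self):
        assert hausdorff_distance([np.array([0.0])], [np.array([1.0])]) == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(GeometryError):
            hausdorff_distance([], [np.array([1.0])])

    def test_truncation_metric_uses_shorter_length(self):
        assert vector_distance(np.array([90.0, 40.0]), np.array([90.0])) == 0.0
        assert vector_distance(np.array([90.0, 40.0]), np.array([90.0]), mode="pad") == pytest.approx(40.0)

    def test_matches_brute_force_max_min(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            A = [rng.uniform(0, 180, 3) for _ in range(rng.integers(1, 6))]
            B = [rng.uniform(0, 180, 3) for _ in range(rng.integers(1, 6))]
            d = np.array([[np.linalg.norm(u - v) for v in B] for u in A])
            oracle = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff_distance(A, B) == pytest.approx(oracle, rel=1e-12)

    def test_matches_scipy_directed_hausdorff(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            A = rng.uniform(0, 180, (6, 4))
            B = rng.uniform(0, 180, (5, 4))
            expect = max(
                directed_hausdorff(A, B, seed=0)[0], directed_hausdorff(B, A, seed=0)[0]
            )
            assert hausdorff_distance(list(A), list(B)) == pytest.approx(expect, rel=1e-12)

    @given(st.data())
    def test_pseudometric_on_equal_length_vectors(self, data):
        vec = st.lists(st.floats(0, 180, allow_nan=False), min_size=3, max_size=3)
        sets = [
            [np.array(data.draw(vec)) for _ in range(data.draw(st.integers(1, 4)))]
            for _ in range(3)
        ]
        A, B, C = sets
        dab, dba = hausdorff_distance(A, B), hausdorff_distance(B, A)
        assert dab == pytest.approx(dba, rel=1e-12, abs=1e-12)  # symmetry
        assert hausdorff_distance(A, A) == 0.0
        dac, dcb = hausdorff_distance(A, C), hausdorff_distance(C, B)
        assert dab <= dac + dcb + 1e-9  # triangle inequality


class TestMinHausdorff:
    def test_recovers_identity_under_offset(self):
        rng = np.random.default_rng(0)
        A = [np.sort(rng.uniform(0, 180, 4))[::-1] for _ in range(6)]
        B = [v - 17.0 for v in A]
        result = min_hausdorff(A, B, seed=1)
        assert result.distance <= 1e-6
        assert result.offset == pytest.approx(17.0, abs=0.01)

    def test_never_exceeds_unminimized_distance(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            A = [rng.uniform(0, 180, 3) for _ in range(4)]
            B = [rng.uniform(0, 180, 3) for _ in range(4)]
            assert min_hausdorff(A, B, seed=seed).distance <= hausdorff_distance(A, B) + 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        A = [rng.uniform(0, 180, 3) for _ in range(4)]
        B = [rng.uniform(0, 180, 3) for _ in range(4)]
        r1 = min_hausdorff(A, B, seed=42)
        r2 = min_hausdorff(A, B, seed=42)
        assert r1 == r2

    def test_invalid_schedule_rejected(self):
        with pytest.raises(GeometryError):
            AnnealingSchedule(t0=-1)
        with pytest.raises(GeometryError):
            AnnealingSchedule(alpha=1.5)


class TestHydrophobicContactAngles:
    def test_helix_vectors_are_canonical_and_bounded(self, helix20):
        cg = build_contact_map(helix20, 5.0)
        angle_set = hydrophobic_contact_angles(helix20, cg)
        assert len(angle_set) > 0
        for vec in angle_set.vectors.values():
            assert np.all((0.0 <= vec) & (vec <= 180.0))
            assert np.all(np.diff(vec) <= 0)  # sorted descending

    def test_polar_residues_excluded(self):
        decoy = make_globular_decoy(40, seed=2, hydrophobic_fraction=0.5)
        cg = build_contact_map(decoy, 5.0)
        angle_set = hydrophobic_contact_angles(decoy, cg)
        hydrophobic_positions = {
            r.index for r in decoy.residues if r.name in "AVLIMFWC"
        }
        assert set(angle_set.vectors) <= hydrophobic_positions

    def test_rigid_motion_invariance(self, helix20):
        from scipy.spatial.transform import Rotation

        cg = build_contact_map(helix20, 5.0)
        base = hydrophobic_contact_angles(helix20, cg)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = helix20.transformed(rot, np.array([5.0, -3.0, 12.0]))
        cg2 = build_contact_map(moved, 5.0)
        other = hydrophobic_contact_angles(moved, cg2)
        assert set(base.vectors) == set(other.vectors)
        for k in base.vectors:
            assert base.vectors[k] == pytest.approx(other.vectors[k], abs=1e-8)


class TestCompareCohort:
    def _angle_sets(self, chains):
        sets = {}
        for name, chain in chains.items():
            cg = build_contact_map(chain, 5.0)
            avs = hydrophobic_contact_angles(chain, cg)
            avs.protein_id = name
            sets[name] = avs
        return sets

    def test_identical_helix_bundle_cohort(self):
        chains = {f"h{i}": make_ideal_helix(15) for i in range(5)}
        sets = self._angle_sets(chains)
        result = compare_cohort(sets, {k: "1.20.5" for k in sets}, seed=1)
        assert len(result.comparisons) == 10  # 5 choose 2
        assert all(c.min_hausdorff <= 1e-6 for c in result.comparisons)
        assert result.fraction_identical == 1.0

    def test_different_cath_classes_not_compared(self):
        chains = {"a": make_ideal_helix(15), "b": make_ideal_helix(15)}
        sets = self._angle_sets(chains)
        result = compare_cohort(sets, {"a": "1.20.5", "b": "2.40.10"}, seed=0)
        assert result.comparisons == []

    def test_length_difference_filter_is_strict(self):
        chains = {"short": make_ideal_helix(30), "long": make_ideal_helix(51)}
        sets = self._angle_sets(chains)
        labels = {"short": "1.20.5", "long": "1.20.5"}
        assert compare_cohort(sets, labels, seed=0).comparisons == []  # diff 21 > 20
        chains2 = {"short": make_ideal_helix(30), "long": make_ideal_helix(50)}
        sets2 = self._angle_sets(chains2)
        assert len(compare_cohort(sets2, labels, seed=0).comparisons) == 1  # diff 20 kept

    def test_missing_cath_label_rejected(self):
        chains = {"a": make_ideal_helix(12)}
        with pytest.raises(GeometryError):
            compare_cohort(self._angle_sets(chains), {}, seed=0)
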
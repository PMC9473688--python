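import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemegeom import (
    PairSpec,
    classify_motif,
    contact_pairs,
    extract_hemes,
    ideal_porphyrin,
    make_pair,
    min_ring_distance,
    pruned_superposition,
    rotation_angle,
    superpose_rings,
)
from hemegeom.structure_io import PorphyrinRing

from oracles import axis_angle, brute_force_min_distance, quaternion_superpose, random_rotation


def moved_copy(ring, R, t, seq=2):
    return PorphyrinRing(("A", seq, "HEC"), ring.ring_coords @ R.T + t)


class TestMinRingDistance:
    def test_normal_translation_is_exact(self, ring):
        other = moved_copy(ring, np.eye(3), [0, 0, 4.0])
        assert min_ring_distance(ring, other) == pytest.approx(4.0, abs=1e-12)

    def test_self_pair_rejected(self, ring):
        with pytest.raises(ValueError):
            min_ring_distance(ring, ring)

    def test_zero_distance_for_coincident_rings(self, ring):
        assert min_ring_distance(ring, moved_copy(ring, np.eye(3), [0, 0, 0])) == 0.0

    def test_matches_brute_force_on_random_pairs(self, rng, ring):
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-8, 8, size=3)
            other = moved_copy(ring, R, t)
            expected = brute_force_min_distance(ring.ring_coords, other.ring_coords)
            assert min_ring_distance(ring, other) == expected

    def test_symmetry(self, rng, ring):
        other = moved_copy(ring, random_rotation(rng), [3, 1, 4])
        assert min_ring_distance(ring, other) == min_ring_distance(other, ring)


class TestSuperposition:
    def test_identity_on_self(self, ring):
        res = superpose_rings(ring, moved_copy(ring, np.eye(3), [0, 0, 0]))
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert res.rmsd < 1e-9

    def test_recovers_constructed_transform(self, rng, ring):
        R0 = random_rotation(rng)
        t0 = np.array([1.0, -2.0, 3.0])
        res = superpose_rings(ring, moved_copy(ring, R0, t0))
        assert np.abs(res.rotation - R0).max() < 1e-9
        assert np.allclose(res.translation, t0, atol=1e-9)
        assert res.rmsd < 1e-9

    def test_proper_rotation_only(self, rng, ring):
        res = superpose_rings(ring, moved_copy(ring, random_rotation(rng), [5, 5, 5]))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_noisy_pairs(self, rng, ring):
        """Kabsch and Horn's quaternion method agree to 1e-6 Å rmsd."""
        for _ in range(10):
            R0 = random_rotation(rng)
            t0 = rng.uniform(-10, 10, size=3)
            noisy = ring.ring_coords @ R0.T + t0 + rng.normal(0, 0.05, size=(25, 3))
            other = PorphyrinRing(("A", 2, "HEC"), noisy)
            res = superpose_rings(ring, other)
            _, _, rmsd_q = quaternion_superpose(ring.ring_coords, noisy)
            assert res.rmsd == pytest.approx(rmsd_q, abs=1e-6)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(25.0), np.zeros(25), np.zeros(25)])
        a = PorphyrinRing(("A", 1, "HEC"), line)
        b = PorphyrinRing(("A", 2, "HEC"), line + 1.0)
        with pytest.raises(ValueError):
            superpose_rings(a, b)


class TestRotationAngle:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            (np.eye(3), 0.0),
            (np.diag([1.0, -1.0, -1.0]), 180.0),  # half-turn about x
            (axis_angle([0, 0, 1], 90.0), 90.0),
        ],
    )
    def test_closed_forms(self, matrix, expected):
        assert rotation_angle(matrix) == pytest.approx(expected, abs=1e-9)

    def test_recovers_constructed_axis_angle(self, rng):
        for _ in range(20):
            axis = rng.normal(size=3)
            angle = rng.uniform(0, 180)
            assert rotation_angle(axis_angle(axis, angle)) == pytest.approx(angle, abs=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(np.diag([1.0, 1.0, -1.0]))  # reflection
        with pytest.raises(ValueError):
            rotation_angle(2 * np.eye(3))

    @settings(derandomize=True, max_examples=50)
    @given(
        ax=st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
            lambda v: sum(x * x for x in v) > 1e-4
        ),
        angle=st.floats(0, 180),
    )
    def test_angle_of_transpose_equal(self, ax, angle):
        """θ(R) = θ(Rᵀ): the pair statistic is direction-independent."""
        R = axis_angle(np.array(ax), angle)
        assert rotation_angle(R) == pytest.approx(rotation_angle(R.T), abs=1e-9)


class TestThetaInvariance:
    def test_theta_invariant_under_common_rigid_transform(self, rng, ring):
        other = moved_copy(ring, axis_angle([1, 1, 0], 73.2), [0, 0, 6])
        theta0 = rotation_angle(superpose_rings(ring, other).rotation)
        R, t = random_rotation(rng), rng.uniform(-20, 20, size=3)
        a2, b2 = moved_copy(ring, R, t, seq=1), moved_copy(other, R, t, seq=2)
        theta1 = rotation_angle(superpose_rings(a2, b2).rotation)
        assert theta1 == pytest.approx(theta0, abs=1e-9)

    def test_theta_symmetric_in_pair_order(self, rng, ring):
        other = moved_copy(ring, random_rotation(rng), [1, 2, 5])
        tab = rotation_angle(superpose_rings(ring, other).rotation)
        tba = rotation_angle(superpose_rings(other, ring).rotation)
        assert tab == pytest.approx(tba, abs=1e-9)


class TestClassifyMotif:
    @pytest.mark.parametrize(
        "theta,plane,expected",
        [
            (0.0, 0.0, "parallel"),
            (180.0, 0.0, "antiparallel"),
            (39.9, 10.0, "parallel"),
            (90.0, 90.0, "T_shaped"),
            (56.0, 56.0, "intermediate"),
            (82.0, 82.0, "T_shaped"),
            (130.0, 20.0, "intermediate"),
        ],
    )
    def test_thresholds(self, theta, plane, expected):
        assert classify_motif(theta, plane) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_motif(-1.0)
        with pytest.raises(ValueError):
            classify_motif(181.0)


class TestContactPairs:
    def test_distant_rings_filtered(self, ring):
        far = moved_copy(ring, np.eye(3), [0, 0, 10.0])
        assert contact_pairs([ring, far], cutoff=6.0) == []

    def test_linear_chain_pair_count(self, ring):
        rings = [
            PorphyrinRing(("A", i + 1, "HEC"), ring.ring_coords + [0, 0, 4.0 * i])
            for i in range(5)
        ]
        pairs = contact_pairs(rings, cutoff=6.0)
        assert len(pairs) == 4
        assert all(p.min_distance == pytest.approx(4.0, abs=1e-9) for p in pairs)

    def test_pairs_sorted_and_populated(self, rare_pair):
        pairs = contact_pairs(extract_hemes(rare_pair))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.theta == pytest.approx(56.0, abs=1e-6)
        assert p.min_distance == pytest.approx(4.8, abs=1e-6)
        assert p.motif == "intermediate"
        assert np.linalg.det(p.rotation) == pytest.approx(1.0, abs=1e-9)


class TestPrunedSuperposition:
    def test_identical_sets_keep_all(self, rng):
        pts = rng.uniform(-10, 10, size=(30, 3))
        res = pruned_superposition(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_pairs_used == 30

    def test_displaced_outliers_pruned(self, rng):
        pts = rng.uniform(-10, 10, size=(25, 3))
        R0, t0 = random_rotation(rng), np.array([3.0, 2.0, 1.0])
        moved = pts @ R0.T + t0
        kicks = rng.normal(size=(5, 3))
        moved[20:] += 10.0 * kicks / np.linalg.norm(kicks, axis=1, keepdims=True)
        res = pruned_superposition(pts, moved)
        assert res.n_pairs_used == 20
        assert res.rmsd < 1e-6

    def test_pruned_rmsd_never_exceeds_unpruned(self, rng):
        for _ in range(5):
            a = rng.uniform(-10, 10, size=(20, 3))
            b = a @ random_rotation(rng).T + rng.normal(0, 0.5, size=(20, 3))
            full = pruned_superposition(a, b, prune_factor=1e9)
            pruned = pruned_superposition(a, b, prune_factor=1.5)
            assert pruned.rmsd <= full.rmsd + 1e-12

    def test_too_few_points_rejected(self):
        pts = np.eye(3)
        with pytest.raises(ValueError):
            pruned_superposition(pts, pts)
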
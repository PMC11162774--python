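"""Superposition, axis-angle extraction, rotation measurement, state calls."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation as ScipyRotation

from riboframe import rotation, synthetic
from riboframe.errors import DegenerateFitError, MeasurementUnresolvedError
from riboframe.rotation import (RotationMeasurement, StateWindows, axis_angle,
                                classify_state, measure_rotations,
                                rotation_from_axis_angle, superpose)


class TestSuperpose:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(40, 3))
        R, t, rmsd = superpose(pts, pts)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(60, 3))
        R0 = rotation_from_axis_angle(25.0, (0, 0, 1))
        t0 = np.array([1.0, 2.0, 3.0])
        moved = pts @ R0.T + t0
        R, t, rmsd = superpose(pts, moved)
        assert np.allclose(R, R0, atol=1e-9)
        assert np.allclose(t, t0, atol=1e-8)
        assert rmsd < 1e-9

    def test_rmsd_matches_noise_level(self):
        """Post-fit rmsd of a noisy copy ~ sigma * sqrt(3 * (1 - k/n)) with
        k = 6/3 effective parameters per coordinate; Monte-Carlo check."""
        rng = np.random.default_rng(2)
        n, sigma = 500, 0.3
        pts = rng.normal(0, 20, size=(n, 3))
        noisy = pts + rng.normal(0, sigma, size=(n, 3))
        _, _, rmsd = superpose(pts, noisy)
        # 3D displacement rmsd ~ sigma*sqrt(3); the fit absorbs ~6 of 3n dof
        expected = sigma * np.sqrt(3 * (1 - 2 / n))
        assert rmsd == pytest.approx(expected, rel=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateFitError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(DegenerateFitError):
            superpose(line, line)


class TestAxisAngle:
    def test_identity_is_zero_degrees(self):
        theta, _ = axis_angle(np.eye(3))
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_recovers_constructed_rotation(self):
        rng = np.random.default_rng(3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rotation_from_axis_angle(17.3, axis)
        theta, ax = axis_angle(R)
        assert theta == pytest.approx(17.3, abs=1e-9)
        assert abs(abs(np.dot(ax, axis)) - 1) < 1e-9

    def test_stable_near_pi(self):
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        R = rotation_from_axis_angle(179.9, axis)
        theta, ax = axis_angle(R)
        R2 = rotation_from_axis_angle(theta, ax)
        assert np.abs(R2 - R).max() < 1e-6

    @pytest.mark.parametrize("theta", [0.01, 1.0, 17.3, 90.0, 150.0, 179.0])
    def test_agrees_with_scipy(self, theta):
        rng = np.random.default_rng(int(theta * 10))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rotation_from_axis_angle(theta, axis)
        got, _ = axis_angle(R)
        expected = np.degrees(ScipyRotation.from_matrix(R).magnitude())
        assert got == pytest.approx(expected, abs=1e-8)

    def test_round_trip_identity_on_open_interval(self):
        rng = np.random.default_rng(5)
        for theta in rng.uniform(0.5, 179.5, 25):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = rotation_from_axis_angle(theta, axis)
            th, ax = axis_angle(R)
            assert np.abs(rotation_from_axis_angle(th, ax) - R).max() < 1e-9

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            axis_angle(np.diag([1.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            axis_angle(np.diag([1.0, 1.0, -1.0]) @ rotation_from_axis_angle(30, (1, 0, 0)))


class TestMeasureRotations:
    def test_self_measurement_is_zero(self, subunit_cm):
        ref, _, _ = synthetic.make_rotated_subunit(synthetic.SubunitSpec(seed=8))
        m = measure_rotations(ref, ref, subunit_cm, subunit_cm)
        assert m.body_angle == pytest.approx(0.0, abs=1e-9)
        assert m.head_angle == pytest.approx(0.0, abs=1e-9)

    def test_recovers_injected_body_rotation(self, subunit_cm):
        ref, rot, _ = synthetic.make_rotated_subunit(
            synthetic.SubunitSpec(body_angle=8.0, head_angle=0.0, seed=9))
        m = measure_rotations(rot, ref, subunit_cm, subunit_cm)
        assert m.body_angle == pytest.approx(8.0, abs=0.01)
        assert m.head_angle == pytest.approx(0.0, abs=0.01)

    def test_recovers_head_rotation_under_noise(self, subunit_cm):
        ref, rot, _ = synthetic.make_rotated_subunit(
            synthetic.SubunitSpec(body_angle=0.0, head_angle=18.0,
                                  noise_sd=0.3, seed=10))
        m = measure_rotations(rot, ref, subunit_cm, subunit_cm)
        assert m.head_angle == pytest.approx(18.0, abs=0.5)

    def test_too_few_atoms_is_unresolved(self, subunit_cm):
        ref, rot, _ = synthetic.make_rotated_subunit(synthetic.SubunitSpec(seed=11))
        starved = rotation.DomainDefinition(min_paired_atoms=10 ** 6)
        with pytest.raises(MeasurementUnresolvedError):
            measure_rotations(rot, ref, subunit_cm, subunit_cm, starved)


def _meas(body, head):
    z = np.array([0.0, 0.0, 1.0])
    return RotationMeasurement(body, head, z, z)


class TestStateWindows:
    @pytest.mark.parametrize("body,head,expected", [
        (7.0, 18.0, "chimeric_hybrid"),
        (2.0, 18.0, "chimeric_hybrid"),
        (8.0, 2.0, "hybrid"),
        (6.0, 0.0, "hybrid"),
        (10.0, 0.0, "hybrid"),
        (0.5, 1.0, "classical"),
        (3.0, 6.0, "classical"),
        (12.0, 12.0, "unassigned"),
        (4.0, 2.0, "unassigned"),
    ])
    def test_window_assignment(self, body, head, expected):
        assert classify_state(_meas(body, head)).state == expected

    def test_total_and_deterministic(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            m = _meas(rng.uniform(0, 30), rng.uniform(0, 30))
            s1, s2 = classify_state(m).state, classify_state(m).state
            assert s1 == s2
            assert s1 in {"classical", "hybrid", "chimeric_hybrid", "unassigned"}

    def test_reverse_body_rotation_not_hybrid(self):
        m = _meas(8.0, 2.0)
        m.body_sign = "reverse"
        assert classify_state(m).state == "unassigned"
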
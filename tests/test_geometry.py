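"""Center-of-mass domain angles, drift estimation, replica consistency."""

import numpy as np
import pytest

from channelgauge.geometry import (
    AngleSeries,
    angle_timeseries,
    center_of_mass,
    domain_angle,
    drift,
    replica_consistency,
)
from channelgauge.structure import AtomRecord, DomainDefinition, Structure


def _point_structure(points, masses):
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", res_name="GLY",
                   res_id=i + 1, chain_id="A", coords=tuple(p),
                   vdw_radius=1.7, mass=m)
        for i, (p, m) in enumerate(zip(points, masses))
    ]
    return Structure(atoms)


class TestCenterOfMass:
    def test_equal_masses_symmetric(self):
        c = center_of_mass(np.array([[1.0, 0, 0], [-1.0, 0, 0]]), np.array([1.0, 1.0]))
        assert np.allclose(c, 0.0)

    def test_weighted_closed_form(self):
        c = center_of_mass(np.array([[0.0, 0, 0], [4.0, 0, 0]]), np.array([1.0, 3.0]))
        assert c[0] == pytest.approx(3.0)

    def test_matches_direct_sum(self, rng):
        x = rng.uniform(-5, 5, (50, 3))
        m = rng.uniform(1, 20, 50)
        assert np.allclose(center_of_mass(x, m), (m[:, None] * x).sum(0) / m.sum())

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass(np.empty((0, 3)), np.empty(0))


def _three_blob_structure(p_dom, p_hinge, p_tmd):
    pts, masses = [], []
    for center in (p_dom, p_hinge, p_tmd):
        for d in ((0.1, 0, 0), (-0.1, 0, 0)):
            pts.append(np.asarray(center) + d)
            masses.append(1.0)
    s = _point_structure(pts, masses)
    dom = DomainDefinition.make("PAS", {"A": [(1, 2)]})
    hinge = DomainDefinition.make("hinge_PAS", {"A": [(3, 4)]})
    tmd = DomainDefinition.make("TMD", {"A": [(5, 6)]})
    return s, dom, hinge, tmd


class TestDomainAngle:
    def test_right_angle(self):
        s, dom, hinge, tmd = _three_blob_structure((0, 0, 0), (1, 0, 0), (1, 1, 0))
        a = domain_angle(s, s.coords, dom, hinge, tmd)
        assert a == pytest.approx(90.0, abs=1e-9)

    def test_collinear_is_180(self):
        s, dom, hinge, tmd = _three_blob_structure((0, 0, 0), (5, 0, 0), (9, 0, 0))
        assert domain_angle(s, s.coords, dom, hinge, tmd) == pytest.approx(180.0)

    def test_random_triples_match_arccos(self, rng):
        for _ in range(10):
            a, b, c = rng.uniform(-10, 10, (3, 3))
            s, dom, hinge, tmd = _three_blob_structure(a, b, c)
            got = domain_angle(s, s.coords, dom, hinge, tmd)
            va, vc = a - b, c - b
            expect = np.degrees(np.arccos(np.clip(
                va @ vc / np.linalg.norm(va) / np.linalg.norm(vc), -1, 1)))
            assert got == pytest.approx(expect, abs=1e-9)

    def test_symmetric_in_domain_and_tmd(self, rng):
        a, b, c = rng.uniform(-10, 10, (3, 3))
        s, dom, hinge, tmd = _three_blob_structure(a, b, c)
        assert domain_angle(s, s.coords, dom, hinge, tmd) == pytest.approx(
            domain_angle(s, s.coords, tmd, hinge, dom), abs=1e-12
        )

    def test_coincident_coms_rejected(self):
        s, dom, hinge, tmd = _three_blob_structure((1, 0, 0), (1, 0, 0), (5, 0, 0))
        with pytest.raises(ValueError, match="degenerate"):
            domain_angle(s, s.coords, dom, hinge, tmd)

    def test_invariance_to_rigid_motion_and_mass_rescale(self, rng):
        from scipy.spatial.transform import Rotation

        a, b, c = rng.uniform(-10, 10, (3, 3))
        s, dom, hinge, tmd = _three_blob_structure(a, b, c)
        base = domain_angle(s, s.coords, dom, hinge, tmd)
        R = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        moved = s.coords @ R.T + rng.uniform(-50, 50, 3)
        assert domain_angle(s, moved, dom, hinge, tmd) == pytest.approx(base, abs=1e-9)
        s2 = Structure([
            AtomRecord(a_.serial, a_.name, a_.element, a_.res_name, a_.res_id,
                       a_.chain_id, a_.coords, a_.vdw_radius, a_.mass * 7.0)
            for a_ in s.atoms
        ])
        assert domain_angle(s2, s.coords, dom, hinge, tmd) == pytest.approx(base, abs=1e-12)


class TestDrift:
    @pytest.mark.parametrize("total", [-20.0, -10.0, 0.0, 10.0, 20.0])
    def test_recovers_programmed_linear_drift_under_noise(self, total):
        """1000 frames, 2° frame noise: programmed drift back within 1°
        in every one of 20 seeded replicates."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.linspace(0, 1, 1000)
            series = 120.0 + total * t + rng.normal(0, 2.0, 1000)
            assert drift(series) == pytest.approx(total, abs=1.0)

    def test_exact_for_noiseless_linear_schedule(self):
        series = 100.0 - 20.0 * np.linspace(0, 1, 50)
        assert drift(series) == pytest.approx(-20.0, abs=1e-9)

    def test_static_series_zero(self):
        assert drift(np.full(100, 77.0)) == 0.0


class TestAngleTimeseries:
    def test_static_trajectory_zero_drift(self, motif_channel):
        from channelgauge.structure import Trajectory

        structure, layout = motif_channel
        traj = Trajectory(structure, np.stack([structure.coords] * 20))
        series = angle_timeseries(traj, layout.domains["PAS"],
                                  layout.domains["hinge_PAS"], layout.domains["TMD"])
        assert series.drift_deg == pytest.approx(0.0, abs=1e-9)

    def test_programmed_hinge_drifts_recovered(self, hinge_trajectory):
        traj, layout, manifest = hinge_trajectory
        pas = angle_timeseries(traj, layout.domains["PAS"],
                               layout.domains["hinge_PAS"], layout.domains["TMD"])
        cnbd = angle_timeseries(traj, layout.domains["CNBD"],
                                layout.domains["hinge_CNBD"], layout.domains["TMD"])
        assert pas.drift_deg == pytest.approx(
            manifest["hinge_drift_total_deg"]["PAS"], abs=1.0)
        assert cnbd.drift_deg == pytest.approx(
            manifest["hinge_drift_total_deg"]["CNBD"], abs=1.0)
        assert np.all((0 <= pas.averaged) & (pas.averaged <= 180))


class TestReplicaConsistency:
    def _series(self, values):
        return AngleSeries(label="x", per_monomer={}, averaged=np.asarray(values),
                           times_ns=np.arange(len(values)) * 0.01,
                           drift_deg=drift(np.asarray(values)))

    def test_identical_replicas_deviation_zero(self):
        s = self._series(100 - 20 * np.linspace(0, 1, 100))
        out = replica_consistency([s, s, s])
        assert out["max_pairwise_deviation_deg"] == pytest.approx(0.0)

    def test_two_known_drifts(self):
        s1 = self._series(100 - 20 * np.linspace(0, 1, 200))
        s2 = self._series(100 - 16 * np.linspace(0, 1, 200))
        out = replica_consistency([s1, s2])
        assert out["max_pairwise_deviation_deg"] == pytest.approx(4.0, abs=1e-9)

    def test_noisy_replicas_agree_within_five_degrees(self):
        """Three seeded replicas of the same −20° schedule with 2° frame
        noise: max pairwise drift deviation ≤ 5° in ≥ 90 % of 20 runs."""
        hits = 0
        for run in range(20):
            reps = []
            for r in range(3):
                rng = np.random.default_rng(1000 * run + r)
                vals = 130.0 - 20.0 * np.linspace(0, 1, 500) + rng.normal(0, 2.0, 500)
                reps.append(self._series(vals))
            out = replica_consistency(reps)
            hits += out["max_pairwise_deviation_deg"] <= 5.0
        assert hits >= 18

    def test_needs_two_replicas(self):
        with pytest.raises(ValueError):
            replica_consistency([self._series(np.linspace(0, 1, 50))])
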
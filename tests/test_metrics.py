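"""Superposition, RMSD series, RMSF profiles and low-RMSF anchors."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from channelgauge.metrics import (
    apply_superposition,
    kabsch_superpose,
    ligand_rmsd,
    low_rmsf_anchors,
    rmsd_series,
    rmsf_profile,
    RmsfProfile,
)
from channelgauge.structure import SelectionSpec, Structure, Trajectory
from channelgauge.synth import make_ideal_helix


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-20, 20, 3)


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self, rng):
        x = rng.uniform(-5, 5, (10, 3))
        fit = kabsch_superpose(x, x)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_copy_recovers_exactly(self, rng):
        x = rng.uniform(-5, 5, (12, 3))
        R, t = _random_rigid(rng)
        fit = kabsch_superpose(x @ R.T + t, x)
        assert fit.rmsd < 1e-8

    def test_matches_brute_force_rotation_search(self, rng):
        """Optimal RMSD equals a direct minimization over rotation vectors."""
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        mob = ref.copy()
        mob[3] += [1.0, -0.5, 0.7]
        fit = kabsch_superpose(mob, ref)

        mc = mob - mob.mean(axis=0)
        rc = ref - ref.mean(axis=0)

        def cost(rv):
            Rm = Rotation.from_rotvec(rv).as_matrix()
            return np.sqrt(np.mean(np.sum((mc @ Rm.T - rc) ** 2, axis=1)))

        best = min(
            (minimize(cost, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14}).fun
             for x0 in rng.uniform(-np.pi, np.pi, (24, 3))),
        )
        assert fit.rmsd == pytest.approx(best, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(line[:2], line[:2])

    def test_rmsd_invariant_to_rigid_motion_of_either_input(self, rng):
        x = rng.uniform(-5, 5, (20, 3))
        y = x + rng.normal(0, 0.5, x.shape)
        base = kabsch_superpose(x, y).rmsd
        for _ in range(3):
            R, t = _random_rigid(rng)
            assert kabsch_superpose(x @ R.T + t, y).rmsd == pytest.approx(base, abs=1e-8)
            assert kabsch_superpose(x, y @ R.T + t).rmsd == pytest.approx(base, abs=1e-8)


class TestRmsdSeries:
    def test_identical_frames_all_zero(self):
        s = make_ideal_helix(10)
        traj = Trajectory(s, np.stack([s.coords] * 4))
        sel = SelectionSpec.make(backbone_only=True)
        out = rmsd_series(traj, s, sel, sel)
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_single_displaced_atom_closed_form(self):
        """With the fit anchored on unmoved residues, RMSD = d / sqrt(N)."""
        s = make_ideal_helix(10)
        coords = s.coords.copy()
        d = 2.37
        coords[30] += [0, 0, d]  # an atom of residue 8
        traj = Trajectory(s, coords[None])
        fit_sel = SelectionSpec.make(res_range=(1, 5))
        measure_sel = SelectionSpec.make(res_range=(1, 10))
        out = rmsd_series(traj, s, fit_sel, measure_sel)
        assert out.values[0] == pytest.approx(d / np.sqrt(40), abs=1e-9)

    def test_matches_per_frame_kabsch_oracle(self, rng):
        s = make_ideal_helix(8)
        frames = s.coords + rng.normal(0, 0.8, (6, s.n_atoms, 3))
        traj = Trajectory(s, frames)
        sel = SelectionSpec.make(backbone_only=True)
        out = rmsd_series(traj, s, sel, sel, mass_weighted=False)
        for i, frame in enumerate(frames):
            assert out.values[i] == pytest.approx(
                kabsch_superpose(frame, s.coords).rmsd, abs=1e-9
            )


class TestLigandRmsd:
    @staticmethod
    def _system():
        prot = make_ideal_helix(8)
        from channelgauge.structure import AtomRecord

        lig_atoms = [
            AtomRecord(serial=1000 + i, name=f"L{i}", element="C", res_name="LIG",
                       res_id=500, chain_id="X", coords=(20.0 + i, 5.0, float(i)),
                       vdw_radius=1.7, mass=12.011)
            for i in range(4)
        ]
        full = Structure(prot.atoms + lig_atoms)
        return full

    def test_unmoved_ligand_is_zero(self):
        s = self._system()
        traj = Trajectory(s, s.coords[None])
        out = ligand_rmsd(traj, SelectionSpec.make(chains=["X"]), s,
                          SelectionSpec.make(chains=["A"]))
        assert out.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_translated_ligand_measures_displacement(self):
        s = self._system()
        coords = s.coords.copy()
        lig = s.chain_ids == "X"
        coords[lig] += [0.0, 2.0, 0.0]
        traj = Trajectory(s, coords[None])
        out = ligand_rmsd(traj, SelectionSpec.make(chains=["X"]), s,
                          SelectionSpec.make(chains=["A"]))
        assert out.values[0] == pytest.approx(2.0, abs=1e-9)

    def test_global_rotation_with_ligand_is_zero(self, rng):
        s = self._system()
        R, t = _random_rigid(rng)
        traj = Trajectory(s, (s.coords @ R.T + t)[None])
        out = ligand_rmsd(traj, SelectionSpec.make(chains=["X"]), s,
                          SelectionSpec.make(chains=["A"]))
        assert out.values[0] == pytest.approx(0.0, abs=1e-7)

    def test_name_mismatch_lists_unmatched(self):
        s = self._system()
        traj = Trajectory(s, s.coords[None])
        with pytest.raises(ValueError, match="L3"):
            ligand_rmsd(traj, SelectionSpec.make(chains=["X"], atom_names=["L0", "L3"]),
                        s.subset(np.flatnonzero(s.names != "L3")),
                        SelectionSpec.make(chains=["A"]))


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        s = make_ideal_helix(8)
        traj = Trajectory(s, np.stack([s.coords] * 5))
        prof = rmsf_profile(traj, SelectionSpec.make(backbone_only=True), ["A"])
        assert np.allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        s = make_ideal_helix(8)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_profile(Trajectory(s, s.coords[None]),
                         SelectionSpec.make(backbone_only=True), ["A"])

    def test_oscillating_residue_dominates_profile(self):
        """One residue moving ±a along x: its RMSF ≈ a, the rest near zero
        (the shared alignment leaks a small 1/N contamination)."""
        s = make_ideal_helix(50)
        a = 1.2
        frames = np.stack([s.coords] * 6)
        mover = s.res_ids == 25
        for f in range(6):
            frames[f, mover, 0] += a if f % 2 == 0 else -a
        traj = Trajectory(s, frames)
        prof = rmsf_profile(traj, SelectionSpec.make(backbone_only=True), ["A"])
        i = int(np.flatnonzero(prof.res_ids == 25)[0])
        assert prof.rmsf[i] == pytest.approx(a, rel=0.05)
        others = np.delete(prof.rmsf, i)
        assert np.all(others < 0.1 * a)

    def test_rigid_motion_injected_into_frames_changes_nothing(self, rng):
        s = make_ideal_helix(10)
        frames = s.coords + rng.normal(0, 0.3, (8, s.n_atoms, 3))
        traj = Trajectory(s, frames)
        sel = SelectionSpec.make(backbone_only=True)
        base = rmsf_profile(traj, sel, ["A"]).rmsf
        moved = np.empty_like(frames)
        for f in range(8):
            R, t = _random_rigid(rng)
            moved[f] = frames[f] @ R.T + t
        prof2 = rmsf_profile(Trajectory(s, moved), sel, ["A"]).rmsf
        assert np.allclose(prof2, base, atol=1e-7)

    def test_four_chain_noise_profile_recovers_sigma(self, motif_channel, rng):
        """Isotropic per-atom noise σ ⇒ per-residue RMSF ≈ σ√3, averaged
        over the four monomers (single-atom pseudo-residues)."""
        structure, layout = motif_channel
        sigma = 0.5
        n_frames = 300
        lo, hi = layout.domains["PAS"].ranges["A"][0]
        sel = SelectionSpec.make(res_range=(lo, hi))
        idx = np.flatnonzero((structure.res_ids >= lo) & (structure.res_ids <= hi))
        frames = np.repeat(structure.coords[None], n_frames, axis=0)
        frames[:, idx, :] += rng.normal(0, sigma, (n_frames, idx.size, 3))
        traj = Trajectory(structure, frames)
        prof = rmsf_profile(traj, sel, list("ABCD"))
        expected = sigma * np.sqrt(3)
        assert prof.rmsf.mean() == pytest.approx(expected, rel=0.10)


class TestLowRmsfAnchors:
    def test_deep_valley_is_returned_exactly(self):
        res = np.arange(1, 101)
        rmsf = np.full(100, 3.0)
        rmsf[40:60] = 0.5
        prof = RmsfProfile(res_ids=res, rmsf=rmsf, chains=("A",))
        segs = low_rmsf_anchors(prof, 0.2)
        assert len(segs) == 1
        assert segs[0].res_range == (41, 60)

    def test_uniform_profile_ties_break_by_residue_order(self):
        res = np.arange(1, 51)
        prof = RmsfProfile(res_ids=res, rmsf=np.ones(50), chains=("A",))
        segs = low_rmsf_anchors(prof, 0.2)
        assert segs[0].res_range == (1, 10)

    def test_too_strict_quantile_warns_and_returns_empty(self):
        res = np.arange(1, 51)
        rmsf = np.arange(50, dtype=float)
        prof = RmsfProfile(res_ids=res, rmsf=rmsf, chains=("A",))
        with pytest.warns(UserWarning):
            segs = low_rmsf_anchors(prof, 0.05, min_length=5)
        assert segs == []
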
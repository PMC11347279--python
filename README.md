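# channelgauge

Structural analysis of ion-channel molecular-dynamics trajectories, built
around the workflow used to characterize trafficking-deficient hERG (Kv11.1)
channel mutants: does the pore collapse, do the intracellular domains swing
relative to the membrane, does a linker helix unfold, and do internalization
motifs become solvent-exposed?

The package is aimed at computational structural biologists who have
trajectories (multi-model PDB or DCD) of a tetrameric channel — or who want
to validate an analysis protocol on synthetic trajectories with known ground
truth before spending it on microseconds of sampling.

## What it computes

- **Pore-radius profile** R(z): at each position z along the channel axis,
  the radius of the largest sphere centered in that plane that touches no
  atom's van der Waals sphere, `f(c) = min_i(|c − a_i| − r_i)` maximized
  over the plane by a deterministic grid + Nelder–Mead search (HOLE-style,
  seed-free). Per frame, and as mean ± SD over the trajectory; negative
  values report the occlusion depth of a collapsed slice.
- **Per-domain RMSD / per-residue RMSF** after mass-weighted Kabsch
  superposition, averaged over the four monomers, plus extraction of
  low-RMSF anchor segments for superposing representative structures.
- **Conformational clustering** of frames by pairwise backbone RMSD
  (typically on the pore-lining S6 helix): unweighted average linkage
  (UPGMA), Davies–Bouldin index in the medoid formulation, explained
  variance SSR/SST, and a two-stage cluster-count choice (smallest k that is
  a DBI local minimum and sits on the variance plateau, overridable per
  system), with medoid representatives.
- **Helix propensity** per residue from a 3-state hydrogen-bond secondary
  structure assignment (Kabsch–Sander energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond below
  −0.5), with condition-vs-condition deltas that localize helix loss.
- **Domain angles**: the angle at the hinge-segment center of mass between
  the PAS (or CNBD) domain COM and the transmembrane-domain COM, per frame
  and per monomer, with a window-based linear-drift estimate.
- **Motif exposure**: Shrake–Rupley SASA (deterministic golden-spiral
  points) of linear internalization motifs, normalized by the occluder-free
  reference to a relative exposure in [0, 1]; the four hERG signals
  (K21-Q25, Y54-A57, Y827-L830, Y845-F848) are built in.
- **Accelerated-MD dual-boost math**: `ΔV = (E − V)²/(α + (E − V))` for
  V < E, the modified potential `V* = V + ΔV`, the (E, α) parameterization
  from unbiased-run mean energies, and exponential reweighting with an
  effective-sample-size diagnostic.
- **Synthetic data**: pseudo-atom tetramers realizing a prescribed pore
  profile, rigid domain blobs with hinges, motifs placed on surfaces or at
  occluded interfaces, backbone helices with scriptable unfolding, and
  seeded motion schedules (constriction, hinge drift, occluder displacement,
  thermal noise) that emit a ground-truth manifest.

## Worked example

```python
import numpy as np
from channelgauge import parse_glycan_composition
from channelgauge.synth import (ChannelSpec, MotionSchedule, linear_schedule,
                                make_channel, make_trajectory)
from channelgauge.pore import PoreAxis, pore_timeseries
from channelgauge.geometry import angle_timeseries
from channelgauge.structure import SelectionSpec

counts, total = parse_glycan_composition("Glc3Man9GlcNAc2")
print(f"core N-glycan: {counts} -> {total} residues")

spec = ChannelSpec(z_range=(-12, 12),
                   motif_surface=("K21-Q25",), motif_interface=("Y54-A57",))
structure, layout = make_channel(spec)
schedule = MotionSchedule(            # a "mutant-like" condition
    pore_radius=lambda z, t: 5.0 - 2.5 * t * np.exp(-(z - 4.0) ** 2 / 8.0),
    hinge_drift_deg={"PAS": linear_schedule(-20.0)},
    noise_sigma=0.2, seed=1)
traj, manifest = make_trajectory(structure, schedule, 20, layout)

lo, hi = layout.domains["TMD"].ranges["A"][0]
profile = pore_timeseries(traj, PoreAxis(z_range=(-8, 8), dz=1.0),
                          selection=SelectionSpec.make(res_range=(lo, hi)))
i = profile.mean.argmin()
print(f"min mean pore radius {profile.mean[i]:.2f} +/- {profile.sd[i]:.2f} A "
      f"at z = {profile.z[i]:+.1f} A")

pas = angle_timeseries(traj, layout.domains["PAS"],
                       layout.domains["hinge_PAS"], layout.domains["TMD"])
print(f"PAS domain angle: start {pas.averaged[0]:.1f} deg, "
      f"drift {pas.drift_deg:+.1f} deg")
```

prints

```
core N-glycan: {'Glc': 3, 'Man': 9, 'GlcNAc': 2} -> 14 residues
min mean pore radius 1.84 +/- 0.75 A at z = +4.0 A
PAS domain angle: start 135.2 deg, drift -19.6 deg
```

The pore narrows where the schedule constricts it (just below the top of
the span, the "selectivity-filter" side), the large SD there reflects the
progressive collapse, and the programmed −20° hinge closure is read back
from the angle series within the noise.

A `channelgauge` CLI wraps the same stages
(`synth`, `pore`, `amd-params`, `validate`, `report`); `channelgauge report`
runs the full wildtype-vs-mutant comparison from a YAML/TOML config and
writes deterministic CSV/JSON with a config-hash provenance header.

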
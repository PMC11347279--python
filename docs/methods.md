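# Methods

This note documents the models, estimators, numerical choices and known
limitations of channelgauge, in the order the pipeline runs them.

## Structures, trajectories, selections

Coordinates are Å throughout; residue ranges are 1-based and inclusive
("Lys362–Pro386" style). Van der Waals radii are the Bondi set (C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20 Å), shipped as a CSV table so a deployment
can substitute its own. Altloc records collapse to the highest-occupancy
conformer; hydrogens are not required on input — the secondary-structure
stage reconstructs backbone amides geometrically. Multi-model PDB
(`MODEL`/`ENDMDL`) is the canonical text trajectory dialect; CHARMM/X-PLOR
32-bit DCD is supported through MDAnalysis' low-level codec. The snapshot
interval defaults to 0.01 ns, the capture rate the analyses assume.

Domain boundaries (PAS, TMD, CNBD, the two hinge linkers, S6) are
configuration inputs, not constants: real channel constructs differ in
numbering, and the synthetic tetramer uses its own layout, so every
analysis takes explicit per-chain residue ranges.

## Superposition, RMSD, RMSF

Superposition is Kabsch/SVD with the determinant correction (reflections
excluded), mass-weighted by default with a flag for uniform weights.
Collinear or sub-3-point sets are rejected rather than silently resolved.
Per-domain RMSD fits and measures on the same domain by default (the
alternative — fit on the whole protein — is a config switch) and averages
the per-chain series over the four monomers. Ligand RMSD fits on the
protein and never re-fits the ligand, so drift inside the binding site is
preserved while global motion is removed.

RMSF uses the time-average structure as reference: frames are first aligned
to frame 0 (the mean of freely tumbling frames is meaningless), the mean is
formed, frames are re-aligned to it once, and the mean recomputed. This
one-iteration scheme makes the profile exactly invariant to rigid motion
injected into every frame. The per-residue value is the RMS 3-D deviation
of the residue's backbone centroid; profiles are averaged across monomer
chains on the intersection of their residue ids. Low-RMSF anchor segments
are the lowest-quantile residues (ties broken by residue order, so the
result is deterministic), kept only as contiguous runs of at least 5
residues.

One estimator property worth knowing: because the shared alignment absorbs
part of any single residue's motion, a lone oscillating residue reads back
slightly below its true amplitude (a ~1/N leak into its neighbours). The
tests budget for this rather than pretend it away.

## Pore-radius profile

At each z on the axis grid (default spacing 0.5 Å) the profiler maximizes
the clearance `f(c) = min_i(|c − a_i| − r_i)` over sphere centers `c`
constrained to the plane, within a lateral window of 10 Å around the axis:
a 0.25 Å coarse grid followed by Nelder–Mead refinement from the best cell.
The search is fully deterministic — no annealing, no seed.

Three slice outcomes exist. *ok*: the optimum is interior; on fixtures with
≤ 100 atoms it agrees with an exhaustive 0.05 Å grid to 0.05 Å. *open*: no
atom lies in the window; the radius caps at the window radius. *escaped*:
the optimum runs to the lateral window boundary, meaning the sphere is not
laterally enclosed at this z; the slice then reports the clearance of the
on-axis center, which for an axis blocked by an atom is the (negative)
occlusion depth. Negative radii are reported, not clamped — the depth of a
collapse is signal.

A geometric subtlety: with the center constrained to a plane, the
inscribed sphere at z may be limited by atoms of neighbouring rings when
the profile is steep. The correct analytic target for a ring stack is the
envelope `min_z' sqrt(R(z')² + (z − z')²) − r`, which only reduces to
`R(z) − r` where |dR/dz| is small. The hourglass fixtures are validated
against the envelope.

## Conformational clustering

Frames (default stride 10, recorded in the output) are compared by RMSD
after per-pair superposition on the selection — fit equals measure, so
rigid-body-equivalent frames are at distance zero. Agglomeration is
unweighted average linkage (UPGMA) with ties broken by the smallest
(i, j) cluster-index pair, clusters indexed by their smallest member frame;
this makes the dendrogram, and hence every cut, deterministic.

RMSD space has no coordinates, so cluster quality uses the medoid
formulation: S_i is the mean distance of members to the cluster medoid
(the member minimizing mean within-cluster distance, smallest index on
ties) and M_ij the medoid–medoid distance;
DBI = (1/k) Σ_i max_j (S_i + S_j)/M_ij. Explained variance is
SSR/SST with SST = Σ_pairs d²/n and SSE = Σ_c Σ_within d²/|c|.

The cluster count is chosen in two stages. Stage one scans k (default
2..min(100, n−1)) and picks the smallest k that is a local DBI minimum
*and* whose SSR/SST gain to the next k falls below 0.01 (the plateau
threshold — an explicit numerical stand-in for what is usually an eyeball
judgement). If no k satisfies both, the best-DBI k is returned flagged
"no_plateau". Stage two is a per-system override, since different systems
legitimately settle on different counts. The full metric trace is always
emitted so the override is an informed one.

## Secondary structure and helix propensity

Backbone amide H is placed 1.01 Å from N, anti to the C(prev)–N–Cα
bisector, in the peptide plane; prolines and chain N-termini get none. The
Kabsch–Sander electrostatic energy with the −0.5 kcal/mol cutoff defines
hydrogen bonds (overlapping atoms clamp to −9.9). The assignment is
3-state: residue i is H when the two consecutive i→i+4 turns closing on it
(acceptor i−1 → donor i+3+1, acceptor i → donor i+4) both exist — the
minimal two-turn helix; E requires a parallel or antiparallel paired
bridge; everything else, including 3₁₀/π patterns and lone extended
strands, is C. This is deliberately coarser than 8-class DSSP: only
alpha-helix propensity is consumed downstream. Under this rule a 20-residue
ideal helix is helical from residue 2 through 16; chain termini can never
satisfy the turn pattern.

Helix propensity is the per-residue fraction of frames assigned H (≥ 10
frames required). Condition comparisons attach the domain-mean delta and
the per-residue delta; a localized unfolding event appears as a contiguous
negative segment, eroded by one or two residues at each flank where the
boundary turns break.

## Domain angles

The descriptor is the angle at the hinge-segment COM between the domain COM
and the TMD COM (vertex at the hinge; symmetric in its outer arguments,
clamped arccos, coincident COMs rejected). Per-monomer angles use that
monomer's own three selections by default — the tetramer-TMD convention is
a switch. Drift is estimated as the difference of the first and last 10%
window means divided by the exact window-center separation; the division
makes the estimator unbiased for a linear schedule (the raw window
difference underestimates it by ~(1 − w)) while keeping the windows' noise
averaging. On 1000-frame series with 2° frame noise the estimator recovers
±20° programmed drifts well within 1°. Replica consistency reports
per-replica drifts and their maximum pairwise deviation.

## Motif exposure

Shrake–Rupley SASA with deterministic golden-spiral (Fibonacci-lattice)
points, probe 1.4 Å, default 960 points per atom (92 minimum; the two
defaults agree within 1% on the fixtures). A motif's relative exposure is
its summed residue SASA divided by the same atoms' occluder-free SASA; for
a linear pseudo-atom motif this reference equals its extended-chain
accessibility, and for peptides with backbone an extended rebuild is used.
A motif is "exposed" in a frame when relative exposure exceeds 0.25 — a
documented convention, not a literature constant; the threshold is a
parameter. Membrane-like atoms can be excluded from the occluder set by
element since the motifs of interest are intracellular.

Shrake–Rupley is strictly local: a motif inside a large hollow cavity is
"accessible". The synthetic buried-motif fixture therefore packs an
occluder slab directly against the motif (a genuine interface), not a
distant shell.

## Accelerated-MD boost

ΔV = (E − V)²/(α + (E − V)) for V < E, else 0, with the identities
0 ≤ ΔV ≤ E − V, ΔV(E − α) = (E − V)/2, and V* = V + ΔV continuous,
non-decreasing, and capped by E below threshold. The printed form of this
expression in some sources drops the squared exponent to citation markup;
the squared-numerator form is the one with these properties and is what is
implemented. Dual-boost parameterization from unbiased-run means uses the
standard per-residue/per-atom recipe — E_dih = ⟨V_dih⟩ + 3.5·n_res,
α_dih = 3.5·n_res/5, E_tot = ⟨V_tot⟩ + 0.16·n_atoms, α_tot = 0.16·n_atoms —
with all three constants explicit arguments recorded in the provenance,
because published variants differ. Exponential reweighting
(w ∝ exp(ΔV/kT), max-subtracted) reports the effective sample size and
flags ESS < 10% of n; beyond a few kT of boost spread the estimator is
honest but useless, which is why the flag exists. k_B = 0.0019872041
kcal/mol/K.

## Synthetic data: what it emulates, and what it does not

The generators encode the geometric and statistical structure the analyses
assume: a 4-fold-symmetric pseudo-atom tetramer whose pore rings realize a
prescribed R(z) (ring atom centers at lateral distance R, so the measured
profile is R − r_atom); rigid 64-point domain lattices at prescribed COMs
with 5-atom hinge lines; motifs as atom lines on an outward face (surface)
or pressed under a packed occluder slab (interface); ideal poly-alanine
backbone helices built by natural-extension from φ = −57°, ψ = −47°
(≈1.5 Å rise, ≈100°/residue, Cα–Cα 3.80 Å) with per-frame random-coil
rebuilds for scripted unfolding; Gaussian energy series; and frame sets
drawn from c well-separated conformational basins. Motion schedules apply
exact transformations — hinge drift is a rigid rotation of the domain about
an axis normal to the domain/hinge/TMD plane, so the programmed angle
change is realized exactly — plus i.i.d. isotropic Gaussian noise. Every
generator returns a JSON-serializable manifest of its ground truth, and all
randomness flows from one integer seed.

Default study conditions: hinge drifts of −20° (PAS) and +10° (CNBD),
pore constriction of 2.5 Å localized below the upper (filter-side) end of
the span, a 25-residue linker-helix unfolding, frame noise σ = 0.25 Å, and
an occluder step at half-run that flips a buried motif to exposed for 50%
of frames. These mirror, at desk scale, the magnitudes of the phenomena the
pipeline is designed to detect.

What passing these tests does **not** show: pseudo-atoms carry no
chemistry, no membrane, no water, and no force-field dynamics — noise is
white, not autocorrelated, so statistical error bars on real trajectories
will be larger at equal frame counts; the helix fixtures are backbone-only
poly-alanine; and absolute RMSD/RMSF magnitudes of real microsecond
ensembles are not reproduced, only the estimators' correctness on known
ground truth.

## Pipeline and problem sizes

The comparison pipeline runs rmsd → rmsf → cluster → pore → ss → angles →
sasa per condition, marks a failing stage and continues with independent
ones, extracts one scalar per metric, and reports deltas against the first
(reference) condition. Outputs are deterministic: every CSV/JSON carries a
config hash (over the scientific parameters; the output directory is
excluded) and seed, floats are formatted to fixed precision, and reruns are
byte-identical. The shipped test and acceptance configurations use 10–50
frame trajectories, 0.5–2 Å slice spacing, 92–960 SASA points and k-scans
to 8 — sizes chosen so the full ground-truth battery, including a double
pipeline run for the determinism check, completes in minutes on one CPU
while still exercising every estimator in its operating regime.
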
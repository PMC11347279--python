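"""Superposition (Kabsch), per-domain RMSD series, per-residue RMSF.

RMSD is measured after an optimal rigid-body fit on a fit selection;
per-domain analyses fit and measure on the same domain by default and
average over the four channel monomers. RMSF uses the time-average structure
(after one alignment pass) as the reference, and profiles are averaged over
monomer chains aligned by residue id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import (
    SelectionSpec,
    SelectionWarning,
    Structure,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "ligand_rmsd",
    "rmsf_profile",
    "low_rmsf_anchors",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mobile → reference: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass
class RmsdSeries:
    domain: str
    values: np.ndarray  # Å, per frame
    reference: str
    times_ns: np.ndarray | None = None


@dataclass
class RmsfProfile:
    res_ids: np.ndarray
    rmsf: np.ndarray  # Å, per residue, averaged over monomer chains
    chains: tuple[str, ...]


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Kabsch/SVD with the determinant correction, so reflections are excluded
    and ``det(R) = +1``. ``weights`` (e.g. masses) weight both the fit and
    the reported RMSD. Degenerate inputs (< 3 points, or a collinear point
    set, which leaves the rotation about the line undetermined) raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,) or np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = weights / weights.sum()

    cm_mob = w @ mobile
    cm_ref = w @ reference
    x = mobile - cm_mob
    y = reference - cm_ref
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    # Collinear sets have rank <= 1 covariance: rotation underdetermined.
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    D = np.diag([1.0, 1.0, d])
    rot = vt.T @ D @ u.T
    xr = x @ rot.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (xr - y) ** 2)))
    trans = cm_ref - rot @ cm_mob
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords) @ fit.rotation.T + fit.translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    ref: Structure,
    fit_sel: SelectionSpec | None,
    measure_sel: SelectionSpec,
    *,
    mass_weighted: bool = True,
    domain: str = "selection",
    reference_label: str = "reference",
) -> RmsdSeries:
    """Per-frame RMSD: fit each frame on ``fit_sel``, measure on ``measure_sel``.

    ``fit_sel=None`` skips superposition (coordinates compared as-is). The
    measured RMSD is unweighted; ``mass_weighted`` controls the fit only.
    """
    m_idx = resolve_selection(traj.topology, measure_sel)
    if m_idx.size == 0:
        raise ValueError("empty measure selection")
    f_idx = None
    if fit_sel is not None:
        f_idx = resolve_selection(traj.topology, fit_sel)
        if f_idx.size == 0:
            raise ValueError("empty fit selection")
    weights = traj.topology.masses[f_idx] if (mass_weighted and f_idx is not None) else None

    ref_coords = ref.coords
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        if f_idx is not None:
            fit = kabsch_superpose(frame[f_idx], ref_coords[f_idx], weights)
            moved = apply_superposition(frame[m_idx], fit)
        else:
            moved = frame[m_idx]
        values[i] = _rmsd(moved, ref_coords[m_idx])
    return RmsdSeries(domain=domain, values=values, reference=reference_label,
                      times_ns=traj.times_ns)


def ligand_rmsd(
    traj: Trajectory,
    ligand_sel: SelectionSpec,
    docked_ref: Structure,
    protein_fit_sel: SelectionSpec,
    *,
    mass_weighted: bool = True,
) -> RmsdSeries:
    """Ligand RMSD from a docked pose: fit on the protein, measure the ligand.

    The ligand is never re-fit, so genuine ligand drift inside the pose frame
    is preserved while global protein motion is removed. Ligand atom names
    must match between trajectory topology and reference.
    """
    top = traj.topology
    lig_idx = resolve_selection(top, ligand_sel)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    ref_lig_idx = resolve_selection(docked_ref, ligand_sel)
    traj_names = set(top.names[lig_idx])
    ref_names = set(docked_ref.names[ref_lig_idx])
    if traj_names != ref_names or lig_idx.size != ref_lig_idx.size:
        unmatched = sorted(traj_names ^ ref_names)
        raise ValueError(f"ligand atom-name mismatch; unmatched names: {unmatched}")
    return rmsd_series(
        traj,
        docked_ref,
        protein_fit_sel,
        ligand_sel,
        mass_weighted=mass_weighted,
        domain="ligand",
        reference_label="docked_pose",
    )


def _residue_centroids(
    structure: Structure,
    coords: np.ndarray,
    idx: np.ndarray,
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Centroid of the selected atoms per (chain, residue), in atom order."""
    keys: list[tuple[str, int]] = []
    groups: dict[tuple[str, int], list[int]] = {}
    for i in idx:
        key = (structure.chain_ids[i], int(structure.res_ids[i]))
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(i)
    cents = np.array([coords[groups[k]].mean(axis=0) for k in keys])
    return keys, cents


def rmsf_profile(
    traj: Trajectory,
    sel: SelectionSpec,
    monomer_chains: Sequence[str] | None = None,
    *,
    mass_weighted: bool = True,
) -> RmsfProfile:
    """Per-residue RMSF about the time-average structure, averaged over monomers.

    Frames are aligned to their mean once, the mean recomputed, and RMSF per
    residue is the RMS over frames of the deviation of the residue centroid
    (on the selected atoms, typically backbone). Profiles from the listed
    monomer chains are averaged on the intersection of their residue ids.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = resolve_selection(traj.topology, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    weights = traj.topology.masses[idx] if mass_weighted else None

    sub = traj.frames[:, idx, :]
    # Remove global motion against frame 0 first (otherwise the mean of
    # freely tumbling frames is meaningless), then iterate once against the
    # time average. This makes the profile exactly invariant to rigid motion
    # injected into every frame.
    aligned = np.empty_like(sub)
    for i, frame in enumerate(sub):
        fit = kabsch_superpose(frame, sub[0], weights)
        aligned[i] = apply_superposition(frame, fit)
    mean = aligned.mean(axis=0)
    for i, frame in enumerate(aligned):
        fit = kabsch_superpose(frame, mean, weights)
        aligned[i] = apply_superposition(frame, fit)
    mean = aligned.mean(axis=0)

    keys, _ = _residue_centroids(traj.topology, traj.frames[0], idx)
    groups: dict[tuple[str, int], list[int]] = {}
    for pos, i in enumerate(idx):
        groups.setdefault((traj.topology.chain_ids[i], int(traj.topology.res_ids[i])), []).append(pos)

    per_res: dict[tuple[str, int], float] = {}
    for key in keys:
        g = groups[key]
        cents = aligned[:, g, :].mean(axis=1)
        ref = mean[g].mean(axis=0)
        per_res[key] = float(np.sqrt(np.mean(np.sum((cents - ref) ** 2, axis=1))))

    if monomer_chains is None:
        monomer_chains = sorted({k[0] for k in keys})
    chain_res = {
        c: {rid for (cc, rid) in per_res if cc == c} for c in monomer_chains
    }
    common = sorted(set.intersection(*(chain_res[c] for c in monomer_chains)))
    if not common:
        raise ValueError("monomer chains share no residue ids in the selection")
    prof = np.array([
        np.mean([per_res[(c, rid)] for c in monomer_chains]) for rid in common
    ])
    return RmsfProfile(res_ids=np.array(common), rmsf=prof, chains=tuple(monomer_chains))


def low_rmsf_anchors(
    profile: RmsfProfile,
    quantile: float,
    *,
    min_length: int = 5,
) -> list[SelectionSpec]:
    """Contiguous low-mobility residue segments for anchored superposition.

    Takes the ``quantile`` fraction of residues with the lowest RMSF (ties
    broken by residue order, so the lowest-index residues win), keeps
    contiguous runs of at least ``min_length``, and returns one backbone
    SelectionSpec per segment. Empty result carries a warning.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    n = len(profile.res_ids)
    n_take = int(np.floor(quantile * n))
    if n_take == 0:
        warnings.warn("quantile selects no residues", SelectionWarning, stacklevel=2)
        return []
    order = np.lexsort((profile.res_ids, profile.rmsf))
    chosen = np.sort(profile.res_ids[order[:n_take]])

    segments: list[tuple[int, int]] = []
    start = prev = int(chosen[0])
    for rid in chosen[1:]:
        rid = int(rid)
        if rid == prev + 1:
            prev = rid
        else:
            segments.append((start, prev))
            start = prev = rid
    segments.append((start, prev))
    segments = [(lo, hi) for lo, hi in segments if hi - lo + 1 >= min_length]
    if not segments:
        warnings.warn(
            "no contiguous low-RMSF segment reaches the minimum length",
            SelectionWarning,
            stacklevel=2,
        )
    return [
        SelectionSpec.make(res_range=(lo, hi), backbone_only=True) for lo, hi in segments
    ]
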
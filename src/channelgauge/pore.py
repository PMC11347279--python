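"""Largest-inscribed-sphere pore-radius profiling along the channel axis.

At each z along the pore axis the profiler finds the sphere of maximal
radius whose center lies in that z-plane and which touches but does not
overlap any atom's van der Waals sphere — the same quantity the HOLE family
of tools reports, computed here with a deterministic coarse-grid +
Nelder–Mead search (no annealing, so results are seed-free).

The slice radius can be negative: when atoms occlude the axis the reported
value is the (negative) clearance of the best on-axis sphere, which
preserves the depth of a pore collapse instead of clamping it to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .structure import SelectionSpec, Structure, Trajectory, resolve_selection

__all__ = ["PoreAxis", "SliceResult", "PoreProfile", "slice_radius", "pore_profile",
           "pore_timeseries"]


@dataclass(frozen=True)
class PoreAxis:
    """Pore axis: a point, a unit direction, the z-range and slice step (Å).

    By convention the membrane normal is the laboratory z-axis; any axis may
    be given (e.g. from two center-of-mass anchors).
    """

    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    z_range: tuple[float, float] = (-20.0, 20.0)
    dz: float = 0.5

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")
        if not self.z_range[1] > self.z_range[0]:
            raise ValueError("z_range must be increasing")
        if not self.dz > 0:
            raise ValueError("dz must be positive")

    @property
    def z_grid(self) -> np.ndarray:
        lo, hi = self.z_range
        n = int(round((hi - lo) / self.dz))
        return lo + self.dz * np.arange(n + 1)

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = np.asarray(self.direction, dtype=float)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(w @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(w, helper)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return u, v, w


@dataclass(frozen=True)
class SliceResult:
    z: float
    radius: float
    center: tuple[float, float]  # lateral (u, v) offset from the axis, Å
    status: str  # "ok" | "open" | "escaped"


@dataclass
class PoreProfile:
    """Radius-vs-z, per frame, with mean and SD over frames."""

    z: np.ndarray
    radii: np.ndarray          # (n_frames, n_z), Å; negative = occluded
    statuses: np.ndarray       # (n_frames, n_z) of str
    mean: np.ndarray
    sd: np.ndarray
    min_radius: np.ndarray     # per frame
    min_z: np.ndarray          # per frame

    @classmethod
    def from_stack(cls, z: np.ndarray, radii: np.ndarray, statuses: np.ndarray) -> "PoreProfile":
        imin = np.argmin(radii, axis=1)
        return cls(
            z=z,
            radii=radii,
            statuses=statuses,
            mean=radii.mean(axis=0),
            sd=radii.std(axis=0),
            min_radius=radii[np.arange(radii.shape[0]), imin],
            min_z=z[imin],
        )


def _clearance(points_uv: np.ndarray, z: float, atoms_uvw: np.ndarray,
               radii: np.ndarray) -> np.ndarray:
    """f(c) = min_i(|c - a_i| - r_i) for sphere centers in the z-plane."""
    d2 = (
        (points_uv[:, None, 0] - atoms_uvw[None, :, 0]) ** 2
        + (points_uv[:, None, 1] - atoms_uvw[None, :, 1]) ** 2
        + (z - atoms_uvw[None, :, 2]) ** 2
    )
    return (np.sqrt(d2) - radii[None, :]).min(axis=1)


def slice_radius(
    coords: np.ndarray,
    vdw_radii: np.ndarray,
    axis: PoreAxis,
    z: float,
    *,
    search_radius: float = 10.0,
    grid_step: float = 0.25,
) -> SliceResult:
    """Largest inscribed sphere with center in the plane at ``z``.

    The center is searched over a lateral disk of ``search_radius`` around
    the axis: a coarse grid (``grid_step``) followed by Nelder–Mead
    refinement from the best cell. If no atom lies within the slice window
    the slice is "open" and the radius caps at ``search_radius``. If the
    optimum runs to the window boundary the sphere has escaped the pore
    laterally; the slice reports the on-axis clearance with status
    "escaped" (for an axis blocked by an atom this is the negative
    occlusion depth).
    """
    u, v, w = axis.basis()
    rel = np.asarray(coords, dtype=float) - np.asarray(axis.point, dtype=float)
    atoms_uvw = np.stack([rel @ u, rel @ v, rel @ w], axis=1)
    radii = np.asarray(vdw_radii, dtype=float)

    # Atoms close enough in z and laterally to bound any in-window sphere.
    rmax = radii.max(initial=0.0)
    keep = (np.abs(atoms_uvw[:, 2] - z) <= search_radius + rmax) & (
        np.hypot(atoms_uvw[:, 0], atoms_uvw[:, 1]) <= 2 * search_radius + rmax
    )
    near = atoms_uvw[keep]
    near_r = radii[keep]
    lateral = np.hypot(near[:, 0], near[:, 1]) if near.size else np.empty(0)
    if near.shape[0] == 0 or not np.any(lateral <= search_radius):
        return SliceResult(z=z, radius=search_radius, center=(0.0, 0.0), status="open")

    ticks = np.arange(-search_radius, search_radius + grid_step / 2, grid_step)
    gu, gv = np.meshgrid(ticks, ticks)
    pts = np.stack([gu.ravel(), gv.ravel()], axis=1)
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= search_radius]
    vals = _clearance(pts, z, near, near_r)
    best = pts[int(np.argmax(vals))]

    def neg(c: np.ndarray) -> float:
        if np.hypot(c[0], c[1]) > search_radius:
            return np.inf
        return -float(_clearance(c.reshape(1, 2), z, near, near_r)[0])

    res = minimize(neg, best, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    center = res.x if np.isfinite(res.fun) else best
    radius = float(_clearance(center.reshape(1, 2), z, near, near_r)[0])

    if np.hypot(center[0], center[1]) >= search_radius * (1 - 1e-3):
        on_axis = float(_clearance(np.zeros((1, 2)), z, near, near_r)[0])
        return SliceResult(z=z, radius=on_axis, center=(0.0, 0.0), status="escaped")
    return SliceResult(z=z, radius=min(radius, search_radius),
                       center=(float(center[0]), float(center[1])), status="ok")


def pore_profile(
    coords: np.ndarray,
    vdw_radii: np.ndarray,
    axis: PoreAxis,
    *,
    search_radius: float = 10.0,
    grid_step: float = 0.25,
) -> list[SliceResult]:
    """Independent :func:`slice_radius` at every z of the axis grid."""
    return [
        slice_radius(coords, vdw_radii, axis, float(z),
                     search_radius=search_radius, grid_step=grid_step)
        for z in axis.z_grid
    ]


def pore_timeseries(
    traj: Trajectory,
    axis: PoreAxis,
    *,
    selection: SelectionSpec | None = None,
    search_radius: float = 10.0,
    grid_step: float = 0.25,
) -> PoreProfile:
    """Pore profile for every frame, stacked with mean(z) and sd(z).

    ``selection`` restricts the occluding atom set (e.g. protein only);
    the per-frame minimum radius and its z are reported alongside.
    """
    if selection is not None:
        idx = resolve_selection(traj.topology, selection)
    else:
        idx = np.arange(traj.topology.n_atoms)
    radii_tab = traj.topology.vdw_radii[idx]
    zg = axis.z_grid
    out = np.empty((traj.n_frames, zg.size))
    statuses = np.empty((traj.n_frames, zg.size), dtype=object)
    for f, frame in enumerate(traj.frames):
        slices = pore_profile(frame[idx], radii_tab, axis,
                              search_radius=search_radius, grid_step=grid_step)
        out[f] = [s.radius for s in slices]
        statuses[f] = [s.status for s in slices]
    return PoreProfile.from_stack(zg, out, statuses)
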
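"""Synthetic channel-like structures and trajectories with known ground truth.

Every analysis stage in the package has a generator here that emulates the
statistical or geometric structure the stage assumes, so the whole pipeline
is testable without any external data:

* an ideal poly-alanine backbone α-helix (and arbitrary φ/ψ builds) for the
  secondary-structure stage;
* a pseudo-atom tetrameric channel — pore-lining rings realizing a
  prescribed radius profile R(z), rigid PAS-like / CNBD-like domain blobs
  linked to the membrane region by hinge segments, internalization-motif
  residues placed on a surface or at an occluded interface — for the pore,
  angle, RMSD/RMSF and SASA stages;
* motion schedules (pore constriction, hinge-angle drift, occluder
  displacement, helix unfolding, isotropic thermal noise) applied on top of
  a structure to produce trajectories whose ground truth is emitted as a
  JSON-serializable manifest;
* Gaussian energy series for the accelerated-MD parameterization.

All randomness flows from a single integer seed; two runs with the same
seed are bitwise identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .amd import EnergySeries
from .structure import AtomRecord, DomainDefinition, Structure, Trajectory

__all__ = [
    "ChannelSpec",
    "ChannelLayout",
    "MotionSchedule",
    "build_backbone",
    "make_ideal_helix",
    "make_helix_trajectory",
    "make_channel",
    "make_trajectory",
    "make_energy_series",
    "make_basin_trajectory",
    "linear_schedule",
    "step_schedule",
]

# Ideal backbone internal coordinates (Å, degrees).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.5
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from A-B-C internals."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: Sequence[float],
    psi: Sequence[float],
    *,
    chain_id: str = "A",
    res_name: str = "ALA",
    start_res_id: int = 1,
) -> Structure:
    """Build an all-backbone (N, CA, C, O) peptide from φ/ψ arrays (ω = 180°)."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = phi.size
    if psi.size != n_res:
        raise ValueError("phi and psi must have equal length")
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[i - 1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          _BOND_C_N, _ANG_CA_C_N, psi[i - 1])
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           _BOND_N_CA, _ANG_C_N_CA, 180.0)
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          _BOND_CA_C, _ANG_N_CA_C, phi[i])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(coords):
        nxt_psi = psi[i]
        res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                               _BOND_C_O, _ANG_CA_C_O, nxt_psi + 180.0)

    atoms: list[AtomRecord] = []
    serial = 1
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    from .structure import element_table

    table = element_table()
    for i, res in enumerate(coords):
        rid = start_res_id + i
        for name in ("N", "CA", "C", "O"):
            el = elements[name]
            vdw, mass = table[el]
            atoms.append(AtomRecord(
                serial=serial, name=name, element=el, res_name=res_name,
                res_id=rid, chain_id=chain_id, coords=tuple(res[name]),
                vdw_radius=vdw, mass=mass,
            ))
            serial += 1
    return Structure(atoms)


def make_ideal_helix(n_res: int, **kwargs) -> Structure:
    """Ideal backbone α-helix (φ = −57°, ψ = −47°): ~1.5 Å rise, ~100°/residue."""
    if n_res < 5:
        raise ValueError("an alpha helix needs at least 5 residues")
    return build_backbone([_HELIX_PHI] * n_res, [_HELIX_PSI] * n_res, **kwargs)


def make_helix_trajectory(
    n_res: int,
    n_frames: int,
    *,
    unfold_range: tuple[int, int] | None = None,
    unfold_flags: Sequence[bool] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    frame_interval_ns: float = 0.01,
) -> tuple[Trajectory, dict]:
    """Helix trajectory in which a residue segment unfolds in flagged frames.

    Unfolded residues are rebuilt each flagged frame with seeded random-coil
    φ/ψ (β-region, no i→i+4 bonds); the manifest records the segment, the
    per-frame flags, and the implied unfolded fraction.
    """
    rng = np.random.default_rng(seed)
    if unfold_flags is None:
        unfold_flags = [False] * n_frames
    unfold_flags = list(unfold_flags)
    if len(unfold_flags) != n_frames:
        raise ValueError("unfold_flags length must equal n_frames")
    base = make_ideal_helix(n_res)
    frames = np.empty((n_frames, base.n_atoms, 3))
    for f in range(n_frames):
        phi = np.full(n_res, _HELIX_PHI)
        psi = np.full(n_res, _HELIX_PSI)
        if unfold_range is not None and unfold_flags[f]:
            lo, hi = unfold_range
            sl = slice(lo - 1, hi)  # res ids are 1-based
            m = hi - lo + 1
            phi[sl] = -120.0 + rng.uniform(-25, 25, m)
            psi[sl] = 130.0 + rng.uniform(-25, 25, m)
        s = build_backbone(phi, psi)
        frames[f] = s.coords
        if noise_sigma > 0:
            frames[f] += rng.normal(0.0, noise_sigma, frames[f].shape)
    manifest = {
        "generator": "make_helix_trajectory",
        "n_res": n_res,
        "n_frames": n_frames,
        "unfold_range": list(unfold_range) if unfold_range else None,
        "unfold_flags": [bool(x) for x in unfold_flags],
        "unfolded_fraction": float(np.mean(unfold_flags)),
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return Trajectory(base, frames, frame_interval_ns=frame_interval_ns), manifest


# ---------------------------------------------------------------------------
# Pseudo-atom tetrameric channel


@dataclass
class ChannelSpec:
    """Geometry of the synthetic tetramer (distances in Å).

    ``pore_radius`` is R(z): the lateral distance of the ring atom centers
    from the axis, so the measured inscribed-sphere profile is
    R(z) − atom_radius. Domain
    blobs are rigid lattices placed at ``domain_centers`` (chain-A template,
    replicated by 4-fold symmetry about z). Motifs listed in
    ``motif_surface`` stick out of their domain's outer face; those in
    ``motif_interface`` are tucked against an occluder plate (use
    ``occluded_motifs`` to generate the plate).
    """

    n_chains: int = 4
    pore_radius: Callable[[float], float] = lambda z: 5.0
    z_range: tuple[float, float] = (-15.0, 15.0)
    ring_spacing: float = 1.0
    atoms_per_ring: int = 24
    atom_radius: float = 1.5
    domain_centers: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "PAS": (36.0, 0.0, -20.0),
            "hinge_PAS": (18.0, 0.0, -18.0),
            "CNBD": (34.0, 0.0, -32.0),
            "hinge_CNBD": (16.0, 0.0, -26.0),
        }
    )
    blob_shape: tuple[int, int, int] = (4, 4, 4)
    blob_spacing: float = 2.6
    motif_surface: tuple[str, ...] = ()
    motif_interface: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for z in np.linspace(*self.z_range, 7):
            if self.pore_radius(float(z)) <= 0:
                raise ValueError("pore radius profile must be positive over the span")


# Residue-number layout of each synthetic chain (1-based, hERG-flavoured).
_BLOB_RES = {"PAS": (1, 60), "CNBD": (801, 860)}
_HINGE_RES = {"hinge_PAS": (61, 65), "hinge_CNBD": (781, 785)}
_TM_RES_START = 101
_OCCLUDER_RES_START = 901
_MOTIF_RANGES = {
    "K21-Q25": ("PAS", (21, 25)),
    "Y54-A57": ("PAS", (54, 57)),
    "Y827-L830": ("CNBD", (827, 830)),
    "Y845-F848": ("CNBD", (845, 848)),
}


@dataclass
class ChannelLayout:
    """Ground-truth bookkeeping for a generated channel."""

    spec: ChannelSpec
    domains: dict[str, DomainDefinition]
    rings: list[dict]                      # {"z", "R0", "indices", "lateral0"}
    motifs: dict[str, tuple[str, tuple[int, int]]]
    chain_ids: tuple[str, ...]


def _rotz(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([
        [math.cos(a), -math.sin(a), 0.0],
        [math.sin(a), math.cos(a), 0.0],
        [0.0, 0.0, 1.0],
    ])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def _blob_offsets(shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    nx, ny, nz = shape
    gx, gy, gz = np.meshgrid(
        (np.arange(nx) - (nx - 1) / 2) * spacing,
        (np.arange(ny) - (ny - 1) / 2) * spacing,
        (np.arange(nz) - (nz - 1) / 2) * spacing,
        indexing="ij",
    )
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def make_channel(spec: ChannelSpec) -> tuple[Structure, ChannelLayout]:
    """Build the pseudo-atom tetramer realizing ``spec``.

    Chains are related by exact 4-fold symmetry about z. Pore rings realize
    R(z) to construction accuracy; domain blobs are symmetric lattices whose
    COM sits at the prescribed center (motif repositioning perturbs it
    slightly; analyses read the realized geometry, not the prescription).
    """
    if spec.n_chains != 4:
        raise ValueError("the synthetic channel is a tetramer (n_chains = 4)")
    if spec.atoms_per_ring % spec.n_chains:
        raise ValueError("atoms_per_ring must divide evenly among the chains")
    chain_ids = tuple("ABCD")
    table_c_vdw = spec.atom_radius
    mass = 12.011

    atoms_by_chain: dict[str, list[tuple[int, str, np.ndarray]]] = {c: [] for c in chain_ids}
    rings: list[dict] = []

    # Pore rings: chain quarters of each ring, aligned so symmetry is exact.
    per_chain = spec.atoms_per_ring // spec.n_chains
    z_lo, z_hi = spec.z_range
    n_rings = int(round((z_hi - z_lo) / spec.ring_spacing)) + 1
    zs = z_lo + spec.ring_spacing * np.arange(n_rings)
    circum_spacing = 2 * math.pi * (spec.pore_radius(float(zs[0])) + spec.atom_radius)
    if circum_spacing / spec.atoms_per_ring < 0.5 * spec.atom_radius:
        raise ValueError("infeasible ring spacing: atoms overlap too strongly")
    tm_res = {c: _TM_RES_START for c in chain_ids}
    ring_records: list[list[tuple[str, int]]] = []
    for z in zs:
        R0 = float(spec.pore_radius(float(z)))
        lateral = R0
        members: list[tuple[str, int]] = []
        for k in range(spec.atoms_per_ring):
            theta = 2 * math.pi * k / spec.atoms_per_ring
            chain = chain_ids[k // per_chain]
            pos = np.array([lateral * math.cos(theta), lateral * math.sin(theta), z])
            rid = tm_res[chain]
            tm_res[chain] += 1
            atoms_by_chain[chain].append((rid, "CA", pos))
            members.append((chain, rid))
        ring_records.append(members)
        rings.append({"z": float(z), "R0": R0, "members": members, "lateral0": lateral})

    # Domain blobs and hinges, chain-A template rotated 4-fold.
    offsets = _blob_offsets(spec.blob_shape, spec.blob_spacing)
    n_blob = offsets.shape[0]
    hinge_offsets = np.stack([np.array([0.0, 0.0, dz]) for dz in
                              (np.arange(5) - 2.0) * 2.0])
    motif_res: dict[str, set[int]] = {}
    for mid in spec.motif_surface + spec.motif_interface:
        dom, (lo, hi) = _MOTIF_RANGES[mid]
        motif_res.setdefault(dom, set()).update(range(lo, hi + 1))

    occluder_specs: list[tuple] = []  # (chain, center, along, normal) slabs

    for ci, chain in enumerate(chain_ids):
        rot = _rotz(90.0 * ci)
        for dom, (lo, hi) in _BLOB_RES.items():
            center = rot @ np.asarray(spec.domain_centers[dom], dtype=float)
            n_res_dom = hi - lo + 1
            if n_res_dom > n_blob:
                raise ValueError("blob lattice smaller than its residue range")
            out_dir = center.copy()
            out_dir[2] = 0.0
            out_dir /= max(np.linalg.norm(out_dir), 1e-9)
            placed = 0
            for rid in range(lo, hi + 1):
                if rid in motif_res.get(dom, set()):
                    continue
                atoms_by_chain[chain].append((rid, "CA", center + rot @ offsets[placed]))
                placed += 1
            # Motif residues: a line of atoms on the outward blob face
            # (surface) or on the inward, channel-facing face with a dense
            # occluder shell around it (interface) — the two faces are
            # ~13 Å apart, so the shell never shadows the surface motif.
            half = (np.array(spec.blob_shape) - 1) / 2 * spec.blob_spacing
            for mid in spec.motif_surface + spec.motif_interface:
                mdom, (mlo, mhi) = _MOTIF_RANGES[mid]
                if mdom != dom:
                    continue
                buried = mid in spec.motif_interface
                face_dir = -out_dir if buried else out_dir
                face = center + face_dir * (half[0] + 2.5)
                along = rot @ np.array([0.0, 1.0, 0.0])
                for j, rid in enumerate(range(mlo, mhi + 1)):
                    pos = face + along * (j - (mhi - mlo) / 2) * 3.4
                    atoms_by_chain[chain].append((rid, "CA", pos))
                if buried:
                    occluder_specs.append((chain, face, along, face_dir))
        for hinge, (lo, hi) in _HINGE_RES.items():
            center = rot @ np.asarray(spec.domain_centers[hinge], dtype=float)
            for j, rid in enumerate(range(lo, hi + 1)):
                atoms_by_chain[chain].append((rid, "CA", center + rot @ hinge_offsets[j]))

    # Occluder slabs burying interface motifs: a packed grid pressed against
    # the motif line (spacing 2.2 Å), so the motif sits at a tight
    # blob–occluder interface until the slab is moved away by a schedule.
    occ_res = {c: _OCCLUDER_RES_START for c in chain_ids}
    for chain, center, along, normal in occluder_specs:
        up = np.cross(normal, along)
        up /= np.linalg.norm(up)
        for a in (np.arange(9) - 4) * 2.2:
            for u in (np.arange(3) - 1) * 2.2:
                for nn in (2.2, 4.4):
                    p = center + a * along + u * up + nn * normal
                    atoms_by_chain[chain].append((occ_res[chain], "CA", p))
                    occ_res[chain] += 1

    atoms: list[AtomRecord] = []
    serial = 1
    for chain in chain_ids:
        for rid, name, pos in sorted(atoms_by_chain[chain], key=lambda t: t[0]):
            atoms.append(AtomRecord(
                serial=serial, name=name, element="C", res_name="GLY",
                res_id=rid, chain_id=chain, coords=tuple(pos),
                vdw_radius=table_c_vdw, mass=mass,
            ))
            serial += 1
    structure = Structure(atoms)

    # Ring member -> atom index resolution.
    atom_index = {
        (structure.chain_ids[i], int(structure.res_ids[i])): i
        for i in range(structure.n_atoms)
    }
    for ring in rings:
        ring["indices"] = np.array([atom_index[m] for m in ring["members"]])

    tm_hi = max(tm_res.values()) - 1
    domains = {
        "PAS": DomainDefinition.make("PAS", {c: [_BLOB_RES["PAS"]] for c in chain_ids}),
        "CNBD": DomainDefinition.make("CNBD", {c: [_BLOB_RES["CNBD"]] for c in chain_ids}),
        "hinge_PAS": DomainDefinition.make(
            "hinge_PAS", {c: [_HINGE_RES["hinge_PAS"]] for c in chain_ids}),
        "hinge_CNBD": DomainDefinition.make(
            "hinge_CNBD", {c: [_HINGE_RES["hinge_CNBD"]] for c in chain_ids}),
        "TMD": DomainDefinition.make(
            "TMD", {c: [(_TM_RES_START, tm_hi)] for c in chain_ids}),
    }
    if occluder_specs:
        domains["occluder"] = DomainDefinition.make(
            "occluder",
            {c: [(_OCCLUDER_RES_START, occ_res[c] - 1)] for c in chain_ids
             if occ_res[c] > _OCCLUDER_RES_START},
        )
    motifs = {
        mid: _MOTIF_RANGES[mid]
        for mid in spec.motif_surface + spec.motif_interface
    }
    layout = ChannelLayout(
        spec=spec, domains=domains, rings=rings, motifs=motifs, chain_ids=chain_ids
    )
    return structure, layout


def linear_schedule(total: float) -> Callable[[float], float]:
    """Schedule value = total · t_frac (t_frac ∈ [0, 1])."""
    return lambda tf: total * tf


def step_schedule(value: float, at: float = 0.5) -> Callable[[float], float]:
    """0 before fraction ``at``, ``value`` from there on."""
    return lambda tf: value if tf >= at else 0.0


@dataclass
class MotionSchedule:
    """Programmed motions applied frame by frame (t_frac = f/(n_frames−1)).

    * ``pore_radius``: R(z, t_frac) replacing the construction profile.
    * ``hinge_drift_deg``: domain name → Δθ(t_frac): signed change of the
      domain's COM angle at its hinge (applied as an exact rigid rotation of
      the domain blob about the hinge COM, per chain).
    * ``translations``: domain name → (vector, g(t_frac)): displacement
      vector · g, e.g. a step that slides an occluder off a motif.
    * ``noise_sigma``: isotropic Gaussian Å noise per atom per frame.
    """

    pore_radius: Callable[[float, float], float] | None = None
    hinge_drift_deg: Mapping[str, Callable[[float], float]] = field(default_factory=dict)
    translations: Mapping[str, tuple[Sequence[float], Callable[[float], float]]] = field(
        default_factory=dict
    )
    noise_sigma: float = 0.0
    seed: int = 0


_HINGE_OF = {"PAS": "hinge_PAS", "CNBD": "hinge_CNBD"}


def make_trajectory(
    structure: Structure,
    schedule: MotionSchedule,
    n_frames: int,
    layout: ChannelLayout | None = None,
    frame_interval_ns: float = 0.01,
) -> tuple[Trajectory, dict]:
    """Realize a motion schedule over a structure; returns (trajectory, manifest).

    Pore and hinge motions need the generator's ``layout``; pure-noise and
    translation-free schedules work on any structure. The manifest records
    every programmed ground truth (total drifts, schedule endpoints, noise,
    seed, initial per-chain domain angles).
    """
    from .geometry import center_of_mass, domain_angle

    rng = np.random.default_rng(schedule.seed)
    base = structure.coords
    frames = np.empty((n_frames, structure.n_atoms, 3))

    hinge_info: dict[str, list[dict]] = {}
    initial_angles: dict[str, dict[str, float]] = {}
    if schedule.hinge_drift_deg:
        if layout is None:
            raise ValueError("hinge drift needs the channel layout")
        for dom_name in schedule.hinge_drift_deg:
            hinge_name = _HINGE_OF[dom_name]
            dom = layout.domains[dom_name]
            hinge = layout.domains[hinge_name]
            tmd = layout.domains["TMD"]
            infos = []
            initial_angles[dom_name] = {}
            for chain in layout.chain_ids:
                d1 = DomainDefinition(dom_name, {chain: dom.ranges[chain]})
                h1 = DomainDefinition(hinge_name, {chain: hinge.ranges[chain]})
                t1 = DomainDefinition("TMD", {chain: tmd.ranges[chain]})
                di = d1.atom_indices(structure)
                hi = h1.atom_indices(structure)
                ti = t1.atom_indices(structure)
                m = structure.masses
                com_d = center_of_mass(base[di], m[di])
                com_h = center_of_mass(base[hi], m[hi])
                com_t = center_of_mass(base[ti], m[ti])
                v_d = com_d - com_h
                v_t = com_t - com_h
                axis = np.cross(v_d, v_t)
                axis /= np.linalg.norm(axis)
                infos.append({"idx": di, "hinge_com": com_h, "axis": axis})
                initial_angles[dom_name][chain] = domain_angle(
                    structure, base, d1, h1, t1
                )
            hinge_info[dom_name] = infos

    if schedule.pore_radius is not None and layout is None:
        raise ValueError("pore schedule needs the channel layout")

    trans_idx: dict[str, np.ndarray] = {}
    for name in schedule.translations:
        if layout is None or name not in layout.domains:
            raise ValueError(f"translation target {name!r} not in layout")
        trans_idx[name] = layout.domains[name].atom_indices(structure)

    for f in range(n_frames):
        tf = f / (n_frames - 1) if n_frames > 1 else 0.0
        coords = base.copy()
        if schedule.pore_radius is not None:
            for ring in layout.rings:
                R_t = schedule.pore_radius(ring["z"], tf)
                scale = R_t / ring["lateral0"]
                idx = ring["indices"]
                coords[idx, 0] *= scale
                coords[idx, 1] *= scale
        for dom_name, drift_fn in schedule.hinge_drift_deg.items():
            delta = drift_fn(tf)
            for info in hinge_info[dom_name]:
                # Rotating the domain COM about +axis closes the angle, so a
                # positive programmed drift rotates by -delta.
                Rm = rotation_about_axis(info["axis"], -delta)
                idx = info["idx"]
                coords[idx] = (coords[idx] - info["hinge_com"]) @ Rm.T + info["hinge_com"]
        for name, (vec, g) in schedule.translations.items():
            coords[trans_idx[name]] += np.asarray(vec, dtype=float) * g(tf)
        if schedule.noise_sigma > 0:
            coords += rng.normal(0.0, schedule.noise_sigma, coords.shape)
        frames[f] = coords

    manifest: dict = {
        "generator": "make_trajectory",
        "n_frames": n_frames,
        "noise_sigma": schedule.noise_sigma,
        "seed": schedule.seed,
        "hinge_drift_total_deg": {
            d: float(fn(1.0) - fn(0.0)) for d, fn in schedule.hinge_drift_deg.items()
        },
        "initial_angles_deg": {
            d: {c: float(a) for c, a in per.items()} for d, per in initial_angles.items()
        },
        "translations": {
            name: {"vector": list(map(float, vec)), "g0": float(g(0.0)), "g1": float(g(1.0))}
            for name, (vec, g) in schedule.translations.items()
        },
    }
    if schedule.pore_radius is not None:
        z_samples = [ring["z"] for ring in layout.rings[:: max(1, len(layout.rings) // 8)]]
        manifest["pore_schedule"] = {
            "z_samples": z_samples,
            "R_start": [float(schedule.pore_radius(z, 0.0)) for z in z_samples],
            "R_end": [float(schedule.pore_radius(z, 1.0)) for z in z_samples],
        }
    return Trajectory(structure, frames, frame_interval_ns=frame_interval_ns), manifest


def make_energy_series(
    mu_total: float,
    sigma_total: float,
    mu_dihedral: float,
    sigma_dihedral: float,
    n: int,
    seed: int = 0,
) -> tuple[EnergySeries, dict]:
    """Seeded Gaussian potential/dihedral energy draws with a manifest."""
    if n < 1 or sigma_total < 0 or sigma_dihedral < 0:
        raise ValueError("need n >= 1 and non-negative sigmas")
    rng = np.random.default_rng(seed)
    series = EnergySeries(
        v_total=mu_total + sigma_total * rng.standard_normal(n),
        v_dihedral=mu_dihedral + sigma_dihedral * rng.standard_normal(n),
    )
    manifest = {
        "generator": "make_energy_series",
        "mu_total": mu_total, "sigma_total": sigma_total,
        "mu_dihedral": mu_dihedral, "sigma_dihedral": sigma_dihedral,
        "n": n, "seed": seed,
    }
    return series, manifest


def make_basin_trajectory(
    n_basins: int,
    frames_per_basin: int,
    *,
    n_atoms: int = 40,
    separation: float = 6.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
    shuffle: bool = True,
) -> tuple[Trajectory, dict]:
    """Frames drawn from ``n_basins`` distinct conformational basins.

    Basin centers are a common random backbone-like scaffold plus per-basin
    displacements of RMS magnitude ``separation``; frames add isotropic
    noise of ``noise_sigma``. The manifest carries the true frame→basin map
    — the ground truth a cluster-count scan must recover.
    """
    rng = np.random.default_rng(seed)
    scaffold = rng.uniform(-10, 10, (n_atoms, 3))
    centers = [
        scaffold + rng.normal(0.0, separation / math.sqrt(3), (n_atoms, 3))
        for _ in range(n_basins)
    ]
    labels = np.repeat(np.arange(n_basins), frames_per_basin)
    if shuffle:
        rng.shuffle(labels)
    frames = np.stack([
        centers[b] + rng.normal(0.0, noise_sigma, (n_atoms, 3)) for b in labels
    ])
    from .structure import element_table

    vdw, mass = element_table()["C"]
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", res_name="GLY",
                   res_id=i + 1, chain_id="A", coords=tuple(scaffold[i]),
                   vdw_radius=vdw, mass=mass)
        for i in range(n_atoms)
    ]
    traj = Trajectory(Structure(atoms), frames)
    manifest = {
        "generator": "make_basin_trajectory",
        "n_basins": n_basins,
        "frames_per_basin": frames_per_basin,
        "true_labels": labels.tolist(),
        "separation": separation,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return traj, manifest
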
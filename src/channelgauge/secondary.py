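"""Hydrogen-bond-based secondary structure and alpha-helix propensity.

A simplified 3-state (H/E/C) assignment built on the Kabsch–Sander
electrostatic hydrogen-bond energy: backbone amide hydrogens are
reconstructed geometrically, a bond exists when the dipole–dipole energy
falls below −0.5 kcal/mol, residue i is helical when the two consecutive
i→i+4 turns closing on it both exist, and strand requires a paired bridge
partner. Helix propensity is the per-residue fraction of frames assigned H,
which localizes helix loss events (e.g. the unfolding of a linker helix in
a mutant condition) as a per-residue propensity delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import DomainDefinition, Structure, Trajectory

__all__ = [
    "SSAssignment",
    "HelixPropensity",
    "reconstruct_amide_H",
    "hbond_energy",
    "assign_ss",
    "helix_propensity",
    "KS_COUPLING",
    "HBOND_CUTOFF",
]

#: Kabsch–Sander coupling constant: q1·q2·f = 0.42 · 0.20 · 332 kcal·Å/mol.
KS_COUPLING = 0.084 * 332.0
#: H-bond energy threshold (kcal/mol); more negative = bonded.
HBOND_CUTOFF = -0.5
#: Clamp value for overlapping atoms (r < 0.5 Å), as in DSSP.
E_CLAMP = -9.9


@dataclass
class SSAssignment:
    """Per-frame, per-residue codes in {H, E, C}, keyed by chain."""

    chains: tuple[str, ...]
    res_ids: dict[str, np.ndarray]
    codes: dict[str, np.ndarray]  # chain -> (n_frames, n_res) of 'H'/'E'/'C'

    def frame_string(self, chain: str, frame: int) -> str:
        return "".join(self.codes[chain][frame])


@dataclass
class HelixPropensity:
    """Fraction of frames helical per residue, plus the domain mean."""

    chains: tuple[str, ...]
    res_ids: dict[str, np.ndarray]
    fractions: dict[str, np.ndarray]  # chain -> per-residue H fraction
    domain_mean: float
    condition: str = ""
    delta_vs_reference: float | None = None
    per_residue_delta: dict[str, np.ndarray] | None = None


def _amide_h(n: np.ndarray, prev_c: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Amide H: 1.01 Å from N, anti to the C(prev)–N–Cα bisector (peptide plane)."""
    u1 = prev_c - n
    u1 /= np.linalg.norm(u1)
    u2 = ca - n
    u2 /= np.linalg.norm(u2)
    h_dir = -(u1 + u2)
    h_dir /= np.linalg.norm(h_dir)
    return n + 1.01 * h_dir


def reconstruct_amide_H(structure: Structure) -> dict[tuple[str, int], np.ndarray]:
    """Backbone amide H positions keyed by (chain, res_id).

    Prolines and chain N-terminal residues get no H; residues missing any of
    N, Cα or the previous C are skipped.
    """
    coords = _chain_residues(structure, structure.coords)
    out: dict[tuple[str, int], np.ndarray] = {}
    for chain, residues in coords.items():
        for i, res in enumerate(residues):
            if i == 0 or res["res_name"] == "PRO":
                continue
            prev = residues[i - 1]
            if "N" not in res or "CA" not in res or "C" not in prev:
                continue
            out[(chain, res["res_id"])] = _amide_h(res["N"], prev["C"], res["CA"])
    return out


def hbond_energy(
    donor_n: np.ndarray,
    donor_h: np.ndarray | None,
    acceptor_c: np.ndarray,
    acceptor_o: np.ndarray,
) -> float:
    """Kabsch–Sander electrostatic H-bond energy (kcal/mol).

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN). A donor without an
    amide H (proline, chain start) cannot bond and returns 0. Overlapping
    atoms (any r < 0.5 Å) clamp to −9.9.
    """
    if donor_h is None:
        return 0.0
    r_on = np.linalg.norm(acceptor_o - donor_n)
    r_ch = np.linalg.norm(acceptor_c - donor_h)
    r_oh = np.linalg.norm(acceptor_o - donor_h)
    r_cn = np.linalg.norm(acceptor_c - donor_n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return E_CLAMP
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _chain_residues(structure: Structure, coords: np.ndarray) -> dict[str, list[dict]]:
    """Per-chain ordered residue dicts: backbone atom name -> coords."""
    out: dict[str, list[dict]] = {}
    index: dict[tuple[str, int], dict] = {}
    for i in range(structure.n_atoms):
        chain = structure.chain_ids[i]
        rid = int(structure.res_ids[i])
        key = (chain, rid)
        if key not in index:
            res = {"res_id": rid, "res_name": structure.res_names[i]}
            index[key] = res
            out.setdefault(chain, []).append(res)
        name = structure.names[i]
        if name in ("N", "CA", "C", "O"):
            index[key][name] = coords[i]
    return out


def _hbond_set(residues: list[dict]) -> set[tuple[int, int]]:
    """Bonds as (acceptor chain-position, donor chain-position)."""
    n = len(residues)
    h_pos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        res, prev = residues[i], residues[i - 1]
        if res["res_name"] == "PRO":
            continue
        if "N" in res and "CA" in res and "C" in prev:
            h_pos[i] = _amide_h(res["N"], prev["C"], res["CA"])
    bonds: set[tuple[int, int]] = set()
    # CA-distance prefilter keeps the pair loop cheap on big chains.
    cas = np.array([r.get("CA", np.full(3, np.nan)) for r in residues])
    for j in range(n):  # acceptor
        if "C" not in residues[j] or "O" not in residues[j]:
            continue
        for i in range(n):  # donor
            if abs(i - j) < 2 or h_pos[i] is None or "N" not in residues[i]:
                continue
            if np.linalg.norm(cas[i] - cas[j]) > 9.0:
                continue
            e = hbond_energy(residues[i]["N"], h_pos[i],
                             residues[j]["C"], residues[j]["O"])
            if e < HBOND_CUTOFF:
                bonds.add((j, i))
    return bonds


def _assign_chain(residues: list[dict]) -> np.ndarray:
    n = len(residues)
    bonds = _hbond_set(residues)

    def hb(a: int, d: int) -> bool:
        return 0 <= a < n and 0 <= d < n and (a, d) in bonds

    turn = [hb(i, i + 4) for i in range(n)]
    codes = np.full(n, "C", dtype="<U1")
    for i in range(n):
        if i >= 1 and turn[i - 1] and i < n and turn[i]:
            codes[i] = "H"
    # Simplified bridge ladder: parallel or antiparallel paired H-bond pattern.
    for i in range(n):
        if codes[i] == "H":
            continue
        for j in range(n):
            if abs(i - j) < 3:
                continue
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if parallel or anti:
                codes[i] = "E"
                break
    return codes


def assign_ss(structure: Structure, coords: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Assign H/E/C per residue for one conformation; keyed by chain.

    The assignment depends only on interatomic distances, so it is invariant
    under global rigid motion of the frame.
    """
    if coords is None:
        coords = structure.coords
    chains = _chain_residues(structure, np.asarray(coords, dtype=float))
    return {chain: _assign_chain(residues) for chain, residues in chains.items()}


def assign_ss_trajectory(traj: Trajectory) -> SSAssignment:
    """Per-frame assignment over a trajectory."""
    per_frame = [assign_ss(traj.topology, frame) for frame in traj.frames]
    chains = tuple(sorted(per_frame[0]))
    res_ids = {
        c: np.array([r["res_id"] for r in _chain_residues(traj.topology, traj.frames[0])[c]])
        for c in chains
    }
    codes = {c: np.stack([fr[c] for fr in per_frame]) for c in chains}
    return SSAssignment(chains=chains, res_ids=res_ids, codes=codes)


def helix_propensity(
    traj: Trajectory,
    domain: DomainDefinition,
    *,
    condition: str = "",
    reference: HelixPropensity | None = None,
) -> HelixPropensity:
    """Alpha-helix propensity per residue and averaged over a domain.

    Needs at least 10 frames for the fractions to be meaningful. When a
    reference condition's result is supplied, the domain-mean delta and the
    per-residue delta (this − reference) are attached, which is how a
    localized helix loss shows up as a contiguous negative segment.
    """
    if traj.n_frames < 10:
        raise ValueError("helix propensity needs >= 10 frames")
    ss = assign_ss_trajectory(traj)
    for chain in domain.ranges:
        if chain not in ss.chains:
            raise ValueError(f"domain chain {chain!r} not present in trajectory")
    fractions: dict[str, np.ndarray] = {}
    res_ids: dict[str, np.ndarray] = {}
    member_vals: list[np.ndarray] = []
    for chain, ranges in domain.ranges.items():
        rid = ss.res_ids[chain]
        frac = (ss.codes[chain] == "H").mean(axis=0)
        mask = np.zeros(rid.size, dtype=bool)
        for lo, hi in ranges:
            mask |= (rid >= lo) & (rid <= hi)
        fractions[chain] = frac[mask]
        res_ids[chain] = rid[mask]
        member_vals.append(frac[mask])
    all_vals = np.concatenate(member_vals)
    if all_vals.size == 0:
        raise ValueError(f"domain {domain.name} selects no residues")
    mean = float(all_vals.mean())
    delta = None
    per_res_delta = None
    if reference is not None:
        delta = mean - reference.domain_mean
        per_res_delta = {}
        for chain in fractions:
            if chain in reference.fractions and np.array_equal(
                res_ids[chain], reference.res_ids.get(chain)
            ):
                per_res_delta[chain] = fractions[chain] - reference.fractions[chain]
    return HelixPropensity(
        chains=tuple(sorted(fractions)),
        res_ids=res_ids,
        fractions=fractions,
        domain_mean=mean,
        condition=condition,
        delta_vs_reference=delta,
        per_residue_delta=per_res_delta,
    )
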
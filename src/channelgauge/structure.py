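"""Structures, trajectories, atom selections and domain definitions.

This module is the shared substrate for every analysis stage: a
:class:`Structure` holds per-atom records (coordinates in Å, van der Waals
radii, masses), a :class:`Trajectory` stacks frames over one topology, and
:class:`SelectionSpec` / :class:`DomainDefinition` resolve deterministic,
sorted atom index sets for the downstream geometry.

File formats: PDB (``ATOM``/``HETATM``; ``MODEL``/``ENDMDL`` delimits frames
in the multi-model trajectory dialect) and CHARMM/X-PLOR 32-bit DCD (read and
written through MDAnalysis' low-level DCD codec).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "DomainDefinition",
    "StructureError",
    "SelectionWarning",
    "element_table",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "parse_glycan_composition",
    "BACKBONE_NAMES",
]

#: Backbone heavy-atom names used when a selection asks for backbone only.
BACKBONE_NAMES = ("CA", "C", "N", "O")


class StructureError(ValueError):
    """Raised for malformed structure files or invariant violations."""


class SelectionWarning(UserWarning):
    """Emitted when a selection resolves to zero atoms."""


_ELEMENT_TABLE: dict[str, tuple[float, float]] | None = None


def element_table() -> dict[str, tuple[float, float]]:
    """Return the packaged element table as ``{element: (vdw_radius, mass)}``.

    Radii are the Bondi set (Å); masses in amu. The table ships as CSV so a
    deployment can swap it without touching code.
    """
    global _ELEMENT_TABLE
    if _ELEMENT_TABLE is None:
        table = {}
        with resources.files("channelgauge.data").joinpath("elements.csv").open() as fh:
            for row in csv.DictReader(fh):
                table[row["element"]] = (float(row["vdw_radius"]), float(row["mass"]))
        _ELEMENT_TABLE = table
    return _ELEMENT_TABLE


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates (Å), vdW radius (Å), mass (amu)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain_id: str
    coords: tuple[float, float, float]
    vdw_radius: float
    mass: float

    def __post_init__(self) -> None:
        if not (self.vdw_radius > 0 and self.mass > 0):
            raise StructureError(
                f"atom {self.serial} {self.name}: vdw_radius and mass must be positive"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} {self.name}: non-finite coordinates")


class Structure:
    """An ordered collection of atoms with column-wise numpy views.

    Atom identity ``(chain_id, res_id, name)`` must be unique, and residues
    within a chain appear in non-decreasing ``res_id`` order.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self._atoms = list(atoms)
        n = len(self._atoms)
        self.coords = np.array([a.coords for a in self._atoms], dtype=float).reshape(n, 3)
        self.names = np.array([a.name for a in self._atoms])
        self.elements = np.array([a.element for a in self._atoms])
        self.res_names = np.array([a.res_name for a in self._atoms])
        self.res_ids = np.array([a.res_id for a in self._atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in self._atoms])
        self.serials = np.array([a.serial for a in self._atoms], dtype=int)
        self.vdw_radii = np.array([a.vdw_radius for a in self._atoms], dtype=float)
        self.masses = np.array([a.mass for a in self._atoms], dtype=float)
        self._check_invariants()

    def _check_invariants(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        last_res: dict[str, int] = {}
        for a in self._atoms:
            key = (a.chain_id, a.res_id, a.name)
            if key in seen:
                raise StructureError(
                    f"duplicate atom (chain {a.chain_id}, res {a.res_id}, name {a.name})"
                )
            seen.add(key)
            prev = last_res.get(a.chain_id)
            if prev is not None and a.res_id < prev:
                raise StructureError(
                    f"chain {a.chain_id}: residue order not monotone at res {a.res_id}"
                )
            last_res[a.chain_id] = a.res_id

    @property
    def atoms(self) -> list[AtomRecord]:
        return self._atoms

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    @property
    def chains(self) -> dict[str, list[int]]:
        """Map chain_id → ordered unique residue ids."""
        out: dict[str, list[int]] = {}
        for a in self._atoms:
            lst = out.setdefault(a.chain_id, [])
            if not lst or lst[-1] != a.res_id:
                lst.append(a.res_id)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (n_atoms × 3, Å)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        atoms = [replace(a, coords=tuple(c)) for a, c in zip(self._atoms, coords)]
        return Structure(atoms)

    def subset(self, indices: Sequence[int]) -> "Structure":
        return Structure([self._atoms[i] for i in indices])


@dataclass
class Trajectory:
    """Frames (n_frames × n_atoms × 3, Å) over one topology.

    ``frame_interval_ns`` is the snapshot spacing; the production default of
    0.01 ns matches the capture interval the analyses assume.
    """

    topology: Structure
    frames: np.ndarray
    frame_interval_ns: float = 0.01

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise StructureError(
                f"frame array shape {self.frames.shape} inconsistent with "
                f"{self.topology.n_atoms} topology atoms"
            )
        if not self.frame_interval_ns > 0:
            raise StructureError("frame_interval_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection; criteria combine with AND.

    ``backbone_only`` restricts to the Cα/C/N/O backbone names. Resolution is
    deterministic: the result is always a sorted index array.
    """

    chains: frozenset[str] | None = None
    res_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    backbone_only: bool = False

    @staticmethod
    def make(
        chains: Iterable[str] | None = None,
        res_range: Sequence[int] | None = None,
        atom_names: Iterable[str] | None = None,
        backbone_only: bool = False,
    ) -> "SelectionSpec":
        return SelectionSpec(
            chains=frozenset(chains) if chains is not None else None,
            res_range=tuple(res_range) if res_range is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            backbone_only=backbone_only,
        )


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain as per-chain 1-based inclusive residue ranges.

    ``ranges`` maps chain_id → list of (lo, hi). Canonical names follow the
    channel architecture (PAS, TMD, CNBD, the two hinge linkers, S6), but any
    custom name is accepted.
    """

    name: str
    ranges: Mapping[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise StructureError(f"domain {self.name}: no residue ranges")
        for chain, rs in self.ranges.items():
            for lo, hi in rs:
                if hi < lo:
                    raise StructureError(
                        f"domain {self.name}: empty range {lo}-{hi} on chain {chain}"
                    )

    @staticmethod
    def make(name: str, ranges: Mapping[str, Sequence[Sequence[int]]]) -> "DomainDefinition":
        return DomainDefinition(
            name,
            {c: tuple(tuple(r) for r in rs) for c, rs in ranges.items()},
        )

    def atom_indices(self, structure: Structure) -> np.ndarray:
        mask = np.zeros(structure.n_atoms, dtype=bool)
        for chain, rs in self.ranges.items():
            cmask = structure.chain_ids == chain
            for lo, hi in rs:
                mask |= cmask & (structure.res_ids >= lo) & (structure.res_ids <= hi)
        return np.flatnonzero(mask)

    def overlaps(self, other: "DomainDefinition") -> bool:
        for chain in set(self.ranges) & set(other.ranges):
            for lo1, hi1 in self.ranges[chain]:
                for lo2, hi2 in other.ranges[chain]:
                    if lo1 <= hi2 and lo2 <= hi1:
                        return True
        return False


# ---------------------------------------------------------------------------
# Selection resolution

def resolve_selection(structure: Structure, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to a sorted atom index array.

    An empty result is legal but flagged with :class:`SelectionWarning`.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    if spec.chains is not None:
        mask &= np.isin(structure.chain_ids, sorted(spec.chains))
    if spec.res_range is not None:
        lo, hi = spec.res_range
        mask &= (structure.res_ids >= lo) & (structure.res_ids <= hi)
    if spec.atom_names is not None:
        mask &= np.isin(structure.names, sorted(spec.atom_names))
    if spec.backbone_only:
        mask &= np.isin(structure.names, BACKBONE_NAMES)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {spec} matched no atoms", SelectionWarning, stacklevel=2)
    return idx


# ---------------------------------------------------------------------------
# PDB I/O

def _guess_element(atom_name: str, res_name: str) -> str:
    name = atom_name.strip()
    table = element_table()
    if len(name) >= 2 and name[:2].capitalize() in table and not name[0].isdigit():
        two = name[:2].capitalize()
        # Avoid mis-reading e.g. "CA" (calcium) in a protein residue context.
        if two in ("Ca", "Cd", "Na") and res_name.strip() not in (two.upper(),):
            pass
        else:
            return two
    stripped = name.lstrip("0123456789")
    if stripped and stripped[0].upper() in table:
        return stripped[0].upper()
    raise StructureError(f"cannot infer element for atom name {atom_name!r}")


def _parse_pdb_atom(line: str, lineno: int) -> tuple[AtomRecord, str, float]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_str = line[54:60].strip()
        occupancy = float(occ_str) if occ_str else 1.0
        elem_field = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise StructureError(f"malformed PDB record at line {lineno}: {line.rstrip()!r}") from exc

    table = element_table()
    if elem_field:
        element = elem_field.capitalize()
        if element not in table:
            raise StructureError(
                f"unknown element {element!r} for atom serial {serial} ({name}) "
                f"at line {lineno}"
            )
    else:
        element = _guess_element(name, res_name)
        if element not in table:
            raise StructureError(
                f"unknown element {element!r} for atom serial {serial} ({name})"
            )
    vdw, mass = table[element]
    rec = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        res_id=res_id,
        chain_id=chain_id,
        coords=(x, y, z),
        vdw_radius=vdw,
        mass=mass,
    )
    return rec, altloc, occupancy


def _collapse_altlocs(
    records: list[tuple[AtomRecord, str, float]]
) -> list[AtomRecord]:
    """Keep the highest-occupancy altloc per (chain, res, name); ties → first."""
    best: dict[tuple[str, int, str], tuple[float, int, AtomRecord]] = {}
    order: list[tuple[str, int, str]] = []
    for i, (rec, altloc, occ) in enumerate(records):
        key = (rec.chain_id, rec.res_id, rec.name)
        if key not in best:
            best[key] = (occ, i, rec)
            order.append(key)
        else:
            if not altloc and not records[best[key][1]][1]:
                # Two records without altloc markers: genuine duplicate.
                raise StructureError(
                    f"duplicate atom (chain {rec.chain_id}, res {rec.res_id}, "
                    f"name {rec.name}) without altloc markers"
                )
            if occ > best[key][0]:
                best[key] = (occ, i, rec)
    return [best[k][2] for k in order]


def read_structure(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only ``ATOM``/``HETATM`` records are interpreted; altlocs collapse to the
    highest-occupancy conformer; vdW radii and masses come from the packaged
    element table. For multi-model files, the first model defines the
    structure (use :func:`read_trajectory` for the frame stack).
    """
    path = Path(path)
    records: list[tuple[AtomRecord, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag in ("ATOM", "HETATM"):
                records.append(_parse_pdb_atom(line, lineno))
            elif tag == "ENDMDL":
                break
    if not records:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    return Structure(_collapse_altlocs(records))


def _format_pdb_atom(a: AtomRecord, coords: np.ndarray) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial % 100000:5d} {name}{'':1s}{a.res_name:<3s} "
        f"{a.chain_id:1s}{a.res_id % 10000:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}\n"
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        for a, c in zip(structure.atoms, structure.coords):
            fh.write(_format_pdb_atom(a, c))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory I/O

def read_trajectory(
    path: str | Path,
    topology: Structure,
    frame_interval_ns: float = 0.01,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a DCD file.

    The frame atom count must match the topology; a mismatch (including a
    truncated final model) raises with both counts.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        frames = _read_dcd(path, topology.n_atoms)
    else:
        frames = _read_multimodel_pdb(path, topology.n_atoms)
    return Trajectory(topology, frames, frame_interval_ns=frame_interval_ns)


def _read_multimodel_pdb(path: Path, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag == "MODEL":
                in_model = True
                current = []
            elif tag in ("ATOM", "HETATM"):
                rec, _, _ = _parse_pdb_atom(line, lineno)
                current.append(rec.coords)
                if not in_model and len(frames) == 0:
                    in_model = True  # single-model file without MODEL cards
            elif tag == "ENDMDL":
                if len(current) != n_atoms:
                    raise StructureError(
                        f"{path}: model ending at line {lineno} has {len(current)} "
                        f"atoms, topology has {n_atoms}"
                    )
                frames.append(np.array(current))
                current = []
                in_model = False
    if current:
        if len(current) != n_atoms:
            raise StructureError(
                f"{path}: truncated final model has {len(current)} atoms, "
                f"topology has {n_atoms}"
            )
        frames.append(np.array(current))
    if not frames:
        raise StructureError(f"{path}: no frames found")
    return np.stack(frames)


def _read_dcd(path: Path, n_atoms: int) -> np.ndarray:
    from MDAnalysis.lib.formats.libdcd import DCDFile

    with DCDFile(str(path)) as dcd:
        if dcd.header["natoms"] != n_atoms:
            raise StructureError(
                f"{path}: DCD has {dcd.header['natoms']} atoms, topology has {n_atoms}"
            )
        frames = np.stack([frame.xyz.astype(float) for frame in dcd])
    return frames


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (``.pdb``) or 32-bit DCD (``.dcd``)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        from MDAnalysis.lib.formats.libdcd import DCDFile

        with DCDFile(str(path), "w") as dcd:
            dcd.write_header(
                remarks="channelgauge trajectory",
                natoms=traj.topology.n_atoms,
                nsavc=1,
                delta=float(traj.frame_interval_ns),
                is_periodic=0,
                istart=0,
            )
            for frame in traj.frames:
                dcd.write(np.ascontiguousarray(frame, dtype=np.float32))
    else:
        with open(path, "w") as fh:
            for i, frame in enumerate(traj.frames, start=1):
                fh.write(f"MODEL     {i:4d}\n")
                for a, c in zip(traj.topology.atoms, frame):
                    fh.write(_format_pdb_atom(a, c))
                fh.write("ENDMDL\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# Glycan composition parsing

#: Monosaccharide tokens accepted in condensed composition strings, longest
#: match first so that GlcNAc is not read as Glc + NAc.
_MONOSACCHARIDES = (
    "GlcNAc",
    "GalNAc",
    "Neu5Ac",
    "Neu5Gc",
    "GlcA",
    "IdoA",
    "Glc",
    "Gal",
    "Man",
    "Fuc",
    "Xyl",
    "Rib",
    "Ara",
)
_GLYCAN_RE = re.compile(
    "(" + "|".join(_MONOSACCHARIDES) + r")(\d*)"
)


def parse_glycan_composition(composition: str) -> tuple[dict[str, int], int]:
    """Parse a condensed glycan composition like ``"Glc3Man9GlcNAc2"``.

    Returns ``(counts, total)`` where an omitted count means 1. The canonical
    ER core N-glycan Glc3Man9GlcNAc2 parses to 14 residues: three glucoses,
    nine mannoses and two N-acetylglucosamines.
    """
    if not composition:
        raise StructureError("empty glycan composition string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(composition):
        m = _GLYCAN_RE.match(composition, pos)
        if m is None:
            raise StructureError(
                f"unparseable glycan token at {composition[pos:]!r} in {composition!r}"
            )
        token, num = m.group(1), m.group(2)
        counts[token] = counts.get(token, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts, sum(counts.values())
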
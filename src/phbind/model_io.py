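"""Neutral in-memory topology/trajectory model plus readers and writers.

The containers are deliberately format-agnostic: a :class:`Topology` is a
columnar record of particle metadata (numpy-backed), a :class:`Frame` is a
time-stamped coordinate block in an orthorhombic periodic box, and a
:class:`Trajectory` pairs one topology with an ordered frame list.

Supported formats
-----------------
* GRO (read): hand-parsed fixed-width records so malformed lines can be
  reported with their line number.
* PDB (read): via MDAnalysis; coordinates converted from A to nm.
* XTC (read/write): via MDAnalysis; nm on disk, ~1e-3 nm quantisation.
* Columnar TSV (read/write): this package's plain-text trajectory dialect,
  one ``time x y z`` row per particle per frame block, bit-exact round trip.
* TSV tables (write): all analysis outputs.

Units: coordinates and box lengths in nm, times in ps, masses in Da.
Only orthorhombic boxes are accepted; triclinic inputs raise
:class:`StructureError`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "StructureError",
    "RoleMap",
    "load_role_map",
    "Topology",
    "Frame",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "write_table",
]

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06,
}
#: Mass assigned to coarse-grained beads whose element cannot be guessed.
CG_BEAD_MASS = 72.0


class ParseError(ValueError):
    """A file record could not be parsed; the message names the line."""


class StructureError(ValueError):
    """The parsed content is internally inconsistent (counts, box, ...)."""


@dataclass(frozen=True)
class RoleMap:
    """Residue-name -> role map plus phosphate/backbone naming rules."""

    residue_roles: dict
    pip_phosphate_names: frozenset
    backbone_names: frozenset

    def role_of(self, residue_name: str) -> str:
        name = residue_name.strip().upper()
        if name in self.residue_roles:
            return self.residue_roles[name]
        if name in PROTEIN_RESIDUES:
            return "protein"
        logger.warning("unknown residue %r assigned role 'other'", residue_name)
        return "other"

    def is_pip_phosphate(self, particle_name: str) -> bool:
        name = particle_name.strip().upper()
        return name in self.pip_phosphate_names or name.startswith("P")

    def is_backbone(self, particle_name: str) -> bool:
        return particle_name.strip().upper() in self.backbone_names


def load_role_map(path: str | Path | None = None) -> RoleMap:
    """Load the residue->role map; the packaged default when ``path`` is None."""
    if path is None:
        text = resources.files("phbind.data").joinpath("residue_roles.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return RoleMap(
        residue_roles={k.upper(): v for k, v in raw["roles"].items()},
        pip_phosphate_names=frozenset(n.upper() for n in raw["pip_phosphate_names"]),
        backbone_names=frozenset(n.upper() for n in raw["backbone_names"]),
    )


def _valid_role(role: str) -> bool:
    return role in ("protein", "solvent", "other") or role.startswith("lipid:")


@dataclass
class Topology:
    """Columnar particle metadata.

    ``molecule_ids`` group particles into molecules: each lipid or solvent
    residue is one molecule; all protein particles of a chain share one id.
    """

    ids: np.ndarray
    names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    molecule_ids: np.ndarray
    roles: np.ndarray
    masses: np.ndarray
    is_phosphate: np.ndarray
    is_backbone: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.is_phosphate = np.asarray(self.is_phosphate, dtype=bool)
        self.is_backbone = np.asarray(self.is_backbone, dtype=bool)
        for name in ("names", "residue_names", "roles"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        for name in ("residue_ids", "molecule_ids"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if not np.array_equal(self.ids, np.arange(n)):
            raise StructureError("particle ids must be dense 0..N-1")
        if np.any(self.masses <= 0):
            raise StructureError("particle masses must be positive")
        bad = [r for r in set(self.roles.tolist()) if not _valid_role(r)]
        if bad:
            raise StructureError(f"invalid roles: {bad}")
        for role in ("lipid:PIP2", "lipid:PIP3"):
            for mol in np.unique(self.molecule_ids[self.roles == role]):
                sel = self.molecule_ids == mol
                if not np.any(self.is_phosphate[sel]):
                    raise StructureError(
                        f"{role} molecule {mol} has no phosphate particle"
                    )

    @property
    def n_particles(self) -> int:
        return len(self.ids)

    def role_mask(self, role: str) -> np.ndarray:
        return self.roles == role

    def lipid_mask(self) -> np.ndarray:
        return np.array([r.startswith("lipid:") for r in self.roles], dtype=bool)

    def protein_mask(self) -> np.ndarray:
        return self.role_mask("protein")

    def phosphate_indices(self, role: str) -> np.ndarray:
        """Indices of phosphate particles of the given lipid role."""
        return np.flatnonzero((self.roles == role) & self.is_phosphate)

    def molecules_of_role(self, role: str) -> dict:
        """Map molecule id -> particle index array, for one role."""
        out: dict[int, list] = {}
        for i in np.flatnonzero(self.roles == role):
            out.setdefault(int(self.molecule_ids[i]), []).append(i)
        return {m: np.asarray(ix, dtype=int) for m, ix in out.items()}


@dataclass
class Frame:
    """One coordinate snapshot: time (ps), orthorhombic box (nm), N x 3 nm."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be an N x 3 array")
        if np.any(self.box <= 0):
            raise StructureError("box edge lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")


@dataclass
class Trajectory:
    topology: Topology
    frames: list = field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_particles
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise StructureError(
                    f"frame {i}: {fr.coords.shape[0]} coordinates for "
                    f"{n} topology particles"
                )
        times = [fr.time for fr in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise StructureError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])


# ---------------------------------------------------------------------------
# structure readers


def _assign_molecule_ids(residue_ids: np.ndarray, roles: Sequence[str]) -> np.ndarray:
    """One molecule per residue, except consecutive protein residues fuse."""
    mol_ids = np.empty(len(residue_ids), dtype=int)
    current = -1
    prev_res = None
    prev_protein = False
    for i, (res, role) in enumerate(zip(residue_ids, roles)):
        is_protein = role == "protein"
        if res != prev_res and not (is_protein and prev_protein):
            current += 1
        mol_ids[i] = current
        prev_res, prev_protein = res, is_protein
    return mol_ids


def _guess_mass(name: str) -> float:
    token = name.strip()
    for ch in token:
        if ch.isalpha():
            return _ELEMENT_MASSES.get(ch.upper(), CG_BEAD_MASS)
    return CG_BEAD_MASS


def _build_topology(
    names: list, residue_ids: list, residue_names: list, role_map: RoleMap
) -> Topology:
    roles = [role_map.role_of(rn) for rn in residue_names]
    mol_ids = _assign_molecule_ids(np.asarray(residue_ids), roles)
    is_phos = [
        role in ("lipid:PIP2", "lipid:PIP3") and role_map.is_pip_phosphate(nm)
        for nm, role in zip(names, roles)
    ]
    is_bb = [
        role == "protein" and role_map.is_backbone(nm) for nm, role in zip(names, roles)
    ]
    masses = [_guess_mass(nm) for nm in names]
    return Topology(
        ids=np.arange(len(names)),
        names=names,
        residue_ids=residue_ids,
        residue_names=residue_names,
        molecule_ids=mol_ids,
        roles=roles,
        masses=masses,
        is_phosphate=is_phos,
        is_backbone=is_bb,
    )


def _read_gro(path: Path, role_map: RoleMap):
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: not a GRO file (fewer than 3 lines)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}:2: cannot parse atom count: {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise StructureError(
            f"{path}: header declares {n_atoms} atoms but file has "
            f"{len(lines) - 3} atom lines"
        )
    names, resids, resnames, coords = [], [], [], []
    for k in range(n_atoms):
        lineno = k + 3
        ln = lines[lineno - 1]
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            coords.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed GRO atom record") from exc
    box_line = lines[n_atoms + 2].split()
    try:
        box_vals = [float(v) for v in box_line]
    except ValueError as exc:
        raise ParseError(f"{path}:{n_atoms + 3}: malformed box line") from exc
    if len(box_vals) not in (3, 9):
        raise ParseError(f"{path}:{n_atoms + 3}: box line must have 3 or 9 values")
    if len(box_vals) == 9 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise StructureError(f"{path}: triclinic box not supported")
    topo = _build_topology(names, resids, resnames, role_map)
    frame = Frame(time=0.0, box=box_vals[:3], coords=np.asarray(coords))
    return topo, frame


def _read_pdb(path: Path, role_map: RoleMap, box=None):
    import warnings

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: PDB parse failed: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise ParseError(f"{path}: PDB contains no atoms")
    if box is None:
        dims = u.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise StructureError(
                f"{path}: no CRYST1 box; pass box=(lx, ly, lz) in nm explicitly"
            )
        if np.any(np.abs(dims[3:] - 90.0) > 1e-3):
            raise StructureError(f"{path}: triclinic box not supported")
        box = dims[:3] / 10.0
    topo = _build_topology(
        [a.name for a in u.atoms],
        [int(a.resid) for a in u.atoms],
        [a.resname for a in u.atoms],
        role_map,
    )
    frame = Frame(time=0.0, box=box, coords=u.atoms.positions / 10.0)
    return topo, frame


def read_structure(path, fmt: str | None = None, role_map: RoleMap | None = None, box=None):
    """Read a structure file, returning ``(Topology, Frame)``.

    ``fmt`` is ``"GRO"`` or ``"PDB"``; inferred from the suffix when None.
    Roles are assigned from residue names via ``role_map`` (packaged
    default when None); unknown residues become role ``other`` with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper()
    fmt = fmt.upper()
    role_map = role_map or load_role_map()
    if fmt == "GRO":
        return _read_gro(path, role_map)
    if fmt == "PDB":
        return _read_pdb(path, role_map, box=box)
    raise ValueError(f"unsupported structure format {fmt!r}")


# ---------------------------------------------------------------------------
# trajectory I/O

_TSV_MAGIC = "# phbind trajectory v1"


def _read_tsv_trajectory(path: Path, topology: Topology) -> Trajectory:
    n = topology.n_particles
    frames = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _TSV_MAGIC:
            raise ParseError(f"{path}:1: not a phbind columnar trajectory")
        frame_idx = 0
        while True:
            header = fh.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.strip():
                continue
            parts = header.split()
            if parts[0] != "#frame" or len(parts) != 5:
                raise ParseError(
                    f"{path}: frame {frame_idx}: malformed frame header {header!r}"
                )
            time = float(parts[1])
            box = [float(v) for v in parts[2:5]]
            coords = np.empty((n, 3))
            for i in range(n):
                row = fh.readline()
                if not row:
                    raise ParseError(
                        f"{path}: truncated final frame (frame index {frame_idx}, "
                        f"got {i} of {n} rows)"
                    )
                vals = row.split("\t")
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}: frame {frame_idx}: row has {len(vals)} columns"
                    )
                coords[i] = [float(vals[1]), float(vals[2]), float(vals[3])]
            frames.append(Frame(time=time, box=box, coords=coords))
            frame_idx += 1
    return Trajectory(topology=topology, frames=frames)


def _write_tsv_trajectory(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_MAGIC + "\n")
        for fr in traj.frames:
            fh.write(
                "#frame %.17g %.17g %.17g %.17g\n" % (fr.time, *fr.box)
            )
            t = "%.17g" % fr.time
            for row in fr.coords:
                fh.write("%s\t%.17g\t%.17g\t%.17g\n" % (t, row[0], row[1], row[2]))


def _read_xtc_trajectory(path: Path, topology: Topology) -> Trajectory:
    from MDAnalysis.coordinates.XTC import XTCReader

    frames = []
    try:
        reader = XTCReader(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: XTC open failed: {exc}") from exc
    with reader:
        for idx, ts in enumerate(reader):
            if ts.n_atoms != topology.n_particles:
                raise StructureError(
                    f"{path}: frame {idx} has {ts.n_atoms} atoms, topology has "
                    f"{topology.n_particles}"
                )
            dims = ts.dimensions
            if np.any(np.abs(dims[3:] - 90.0) > 1e-3):
                raise StructureError(f"{path}: triclinic box not supported")
            frames.append(
                Frame(time=float(ts.time), box=dims[:3] / 10.0, coords=ts.positions / 10.0)
            )
    return Trajectory(topology=topology, frames=frames)


def _write_xtc_trajectory(traj: Trajectory, path: Path) -> None:
    from MDAnalysis.coordinates.XTC import XTCWriter

    n = traj.topology.n_particles
    with XTCWriter(str(path), n_atoms=n) as writer:
        import MDAnalysis as mda

        u = mda.Universe.empty(n, trajectory=True)
        for fr in traj.frames:
            u.atoms.positions = fr.coords * 10.0
            u.trajectory.ts.time = fr.time
            u.trajectory.ts.dimensions = [*(fr.box * 10.0), 90.0, 90.0, 90.0]
            writer.write(u.atoms)


def read_trajectory(path, topology: Topology, fmt: str | None = None) -> Trajectory:
    """Read a trajectory (``XTC`` or columnar ``TSV``) onto a topology."""
    path = Path(path)
    if fmt is None:
        fmt = "XTC" if path.suffix.lower() == ".xtc" else "TSV"
    fmt = fmt.upper()
    if fmt == "XTC":
        return _read_xtc_trajectory(path, topology)
    if fmt == "TSV":
        return _read_tsv_trajectory(path, topology)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "XTC" if path.suffix.lower() == ".xtc" else "TSV"
    fmt = fmt.upper()
    if fmt == "XTC":
        _write_xtc_trajectory(traj, path)
    elif fmt == "TSV":
        _write_tsv_trajectory(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# tabular output


def write_table(records, path) -> None:
    """Write rectangular analysis records as TSV with a header row.

    ``records`` may be a pandas DataFrame or an iterable of dicts with a
    common key set. Floats are rendered with 6 significant digits; row
    order is preserved (callers emit deterministic order).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty table")
        keys = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != keys:
                raise ValueError(f"record {i} is not rectangular with record 0")
        df = pd.DataFrame.from_records(records, columns=keys)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
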
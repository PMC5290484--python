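"""Per-frame geometric descriptors of membrane association.

The orientation descriptor is the zz element of the least-squares (Kabsch)
rotation superposing a reference backbone geometry onto the instantaneous
backbone: R_zz = 1 means the body z-axis points as in the reference,
R_zz = -1 means it is flipped. Together with the protein-bilayer
centre-of-mass z separation d_z it spans the 2-D binding landscape, and a
single threshold on d_z (default 4.75 nm, strict) classifies frames as
membrane-bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ANNULUS_WIDTH_NM, BOUND_THRESHOLD_NM, CONTACT_CUTOFF_NM
from .model_io import Frame, Topology, Trajectory

__all__ = [
    "AnalysisConfig",
    "ReferenceOrientation",
    "OrientationSeries",
    "LandscapeHistogram",
    "ResidueProfile",
    "dz_protein_bilayer",
    "rzz",
    "classify_bound",
    "compute_orientation_series",
    "orientation_landscape",
    "rmsf",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and bin widths for the encounter/contact analyses.

    ``loop_ranges`` maps loop labels to inclusive residue-id ranges; the
    beta1/beta2 loop default covers residues 360-372, the positively
    charged loop that dominates PIP engagement. The beta3/beta4 and
    beta5/beta6 ranges are system-specific and must be set by the user
    before site classification.
    """

    bound_threshold: float = BOUND_THRESHOLD_NM
    contact_cutoff: float = CONTACT_CUTOFF_NM
    annulus_width: float = ANNULUS_WIDTH_NM
    dz_bin_width: float = 0.1
    rzz_bin_width: float = 0.05
    loop_ranges: dict = field(
        default_factory=lambda: {"b1b2": (360, 372), "b3b4": None, "b5b6": None}
    )
    persistence_cutoff: float = 0.55  # nm; CG bead default, 0.35 for atomistic

    def __post_init__(self):
        for name in ("bound_threshold", "contact_cutoff", "annulus_width",
                     "dz_bin_width", "rzz_bin_width", "persistence_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _wrapped_com_z(z: np.ndarray, masses: np.ndarray, box_z: float) -> float:
    """Mass-weighted COM of a z coordinate set, minimum-imaged about the
    group's first particle so groups split across the periodic boundary
    average correctly."""
    ref = z[0]
    delta = z - ref
    delta -= box_z * np.round(delta / box_z)
    com = ref + np.average(delta, weights=masses)
    return com % box_z


def dz_protein_bilayer(frame: Frame, topology: Topology, signed: bool = False) -> float:
    """z distance between protein COM and bilayer (all-lipid) COM, nm.

    Both centres of mass are mass-weighted and minimum-image corrected
    about each group's first particle. Returns |dz| unless ``signed``.
    """
    box_z = frame.box[2]
    out = []
    for label, mask in (("protein", topology.protein_mask()),
                        ("lipid", topology.lipid_mask())):
        if not np.any(mask):
            raise ValueError(f"topology contains no {label} particles")
        out.append(
            _wrapped_com_z(frame.coords[mask, 2], topology.masses[mask], box_z)
        )
    dz = out[0] - out[1]
    dz -= box_z * np.round(dz / box_z)
    return float(dz) if signed else float(abs(dz))


@dataclass
class ReferenceOrientation:
    """Backbone particle ids plus their reference coordinates centred on
    the COM (so rotations are the only degree of freedom left)."""

    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.ids) < 4:
            raise ValueError("need at least 4 reference particles")
        com = self.coords.mean(axis=0)
        if np.any(np.abs(com) > 1e-9):
            raise ValueError("reference coordinates must be centred on their COM")
        if np.linalg.matrix_rank(self.coords, tol=1e-9) < 2:
            raise ValueError("reference geometry is collinear; orientation undefined")

    @classmethod
    def from_frame(cls, frame: Frame, topology: Topology) -> "ReferenceOrientation":
        ids = np.flatnonzero(topology.protein_mask() & topology.is_backbone)
        if ids.size < 4:
            ids = np.flatnonzero(topology.protein_mask())
        coords = frame.coords[ids]
        return cls(ids=ids, coords=coords - coords.mean(axis=0))


def _kabsch(reference: np.ndarray, current: np.ndarray) -> Rotation:
    """Proper rotation R minimising |current - R reference| (both centred)."""
    cov = current.T @ reference
    s = np.linalg.svd(cov, compute_uv=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) geometry; rotation ill-defined")
    rot, _ = Rotation.align_vectors(current, reference)
    return rot


def rzz(frame: Frame, reference: ReferenceOrientation) -> float:
    """R_zz of the Kabsch rotation taking the reference onto the frame."""
    current = frame.coords[reference.ids]
    current = current - current.mean(axis=0)
    rot = _kabsch(reference.coords, current)
    return float(rot.as_matrix()[2, 2])


def classify_bound(d_z: float, config: AnalysisConfig | None = None) -> bool:
    """Membrane-bound iff d_z is strictly below the threshold."""
    if d_z < 0:
        raise ValueError("d_z must be non-negative")
    config = config or AnalysisConfig()
    return d_z < config.bound_threshold


@dataclass
class OrientationSeries:
    """Per-frame (time, d_z, R_zz, bound) records."""

    times: np.ndarray
    d_z: np.ndarray
    r_zz: np.ndarray
    bound: np.ndarray

    def __post_init__(self):
        for name in ("times", "d_z", "r_zz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.bound = np.asarray(self.bound, dtype=bool)
        if np.any(np.abs(self.r_zz) > 1.0 + 1e-9):
            raise ValueError("r_zz outside [-1, 1]")

    def __len__(self):
        return len(self.times)


def compute_orientation_series(
    trajectory: Trajectory,
    reference: ReferenceOrientation | None = None,
    config: AnalysisConfig | None = None,
) -> OrientationSeries:
    """Evaluate d_z, R_zz and the bound flag for every frame.

    The reference defaults to the first frame's backbone (logged choice:
    landscapes are relative to an explicit reference geometry).
    """
    config = config or AnalysisConfig()
    if reference is None:
        reference = ReferenceOrientation.from_frame(
            trajectory.frames[0], trajectory.topology
        )
    d = np.array([dz_protein_bilayer(fr, trajectory.topology) for fr in trajectory.frames])
    r = np.array([rzz(fr, reference) for fr in trajectory.frames])
    return OrientationSeries(
        times=trajectory.times, d_z=d, r_zz=r,
        bound=d < config.bound_threshold,
    )


@dataclass
class LandscapeHistogram:
    """2-D (d_z, R_zz) histogram with bin edges aligned to multiples of
    the bin widths; the final bin's top edge is closed so no frame at the
    range boundary is dropped."""

    dz_edges: np.ndarray
    rzz_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray

    @property
    def mode_bin(self):
        """((dz_lo, dz_hi), (rzz_lo, rzz_hi)) of the highest-count bin;
        ties resolve toward smaller d_z (membrane-proximal mode)."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            (float(self.dz_edges[i]), float(self.dz_edges[i + 1])),
            (float(self.rzz_edges[j]), float(self.rzz_edges[j + 1])),
        )

    def mode_contains(self, d_z: float, r_zz: float) -> bool:
        """Whether the mode bin's closed intervals contain the point."""
        (dlo, dhi), (rlo, rhi) = self.mode_bin
        return dlo <= d_z <= dhi and rlo <= r_zz <= rhi


def _aligned_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo + 1e-12:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def orientation_landscape(
    series: OrientationSeries,
    config: AnalysisConfig | None = None,
    bound_only: bool = False,
) -> LandscapeHistogram:
    """Build the normalised 2-D binding landscape over (d_z, R_zz)."""
    config = config or AnalysisConfig()
    if len(series) == 0:
        raise ValueError("empty orientation series")
    sel = series.bound if bound_only else np.ones(len(series), dtype=bool)
    if not np.any(sel):
        raise ValueError("all frames filtered out; landscape is empty")
    d, r = series.d_z[sel], series.r_zz[sel]
    dz_edges = _aligned_edges(d, config.dz_bin_width)
    rzz_edges = _aligned_edges(r, config.rzz_bin_width)
    counts, _, _ = np.histogram2d(d, r, bins=[dz_edges, rzz_edges])
    return LandscapeHistogram(
        dz_edges=dz_edges,
        rzz_edges=rzz_edges,
        counts=counts,
        density=counts / counts.sum(),
    )


@dataclass
class ResidueProfile:
    residue_ids: np.ndarray
    rmsf: np.ndarray  # nm
    n_frames: int
    n_repeats: int

    def to_dict(self) -> dict:
        return dict(zip(self.residue_ids.tolist(), self.rmsf.tolist()))


def _single_rmsf(
    traj: Trajectory, reference: ReferenceOrientation, align: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF for one trajectory over the reference selection."""
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ids = reference.ids
    stack = np.empty((len(traj), len(ids), 3))
    for k, fr in enumerate(traj.frames):
        x = fr.coords[ids]
        if align:
            x = x - x.mean(axis=0)
            rot = _kabsch(x, reference.coords)  # superpose frame ONTO reference
            x = rot.apply(x)
        stack[k] = x
    mean_pos = stack.mean(axis=0)
    per_particle = np.sqrt(np.mean(np.sum((stack - mean_pos) ** 2, axis=2), axis=0))
    resids = traj.topology.residue_ids[ids]
    unique = np.unique(resids)
    per_residue = np.array([per_particle[resids == r].mean() for r in unique])
    return unique, per_residue


def rmsf(
    trajectories,
    reference: ReferenceOrientation | None = None,
    align: bool = True,
) -> ResidueProfile:
    """Average per-residue RMSF over one or more repeat trajectories.

    Each frame is least-squares superposed (rotation + translation) onto
    the reference backbone before fluctuations about each particle's
    time-mean position are accumulated; repeats (e.g. different force
    fields) are averaged per residue with equal weight. ``align=False``
    skips the superposition and measures raw fluctuations.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if reference is None:
        reference = ReferenceOrientation.from_frame(
            trajectories[0].frames[0], trajectories[0].topology
        )
    profiles = [_single_rmsf(tr, reference, align) for tr in trajectories]
    resids = profiles[0][0]
    for r, _ in profiles[1:]:
        if not np.array_equal(r, resids):
            raise ValueError("repeat trajectories have different residue sets")
    avg = np.mean([p for _, p in profiles], axis=0)
    return ResidueProfile(
        residue_ids=resids,
        rmsf=avg,
        n_frames=sum(len(tr) for tr in trajectories),
        n_repeats=len(trajectories),
    )
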
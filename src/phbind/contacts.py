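"""PIP contact detection, clustering occupancy, and site classification.

A PIP lipid is "in contact" when any of its phosphate particles lies
within the cutoff (default 1 nm, inclusive) of any protein particle,
under minimum-image distances. The clustering statistic counts lipids
whose phosphate sits within a 1 nm annulus of the protein surface
(operationalised as minimum phosphate-to-any-protein-particle distance),
resolved by leaflet because protein-induced clustering is local to the
leaflet the protein is bound to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encounter import AnalysisConfig, OrientationSeries
from .model_io import Frame, Topology, Trajectory
from .neighbor import min_image_distance, pairs_within_cutoff

logger = logging.getLogger(__name__)

__all__ = [
    "ContactSeries",
    "SiteCall",
    "pip_contacts",
    "contact_count_series",
    "residue_contact_ranking",
    "leaflet_assign",
    "proximal_leaflet",
    "annulus_count",
    "uniform_annulus_expectation",
    "classify_binding_site",
    "interaction_persistence",
]


def _phosphate_index(topology: Topology, role: str):
    """(particle indices, molecule ids) of the role's phosphates; for
    roles without a phosphate flag (plain lipids) fall back to all
    particles of the role."""
    idx = topology.phosphate_indices(role)
    if idx.size == 0:
        idx = np.flatnonzero(topology.roles == role)
    return idx, topology.molecule_ids[idx]


def pip_contacts(
    frame: Frame, topology: Topology, config: AnalysisConfig | None = None,
    role: str = "lipid:PIP3",
) -> set:
    """Molecule ids of role-lipids whose phosphate is within the contact
    cutoff (inclusive) of any protein particle."""
    config = config or AnalysisConfig()
    prot = np.flatnonzero(topology.protein_mask())
    if prot.size == 0:
        raise ValueError("topology contains no protein particles")
    phos, mols = _phosphate_index(topology, role)
    if phos.size == 0:
        logger.warning("role %s absent from topology; empty contact set", role)
        return set()
    pairs = pairs_within_cutoff(
        frame.coords[phos], frame.coords[prot], frame.box, config.contact_cutoff
    )
    return {int(mols[i]) for i in np.unique(pairs[:, 0])} if pairs.size else set()


@dataclass
class ContactSeries:
    """Per-frame contact sets plus aggregate statistics for one lipid role."""

    role: str
    times: np.ndarray
    contact_sets: list
    counts: np.ndarray
    annulus_proximal: np.ndarray
    annulus_distal: np.ndarray
    residue_counts: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.times)


def contact_count_series(
    trajectory: Trajectory,
    series: OrientationSeries,
    config: AnalysisConfig | None = None,
    role: str = "lipid:PIP3",
    bound_only: bool = True,
) -> ContactSeries:
    """Per-frame PIP contact counts (and annulus occupancies), optionally
    restricted to membrane-bound frames."""
    config = config or AnalysisConfig()
    if len(series) != len(trajectory):
        raise ValueError(
            f"orientation series ({len(series)}) and trajectory "
            f"({len(trajectory)}) lengths differ"
        )
    topo = trajectory.topology
    times, sets, prox, dist = [], [], [], []
    residue_counts: dict[int, int] = {}
    for frame, t, bound in zip(trajectory.frames, series.times, series.bound):
        if bound_only and not bound:
            continue
        contacts = pip_contacts(frame, topo, config, role)
        times.append(t)
        sets.append(contacts)
        prox.append(annulus_count(frame, topo, config, role, leaflet="proximal"))
        dist.append(annulus_count(frame, topo, config, role, leaflet="distal"))
        for resid, c in _frame_residue_contacts(frame, topo, config, role).items():
            residue_counts[resid] = residue_counts.get(resid, 0) + c
    return ContactSeries(
        role=role,
        times=np.asarray(times),
        contact_sets=sets,
        counts=np.array([len(s) for s in sets], dtype=int),
        annulus_proximal=np.asarray(prox, dtype=int),
        annulus_distal=np.asarray(dist, dtype=int),
        residue_counts=residue_counts,
    )


def _frame_residue_contacts(
    frame: Frame, topology: Topology, config: AnalysisConfig, role: str
) -> dict:
    """resid -> number of contacting lipids whose phosphate is within the
    cutoff of any particle of that residue, this frame."""
    phos, mols = _phosphate_index(topology, role)
    if phos.size == 0:
        return {}
    prot = np.flatnonzero(topology.protein_mask())
    pairs = pairs_within_cutoff(
        frame.coords[phos], frame.coords[prot], frame.box, config.contact_cutoff
    )
    out: dict[int, set] = {}
    for i, j in pairs:
        resid = int(topology.residue_ids[prot[j]])
        out.setdefault(resid, set()).add(int(mols[i]))
    return {r: len(s) for r, s in out.items()}


def residue_contact_ranking(
    trajectory: Trajectory,
    config: AnalysisConfig | None = None,
    role: str = "lipid:PIP3",
) -> list:
    """Protein residues ranked by total lipid-contact events.

    A residue's count increments once per frame per contacting lipid
    whose phosphate is within the cutoff of any particle of the residue.
    Descending by count, ties broken by ascending residue id; residues
    with zero contacts are included at the tail.
    """
    config = config or AnalysisConfig()
    topo = trajectory.topology
    totals = {int(r): 0 for r in np.unique(topo.residue_ids[topo.protein_mask()])}
    for frame in trajectory.frames:
        for resid, c in _frame_residue_contacts(frame, topo, config, role).items():
            totals[resid] += c
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def leaflet_assign(frame: Frame, topology: Topology) -> dict:
    """Lipid molecule id -> ``upper``/``lower`` by the sign of the
    phosphate (or molecule-representative) z relative to the bilayer
    midplane (the all-lipid COM z). Exactly-at-midplane assigns upper."""
    lipid_mask = topology.lipid_mask()
    if not np.any(lipid_mask):
        raise ValueError("topology contains no lipid particles")
    midplane = np.average(
        frame.coords[lipid_mask, 2], weights=topology.masses[lipid_mask]
    )
    out = {}
    for mol in np.unique(topology.molecule_ids[lipid_mask]):
        sel = (topology.molecule_ids == mol) & lipid_mask
        phos = sel & topology.is_phosphate
        z = frame.coords[phos if np.any(phos) else sel, 2].mean()
        out[int(mol)] = "upper" if z >= midplane else "lower"
    return out


def proximal_leaflet(frame: Frame, topology: Topology) -> str:
    """The leaflet nearer the protein COM (mean |z - protein COM z|)."""
    assign = leaflet_assign(frame, topology)
    prot = topology.protein_mask()
    z_prot = np.average(frame.coords[prot, 2], weights=topology.masses[prot])
    lipid_mask = topology.lipid_mask()
    dists = {"upper": [], "lower": []}
    for mol, leaf in assign.items():
        sel = (topology.molecule_ids == mol) & lipid_mask
        dists[leaf].append(abs(frame.coords[sel, 2].mean() - z_prot))
    means = {k: np.mean(v) if v else np.inf for k, v in dists.items()}
    return "upper" if means["upper"] <= means["lower"] else "lower"


def annulus_count(
    frame: Frame,
    topology: Topology,
    config: AnalysisConfig | None = None,
    role: str = "lipid:PIP3",
    leaflet: str = "proximal",
) -> int:
    """Number of role-lipids whose phosphate lies within the annulus
    width of the protein surface (minimum 3-D minimum-image distance to
    any protein particle), restricted to the requested leaflet
    (``proximal``/``distal``/``both``)."""
    config = config or AnalysisConfig()
    phos, mols = _phosphate_index(topology, role)
    if phos.size == 0:
        return 0
    if leaflet != "both":
        assign = leaflet_assign(frame, topology)
        prox = proximal_leaflet(frame, topology)
        want = prox if leaflet == "proximal" else ("lower" if prox == "upper" else "upper")
        keep = np.array([assign[int(m)] == want for m in mols])
        phos, mols = phos[keep], mols[keep]
        if phos.size == 0:
            return 0
    prot = np.flatnonzero(topology.protein_mask())
    pairs = pairs_within_cutoff(
        frame.coords[phos], frame.coords[prot], frame.box, config.annulus_width
    )
    return len({int(mols[i]) for i in np.unique(pairs[:, 0])}) if pairs.size else 0


def uniform_annulus_expectation(
    trajectory: Trajectory,
    config: AnalysisConfig | None = None,
    role: str = "lipid:PIP3",
    leaflet: str = "proximal",
    frame_stride: int = 20,
    grid: float = 0.05,
) -> float:
    """Expected mean annulus occupancy if role-lipids were laterally
    uniform: lateral density times the (frame-averaged) area of the
    leaflet plane lying within the annulus width of the protein surface.

    The annulus cross-section area is integrated numerically on a lateral
    grid at the leaflet's mean phosphate z, per subsampled frame.
    """
    config = config or AnalysisConfig()
    topo = trajectory.topology
    lx, ly = trajectory.frames[0].box[:2]
    areas = []
    n_leaf = []
    for frame in trajectory.frames[::frame_stride]:
        phos, mols = _phosphate_index(topo, role)
        if phos.size == 0:
            return 0.0
        assign = leaflet_assign(frame, topo)
        prox = proximal_leaflet(frame, topo)
        want = prox if leaflet == "proximal" else ("lower" if prox == "upper" else "upper")
        keep = np.array([assign[int(m)] == want for m in mols])
        n_leaf.append(int(keep.sum()))
        z_plane = frame.coords[phos[keep], 2].mean() if keep.any() else np.nan
        if not np.isfinite(z_plane):
            areas.append(0.0)
            continue
        xs = np.arange(0, lx, grid) + grid / 2
        ys = np.arange(0, ly, grid) + grid / 2
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack(
            [gx.ravel(), gy.ravel(), np.full(gx.size, z_plane)]
        )
        prot = frame.coords[topo.protein_mask()]
        d = min_image_distance(pts, prot, frame.box).min(axis=1)
        areas.append(float(np.mean(d <= config.annulus_width) * lx * ly))
    density = np.mean(n_leaf) / (lx * ly)
    return float(density * np.mean(areas))


@dataclass
class SiteCall:
    """Binding-site classification from loop contact fractions."""

    label: str  # canonical | non-canonical | mixed | none
    loop_fractions: dict


def classify_binding_site(
    residue_counts, loop_ranges: dict, min_loop_fraction: float = 0.1
) -> SiteCall:
    """Classify the engaged binding site from per-residue contact counts.

    ``canonical`` when the b1b2 and b3b4 loops carry the two largest loop
    contact fractions, ``non-canonical`` when b1b2 and b5b6 do, ``none``
    when loops capture less than ``min_loop_fraction`` of all contacts,
    ``mixed`` otherwise. Both members of a winning pair must have nonzero
    fraction. Loop ranges are inclusive and must be disjoint.
    """
    if isinstance(residue_counts, list):
        residue_counts = dict(residue_counts)
    ranges = {k: v for k, v in loop_ranges.items() if v is not None}
    spans = sorted(ranges.values())
    for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
        if a2 <= b1:
            raise ValueError(f"loop ranges overlap: ({a1},{b1}) and ({a2},{b2})")
    total = sum(residue_counts.values())
    fractions = {}
    for name, (lo, hi) in ranges.items():
        c = sum(v for r, v in residue_counts.items() if lo <= r <= hi)
        fractions[name] = c / total if total else 0.0
    if total == 0 or sum(fractions.values()) < min_loop_fraction:
        return SiteCall("none", fractions)
    top = sorted(fractions, key=lambda k: (-fractions[k], k))[:2]
    pair = set(top)
    if all(fractions[k] > 0 for k in pair):
        if pair == {"b1b2", "b3b4"}:
            return SiteCall("canonical", fractions)
        if pair == {"b1b2", "b5b6"}:
            return SiteCall("non-canonical", fractions)
    return SiteCall("mixed", fractions)


def interaction_persistence(
    trajectory: Trajectory,
    pair,
    cutoff: float | None = None,
    by: str = "residue",
    config: AnalysisConfig | None = None,
):
    """Fraction of frames a pairwise interaction is formed, plus the
    number of break events (maximal runs of non-contact frames).

    ``pair`` names two members, particle ids (``by="particle"``) or
    residue ids (``by="residue"``); the per-frame criterion is minimum
    inter-member minimum-image distance <= cutoff. The fraction is
    invariant to frame-order permutation; the break-event count is not
    (it counts contiguous runs in time).
    """
    config = config or AnalysisConfig()
    cutoff = config.persistence_cutoff if cutoff is None else cutoff
    a, b = pair
    if a == b:
        raise ValueError("interaction pair members must differ")
    topo = trajectory.topology
    key = topo.ids if by == "particle" else topo.residue_ids
    sel_a = np.flatnonzero(key == a)
    sel_b = np.flatnonzero(key == b)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError(f"pair member absent from topology: {a if not sel_a.size else b}")
    formed = np.array(
        [
            min_image_distance(fr.coords[sel_a], fr.coords[sel_b], fr.box).min()
            <= cutoff
            for fr in trajectory.frames
        ]
    )
    fraction = float(np.mean(formed))
    broken = ~formed
    n_breaks = int(np.sum(broken & np.concatenate([[True], ~broken[:-1]])))
    return fraction, n_breaks
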
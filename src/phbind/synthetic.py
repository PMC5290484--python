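"""Ground-truth synthetic data generators.

Every downstream analysis in this package is validated against data whose
answer is known by construction:

* a rigid "protein" of pseudo-particles performing Metropolis-adjusted
  Brownian dynamics in a prescribed 1-D binding potential U(d_z) above a
  planar bilayer, with an orientation bias toward a preferred R_zz that is
  active only while membrane-bound;
* laterally mobile point lipids in two leaflets, optionally attracted
  toward the bound protein's lateral position (protein-induced PIP
  clustering, local to the proximal leaflet);
* exact Boltzmann samples from a known 1-D potential under harmonic
  umbrella biases (rejection sampling against the analytic Gaussian
  envelope);
* noisy 1:1 Langmuir saturation curves from known KD and Bmax.

All moves are Metropolis-accepted, so the stationary distribution is
exactly the Boltzmann distribution of the stated potentials, which makes
occupancy statistics testable in closed form. Every generator is
bit-reproducible under a fixed seed.

The default configuration mirrors a coarse-grained bilayer system of 78
POPC : 20 POPS plus 4 PIP3 lipids per leaflet at 323 K with frames 20 ps
apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .binding import BindingCurve
from .constants import BOUND_THRESHOLD_NM, DEFAULT_TEMPERATURE_K, kj_to_kcal, kt_kcal
from .model_io import Frame, Topology, Trajectory
from .pmf import UmbrellaWindow
from .potentials import Potential1D, double_well, harmonic

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_topology",
    "initial_frame",
    "generate_encounter_trajectory",
    "generate_umbrella_samples",
    "simulate_saturation",
    "boltzmann_bound_fraction",
    "boltzmann_cdf",
    "default_double_well",
]

#: Rigid pseudo-protein geometry (nm, centred below): 8 non-coplanar beads
#: with no special symmetry so the Kabsch rotation is unique.
_PROTEIN_GEOMETRY = np.array(
    [
        [0.00, 0.00, 0.90],
        [0.80, 0.00, 0.35],
        [-0.45, 0.70, 0.30],
        [-0.40, -0.75, 0.25],
        [0.55, 0.50, -0.55],
        [-0.65, 0.35, -0.50],
        [0.15, -0.80, -0.45],
        [0.05, 0.10, -0.95],
    ]
)
_PROTEIN_GEOMETRY = _PROTEIN_GEOMETRY - _PROTEIN_GEOMETRY.mean(axis=0)

_LIPID_RESNAMES = {
    "lipid:POPC": "POPC",
    "lipid:POPS": "POPS",
    "lipid:PIP2": "POP2",
    "lipid:PIP3": "POP3",
}


def _default_leaflet_counts() -> dict:
    return {"lipid:POPC": 78, "lipid:POPS": 20, "lipid:PIP3": 4}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic membrane-encounter system.

    Energies in kcal/mol, lengths in nm, times in ps. ``true_pmf`` is the
    binding potential over the protein-bilayer COM z separation d_z;
    reflecting walls confine d_z to ``d_range``. The orientation bias
    V(R_zz) acts only while the protein is bound: ``harmonic`` form
    a/2 (R_zz - R_zz*)^2 with a preferred orientation, or the ``linear``
    form -a R_zz (preferred orientation pinned at R_zz = 1).
    """

    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE_K
    timestep: float = 20.0
    n_frames: int = 2000
    box: tuple = (8.0, 8.0, 14.0)
    # default binding potential: a -2.5 kcal/mol Gaussian well of width
    # 0.25 nm at d_z = 4.0 nm, flat (bulk) elsewhere
    true_pmf: Potential1D = field(
        default_factory=lambda: double_well(
            d1=-2.5, z1=4.0, d2=0.0, z2=6.0, width=0.25
        )
    )
    d_range: tuple = (3.2, 6.8)
    start_dz: float = 4.0
    orientation_form: str = "harmonic"
    orientation_strength: float = 100.0
    preferred_rzz: float = 0.8
    n_lipids_per_leaflet: dict = field(default_factory=_default_leaflet_counts)
    protein_diffusion: float = 2.5e-3  # nm^2/ps
    lipid_diffusion: float = 1.0e-4  # nm^2/ps
    rotation_step: float = 0.15  # rad, proposal scale
    clustering_strength: float = 2.0  # kcal/mol, 0 = uniform lipids
    clustering_range: float = 2.0  # nm, Gaussian range of the attraction
    # leaflet (phosphate-plane) offset from the midplane; together with
    # the protein half-height (~0.95 nm) this puts the bound protein's
    # membrane-facing beads within contact range of the proximal leaflet
    # at the binding minimum d_z = 4.0 nm
    bilayer_half_thickness: float = 2.5
    n_protein_particles: int = 8
    bound_threshold: float = BOUND_THRESHOLD_NM

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(c < 0 for c in self.n_lipids_per_leaflet.values()):
            raise ValueError("lipid counts must be >= 0")
        if not 4 <= self.n_protein_particles <= len(_PROTEIN_GEOMETRY):
            raise ValueError(
                "R_zz requires 4 or more non-coplanar protein particles "
                f"(at most {len(_PROTEIN_GEOMETRY)})"
            )
        if self.orientation_form not in ("harmonic", "linear"):
            raise ValueError("orientation_form must be 'harmonic' or 'linear'")
        if not (self.d_range[0] < self.start_dz < self.d_range[1]):
            raise ValueError("start_dz must lie inside d_range")

    def orientation_potential(self, r_zz):
        a = self.orientation_strength
        if self.orientation_form == "harmonic":
            return 0.5 * a * (np.asarray(r_zz) - self.preferred_rzz) ** 2
        return -a * np.asarray(r_zz)

    @property
    def midplane(self) -> float:
        return self.box[2] / 2.0


@dataclass
class GroundTruth:
    """What the generator imposed, for recovery tests."""

    pmf_grid: np.ndarray
    pmf_values: np.ndarray  # kcal/mol over pmf_grid
    preferred_rzz: float
    d_range: tuple
    bound_fraction: float  # analytic Boltzmann occupancy of d_z < threshold
    lateral_density: dict  # (role, leaflet) -> lipids per nm^2
    leaflet_labels: dict  # lipid molecule id -> "upper" / "lower"


def make_topology(config: SyntheticConfig) -> Topology:
    """Topology for the synthetic system: a rigid pseudo-protein (all
    beads flagged backbone) plus single-particle lipids; each PIP lipid's
    particle carries the phosphate flag."""
    names, resids, resnames, mols, roles, masses, phos, bb = (
        [], [], [], [], [], [], [], [],
    )
    for k in range(config.n_protein_particles):
        names.append("BB")
        resids.append(360 + k)
        resnames.append("ALA")
        mols.append(0)
        roles.append("protein")
        masses.append(72.0)
        phos.append(False)
        bb.append(True)
    mol = 1
    resid = 1000
    for leaflet in ("upper", "lower"):
        for role in sorted(config.n_lipids_per_leaflet):
            is_pip = role in ("lipid:PIP2", "lipid:PIP3")
            for _ in range(config.n_lipids_per_leaflet[role]):
                names.append("PO4" if is_pip else "GL1")
                resids.append(resid)
                resnames.append(_LIPID_RESNAMES.get(role, role.split(":", 1)[1][:5]))
                mols.append(mol)
                roles.append(role)
                masses.append(72.0)
                phos.append(is_pip)
                bb.append(False)
                mol += 1
                resid += 1
    return Topology(
        ids=np.arange(len(names)),
        names=names,
        residue_ids=resids,
        residue_names=resnames,
        molecule_ids=mols,
        roles=roles,
        masses=masses,
        is_phosphate=phos,
        is_backbone=bb,
    )


def _leaflet_labels(config: SyntheticConfig, topology: Topology) -> dict:
    n_per_leaflet = sum(config.n_lipids_per_leaflet.values())
    labels = {}
    lipid_mols = np.unique(topology.molecule_ids[topology.lipid_mask()])
    for i, mol in enumerate(sorted(lipid_mols)):
        labels[int(mol)] = "upper" if i < n_per_leaflet else "lower"
    return labels


def initial_frame(
    config: SyntheticConfig, topology: Topology, rng: np.random.Generator
) -> Frame:
    """Starting configuration: protein COM at midplane + start_dz,
    orientation = reference; lipids laterally uniform at their leaflet z."""
    box = np.asarray(config.box, dtype=float)
    coords = np.empty((topology.n_particles, 3))
    n_prot = config.n_protein_particles
    center = np.array([box[0] / 2, box[1] / 2, config.midplane + config.start_dz])
    coords[:n_prot] = _PROTEIN_GEOMETRY[:n_prot] + center
    labels = _leaflet_labels(config, topology)
    lipid_idx = np.flatnonzero(topology.lipid_mask())
    for i in lipid_idx:
        leaf = labels[int(topology.molecule_ids[i])]
        z = config.midplane + (
            config.bilayer_half_thickness if leaf == "upper" else -config.bilayer_half_thickness
        )
        coords[i] = [rng.uniform(0, box[0]), rng.uniform(0, box[1]), z]
    return Frame(time=0.0, box=box, coords=coords)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal into [lo, hi] (preserves proposal symmetry)."""
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def _metropolis_accept(rng: np.random.Generator, delta_u: float, beta: float) -> bool:
    if delta_u <= 0:
        return True
    if not np.isfinite(beta):
        return False
    return rng.random() < np.exp(-beta * delta_u)


def _random_rotation_step(rng: np.random.Generator, angle_sd: float) -> Rotation:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, angle_sd)
    return Rotation.from_rotvec(axis * angle)


def generate_encounter_trajectory(config: SyntheticConfig):
    """Simulate a membrane-encounter trajectory; returns
    ``(Trajectory, GroundTruth)``.

    Protein COM z separation follows random-walk Metropolis in the true
    PMF with reflecting walls at ``d_range``; rigid-body orientation
    follows Metropolis small-rotation dynamics biased by the orientation
    potential while bound; lipids random-walk laterally (fixed leaflet z,
    periodic x/y), with PIP phosphates of the proximal leaflet attracted
    toward the bound protein's lateral position when clustering is on.
    """
    topology = make_topology(config)
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_dyn = (np.random.default_rng(s) for s in ss.spawn(2))
    frame0 = initial_frame(config, topology, rng_init)
    box = frame0.box
    beta = np.inf if config.temperature == 0 else 1.0 / kt_kcal(config.temperature)
    u = config.true_pmf
    d_lo, d_hi = config.d_range
    labels = _leaflet_labels(config, topology)

    n_prot = config.n_protein_particles
    geom = _PROTEIN_GEOMETRY[:n_prot]
    lateral = np.array([box[0] / 2, box[1] / 2])
    lipid_idx = np.flatnonzero(topology.lipid_mask())
    lip_xy = frame0.coords[lipid_idx, :2].copy()
    lip_z = frame0.coords[lipid_idx, 2].copy()
    # lipids subject to the clustering force: PIP phosphates, upper
    # (protein-proximal) leaflet only
    pip_mask = np.array(
        [
            topology.is_phosphate[i] and labels[int(topology.molecule_ids[i])] == "upper"
            for i in lipid_idx
        ]
    )

    sd_p = np.sqrt(2.0 * config.protein_diffusion * config.timestep)
    sd_l = np.sqrt(2.0 * config.lipid_diffusion * config.timestep)
    eps, sig = config.clustering_strength, config.clustering_range

    def cluster_energy(xy: np.ndarray) -> np.ndarray:
        delta = xy - lateral
        delta -= box[:2] * np.round(delta / box[:2])
        r2 = np.sum(delta * delta, axis=1)
        return -eps * np.exp(-r2 / (2.0 * sig * sig))

    d = config.start_dz
    rot = Rotation.identity()
    frames = [frame0]
    for step in range(1, config.n_frames):
        # protein z separation
        d_new = _reflect(d + rng_dyn.normal(0.0, sd_p), d_lo, d_hi)
        if _metropolis_accept(rng_dyn, float(u(d_new) - u(d)), beta):
            d = d_new
        bound = d < config.bound_threshold
        # rigid-body orientation
        step_rot = _random_rotation_step(rng_dyn, config.rotation_step)
        rot_new = step_rot * rot
        if bound:
            dv = float(
                config.orientation_potential(rot_new.as_matrix()[2, 2])
                - config.orientation_potential(rot.as_matrix()[2, 2])
            )
        else:
            dv = 0.0
        if _metropolis_accept(rng_dyn, dv, beta):
            rot = rot_new
        # lipids: lateral random walk, Metropolis against the clustering
        # attraction for proximal-leaflet PIP phosphates while bound
        if lipid_idx.size:
            prop = lip_xy + rng_dyn.normal(0.0, sd_l, size=lip_xy.shape)
            accept = np.ones(len(lip_xy), dtype=bool)
            if bound and eps != 0.0 and pip_mask.any():
                du = cluster_energy(prop[pip_mask]) - cluster_energy(lip_xy[pip_mask])
                if np.isfinite(beta):
                    p = np.exp(-beta * np.maximum(du, 0.0))
                    accept[pip_mask] = rng_dyn.random(int(pip_mask.sum())) < p
                else:
                    accept[pip_mask] = du <= 0
            lip_xy = np.where(accept[:, None], prop, lip_xy)
            lip_xy = np.mod(lip_xy, box[:2])

        coords = np.empty((topology.n_particles, 3))
        coords[:n_prot] = rot.apply(geom) + np.array(
            [lateral[0], lateral[1], config.midplane + d]
        )
        coords[lipid_idx, :2] = lip_xy
        coords[lipid_idx, 2] = lip_z
        frames.append(Frame(time=step * config.timestep, box=box, coords=coords))

    grid = np.linspace(d_lo, d_hi, 801)
    area = box[0] * box[1]
    density = {}
    for role, count in config.n_lipids_per_leaflet.items():
        for leaf in ("upper", "lower"):
            density[(role, leaf)] = count / area
    truth = GroundTruth(
        pmf_grid=grid,
        pmf_values=u(grid),
        preferred_rzz=(
            config.preferred_rzz if config.orientation_form == "harmonic" else 1.0
        ),
        d_range=config.d_range,
        bound_fraction=boltzmann_bound_fraction(
            u, config.d_range, config.bound_threshold, config.temperature
        ),
        lateral_density=density,
        leaflet_labels=labels,
    )
    return Trajectory(topology=topology, frames=frames), truth


def boltzmann_bound_fraction(
    potential: Potential1D, d_range, threshold: float, temperature: float
) -> float:
    """Closed-form equilibrium probability of d_z < threshold under the
    potential with reflecting walls at d_range (numerical quadrature)."""
    z = np.linspace(d_range[0], d_range[1], 20001)
    u = potential(z)
    if temperature == 0:  # zero-temperature limit: all weight at the minimum
        w = (u == u.min()).astype(float)
    else:
        kt = kt_kcal(temperature)
        w = np.exp(-(u - u.min()) / kt)
    total = np.trapezoid(w, z)
    below = np.trapezoid(np.where(z < threshold, w, 0.0), z)
    return float(below / total)


def boltzmann_cdf(potential: Potential1D, d_range, temperature: float):
    """Analytic-quadrature CDF of the Boltzmann distribution on d_range;
    returns a callable for Kolmogorov-Smirnov style tests."""
    z = np.linspace(d_range[0], d_range[1], 20001)
    kt = kt_kcal(temperature)
    w = np.exp(-(potential(z) - potential(z).min()) / kt)
    cum = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(z))])
    cum /= cum[-1]
    return lambda x: np.interp(x, z, cum)


def default_double_well() -> Potential1D:
    """The double-well ground truth used by the umbrella/WHAM recovery
    studies: a -3 kcal/mol binding well at 1.5 nm separation and a
    -1 kcal/mol outer well at 2.5 nm (width 0.2 nm), decaying to 0 in
    bulk."""
    from .potentials import double_well

    return double_well(d1=-3.0, z1=1.5, d2=-1.0, z2=2.5, width=0.2)


def generate_umbrella_samples(
    true_pmf: Potential1D,
    windows,
    n_samples: int,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
    z_range=None,
) -> list:
    """Exact Boltzmann samples per umbrella window.

    ``windows`` is a sequence of ``(z0_nm, k_z_kJ_per_mol_nm2)``. For a
    biased window the total potential U(z) + k/2 (z-z0)^2 is sampled by
    rejection against the analytic Gaussian envelope of the bias; a
    window with k = 0 (unbiased special case) requires ``z_range`` and is
    sampled by inverse-CDF on a fine grid. Fixed seed gives bit-identical
    output.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    kt = kt_kcal(temperature)
    out = []
    seeds = np.random.SeedSequence(seed).spawn(len(windows))
    for (z0, k_kj), s in zip(windows, seeds):
        rng = np.random.default_rng(s)
        if k_kj < 0:
            raise ValueError("force constant must be >= 0")
        if k_kj == 0:
            if z_range is None:
                raise ValueError("unbiased window (k_z = 0) requires z_range")
            grid = np.linspace(z_range[0], z_range[1], 4001)
            w = np.exp(-(true_pmf(grid) - true_pmf(grid).min()) / kt)
            cum = np.concatenate(
                [[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))]
            )
            cum /= cum[-1]
            samples = np.interp(rng.random(n_samples), cum, grid)
            out.append(UmbrellaWindow(z0=z0, k_z=0.0, samples=samples))
            continue
        k_kcal = kj_to_kcal(k_kj)
        sigma = np.sqrt(kt / k_kcal)
        support = np.linspace(z0 - 8 * sigma, z0 + 8 * sigma, 2001)
        u_min = float(true_pmf(support).min())
        collected = np.empty(0)
        proposed = accepted = 0
        while collected.size < n_samples:
            batch = max(4 * n_samples, 1000)
            z = rng.normal(z0, sigma, size=batch)
            p = np.exp(-(true_pmf(z) - u_min) / kt)
            keep = rng.random(batch) < p
            proposed += batch
            accepted += int(keep.sum())
            collected = np.concatenate([collected, z[keep]])
            if proposed >= 100 * n_samples and accepted / proposed < 1e-4:
                raise RuntimeError(
                    f"window z0={z0:g}: rejection acceptance rate "
                    f"{accepted / proposed:.2e} < 1e-4; rescale the envelope "
                    "(the true potential varies too strongly under the bias)"
                )
        out.append(
            UmbrellaWindow(z0=z0, k_z=float(k_kj), samples=collected[:n_samples])
        )
    # report adjacent-window histogram overlap
    for a, b in zip(out[:-1], out[1:]):
        lo = max(a.samples.min(), b.samples.min())
        hi = min(a.samples.max(), b.samples.max())
        frac = 0.0
        if hi > lo:
            frac = np.mean((a.samples >= lo) & (a.samples <= hi))
        logger.debug(
            "windows z0=%g/%g overlap range %.3f nm (%.1f%% of first window)",
            a.z0, b.z0, max(hi - lo, 0.0), 100 * frac,
        )
    return out


def simulate_saturation(
    kd: float,
    bmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """Noisy 1:1 Langmuir saturation curve B = Bmax C / (KD + C) + noise."""
    if kd <= 0 or bmax <= 0:
        raise ValueError("KD and Bmax must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    b = bmax * c / (kd + c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        b = b + rng.normal(0.0, noise_sd, size=c.shape)
    return BindingCurve(concentrations=c, responses=b)
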
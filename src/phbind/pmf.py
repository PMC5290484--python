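"""Umbrella-sampling bookkeeping and WHAM free-energy estimation.

The estimator is the standard weighted-histogram self-consistency: with
windows i carrying :math:`N_i` samples of the reaction coordinate z under
harmonic biases :math:`w_i(z) = k_i/2 (z - z_i^0)^2`, iterate

.. math::

    P_b = \\frac{\\sum_i h_{ib}}{\\sum_i N_i f_i c_{ib}}, \\qquad
    f_i^{-1} = \\sum_b c_{ib} P_b,

until the window free-energy constants :math:`-kT \\ln f_i` stop moving,
then :math:`G(z_b) = -kT \\ln P_b`, shifted so the bulk region averages to
zero. The bias Boltzmann factor :math:`c_{ib}` is the *bin average* of
:math:`e^{-w_i(z)/kT}` (a closed-form Gaussian integral), not its value at
the bin centre; at stiff restraints (1000 kJ/mol/nm^2 gives a 0.05 nm
thermal width at 323 K) the centre-point approximation is the dominant
discretisation error and the bin average removes it.

Force constants are accepted in kJ/mol/nm^2 (the unit umbrella restraints
are customarily quoted in); free energies are reported in kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr
from scipy.signal import find_peaks, peak_prominences

from .constants import DEFAULT_TEMPERATURE_K, kj_to_kcal, kt_kcal

logger = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "UmbrellaPlan",
    "PMFProfile",
    "WellReport",
    "ConvergenceReport",
    "ConnectivityError",
    "ConvergenceError",
    "plan_umbrella_centers",
    "extract_windows",
    "wham",
    "shift_to_bulk",
    "bootstrap_errors",
    "convergence_profiles",
    "find_wells",
]


class ConnectivityError(ValueError):
    """Adjacent umbrella windows share no sampled histogram bin."""


class ConvergenceError(RuntimeError):
    """WHAM self-consistency failed to converge within max_iter."""


@dataclass
class UmbrellaWindow:
    """One biased window: centre (nm), z force constant (kJ/mol/nm^2),
    reaction-coordinate samples (nm). ``k_xy`` is provenance bookkeeping
    for the lateral restraint and plays no role in the 1-D estimator."""

    z0: float
    k_z: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    k_xy: float | None = None
    sampling_interval_ps: float = 20.0

    def __post_init__(self):
        if self.k_z < 0:
            raise ValueError("k_z must be >= 0 (0 = unbiased special case)")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")


@dataclass(frozen=True)
class UmbrellaPlan:
    """Window-placement protocol: fine spacing over the first stretch of
    the pull, coarse spacing thereafter."""

    start: float
    total: float = 2.6
    fine_spacing: float = 0.1
    fine_range: float = 2.0
    coarse_spacing: float = 0.2
    pull_rate: float = 0.001  # nm/ps, provenance only

    def __post_init__(self):
        if self.fine_spacing <= 0 or self.coarse_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.total < self.fine_range:
            raise ValueError(
                f"total pull distance {self.total} shorter than the fine "
                f"range {self.fine_range}"
            )


def plan_umbrella_centers(plan: UmbrellaPlan) -> np.ndarray:
    """Window centres: fine steps over the first stretch, coarse beyond.

    The default protocol (total 2.6 nm, 0.1 nm steps over the first
    2.0 nm, 0.2 nm steps after) yields 24 centres.
    """
    n_fine = int(round(plan.fine_range / plan.fine_spacing))
    offsets = [i * plan.fine_spacing for i in range(n_fine + 1)]
    z = plan.fine_range + plan.coarse_spacing
    while z <= plan.total + 1e-9:
        offsets.append(z)
        z += plan.coarse_spacing
    centers = plan.start + np.asarray(offsets)
    centers = np.round(centers / 1e-6) * 1e-6
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centres are not strictly increasing")
    return centers


def extract_windows(pull_traj, plan: UmbrellaPlan, reaction_coordinate):
    """Pick, per planned centre, the pull-trajectory frame whose reaction
    coordinate is nearest that centre (earliest frame on ties).

    ``reaction_coordinate`` is a callable ``frame -> z`` (nm). Any centre
    farther than half the local spacing from every frame raises an error
    listing the unreachable centres.
    """
    centers = plan_umbrella_centers(plan)
    rc = np.array([reaction_coordinate(fr) for fr in pull_traj.frames])
    out, missing = [], []
    for z0 in centers:
        local = plan.fine_spacing if z0 <= plan.start + plan.fine_range + 1e-9 else plan.coarse_spacing
        idx = int(np.argmin(np.abs(rc - z0)))  # argmin -> first (earliest) on ties
        if abs(rc[idx] - z0) > 0.5 * local:
            missing.append(float(z0))
            continue
        out.append((pull_traj.frames[idx], float(z0)))
    if missing:
        raise ValueError(f"pull trajectory does not reach window centres: {missing}")
    return out


# ---------------------------------------------------------------------------
# WHAM


@dataclass
class PMFProfile:
    """Binned free-energy profile. Bins never visited by any window carry
    ``nan`` (an explicit missing marker), not zero."""

    z: np.ndarray
    free_energy: np.ndarray  # kcal/mol
    counts: np.ndarray
    temperature: float
    bin_width: float
    errors: np.ndarray | None = None
    bulk_shifted: bool = False
    n_iterations: int = 0
    window_log_f: np.ndarray | None = None  # converged constants, warm starts

    @property
    def sampled(self) -> np.ndarray:
        return (self.counts > 0) & np.isfinite(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"z_nm": self.z, "G_kcal_mol": self.free_energy, "n_samples": self.counts}
        )
        if self.errors is not None:
            df["G_err_kcal_mol"] = self.errors
        return df


def _log_bin_bias(edges: np.ndarray, z0: float, k_kcal: float, kt: float) -> np.ndarray:
    """log of the bin-averaged Boltzmann factor of a harmonic bias.

    For k = 0 this is identically 0. Underflowing far-tail bins fall back
    to the centre-point value (their weight is negligible; the fallback
    only keeps the log finite and the iteration stable).
    """
    n_bins = len(edges) - 1
    if k_kcal == 0.0:
        return np.zeros(n_bins)
    sigma = np.sqrt(kt / k_kcal)
    t_lo = (edges[:-1] - z0) / sigma
    t_hi = (edges[1:] - z0) / sigma
    width = edges[1:] - edges[:-1]
    diff = ndtr(t_hi) - ndtr(t_lo)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fallback = -0.5 * ((centers - z0) / sigma) ** 2
    with np.errstate(divide="ignore"):
        log_avg = np.log(np.sqrt(2.0 * np.pi) * sigma * diff / width)
    return np.where(diff > 1e-300, log_avg, fallback)


def _check_connectivity(windows, hists) -> None:
    order = np.argsort([w.z0 for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[b] > 0)):
            raise ConnectivityError(
                f"windows at z0={windows[a].z0:g} and z0={windows[b].z0:g} nm "
                "share no sampled bin; the histogram support is disconnected"
            )


def wham(
    windows,
    bin_width: float = 0.05,
    temperature: float = DEFAULT_TEMPERATURE_K,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
    z_range: tuple | None = None,
    initial_log_f: np.ndarray | None = None,
) -> PMFProfile:
    """Estimate the unbiased free-energy profile from umbrella windows.

    ``tolerance`` applies to the max change of the window free-energy
    constants -kT ln f_i per iteration, in kcal/mol. ``z_range`` truncates
    the histogram support (typically to the planned window-centre span;
    samples in the thinly visited tails beyond the outermost windows
    otherwise produce a few high-variance edge bins).
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one umbrella window")
    for w in windows:
        if w.samples.size == 0:
            raise ValueError(f"window at z0={w.z0:g} has no samples")
    kt = kt_kcal(temperature)

    all_samples = np.concatenate([w.samples for w in windows])
    z_lo, z_hi = (all_samples.min(), all_samples.max()) if z_range is None else z_range
    lo = np.floor(z_lo / bin_width) * bin_width
    hi = np.ceil(z_hi / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)

    hists = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    _check_connectivity(windows, hists)

    n_i = hists.sum(axis=1).astype(float)
    log_n = np.log(n_i)
    log_c = np.stack(
        [_log_bin_bias(edges, w.z0, kj_to_kcal(w.k_z), kt) for w in windows]
    )
    pooled = hists.sum(axis=0).astype(float)
    sampled = pooled > 0
    with np.errstate(divide="ignore"):
        log_pooled = np.log(pooled)

    if initial_log_f is not None and len(initial_log_f) == len(windows):
        log_f = np.asarray(initial_log_f, dtype=float).copy()
    else:
        log_f = np.zeros(len(windows))
    g_old = -kt * log_f
    n_done = 0
    for it in range(1, max_iter + 1):
        log_den = logsumexp(log_n[:, None] + log_f[:, None] + log_c, axis=0)
        log_p = np.where(sampled, log_pooled - log_den, -np.inf)
        log_f = -logsumexp(log_p[None, :] + log_c, axis=1)
        g_new = -kt * log_f
        resid = np.max(np.abs(g_new - g_old))
        g_old = g_new
        n_done = it
        if resid < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} kcal/mol)"
        )
    logger.debug("WHAM converged in %d iterations", n_done)

    log_p = log_p - logsumexp(log_p[sampled])
    free_energy = np.where(sampled, -kt * log_p, np.nan)
    return PMFProfile(
        z=0.5 * (edges[:-1] + edges[1:]),
        free_energy=free_energy,
        counts=pooled,
        temperature=temperature,
        bin_width=bin_width,
        n_iterations=n_done,
        window_log_f=log_f,
    )


def _bulk_mask(profile: PMFProfile, bulk) -> np.ndarray:
    sampled = profile.sampled
    if not np.any(sampled):
        raise ValueError("profile has no sampled bins")
    if isinstance(bulk, tuple):
        z_lo, z_hi = bulk
        mask = sampled & (profile.z >= z_lo) & (profile.z <= z_hi)
    else:
        z_min, z_max = profile.z[sampled].min(), profile.z[sampled].max()
        mask = sampled & (profile.z >= z_max - float(bulk) * (z_max - z_min))
    if not np.any(mask):
        raise ValueError("bulk region contains no sampled bins")
    return mask


def shift_to_bulk(profile: PMFProfile, bulk=0.10) -> PMFProfile:
    """Shift so the count-weighted bulk mean is exactly zero.

    ``bulk`` is either the outermost fraction of the sampled z range
    (default: largest-z 10%) or an explicit ``(z_lo, z_hi)`` tuple.
    Bootstrap errors are unchanged (a uniform shift has no variance).
    """
    mask = _bulk_mask(profile, bulk)
    w = profile.counts[mask]
    offset = np.average(profile.free_energy[mask], weights=w)
    return replace(
        profile, free_energy=profile.free_energy - offset, bulk_shifted=True
    )


def bootstrap_errors(
    windows,
    n_boot: int = 200,
    seed: int | None = None,
    discard_fraction: float = 0.0,
    bulk=0.10,
    **wham_kwargs,
) -> np.ndarray:
    """Complete-histogram bootstrap standard errors per bin.

    Each replicate resamples every window's (post-equilibration) samples
    with replacement, reruns WHAM, and shifts to bulk; the per-bin
    standard deviation across replicates is returned on the same bin grid
    as ``wham(windows, **wham_kwargs)``. Replicates that fail to converge
    are dropped (error if more than 20% drop).
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    kept = [
        UmbrellaWindow(
            w.z0,
            w.k_z,
            w.samples[int(discard_fraction * len(w.samples)):],
            k_xy=w.k_xy,
            sampling_interval_ps=w.sampling_interval_ps,
        )
        for w in windows
    ]
    base = shift_to_bulk(wham(kept, **wham_kwargs), bulk=bulk)
    profiles, dropped = [], 0
    for _ in range(n_boot):
        rep = [
            UmbrellaWindow(
                w.z0, w.k_z, rng.choice(w.samples, size=len(w.samples), replace=True)
            )
            for w in kept
        ]
        try:
            prof = shift_to_bulk(
                wham(rep, initial_log_f=base.window_log_f, **wham_kwargs), bulk=bulk
            )
        except (ConvergenceError, ConnectivityError) as exc:
            dropped += 1
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        # replicate grids can differ at the extreme tails; align on base z
        g = np.full_like(base.free_energy, np.nan)
        idx = np.round((prof.z - base.z[0]) / base.bin_width).astype(int)
        ok = (idx >= 0) & (idx < len(g))
        g[idx[ok]] = prof.free_energy[ok]
        profiles.append(g)
    if dropped > 0.2 * n_boot:
        raise ConvergenceError(
            f"{dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    stack = np.stack(profiles)
    with np.errstate(invalid="ignore"):
        errors = np.nanstd(stack, axis=0, ddof=1)
    errors = np.where(base.sampled, errors, np.nan)
    return errors


@dataclass
class ConvergenceReport:
    block_profiles: list
    metrics: np.ndarray  # metric[k] compares block k with block k-1
    equilibration_end_block: int | None
    final_profile: PMFProfile


def convergence_profiles(
    windows,
    n_blocks: int = 2,
    threshold: float = 0.5,
    bulk=0.10,
    **wham_kwargs,
) -> ConvergenceReport:
    """Sequential-interval convergence diagnostic.

    Every window's sample series is cut into ``n_blocks`` equal sequential
    blocks; WHAM runs per block and the metric is the max absolute
    free-energy change between consecutive block profiles (bins sampled
    in both). The first block pair whose metric drops below ``threshold``
    (kcal/mol) marks the end of equilibration; the final profile pools all
    blocks from that point on.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    for w in windows:
        if len(w.samples) < n_blocks:
            raise ValueError(f"window at z0={w.z0:g} has fewer samples than blocks")

    def block(w, k):
        edges = np.linspace(0, len(w.samples), n_blocks + 1).astype(int)
        return UmbrellaWindow(w.z0, w.k_z, w.samples[edges[k]:edges[k + 1]])

    profiles = [
        shift_to_bulk(wham([block(w, k) for w in windows], **wham_kwargs), bulk=bulk)
        for k in range(n_blocks)
    ]
    metrics = np.full(n_blocks, np.nan)
    for k in range(1, n_blocks):
        a, b = profiles[k - 1], profiles[k]
        n = min(len(a.z), len(b.z))
        ga = np.full(n, np.nan)
        gb = np.full(n, np.nan)
        # align on the earlier profile's grid
        for g, p in ((ga, a), (gb, b)):
            idx = np.round((p.z - a.z[0]) / a.bin_width).astype(int)
            ok = (idx >= 0) & (idx < n)
            g[idx[ok]] = p.free_energy[ok]
        both = np.isfinite(ga) & np.isfinite(gb)
        metrics[k] = np.max(np.abs(ga[both] - gb[both])) if np.any(both) else np.nan

    eq_end = None
    for k in range(1, n_blocks):
        if np.isfinite(metrics[k]) and metrics[k] < threshold:
            eq_end = k - 1
            break
    start_block = eq_end if eq_end is not None else 0
    pooled = []
    for w in windows:
        edges = np.linspace(0, len(w.samples), n_blocks + 1).astype(int)
        pooled.append(UmbrellaWindow(w.z0, w.k_z, w.samples[edges[start_block]:]))
    final = shift_to_bulk(wham(pooled, **wham_kwargs), bulk=bulk)
    return ConvergenceReport(profiles, metrics, eq_end, final)


# ---------------------------------------------------------------------------
# well extraction


@dataclass
class WellReport:
    """Local minima of a bulk-shifted profile, ordered by z.

    ``wells`` is a list of ``(z_nm, depth_kcal_mol)``; ``barriers`` holds
    the maximum free energy between consecutive wells.
    """

    wells: list
    barriers: list

    @property
    def global_minimum(self):
        if not self.wells:
            return None
        return min(self.wells, key=lambda w: w[1])


def find_wells(profile: PMFProfile) -> WellReport:
    """Locate significant wells on a bulk-shifted profile.

    A well is a local minimum whose prominence (height of the enclosing
    barrier above the minimum) exceeds the combined standard error of the
    minimum bin and its barrier bins — the prominence is a difference of
    two estimates, so both uncertainties enter. Without bootstrap errors
    any strictly positive prominence qualifies. A monotone or flat
    profile yields an empty report.
    """
    if not profile.bulk_shifted:
        raise ValueError("shift the profile to bulk before extracting wells")
    sampled = profile.sampled
    wells = []
    idx = np.flatnonzero(sampled)
    if idx.size == 0:
        return WellReport([], [])
    # scan contiguous sampled segments independently
    splits = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, splits + 1):
        if len(seg) < 3:
            continue
        g = profile.free_energy[seg]
        peaks, _ = find_peaks(-g)
        if peaks.size == 0:
            continue
        prom, left_bases, right_bases = peak_prominences(-g, peaks)
        for p, pr, lb, rb in zip(peaks, prom, left_bases, right_bases):
            err = 0.0
            if profile.errors is not None:
                bins = [seg[p], seg[lb], seg[rb]]
                errs = [
                    profile.errors[b]
                    for b in bins
                    if np.isfinite(profile.errors[b])
                ]
                if errs:
                    err = float(np.sqrt(errs[0] ** 2 + max(errs[1:], default=0.0) ** 2))
            if pr > err:
                wells.append((float(profile.z[seg[p]]), float(g[p])))
    wells.sort(key=lambda w: w[0])
    barriers = []
    z = profile.z
    for (z_a, _), (z_b, _) in zip(wells[:-1], wells[1:]):
        between = sampled & (z > z_a) & (z < z_b)
        barriers.append(float(np.max(profile.free_energy[between])))
    return WellReport(wells, barriers)


# ---------------------------------------------------------------------------
# window file I/O (two-column TSV + YAML sidecar with restraint metadata)


def write_window_file(window: UmbrellaWindow, path) -> None:
    """Write a window as TSV (time_ps, z_nm) with a YAML sidecar holding
    z0/k_z/k_xy metadata (same stem, .yaml suffix)."""
    from pathlib import Path

    import yaml

    path = Path(path)
    times = window.sampling_interval_ps * np.arange(len(window.samples))
    with open(path, "w") as fh:
        fh.write("time_ps\tz_nm\n")
        for t, z in zip(times, window.samples):
            fh.write("%.17g\t%.17g\n" % (t, z))
    meta = {"z0": float(window.z0), "k_z": float(window.k_z)}
    if window.k_xy is not None:
        meta["k_xy"] = float(window.k_xy)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_window_file(path) -> UmbrellaWindow:
    from pathlib import Path

    import yaml

    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    dt = float(data[1, 0] - data[0, 0]) if len(data) > 1 else 20.0
    return UmbrellaWindow(
        z0=float(meta["z0"]),
        k_z=float(meta["k_z"]),
        samples=data[:, 1],
        k_xy=meta.get("k_xy"),
        sampling_interval_ps=dt,
    )
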
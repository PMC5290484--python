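"""Equilibrium binding-curve construction and 1:1 Langmuir fitting.

The model is B(C) = Bmax C / (KD + C): ``B`` the equilibrium response at
analyte concentration ``C``, ``KD`` the dissociation constant (the
concentration at half-maximal binding), ``Bmax`` the saturation response.
Fits are unweighted nonlinear least squares in log-parameters, which
enforces positivity without constraints; standard errors come from the
curvature (Jacobian) at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "BindingCurve",
    "LangmuirFit",
    "langmuir",
    "serial_dilution",
    "fit_langmuir",
    "compare_conditions",
]


def langmuir(c, kd: float, bmax: float):
    """1:1 Langmuir adsorption isotherm B = Bmax C / (KD + C)."""
    c = np.asarray(c, dtype=float)
    return bmax * c / (kd + c)


@dataclass
class BindingCurve:
    """Concentration-response data (concentrations in uM, responses in
    instrument response units); optional replicate response columns."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None  # (n_replicates, n_points)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration/response lengths differ")
        if self.replicates is not None:
            self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
            if self.replicates.shape[1] != len(self.concentrations):
                raise ValueError("replicate columns do not match concentrations")

    def sorted(self) -> "BindingCurve":
        order = np.argsort(self.concentrations)
        return BindingCurve(
            self.concentrations[order],
            self.responses[order],
            None if self.replicates is None else self.replicates[:, order],
        )

    def mean_responses(self) -> np.ndarray:
        """Replicate-averaged responses (the plain responses if no
        replicates were recorded)."""
        if self.replicates is None:
            return self.responses
        return self.replicates.mean(axis=0)


def serial_dilution(c_max: float, n_points: int, factor: float = 2.0) -> np.ndarray:
    """Concentration series from a top concentration by serial dilution:
    [c_max, c_max/factor, ..., c_max/factor^(n_points-1)]."""
    if c_max <= 0:
        raise ValueError("top concentration must be positive")
    if n_points < 1:
        raise ValueError("need at least one point")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    return c_max / factor ** np.arange(n_points)


@dataclass
class LangmuirFit:
    kd: float  # uM
    bmax: float
    kd_se: float
    bmax_se: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, c):
        return langmuir(c, self.kd, self.bmax)


def fit_langmuir(curve: BindingCurve, init: tuple | None = None) -> LangmuirFit:
    """Fit the 1:1 Langmuir model by nonlinear least squares.

    Positivity of (KD, Bmax) is enforced by fitting their logarithms.
    Default initial guess: Bmax = 1.1 max(B), KD = the concentration whose
    response is nearest Bmax/2. Non-convergence returns a flagged result
    with diagnostics rather than raising.
    """
    curve = curve.sorted()
    c = curve.concentrations
    b = curve.mean_responses()
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.allclose(b, 0):
        raise ValueError("all responses are zero; nothing to fit")
    if init is None:
        bmax0 = 1.1 * float(b.max())
        kd0 = float(c[np.argmin(np.abs(b - bmax0 / 2))])
    else:
        kd0, bmax0 = init
    if kd0 <= 0 or bmax0 <= 0:
        raise ValueError("initial KD and Bmax must be positive")

    def model(cc, log_kd, log_bmax):
        return langmuir(cc, np.exp(log_kd), np.exp(log_bmax))

    try:
        popt, pcov = curve_fit(
            model, c, b, p0=[np.log(kd0), np.log(bmax0)], maxfev=20000
        )
    except RuntimeError as exc:
        logger.warning("Langmuir fit failed to converge: %s", exc)
        return LangmuirFit(
            kd=np.nan, bmax=np.nan, kd_se=np.nan, bmax_se=np.nan,
            rss=np.nan, converged=False, message=str(exc),
        )
    kd, bmax = np.exp(popt)
    perr = np.sqrt(np.diag(pcov))
    resid = b - langmuir(c, kd, bmax)
    return LangmuirFit(
        kd=float(kd),
        bmax=float(bmax),
        kd_se=float(kd * perr[0]),  # delta method from log-parameter SE
        bmax_se=float(bmax * perr[1]),
        rss=float(np.sum(resid**2)),
        converged=True,
    )


def compare_conditions(fits: dict) -> pd.DataFrame:
    """Pairwise KD ratios across conditions with propagated relative
    errors. Failed fits are excluded with a warning; at least two
    successful fits are required."""
    ok = {}
    for name, fit in fits.items():
        if fit.converged and np.isfinite(fit.kd):
            ok[name] = fit
        else:
            logger.warning("condition %r excluded: fit did not converge", name)
    if len(ok) < 2:
        raise ValueError("need at least 2 successful fits to compare")
    rows = []
    names = sorted(ok)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            fa, fb = ok[a], ok[b]
            ratio = fa.kd / fb.kd
            rel = np.sqrt((fa.kd_se / fa.kd) ** 2 + (fb.kd_se / fb.kd) ** 2)
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "kd_a_uM": fa.kd,
                    "kd_b_uM": fb.kd,
                    "kd_ratio": ratio,
                    "kd_ratio_se": ratio * rel,
                }
            )
    return pd.DataFrame(rows)
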
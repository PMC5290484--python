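"""Analytic 1-D potentials used as ground truth by the synthetic generators.

A potential is a small frozen object with a vectorised ``__call__``
returning energies in kcal/mol. Three forms cover everything the package
needs: a flat potential, a harmonic well, and a sum of two Gaussian wells
(the "double well" used to emulate a membrane-binding free-energy profile
with a contact minimum and a shallower outer minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kj_to_kcal

__all__ = ["Potential1D", "flat", "harmonic", "double_well", "make_potential"]


@dataclass(frozen=True)
class Potential1D:
    """Analytic potential U(z), energies in kcal/mol, z in nm."""

    tag: str
    params: dict = field(default_factory=dict)

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.tag == "flat":
            return np.zeros_like(z)
        if self.tag == "harmonic":
            return 0.5 * p["k"] * (z - p["z0"]) ** 2
        if self.tag == "double_well":
            w = p["width"]
            return p["d1"] * np.exp(-((z - p["z1"]) ** 2) / (2.0 * w * w)) + p[
                "d2"
            ] * np.exp(-((z - p["z2"]) ** 2) / (2.0 * w * w))
        raise ValueError(f"unknown potential tag {self.tag!r}")


def flat() -> Potential1D:
    return Potential1D("flat")


def harmonic(z0: float, k: float) -> Potential1D:
    """Harmonic well with minimum at ``z0`` (nm), stiffness ``k`` kcal/mol/nm^2."""
    if k <= 0:
        raise ValueError("harmonic stiffness must be positive")
    return Potential1D("harmonic", {"z0": float(z0), "k": float(k)})


def double_well(d1: float, z1: float, d2: float, z2: float, width: float) -> Potential1D:
    """Two Gaussian wells of (signed) depths ``d1``, ``d2`` kcal/mol.

    Depths are the well energies relative to bulk, so a binding well has a
    negative depth. ``width`` is the common Gaussian sigma in nm.
    """
    if width <= 0:
        raise ValueError("well width must be positive")
    return Potential1D(
        "double_well",
        {"d1": float(d1), "z1": float(z1), "d2": float(d2), "z2": float(z2), "width": float(width)},
    )


def make_potential(tag: str, units: str = "kcal/mol", **params) -> Potential1D:
    """Build a potential from a config tag + parameters.

    ``units`` may be ``"kcal/mol"`` (default) or ``"kJ/mol"``; energetic
    parameters (k, d1, d2) are converted to kcal/mol on construction.
    """
    if units not in ("kcal/mol", "kJ/mol"):
        raise ValueError(f"unknown energy units {units!r}")
    if units == "kJ/mol":
        params = {
            k: (kj_to_kcal(v) if k in ("k", "d1", "d2") else v) for k, v in params.items()
        }
    if tag == "flat":
        return flat()
    if tag == "harmonic":
        return harmonic(**params)
    if tag == "double_well":
        return double_well(**params)
    raise ValueError(f"unknown potential tag {tag!r}")
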
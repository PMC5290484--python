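"""Physical constants and analysis defaults shared across the package.

All energies are kept in kcal/mol internally; force constants quoted in
kJ/mol/nm^2 (the unit customary for umbrella restraints) are converted at
the module boundary with the single factor below.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Exact thermochemical calorie conversion.
KJ_PER_KCAL = 4.184

#: Coarse-grained simulation temperature (K).
DEFAULT_TEMPERATURE_K = 323.0

#: A protein counts as membrane-bound when the z distance between the
#: protein and bilayer centres of mass is strictly below this (nm).
BOUND_THRESHOLD_NM = 4.75

#: A PIP lipid is in contact when its phosphate is within this distance
#: of any protein particle (nm, inclusive).
CONTACT_CUTOFF_NM = 1.0

#: Width of the annulus around the protein surface used for clustering
#: statistics (nm).
ANNULUS_WIDTH_NM = 1.0


def kt_kcal(temperature_k: float) -> float:
    """Thermal energy kT in kcal/mol at the given temperature."""
    return KB_KCAL_PER_MOL_K * temperature_k


def kj_to_kcal(x: float) -> float:
    """Convert an energy (or force constant) from kJ- to kcal-based units."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL
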
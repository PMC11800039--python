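"""Unit conversions for the internal (Å, fs, amu, kcal/mol) unit system.

The simulator works internally in Ångström, femtosecond, atomic mass unit
and kcal/mol.  User-facing forces are reported in pN and spring stiffness is
entered in N/cm, matching the conventions of single-molecule pulling work.
A single conversion layer lives here; nothing else in the package hard-codes
unit factors.
"""

from __future__ import annotations

__all__ = [
    "KB_KCAL_MOL_K",
    "KCAL_MOL_A_TO_PN",
    "KCAL_MOL_TO_AKMA",
    "convert_units",
]

#: Boltzmann constant, kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872041

#: 1 kcal/(mol Å) expressed in pN.
KCAL_MOL_A_TO_PN = 69.4786

#: 1 kcal/mol expressed in amu Å²/fs² (the internal "mechanical" energy unit).
#: Exact: 4184 J/mol / (1 g/mol) = 4.184e6 m²/s² = 4.184e-4 Å²/fs².
KCAL_MOL_TO_AKMA = 4.184e-4

# Conversion graph: every unit maps to a canonical base unit with a scale.
# Dimensions: force/length (stiffness), speed, force rate, energy,
# force, temperature.
_CANONICAL = {
    # stiffness -> pN/Å
    "N/cm": ("stiffness", 100.0),  # 0.01 N/cm = 1 N/m = 100 pN/Å... see note
    "pN/A": ("stiffness", 1.0),
    "kcal/(mol*A^2)": ("stiffness", KCAL_MOL_A_TO_PN),
    # speed -> Å/fs
    "A/fs": ("speed", 1.0),
    # force rate -> pN/fs
    "pN/fs": ("force_rate", 1.0),
    # energy -> kcal/mol
    "kcal/mol": ("energy", 1.0),
    # force -> pN
    "pN": ("force", 1.0),
    "kcal/(mol*A)": ("force", KCAL_MOL_A_TO_PN),
    # temperature -> K
    "K": ("temperature", 1.0),
}

# Note on N/cm: 1 N/cm = 100 N/m = 100 * (1e12 pN) / (1e10 Å) = 1e4 pN/Å.
# The table stores the scale for the *unit itself*:
#   x N/cm = x * 1e4 pN/Å.  (0.01 N/cm -> 100 pN/Å.)
_CANONICAL["N/cm"] = ("stiffness", 1.0e4)

_ALIASES = {
    "n/cm": "N/cm",
    "pn/a": "pN/A",
    "pn/Å": "pN/A",
    "pN/Å": "pN/A",
    "a/fs": "A/fs",
    "Å/fs": "A/fs",
    "pn/fs": "pN/fs",
    "kcal/mol": "kcal/mol",
    "pn": "pN",
    "k": "K",
    "kcal/(mol*Å)": "kcal/(mol*A)",
    "kcal/(mol*Å^2)": "kcal/(mol*A^2)",
}


def _resolve(unit: str) -> tuple[str, float]:
    key = _ALIASES.get(unit, _ALIASES.get(unit.lower(), unit))
    if key not in _CANONICAL:
        raise ValueError(f"unknown unit {unit!r}; known: {sorted(_CANONICAL)}")
    return _CANONICAL[key]


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension.

    Supported units: N/cm, pN/A, kcal/(mol*A^2) (stiffness); A/fs (speed);
    pN/fs (force rate); kcal/mol (energy); pN, kcal/(mol*A) (force); K.

    Raises
    ------
    ValueError
        If either unit is unknown or the two units are dimensionally
        incompatible.
    """
    dim_from, scale_from = _resolve(from_unit)
    dim_to, scale_to = _resolve(to_unit)
    if dim_from != dim_to:
        raise ValueError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return value * scale_from / scale_to


def pulling_rate_pn_per_fs(stiffness_n_per_cm: float, tip_speed_a_per_fs: float) -> float:
    """Pulling rate k·v in pN/fs from stiffness in N/cm and tip speed in Å/fs.

    For the defaults k = 0.01 N/cm and v = 0.002 Å/fs this is 0.20 pN/fs:
    the tension on a held bead grows by 0.2 pN every femtosecond.
    """
    k_pn_a = convert_units(stiffness_n_per_cm, "N/cm", "pN/A")
    return k_pn_a * tip_speed_a_per_fs
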
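"""Shared two-state thermodynamic relations.

Every fitting module in this package reduces an observable to the folded
fraction of a two-state equilibrium N <-> U with equilibrium constant
``Ku = [U]/[N] = exp(-dG/(R*T))``.  This module holds that core algebra in
one place, in consistent units: energies in kJ/mol, temperatures in K.
User-facing readers convert degrees Celsius on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_KJ",
    "T_REF",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "TwoStateThermalParams",
    "LEMParams",
    "BaselinePair",
    "equilibrium_constant",
    "folded_fraction",
    "dG_thermal",
    "dG_chemical",
    "dG_from_populations",
]

#: Ideal gas constant in kJ/(mol K).
R_KJ = 8.314e-3

#: Reference temperature (25 degC) used for chemical denaturation and CEST energies.
T_REF = 298.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15


@dataclass(frozen=True)
class TwoStateThermalParams:
    """Melting temperature and van't Hoff unfolding enthalpy at Tm.

    Parameters
    ----------
    Tm : float
        Melting temperature in K (> 0).
    dH_Tm : float
        Unfolding enthalpy at Tm in kJ/mol; positive for cooperative
        unfolding.
    """

    Tm: float
    dH_Tm: float

    def __post_init__(self) -> None:
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive (got {self.Tm})")
        if not math.isfinite(self.dH_Tm):
            raise ValueError("dH_Tm must be finite")


@dataclass(frozen=True)
class LEMParams:
    """Linear-extrapolation parameters for chemical denaturation.

    ``dG_H2O`` is the unfolding free energy in water (kJ/mol) and
    ``m_value`` its denaturant dependence (kJ/(mol M)); the transition
    midpoint is ``dG_H2O / m_value``.
    """

    dG_H2O: float
    m_value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dG_H2O) and math.isfinite(self.m_value)):
            raise ValueError("LEM parameters must be finite")


@dataclass(frozen=True)
class BaselinePair:
    """Linear native/unfolded baselines: intercepts yN/yU, slopes mN/mU.

    For thermal fits the slopes are per K with the baseline anchored at Tm
    (signal = yN + mN*(T - Tm)); for chemical fits they are per M anchored
    at zero denaturant (signal = yN + mN*[denat]).
    """

    yN: float
    mN: float
    yU: float
    mU: float

    def __post_init__(self) -> None:
        for name in ("yN", "mN", "yU", "mU"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"baseline {name} must be finite")


def equilibrium_constant(dG, T):
    """Unfolding equilibrium constant Ku = exp(-dG/(R*T)).

    ``dG`` in kJ/mol, ``T`` in K.  Accepts scalars or numpy arrays in
    ``dG``; ``T`` must be positive.
    """
    import numpy as np

    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive (K)")
    return np.exp(-np.asarray(dG, dtype=float) / (R_KJ * T))


def folded_fraction(Ku):
    """Fraction of folded molecules, fN = 1/(1 + Ku)."""
    import numpy as np

    if np.any(np.asarray(Ku) < 0):
        raise ValueError("Ku must be non-negative")
    return 1.0 / (1.0 + np.asarray(Ku, dtype=float))


def dG_thermal(T, p: TwoStateThermalParams):
    """Unfolding free energy of the spectroscopic-melt model.

    dG(T) = dH(Tm) * (1 - T/Tm) -- no heat-capacity term; the DSC module
    carries the dCp-dependent form.  Zero exactly at T = Tm.
    """
    import numpy as np

    if np.any(np.asarray(T) <= 0):
        raise ValueError("temperature must be positive (K)")
    return p.dH_Tm * (1.0 - np.asarray(T, dtype=float) / p.Tm)


def dG_chemical(denat, p: LEMParams):
    """Linear-extrapolation free energy dG = dG_H2O - m*[denat]."""
    import numpy as np

    if np.any(np.asarray(denat) < 0):
        raise ValueError("denaturant concentration must be >= 0")
    return p.dG_H2O - p.m_value * np.asarray(denat, dtype=float)


def dG_from_populations(pA: float, pB: float, T: float = T_REF) -> float:
    """Free-energy gap between two exchanging species from their populations.

    Returns -R*T*ln(pB/pA) in kJ/mol; positive when the minor species B is
    less populated than A.  Populations must be positive and sum to 1
    within 1e-6.
    """
    if pA <= 0 or pB <= 0:
        raise ValueError("populations must be positive")
    if abs(pA + pB - 1.0) > 1e-6:
        raise ValueError(f"populations must sum to 1 (got {pA + pB})")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return -R_KJ * T * math.log(pB / pA)
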
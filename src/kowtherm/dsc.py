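"""Two-state DSC thermogram model with a temperature-dependent dCp.

The molar heat capacity of a two-state unfolder is modelled as

    Cp(T) = Cp0(T) + dCp_int(T) + dCp_exc(T)

with a linear native baseline Cp0 = a0 + b0*T (the intercept absorbs the
instrument-specific offset), a parabolic unfolded-native heat-capacity
difference dCp_u(T) = a + b*T + c*T^2, and

    dHu(T) = dHu(Tm) + a*(T-Tm) + b/2*(T^2-Tm^2) + c/3*(T^3-Tm^3)
    dSu(T) = dHu(Tm)/Tm + a*ln(T/Tm) + b*(T-Tm) + c/2*(T^2-Tm^2)
    Ku     = exp(-(dHu - T*dSu)/(R*T))
    dCp_int = dCp_u * Ku/(1+Ku)          (unfolded-fraction weighted step)
    dCp_exc = dHu^2/(R*T^2) * Ku/(1+Ku)^2  (excess heat of the transition)

During fitting a0, b0, a, b, Tm and dHu(Tm) float while the quadratic
coefficient c is held fixed; c can be obtained from the theoretical
unfolded-state heat capacity of the sequence (``unfolded_cp_points`` +
``parabola_quadratic_coefficient``) or supplied directly.

Units: T in K, Cp in kJ/(K mol), dH in kJ/mol.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import expit

from .thermo import R_KJ, celsius_to_kelvin

__all__ = [
    "Thermogram",
    "DSCModelParams",
    "ResidueCpTable",
    "DSCFitResult",
    "load_default_cp_table",
    "unfolded_cp_points",
    "parabola_quadratic_coefficient",
    "dsc_model_cp",
    "fit_dsc",
]

#: Temperatures (degC) at which the unfolded-state Cp is tabulated.
CP_TABLE_TEMPS_C = (5.0, 25.0, 50.0, 75.0, 100.0, 125.0)


@dataclass
class Thermogram:
    """A molar-normalized, buffer-subtracted DSC scan."""

    T: np.ndarray
    Cp: np.ndarray
    scan_rate_K_min: float | None = None
    protein: str | None = None
    buffer: str | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        Cp = np.asarray(self.Cp, dtype=float)
        if T.shape != Cp.shape or T.ndim != 1:
            raise ValueError("T and Cp must be 1-D arrays of equal length")
        if T.size < 50:
            raise ValueError("thermogram needs at least 50 points")
        if np.any(np.diff(T) <= 0):
            order = np.argsort(T)
            T, Cp = T[order], Cp[order]
            if np.any(np.diff(T) <= 0):
                raise ValueError("temperature axis must be strictly increasing")
        if not (np.all(np.isfinite(T)) and np.all(np.isfinite(Cp))):
            raise ValueError("thermogram contains non-finite values")
        self.T, self.Cp = T, Cp


@dataclass(frozen=True)
class DSCModelParams:
    """Native baseline, dCp parabola, and transition parameters."""

    a0: float  # kJ/(K mol)
    b0: float  # kJ/(K^2 mol)
    a: float   # kJ/(K mol)
    b: float   # kJ/(K^2 mol)
    c: float   # kJ/(K^3 mol), fixed during fitting
    Tm: float  # K
    dH_Tm: float  # kJ/mol

    def __post_init__(self) -> None:
        if not self.Tm > 0:
            raise ValueError("Tm must be positive")

    def dCp_u(self, T):
        """Unfolded-minus-native heat capacity difference at T."""
        T = np.asarray(T, dtype=float)
        return self.a + self.b * T + self.c * T**2

    def dH_u(self, T):
        T = np.asarray(T, dtype=float)
        Tm = self.Tm
        return (
            self.dH_Tm
            + self.a * (T - Tm)
            + self.b / 2.0 * (T**2 - Tm**2)
            + self.c / 3.0 * (T**3 - Tm**3)
        )

    def dS_u(self, T):
        T = np.asarray(T, dtype=float)
        Tm = self.Tm
        return (
            self.dH_Tm / Tm
            + self.a * np.log(T / Tm)
            + self.b * (T - Tm)
            + self.c / 2.0 * (T**2 - Tm**2)
        )

    def dG_u(self, T):
        T = np.asarray(T, dtype=float)
        return self.dH_u(T) - T * self.dS_u(T)


@dataclass
class ResidueCpTable:
    """Per-residue unfolded-state heat-capacity contributions.

    ``residues`` maps one-letter code -> 6 values (J/(K mol)) at
    ``CP_TABLE_TEMPS_C``; ``terminal`` holds the additive end-group
    correction per chain at the same temperatures.
    """

    residues: dict[str, tuple[float, ...]]
    terminal: tuple[float, ...] = (0.0,) * 6
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.residues)
        if missing:
            raise ValueError(f"Cp table incomplete; missing residues: {sorted(missing)}")
        for aa, vals in self.residues.items():
            if len(vals) != len(CP_TABLE_TEMPS_C):
                raise ValueError(f"residue {aa}: expected {len(CP_TABLE_TEMPS_C)} values")


def load_default_cp_table() -> ResidueCpTable:
    """Load the packaged unfolded-state Cp table.

    The packaged file carries synthetic stand-in values (see its header):
    they reproduce the characteristic rise-and-flatten temperature
    dependence of unfolded-polypeptide heat capacities but are not a
    transcription of a published table.  Supply your own table, or the
    quadratic coefficient ``c`` directly, for publication-grade work.
    """
    ref = resources.files("kowtherm.data") / "residue_cp_unfolded_synthetic.csv"
    with resources.as_file(ref) as path:
        return read_cp_table(path)


def read_cp_table(path: str | Path) -> ResidueCpTable:
    residues: dict[str, tuple[float, ...]] = {}
    terminal = (0.0,) * 6
    provenance = ""
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            provenance = first.lstrip("# ").strip()
            reader = csv.DictReader(fh)
        else:
            fh.seek(0)
            reader = csv.DictReader(fh)
        cols = [f"cp_{int(t)}C" for t in CP_TABLE_TEMPS_C]
        for row in reader:
            key = row["residue"].strip()
            vals = tuple(float(row[c]) for c in cols)
            if key.upper() == "TERMINAL":
                terminal = vals
            else:
                residues[key.upper()] = vals
    return ResidueCpTable(residues=residues, terminal=terminal, provenance=provenance)


def unfolded_cp_points(
    sequence: str, table: ResidueCpTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical unfolded-state Cp of a sequence at the six tabulated temperatures.

    Returns ``(T_kelvin, Cp_kJ_per_K_mol)``; the sum over residue
    contributions plus one terminal correction per chain.
    """
    if table is None:
        table = load_default_cp_table()
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    totals = np.array(table.terminal, dtype=float)
    for i, aa in enumerate(seq):
        if aa not in table.residues:
            raise ValueError(f"residue {aa!r} at position {i + 1} not in Cp table")
        totals = totals + np.array(table.residues[aa], dtype=float)
    T = np.array([celsius_to_kelvin(t) for t in CP_TABLE_TEMPS_C])
    return T, totals / 1000.0  # J -> kJ


def parabola_quadratic_coefficient(T, Cp) -> float:
    """Quadratic coefficient of an OLS parabola through (T, Cp) points."""
    T = np.asarray(T, dtype=float)
    Cp = np.asarray(Cp, dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    coeffs = np.polyfit(T, Cp, 2)
    return float(coeffs[0])


def dsc_model_cp(T, p: DSCModelParams):
    """Model molar heat capacity at temperature(s) T (K).

    The unfolded fraction and the Ku/(1+Ku)^2 factor are evaluated through
    the logistic function of -dG/(R*T), so large |dG| cannot overflow.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    dH = p.dH_u(T)
    dG = dH - T * p.dS_u(T)
    fU = expit(-dG / (R_KJ * T))  # Ku/(1+Ku)
    cp0 = p.a0 + p.b0 * T
    dcp_int = p.dCp_u(T) * fU
    dcp_exc = dH**2 / (R_KJ * T**2) * fU * (1.0 - fU)
    return cp0 + dcp_int + dcp_exc


@dataclass
class DSCFitResult:
    params: DSCModelParams
    errors: dict[str, float]
    converged: bool
    residual_norm: float
    message: str = ""
    warnings: list[str] = field(default_factory=list)


def fit_dsc(
    thermogram: Thermogram,
    c_fixed: float,
    init: DSCModelParams | None = None,
) -> DSCFitResult:
    """Fit the two-state DSC model; a0, b0, a, b, Tm, dH_Tm float, c is fixed.

    Expects a buffer-subtracted, molar-normalized thermogram.  Raises
    RuntimeError on non-convergence; a fitted Tm outside the scanned
    range or an unresolved peak sets a warning instead.
    """
    T, Cp = thermogram.T, thermogram.Cp

    def residuals(theta: np.ndarray) -> np.ndarray:
        a0, b0, a, b, Tm, dH = theta
        p = DSCModelParams(a0=a0, b0=b0, a=a, b=b, c=c_fixed, Tm=Tm, dH_Tm=dH)
        return dsc_model_cp(T, p) - Cp

    if init is not None:
        theta0 = np.array([init.a0, init.b0, init.a, init.b, init.Tm, init.dH_Tm])
        starts = [theta0]
    else:
        starts = _heuristic_dsc_starts(T, Cp, c_fixed)

    lo = [-np.inf, -np.inf, -np.inf, -np.inf, T.min() - 5.0, 1.0]
    hi = [np.inf, np.inf, np.inf, np.inf, T.max() + 5.0, 5000.0]

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("DSC fit failed to converge from any start")

    a0, b0, a, b, Tm, dH = best.x
    params = DSCModelParams(a0=a0, b0=b0, a=a, b=b, c=c_fixed, Tm=Tm, dH_Tm=dH)

    m, n = best.jac.shape
    s2 = 2.0 * best.cost / max(m - n, 1)
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    errors = dict(zip(["a0", "b0", "a", "b", "Tm", "dH_Tm"], se))

    result = DSCFitResult(
        params=params,
        errors=errors,
        converged=bool(best.success),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        message=str(best.message),
    )
    if not (T.min() <= Tm <= T.max()):
        result.warnings.append("fitted Tm lies outside the scanned range; unreliable")
    # peak prominence check: excess heat at Tm should rise above the baseline noise
    peak_height = params.dH_Tm**2 / (4.0 * R_KJ * params.Tm**2)
    resid_sd = result.residual_norm / math.sqrt(len(T))
    if peak_height < 5.0 * resid_sd:
        result.warnings.append("no resolvable transition peak; parameters unreliable")
    # degeneracy check: a straight line explaining the scan equally well means
    # there is no transition for the model to fit
    slope, icpt = np.polyfit(T, Cp, 1)
    ssr_line = float(np.sum((Cp - (icpt + slope * T)) ** 2))
    ssr_fit = 2.0 * best.cost
    if ssr_line <= 0 or ssr_fit > 0.95 * ssr_line:
        result.warnings.append("no resolvable transition peak; parameters unreliable")
    return result


def _heuristic_dsc_starts(T: np.ndarray, Cp: np.ndarray, c_fixed: float) -> list[np.ndarray]:
    k = max(len(T) // 10, 5)
    b0, a0 = np.polyfit(T[:k], Cp[:k], 1)
    excess = Cp - (a0 + b0 * T)
    i_peak = int(np.argmax(excess))
    Tm0 = float(T[i_peak])
    peak = max(float(excess[i_peak]), 1e-3)
    # two-state peak height: dCp_exc(Tm) = dH^2/(4 R Tm^2)
    dH0 = 2.0 * Tm0 * math.sqrt(R_KJ * peak)
    # post-transition offset informs the linear part of dCp_u
    tail = float(np.median(Cp[-k:]) - (a0 + b0 * np.median(T[-k:])))
    a_init = tail - c_fixed * Tm0**2
    return [
        np.array([a0, b0, a_init, 0.0, Tm0, dH0]),
        np.array([a0, b0, 0.0, 0.0, Tm0, 1.5 * dH0]),
        np.array([a0, b0, a_init, 0.0, Tm0, 0.6 * dH0]),
    ]
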
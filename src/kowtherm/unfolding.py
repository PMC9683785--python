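"""Two-state fits of spectroscopic unfolding curves.

Thermal melts (CD, fluorescence) are fitted to

    S(T) = fN*(yN + mN*(T - Tm)) + (1 - fN)*(yU + mU*(T - Tm)),
    fN   = 1/(1 + exp(-dH(Tm)*(1 - T/Tm)/(R*T)))

and chemical denaturation series (CD, fluorescence, or normalized NMR peak
volumes) to the linear extrapolation method (LEM)

    S(x) = fN*(yN + mN*x) + (1 - fN)*(yU + mU*x),
    fN   = 1/(1 + exp(-(dG_H2O - m*x)/(R*T)))

with x the denaturant molarity.  Both are unweighted nonlinear least
squares with asymptotic standard errors from the scaled covariance.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .thermo import (
    T_REF,
    BaselinePair,
    LEMParams,
    TwoStateThermalParams,
    dG_chemical,
    dG_thermal,
    equilibrium_constant,
    folded_fraction,
)

__all__ = [
    "Technique",
    "AxisKind",
    "UnfoldingCurve",
    "ThermalFitResult",
    "LEMFitResult",
    "mrw_normalize",
    "predict_thermal_signal",
    "predict_chemical_signal",
    "fit_thermal_two_state",
    "fit_chemical_lem",
    "midpoint",
]


class Technique(str, enum.Enum):
    CD_far_UV = "CD_far_UV"
    CD_near_UV = "CD_near_UV"
    fluorescence = "fluorescence"
    NMR_peak_volume = "NMR_peak_volume"


class AxisKind(str, enum.Enum):
    temperature = "temperature"
    urea = "urea"
    GdmCl = "GdmCl"


@dataclass
class UnfoldingCurve:
    """An (x, signal) unfolding series with technique/condition metadata.

    ``x`` is temperature in K (``axis_kind = temperature``) or denaturant
    molarity; arrays are sorted by x on construction and must hold at
    least 8 finite points for fitting.
    """

    x: np.ndarray
    signal: np.ndarray
    technique: Technique = Technique.CD_far_UV
    axis_kind: AxisKind = AxisKind.temperature
    pH: float | None = None
    protein: str | None = None
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if x.shape != s.shape or x.ndim != 1:
            raise ValueError("x and signal must be 1-D arrays of equal length")
        keep = np.isfinite(x) & np.isfinite(s)
        x, s = x[keep], s[keep]
        order = np.argsort(x)
        self.x, self.signal = x[order], s[order]
        if np.any(np.diff(self.x) <= 0):
            # collapse exact duplicates by averaging so x is strictly increasing
            ux, inv = np.unique(self.x, return_inverse=True)
            self.signal = np.bincount(inv, weights=self.signal) / np.bincount(inv)
            self.x = ux
        self.technique = Technique(self.technique)
        self.axis_kind = AxisKind(self.axis_kind)

    def __len__(self) -> int:
        return self.x.size


@dataclass
class FitDiagnostics:
    converged: bool
    residual_norm: float
    n_points: int
    message: str = ""
    baseline_coverage_ok: bool = True
    multistate_suspected: bool = False
    runs_test_p: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class ThermalFitResult:
    params: TwoStateThermalParams
    baselines: BaselinePair
    errors: dict[str, float]
    diagnostics: FitDiagnostics


@dataclass
class LEMFitResult:
    params: LEMParams
    baselines: BaselinePair
    errors: dict[str, float]
    diagnostics: FitDiagnostics

    @property
    def midpoint(self) -> float:
        return midpoint(self.params)


def mrw_normalize(theta_mdeg, n_residues: int, conc_mM: float, path_cm: float):
    """Mean residue-weighted ellipticity, 100*theta/(N*c*d).

    ``theta_mdeg`` ellipticity in mdeg, ``conc_mM`` protein concentration
    in mM, ``path_cm`` cuvette pathlength in cm.  Result in deg cm^2/dmol.
    """
    if n_residues <= 0 or conc_mM <= 0 or path_cm <= 0:
        raise ValueError("n_residues, conc_mM and path_cm must be positive")
    return 100.0 * np.asarray(theta_mdeg, dtype=float) / (n_residues * conc_mM * path_cm)


def midpoint(params: LEMParams) -> float:
    """Transition midpoint [denat]_1/2 = dG_H2O / m."""
    if params.m_value <= 0:
        raise ValueError("m value must be positive for a meaningful midpoint")
    return params.dG_H2O / params.m_value


def predict_thermal_signal(T, params: TwoStateThermalParams, baselines: BaselinePair):
    """Evaluate the two-state thermal model on a temperature grid (K)."""
    T = np.asarray(T, dtype=float)
    fN = folded_fraction(equilibrium_constant(dG_thermal(T, params), T))
    dT = T - params.Tm
    return fN * (baselines.yN + baselines.mN * dT) + (1.0 - fN) * (
        baselines.yU + baselines.mU * dT
    )


def predict_chemical_signal(
    denat, params: LEMParams, baselines: BaselinePair, T: float = T_REF
):
    """Evaluate the LEM model on a denaturant grid (M)."""
    x = np.asarray(denat, dtype=float)
    fN = folded_fraction(equilibrium_constant(dG_chemical(x, params), T))
    return fN * (baselines.yN + baselines.mN * x) + (1.0 - fN) * (
        baselines.yU + baselines.mU * x
    )


def _runs_test_p(residuals: np.ndarray) -> float:
    """Two-sided p for the Wald-Wolfowitz runs test on residual signs."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return 2.0 * stats.norm.sf(abs(z))


def _std_errors(res, names: Sequence[str]) -> dict[str, float]:
    """Asymptotic standard errors from the scaled covariance of a least_squares result."""
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return dict(zip(names, se))


def _heuristic_inits(x: np.ndarray, y: np.ndarray) -> tuple[float, BaselinePair]:
    """Transition midpoint from max |dS/dx|; baselines from the end tertiles."""
    k = max(len(x) // 3, 2)
    slope_n, icpt_n = np.polyfit(x[:k], y[:k], 1)
    slope_u, icpt_u = np.polyfit(x[-k:], y[-k:], 1)
    dy = np.gradient(y, x)
    if len(dy) >= 7:  # light smoothing so a noise spike does not set the midpoint
        kernel = np.ones(5) / 5.0
        dy = np.convolve(dy, kernel, mode="same")
    x_mid = float(x[np.argmax(np.abs(dy))])
    bl = BaselinePair(
        yN=icpt_n + slope_n * x_mid, mN=slope_n, yU=icpt_u + slope_u * x_mid, mU=slope_u
    )
    return x_mid, bl


def _check_baseline_coverage(fN: np.ndarray) -> bool:
    """True when the fitted curve reaches both baselines (fN ~ 1 and ~ 0)."""
    return bool(fN.max() > 0.95 and fN.min() < 0.05)


def fit_thermal_two_state(
    curve: UnfoldingCurve,
    init: tuple[float, float] | None = None,
) -> ThermalFitResult:
    """Fit the two-state thermal model to a melt curve.

    Parameters
    ----------
    curve : UnfoldingCurve
        Temperature-axis curve (x in K).
    init : (Tm, dH_Tm), optional
        Starting values; when omitted, three heuristic multi-starts are
        tried (midpoint from the steepest signal change, enthalpies
        spanning the regime typical of small beta-barrel domains) and the
        lowest-cost converged fit is kept.

    Raises
    ------
    RuntimeError
        If no start converges.  Insufficient baseline coverage or
        residual sign structure set diagnostic flags instead of raising.
    """
    if curve.axis_kind is not AxisKind.temperature:
        raise ValueError("fit_thermal_two_state needs a temperature-axis curve")
    x, y = curve.x, curve.signal
    if len(x) < 8:
        raise ValueError("need at least 8 points to fit")

    def residuals(theta: np.ndarray) -> np.ndarray:
        Tm, dH, yN, mN, yU, mU = theta
        p = TwoStateThermalParams(Tm=Tm, dH_Tm=dH)
        bl = BaselinePair(yN=yN, mN=mN, yU=yU, mU=mU)
        return predict_thermal_signal(x, p, bl) - y

    x_mid, bl0 = _heuristic_inits(x, y)
    if init is not None:
        starts = [np.array([init[0], init[1], bl0.yN, bl0.mN, bl0.yU, bl0.mU])]
    else:
        starts = [
            np.array([x_mid, dH0, bl0.yN, bl0.mN, bl0.yU, bl0.mU])
            for dH0 in (80.0, 150.0, 250.0)
        ]

    span = x.max() - x.min()
    lo = [x.min() - 0.2 * span, -5000.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [x.max() + 0.2 * span, 5000.0, np.inf, np.inf, np.inf, np.inf]

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
        raise RuntimeError("thermal two-state fit failed to converge from any start")

    Tm, dH, yN, mN, yU, mU = best.x
    params = TwoStateThermalParams(Tm=Tm, dH_Tm=dH)
    baselines = BaselinePair(yN=yN, mN=mN, yU=yU, mU=mU)
    errors = _std_errors(best, ["Tm", "dH_Tm", "yN", "mN", "yU", "mU"])

    resid = best.fun
    fN = folded_fraction(equilibrium_constant(dG_thermal(x, params), x))
    diag = _make_diagnostics(best, resid, fN, x, y)
    return ThermalFitResult(params=params, baselines=baselines, errors=errors, diagnostics=diag)


def fit_chemical_lem(
    curve: UnfoldingCurve,
    init: tuple[float, float] | None = None,
    T: float = T_REF,
) -> LEMFitResult:
    """Fit the linear-extrapolation model to a chemical denaturation series.

    Applies equally to far-UV CD, Trp fluorescence, and normalized NMR
    peak volumes.  The midpoint is derived as dG_H2O/m, never fitted
    independently.
    """
    if curve.axis_kind not in (AxisKind.urea, AxisKind.GdmCl):
        raise ValueError("fit_chemical_lem needs a urea or GdmCl axis curve")
    x, y = curve.x, curve.signal
    if len(x) < 8:
        raise ValueError("need at least 8 points to fit")

    def residuals(theta: np.ndarray) -> np.ndarray:
        dG, m, yN, mN, yU, mU = theta
        p = LEMParams(dG_H2O=dG, m_value=m)
        bl = BaselinePair(yN=yN, mN=mN, yU=yU, mU=mU)
        return predict_chemical_signal(x, p, bl, T=T) - y

    x_mid, bl_mid = _heuristic_inits(x, y)
    # baselines for the LEM model are anchored at x = 0
    bl0 = BaselinePair(
        yN=bl_mid.yN - bl_mid.mN * x_mid,
        mN=bl_mid.mN,
        yU=bl_mid.yU - bl_mid.mU * x_mid,
        mU=bl_mid.mU,
    )
    if init is not None:
        starts = [np.array([init[0], init[1], bl0.yN, bl0.mN, bl0.yU, bl0.mU])]
    else:
        starts = [
            np.array([m0 * max(x_mid, 0.3), m0, bl0.yN, bl0.mN, bl0.yU, bl0.mU])
            for m0 in (2.0, 5.0, 9.0)
        ]

    lo = [-200.0, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [500.0, 100.0, np.inf, np.inf, np.inf, np.inf]

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
        raise RuntimeError("LEM fit failed to converge from any start")

    dG, m, yN, mN, yU, mU = best.x
    params = LEMParams(dG_H2O=dG, m_value=m)
    baselines = BaselinePair(yN=yN, mN=mN, yU=yU, mU=mU)
    errors = _std_errors(best, ["dG_H2O", "m_value", "yN", "mN", "yU", "mU"])

    resid = best.fun
    fN = folded_fraction(equilibrium_constant(dG_chemical(x, params), T))
    diag = _make_diagnostics(best, resid, fN, x, y)
    return LEMFitResult(params=params, baselines=baselines, errors=errors, diagnostics=diag)


def _make_diagnostics(res, resid: np.ndarray, fN: np.ndarray, x: np.ndarray, y: np.ndarray) -> FitDiagnostics:
    diag = FitDiagnostics(
        converged=bool(res.success),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_points=len(x),
        message=str(res.message),
    )
    diag.baseline_coverage_ok = _check_baseline_coverage(fN)
    if not diag.baseline_coverage_ok:
        diag.warnings.append(
            "transition does not reach both baselines; parameters unreliable"
        )
    # a straight line explaining the data as well as the two-state model means
    # there is no transition to fit (all-native or all-unfolded data);
    # compare dof-adjusted residual variances so overfitting does not mask it
    slope, icpt = np.polyfit(x, y, 1)
    n = len(x)
    s2_line = float(np.sum((y - (icpt + slope * x)) ** 2)) / max(n - 2, 1)
    s2_fit = 2.0 * res.cost / max(n - 6, 1)
    if s2_line <= 0 or s2_fit > 0.5 * s2_line:
        diag.baseline_coverage_ok = False
        diag.warnings.append("no resolvable transition in the data")
    p_runs = _runs_test_p(resid)
    diag.runs_test_p = p_runs
    if p_runs < 0.01:
        diag.multistate_suspected = True
        diag.warnings.append(
            "systematic residual structure (runs test p < 0.01); "
            "a two-state description may be inadequate"
        )
    return diag
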
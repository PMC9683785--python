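"""Two-state CEST: Bloch-McConnell simulation, per-residue and global fits.

Chemical exchange saturation transfer detects a sparsely populated state B
in slow exchange with a major state A (rate ``kex = k_AB + k_BA``,
population ``pB``): weak B1 irradiation placed on the B resonance
saturates it, exchange carries the saturation to A, and the A-state
intensity profile I/I0 versus saturation offset develops a secondary dip
at the B-state shift.

The magnetization of the two exchanging states evolves under the
Bloch-McConnell equations.  For each saturation offset the 6x6 generator
over (Ix, Iy, Iz) of A and B — offset precession, B1 nutation, R1/R2
relaxation (toward zero; return-to-equilibrium neglected, the standard
approximation for heteronuclear CEST) and first-order exchange — is
propagated for the exchange period Tex by matrix exponential, starting
from equilibrium longitudinal magnetization (Iz_A, Iz_B) = (pA, pB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import expm

from .thermo import T_REF, dG_from_populations

__all__ = [
    "CESTProfile",
    "ResidueSpinParams",
    "ExchangeParams",
    "exchange_thermodynamics",
    "bloch_mcconnell_generator",
    "simulate_cest",
    "fit_cest_residue",
    "fit_cest_global",
    "minor_species_shift",
    "compare_to_reference",
    "ResidueFitResult",
    "GlobalFitResult",
]


@dataclass
class CESTProfile:
    """A single residue/B1-field saturation profile."""

    residue: str | int
    offsets_ppm: np.ndarray
    intensity_ratio: np.ndarray
    nu1_Hz: float
    larmor_MHz: float  # nucleus frequency, converts ppm to Hz
    Tex_s: float = 0.5
    nucleus: str = "N15"

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets_ppm, dtype=float)
        inten = np.asarray(self.intensity_ratio, dtype=float)
        if off.shape != inten.shape or off.ndim != 1:
            raise ValueError("offsets and intensities must be 1-D arrays of equal length")
        if not np.all(np.isfinite(off)):
            raise ValueError("offsets must be finite")
        if np.any(inten < -0.2) or np.any(inten > 1.2):
            raise ValueError("I/I0 outside the plausible [-0.2, 1.2] range")
        self.offsets_ppm, self.intensity_ratio = off, inten


@dataclass(frozen=True)
class ResidueSpinParams:
    """Per-residue spin parameters of the two-state exchange model.

    ``delta_A`` is the major-state shift (ppm), ``delta_omega`` the signed
    minor-minus-major shift difference (ppm).  R1 is shared between the
    states (the minor-state R1 is unidentifiable at percent-level pB);
    R2_A and R2_B are independent.
    """

    delta_A: float
    delta_omega: float
    R1: float
    R2_A: float
    R2_B: float

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2_A <= 0 or self.R2_B <= 0:
            raise ValueError("relaxation rates must be positive")


@dataclass(frozen=True)
class ExchangeParams:
    """Two-state exchange thermodynamics/kinetics: pB and kex plus derived rates."""

    pB: float
    kex: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pB < 0.5:
            raise ValueError("pB must lie in (0, 0.5): B is the minor state")
        if self.kex <= 0:
            raise ValueError("kex must be positive")

    @property
    def pA(self) -> float:
        return 1.0 - self.pB

    @property
    def k_AB(self) -> float:
        return self.pB * self.kex

    @property
    def k_BA(self) -> float:
        return self.pA * self.kex

    @property
    def tau_A(self) -> float:
        return 1.0 / self.k_AB

    @property
    def tau_B(self) -> float:
        return 1.0 / self.k_BA

    def dG(self, T: float = T_REF) -> float:
        return dG_from_populations(self.pA, self.pB, T)


def exchange_thermodynamics(pB: float, kex: float, T: float = T_REF) -> dict[str, float]:
    """Rates, lifetimes and free-energy gap from (pB, kex) at temperature T."""
    ex = ExchangeParams(pB=pB, kex=kex)
    return {
        "pA": ex.pA,
        "pB": ex.pB,
        "k_AB": ex.k_AB,
        "k_BA": ex.k_BA,
        "kex": ex.kex,
        "tau_A_s": ex.tau_A,
        "tau_B_s": ex.tau_B,
        "dG_kJ_mol": ex.dG(T),
    }


def minor_species_shift(delta_A: float, delta_omega: float) -> float:
    """Minor-state chemical shift, delta_B = delta_A + delta_omega (ppm)."""
    return delta_A + delta_omega


def bloch_mcconnell_generator(
    spin: ResidueSpinParams,
    exch: ExchangeParams,
    nu1_Hz: float,
    offset_ppm: float,
    larmor_MHz: float,
) -> np.ndarray:
    """6x6 evolution matrix over (IxA, IyA, IzA, IxB, IyB, IzB).

    Offset terms are 2*pi*(delta - offset)*larmor_MHz rad/s (ppm * MHz =
    Hz); B1 along x couples Iy and Iz with omega1 = 2*pi*nu1.
    """
    wA = 2.0 * math.pi * (spin.delta_A - offset_ppm) * larmor_MHz
    wB = 2.0 * math.pi * (spin.delta_A + spin.delta_omega - offset_ppm) * larmor_MHz
    w1 = 2.0 * math.pi * nu1_Hz
    kab, kba = exch.k_AB, exch.k_BA

    L = np.zeros((6, 6))
    # state A block
    L[0, 0] = -spin.R2_A - kab
    L[0, 1] = -wA
    L[1, 0] = wA
    L[1, 1] = -spin.R2_A - kab
    L[1, 2] = w1
    L[2, 1] = -w1
    L[2, 2] = -spin.R1 - kab
    # state B block
    L[3, 3] = -spin.R2_B - kba
    L[3, 4] = -wB
    L[4, 3] = wB
    L[4, 4] = -spin.R2_B - kba
    L[4, 5] = w1
    L[5, 4] = -w1
    L[5, 5] = -spin.R1 - kba
    # exchange coupling
    for i in range(3):
        L[i, i + 3] += kba
        L[i + 3, i] += kab
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite Bloch-McConnell generator")
    return L


def _generator_stack(
    spin: ResidueSpinParams,
    exch: ExchangeParams,
    nu1_Hz: float,
    offsets_ppm: np.ndarray,
    larmor_MHz: float,
) -> np.ndarray:
    """Stack of 6x6 generators, one per saturation offset."""
    n = offsets_ppm.size
    base = bloch_mcconnell_generator(spin, exch, nu1_Hz, 0.0, larmor_MHz)
    Ls = np.broadcast_to(base, (n, 6, 6)).copy()
    wA = 2.0 * math.pi * (spin.delta_A - offsets_ppm) * larmor_MHz
    wB = 2.0 * math.pi * (spin.delta_A + spin.delta_omega - offsets_ppm) * larmor_MHz
    Ls[:, 0, 1] = -wA
    Ls[:, 1, 0] = wA
    Ls[:, 3, 4] = -wB
    Ls[:, 4, 3] = wB
    return Ls


def simulate_cest(
    spin: ResidueSpinParams,
    exch: ExchangeParams,
    nu1_Hz: float,
    Tex_s: float,
    offsets_ppm: Sequence[float] | np.ndarray,
    larmor_MHz: float,
) -> np.ndarray:
    """Simulate a CEST profile: I/I0 = IzA(Tex)/pA at each saturation offset.

    The stack of generators is propagated by eigendecomposition (the
    matrix exponential of a diagonalizable generator); any offset whose
    eigenbasis is ill-conditioned falls back to scipy's expm.
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    Ls = _generator_stack(spin, exch, nu1_Hz, offsets, larmor_MHz)
    v0 = np.array([0.0, 0.0, exch.pA, 0.0, 0.0, exch.pB])
    try:
        lam, P = np.linalg.eig(Ls * Tex_s)
        coeff = np.linalg.solve(P, np.broadcast_to(v0, (offsets.size, 6)).astype(complex)[..., None])
        out = (P @ (np.exp(lam)[..., None] * coeff))[:, 2, 0].real / exch.pA
        cond_bad = ~np.isfinite(out) | (np.linalg.cond(P) > 1e12)
    except np.linalg.LinAlgError:
        out = np.full(offsets.size, np.nan)
        cond_bad = np.ones(offsets.size, dtype=bool)
    if np.any(cond_bad):
        for i in np.flatnonzero(cond_bad):
            out[i] = (expm(Ls[i] * Tex_s) @ v0)[2] / exch.pA
    return out


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ResidueFitResult:
    residue: str | int
    spin: ResidueSpinParams
    exchange: ExchangeParams
    errors: dict[str, float]
    converged: bool
    residual_norm: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class GlobalFitResult:
    exchange: ExchangeParams
    exchange_errors: dict[str, float]
    spins: dict[str | int, ResidueSpinParams]
    spin_errors: dict[str | int, dict[str, float]]
    included: list[str | int]
    excluded: dict[str | int, str]
    converged: bool
    residual_norm: float


def _profile_residuals(
    theta: np.ndarray, profiles: Sequence[CESTProfile]
) -> np.ndarray:
    # exchange parameters fitted on a log scale: the sloppy direction of
    # slow-exchange CEST (pB*kex ~ constant) is then a straight valley
    ln_pB, ln_kex, dA, dw, R1, R2A, R2B = theta
    spin = ResidueSpinParams(delta_A=dA, delta_omega=dw, R1=R1, R2_A=R2A, R2_B=R2B)
    exch = ExchangeParams(pB=math.exp(ln_pB), kex=math.exp(ln_kex))
    out = []
    for p in profiles:
        model = simulate_cest(spin, exch, p.nu1_Hz, p.Tex_s, p.offsets_ppm, p.larmor_MHz)
        out.append(model - p.intensity_ratio)
    return np.concatenate(out)


def _initial_spin_guess(profiles: Sequence[CESTProfile]) -> tuple[float, float, float]:
    """(delta_A, delta_omega, R1) from dip positions and the far-offset plateau."""
    p = profiles[0]
    off, inten = p.offsets_ppm, p.intensity_ratio
    i_major = int(np.argmin(inten))
    delta_A = float(off[i_major])
    # far-offset plateau -> R1
    edge = np.concatenate([inten[:3], inten[-3:]])
    plateau = float(np.clip(np.median(edge), 1e-3, 1.0))
    R1 = max(-math.log(plateau) / p.Tex_s, 0.05)
    # minor dip: deepest point at least 1 ppm from the major dip
    mask = np.abs(off - delta_A) > 1.0
    if np.any(mask):
        i_minor = int(np.flatnonzero(mask)[np.argmin(inten[mask])])
        dw = float(off[i_minor] - delta_A)
    else:
        dw = 2.0
    return delta_A, dw, R1


def fit_cest_residue(
    profiles: Sequence[CESTProfile],
    init: dict | None = None,
) -> ResidueFitResult:
    """Joint least-squares fit of one residue's profiles (both B1 fields).

    Fits pB, kex, delta_A, delta_omega, R1, R2_A, R2_B across all supplied
    profiles simultaneously.  Both +dw and -dw starts are tried and the
    lower-residual sign kept; a near-tie is reported as a warning.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    warnings: list[str] = []
    if len({p.nu1_Hz for p in profiles}) < 2:
        warnings.append("single B1 field: pB/kex may be poorly constrained")

    dA0, dw0, R10 = _initial_spin_guess(profiles)
    defaults = dict(pB=0.02, kex=50.0, delta_A=dA0, delta_omega=dw0, R1=R10, R2_A=10.0, R2_B=20.0)
    if init:
        defaults.update(init)

    lo = np.array([math.log(1e-5), math.log(1e-2), dA0 - 2.0, -12.0, 0.01, 0.1, 0.1])
    hi = np.array([math.log(0.45), math.log(2000.0), dA0 + 2.0, 12.0, 20.0, 200.0, 400.0])

    starts = []
    for sgn in (1.0, -1.0):
        theta = np.array(
            [
                math.log(defaults["pB"]),
                math.log(defaults["kex"]),
                defaults["delta_A"],
                sgn * abs(defaults["delta_omega"]),
                defaults["R1"],
                defaults["R2_A"],
                defaults["R2_B"],
            ]
        )
        starts.append(np.clip(theta, lo, hi))

    results = []
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                _profile_residuals,
                theta0,
                args=(profiles,),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
            )
        except Exception:
            continue
        if res.success:
            results.append(res)
    if not results:
        raise RuntimeError("CEST residue fit failed to converge")
    results.sort(key=lambda r: r.cost)
    best = results[0]
    if len(results) > 1 and results[1].cost > 0:
        if abs(results[0].cost - results[1].cost) < 0.05 * results[1].cost and (
            np.sign(results[0].x[3]) != np.sign(results[1].x[3])
        ):
            warnings.append("sign of delta_omega ambiguous (residuals differ by < 5%)")

    ln_pB, ln_kex, dA, dw, R1, R2A, R2B = best.x
    pB, kex = math.exp(ln_pB), math.exp(ln_kex)
    names = ["ln_pB", "ln_kex", "delta_A", "delta_omega", "R1", "R2_A", "R2_B"]
    errors = _cov_errors(best, names)
    # delta method back to the natural scale
    errors["pB"] = pB * errors.pop("ln_pB")
    errors["kex"] = kex * errors.pop("ln_kex")
    if abs(dw) < 0.2 or (np.isfinite(errors.get("pB", np.nan)) and errors["pB"] > pB):
        warnings.append("no resolvable minor dip: exchange parameters unidentifiable")

    return ResidueFitResult(
        residue=profiles[0].residue,
        spin=ResidueSpinParams(delta_A=dA, delta_omega=dw, R1=R1, R2_A=R2A, R2_B=R2B),
        exchange=ExchangeParams(pB=pB, kex=kex),
        errors=errors,
        converged=bool(best.success),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        warnings=warnings,
    )


def _cov_errors(res, names: Sequence[str]) -> dict[str, float]:
    m, n = res.jac.shape
    s2 = 2.0 * res.cost / max(m - n, 1)
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return dict(zip(names, se))


def fit_cest_global(
    profiles_by_residue: dict[str | int, Sequence[CESTProfile]],
    dw_min: float = 1.0,
    residue_fits: dict[str | int, ResidueFitResult] | None = None,
) -> GlobalFitResult:
    """Global two-state fit: shared (pB, kex), residue-specific spin parameters.

    Per-residue fits seed the global fit and supply the |delta_omega| >
    ``dw_min`` inclusion filter (profiles with smaller shift differences
    carry no exchange information and would dilute the fit).  Refuses to
    run with fewer than two included residues.
    """
    if residue_fits is None:
        residue_fits = {
            rid: fit_cest_residue(profs) for rid, profs in profiles_by_residue.items()
        }

    included, excluded = [], {}
    for rid in profiles_by_residue:
        fit = residue_fits[rid]
        if abs(fit.spin.delta_omega) > dw_min:
            included.append(rid)
        else:
            excluded[rid] = (
                f"|delta_omega| = {abs(fit.spin.delta_omega):.2f} ppm <= {dw_min} ppm"
            )
    if len(included) < 2:
        raise RuntimeError(
            f"global fit needs >= 2 residues passing the {dw_min} ppm filter "
            f"(got {len(included)})"
        )

    # parameter vector: [ln pB, ln kex] + per-residue [delta_A, dw, ln R1,
    # ln R2A, ln R2B].  Rates and populations are fitted on the log scale,
    # which keeps them positive without box constraints and straightens the
    # sloppy slow-exchange valley (pB*kex ~ constant), so unconstrained
    # Levenberg-Marquardt converges quickly.  kex is seeded from the median
    # per-residue kex; pB from the median per-residue k_AB (the
    # well-determined combination) divided by that kex.
    kex0 = float(np.median([residue_fits[r].exchange.kex for r in included]))
    kab0 = float(np.median([residue_fits[r].exchange.k_AB for r in included]))
    pB0 = min(max(kab0 / kex0, 2e-5), 0.4)
    theta0 = [math.log(pB0), math.log(kex0)]
    for rid in included:
        s = residue_fits[rid].spin
        theta0 += [s.delta_A, s.delta_omega, math.log(s.R1), math.log(s.R2_A), math.log(s.R2_B)]
    theta0 = np.array(theta0)

    prof_list = [list(profiles_by_residue[rid]) for rid in included]
    n_pts = [sum(p.offsets_ppm.size for p in profs) for profs in prof_list]

    def residuals(theta: np.ndarray) -> np.ndarray:
        pB = min(math.exp(theta[0]), 0.4999)
        exch = ExchangeParams(pB=pB, kex=math.exp(theta[1]))
        out = []
        for j, profs in enumerate(prof_list):
            dA, dw, lnR1, lnR2A, lnR2B = theta[2 + 5 * j : 7 + 5 * j]
            spin = ResidueSpinParams(
                delta_A=dA,
                delta_omega=dw,
                R1=math.exp(lnR1),
                R2_A=math.exp(lnR2A),
                R2_B=math.exp(lnR2B),
            )
            for p in profs:
                model = simulate_cest(
                    spin, exch, p.nu1_Hz, p.Tex_s, p.offsets_ppm, p.larmor_MHz
                )
                out.append(model - p.intensity_ratio)
        return np.concatenate(out)

    res = optimize.least_squares(
        residuals,
        theta0,
        method="lm",
        xtol=1e-10,
        ftol=1e-10,
        max_nfev=40000,
    )
    if not res.success:
        raise RuntimeError(f"global CEST fit did not converge: {res.message}")

    # dense-Jacobian covariance at the solution
    names = ["ln_pB", "ln_kex"]
    for rid in included:
        names += [f"{rid}:delta_A", f"{rid}:delta_omega", f"{rid}:R1", f"{rid}:R2_A", f"{rid}:R2_B"]
    jac = res.jac.toarray() if hasattr(res.jac, "toarray") else res.jac
    m, n = jac.shape
    s2 = 2.0 * res.cost / max(m - n, 1)
    try:
        diag = np.sqrt(np.clip(np.diag(np.linalg.pinv(jac.T @ jac) * s2), 0.0, None))
    except np.linalg.LinAlgError:
        diag = np.full(n, np.nan)
    all_errors = dict(zip(names, diag))

    exch = ExchangeParams(pB=math.exp(res.x[0]), kex=math.exp(res.x[1]))
    all_errors["pB"] = exch.pB * all_errors.pop("ln_pB")
    all_errors["kex"] = exch.kex * all_errors.pop("ln_kex")
    spins, spin_errors = {}, {}
    for j, rid in enumerate(included):
        dA, dw, lnR1, lnR2A, lnR2B = res.x[2 + 5 * j : 7 + 5 * j]
        spin = ResidueSpinParams(
            delta_A=dA,
            delta_omega=dw,
            R1=math.exp(lnR1),
            R2_A=math.exp(lnR2A),
            R2_B=math.exp(lnR2B),
        )
        spins[rid] = spin
        errs = {
            k.split(":", 1)[1]: v for k, v in all_errors.items() if k.startswith(f"{rid}:")
        }
        # delta method: log-scale rate errors back to natural units
        errs["R1"] = spin.R1 * errs["R1"]
        errs["R2_A"] = spin.R2_A * errs["R2_A"]
        errs["R2_B"] = spin.R2_B * errs["R2_B"]
        spin_errors[rid] = errs

    return GlobalFitResult(
        exchange=exch,
        exchange_errors={"pB": all_errors["pB"], "kex": all_errors["kex"]},
        spins=spins,
        spin_errors=spin_errors,
        included=included,
        excluded=excluded,
        converged=bool(res.success),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
    )


def compare_to_reference(
    minor_shifts: dict[str | int, float],
    reference_shifts: dict[str | int, float],
) -> dict:
    """Squared Pearson correlation, rmsd, and per-residue differences.

    Pairs residues by id; requires at least 3 common residues.  This is
    the minor-species-versus-random-coil comparison: an R^2 near 1 and a
    small rmsd mean the minor state is spectroscopically indistinguishable
    from an unfolded chain.
    """
    common = sorted(set(minor_shifts) & set(reference_shifts), key=str)
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired residues (got {len(common)})")
    a = np.array([minor_shifts[r] for r in common], dtype=float)
    b = np.array([reference_shifts[r] for r in common], dtype=float)
    r = np.corrcoef(a, b)[0, 1]
    diffs = a - b
    return {
        "R2": float(r**2),
        "rmsd": float(np.sqrt(np.mean(diffs**2))),
        "residues": common,
        "differences": {rid: float(d) for rid, d in zip(common, diffs)},
    }
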
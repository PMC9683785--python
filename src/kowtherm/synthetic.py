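"""Seeded generators for all four measurement types.

Each generator evaluates the corresponding forward model exactly and adds
iid Gaussian noise on the signal axis, so every fitting stage of the
package can be exercised closed-loop without external data.  Default
grids mirror the experimental protocols: melts 20-95 degC at 0.5 K steps,
denaturation series of ~25 individually prepared samples, DSC scans
5-130 degC, CEST offsets +/-8 ppm around the major dip at 0.25 ppm steps
with B1 of 13 and 26 Hz and a 0.5 s exchange period.

``SCENARIOS`` holds named parameter regimes for six NusG/Spt5/RfaH KOW
domains — melting temperatures and unfolding enthalpies from thermal
denaturation, LEM parameters from chemical denaturation, and global
exchange parameters from CEST — so recovery simulations run at realistic
operating points for small beta-barrel domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cest import CESTProfile, ExchangeParams, ResidueSpinParams, simulate_cest
from .dsc import DSCModelParams, Thermogram, dsc_model_cp
from .thermo import BaselinePair, LEMParams, TwoStateThermalParams, celsius_to_kelvin
from .unfolding import (
    AxisKind,
    Technique,
    UnfoldingCurve,
    predict_chemical_signal,
    predict_thermal_signal,
)

__all__ = [
    "NoiseSpec",
    "SCENARIOS",
    "gen_thermal_curve",
    "gen_chem_curve",
    "gen_dsc",
    "gen_cest",
    "default_melt_grid",
    "default_denat_grid",
    "default_dsc_grid",
    "default_cest_offsets",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise of standard deviation ``sigma`` (signal units), seeded."""

    sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Named parameter regimes (temperatures degC, energies kJ/mol, m kJ/(mol M),
#: kex 1/s).  Each entry records which measurement it parameterizes.
SCENARIOS: dict[str, dict] = {
    "EcRfaH_CD_pH7": {"kind": "thermal", "Tm_C": 50.3, "dH_Tm": 121.0},
    "VcRfaH_CD_pH7": {"kind": "thermal", "Tm_C": 65.2, "dH_Tm": 162.0},
    "MtNusG_CD_pH7": {"kind": "thermal", "Tm_C": 76.6, "dH_Tm": 193.0},
    "hSpt5_CD_pH4": {"kind": "thermal", "Tm_C": 60.5, "dH_Tm": 140.0},
    "EcNusG_DSC_pH7": {"kind": "dsc", "Tm_C": 87.0, "dH_Tm": 222.0, "dCp_Tm": 0.800},
    "MjSpt5_DSC_pH7": {"kind": "dsc", "Tm_C": 111.0, "dH_Tm": 293.0, "dCp_Tm": 0.5},
    "EcRfaH_DSC_pH7": {"kind": "dsc", "Tm_C": 47.3, "dH_Tm": 129.0, "dCp_Tm": 2.18},
    "VcRfaH_DSC_pH7": {"kind": "dsc", "Tm_C": 70.2, "dH_Tm": 169.0, "dCp_Tm": 0.148},
    "EcNusG_urea_pH4": {"kind": "chemical", "dG_H2O": 19.8, "m": 2.51},
    "VcRfaH_urea_pH7": {"kind": "chemical", "dG_H2O": 14.0, "m": 2.98},
    "hSpt5_urea_pH7": {"kind": "chemical", "dG_H2O": 14.3, "m": 3.83},
    "MjSpt5_GdmCl_pH7": {"kind": "chemical", "dG_H2O": 45.4, "m": 9.02},
    "EcRfaH_S139_volume": {"kind": "chemical", "dG_H2O": 7.0, "m": 3.4},
    "hSpt5_CEST": {"kind": "cest", "pB": 0.0085, "kex": 89.38},
    "VcRfaH_CEST": {"kind": "cest", "pB": 0.0043, "kex": 74.57},
    "EcRfaH_CEST": {"kind": "cest", "pB": 0.0553, "kex": 14.80},
}


def default_melt_grid(step_K: float = 0.5) -> np.ndarray:
    """20-95 degC melt grid in K."""
    return celsius_to_kelvin(np.arange(20.0, 95.0 + 1e-9, step_K))


def default_denat_grid(max_M: float = 10.0, n: int = 25) -> np.ndarray:
    return np.linspace(0.0, max_M, n)


def default_dsc_grid(step_K: float = 0.2) -> np.ndarray:
    """5-130 degC DSC grid in K."""
    return celsius_to_kelvin(np.arange(5.0, 130.0 + 1e-9, step_K))


def default_cest_offsets(center_ppm: float, half_width_ppm: float = 8.0, step_ppm: float = 0.25) -> np.ndarray:
    return center_ppm + np.arange(-half_width_ppm, half_width_ppm + 1e-9, step_ppm)


def gen_thermal_curve(
    params: TwoStateThermalParams,
    baselines: BaselinePair,
    T_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0, seed=0),
    technique: Technique = Technique.CD_far_UV,
) -> UnfoldingCurve:
    """Synthetic thermal melt: exact two-state model plus Gaussian noise."""
    if T_grid is None:
        T_grid = default_melt_grid()
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("empty temperature grid")
    signal = predict_thermal_signal(T_grid, params, baselines)
    if noise.sigma > 0:
        signal = signal + noise.rng().normal(0.0, noise.sigma, size=signal.shape)
    return UnfoldingCurve(
        x=T_grid, signal=signal, technique=technique, axis_kind=AxisKind.temperature
    )


def gen_chem_curve(
    params: LEMParams,
    baselines: BaselinePair,
    denat_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0, seed=0),
    axis_kind: AxisKind = AxisKind.urea,
    technique: Technique = Technique.CD_far_UV,
) -> UnfoldingCurve:
    """Synthetic chemical denaturation series under the LEM model."""
    if denat_grid is None:
        denat_grid = default_denat_grid()
    denat_grid = np.asarray(denat_grid, dtype=float)
    if denat_grid.size == 0:
        raise ValueError("empty denaturant grid")
    signal = predict_chemical_signal(denat_grid, params, baselines)
    if noise.sigma > 0:
        signal = signal + noise.rng().normal(0.0, noise.sigma, size=signal.shape)
    return UnfoldingCurve(
        x=denat_grid, signal=signal, technique=technique, axis_kind=axis_kind
    )


def gen_dsc(
    params: DSCModelParams,
    T_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0, seed=0),
) -> Thermogram:
    """Synthetic molar-normalized DSC thermogram."""
    if T_grid is None:
        T_grid = default_dsc_grid()
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0:
        raise ValueError("empty temperature grid")
    Cp = dsc_model_cp(T_grid, params)
    if noise.sigma > 0:
        Cp = Cp + noise.rng().normal(0.0, noise.sigma, size=Cp.shape)
    return Thermogram(T=T_grid, Cp=Cp)


def dsc_params_for_scenario(
    name: str,
    a0: float = -5.0,
    b0: float = 0.05,
    c: float = -5.0e-5,
    T_peak_dCp: float = 373.15,
) -> DSCModelParams:
    """Build full DSC model parameters from a named (Tm, dH, dCp(Tm)) regime.

    The dCp parabola is anchored so its maximum sits at ``T_peak_dCp``
    (unfolded-state heat capacities flatten near 100 degC) and its value
    at Tm equals the regime's dCp(Tm).
    """
    sc = SCENARIOS[name]
    if sc["kind"] != "dsc":
        raise ValueError(f"scenario {name} is not a DSC regime")
    Tm = celsius_to_kelvin(sc["Tm_C"])
    b = -2.0 * c * T_peak_dCp
    # a such that a + b*Tm + c*Tm^2 = dCp_Tm
    a = sc["dCp_Tm"] - b * Tm - c * Tm**2
    return DSCModelParams(a0=a0, b0=b0, a=a, b=b, c=c, Tm=Tm, dH_Tm=sc["dH_Tm"])


def gen_cest(
    spins: dict[str | int, ResidueSpinParams],
    exch: ExchangeParams,
    nu1_list: tuple[float, ...] = (13.0, 26.0),
    Tex_s: float = 0.5,
    offsets_by_residue: dict[str | int, np.ndarray] | None = None,
    larmor_MHz: float = 70.95,
    noise: NoiseSpec = NoiseSpec(sigma=0.0, seed=0),
) -> dict[str | int, list[CESTProfile]]:
    """Synthetic dual-B1 CEST profiles for a set of residues.

    Offsets default to +/-8 ppm around each residue's major-state shift at
    0.25 ppm steps.  One shared noise stream (from ``noise.seed``) covers
    the whole dataset so a single seed reproduces it bit-for-bit.
    """
    rng = noise.rng()
    out: dict[str | int, list[CESTProfile]] = {}
    for rid, spin in spins.items():
        offsets = (
            offsets_by_residue[rid]
            if offsets_by_residue is not None
            else default_cest_offsets(spin.delta_A)
        )
        profiles = []
        for nu1 in nu1_list:
            inten = simulate_cest(spin, exch, nu1, Tex_s, offsets, larmor_MHz)
            if noise.sigma > 0:
                inten = inten + rng.normal(0.0, noise.sigma, size=inten.shape)
                inten = np.clip(inten, -0.2, 1.2)
            profiles.append(
                CESTProfile(
                    residue=rid,
                    offsets_ppm=offsets,
                    intensity_ratio=inten,
                    nu1_Hz=nu1,
                    larmor_MHz=larmor_MHz,
                    Tex_s=Tex_s,
                )
            )
        out[rid] = profiles
    return out
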
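import numpy as np
import pytest

from kowtherm.cest import ExchangeParams, ResidueSpinParams
from kowtherm.synthetic import NoiseSpec, gen_cest
from kowtherm.thermo import BaselinePair, LEMParams, TwoStateThermalParams, celsius_to_kelvin


@pytest.fixture
def thermal_params():
    """Spectroscopic-melt regime of a marginally stable beta-barrel (Tm 50.3 degC)."""
    return TwoStateThermalParams(Tm=celsius_to_kelvin(50.3), dH_Tm=121.0)


@pytest.fixture
def cd_baselines():
    """Mean-residue-weight ellipticity baselines typical of a far-UV CD melt."""
    return BaselinePair(yN=-5500.0, mN=10.0, yU=-2500.0, mU=5.0)


@pytest.fixture
def lem_params():
    return LEMParams(dG_H2O=14.0, m_value=2.98)


@pytest.fixture
def chem_baselines():
    return BaselinePair(yN=-6000.0, mN=50.0, yU=-2000.0, mU=30.0)


def make_cest_dataset(
    exch: ExchangeParams,
    n_residues: int = 4,
    sigma: float = 0.01,
    seed: int = 11,
    step_ppm: float = 0.25,
    spin_seed: int = 42,
):
    """Dual-B1 synthetic CEST dataset with randomized shifts, fixed rates."""
    rng = np.random.default_rng(spin_seed)
    spins = {
        f"R{i}": ResidueSpinParams(
            delta_A=float(rng.uniform(105.0, 130.0)),
            delta_omega=float(rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 4.0)),
            R1=1.5,
            R2_A=8.0,
            R2_B=20.0,
        )
        for i in range(n_residues)
    }
    offsets = {
        rid: s.delta_A + np.arange(-8.0, 8.0 + 1e-9, step_ppm) for rid, s in spins.items()
    }
    data = gen_cest(
        spins,
        exch,
        offsets_by_residue=offsets,
        noise=NoiseSpec(sigma=sigma, seed=seed),
    )
    return spins, data
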
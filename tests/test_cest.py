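import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from kowtherm.cest import (
    ExchangeParams,
    ResidueSpinParams,
    bloch_mcconnell_generator,
    compare_to_reference,
    exchange_thermodynamics,
    fit_cest_global,
    fit_cest_residue,
    minor_species_shift,
    simulate_cest,
)
from kowtherm.synthetic import NoiseSpec, gen_cest
from conftest import make_cest_dataset

F_MHZ = 70.95


class TestExchangeParams:
    def test_detailed_balance_exact(self):
        for pB, kex in [(0.0085, 89.38), (0.0043, 74.57), (0.0553, 14.80), (0.3, 500.0)]:
            ex = ExchangeParams(pB=pB, kex=kex)
            assert ex.k_AB + ex.k_BA == pytest.approx(kex, rel=1e-14)
            assert ex.k_AB * ex.pA == pytest.approx(ex.k_BA * ex.pB, rel=1e-12)
            assert ex.k_AB / ex.k_BA == pytest.approx(ex.pB / ex.pA, rel=1e-12)

    @pytest.mark.parametrize(
        "k_AB,k_BA,kex_expected",
        [(0.76, 88.62, 89.38), (0.82, 13.98, 14.80)],
    )
    def test_rate_sums(self, k_AB, k_BA, kex_expected):
        kex = k_AB + k_BA
        assert kex == pytest.approx(kex_expected, abs=0.005)
        out = exchange_thermodynamics(pB=k_AB / kex, kex=kex)
        assert out["k_AB"] == pytest.approx(k_AB, abs=0.005)
        assert out["k_BA"] == pytest.approx(k_BA, abs=0.005)

    def test_symmetric_exchange_lifetimes(self):
        with pytest.raises(ValueError):
            ExchangeParams(pB=0.5, kex=100.0)  # pB must be the minor state
        ex = ExchangeParams(pB=0.4999999, kex=100.0)
        assert ex.tau_A == pytest.approx(0.02, rel=1e-5)
        assert ex.tau_B == pytest.approx(0.02, rel=1e-5)

    def test_free_energy_gap(self):
        assert exchange_thermodynamics(0.0085, 89.38)["dG_kJ_mol"] == pytest.approx(11.80, abs=0.01)


class TestMinorShift:
    def test_arithmetic(self):
        assert minor_species_shift(120.0, -2.5) == pytest.approx(117.5)
        assert minor_species_shift(120.0, 0.0) == pytest.approx(120.0)

    def test_sign_convention_matches_simulated_dip(self):
        """The secondary dip in a simulated profile sits at delta_A + delta_omega."""
        spin = ResidueSpinParams(delta_A=118.0, delta_omega=-3.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=0.06, kex=20.0)
        offs = np.arange(110.0, 126.0, 0.05)
        prof = simulate_cest(spin, exch, 13.0, 0.5, offs, F_MHZ)
        minor_region = (offs > 112.0) & (offs < 117.0)
        dip = offs[minor_region][np.argmin(prof[minor_region])]
        assert dip == pytest.approx(minor_species_shift(118.0, -3.0), abs=0.1)


class TestSimulate:
    def test_one_state_limit(self):
        """Vanishing pB gives a single dip at the major-state shift."""
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=-3.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=1e-5, kex=1e-2)
        offs = np.arange(112.0, 128.0, 0.25)
        prof = simulate_cest(spin, exch, 13.0, 0.5, offs, F_MHZ)
        assert offs[np.argmin(prof)] == pytest.approx(120.0, abs=0.25)
        minor_side = prof[offs < 118.0]
        far = math.exp(-1.5 * 0.5)
        assert np.all(minor_side > 0.8 * far)

    def test_far_offset_pure_longitudinal_decay(self):
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=2.0, R1=2.0, R2_A=10.0, R2_B=30.0)
        exch = ExchangeParams(pB=0.05, kex=50.0)
        prof = simulate_cest(spin, exch, 13.0, 0.5, np.array([400.0]), F_MHZ)
        assert prof[0] == pytest.approx(math.exp(-2.0 * 0.5), rel=1e-3)

    def test_saturation_only_removes_magnetization(self):
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=3.0, R1=1.0, R2_A=8.0, R2_B=25.0)
        exch = ExchangeParams(pB=0.03, kex=100.0)
        offs = np.arange(110.0, 130.0, 0.25)
        for nu1 in (13.0, 26.0):
            prof = simulate_cest(spin, exch, nu1, 0.5, offs, F_MHZ)
            # saturation can only remove observable magnetization; small
            # negative excursions near resonance are Rabi-nutation transients
            assert np.all(prof <= math.exp(-1.0 * 0.5) * (1.0 + 1e-9))
            assert np.all(prof > -0.2)

    def test_matrix_exponential_agrees_with_ode_oracle(self):
        """Eigen-propagation equals adaptive ODE integration of the same generator."""
        rng = np.random.default_rng(1)
        for _ in range(8):
            spin = ResidueSpinParams(
                delta_A=float(rng.uniform(100, 135)),
                delta_omega=float(rng.uniform(-6, 6)),
                R1=float(rng.uniform(0.3, 4)),
                R2_A=float(rng.uniform(2, 50)),
                R2_B=float(rng.uniform(2, 100)),
            )
            exch = ExchangeParams(pB=float(rng.uniform(0.002, 0.3)), kex=float(rng.uniform(1, 300)))
            nu1 = float(rng.uniform(5, 50))
            offs = spin.delta_A + rng.uniform(-6, 6, size=2)
            prof = simulate_cest(spin, exch, nu1, 0.5, offs, F_MHZ)
            v0 = np.array([0, 0, exch.pA, 0, 0, exch.pB])
            for j, off in enumerate(offs):
                L = bloch_mcconnell_generator(spin, exch, nu1, float(off), F_MHZ)
                sol = solve_ivp(
                    lambda t, v: L @ v, (0, 0.5), v0, method="DOP853", rtol=2.5e-14, atol=1e-16
                )
                assert prof[j] == pytest.approx(sol.y[2, -1] / exch.pA, abs=1e-8)

    def test_label_swap_symmetry(self):
        """Relabelling A<->B permutes the generator blocks exactly, and reading
        Iz_B/pB of the swapped system reproduces the original profile."""
        spin = ResidueSpinParams(delta_A=118.0, delta_omega=-3.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=0.055, kex=15.0)
        swapped_spin = ResidueSpinParams(
            delta_A=spin.delta_A + spin.delta_omega,
            delta_omega=-spin.delta_omega,
            R1=spin.R1,
            R2_A=spin.R2_B,
            R2_B=spin.R2_A,
        )
        # the swapped "exchange" has pB>0.5, outside ExchangeParams' domain;
        # a duck-typed stand-in supplies the same rate/population interface
        swapped_exch = SimpleNamespace(
            pA=exch.pB, pB=exch.pA, k_AB=exch.k_BA, k_BA=exch.k_AB
        )
        P = np.zeros((6, 6))
        P[:3, 3:] = np.eye(3)
        P[3:, :3] = np.eye(3)
        offs = np.arange(110.0, 126.0, 0.5)
        for off in offs[:5]:
            L = bloch_mcconnell_generator(spin, exch, 13.0, float(off), F_MHZ)
            Ls = bloch_mcconnell_generator(swapped_spin, swapped_exch, 13.0, float(off), F_MHZ)
            assert np.allclose(P @ Ls @ P.T, L, atol=1e-12)
        orig = simulate_cest(spin, exch, 13.0, 0.5, offs, F_MHZ)
        mirrored = np.array(
            [
                (expm(bloch_mcconnell_generator(swapped_spin, swapped_exch, 13.0, float(o), F_MHZ) * 0.5)
                 @ np.array([0, 0, swapped_exch.pA, 0, 0, swapped_exch.pB]))[5] / swapped_exch.pB
                for o in offs
            ]
        )
        assert np.allclose(orig, mirrored, atol=1e-10)


class TestResidueFit:
    def test_noise_free_exact(self):
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=-3.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=0.055, kex=15.0)
        data = gen_cest({"X": spin}, exch, noise=NoiseSpec(sigma=0.0, seed=0))
        fit = fit_cest_residue(data["X"])
        assert fit.exchange.pB == pytest.approx(0.055, rel=1e-4)
        assert fit.exchange.kex == pytest.approx(15.0, rel=1e-4)
        assert fit.spin.delta_omega == pytest.approx(-3.0, abs=1e-4)

    def test_noisy_recovery_within_combined_errors(self):
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=-3.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=0.055, kex=15.0)
        data = gen_cest({"X": spin}, exch, noise=NoiseSpec(sigma=0.005, seed=5))
        fit = fit_cest_residue(data["X"])
        for name, truth in [("pB", 0.055), ("kex", 15.0), ("delta_omega", -3.0),
                            ("R1", 1.5), ("R2_A", 8.0), ("R2_B", 20.0)]:
            est = getattr(fit.exchange, name, None)
            if est is None:
                est = getattr(fit.spin, name)
            se = max(fit.errors[name], 1e-6)
            assert abs(est - truth) < 3.0 * se, f"{name}: {est} vs {truth} (se {se})"

    def test_zero_dw_flagged_unidentifiable(self):
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=0.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=0.05, kex=30.0)
        data = gen_cest({"X": spin}, exch, noise=NoiseSpec(sigma=0.003, seed=2))
        fit = fit_cest_residue(data["X"])
        assert fit.warnings  # degenerate: no separable minor dip

    def test_single_b1_field_flagged(self):
        spin = ResidueSpinParams(delta_A=120.0, delta_omega=2.0, R1=1.5, R2_A=8.0, R2_B=20.0)
        exch = ExchangeParams(pB=0.05, kex=30.0)
        data = gen_cest({"X": spin}, exch, nu1_list=(13.0,), noise=NoiseSpec(sigma=0.0, seed=0))
        fit = fit_cest_residue(data["X"])
        assert any("single B1" in w for w in fit.warnings)


class TestGlobalFit:
    def test_dw_filter_excludes_small_shift_differences(self):
        exch = ExchangeParams(pB=0.03, kex=60.0)
        spins = {
            "A": ResidueSpinParams(delta_A=115.0, delta_omega=3.0, R1=1.5, R2_A=8.0, R2_B=20.0),
            "B": ResidueSpinParams(delta_A=122.0, delta_omega=-2.5, R1=1.5, R2_A=8.0, R2_B=20.0),
            "C": ResidueSpinParams(delta_A=127.0, delta_omega=0.5, R1=1.5, R2_A=8.0, R2_B=20.0),
        }
        offsets = {r: s.delta_A + np.arange(-6.0, 6.01, 0.5) for r, s in spins.items()}
        data = gen_cest(spins, exch, offsets_by_residue=offsets, noise=NoiseSpec(sigma=0.002, seed=3))
        g = fit_cest_global(data, dw_min=1.0)
        assert "C" in g.excluded
        assert set(g.included) == {"A", "B"}
        assert g.exchange.pB == pytest.approx(0.03, rel=0.25)

    def test_refuses_single_included_residue(self):
        exch = ExchangeParams(pB=0.03, kex=60.0)
        spins = {
            "A": ResidueSpinParams(delta_A=115.0, delta_omega=3.0, R1=1.5, R2_A=8.0, R2_B=20.0),
            "B": ResidueSpinParams(delta_A=122.0, delta_omega=0.3, R1=1.5, R2_A=8.0, R2_B=20.0),
        }
        offsets = {r: s.delta_A + np.arange(-6.0, 6.01, 0.5) for r, s in spins.items()}
        data = gen_cest(spins, exch, offsets_by_residue=offsets, noise=NoiseSpec(sigma=0.002, seed=3))
        with pytest.raises(RuntimeError, match=">= 2 residues"):
            fit_cest_global(data, dw_min=1.0)

    def test_duplicate_residue_leaves_estimates_stable(self):
        exch = ExchangeParams(pB=0.05, kex=40.0)
        spins, data = make_cest_dataset(exch, n_residues=3, sigma=0.002, seed=5, step_ppm=0.5)
        g1 = fit_cest_global(data)
        dup = dict(data)
        dup["R0_copy"] = data["R0"]
        g2 = fit_cest_global(dup)
        assert g2.exchange.pB == pytest.approx(g1.exchange.pB, rel=0.05)
        assert g2.exchange.kex == pytest.approx(g1.exchange.kex, rel=0.05)

    @pytest.mark.parametrize("pB,kex", [(0.0085, 89.4), (0.055, 14.8)])
    def test_regime_recovery_reduced_scale(self, pB, kex):
        """Global (pB, kex) recovery at two printed exchange regimes, scaled down."""
        exch = ExchangeParams(pB=pB, kex=kex)
        spins, data = make_cest_dataset(exch, n_residues=4, sigma=0.005, seed=17, step_ppm=0.5)
        g = fit_cest_global(data)
        comb_p = math.hypot(g.exchange_errors["pB"], 0.1 * pB)
        comb_k = math.hypot(g.exchange_errors["kex"], 0.1 * kex)
        assert abs(g.exchange.pB - pB) < 2.5 * comb_p
        assert abs(g.exchange.kex - kex) < 2.5 * comb_k


class TestCompareToReference:
    def test_identical_and_translated(self):
        shifts = {i: 110.0 + i for i in range(6)}
        out = compare_to_reference(shifts, shifts)
        assert out["R2"] == pytest.approx(1.0)
        assert out["rmsd"] == pytest.approx(0.0, abs=1e-12)
        offset = {k: v + 1.3 for k, v in shifts.items()}
        out2 = compare_to_reference(offset, shifts)
        assert out2["R2"] == pytest.approx(1.0)
        assert out2["rmsd"] == pytest.approx(1.3, rel=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        a = {i: float(v) for i, v in enumerate(rng.normal(118, 4, 10))}
        b = {i: float(v) for i, v in enumerate(rng.normal(118, 4, 10))}
        out = compare_to_reference(a, b)
        av = np.array([a[i] for i in range(10)])
        bv = np.array([b[i] for i in range(10)])
        r = np.sum((av - av.mean()) * (bv - bv.mean())) / math.sqrt(
            np.sum((av - av.mean()) ** 2) * np.sum((bv - bv.mean()) ** 2)
        )
        assert out["R2"] == pytest.approx(r**2, rel=1e-12)
        assert out["rmsd"] == pytest.approx(math.sqrt(np.mean((av - bv) ** 2)), rel=1e-12)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            compare_to_reference({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0})
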
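"""Forward-model physics: spectral densities, relaxation rates, and the
two CPMG dispersion models."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from nmrelax.spin import (
    CpmgDesign,
    DiffusionTensor,
    MotionalModel,
    SpinSystem,
    TwoStateExchange,
    bloch_mcconnell_r2eff,
    carver_richards_r2eff,
    cpmg_exchange_excess,
    lipari_szabo_J,
    n_cpmg_pulses,
    rates_from_model,
)


class TestSpectralDensity:
    def test_rigid_rotor_limit(self, spin800, iso_tensor):
        """S2 = 1 gives the pure Lorentzian J = (2/5) tau_m/(1+(w tau)^2)."""
        m = MotionalModel("M1", S2=1.0)
        for w in [0.0, spin800.omega_N, spin800.omega_H]:
            expected = 0.4 * iso_tensor.tau_m / (
                1 + (w * iso_tensor.tau_m) ** 2)
            assert lipari_szabo_J(w, m, iso_tensor) == pytest.approx(
                expected, rel=1e-12)

    def test_zero_frequency_value(self):
        tensor = DiffusionTensor("isotropic", 10.0e-9)
        m = MotionalModel("M2", S2=0.8, tau_e=0.0)
        assert lipari_szabo_J(0.0, m, tensor) == pytest.approx(
            0.4 * 0.8 * 10.0e-9, rel=1e-12)

    def test_against_numerical_cosine_transform(self, spin800):
        """J(w) must match the numerical cosine transform of the
        model-free correlation function C(t)."""
        s2, tau_e, tau_m = 0.85, 50e-12, 10.7e-9
        tensor = DiffusionTensor("isotropic", tau_m)
        m = MotionalModel("M2", S2=s2, tau_e=tau_e)
        w = spin800.omega_N

        def corr(t):
            internal = s2 + (1 - s2) * math.exp(-t / tau_e)
            return 0.4 * internal * math.exp(-t / tau_m)

        # split the oscillatory integral at the period scale
        period = 2 * math.pi / w
        val, _ = quad(lambda t: corr(t) * math.cos(w * t), 0.0, 50 * tau_m,
                      limit=2000, epsabs=1e-16,
                      points=[period, tau_m])
        assert lipari_szabo_J(w, m, tensor) == pytest.approx(val, rel=1e-3)

    def test_extended_reduces_to_simple(self, iso_tensor):
        """M5 with S2f = 1 is exactly the M2 spectral density."""
        m5 = MotionalModel("M5", S2=0.8, tau_e=80e-12, S2f=1.0)
        m2 = MotionalModel("M2", S2=0.8, tau_e=80e-12)
        w = np.linspace(0, 5e9, 7)
        assert np.allclose(
            lipari_szabo_J(w, m5, iso_tensor),
            lipari_szabo_J(w, m2, iso_tensor), rtol=1e-14)

    def test_axial_reduces_to_isotropic(self, spin800):
        """d_ratio -> 1 collapses the three-term axial form onto the
        isotropic form for every N-H angle."""
        iso = DiffusionTensor("isotropic", 9.5e-9)
        nearly_iso = DiffusionTensor("axial_oblate", 9.5e-9, 1 - 1e-12)
        m = MotionalModel("M2", S2=0.85, tau_e=40e-12)
        freqs = [0.0, spin800.omega_N, spin800.omega_H - spin800.omega_N,
                 spin800.omega_H, spin800.omega_H + spin800.omega_N]
        for angle in np.linspace(0, math.pi / 2, 20):
            for w in freqs:
                j_ax = lipari_szabo_J(w, m, nearly_iso, angle)
                j_iso = lipari_szabo_J(w, m, iso)
                assert abs(j_ax - j_iso) / j_iso < 1e-10

    def test_axial_requires_angle(self, oblate_tensor):
        with pytest.raises(ValueError, match="nh_angle"):
            lipari_szabo_J(0.0, MotionalModel("M1", S2=0.9), oblate_tensor)


class TestMotionalModelInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(model_id="M1", S2=0.9, tau_e=1e-12),  # extra parameter
        dict(model_id="M3", S2=0.9),               # missing Rex
        dict(model_id="M1", S2=1.2),               # S2 out of range
        dict(model_id="M5", S2=0.9, tau_e=1e-9, S2f=0.8),  # S2 > S2f
        dict(model_id="M3", S2=0.9, Rex=-1.0),     # negative Rex
    ])
    def test_invalid_parameter_sets_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MotionalModel(**kwargs)


class TestRelaxationRates:
    def test_extreme_narrowing_noe_limit(self):
        """tau_m -> 0 with no CSA gives NOE -> 1 + gH/(2gN) ~ -3.93."""
        spin = SpinSystem(800.2, csa_N=0.0)
        tensor = DiffusionTensor("isotropic", 1e-13)
        _, _, noe = rates_from_model(MotionalModel("M1", S2=0.9), tensor,
                                     spin)
        assert noe == pytest.approx(1 + spin.gamma_ratio / 2, rel=1e-3)
        assert noe == pytest.approx(-3.93, abs=0.01)

    def test_m1_ratios_independent_of_s2(self, spin800, iso_tensor):
        """Under M1 both NOE and R2/R1 cancel the order parameter."""
        out = {}
        for s2 in (0.5, 0.95):
            r1, r2, noe = rates_from_model(MotionalModel("M1", S2=s2),
                                           iso_tensor, spin800)
            out[s2] = (noe, r2 / r1)
        assert out[0.5][0] == pytest.approx(out[0.95][0], rel=1e-12)
        assert out[0.5][1] == pytest.approx(out[0.95][1], rel=1e-12)

    def test_term_by_term_oracle(self, spin800):
        """R1/R2/NOE match an independent re-derivation evaluating each
        spectral-density term separately."""
        tensor = DiffusionTensor("isotropic", 10.8e-9)
        m = MotionalModel("M1", S2=0.91)
        r1, r2, noe = rates_from_model(m, tensor, spin800)

        tau = tensor.tau_m

        def j(w):
            return 0.4 * 0.91 * tau / (1 + (w * tau) ** 2)

        gh = 2.6752218744e8
        gn = gh / spin800.gamma_ratio
        hbar = 1.054571817e-34
        d = 1e-7 * hbar * gh * abs(gn) / (1.02e-10) ** 3
        wn = spin800.omega_N
        wh = spin800.omega_H
        c = wn * (-160e-6) / math.sqrt(3)
        r1_ref = d**2 / 4 * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) \
            + c**2 * j(wn)
        r2_ref = d**2 / 8 * (4 * j(0) + j(wh - wn) + 3 * j(wn)
                             + 6 * j(wh) + 6 * j(wh + wn)) \
            + c**2 / 6 * (4 * j(0) + 3 * j(wn))
        sigma = d**2 / 4 * (6 * j(wh + wn) - j(wh - wn))
        noe_ref = 1 + spin800.gamma_ratio * sigma / r1_ref
        assert r1 == pytest.approx(r1_ref, rel=1e-12)
        assert r2 == pytest.approx(r2_ref, rel=1e-12)
        assert noe == pytest.approx(noe_ref, rel=1e-12)

    def test_rex_adds_to_r2_only(self, spin800, iso_tensor):
        base = rates_from_model(MotionalModel("M1", S2=0.88), iso_tensor,
                                spin800)
        withx = rates_from_model(MotionalModel("M3", S2=0.88, Rex=4.0),
                                 iso_tensor, spin800)
        assert withx[0] == pytest.approx(base[0], rel=1e-12)
        assert withx[1] == pytest.approx(base[1] + 4.0, rel=1e-12)
        assert withx[2] == pytest.approx(base[2], rel=1e-12)

    def test_r2_over_r1_increases_with_tau_m(self, spin800):
        """The tumbling-time dependence underlying tau_m estimation."""
        ratios = []
        for tau in np.linspace(5e-9, 15e-9, 11):
            r1, r2, _ = rates_from_model(
                MotionalModel("M1", S2=0.9),
                DiffusionTensor("isotropic", tau), spin800)
            ratios.append(r2 / r1)
        assert np.all(np.diff(ratios) > 0)


class TestCpmgDesignRules:
    def test_even_pulse_count(self):
        assert n_cpmg_pulses(50.0, 0.06) == 6
        assert n_cpmg_pulses(750.0, 0.06) == 90

    def test_incompatible_frequency_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            n_cpmg_pulses(58.3, 0.06)

    def test_default_design_matches_experiment(self, design):
        assert design.t_relax == 0.060
        assert len(design.nu_cpmg) == 14
        assert design.nu_cpmg.count(100.0) == 2
        assert 0.0 in design.nu_cpmg
        assert design.fields == (800.2, 600.13)

    def test_field_scaling_of_delta_omega(self, spin800, spin600):
        """A ppm shift difference in rad/s scales linearly with field."""
        assert spin800.ppm_to_rads(2.0) / spin600.ppm_to_rads(2.0) == \
            pytest.approx(800.2 / 600.13, rel=1e-12)


class TestCarverRichards:
    def test_no_exchange_returns_r20(self, spin800):
        ex = TwoStateExchange(1500.0, 0.97, 0.0, 14.0)
        for nu in (50.0, 250.0, 750.0):
            assert carver_richards_r2eff(ex, nu, spin800) == 14.0

    def test_single_state_returns_r20(self, spin800):
        ex = TwoStateExchange(1500.0, 1.0, 2.0, 14.0)
        for nu in (50.0, 250.0, 750.0):
            assert carver_richards_r2eff(ex, nu, spin800) == 14.0

    def test_fast_exchange_limit(self, spin800):
        """In fast exchange the zero-frequency excess tends to
        pA pB dw^2 / kex."""
        kex, pa, dw = 40000.0, 0.95, 1.0
        ex = TwoStateExchange(kex, pa, dw, 10.0)
        excess = carver_richards_r2eff(ex, 10.0, spin800) - 10.0
        expected = pa * (1 - pa) * spin800.ppm_to_rads(dw) ** 2 / kex
        assert excess == pytest.approx(expected, rel=0.05)


class TestBlochMcConnell:
    def test_no_exchange_exact(self, spin800):
        ex = TwoStateExchange(1500.0, 0.97, 0.0, 14.0)
        assert bloch_mcconnell_r2eff(ex, 250.0, spin800) == pytest.approx(
            14.0, abs=1e-9)
        ex1 = TwoStateExchange(1500.0, 1.0, 2.0, 14.0)
        assert bloch_mcconnell_r2eff(ex1, 250.0, spin800) == pytest.approx(
            14.0, abs=1e-9)

    def test_matches_bruteforce_propagation(self, spin800, rng):
        """The closed-form per-block propagator and Cayley-Hamilton
        matrix power must reproduce step-by-step scipy.linalg.expm
        propagation with explicit 180-degree conjugations."""
        for _ in range(10):
            kex = rng.uniform(200, 6000)
            pb = rng.uniform(0.01, 0.1)
            dw = rng.uniform(0.5, 4.0)
            nu = float(rng.choice([50, 100, 250, 500, 750]))
            ex = TwoStateExchange(kex, 1 - pb, dw, 12.0)
            dwr = spin800.ppm_to_rads(dw)
            kab, kba = pb * kex, (1 - pb) * kex
            L = np.array([[-kab + 0j, kba], [kab, -kba - 1j * dwr]])
            n = n_cpmg_pulses(nu, 0.06)
            tau = 0.06 / (2.0 * n)
            A, B = expm(L * tau), expm(L * 2 * tau)
            v = np.array([1 - pb, pb], complex)
            for _ in range(n // 2):
                v = A @ np.conj(B @ np.conj(A @ v))
            ref = 12.0 - math.log(abs(v[0]) / (1 - pb)) / 0.06
            assert bloch_mcconnell_r2eff(ex, nu, spin800) == pytest.approx(
                ref, abs=1e-9)

    def test_agreement_with_carver_richards(self, spin800):
        """The finite-time numerical R2eff tracks the closed-form
        asymptotic rate: within 2% over almost all of the physical
        regime, never beyond 3% (the residual is the initial-projection
        amplitude at small pulse numbers), and it converges onto the
        closed form as the relaxation period grows."""
        devs = []
        for kex in np.linspace(200, 6000, 6):
            for pb in (0.01, 0.05, 0.1):
                for dw in (0.5, 2.0, 4.0):
                    ex = TwoStateExchange(kex, 1 - pb, dw, 12.0)
                    for nu in (50.0, 100.0, 250.0, 500.0, 750.0):
                        bm = bloch_mcconnell_r2eff(ex, nu, spin800)
                        cr = carver_richards_r2eff(ex, nu, spin800)
                        devs.append(abs(bm - cr) / bm)
        devs = np.array(devs)
        assert devs.max() < 0.03
        assert np.quantile(devs, 0.95) < 0.02
        # amplitude effect vanishes for a long echo train
        ex = TwoStateExchange(200.0, 0.9, 0.5, 12.0)
        bm_long = bloch_mcconnell_r2eff(ex, 50.0, spin800, t_relax=1.2)
        cr = carver_richards_r2eff(ex, 50.0, spin800)
        assert abs(bm_long - cr) / cr < 0.005

    def test_dispersion_decays_with_refocusing(self, spin800):
        """R2eff at 50 Hz strictly exceeds R2eff at 750 Hz for
        intermediate exchange."""
        pa = 0.5 * (1 + math.sqrt(1 - 4 * 0.026))
        ex = TwoStateExchange(1822.0, pa, 2.0, 12.0)
        lo = bloch_mcconnell_r2eff(ex, 50.0, spin800)
        hi = bloch_mcconnell_r2eff(ex, 750.0, spin800)
        assert lo > hi

    def test_vectorized_curve_matches_scalar(self, spin800):
        ex = TwoStateExchange(1095.0, 0.9755, 2.5, 0.0)
        nus = np.array([50.0, 150.0, 400.0, 750.0])
        curve = cpmg_exchange_excess(
            ex.p_A, ex.k_ex, spin800.ppm_to_rads(2.5), nus, 0.06)
        for nu, val in zip(nus, curve):
            assert val == pytest.approx(
                bloch_mcconnell_r2eff(ex, nu, spin800), abs=1e-10)
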
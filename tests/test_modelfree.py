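"""Model-free analysis: diffusion-tensor estimation, per-residue model
fitting/selection, Monte Carlo errors, inertia utility."""

import math

import numpy as np
import pytest

from nmrelax.modelfree import (
    estimate_diffusion,
    fit_model,
    inertia_ratio,
    monte_carlo_errors,
    select_model,
    select_rigid_subset,
)
from nmrelax.rates import RelaxationRecord, records_from_tables
from nmrelax.spin import DiffusionTensor, MotionalModel, SpinSystem, \
    rates_from_model
from nmrelax.synth import make_relaxation_dataset, rigid_residue_truth


def record_from(model, tensor, spin, nh_angle=None, residue=1,
                noise_frac=0.02, rng=None):
    """A RelaxationRecord back-calculated from a motional model, with
    nominal (or sampled) errors."""
    r1, r2, noe = rates_from_model(model, tensor, spin, nh_angle)
    e1, e2, en = noise_frac * r1, noise_frac * r2, 0.02
    if rng is not None:
        r1 += rng.normal(0, e1)
        r2 += rng.normal(0, e2)
        noe += rng.normal(0, en)
    return RelaxationRecord(residue, r1, e1, r2, e2, noe, en)


@pytest.fixture(scope="module")
def spin():
    return SpinSystem(800.2)


@pytest.fixture(scope="module")
def tensor():
    return DiffusionTensor("isotropic", 10.8e-9)


class TestFitModel:
    def test_noiseless_m1_exact(self, spin, tensor):
        rec = record_from(MotionalModel("M1", S2=0.87), tensor, spin)
        m, chi2, info = fit_model(rec, "M1", tensor, None, spin)
        assert m.S2 == pytest.approx(0.87, abs=1e-9)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert info["converged"]

    def test_model_mismatch_vs_match(self, spin, tensor):
        """Data generated with Rex misfit by M1 but fit exactly by M3."""
        rec = record_from(MotionalModel("M3", S2=0.88, Rex=3.0), tensor,
                          spin)
        _, chi2_m1, _ = fit_model(rec, "M1", tensor, None, spin)
        m3, chi2_m3, _ = fit_model(rec, "M3", tensor, None, spin)
        assert chi2_m1 > 20.0
        assert chi2_m3 == pytest.approx(0.0, abs=1e-10)
        assert m3.Rex == pytest.approx(3.0, abs=1e-6)

    def test_noisy_m2_matches_grid_oracle(self, spin, tensor):
        """A noisy M2 fit lands on the same chi2 minimum as a dense 2-D
        grid search and within 3 sigma of the generating values."""
        rng = np.random.default_rng(5)
        true = MotionalModel("M2", S2=0.82, tau_e=40e-12)
        rec = record_from(true, tensor, spin, rng=rng)
        m, chi2, _ = fit_model(rec, "M2", tensor, None, spin)

        obs = np.array([rec.r1, rec.r2, rec.noe])
        sig = np.array([rec.r1_err, rec.r2_err, rec.noe_err])
        best = (np.inf, None)
        for s2 in np.linspace(0.70, 0.95, 126):
            for te in np.linspace(0.0, 200e-12, 201):
                calc = rates_from_model(
                    MotionalModel("M2", S2=s2, tau_e=te), tensor, spin)
                c = float(np.sum(((obs - np.array(calc)) / sig) ** 2))
                if c < best[0]:
                    best = (c, (s2, te))
        assert chi2 <= best[0] + 1e-6
        assert m.S2 == pytest.approx(best[1][0], abs=0.005)
        # parameter recovery at 2% noise (generous 3-sigma style bound)
        assert abs(m.S2 - 0.82) < 0.08

    def test_unknown_model_rejected(self, spin, tensor):
        rec = record_from(MotionalModel("M1", S2=0.9), tensor, spin)
        with pytest.raises(ValueError):
            fit_model(rec, "M9", tensor, None, spin)


class TestSelectModel:
    def test_noiseless_m1_selected_deterministically(self, spin, tensor):
        rec = record_from(MotionalModel("M1", S2=0.91), tensor, spin)
        for _ in range(3):
            assert select_model(rec, tensor, None, spin).model_id == "M1"

    def test_extra_parameters_never_unjustified_on_exact_data(
            self, spin, tensor):
        """Noiseless data from each simple generating model never gets a
        more complex model assigned."""
        cases = [MotionalModel("M1", S2=0.9),
                 MotionalModel("M1", S2=0.5)]
        for true in cases:
            rec = record_from(true, tensor, spin)
            assert select_model(rec, tensor, None, spin).model_id == "M1"

    def test_m1_truth_recovered_in_most_replicates(self, spin, tensor):
        rng = np.random.default_rng(17)
        hits = 0
        n = 200
        for _ in range(n):
            rec = record_from(MotionalModel("M1", S2=0.90), tensor, spin,
                              rng=rng)
            if select_model(rec, tensor, None, spin).model_id == "M1":
                hits += 1
        assert hits >= 0.9 * n

    def test_rex_truth_yields_exchange_model(self, spin, tensor):
        rng = np.random.default_rng(23)
        hits = 0
        n = 25
        for _ in range(n):
            rec = record_from(MotionalModel("M3", S2=0.88, Rex=5.0),
                              tensor, spin, rng=rng)
            if select_model(rec, tensor, None, spin).model_id in \
                    ("M3", "M4"):
                hits += 1
        assert hits >= 0.9 * n

    def test_trace_records_all_candidates(self, spin, tensor):
        rec = record_from(MotionalModel("M1", S2=0.9), tensor, spin)
        mf = select_model(rec, tensor, None, spin)
        assert set(mf.trace) == {"M1", "M2", "M3", "M4", "M5"}


class TestMonteCarloErrors:
    def test_errors_vanish_with_observational_noise(self, spin, tensor):
        rec = record_from(MotionalModel("M1", S2=0.9), tensor, spin,
                          noise_frac=1e-9)
        rec = RelaxationRecord(1, rec.r1, 1e-9 * rec.r1, rec.r2,
                               1e-9 * rec.r2, rec.noe, 1e-9)
        mf = select_model(rec, tensor, None, spin)
        errs = monte_carlo_errors(mf, rec, tensor, None, spin, n_iter=100,
                                  seed=1)
        assert errs["S2"] < 1e-8

    def test_errors_scale_linearly(self, spin, tensor):
        """Doubling the observational sigma roughly doubles the S2
        error (first-order propagation)."""
        rec1 = record_from(MotionalModel("M1", S2=0.9), tensor, spin,
                           noise_frac=0.02)
        rec2 = RelaxationRecord(1, rec1.r1, 2 * rec1.r1_err, rec1.r2,
                                2 * rec1.r2_err, rec1.noe,
                                2 * rec1.noe_err)
        mf = select_model(rec1, tensor, None, spin)
        e1 = monte_carlo_errors(mf, rec1, tensor, None, spin, n_iter=500,
                                seed=3)
        e2 = monte_carlo_errors(mf, rec2, tensor, None, spin, n_iter=500,
                                seed=4)
        assert e2["S2"] / e1["S2"] == pytest.approx(2.0, rel=0.25)

    def test_seed_determinism(self, spin, tensor):
        rec = record_from(MotionalModel("M1", S2=0.9), tensor, spin)
        mf = select_model(rec, tensor, None, spin)
        a = monte_carlo_errors(mf, rec, tensor, None, spin, n_iter=100,
                               seed=9)
        b = monte_carlo_errors(mf, rec, tensor, None, spin, n_iter=100,
                               seed=9)
        assert a == b


class TestEstimateDiffusion:
    def test_isotropic_truth_selects_isotropic(self, spin):
        truth = rigid_residue_truth(
            30, DiffusionTensor("isotropic", 10.8e-9), noise=0.02, seed=3)
        ds = make_relaxation_dataset(truth, spin)
        recs = records_from_tables(ds["r1"], ds["r2"], ds["noe"])
        orient = {r.residue: r.nh_vector for r in truth.residues}
        rep = estimate_diffusion(recs, orient, spin)
        assert rep.tensor.kind == "isotropic"
        assert rep.tensor.d_ratio == 1.0
        assert rep.tensor.tau_m == pytest.approx(10.8e-9, rel=0.03)

    def test_oblate_preferred_over_prolate(self, spin):
        """Strongly oblate truth wins the F-test in seeded replicates."""
        wins = 0
        for seed in range(5):
            truth = rigid_residue_truth(
                44, DiffusionTensor("axial_oblate", 10.8e-9, 0.83),
                noise=0.02, seed=100 + seed)
            ds = make_relaxation_dataset(truth, spin)
            recs = records_from_tables(ds["r1"], ds["r2"], ds["noe"])
            orient = {r.residue: r.nh_vector for r in truth.residues}
            rep = estimate_diffusion(recs, orient, spin)
            if rep.tensor.kind == "axial_oblate":
                wins += 1
        assert wins == 5

    def test_missing_orientations_fall_back_isotropic(self, spin):
        truth = rigid_residue_truth(
            20, DiffusionTensor("isotropic", 10.8e-9), noise=0.02, seed=4)
        ds = make_relaxation_dataset(truth, spin)
        recs = records_from_tables(ds["r1"], ds["r2"], ds["noe"])
        rep = estimate_diffusion(recs, None, spin)
        assert rep.tensor.kind == "isotropic"
        assert any("isotropic" in w for w in rep.warnings)

    def test_too_few_rigid_residues_rejected(self, spin, tensor):
        recs = [record_from(MotionalModel("M1", S2=0.9), tensor, spin,
                            residue=i) for i in range(1, 6)]
        with pytest.raises(ValueError, match="rigid"):
            estimate_diffusion(recs, None, spin)

    def test_rigid_subset_filters_flexible_and_exchange(self, spin,
                                                        tensor):
        recs = [record_from(MotionalModel("M1", S2=0.9), tensor, spin,
                            residue=i) for i in range(1, 21)]
        flexible = record_from(MotionalModel("M2", S2=0.3, tau_e=1.5e-9),
                               tensor, spin, residue=50)
        exchanging = record_from(MotionalModel("M3", S2=0.9, Rex=12.0),
                                 tensor, spin, residue=51)
        subset = select_rigid_subset(recs + [flexible, exchanging])
        ids = {r.residue for r in subset}
        assert 50 not in ids  # NOE too low
        assert 51 not in ids  # R2/R1 outlier
        assert len(ids) == 20

    def test_invariant_to_intensity_rescaling(self, spin):
        """Rates (and hence the tensor) are unchanged when every decay
        intensity is rescaled uniformly."""
        truth = rigid_residue_truth(
            15, DiffusionTensor("isotropic", 10.8e-9), noise=0.02, seed=6)
        ds = make_relaxation_dataset(truth, spin)
        recs_a = records_from_tables(ds["r1"], ds["r2"], ds["noe"])
        scaled = {k: ds[k].copy() for k in ("r1", "r2", "noe")}
        for k in ("r1", "r2"):
            scaled[k]["intensity"] *= 7.3
            scaled[k]["sigma"] *= 7.3
        for c in ("i_sat", "i_ref", "sigma_sat", "sigma_ref"):
            scaled["noe"][c] *= 7.3
        recs_b = records_from_tables(scaled["r1"], scaled["r2"],
                                     scaled["noe"])
        for a, b in zip(recs_a, recs_b):
            assert a.r1 == pytest.approx(b.r1, rel=1e-6)
            assert a.r2 == pytest.approx(b.r2, rel=1e-6)
            assert a.noe == pytest.approx(b.noe, rel=1e-9)
        orient = {r.residue: r.nh_vector for r in truth.residues}
        rep_a = estimate_diffusion(recs_a, orient, spin)
        rep_b = estimate_diffusion(recs_b, orient, spin)
        assert rep_a.tensor.tau_m == pytest.approx(rep_b.tensor.tau_m,
                                                   rel=1e-6)


class TestInertia:
    def test_cube_is_spherical(self):
        pts = [(x, y, z) for x in (-1, 1) for y in (-1, 1)
               for z in (-1, 1)]
        res = inertia_ratio(pts)
        assert res.ratios == pytest.approx((1.0, 1.0, 1.0), abs=1e-12)

    def test_planar_cross_matches_eigen_oracle(self):
        """Four unit masses at (+-1,0,0), (0,+-2,0): moments from the
        direct 3x3 eigen-decomposition."""
        pts = np.array([(1, 0, 0), (-1, 0, 0), (0, 2, 0), (0, -2, 0)],
                       float)
        res = inertia_ratio(pts)
        m = np.ones(4)
        r = pts - pts.mean(0)
        I = np.diag((m * (r**2).sum(1)).sum() * np.ones(3)) - \
            np.einsum("i,ij,ik->jk", m, r, r)
        ref = np.sort(np.linalg.eigvalsh(I))[::-1]
        assert res.moments == pytest.approx(tuple(ref), rel=1e-12)
        assert res.ratios == pytest.approx((1.0, 0.8, 0.2), abs=1e-12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            inertia_ratio([(0.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="collinear"):
            inertia_ratio([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])

    def test_ratio_ordering_invariant(self, rng):
        pts = rng.normal(size=(30, 3)) * np.array([3.0, 2.0, 1.0])
        res = inertia_ratio(pts, masses=rng.uniform(1, 16, 30))
        assert res.ratios[0] == 1.0
        assert 1.0 >= res.ratios[1] >= res.ratios[2] > 0.0
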
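import numpy as np
import pytest

from mrkit.estimators import (
    InsufficientInstrumentsError,
    contamination_mixture,
    egger,
    ivw,
    leave_one_out,
    select_primary_estimate,
    steiger,
    wald_ratio,
    weighted_median,
)
from mrkit.simulate import SimulationConfig, simulate_sumstats
from mrkit.sumstats import harmonize

from conftest import make_hset
from oracles import (
    contamination_oracle,
    egger_oracle_oriented,
    ivw_oracle,
    weighted_median_oracle,
)


class TestWaldRatio:
    def test_direct_division(self):
        r = wald_ratio(0.1, 0.01, 0.02, 0.005)
        assert r.estimate == pytest.approx(0.2)
        assert r.se == pytest.approx(0.05)

    def test_zero_outcome(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.005).estimate == 0.0

    def test_sign_symmetry(self):
        a = wald_ratio(0.1, 0.01, 0.02, 0.005)
        b = wald_ratio(-0.1, 0.01, 0.02, 0.005)
        assert b.estimate == -a.estimate
        assert b.se == a.se

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.02, 0.005)

    def test_second_order_se_larger(self):
        first = wald_ratio(0.1, 0.05, 0.02, 0.005)
        second = wald_ratio(0.1, 0.05, 0.02, 0.005, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_identical_ratios(self):
        hset = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.01] * 3)
        r = ivw(hset)
        assert r.estimate == pytest.approx(0.5)
        assert r.q == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_equal_weights(self):
        hset = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.03, 0.04, 0.05], [0.01] * 3)
        assert ivw(hset).estimate == pytest.approx(0.026 / 0.14)

    def test_two_snp_equals_weighted_wald_average(self):
        bx, by, sy = [0.1, 0.25], [0.03, 0.02], [0.01, 0.02]
        hset = make_hset(bx, [0.01] * 2, by, sy)
        ratios = np.array(by) / np.array(bx)
        w = (np.array(bx) / np.array(sy)) ** 2
        assert ivw(hset).estimate == pytest.approx(np.average(ratios, weights=w))

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_hset([0.1], [0.01], [0.02], [0.01]))

    def test_matches_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(2, 12)
            bx = rng.normal(0.1, 0.05, n)
            bx[bx == 0] = 0.05
            by = rng.normal(0.02, 0.03, n)
            sy = rng.uniform(0.005, 0.05, n)
            hset = make_hset(bx, np.full(n, 0.01), by, sy)
            r = ivw(hset)
            est, se, q = ivw_oracle(bx, None, by, sy)
            assert r.estimate == pytest.approx(est, rel=1e-10)
            assert r.se == pytest.approx(se, rel=1e-10)
            assert r.q == pytest.approx(q, rel=1e-10)

    def test_order_and_flip_invariance(self, rng):
        n = 8
        bx = rng.normal(0.1, 0.05, n)
        by = rng.normal(0.02, 0.03, n)
        sy = rng.uniform(0.005, 0.05, n)
        base = ivw(make_hset(bx, np.full(n, 0.01), by, sy))
        perm = rng.permutation(n)
        shuffled = ivw(make_hset(bx[perm], np.full(n, 0.01), by[perm], sy[perm]))
        assert shuffled.estimate == pytest.approx(base.estimate)
        flip = rng.choice([-1.0, 1.0], n)
        flipped = ivw(make_hset(bx * flip, np.full(n, 0.01), by * flip, sy))
        assert flipped.estimate == pytest.approx(base.estimate)
        assert flipped.se == pytest.approx(base.se)


class TestEgger:
    def test_exact_proportionality(self):
        hset = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.01] * 3)
        r = egger(hset)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.estimate == pytest.approx(0.5)

    def test_hand_ols_three_points(self):
        hset = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.03, 0.04, 0.05], [0.01] * 3)
        r = egger(hset)
        assert r.estimate == pytest.approx(0.1)
        assert r.intercept == pytest.approx(0.02)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.01] * 2, [0.03, 0.04], [0.01] * 2))

    def test_matches_oracle_with_orientation(self, rng):
        for _ in range(20):
            n = rng.integers(3, 12)
            bx = rng.normal(0.0, 0.1, n)
            bx[bx == 0] = 0.05
            by = rng.normal(0.0, 0.05, n)
            sy = rng.uniform(0.005, 0.05, n)
            r = egger(make_hset(bx, np.full(n, 0.01), by, sy))
            slope, intercept = egger_oracle_oriented(bx, by, sy)
            assert r.estimate == pytest.approx(slope, rel=1e-9, abs=1e-12)
            assert r.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-12)

    def test_zero_intercept_constraint_reproduces_ivw(self, rng):
        # the no-intercept weighted normal equation solved by IVW is the
        # intercept-constrained Egger fit
        n = 10
        bx = np.abs(rng.normal(0.2, 0.05, n))
        by = 0.3 * bx + rng.normal(0, 0.01, n)
        sy = rng.uniform(0.005, 0.02, n)
        hset = make_hset(bx, np.full(n, 0.01), by, sy)
        w = 1 / sy**2
        constrained_slope = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert ivw(hset).estimate == pytest.approx(constrained_slope, rel=1e-12)

    def test_directional_pleiotropy_power(self):
        reps = 40
        hits = 0
        for i in range(reps):
            cfg = SimulationConfig(
                m_snps=150, m_instruments=150, sigma_gamma=0.15,
                theta_direct=0.2, pleiotropy_fraction=1.0,
                pleiotropy_mean=0.02, pleiotropy_sd=0.005,
                n_exposure=100_000, n_outcome=100_000, n_mediator=1000,
                seed=3000 + i)
            data, _ = simulate_sumstats(cfg)
            hset = harmonize(data["exposure"][0], data["outcome"][0])
            if egger(hset).intercept_p < 0.05:
                hits += 1
        assert hits / reps > 0.5


class TestWeightedMedian:
    def test_equal_ratios(self):
        hset = make_hset([0.1, 0.2, 0.4], [0.001] * 3, [0.05, 0.1, 0.2], [0.001] * 3)
        r = weighted_median(hset, n_boot=200, seed=1)
        assert r.estimate == pytest.approx(0.5)
        assert r.se < 0.05

    def test_equal_weight_median(self):
        hset = make_hset([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.01] * 3)
        assert weighted_median(hset, n_boot=10, seed=1).estimate == pytest.approx(0.2)

    def test_interpolation_matches_oracle(self):
        # ratios (0.1, 0.2, 0.9), weights (0.45, 0.45, 0.10)
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        sy = 1.0 / np.sqrt(np.array([0.45, 0.45, 0.10]))
        hset = make_hset(bx, [0.01] * 3, by, sy)
        r = weighted_median(hset, n_boot=10, seed=1)
        expected = weighted_median_oracle([0.1, 0.2, 0.9], [0.45, 0.45, 0.10])
        assert 0.1 < r.estimate < 0.2
        assert r.estimate == pytest.approx(expected, rel=1e-12)

    def test_majority_weight_snp_wins(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.5, 0.9])
        sy = 1.0 / np.sqrt(np.array([0.1, 0.8, 0.1]))
        r = weighted_median(make_hset(bx, [0.01] * 3, by, sy), n_boot=10, seed=1)
        assert r.estimate == pytest.approx(0.5)

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            n = rng.integers(3, 12)
            ratios = rng.normal(0.2, 0.3, n)
            weights = rng.uniform(0.1, 2.0, n)
            bx = np.ones(n)
            by = ratios
            sy = 1.0 / np.sqrt(weights)
            r = weighted_median(make_hset(bx, np.full(n, 0.01), by, sy),
                                n_boot=10, seed=1)
            assert r.estimate == pytest.approx(
                weighted_median_oracle(list(ratios), list(weights)), rel=1e-9)

    def test_bootstrap_seeded(self, simple_hset):
        a = weighted_median(simple_hset, n_boot=100, seed=42)
        b = weighted_median(simple_hset, n_boot=100, seed=42)
        assert a.se == b.se


class TestContaminationMixture:
    def test_no_contamination(self):
        rng = np.random.default_rng(5)
        n = 20
        bx = np.full(n, 1.0)
        by = 0.2 + rng.normal(0, 0.005, n)
        sy = np.full(n, 0.005)
        r = contamination_mixture(make_hset(bx, np.full(n, 0.01), by, sy), psi=0.1)
        assert r.estimate == pytest.approx(0.2, abs=0.01)
        assert len(r.ci_set) == 1

    def test_bimodal_contamination_matches_oracle(self):
        # 7 SNPs exactly at 0.2, 5 at 0.8: the larger cluster carries more
        # likelihood, so the estimate sits at the 0.2 mode
        bx = np.ones(12)
        by = np.array([0.2] * 7 + [0.8] * 5)
        sy = np.full(12, 0.01)
        hset = make_hset(bx, np.full(12, 0.01), by, sy)
        r = contamination_mixture(hset, psi=0.5, grid_resolution=500)
        ratios = by / bx
        ratio_se = sy / np.abs(bx)
        span = ratios.max() - ratios.min()
        grid = np.linspace(ratios.min() - 0.25 * span, ratios.max() + 0.25 * span, 501)
        best, lls = contamination_oracle(list(ratios), list(ratio_se), 0.5, grid)
        assert r.estimate == pytest.approx(best, abs=1e-9)
        assert r.estimate == pytest.approx(0.2, abs=0.02)  # better-supported mode

    def test_ci_set_contains_estimate(self, simple_hset):
        r = contamination_mixture(simple_hset)
        assert any(lo <= r.estimate <= hi for lo, hi in r.ci_set)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            contamination_mixture(make_hset([0.1, 0.2], [0.01] * 2,
                                            [0.03, 0.04], [0.01] * 2))

    def test_psi_must_be_positive(self, simple_hset):
        with pytest.raises(ValueError):
            contamination_mixture(simple_hset, psi=0.0)


class TestLeaveOneOut:
    def test_homogeneous_no_flags(self):
        rng = np.random.default_rng(7)
        n = 10
        bx = rng.uniform(0.1, 0.3, n)
        by = 0.2 * bx + rng.normal(0, 0.0005, n)
        hset = make_hset(bx, np.full(n, 0.01), by, np.full(n, 0.01))
        entries = leave_one_out(hset)
        assert len(entries) == n
        assert not any(e.flagged for e in entries)

    def test_outlier_flagged_as_driver(self):
        n = 10
        bx = np.full(n, 0.2)
        by = np.zeros(n)
        by[-1] = 0.4  # ratio 2.0 vs 0.0 elsewhere
        sy = np.full(n, 0.01)
        sy[-1] = 0.001  # tiny se: dominates
        hset = make_hset(bx, np.full(n, 0.01), by, sy)
        entries = leave_one_out(hset)
        outlier = entries[-1]
        assert outlier.flagged
        # verify by direct refit
        sub = hset.subset(list(range(n - 1)))
        from mrkit.estimators import ivw as _ivw
        assert outlier.result.estimate == pytest.approx(_ivw(sub).estimate)

    def test_output_length(self, simple_hset):
        assert len(leave_one_out(simple_hset)) == len(simple_hset)


class TestSteiger:
    def test_clear_direction(self):
        hset = make_hset([0.1], [0.01], [0.001], [0.01], mafs=[0.3])
        # pad to allow vector ops
        hset = make_hset([0.1, 0.12, 0.09], [0.01] * 3, [0.001, 0.002, 0.001],
                         [0.01] * 3, mafs=[0.3, 0.3, 0.3])
        res = steiger(hset, n_exp=100_000, n_out=100_000,
                      exposure_binary=False, outcome_binary=False)
        assert res.direction_correct.all()
        assert len(res.retained) == 3

    def test_equal_r2_not_correct(self):
        hset = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.1, 0.1],
                         [0.01] * 3, mafs=[0.3] * 3)
        res = steiger(hset, n_exp=50_000, n_out=50_000,
                      exposure_binary=False, outcome_binary=False)
        assert not res.direction_correct.any()  # strict >
        np.testing.assert_allclose(res.steiger_p, 1.0)

    def test_missing_sample_size(self, simple_hset):
        with pytest.raises(ValueError):
            steiger(simple_hset, n_exp=0, n_out=100_000)

    def test_reverse_causal_removed_in_simulation(self):
        cfg = SimulationConfig(
            m_snps=200, m_instruments=100, sigma_gamma=0.15,
            theta_direct=0.1, m_reverse=100, reverse_effect_sd=0.15,
            reverse_transmission=0.3,
            n_exposure=100_000, n_outcome=100_000, n_mediator=1000, seed=11)
        data, truth = simulate_sumstats(cfg)
        hset = harmonize(data["exposure"][0], data["outcome"][0])
        res = steiger(hset, n_exp=100_000, n_out=100_000,
                      exposure_binary=False, outcome_binary=True)
        ids = np.array(res.variant_ids)
        reverse = np.isin(ids, truth.reverse_instrument_ids)
        removed_frac = (~res.direction_correct[reverse]).mean()
        assert removed_frac > 0.8
        forward = np.isin(ids, truth.valid_instrument_ids)
        kept_frac = res.direction_correct[forward].mean()
        assert kept_frac > 0.8


class TestSelectPrimaryEstimate:
    def _results(self, intercept_p):
        from mrkit.estimators import MRResult
        ivw_r = MRResult("ivw", 0.3, 0.05, 0.2, 0.4, 1e-9, 10)
        egg_r = MRResult("egger", 0.4, 0.1, 0.2, 0.6, 1e-4, 10,
                         intercept=0.01, intercept_se=0.005, intercept_p=intercept_p)
        return ivw_r, egg_r

    def test_null_intercept_selects_ivw(self):
        chosen, rationale = select_primary_estimate(*self._results(0.33))
        assert chosen.method == "ivw"
        assert "IVW" in rationale

    def test_pleiotropic_intercept_selects_egger(self):
        chosen, _ = select_primary_estimate(*self._results(0.04))
        assert chosen.method == "egger"

    def test_boundary_exactly_005_selects_ivw(self):
        chosen, _ = select_primary_estimate(*self._results(0.05))
        assert chosen.method == "ivw"
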
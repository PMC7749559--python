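"""Non-steady-state turnover estimation: closed forms vs the ODE oracle,
limit behaviour, identifiability guards, and cohort-level recovery."""

import dataclasses
import math
import statistics

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from heavywater.kinetics import (
    InvalidEstimateError,
    estimate_cohort_turnover,
    kdeg_nonsteady,
    kdeg_steady,
    ksyn_for_pool_ratio,
    ksyn_nonsteady,
    summarize_turnover,
)
from heavywater.simulate import NoiseModel, default_groups, simulate_cohort, simulate_pool


def ode_survival(kdeg, t):
    """Numerically integrated fraction of original protein surviving to t."""
    sol = solve_ivp(lambda _, s: [-kdeg * s[0]], (0, t), [1.0], rtol=1e-11, atol=1e-14)
    return sol.y[0][-1]


def ode_observables(ksyn, kdeg, t, p0=1.0):
    sol = solve_ivp(
        lambda _, y: [ksyn - kdeg * y[0], ksyn - kdeg * y[1]],
        (0, t),
        [p0, 0.0],
        rtol=1e-11,
        atol=1e-14,
    )
    pt, new = sol.y[0][-1], sol.y[1][-1]
    return new / pt, pt / p0


def oracle_kdeg(f, r, t):
    """Independent estimate: root of ODE-integrated survival = r(1-f)."""
    target = r * (1.0 - f)
    return brentq(lambda k: ode_survival(k, t) - target, 0.0, 5.0, xtol=1e-12)


class TestSteady:
    def test_zero_fraction_gives_zero_rate(self):
        assert kdeg_steady(0.0, 5.0) == 0.0

    def test_inverse_pair(self):
        assert kdeg_steady(1 - math.exp(-1.0), 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_generator_round_trip_at_steady_state(self):
        kdeg = 0.0211
        pool = simulate_pool(kdeg * 1.0, kdeg, 1.0, 5.0)
        assert kdeg_steady(pool.fraction_new, 5.0) == pytest.approx(kdeg, rel=1e-10)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            kdeg_steady(1.0, 5.0)
        with pytest.raises(ValueError):
            kdeg_steady(-0.1, 5.0)


class TestNonSteady:
    def test_r_one_equals_steady_exactly(self):
        for f in (0.0, 0.041, 0.2, 0.5, 0.9):
            assert kdeg_nonsteady(f, 1.0, 5.0) == kdeg_steady(f, 5.0)

    def test_steady_limit_is_continuous_near_r_one(self):
        f = 0.2
        for r in (1.0 - 1e-6, 1.0 + 1e-6):
            assert kdeg_nonsteady(f, r, 5.0) == pytest.approx(
                kdeg_steady(f, 5.0), abs=1e-6
            )

    def test_pure_decay_limit(self):
        k = 0.3
        assert kdeg_nonsteady(0.0, math.exp(-k * 5.0), 5.0) == pytest.approx(k, rel=1e-12)

    def test_recovery_against_ode_oracle(self):
        pool = simulate_pool(0.02, 0.049, 1.0, 5.0)
        f, r = pool.fraction_new, pool.r
        assert kdeg_nonsteady(f, r, 5.0) == pytest.approx(0.049, rel=1e-8)
        assert oracle_kdeg(f, r, 5.0) == pytest.approx(0.049, rel=1e-8)

    def test_closed_form_and_root_methods_agree(self):
        pool = simulate_pool(0.02, 0.049, 1.0, 5.0)
        a = kdeg_nonsteady(pool.fraction_new, pool.r, 5.0, method="closed_form")
        b = kdeg_nonsteady(pool.fraction_new, pool.r, 5.0, method="root")
        assert a == pytest.approx(b, rel=1e-10)

    def test_negative_rate_guard(self):
        """r(1-f) > 1 implies a negative degradation rate; never emitted."""
        with pytest.raises(InvalidEstimateError):
            kdeg_nonsteady(0.01, 1.1, 5.0)

    def test_boundary_r_times_one_minus_f_equal_one_is_zero_rate(self):
        assert kdeg_nonsteady(0.0, 1.0, 5.0) == 0.0


class TestKsyn:
    def test_steady_state_is_kdeg_times_p0(self):
        assert ksyn_nonsteady(0.02, 0.095, 1.0, 1.0, 5.0) == pytest.approx(0.02, rel=1e-12)

    def test_pure_decay_recovers_zero(self):
        pool = simulate_pool(0.0, 0.1, 1.0, 5.0)
        k = kdeg_nonsteady(pool.fraction_new, pool.r, 5.0)
        assert ksyn_nonsteady(k, pool.fraction_new, pool.r, 1.0, 5.0) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_grid_round_trip_noise_free(self):
        """Planted (ksyn, kdeg) grid recovered through (f, r) to 1e-8."""
        for ksyn in np.linspace(0.005, 0.2, 7):
            for kdeg in np.linspace(0.005, 0.2, 7):
                pool = simulate_pool(ksyn, kdeg, 1.0, 5.0)
                k_hat = kdeg_nonsteady(pool.fraction_new, pool.r, 5.0)
                s_hat = ksyn_nonsteady(k_hat, pool.fraction_new, pool.r, 1.0, 5.0)
                assert abs(k_hat - kdeg) / kdeg <= 1e-8
                assert abs(s_hat - ksyn) / ksyn <= 1e-8

    def test_estimates_reproduce_observables_via_ode(self):
        pool = simulate_pool(0.033, 0.07, 1.0, 5.0)
        k = kdeg_nonsteady(pool.fraction_new, pool.r, 5.0)
        s = ksyn_nonsteady(k, pool.fraction_new, pool.r, 1.0, 5.0)
        f_num, r_num = ode_observables(s, k, 5.0)
        assert f_num == pytest.approx(pool.fraction_new, rel=1e-8)
        assert r_num == pytest.approx(pool.r, rel=1e-8)

    def test_ksyn_for_pool_ratio_inverts_forward_model(self):
        ksyn = ksyn_for_pool_ratio(0.05, 0.85, 5.0)
        assert simulate_pool(ksyn, 0.05, 1.0, 5.0).r == pytest.approx(0.85, rel=1e-12)


class TestCohortEstimation:
    def test_noise_free_cohort_recovers_planted_rates_exactly(self, noise_free_cohort):
        est = estimate_cohort_turnover(noise_free_cohort)
        truth = noise_free_cohort.to_frame()[["animal_id", "fraction", "true_kdeg", "true_ksyn"]]
        merged = est.merge(truth, on=["animal_id", "fraction"])
        assert merged["valid"].all()
        assert np.allclose(merged["kdeg"], merged["true_kdeg"], rtol=1e-9)
        nonsteady = merged[merged["method"] == "non_steady"]
        assert np.allclose(nonsteady["ksyn"], nonsteady["true_ksyn"], rtol=1e-9)

    def test_group_means_match_plants(self, noise_free_cohort):
        summary = summarize_turnover(estimate_cohort_turnover(noise_free_cohort))
        frame = noise_free_cohort.to_frame()
        for _, row in summary.iterrows():
            planted = frame[
                (frame["group"] == row["group"]) & (frame["fraction"] == row["fraction"])
            ]["true_kdeg"].iloc[0]
            assert row["kdeg_mean"] == pytest.approx(planted, rel=1e-9)
        assert (summary["n_invalid"] == 0).all()

    def test_steady_cohort_methods_agree(self, zero_noise):
        # all groups at steady state: non-steady and steady estimates coincide
        groups = []
        for g in default_groups(n_per_group=2):
            kdeg = g.true_kdeg
            groups.append(dataclasses.replace(g, true_ksyn={k: v for k, v in kdeg.items()}))
        ds = simulate_cohort(groups, noise=zero_noise, n_fibers=2)
        nonsteady = estimate_cohort_turnover(ds)
        steady = estimate_cohort_turnover(
            ds, marker_policy={f: "steady" for f in ("myofibrillar", "cytosolic", "mitochondrial")}
        )
        assert np.allclose(nonsteady["kdeg"], steady["kdeg"], rtol=1e-9)

    def test_missing_marker_downgrades_to_steady(self, noise_free_cohort):
        est = estimate_cohort_turnover(noise_free_cohort)
        cyt = est[est["fraction"] == "cytosolic"]
        assert (cyt["method"] == "steady").all()
        frame = noise_free_cohort.to_frame()
        frame.loc[frame["fraction"] == "mitochondrial", "marker_ratio"] = np.nan
        est2 = estimate_cohort_turnover(frame)
        mito = est2[est2["fraction"] == "mitochondrial"]
        assert (mito["method"] == "steady").all()
        assert mito["marker_downgraded"].all()

    def test_invalid_samples_flagged_not_dropped_silently(self, noise_free_cohort):
        frame = noise_free_cohort.to_frame()
        # force one mitochondrial marker to imply negative degradation
        idx = frame[frame["fraction"] == "mitochondrial"].index[0]
        frame.loc[idx, "marker_ratio"] = 2.0
        est = estimate_cohort_turnover(frame)
        bad = est[~est["valid"]]
        assert len(bad) == 1
        assert np.isnan(bad["kdeg"].iloc[0])
        summary = summarize_turnover(est)
        assert summary["n_invalid"].sum() == 1

    def test_median_bias_small_under_default_noise(self):
        """Group-mean kdeg is nearly unbiased (|median bias| <= 2%) at n = 8
        under the default measurement-noise model."""
        groups = default_groups()
        truth = {g.label: g.true_kdeg["myofibrillar"] for g in groups}
        means = {label: [] for label in truth}
        for rep in range(100):
            ds = simulate_cohort(groups, noise=NoiseModel(seed=20_000 + rep), n_fibers=2)
            frame = ds.to_frame()
            sub = frame[frame["fraction"] == "myofibrillar"]
            est = estimate_cohort_turnover(sub)
            for label, mean in est[est["valid"]].groupby("group")["kdeg"].mean().items():
                means[label].append(mean)
        for label, vals in means.items():
            med = statistics.median(vals)
            assert abs(med - truth[label]) / truth[label] <= 0.02
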
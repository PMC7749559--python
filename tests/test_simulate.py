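"""Synthetic-data generator: body water, pool kinetics, isotopomer forward map,
cohort assembly and its determinism/physicality contracts."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from heavywater import mida
from heavywater.enrichment import correct_natural_abundance
from heavywater.simulate import (
    FRACTIONS,
    GroupSpec,
    LabelingProtocol,
    NoiseModel,
    default_groups,
    isotopomerize,
    simulate_alanine_enrichment,
    simulate_body_water,
    simulate_cohort,
    simulate_pool,
)


class TestBodyWater:
    def test_no_label_gives_zero_curve(self):
        protocol = LabelingProtocol(bolus_dose=0.0, water_enrichment=0.0)
        _, curve = simulate_body_water(protocol)
        assert np.all(curve == 0.0)

    def test_bolus_matching_plateau_gives_constant_curve(self):
        # choose the bolus so the initial enrichment equals the plateau
        plateau = 0.05
        pool_ul = 600.0
        bolus = plateau * pool_ul / (0.99 - plateau)
        protocol = LabelingProtocol(bolus_dose=bolus, water_enrichment=plateau)
        _, curve = simulate_body_water(protocol)
        assert np.allclose(curve, plateau, rtol=0, atol=1e-12)

    def test_closed_form_matches_ode_integration(self, protocol):
        """One-compartment closed form vs numerical integration oracle."""
        days = np.arange(0.0, protocol.label_duration_t + 0.5, 1.0)
        _, curve = simulate_body_water(protocol, times=days)
        lam, plat = protocol.water_turnover, protocol.plateau_enrichment
        sol = solve_ivp(
            lambda t, a: lam * (plat - a),
            (0.0, days[-1]),
            [protocol.initial_enrichment],
            t_eval=days,
            rtol=1e-11,
            atol=1e-14,
        )
        assert np.allclose(curve, sol.y[0], rtol=1e-8, atol=1e-12)

    def test_curve_stays_physical(self, protocol):
        _, curve = simulate_body_water(protocol, times=np.linspace(0, 30, 200))
        assert np.all((curve >= 0) & (curve < 0.5))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            LabelingProtocol(label_duration_t=0.0)


def _ode_pool(ksyn, kdeg, p0, t):
    """Numerical-integration oracle for the pool ODE (P and new mass N)."""
    sol = solve_ivp(
        lambda _, y: [ksyn - kdeg * y[0], ksyn - kdeg * y[1]],
        (0.0, t),
        [p0, 0.0],
        rtol=1e-11,
        atol=1e-14,
    )
    return sol.y[0][-1], sol.y[1][-1]


class TestPool:
    def test_steady_state_pool_is_constant(self):
        # ksyn = kdeg * P0 holds the pool at its equilibrium value
        kdeg, p0 = 0.0211, 1.0
        pool = simulate_pool(kdeg * p0, kdeg, p0, 5.0)
        assert pool.pt == pytest.approx(p0, rel=1e-12)
        assert pool.r == pytest.approx(1.0, rel=1e-12)

    def test_pure_decay(self):
        pool = simulate_pool(0.0, 0.1, 2.0, 5.0)
        assert pool.pt == pytest.approx(2.0 * math.exp(-0.5), rel=1e-12)
        assert pool.new_mass == 0.0

    def test_zero_rates_keep_pool_constant(self):
        pool = simulate_pool(0.0, 0.0, 1.0, 5.0)
        assert pool.pt == 1.0 and pool.new_mass == 0.0

    def test_kdeg_zero_is_linear_growth(self):
        pool = simulate_pool(0.03, 0.0, 1.0, 5.0)
        assert pool.pt == pytest.approx(1.15, rel=1e-12)
        assert pool.new_mass == pytest.approx(0.15, rel=1e-12)

    def test_closed_form_matches_ode_oracle(self):
        pool = simulate_pool(0.02, 0.049, 1.0, 5.0)
        pt, new = _ode_pool(0.02, 0.049, 1.0, 5.0)
        assert pool.pt == pytest.approx(pt, rel=1e-8)
        assert pool.new_mass == pytest.approx(new, rel=1e-8)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ksyn=st.floats(0.0, 0.3),
        kdeg=st.floats(0.0, 0.5),
        t=st.floats(0.1, 30.0),
    )
    def test_closed_form_ode_agreement_and_physicality(self, ksyn, kdeg, t):
        pool = simulate_pool(ksyn, kdeg, 1.0, t)
        assert pool.pt > 0
        assert 0.0 <= pool.new_mass <= pool.pt + 1e-12
        pt, new = _ode_pool(ksyn, kdeg, 1.0, t)
        assert pool.pt == pytest.approx(pt, rel=1e-8, abs=1e-10)
        assert pool.new_mass == pytest.approx(new, rel=1e-8, abs=1e-10)


class TestAlanineEnrichment:
    def test_zero_precursor_gives_zero(self):
        pool = simulate_pool(0.02, 0.049, 1.0, 5.0)
        assert simulate_alanine_enrichment(pool, 0.0) == 0.0

    def test_fully_renewed_pool_reaches_precursor(self):
        # steady state, kdeg * t >> 1: the whole pool is new
        pool = simulate_pool(0.5, 0.5, 1.0, 200.0)
        assert simulate_alanine_enrichment(pool, 0.0555) == pytest.approx(0.0555, rel=1e-9)

    def test_composition_with_ode_oracle(self):
        pool = simulate_pool(0.02, 0.049, 1.0, 5.0)
        pt, new = _ode_pool(0.02, 0.049, 1.0, 5.0)
        assert simulate_alanine_enrichment(pool, 0.0555) == pytest.approx(
            0.0555 * new / pt, rel=1e-8
        )

    def test_bounds(self):
        pool = simulate_pool(0.02, 0.049, 1.0, 5.0)
        e = simulate_alanine_enrichment(pool, 0.1)
        assert 0.0 <= e <= 0.1


class TestIsotopomerize:
    def test_zero_enrichment_is_baseline(self, natural_dist):
        dist = isotopomerize(0.0, natural_dist=natural_dist)
        assert np.allclose(dist.fractions, natural_dist, atol=1e-15)

    @pytest.mark.parametrize("excess", [0.001, 0.01, 0.05, 0.1])
    def test_round_trip_is_identity(self, natural_dist, excess):
        dist = isotopomerize(excess, natural_dist=natural_dist)
        assert correct_natural_abundance(dist, natural_dist) == pytest.approx(
            excess, abs=1e-12
        )

    def test_linear_m1_excess_matches_binomial_expansion(self, natural_dist):
        """The linear map's M1 excess agrees with the exact integer-site
        binomial expansion to within the first-order approximation bound."""
        body_water, n_sites, excess = 0.005, 4, 0.02
        linear = isotopomerize(excess, natural_dist=natural_dist)
        exact = isotopomerize(
            excess, n_sites=n_sites, natural_dist=natural_dist,
            mode="binomial", body_water=body_water,
        )
        m1_lin = linear.fractions[1] - natural_dist[1]
        m1_bin = exact.fractions[1] - natural_dist[1]
        # relative agreement bounded by the per-site enrichment scale
        assert m1_lin == pytest.approx(m1_bin, rel=(n_sites - 1) * body_water * 2)

    def test_distribution_sums_to_one_under_noise(self, natural_dist):
        rng = np.random.default_rng(0)
        noise = NoiseModel(isotopomer_sd=0.01)
        for _ in range(20):
            dist = isotopomerize(0.02, natural_dist=natural_dist, noise=noise, rng=rng)
            assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(dist.fractions >= 0)


class TestCohort:
    def test_duplicate_group_labels_rejected(self):
        g = default_groups()[0]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort([g, dataclasses.replace(g)])

    def test_fixed_seed_is_byte_identical(self):
        groups = [dataclasses.replace(g, n_animals=2) for g in default_groups()]
        a = simulate_cohort(groups, noise=NoiseModel(seed=42), n_fibers=10)
        b = simulate_cohort(groups, noise=NoiseModel(seed=42), n_fibers=10)
        assert a.to_frame().to_csv(index=False) == b.to_frame().to_csv(index=False)
        assert a.fibers_frame().to_csv(index=False) == b.fibers_frame().to_csv(index=False)

    def test_zero_noise_identical_groups_give_identical_animals(self, zero_noise):
        base = default_groups()[0]
        groups = [
            dataclasses.replace(base, n_animals=3),
            dataclasses.replace(base, n_animals=3, treatment="LLC"),
        ]
        groups[1] = dataclasses.replace(
            groups[1],
            true_ksyn=base.true_ksyn,
            true_kdeg=base.true_kdeg,
            sd_conduction_velocity=0.0,
            csa_sigma=1e-9,
        )
        groups[0] = dataclasses.replace(
            groups[0], sd_conduction_velocity=0.0, csa_sigma=1e-9
        )
        ds = simulate_cohort(groups, noise=zero_noise, n_fibers=3)
        frame = ds.to_frame().drop(columns=["animal_id", "group", "treatment"])
        myof = frame[frame["fraction"] == "myofibrillar"].drop_duplicates()
        assert len(myof) == 1  # every animal identical

    def test_ground_truth_carried_for_all_fractions(self, noise_free_cohort):
        frame = noise_free_cohort.to_frame()
        assert set(frame["fraction"]) == set(FRACTIONS)
        assert frame["true_kdeg"].notna().all()
        mass_cols = frame[["m0", "m1", "m2", "m3"]].to_numpy()
        assert np.allclose(mass_cols.sum(axis=1), 1.0, atol=1e-12)

    def test_noise_free_marker_equals_true_pool_ratio(self, noise_free_cohort):
        frame = noise_free_cohort.to_frame()
        sub = frame[frame["fraction"] != "cytosolic"]
        assert np.allclose(sub["marker_ratio"], sub["true_r"], atol=1e-12)
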
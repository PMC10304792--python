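"""Simulator behaviour: single wells, MIC assays, dose-response, panels."""

import math
import warnings

import numpy as np
import pytest

from heterores import (
    AssayDesign,
    HeteroresError,
    InoculumEffectModel,
    ResistanceDistribution,
    SimulationDesignError,
    expected_max_quantile,
    fit_inoculum_effect,
    generate_panel,
    sample_population,
    simulate_dose_response,
    simulate_mic_exp,
    simulate_well,
)
from heterores.simulate import _score_mic


class TestSamplePopulation:
    def test_homogeneous_population_is_constant(self):
        d = ResistanceDistribution(0.6, 0.0)
        pop = sample_population(d, 100, np.random.default_rng(0))
        assert np.all(pop == pytest.approx(10**0.6))

    def test_median_and_log_spread_match_parameters(self, dist):
        pop = sample_population(dist, 100_000, np.random.default_rng(1))
        assert np.median(pop) == pytest.approx(dist.ic50_mM, rel=0.01)
        assert np.std(np.log10(pop), ddof=1) == pytest.approx(
            dist.sigma_log10, rel=0.02
        )

    def test_rejects_empty_population(self, dist):
        with pytest.raises(ValueError):
            sample_population(dist, 0, np.random.default_rng(0))


class TestSimulateWell:
    def test_zero_cells_never_grow(self, dist):
        assert simulate_well(dist, 0, 1.0, np.random.default_rng(0)) is False

    def test_homogeneous_wells_are_deterministic(self):
        d = ResistanceDistribution(math.log10(4.0), 0.0)
        rng = np.random.default_rng(0)
        assert simulate_well(d, 10, 3.9, rng) is True
        assert simulate_well(d, 10, 4.1, rng) is False
        # strict exceedance: resistance exactly equal to c does not grow
        assert simulate_well(d, 10, 4.0, rng) is False

    def test_growth_probability_matches_closed_form(self, dist):
        # P(no growth) = Phi((log10 c - mu)/sigma)^n
        rng = np.random.default_rng(5)
        n, c, wells = 100, 5.0, 5000
        grown = simulate_well(dist, n, c, rng, size=wells)
        p_clear = dist.cdf_log10(math.log10(c)) ** n
        se = math.sqrt(p_clear * (1 - p_clear) / wells)
        assert (~grown).mean() == pytest.approx(p_clear, abs=3 * se)


class TestScoringRules:
    def test_any_clear_never_exceeds_all_clear(self):
        rng = np.random.default_rng(9)
        grid = np.arange(0.125, 5.0, 0.125)
        for _ in range(200):
            clear = rng.integers(0, 5, size=len(grid))
            any_mic = _score_mic(clear, grid, 4, "any-clear")
            all_mic = _score_mic(clear, grid, 4, "all-clear")
            if not math.isnan(any_mic) and not math.isnan(all_mic):
                assert any_mic <= all_mic
            if math.isnan(any_mic):  # no clear well at all
                assert math.isnan(all_mic)

    def test_rules_ordered_on_identical_assay_draws(self, dist):
        # same seed => identical well outcomes; only the scoring differs
        kw = dict(
            inoculum_sizes=(1e2, 1e4),
            biological_replicates=3,
        )
        obs_any = simulate_mic_exp(
            dist, AssayDesign(scoring_rule="any-clear", **kw),
            np.random.default_rng(21),
        )
        obs_all = simulate_mic_exp(
            dist, AssayDesign(scoring_rule="all-clear", **kw),
            np.random.default_rng(21),
        )
        for a, b in zip(obs_any, obs_all):
            assert a.mic_exp_mM <= b.mic_exp_mM


class TestSimulateMicExp:
    def test_homogeneous_population_reads_first_grid_value_above_ic50(self):
        d = ResistanceDistribution(math.log10(4.03), 0.0)
        design = AssayDesign(poisson_inoculum=False, biological_replicates=2)
        obs = simulate_mic_exp(d, design, np.random.default_rng(0))
        for o in obs:
            assert o.mic_exp_mM == pytest.approx(4.125)  # ceil to the 0.125 grid

    def test_mean_mic_increases_with_inoculum_when_heteroresistant(self, dist):
        design = AssayDesign(scoring_rule="all-clear", biological_replicates=10)
        obs = simulate_mic_exp(dist, design, np.random.default_rng(3))
        means = {
            n: np.mean([o.mic_exp_mM for o in obs if o.inoculum_cells == n])
            for n in (1e2, 1e5)
        }
        assert means[1e5] > means[1e2]

    def test_single_well_all_clear_tracks_order_statistic_curve(self, dist):
        # 1 technical replicate, all-clear: E[log10 MIC] ~ mu + sigma*z(n)
        design = AssayDesign(
            technical_replicates=1,
            biological_replicates=60,
            scoring_rule="all-clear",
            poisson_inoculum=False,
        )
        obs = simulate_mic_exp(dist, design, np.random.default_rng(17))
        for n in design.inoculum_sizes:
            mean_mic = np.mean([o.mic_exp_mM for o in obs if o.inoculum_cells == n])
            predicted = dist.predicted_mic_exp(n)
            assert abs(mean_mic - predicted) < 2 * design.concentration_increment

    def test_grid_exhaustion_raises_design_error(self):
        d = ResistanceDistribution(math.log10(8.0), 0.05)
        design = AssayDesign(concentration_max=2.0, biological_replicates=2)
        with pytest.raises(SimulationDesignError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            simulate_mic_exp(d, design, np.random.default_rng(0))

    def test_partial_censoring_flagged_and_excluded_from_fit(self, dist):
        # grid covers the small inocula but not the 1e5-cell tail
        design = AssayDesign(concentration_max=7.0, biological_replicates=4,
                             scoring_rule="all-clear")
        with pytest.warns(UserWarning):
            obs = simulate_mic_exp(dist, design, np.random.default_rng(12))
        censored = [o for o in obs if o.censored]
        assert censored and all(math.isnan(o.mic_exp_mM) for o in censored)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_inoculum_effect(obs)
        assert res.nobs == len(obs) - len(censored)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            AssayDesign(concentration_increment=0.0)
        with pytest.raises(ValueError):
            AssayDesign(scoring_rule="median")
        with pytest.raises(ValueError):
            AssayDesign(inoculum_sizes=(0.5, 100))


class TestRecovery:
    def test_default_assay_recovers_parameters(self, dist, all_clear_design):
        """Per-replicate fits + aggregation recover sigma and IC50 on average
        (40 simulated assays; the full 100-run check with the tight IC50
        band runs in the acceptance suite)."""
        rng = np.random.default_rng(101)
        ic50s, sigmas = [], []
        for _ in range(40):
            obs = simulate_mic_exp(dist, all_clear_design, rng)
            fits = [
                fit_inoculum_effect([o for o in obs if o.replicate_id == rep])
                for rep in sorted({o.replicate_id for o in obs})
            ]
            ic50s.append(np.mean([f.ic50_mM for f in fits]))
            sigmas.append(np.mean([f.heteroresistance for f in fits]))
        assert np.mean(sigmas) == pytest.approx(dist.sigma_log10, rel=0.30)
        assert np.mean(ic50s) == pytest.approx(dist.ic50_mM, rel=0.10)

    def test_grid_refinement_never_worsens_bias(self, dist):
        """Halving the concentration step shrinks |recovery bias| under
        all-clear scoring (common random seeds across increments)."""
        biases = {}
        for inc in (0.25, 0.125, 0.0625):
            sig_hat, mu_hat = [], []
            for run in range(40):
                rng = np.random.default_rng(3000 + run)
                design = AssayDesign(
                    concentration_start=inc,
                    concentration_increment=inc,
                    scoring_rule="all-clear",
                )
                obs = simulate_mic_exp(dist, design, rng)
                fits = [
                    fit_inoculum_effect([o for o in obs if o.replicate_id == rep])
                    for rep in sorted({o.replicate_id for o in obs})
                ]
                sig_hat.append(np.mean([f.heteroresistance for f in fits]))
                mu_hat.append(np.mean([np.log10(f.ic50_mM) for f in fits]))
            biases[inc] = (
                abs(np.mean(sig_hat) - dist.sigma_log10) / dist.sigma_log10,
                abs(np.mean(mu_hat) - dist.mu_log10),
            )
        slack = 0.01  # Monte-Carlo allowance on a relative bias
        assert biases[0.125][0] <= biases[0.25][0] + slack
        assert biases[0.0625][0] <= biases[0.125][0] + slack
        assert biases[0.125][1] <= biases[0.25][1] + slack
        assert biases[0.0625][1] <= biases[0.125][1] + slack


class TestSimulateDoseResponse:
    CONCS = np.concatenate([[0.0], np.linspace(2.0, 6.5, 10)])

    def test_control_is_exactly_100_without_poisson(self, dist):
        obs = simulate_dose_response(
            dist, self.CONCS, np.random.default_rng(0), poisson_inoculum=False
        )
        for o in obs:
            if o.concentration_mM == 0.0:
                assert o.percent_survival == 100.0

    def test_mean_survival_matches_closed_form(self, dist):
        c = 4.5
        obs = simulate_dose_response(
            dist, [0.0, c], np.random.default_rng(8),
            inoculum_sizes=(1e4,), biological_replicates=50,
            poisson_inoculum=False,
        )
        vals = [o.percent_survival for o in obs if o.concentration_mM == c]
        expected = 100.0 * dist.survival_fraction(c)
        se = 100.0 * math.sqrt(expected / 100 * (1 - expected / 100) / 1e4 / 50)
        assert np.mean(vals) == pytest.approx(expected, abs=4 * se)

    def test_survival_at_ic50_is_half(self, dist):
        obs = simulate_dose_response(
            dist, [0.0, dist.ic50_mM], np.random.default_rng(4),
            inoculum_sizes=(1e4,), biological_replicates=30,
        )
        vals = [o.percent_survival for o in obs if o.concentration_mM > 0]
        assert np.mean(vals) == pytest.approx(50.0, abs=1.0)

    def test_requires_control_concentration(self, dist):
        with pytest.raises(ValueError):
            simulate_dose_response(dist, [1.0, 2.0], np.random.default_rng(0))

    def test_zero_cfu_control_dropped_with_warning(self, dist):
        with pytest.warns(UserWarning, match="zero CFU"):
            obs = simulate_dose_response(
                dist, [0.0, 4.0], np.random.default_rng(2),
                inoculum_sizes=(0.2,), biological_replicates=20,
            )
        assert all(o.percent_survival >= 0 for o in obs)


class TestGeneratePanel:
    SPECS = [("s1", "sp", math.log10(3.5), 0.05), ("s2", "sp", math.log10(4.5), 0.09)]

    def test_duplicate_strain_ids_rejected(self, all_clear_design):
        with pytest.raises(HeteroresError):
            generate_panel(
                [("a", "sp", 0.6, 0.05), ("a", "sp", 0.7, 0.08)],
                all_clear_design, np.random.default_rng(0),
            )

    def test_truth_table_and_observations_cover_all_strains(self, all_clear_design):
        data = generate_panel(self.SPECS, all_clear_design, np.random.default_rng(1))
        assert set(data.truth.strain_id) == {"s1", "s2"}
        assert {o.strain_id for o in data.mic_observations} == {"s1", "s2"}
        assert {o.strain_id for o in data.dose_observations} == {"s1", "s2"}

    def test_homogeneous_strain_recovered_exactly_to_grid(self):
        design = AssayDesign(poisson_inoculum=False, biological_replicates=2,
                             scoring_rule="all-clear")
        data = generate_panel(
            [("flat", "sp", math.log10(4.03), 0.0)], design, np.random.default_rng(0)
        )
        res = fit_inoculum_effect(data.mic_observations)
        assert res.heteroresistance == 0.0
        assert res.ic50_mM == pytest.approx(4.125)  # grid ceiling of the true IC50

    def test_fixed_seed_reproduces_panel(self, all_clear_design):
        d1 = generate_panel(self.SPECS, all_clear_design, np.random.default_rng(7))
        d2 = generate_panel(self.SPECS, all_clear_design, np.random.default_rng(7))
        assert d1.mic_observations == d2.mic_observations
        assert d1.dose_observations == d2.dose_observations
        assert d1.truth.equals(d2.truth)
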
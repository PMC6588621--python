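import numpy as np
import pandas as pd
import pytest

from prawnvision.spectra import DEFAULT_GRID
from prawnvision.synthetic import (
    ColourChangeSchedule,
    SpectrumModel,
    dulse_model,
    green_prawn_model,
    red_prawn_model,
    sample_reflectance,
    sample_spectrum_library,
    sea_lettuce_model,
    simulate_choice_trials,
    simulate_colour_change,
)


class TestSampleReflectance:
    def test_flat_noiseless_is_constant(self):
        model = SpectrumModel(kind="flat", baseline=0.3, noise_sd=0.0)
        spec = sample_reflectance(model, 0, jitter=False)
        np.testing.assert_allclose(spec.values, 0.3)

    def test_zero_amplitude_peak_equals_baseline(self):
        model = SpectrumModel(kind="green_peak", amplitude=0.0, baseline=0.2, noise_sd=0.0)
        spec = sample_reflectance(model, 0, jitter=False)
        np.testing.assert_allclose(spec.values, 0.2)

    def test_deterministic_under_seed(self):
        model = green_prawn_model()
        s1 = sample_reflectance(model, 42)
        s2 = sample_reflectance(model, 42)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_bounded_in_unit_interval(self):
        for model in (green_prawn_model(), red_prawn_model(), sea_lettuce_model(), dulse_model()):
            spec = sample_reflectance(model, 7)
            assert np.all((spec.values >= 0) & (spec.values <= 1))

    def test_overfull_reflectance_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            SpectrumModel(kind="green_peak", amplitude=0.7, baseline=0.4)

    def test_red_has_higher_short_wave_baseline_than_green(self):
        """The short-wave crossover premise: red coloration carries more
        short-wavelength reflectance than green coloration."""
        g = green_prawn_model().evaluate(DEFAULT_GRID)
        r = red_prawn_model().evaluate(DEFAULT_GRID)
        short = DEFAULT_GRID < 480
        assert r[short].mean() > g[short].mean()


class TestColourChangeSchedule:
    def test_mixing_saturates_at_m_max(self):
        sched = ColourChangeSchedule(k_per_day=100.0)
        assert sched.mixing(5) == pytest.approx(0.8)

    def test_front_loaded_change(self):
        sched = ColourChangeSchedule()
        early = sched.mixing(10) - sched.mixing(0)
        late = sched.mixing(30) - sched.mixing(20)
        assert early > late

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ColourChangeSchedule(days=(5, 0, 10), dropout_hazard=(0.0, 0.0))
        with pytest.raises(ValueError):
            ColourChangeSchedule(k_per_day=-1.0)
        with pytest.raises(ValueError):
            ColourChangeSchedule(dropout_hazard=(0.0,) * 3)


@pytest.fixture(scope="module")
def run():
    return simulate_colour_change(
        green_prawn_model(), red_prawn_model(), n_individuals=25, rng_seed=7
    )


class TestSimulateColourChange:

    def test_truth_covers_all_days_and_individuals(self, run):
        assert len(run.truth) == 25 * 7
        assert sorted(run.truth["day"].unique()) == [0, 5, 10, 15, 20, 25, 30]

    def test_spectra_only_for_survivors(self, run):
        alive = run.truth[run.truth["alive"]]
        assert set(run.spectra) == set(zip(alive["individual"], alive["day"]))

    def test_full_survival_through_day_10(self, run):
        early = run.truth[run.truth["day"] <= 10]
        assert early["alive"].all()

    def test_mixing_monotone_toward_target(self, run):
        for _, traj in run.truth.groupby("individual"):
            m = traj.sort_values("day")["m"].to_numpy()
            assert np.all(np.diff(m) > 0)
            assert m[0] == 0.0 and m[-1] < 0.8

    def test_size_coupling_slows_large_individuals(self, run):
        truth = run.truth.drop_duplicates("individual")
        big = truth.nlargest(5, "size_mm")["k"].mean()
        small = truth.nsmallest(5, "size_mm")["k"].mean()
        assert big < small

    def test_no_size_coupling_when_beta_zero(self):
        sched = ColourChangeSchedule(beta_per_mm=0.0)
        run = simulate_colour_change(
            green_prawn_model(), red_prawn_model(), sched, n_individuals=10, rng_seed=1
        )
        assert run.truth["k"].nunique() == 1

    def test_deterministic_under_seed(self):
        r1 = simulate_colour_change(green_prawn_model(), red_prawn_model(), n_individuals=5, rng_seed=3)
        r2 = simulate_colour_change(green_prawn_model(), red_prawn_model(), n_individuals=5, rng_seed=3)
        pd.testing.assert_frame_equal(r1.truth, r2.truth)

    def test_instant_kinetics_reach_mixture_limit_by_day_5(self):
        sched = ColourChangeSchedule(k_per_day=100.0, beta_per_mm=0.0)
        start = SpectrumModel(kind="flat", baseline=0.2, noise_sd=0.0,
                              peak_jitter_nm=0.0, amplitude_jitter_rel=0.0,
                              baseline_jitter_rel=0.0)
        target = SpectrumModel(kind="flat", baseline=0.6, noise_sd=0.0,
                               peak_jitter_nm=0.0, amplitude_jitter_rel=0.0,
                               baseline_jitter_rel=0.0)
        run = simulate_colour_change(start, target, sched, n_individuals=1, rng_seed=0)
        day5 = run.spectra[("prawn_000", 5)]
        # m = m_max = 0.8: reflectance = 0.2*0.2 + 0.8*0.6
        np.testing.assert_allclose(day5.values, 0.52, atol=1e-9)


class TestSpectrumLibrary:
    def test_size_determinism_and_bounds(self):
        lib = sample_spectrum_library(50, 4)
        lib2 = sample_spectrum_library(50, 4)
        assert len(lib) == 50
        for a, b in zip(lib, lib2):
            np.testing.assert_array_equal(a.values, b.values)
            assert np.all((a.values >= 0) & (a.values <= 1))


class TestChoiceTrials:
    def test_no_choice_probability_zero_choice(self):
        trials = simulate_choice_trials(20, p_choice_made=0.0, rng_seed=0)
        assert (trials["outcome"] == "no_choice").all()

    def test_perfect_matching(self):
        trials = simulate_choice_trials(50, p_choice_made=1.0, p_match_given_choice=1.0, rng_seed=0)
        green = trials[trials["colour_type"] == "green"]
        red = trials[trials["colour_type"] == "red"]
        assert (green["outcome"] == "sea_lettuce").all()
        assert (red["outcome"] == "dulse").all()

    def test_deterministic_and_sized(self):
        t1 = simulate_choice_trials(90, rng_seed=3)
        t2 = simulate_choice_trials(90, rng_seed=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 180

    def test_default_power_against_null(self):
        """With ~44% decision rate and 0.8 matching preference over 90
        trials/type, the exact binomial test rejects p0 = 0.5 at alpha = 0.01
        with probability ~0.9 per test. The Monte-Carlo rejection fraction
        must agree with the exactly enumerated power of the design."""
        from scipy.stats import binom

        from prawnvision.stats import summarise_choices

        # exact power by enumeration over n_choices ~ Bin(90, .44),
        # matched ~ Bin(n, .8), small-mass two-sided p-values
        alpha, power = 0.01, 0.0
        for n in range(1, 91):
            pn = binom.pmf(n, 90, 0.44)
            if pn < 1e-12:
                continue
            pmf_null = binom.pmf(np.arange(n + 1), n, 0.5)
            pvals = np.array(
                [pmf_null[pmf_null <= pmf_null[k] * (1 + 1e-9)].sum() for k in range(n + 1)]
            )
            power += pn * binom.pmf(np.arange(n + 1), n, 0.8)[pvals < alpha].sum()

        n_rep, rejections, n_tests = 200, 0, 0
        for seed in range(n_rep):
            summary = summarise_choices(simulate_choice_trials(rng_seed=seed))
            rejections += int((summary["two_sided_p"] < alpha).sum())
            n_tests += len(summary)
        frac = rejections / n_tests
        se = np.sqrt(power * (1 - power) / n_tests)
        assert abs(frac - power) < 4 * se
        assert frac >= 0.85
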
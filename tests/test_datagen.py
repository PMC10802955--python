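"""Unit and property tests of the cohort generator."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mcibench.datagen import (
    HETEROGENEITY_SHIFTS,
    NACC_FEATURES,
    ConfigurationError,
    FeatureSpec,
    ScenarioConfig,
    SurvivalDataset,
    SurvivalSpec,
    WeightScheme,
    assemble_dataset,
    build_interaction_dummies,
    expand_design,
    generate_features,
    linear_predictor,
    resolve_weights,
    sample_censoring,
    sample_event_times,
    simulate_cohort,
)

SPEC_BY_NAME = {s.name: s for s in NACC_FEATURES}


class TestFeatureSpec:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            FeatureSpec("X", "bernoulli", (0, 1), (0.6, 0.5))

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ConfigurationError):
            FeatureSpec("X", "multinomial", (0, 0, 1), (0.2, 0.3, 0.5))

    def test_uniform_bounds_ordered(self):
        with pytest.raises(ConfigurationError):
            FeatureSpec("X", "uniform", (5.0, 1.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            FeatureSpec("X", "geometric", (0, 1), (0.5, 0.5))


class TestGenerateFeatures:
    def test_empty_cohort_keeps_all_columns(self, rng):
        table = generate_features(NACC_FEATURES, 0, rng)
        assert list(table.columns) == [s.name for s in NACC_FEATURES]
        assert len(table) == 0

    def test_category_codes_preserved(self, rng):
        table = generate_features(NACC_FEATURES, 2000, rng)
        assert set(np.unique(table["COGSTAT"])) <= {0, 1, 9}
        assert set(np.unique(table["TRAVEL"])) <= {0, 1, 2}
        assert table["AGE"].between(55, 85).all()
        assert table["EDUCATION"].between(0, 36).all()

    @pytest.mark.parametrize(
        "name, code, p",
        [
            ("MEMORY", 1, 0.083),
            ("JUDGMENT", 1, 0.04),
            ("DECCLIN", 1, 0.05),
            ("MOTREM", 1, 0.01),
            ("DECIN", 1, 0.12),
            ("SEX", 1, 0.5),
            ("TRAVEL", 2, 0.02),
            ("COGSTAT", 9, 0.14),
        ],
    )
    def test_marginal_frequencies(self, rng, name, code, p):
        """Sample frequencies sit within 3 binomial SDs of their marginals."""
        n = 100_000
        table = generate_features(NACC_FEATURES, n, rng)
        freq = float((table[name] == code).mean())
        band = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < band

    def test_cogstat_goodness_of_fit(self, rng):
        """Chi-square GOF against the stated multinomial cell probabilities."""
        n = 100_000
        table = generate_features(NACC_FEATURES, n, rng)
        observed = [(table["COGSTAT"] == c).sum() for c in (0, 1, 9)]
        expected = [n * p for p in (0.7, 0.16, 0.14)]
        _, pval = stats.chisquare(observed, expected)
        assert pval > 0.01


class TestInteractionDummies:
    @pytest.mark.parametrize(
        "sex, cog, expect",
        [
            (1, 1, (1, 0)),  # female, abnormal score
            (1, 9, (0, 1)),  # female, no clinician opinion
            (1, 0, (0, 0)),
            (0, 0, (0, 0)),  # males always zero
            (0, 1, (0, 0)),
            (0, 9, (0, 0)),
        ],
    )
    def test_truth_table(self, sex, cog, expect):
        table = pd.DataFrame({"SEX": [sex], "COGSTAT": [cog]})
        out = build_interaction_dummies(table)
        assert (out["F_COGSTAT_1"].iloc[0], out["F_COGSTAT_9"].iloc[0]) == expect

    def test_original_columns_untouched(self, rng):
        table = generate_features(NACC_FEATURES, 50, rng)
        out = build_interaction_dummies(table)
        pd.testing.assert_frame_equal(out[table.columns.tolist()], table)

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            build_interaction_dummies(pd.DataFrame({"SEX": [1]}))


class TestResolveWeights:
    def test_none_level_shares_male_weights(self):
        scheme = WeightScheme(heterogeneity_level="none")
        eff = resolve_weights(scheme)
        assert scheme.female_cogstat == scheme.male_cogstat == (0.57, -0.44)
        assert eff["F_COGSTAT_1"] == 0.0 and eff["F_COGSTAT_9"] == 0.0

    def test_small_level_shifts_by_interaction_means(self):
        scheme = WeightScheme(heterogeneity_level="small")
        assert scheme.female_cogstat == pytest.approx((0.57 - 0.13, -0.44 - 0.31))

    def test_large_level_shifts_by_mean_plus_two_sd(self):
        scheme = WeightScheme(heterogeneity_level="large")
        expected = (0.57 - (0.13 + 2 * 0.13), -0.44 - (0.31 + 2 * 0.16))
        assert scheme.female_cogstat == pytest.approx(expected)
        eff = resolve_weights(scheme)
        assert eff["F_COGSTAT_1"] == pytest.approx(-(0.13 + 2 * 0.13))

    def test_effective_map_applies_base_scale(self):
        scheme = WeightScheme(base_weights={"MEMORY": 0.9}, base_scale=2.0)
        eff = resolve_weights(scheme)
        assert eff["MEMORY"] == pytest.approx(1.8)
        assert eff["COGSTAT_1"] == pytest.approx(0.57)  # never rescaled

    def test_unknown_level_rejected(self):
        with pytest.raises(ConfigurationError):
            WeightScheme(heterogeneity_level="huge")


class TestLinearPredictor:
    def test_zero_weights_give_unit_rate(self, rng):
        table = generate_features(NACC_FEATURES, 20, rng)
        design = expand_design(table)
        lam = linear_predictor(design, {c: 0.0 for c in design.columns})
        assert np.allclose(lam, 1.0)

    def test_single_binary_term(self):
        design = pd.DataFrame({"MEMORY": [1.0, 0.0]})
        lam = linear_predictor(design, {"MEMORY": 0.57})
        assert lam == pytest.approx([np.exp(0.57), 1.0])

    def test_matches_dot_product_oracle(self, rng):
        table = generate_features(NACC_FEATURES, 200, rng)
        design = expand_design(build_interaction_dummies(table), include_interactions=True)
        weights = {c: rng.normal() for c in design.columns}
        lam = linear_predictor(design, weights)
        # independent oracle: explicit row-wise dot product and exponentiation
        beta = np.array([weights[c] for c in design.columns])
        oracle = np.exp(design.to_numpy() @ beta)
        assert np.allclose(lam, oracle, atol=1e-12, rtol=1e-12)

    def test_monotone_in_positive_weighted_feature(self):
        design = pd.DataFrame({"MEMORY": np.linspace(0, 3, 7)})
        lam = linear_predictor(design, {"MEMORY": 0.8})
        assert np.all(np.diff(lam) > 0)

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigurationError):
            linear_predictor(pd.DataFrame({"A": [1.0]}), {"B": 1.0})


class _FixedUniform:
    """Stub RNG yielding a fixed uniform value (for closed-form inversion)."""

    def __init__(self, u):
        self.u = u

    def uniform(self, size=None):
        return np.full(size, self.u)


class TestEventTimes:
    def test_exponential_closed_form_inversion(self):
        spec = SurvivalSpec(family="exponential")
        t = sample_event_times(np.array([1.0]), spec, _FixedUniform(np.exp(-1.0)))
        assert t[0] == pytest.approx(1.0, abs=1e-12)

    def test_exponential_mean(self, rng):
        spec = SurvivalSpec(family="exponential")
        t = sample_event_times(np.full(100_000, 2.0), spec, rng)
        assert np.mean(t) == pytest.approx(0.5, rel=0.02)

    def test_weibull_shape_one_equals_exponential(self, rng):
        lam = np.full(10_000, 1.3)
        t_w = sample_event_times(lam, SurvivalSpec(family="weibull", shape=1.0), rng)
        t_e = sample_event_times(lam, SurvivalSpec(family="exponential"), rng)
        _, pval = stats.ks_2samp(t_w, t_e)
        assert pval > 0.01

    def test_loglogistic_median(self, rng):
        # median of (1/lam)*(U/(1-U))^(1/shape) is 1/lam
        t = sample_event_times(np.full(100_000, 2.0), SurvivalSpec(family="loglogistic", shape=1.5), rng)
        assert np.median(t) == pytest.approx(0.5, rel=0.03)

    def test_all_positive(self, rng):
        for fam in ("exponential", "weibull", "loglogistic"):
            t = sample_event_times(np.full(1000, 0.7), SurvivalSpec(family=fam), rng)
            assert np.all(t > 0)

    def test_nonfinite_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_event_times(np.array([np.inf]), SurvivalSpec(), rng)


class TestCensoring:
    def test_nonnegative(self, rng):
        t = sample_censoring(5000, SurvivalSpec(), rng)
        assert np.all(t >= 0)

    def test_zero_mass_matches_normal_cdf(self, rng):
        """The exact point mass at 0 equals Phi(-mu/sigma)."""
        n = 1_000_000
        t = sample_censoring(n, SurvivalSpec(), rng)
        p0 = stats.norm.cdf(-2.0 / 3.611)
        band = 3 * np.sqrt(p0 * (1 - p0) / n)
        assert abs((t == 0).mean() - p0) < band

    def test_mean_matches_quadrature(self, rng):
        """Mean of max(0, N(2, 3.611)) vs numeric integration of the density."""
        n = 1_000_000
        t = sample_censoring(n, SurvivalSpec(), rng)
        mean_oracle, _ = integrate.quad(
            lambda x: x * stats.norm.pdf(x, 2.0, 3.611), 0, np.inf
        )
        se = np.std(t) / np.sqrt(n)
        assert abs(np.mean(t) - mean_oracle) < 4 * se


class TestAssemble:
    def test_censoring_wins(self):
        feats = pd.DataFrame({"SEX": [0]})
        ds = assemble_dataset(feats, [5.0], [2.0])
        assert ds.time[0] == 2.0 and ds.event[0] == 0 and ds.censored[0] == 1

    def test_tie_counts_as_event(self):
        feats = pd.DataFrame({"SEX": [0]})
        ds = assemble_dataset(feats, [2.0], [2.0])
        assert ds.event[0] == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_dataset(pd.DataFrame({"SEX": [0, 1]}), [1.0], [1.0, 2.0])

    def test_observed_time_invariants(self, rng):
        cfg = ScenarioConfig(n_subjects=500, seed=5)
        ds = simulate_cohort(cfg, np.random.default_rng(5))
        assert np.all(ds.time <= ds.true_event_time + 1e-15)
        observed = ds.event == 1
        assert np.allclose(ds.time[observed], ds.true_event_time[observed])

    def test_omitted_feature_same_times_as_full_release(self):
        """Omission hides the column but the generated outcomes are identical."""
        base = ScenarioConfig(n_subjects=300, seed=9)
        omitted = ScenarioConfig(n_subjects=300, seed=9, omitted_features=("COGSTAT",))
        full = simulate_cohort(base, np.random.default_rng(42))
        reduced = simulate_cohort(omitted, np.random.default_rng(42))
        assert "COGSTAT" not in reduced.features.columns
        assert "COGSTAT" in full.features.columns
        np.testing.assert_array_equal(full.time, reduced.time)
        np.testing.assert_array_equal(full.event, reduced.event)

    def test_unknown_omitted_feature_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(omitted_features=("NOPE",))


class TestReproducibilityAndExport:
    def test_same_seed_same_cohort(self):
        cfg = ScenarioConfig(n_subjects=200, seed=77)
        a = simulate_cohort(cfg, np.random.default_rng(77))
        b = simulate_cohort(cfg, np.random.default_rng(77))
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_csv_round_trip(self):
        cfg = ScenarioConfig(n_subjects=50, seed=3)
        ds = simulate_cohort(cfg, np.random.default_rng(3))
        buf = io.StringIO()
        ds.to_csv(buf)
        buf.seek(0)
        back = SurvivalDataset.from_csv(buf)
        np.testing.assert_allclose(back.time, ds.time)
        np.testing.assert_array_equal(back.event, ds.event)
        pd.testing.assert_frame_equal(
            back.features, ds.features, check_dtype=False
        )

    def test_null_weights_give_unit_exponential(self):
        """All-zero weights: event times are iid Exponential(1)."""
        scheme = WeightScheme(
            base_weights={k: 0.0 for k in WeightScheme().base_weights},
            base_scale=0.0,
            male_cogstat=(0.0, 0.0),
        )
        cfg = ScenarioConfig(n_subjects=10_000, seed=4, weights=scheme)
        ds = simulate_cohort(cfg, np.random.default_rng(4))
        _, pval = stats.kstest(ds.true_event_time, "expon")
        assert pval > 0.01
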
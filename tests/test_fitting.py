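"""Refitting machinery: preprocessing, OLS suite, BIC weights, LOOCV."""

import numpy as np
import pandas as pd
import pytest

import allomass as am
from allomass.errors import FittingError, UsageError, ValidationError
from allomass.fitting import MODEL_SPECS, comparison_table


def _records(n, widths=None, larvae=0, mass=None):
    rng = np.random.default_rng(7)
    length = rng.uniform(1, 20, n)
    width = widths if widths is not None else rng.uniform(0.25, 0.4, n) * length
    m = mass if mass is not None else 0.05 * length ** 2.5
    return pd.DataFrame(
        {
            "individual_id": [f"r{i}" for i in range(n)],
            "taxon": "Araneae",
            "region": "temperate",
            "length_mm": length,
            "width_mm": width,
            "mass_mg": m,
            "is_larva": [i < larvae for i in range(n)],
        }
    )


def brute_force_loocv(df, spec):
    """Literal refit-per-observation oracle for leave-one-out CV."""
    errors = []
    for i in df.index:
        train = df.drop(index=i)
        fit = am.fit_single(train, spec)
        by_key = {(p.taxon, p.region): p for p in fit.parameters}
        row = df.loc[i]
        taxon = row["taxon"] if spec.grouping in ("taxreg", "taxon") else None
        region = row["region"] if spec.grouping in ("taxreg", "region") else None
        p = by_key[(taxon, region)]
        pred = p.intercept + p.slope_length * row["log10_length"]
        if spec.use_width:
            pred += p.slope_width * row["log10_width"]
        errors.append((row["log10_mass"] - pred) ** 2)
    return float(np.mean(errors))


class TestPreprocess:
    def test_width_and_length_suite_counts(self):
        df = _records(10)
        df.loc[:2, "width_mm"] = np.nan
        full = am.preprocess(df, require_width=False)
        width_only = am.preprocess(df, require_width=True)
        assert len(full) == 10 and len(width_only) == 7
        assert width_only.attrs["filter_counts"]["missing_width_dropped"] == 3

    def test_larvae_excluded(self):
        df = _records(10, larvae=4)
        out = am.preprocess(df)
        assert len(out) == 6
        assert out.attrs["filter_counts"]["larvae_dropped"] == 4

    def test_tiny_mass_retained_on_log_scale(self):
        df = _records(5)
        df.loc[0, "mass_mg"] = 0.01
        out = am.preprocess(df)
        assert out["log10_mass"].iloc[0] == pytest.approx(-2.0)

    def test_empty_after_filtering_is_usage_error(self):
        df = _records(3, larvae=3)
        with pytest.raises(UsageError):
            am.preprocess(df)


class TestBuildTaxreg:
    def test_levels_distinct_by_region(self):
        a = am.build_taxreg("Araneae", "temperate")
        b = am.build_taxreg("Araneae", "tropical")
        assert a != b and a == "Araneae:temperate"

    def test_builtin_database_yields_32_levels(self, db):
        levels = {
            am.build_taxreg(p.taxon, p.region)
            for p in db if p.model_id == "LWTR"
        }
        assert len(levels) == 32

    def test_missing_field_is_usage_error(self):
        with pytest.raises(UsageError):
            am.build_taxreg("Araneae", None)


class TestBicWeights:
    def test_published_delta_bic_column(self):
        deltas = [0, 196.62, 3490.89, 3585.61, 6759.02, 6994.47, 10707.12, 10894.07]
        w = am.bic_weights(deltas)
        assert np.round(w, 2).tolist() == [1.0] + [0.0] * 7

    def test_two_equal_values_split_evenly(self):
        assert am.bic_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two(self):
        assert am.bic_weights([0.0, 2.0]) == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_normalization_and_shift_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            b = rng.normal(0, 500, size=8)
            w = am.bic_weights(b)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert am.bic_weights(b + 12345.6) == pytest.approx(w, abs=1e-12)

    def test_huge_spread_does_not_overflow(self):
        w = am.bic_weights([0.0, 1e6])
        assert w == pytest.approx([1.0, 0.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            am.bic_weights([0.0, np.nan])


class TestFitSuite:
    def test_zero_noise_recovery_of_generating_equation(self, lw_params):
        cfg = am.SyntheticConfig(
            groups=(am.GroupConfig("Araneae", "temperate", 40, (1.0, 12.0)),),
            parameters={("Araneae", "temperate"): lw_params},
            width_model=am.WidthModel(sigma=0.1),
            mass_noise_sd=0.0,
            seed=11,
        )
        df = am.preprocess(am.generate_community(cfg), require_width=True)
        fit = am.fit_single(df, MODEL_SPECS["LW"])
        (p,) = fit.parameters
        assert p.intercept == pytest.approx(-0.340, abs=1e-9)
        assert p.slope_length == pytest.approx(1.070, abs=1e-9)
        assert p.slope_width == pytest.approx(1.634, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.loocv_mse == pytest.approx(0.0, abs=1e-18)

    def test_suite_minimum_has_delta_zero_and_sorted(self):
        df = am.preprocess(_noisy_two_group(seed=5), require_width=True)
        results = am.fit_model_suite(df)
        assert results[0].delta_bic == 0.0
        bics = [r.bic for r in results]
        assert bics == sorted(bics)
        assert sum(r.bic_weight for r in results) == pytest.approx(1.0)

    def test_generating_family_wins_bic_on_its_own_data(self):
        """Data simulated from taxon x region truths: LWTR should rank first."""
        wins = 0
        for seed in range(3):
            cfg = am.default_community_config(seed=seed, n_per_group=30)
            df = am.preprocess(am.generate_community(cfg), require_width=True)
            results = am.fit_model_suite(df)
            wins += results[0].model_id == "LWTR"
        assert wins >= 2

    def test_nested_models_never_increase_rss(self):
        df = am.preprocess(_noisy_two_group(seed=9), require_width=True)
        fits = {m: am.fit_single(df, MODEL_SPECS[m]) for m in am.MODEL_PREFERENCE}
        for sub, sup in [("L", "LW"), ("L", "LR"), ("LR", "LWR"), ("LW", "LWTR"),
                         ("LT", "LTR"), ("L", "LT")]:
            assert fits[sup].rss <= fits[sub].rss + 1e-10
            assert fits[sup].r2 >= fits[sub].r2 - 1e-12

    def test_undersized_level_error_names_the_level(self):
        df = _records(20)
        extra = _records(2)
        extra["taxon"] = "Odonata"
        extra["individual_id"] = ["odo1", "odo2"]
        both = am.preprocess(pd.concat([df, extra], ignore_index=True), require_width=True)
        with pytest.raises(FittingError, match="Odonata"):
            am.fit_single(both, MODEL_SPECS["LWT"])

    def test_comparison_table_shape(self):
        df = am.preprocess(_noisy_two_group(seed=2), require_width=True)
        table = comparison_table(am.fit_model_suite(df))
        assert list(table.columns) == [
            "model_id", "n_obs", "k_params", "bic", "delta_bic",
            "bic_weight", "r2", "loocv_mse",
        ]
        assert len(table) == 8


class TestLoocv:
    def test_five_point_univariate_matches_brute_force(self):
        df = pd.DataFrame(
            {
                "taxon": "A", "region": "temperate",
                "log10_length": [0.1, 0.4, 0.7, 1.0, 1.3],
                "log10_width": np.nan,
                "log10_mass": [0.0, 0.9, 1.4, 2.3, 2.9],
            }
        )
        shortcut = am.loocv_mse(df, MODEL_SPECS["L"])
        assert shortcut == pytest.approx(brute_force_loocv(df, MODEL_SPECS["L"]), abs=1e-10)

    @pytest.mark.parametrize("model_id", ["L", "LW", "LT"])
    def test_hat_matrix_shortcut_equals_refit_oracle(self, model_id):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 20
            df = pd.DataFrame(
                {
                    "taxon": rng.choice(["A", "B"], n),
                    "region": "temperate",
                    "log10_length": rng.uniform(0, 1.5, n),
                    "log10_width": rng.uniform(-0.5, 1.0, n),
                }
            )
            df["log10_mass"] = (
                -0.3 + 2.0 * df["log10_length"] + 0.5 * df["log10_width"]
                + rng.normal(0, 0.2, n)
            )
            spec = MODEL_SPECS[model_id]
            assert am.loocv_mse(df, spec) == pytest.approx(
                brute_force_loocv(df, spec), rel=1e-8
            )


class TestRSquared:
    def test_noiseless_is_one(self):
        y = np.array([1.0, 2.0, 3.0])
        assert am.r_squared(y, y) == 1.0

    def test_shuffled_response_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1.5, 1000)
        y = -0.3 + 2.0 * x + rng.normal(0, 0.2, 1000)
        y_shuffled = rng.permutation(y)
        slope, intercept = np.polyfit(x, y_shuffled, 1)
        assert abs(am.r_squared(y_shuffled, intercept + slope * x)) < 0.05

    def test_mean_only_model_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert am.r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0, abs=1e-15)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            am.r_squared(np.ones(5), np.ones(5))


def test_smearing_factor_mean_of_backtransformed_residuals():
    res = np.array([0.0, np.log10(2.0)])
    assert am.smearing_factor(res) == pytest.approx(1.5)


def _noisy_two_group(seed=0):
    cfg = am.SyntheticConfig(
        groups=(
            am.GroupConfig("Araneae", "temperate", 60, (1.01, 12.26)),
            am.GroupConfig("Coleoptera", "tropical", 60, (1.10, 43.42)),
        ),
        parameters=None,  # builtin taxon x region truths
        mass_noise_sd=0.13,
        seed=seed,
    )
    return am.generate_community(cfg)
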
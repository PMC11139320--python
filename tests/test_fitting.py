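import math

import numpy as np
import pandas as pd
import pytest

from viscsf.csf_models import PolynomialCSF, exponent_triples, normalize_inputs, polynomial_terms
from viscsf.errors import DataError, DomainError, RankDeficiencyError
from viscsf.fitting import (
    DEFAULT_EXCLUSIONS,
    RidgeConfig,
    ThresholdRecord,
    aggregate_conditions,
    apply_exclusions,
    bt500_ci,
    fit_log_linear_slope,
    read_thresholds,
    records_to_frame,
    ridge_fit,
    should_stop,
    write_thresholds,
)
from viscsf.observer_sim import ExperimentDesign, build_design


def frame_from_conditions(rows):
    """rows: (k, f, l, threshold) -> schema frame, one synthetic participant."""
    return records_to_frame(
        ThresholdRecord("P01", k, f, l, thr) for k, f, l, thr in rows
    )


class TestThresholdRecord:
    def test_validation(self):
        with pytest.raises(DomainError):
            ThresholdRecord("P01", 1.0, 1.0, 120, 0.0)
        with pytest.raises(DomainError):
            ThresholdRecord("P01", 1.0, 1.0, 120, 1.5)
        with pytest.raises(DomainError):
            ThresholdRecord("P01", -1.0, 1.0, 120, 0.5)

    def test_csv_round_trip(self, tmp_path):
        df = frame_from_conditions([(0.0, 10.0, 120, 0.02), (3.0, 5.0, 80, 0.04)])
        path = tmp_path / "thr.csv"
        write_thresholds(df, path)
        back = read_thresholds(path)
        pd.testing.assert_frame_equal(back, df)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,stage\nP01,pattern\n")
        with pytest.raises(DataError):
            read_thresholds(path)


class TestExclusions:
    def test_empty_list_is_identity(self):
        df = frame_from_conditions([(0.0, 40.0, 200, 0.02)])
        out, removed = apply_exclusions(df, [])
        assert removed == 0
        pd.testing.assert_frame_equal(out, df)

    def test_level_120_never_excluded(self):
        df = frame_from_conditions([(0.0, 40.0, 120, 0.02)])
        out, removed = apply_exclusions(df, DEFAULT_EXCLUSIONS)
        assert removed == 0 and len(out) == 1

    def test_full_design_removal_count_matches_brute_force(self):
        # design whose temporal grid contains all the artefact frequencies
        temporal = (1.0, 5.0, 13.0, 15.0, 20.0, 25.0, 30.0, 36.0, 40.0, 46.0, 48.0, 60.0)
        design = ExperimentDesign(
            temporal_frequencies=temporal,
            spatial_frequencies=tuple(np.geomspace(0.5, 15.0, 8)),
            background_levels=(40, 80, 120, 160, 200),
            n_participants=2,
            stages=("flicker", "pattern"),
        )
        df = build_design(design)
        df["threshold_contrast"] = 0.02
        df["replicate_index"] = 0
        out, removed = apply_exclusions(df, DEFAULT_EXCLUSIONS)
        # independent brute-force scan
        expected = sum(
            1
            for _, row in df.iterrows()
            if any(
                math.isclose(row["temporal_freq_hz"], ef) and row["background_level"] == el
                for ef, el in DEFAULT_EXCLUSIONS
            )
        )
        assert removed == expected
        # 8 pairs, each present: 8 spatial x 2 stages x 2 participants each
        assert removed == 8 * 8 * 2 * 2
        assert len(out) + removed == len(df)


class TestBt500:
    def test_identical_samples(self):
        mean, sd, hw = bt500_ci([0.5, 0.5, 0.5])
        assert (mean, sd, hw) == (0.5, 0.0, 0.0)

    def test_one_two_three_hand_computed(self):
        mean, sd, hw = bt500_ci([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)
        assert hw == pytest.approx(1.96 / math.sqrt(3.0))

    def test_scales_inverse_sqrt_n(self, rng):
        # formula identity: halfwidth * sqrt(n) / sd is the fixed 1.96 quantile
        for n in (2, 5, 20, 100):
            x = rng.normal(1.0, 0.3, n)
            mean, sd, hw = bt500_ci(x)
            assert hw * math.sqrt(n) / sd == pytest.approx(1.96)

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            bt500_ci([1.0])


class TestStoppingRule:
    def test_identical_pair_stops(self):
        assert should_stop([0.7, 0.7])

    def test_threshold_straddle(self):
        # mean 1.0; craft sds that put the halfwidth just around 0.05
        def samples_with(hw, n=4):
            sd = hw * math.sqrt(n) / 1.96
            half = sd * math.sqrt((n - 1) / n)
            return [1.0 - half, 1.0 - half, 1.0 + half, 1.0 + half]

        assert should_stop(samples_with(0.049))
        assert not should_stop(samples_with(0.051))

    def test_sequential_replay_matches_oracle(self, rng):
        for _ in range(50):
            stream = 0.05 * (1.0 + 0.2 * rng.standard_normal(64))
            n_rule = next(
                (n for n in range(2, 65) if should_stop(stream[:n])), None
            )
            # brute-force oracle: recompute the CI inequality from scratch
            n_oracle = None
            for n in range(2, 65):
                x = stream[:n]
                m = x.mean()
                s = math.sqrt(((x - m) ** 2).sum() / (n - 1))
                if 1.96 * s / math.sqrt(n) < 0.05 * m:
                    n_oracle = n
                    break
            assert n_rule == n_oracle


class TestAggregation:
    def test_single_record(self):
        df = frame_from_conditions([(1.0, 2.0, 120, 0.02)])
        agg = aggregate_conditions(df)
        assert len(agg) == 1
        assert agg.loc[0, "log10_mean_sensitivity"] == pytest.approx(math.log10(50.0))

    def test_average_then_log(self):
        df = frame_from_conditions([(1.0, 2.0, 120, 0.01), (1.0, 2.0, 120, 0.03)])
        agg = aggregate_conditions(df)
        assert agg.loc[0, "mean_threshold"] == pytest.approx(0.02)
        assert agg.loc[0, "n"] == 2
        assert agg.loc[0, "log10_mean_sensitivity"] == pytest.approx(math.log10(50.0))

    def test_permutation_invariance(self, rng):
        rows = [
            (k, f, l, thr)
            for k in (0.5, 3.0)
            for f in (2.0, 10.0)
            for l in (80, 120)
            for thr in rng.uniform(0.01, 0.1, 3)
        ]
        df = frame_from_conditions(rows)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            aggregate_conditions(df), aggregate_conditions(shuffled)
        )


def random_conditions(rng, n, order=4):
    """Full-rank random condition grid with a known quartic response."""
    template = PolynomialCSF(order=order)
    k = rng.uniform(0, 15, n)
    f = rng.uniform(0, 66.6, n)
    l = rng.uniform(0, 200, n)
    kp, fp, lp = normalize_inputs(k, f, l, template)
    X = polynomial_terms(kp, fp, lp, order)
    return template, k, f, l, X


def conditions_frame(k, f, l, log10_s):
    return pd.DataFrame(
        {
            "spatial_freq_cpd": k,
            "temporal_freq_hz": f,
            "background_level": l,
            "mean_threshold": 10.0 ** (-np.asarray(log10_s)),
            "n": 1,
            "log10_mean_sensitivity": log10_s,
        }
    )


class TestRidgeFit:
    def test_intercept_only_returns_mean(self, rng):
        y = rng.normal(1.5, 0.2, 12)
        df = conditions_frame(np.zeros(12), np.zeros(12), np.zeros(12), y)
        model = ridge_fit(df, RidgeConfig(lam=0.5, order=0))
        # basis is a single all-ones column; unpenalized intercept = mean(y)
        assert model.coefficients[0] == pytest.approx(y.mean(), rel=1e-12)

    def test_lambda_zero_equals_ols_oracle(self, rng):
        _, k, f, l, X = random_conditions(rng, 120)
        y = rng.normal(1.0, 0.3, 120)
        df = conditions_frame(k, f, l, y)
        model = ridge_fit(df, RidgeConfig(lam=0.0, order=4))
        oracle, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(model.coefficients, oracle, atol=1e-10)

    def test_exact_quartic_recovery(self, rng):
        truth = rng.normal(0, 0.5, 35)
        _, k, f, l, X = random_conditions(rng, 200)
        y = X @ truth
        df = conditions_frame(k, f, l, y)
        model = ridge_fit(df, RidgeConfig(lam=0.0, order=4))
        np.testing.assert_allclose(model.coefficients, truth, atol=1e-8)

    def test_plane_in_quartic_span(self, rng):
        # noiseless plane samples: quartic lambda=0 fit reproduces them exactly
        k = rng.uniform(0, 15, 80)
        f = rng.uniform(0, 66.6, 80)
        l = rng.uniform(40, 200, 80)
        y = 2.0 - 0.05 * k - 0.02 * f + 0.002 * l
        df = conditions_frame(k, f, l, y)
        model = ridge_fit(df, RidgeConfig(lam=0.0, order=4))
        np.testing.assert_allclose(model.log10_sensitivity(k, f, l), y, atol=1e-6)

    def test_rank_deficiency_error(self, rng):
        df = conditions_frame(
            np.full(10, 1.0), np.full(10, 2.0), np.full(10, 120.0),
            rng.normal(size=10),
        )
        with pytest.raises(RankDeficiencyError, match="rank"):
            ridge_fit(df, RidgeConfig(lam=0.0, order=4))

    def test_shrinkage_monotone_in_lambda(self, rng):
        _, k, f, l, X = random_conditions(rng, 60)
        y = rng.normal(1.0, 0.3, 60)
        df = conditions_frame(k, f, l, y)
        norms = []
        for lam in (0.0, 1e-3, 1e-2, 1e-1, 1.0, 10.0):
            model = ridge_fit(df, RidgeConfig(lam=lam, order=4))
            norms.append(np.linalg.norm(model.coefficients[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_continuity_in_lambda(self, rng):
        _, k, f, l, _ = random_conditions(rng, 60)
        y = rng.normal(1.0, 0.3, 60)
        df = conditions_frame(k, f, l, y)
        a = ridge_fit(df, RidgeConfig(lam=1e-3, order=4)).coefficients
        b = ridge_fit(df, RidgeConfig(lam=1e-3 + 1e-9, order=4)).coefficients
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_deterministic(self, rng):
        _, k, f, l, _ = random_conditions(rng, 60)
        y = rng.normal(1.0, 0.3, 60)
        df = conditions_frame(k, f, l, y)
        c1 = ridge_fit(df, RidgeConfig()).coefficients
        c2 = ridge_fit(df, RidgeConfig()).coefficients
        np.testing.assert_array_equal(c1, c2)


class TestLogLinearSlope:
    FREQS = np.linspace(5.0, 40.0, 8)

    def make_flicker_frame(self, slope, intercept=4.0, noise=None, rng=None):
        log_s = intercept + slope * self.FREQS
        if noise is not None:
            log_s = log_s + rng.normal(0, noise, self.FREQS.size)
        return frame_from_conditions(
            [(0.0, f, 120, 10.0 ** (-ls)) for f, ls in zip(self.FREQS, log_s)]
        )

    def test_noiseless_recovery(self):
        df = self.make_flicker_frame(-0.064)
        slope, intercept = fit_log_linear_slope(df, 120, (0.0, 100.0))
        assert slope == pytest.approx(-0.064, abs=1e-9)
        assert intercept == pytest.approx(4.0, abs=1e-9)

    def test_offset_changes_intercept_only(self):
        s1, i1 = fit_log_linear_slope(self.make_flicker_frame(-0.05, 3.5), 120, (0, 100))
        s2, i2 = fit_log_linear_slope(self.make_flicker_frame(-0.05, 4.5), 120, (0, 100))
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert i2 - i1 == pytest.approx(1.0, abs=1e-9)

    def test_range_restriction(self):
        df = self.make_flicker_frame(-0.05)
        # perturb the out-of-range points; restricted fit must not see them
        df.loc[df["temporal_freq_hz"] > 30.0, "threshold_contrast"] = 0.9
        slope, _ = fit_log_linear_slope(df, 120, (0.0, 30.0))
        assert slope == pytest.approx(-0.05, abs=1e-9)

    def test_monte_carlo_unbiased(self):
        rng = np.random.default_rng(2024)
        sigma = 0.05
        slopes = [
            fit_log_linear_slope(
                self.make_flicker_frame(-0.058, noise=sigma, rng=rng), 120, (0, 100)
            )[0]
            for _ in range(200)
        ]
        se_single = sigma / math.sqrt(np.sum((self.FREQS - self.FREQS.mean()) ** 2))
        assert np.mean(slopes) == pytest.approx(
            -0.058, abs=3.0 * se_single / math.sqrt(200)
        )

    def test_needs_two_frequencies(self):
        df = frame_from_conditions([(0.0, 10.0, 120, 0.02)])
        with pytest.raises(DataError):
            fit_log_linear_slope(df, 120, (0.0, 100.0))
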
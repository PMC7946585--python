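"""Statistical procedures vs closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from uuscore import inference
from uuscore.errors import InsufficientDataError, ValidationError
from uuscore.inference import (
    bonferroni_threshold,
    fit_rate_model,
    fit_uus_model,
    mixed_anova,
    pearson_chi_square,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        _, p = two_sample_t([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pooled_variance_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 12)
        t, _ = two_sample_t(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) \
            / (len(x) + len(y) - 2)
        oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert t == pytest.approx(oracle, rel=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_sample_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_independent_table(self):
        stat, p, df = pearson_chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_perfect_association_hand_computed(self):
        # all expected cells are 10; sum (O-E)^2/E = 4 * 100/10 = 40
        stat, _, df = pearson_chi_square([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert df == 1

    def test_statistic_scales_linearly_with_counts(self):
        t1, _, _ = pearson_chi_square([[12, 5], [7, 9]])
        t2, _, _ = pearson_chi_square([[24, 10], [14, 18]])
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            pearson_chi_square([[0, 0], [5, 5]])


def _partitioned_ss_oracle(y: np.ndarray, groups: np.ndarray):
    """Brute-force split-plot sums of squares for a balanced design.

    y: (subjects, times); groups: group index per subject.  Returns the
    three F statistics (between, within-time, interaction).
    """
    n, t = y.shape
    labels = np.unique(groups)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    time_means = y.mean(axis=0)
    cell_means = np.array([y[groups == g].mean(axis=0) for g in labels])
    group_means = np.array([y[groups == g].mean() for g in labels])
    n_per = np.array([(groups == g).sum() for g in labels])

    ss_between = t * (n_per * (group_means - grand) ** 2).sum()
    ss_subj_within = t * sum(
        ((subj_means[groups == g] - group_means[i]) ** 2).sum()
        for i, g in enumerate(labels))
    ss_time = n * ((time_means - grand) ** 2).sum()
    ss_inter = (n_per[:, None] * (cell_means - time_means[None, :]
                                  - group_means[:, None] + grand) ** 2).sum()
    ss_err = sum(
        ((y[groups == g] - cell_means[i][None, :]
          - subj_means[groups == g][:, None] + group_means[i]) ** 2).sum()
        for i, g in enumerate(labels))

    df_b, df_sw = len(labels) - 1, n - len(labels)
    df_t = t - 1
    df_i = df_b * df_t
    df_e = df_sw * df_t
    f_between = (ss_between / df_b) / (ss_subj_within / df_sw)
    f_time = (ss_time / df_t) / (ss_err / df_e)
    f_inter = (ss_inter / df_i) / (ss_err / df_e)
    return f_between, f_time, f_inter


class TestMixedAnova:
    def _frame(self, y, ids):
        return pd.DataFrame(y, index=ids, columns=[0, 3, 6, 12])

    def test_identical_group_trajectories_null_between(self):
        pattern = np.array([[8.0, 7.5, 7.2, 7.0],
                            [9.0, 8.5, 8.0, 7.8],
                            [7.5, 7.5, 7.4, 7.2]])
        y = np.vstack([pattern, pattern])
        ids = [f"P{i}" for i in range(6)]
        groups = dict(zip(ids, ["low"] * 3 + ["high"] * 3))
        res = mixed_anova(self._frame(y, ids), groups)
        assert res.between.F == pytest.approx(0.0, abs=1e-10)
        assert res.between.p == pytest.approx(1.0)

    def test_latin_square_time_effect_is_zero(self):
        # each time point has the same column sum -> SS_time = 0 exactly
        y = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 3.0, 4.0, 1.0],
                      [3.0, 4.0, 1.0, 2.0],
                      [4.0, 1.0, 2.0, 3.0]])
        ids = [f"P{i}" for i in range(4)]
        groups = dict(zip(ids, ["low", "low", "high", "high"]))
        res = mixed_anova(self._frame(y, ids), groups)
        assert res.within.F == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_partitioned_ss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(8.0, 1.0, size=(6, 4))
        ids = [f"P{i}" for i in range(6)]
        group_idx = np.array([0, 0, 0, 1, 1, 1])
        groups = dict(zip(ids, np.where(group_idx == 0, "low", "high")))
        res = mixed_anova(self._frame(y, ids), groups)
        f_b, f_t, f_i = _partitioned_ss_oracle(y, group_idx)
        assert res.between.F == pytest.approx(f_b, rel=1e-8)
        assert res.within.F == pytest.approx(f_t, rel=1e-8)
        assert res.interaction.F == pytest.approx(f_i, rel=1e-8)
        assert (res.within.df1, res.within.df2) == (3, 12)
        assert (res.between.df1, res.between.df2) == (1, 4)

    def test_missing_cells_rejected(self):
        y = np.full((4, 4), 8.0)
        y[0, 3] = np.nan
        ids = [f"P{i}" for i in range(4)]
        groups = dict(zip(ids, ["low", "low", "high", "high"]))
        with pytest.raises(ValidationError, match="LOCF"):
            mixed_anova(self._frame(y, ids), groups)


def _toy_fit_inputs(n=40, seed=0, beta=-0.5, noise=0.0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i:03d}" for i in range(n)]
    uus = pd.DataFrame({"participant_id": ids,
                        "uus_total": rng.integers(0, 9, n)})
    baseline = pd.DataFrame({
        "participant_id": ids,
        "age": rng.normal(52, 8, n), "sex": rng.choice(["male", "female"], n),
        "bmi": rng.normal(26, 3, n), "sbp": rng.normal(137, 16, n),
        "ldl": rng.normal(93, 30, n), "hba1c_baseline": rng.normal(8.1, 1.4, n),
        "dm_duration": rng.normal(7, 5, n).clip(0),
        "smoker": rng.random(n) < 0.3, "drinker": rng.random(n) < 0.4,
        "ads_total": rng.normal(19.5, 4.4, n)})
    delta = beta * uus["uus_total"] + rng.normal(0, noise, n)
    changes = pd.DataFrame({"participant_id": ids, "visit_month": 12,
                            "outcome": "hba1c", "delta": delta,
                            "imputed": False})
    return changes, uus, baseline


class TestUUSModel:
    def test_noise_free_linear_data_recovered_exactly(self):
        changes, uus, baseline = _toy_fit_inputs(beta=-0.5, noise=0.0)
        r = fit_uus_model(changes, uus, baseline, "model3", 12)
        assert r.beta == pytest.approx(-0.5, abs=1e-10)
        assert r.n == 40

    @pytest.mark.parametrize("model", ["crude", "model1", "model2", "model3"])
    def test_matches_normal_equations_oracle(self, model):
        changes, uus, baseline = _toy_fit_inputs(seed=3, noise=0.8)
        r = fit_uus_model(changes, uus, baseline, model, 12)
        df = uus.merge(baseline, on="participant_id")
        df["sex_female"] = (df["sex"] == "female").astype(float)
        cols = ["uus_total"] + list(inference.MODEL_COVARIATES[model])
        X = np.column_stack([np.ones(len(df)),
                             df[cols].astype(float).to_numpy()])
        y = changes["delta"].to_numpy()
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.beta == pytest.approx(beta_hat[1], rel=1e-8)

    def test_coefficient_invariant_to_covariate_centering(self):
        changes, uus, baseline = _toy_fit_inputs(seed=5, noise=0.8)
        r1 = fit_uus_model(changes, uus, baseline, "model2", 12)
        centered = baseline.copy()
        for col in ("age", "bmi", "sbp", "ldl", "hba1c_baseline", "dm_duration"):
            centered[col] = 10.0 * (centered[col] - centered[col].mean())
        r2 = fit_uus_model(changes, uus, centered, "model2", 12)
        assert r2.beta == pytest.approx(r1.beta, rel=1e-9)
        assert r2.se == pytest.approx(r1.se, rel=1e-9)

    def test_rank_deficiency_names_collinear_columns(self):
        changes, uus, baseline = _toy_fit_inputs(seed=7, noise=0.5)
        collinear = baseline.copy()
        collinear["ldl"] = 2.0 * collinear["sbp"]
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_uus_model(changes, uus, collinear, "model2", 12)


class TestRateModel:
    def _rates(self, slope, n=30, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        uus = rng.integers(0, 9, n)
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "visit_month": 12, "uus_total": uus,
            "rate": 1.0 + slope * uus + rng.normal(0, noise, n)})

    def test_constant_rates_zero_slope(self):
        r = fit_rate_model(self._rates(slope=0.0), 12)
        assert r.beta == pytest.approx(0.0, abs=1e-12)

    def test_exactly_linear_rates(self):
        r = fit_rate_model(self._rates(slope=-3.0), 12)
        assert r.beta == pytest.approx(-3.0, abs=1e-10)

    def test_matches_simple_regression_closed_form(self):
        rates = self._rates(slope=-2.0, noise=5.0, seed=4)
        r = fit_rate_model(rates, 12)
        x, y = rates["uus_total"].astype(float), rates["rate"]
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / \
            ((x - x.mean()) ** 2).sum()
        assert r.beta == pytest.approx(oracle, rel=1e-10)


class TestBonferroni:
    @pytest.mark.parametrize("alpha, m, exact, truncated", [
        (0.05, 1, 0.05, 0.05),
        (0.05, 3, 0.05 / 3, 0.016),
        (0.05, 5, 0.01, 0.01),
    ])
    def test_threshold_values(self, alpha, m, exact, truncated):
        out = bonferroni_threshold(alpha, m)
        assert out.exact == pytest.approx(exact)
        assert out.truncated == pytest.approx(truncated)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_threshold(1.5, 3)
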
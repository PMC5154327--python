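"""Moderated RM-ANCOVA, simple slopes and hierarchical regression."""

import numpy as np
import pandas as pd
import pytest

from fearext.errors import (
    InsufficientDataError, MissingCellError, RankDeficiencyError,
)
from fearext.stats import (
    CELLS_2X2, build_difference_scores, delta_r_squared, fit_condition_ancova,
    fit_rm_ancova, hierarchical_regression, mean_center, partial_eta_squared,
    simple_slope_contrasts, within_contrast_scores,
)


def normal_equations_F(cells, cov):
    """Brute-force least-squares oracle for every ANCOVA effect."""
    pe, me, pl, ml = (cells[c].to_numpy() for c in CELLS_2X2)
    z = cov - cov.mean()
    scores = {
        "condition": ((pe + pl) / 2 - (me + ml) / 2, 0),
        "time": ((pe + me) / 2 - (pl + ml) / 2, 0),
        "condition_x_time": ((pe - me) - (pl - ml), 0),
        "iu": ((pe + me + pl + ml) / 4, 1),
        "condition_x_iu": ((pe + pl) / 2 - (me + ml) / 2, 1),
        "time_x_iu": ((pe + me) / 2 - (pl + ml) / 2, 1),
        "condition_x_time_x_iu": ((pe - me) - (pl - ml), 1),
    }
    out = {}
    X = np.column_stack([np.ones_like(z), z])
    XtX_inv = np.linalg.inv(X.T @ X)
    for name, (y, which) in scores.items():
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 2)
        out[name] = float(beta[which] ** 2 / (s2 * XtX_inv[which, which]))
    return out


def random_cells(rng, n):
    return pd.DataFrame(rng.normal(0.3, 0.12, (n, 4)), columns=list(CELLS_2X2))


class TestMeanCenter:
    def test_simple_example(self):
        assert np.allclose(mean_center([1, 2, 3]), [-1, 0, 1])

    def test_constant_vector_maps_to_zero(self):
        assert np.allclose(mean_center([5.0] * 8), 0.0)

    def test_centered_mean_is_numerically_zero(self, rng):
        x = rng.normal(63.9, 19.6, 34)
        assert abs(mean_center(x).mean()) < 1e-10

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            mean_center([1.0])


class TestPartialEtaSquared:
    @pytest.mark.parametrize("F, df2, expected", [
        (105.993, 35, 0.75),
        (118.114, 32, 0.79),
    ])
    def test_reproduces_reported_effect_sizes(self, F, df2, expected):
        assert round(partial_eta_squared(F, 1, df2), 2) == expected

    def test_zero_F_gives_zero(self):
        assert partial_eta_squared(0.0, 1, 30) == 0.0

    def test_equals_half_when_F_equals_df2(self):
        assert partial_eta_squared(20.0, 1, 20) == pytest.approx(0.5)

    def test_strictly_increasing_in_F(self):
        vals = [partial_eta_squared(f, 1, 32) for f in np.linspace(0, 50, 100)]
        assert np.all(np.diff(vals) > 0)

    def test_negative_F_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 30)


class TestRmAncova:
    def test_agrees_with_normal_equations_oracle(self, rng):
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(6, 16))
            cells = random_cells(rng, n)
            cov = rng.normal(60, 18, n)
            res = fit_rm_ancova(cells, cov)
            oracle = normal_equations_F(cells, cov)
            for _, row in res.effects.iterrows():
                worst = max(worst, abs(row.F - oracle[row.effect]))
        assert worst < 1e-8

    def test_six_subject_toy_dataset_matches_oracle(self):
        cells = pd.DataFrame(
            [[0.4, 0.3, 0.3, 0.2], [0.5, 0.2, 0.4, 0.3], [0.3, 0.3, 0.2, 0.1],
             [0.6, 0.4, 0.3, 0.3], [0.2, 0.1, 0.2, 0.2], [0.5, 0.3, 0.2, 0.2]],
            columns=list(CELLS_2X2))
        cov = np.array([40.0, 55.0, 60.0, 72.0, 81.0, 95.0])
        res = fit_rm_ancova(cells, cov)
        oracle = normal_equations_F(cells, cov)
        for _, row in res.effects.iterrows():
            assert row.F == pytest.approx(oracle[row.effect], abs=1e-10)

    @pytest.mark.parametrize("n, df2", [(37, 35), (34, 32)])
    def test_degrees_of_freedom_are_n_minus_two(self, rng, n, df2):
        res = fit_rm_ancova(random_cells(rng, n), rng.normal(60, 18, n))
        assert (res.effects.df1 == 1).all()
        assert (res.effects.df2 == df2).all()

    def test_constant_covariate_reduces_to_one_sample_t(self, rng):
        n = 12
        cells = random_cells(rng, n)
        res = fit_rm_ancova(cells, np.zeros(n))
        C = within_contrast_scores(cells)["C"].to_numpy()
        from scipy import stats as sstats
        t, _ = sstats.ttest_1samp(C, 0.0)
        F = res.effects.set_index("effect").loc["condition", "F"]
        assert F == pytest.approx(t ** 2, abs=1e-10)

    def test_moderation_effects_zero_for_constant_covariate(self, rng):
        res = fit_rm_ancova(random_cells(rng, 10), np.zeros(10))
        eff = res.effects.set_index("effect")
        for name in ("condition_x_iu", "time_x_iu", "condition_x_time_x_iu", "iu"):
            assert eff.loc[name, "F"] == 0.0

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_rm_ancova(random_cells(rng, 3), rng.normal(size=3))


class TestSimpleSlopes:
    def test_linear_moderation_recovered_exactly(self):
        # cell means exactly linear in the moderator: contrasts at +-1 SD
        # must equal the analytic linear combination
        n = 20
        z = np.linspace(-2, 2, n)
        a = {"csplus_early": (0.32, 0.03), "csminus_early": (0.29, 0.06),
             "csplus_late": (0.29, 0.035), "csminus_late": (0.22, -0.035)}
        cells = pd.DataFrame({c: b0 + b1 * z for c, (b0, b1) in a.items()})
        cov = 60 + 10 * z  # moderator on its raw scale
        res = fit_rm_ancova(cells, cov)
        sd = np.std(cov, ddof=1)
        zsd = sd / 10.0  # moderator SD in z units
        table = res.contrasts.set_index(["iu_level", "contrast"])
        for mult, lab in ((-1, "-1sd"), (1, "+1sd")):
            exp_early = (0.32 - 0.29) + (0.03 - 0.06) * mult * zsd
            got = table.loc[(lab, "csplus_minus_csminus_early"), "estimate"]
            assert got == pytest.approx(exp_early, abs=1e-10)
            exp_cm = (0.29 - 0.22) + (0.06 + 0.035) * mult * zsd
            got = table.loc[(lab, "csminus_early_minus_late"), "estimate"]
            assert got == pytest.approx(exp_cm, abs=1e-10)

    def test_no_moderation_gives_equal_contrasts_at_both_levels(self, rng):
        # moderator values symmetric and cell data mirrored so that every
        # fitted slope is exactly zero
        half = random_cells(rng, 8)
        cells = pd.concat([half, half], ignore_index=True)
        cov = np.concatenate([50 - np.arange(8.0), 50 + np.arange(8.0)])
        res = fit_rm_ancova(cells, cov)
        t = res.contrasts
        lo = t[t.iu_level == "-1sd"].set_index("contrast").estimate
        hi = t[t.iu_level == "+1sd"].set_index("contrast").estimate
        assert np.allclose(lo, hi, atol=1e-12)

    def test_contrast_table_covers_all_levels_and_contrasts(self, rng):
        res = fit_rm_ancova(random_cells(rng, 10), rng.normal(60, 15, 10))
        table = simple_slope_contrasts(res, (-1.0, 1.0))
        assert len(table) == 8
        assert set(table.df) == {8}


class TestConditionAncova:
    def test_acquisition_model_has_no_time_effects(self, rng):
        cells = pd.DataFrame({
            "acquisition_csplus": rng.normal(0.8, 0.2, 12),
            "acquisition_csminus": rng.normal(0.3, 0.2, 12)})
        res = fit_condition_ancova(cells, rng.normal(60, 15, 12))
        assert list(res.effects.effect) == ["condition", "iu", "condition_x_iu"]
        assert (res.effects.df2 == 10).all()


class TestDifferenceScores:
    def test_published_cell_values_arithmetic(self):
        cells = pd.DataFrame([{"csplus_early": 0.32, "csminus_early": 0.29,
                               "csplus_late": 0.29, "csminus_late": 0.22}])
        d = build_difference_scores(cells)
        assert d.csminus_early_minus_late.iloc[0] == pytest.approx(0.07)
        assert d.csplus_minus_csminus_early.iloc[0] == pytest.approx(0.03)

    def test_equal_cells_give_zero_scores(self):
        cells = pd.DataFrame([{c: 0.3 for c in CELLS_2X2}])
        assert (build_difference_scores(cells) == 0).all().all()

    def test_condition_scores_antisymmetric_under_label_swap(self, rng):
        cells = random_cells(rng, 5)
        swapped = cells.rename(columns={
            "csplus_early": "csminus_early", "csminus_early": "csplus_early",
            "csplus_late": "csminus_late", "csminus_late": "csplus_late"})
        a = build_difference_scores(cells)
        b = build_difference_scores(swapped)
        assert np.allclose(a.csplus_minus_csminus_early,
                           -b.csplus_minus_csminus_early)

    def test_missing_cell_rejected(self):
        with pytest.raises(MissingCellError):
            build_difference_scores(pd.DataFrame({"csplus_early": [0.3]}))


class TestHierarchicalRegression:
    def test_matches_normal_equations_oracle(self, rng):
        n = 10
        x1 = pd.DataFrame({"stai": rng.normal(44, 9, n),
                           "pswq": rng.normal(52, 11, n)})
        x2 = pd.DataFrame({"iu": rng.normal(64, 19, n)})
        y = rng.normal(0.1, 0.05, n)
        res = hierarchical_regression(y, [x1, x2])
        for step, cols in ((0, ["stai", "pswq"]), (1, ["stai", "pswq", "iu"])):
            X = np.column_stack([np.ones(n)] +
                                [pd.concat([x1, x2], axis=1)[c] for c in cols])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            assert res.steps[step].r_squared == pytest.approx(r2, abs=1e-12)
            assert np.allclose(res.steps[step].coefficients.B, beta[1:],
                               atol=1e-10)

    def test_delta_r2_consistency_and_nonnegativity(self, rng):
        n = 30
        x1 = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        x2 = pd.DataFrame({"c": rng.normal(size=n)})
        y = rng.normal(size=n)
        res = hierarchical_regression(y, [x1, x2])
        assert res.steps[1].delta_r_sq == pytest.approx(
            res.steps[1].r_squared - res.steps[0].r_squared, abs=1e-14)
        assert res.steps[1].delta_r_sq >= 0
        assert res.steps[1].r_squared >= res.steps[0].r_squared

    def test_orthogonalized_predictor_adds_no_variance(self, rng):
        n = 40
        x1 = pd.DataFrame({"a": rng.normal(size=n)})
        y = rng.normal(size=n)
        # orthogonalize a candidate against (1, a, y)
        cand = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), x1.a, y])
        cand = cand - basis @ np.linalg.lstsq(basis, cand, rcond=None)[0]
        res = hierarchical_regression(y, [x1, pd.DataFrame({"c": cand})])
        assert res.steps[1].delta_r_sq == pytest.approx(0.0, abs=1e-12)

    def test_outcome_linear_in_added_predictor_gives_r2_one(self, rng):
        n = 15
        x1 = pd.DataFrame({"a": rng.normal(size=n)})
        iu = rng.normal(64, 19, n)
        y = 0.01 * iu - 0.3
        res = hierarchical_regression(y, [x1, pd.DataFrame({"iu": iu})])
        assert res.steps[1].r_squared == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_predictor_raises_rank_error_naming_column(self, rng):
        n = 12
        x1 = pd.DataFrame({"stai": rng.normal(size=n)})
        x2 = pd.DataFrame({"stai_again": x1.stai.to_numpy()})
        with pytest.raises(RankDeficiencyError) as err:
            hierarchical_regression(rng.normal(size=n), [x1, x2])
        assert "stai_again" in err.value.columns

    def test_standardized_beta_matches_zscore_regression(self, rng):
        n = 25
        x1 = pd.DataFrame({"a": rng.normal(2, 3, n), "b": rng.normal(-1, 5, n)})
        y = 0.4 * x1.a - 0.2 * x1.b + rng.normal(size=n)
        res = hierarchical_regression(y.to_numpy(), [x1])
        zx = (x1 - x1.mean()) / x1.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        X = np.column_stack([np.ones(n), zx.a, zx.b])
        beta = np.linalg.lstsq(X, zy, rcond=None)[0]
        assert np.allclose(res.steps[0].coefficients.beta, beta[1:], atol=1e-10)


def test_delta_r_squared_validates_inputs():
    assert delta_r_squared(0.5, 0.2) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        delta_r_squared(1.2, 0.2)
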
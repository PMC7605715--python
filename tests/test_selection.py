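"""Correlation screen, OLS fitting and exhaustive BIC subset search."""

import warnings
from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm

from retinotune.exceptions import ModelFitError
from retinotune.features import FeatureSummary
from retinotune.io import PigmentDataset, PigmentRecord
from retinotune.selection import (
    LinearModel,
    bic_score,
    correlation_screen,
    exhaustive_subset_search,
    fit_ols,
)


def make_dataset(x, y, names=None):
    """Dataset from a plain design matrix (rows = pigments)."""
    x = np.atleast_2d(np.asarray(x, float))
    names = names or [f"Torsion {i+1}" for i in range(x.shape[1])]
    records = []
    for i, (row, lam) in enumerate(zip(x, y)):
        medians = dict(zip(names, map(float, row)))
        records.append(
            PigmentRecord(
                f"species{i}", "Sws2a", float(lam),
                FeatureSummary(medians=medians, frame_count=1),
            )
        )
    return PigmentDataset(records)


class TestCorrelationScreen:
    def test_exactly_linear_parameter_has_unit_r2(self, rng):
        lam = rng.uniform(400, 480, size=8)
        ds = make_dataset(lam[:, None] * 0.3 + 5.0, lam, names=["Angle 1"])
        res = correlation_screen(ds)
        assert res.r2["Angle 1"] == pytest.approx(1.0, abs=1e-12)

    def test_r2_matches_covariance_oracle(self, rng):
        lam = rng.uniform(397, 485, size=11)
        x = rng.permutation(lam)
        ds = make_dataset(x[:, None], lam, names=["Torsion 5"])
        res = correlation_screen(ds)
        # hand-coded covariance oracle
        cx, cy = x - x.mean(), lam - lam.mean()
        oracle = (cx @ cy) ** 2 / ((cx @ cx) * (cy @ cy))
        assert res.r2["Torsion 5"] == pytest.approx(oracle, abs=1e-12)

    def test_exclusion_list_and_shortlist_cut(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        res = correlation_screen(dataset, exclude=["Angle 3"], shortlist_size=5)
        assert "Angle 3" not in res.shortlist
        assert len(res.shortlist) == 5
        assert set(res.shortlist) <= set(res.ranked)

    def test_constant_parameter_dropped_with_warning(self, rng):
        lam = rng.uniform(400, 480, size=6)
        x = np.column_stack([lam, np.full(6, 42.0)])
        ds = make_dataset(x, lam, names=["Angle 1", "Angle 2"])
        with pytest.warns(UserWarning, match="Angle 2"):
            res = correlation_screen(ds)
        assert "Angle 2" in res.dropped_constant
        assert "Angle 2" not in res.r2

    def test_too_few_pigments(self, rng):
        ds = make_dataset(np.ones((2, 1)), [400.0, 410.0])
        with pytest.raises(ModelFitError):
            correlation_screen(ds)


class TestFitOls:
    def test_noiseless_recovery_of_published_constants(self, rng):
        """y built from the published three-term model is recovered exactly."""
        a3 = rng.uniform(125, 140, size=11)
        t3 = rng.uniform(5, 20, size=11)
        t12 = rng.uniform(-15, 5, size=11)
        y = 2677.5348 - 17.052 * a3 + 5.1634 * t3 + 2.3642 * t12
        ds = make_dataset(
            np.column_stack([a3, t3, t12]), y, names=["Angle 3", "Torsion 3", "Torsion 12"]
        )
        m = fit_ols(ds, ["Angle 3", "Torsion 3", "Torsion 12"])
        assert m.intercept == pytest.approx(2677.5348, abs=1e-6)
        assert m.coef["Angle 3"] == pytest.approx(-17.052, abs=1e-6)
        assert m.coef["Torsion 3"] == pytest.approx(5.1634, abs=1e-6)
        assert m.coef["Torsion 12"] == pytest.approx(2.3642, abs=1e-6)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_intercept_only_model_predicts_mean(self, rng):
        lam = rng.uniform(400, 480, size=9)
        ds = make_dataset(rng.normal(size=(9, 1)), lam)
        m = fit_ols(ds, [])
        assert m.intercept == pytest.approx(lam.mean(), abs=1e-9)
        assert m.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(11, 3))
        y = rng.normal(450, 20, size=11)
        ds = make_dataset(x, y)
        m = fit_ols(ds, ds.medians_frame().columns.tolist())
        design = np.column_stack([np.ones(11), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-9)
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-9)

    def test_matches_statsmodels(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        terms = ["Angle 3", "Torsion 3", "Torsion 12"]
        m = fit_ols(dataset, terms)
        x = dataset.medians_frame()[terms].to_numpy()
        res = sm.OLS(dataset.lambda_max(), sm.add_constant(x)).fit()
        assert m.intercept == pytest.approx(res.params[0], rel=1e-9)
        np.testing.assert_allclose(m.coefficients, res.params[1:], rtol=1e-9)
        assert m.rss == pytest.approx(res.ssr, rel=1e-9)
        assert m.r_squared == pytest.approx(res.rsquared, rel=1e-9)

    def test_rank_deficiency_names_collinear_terms(self, rng):
        x = rng.normal(size=(10, 1))
        ds = make_dataset(
            np.column_stack([x, 2 * x]), rng.normal(450, 10, size=10),
            names=["Torsion 1", "Torsion 2"],
        )
        with pytest.raises(ModelFitError, match="Torsion"):
            fit_ols(ds, ["Torsion 1", "Torsion 2"])

    def test_saturated_fit_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(4, 3)), rng.normal(450, 10, size=4))
        with pytest.raises(ModelFitError, match="n > k\\+1"):
            fit_ols(ds, ds.medians_frame().columns.tolist())


def brute_force_best(ds, shortlist, n):
    """Independent enumeration: normal equations + direct BIC formula."""
    med = ds.medians_frame()
    y = ds.lambda_max()
    best = None
    for k in range(1, len(shortlist) + 1):
        for subset in combinations(shortlist, k):
            design = np.column_stack([np.ones(n), med[list(subset)].to_numpy()])
            if np.linalg.matrix_rank(design) < design.shape[1] or n <= k + 1:
                continue
            beta = np.linalg.pinv(design) @ y
            rss = float(np.sum((y - design @ beta) ** 2))
            bic = n * np.log(max(rss, 1e-12) / n) + (k + 1) * np.log(n)
            key = (bic, len(subset), subset)
            if best is None or key < best[0]:
                best = (key, subset)
    return best[1]


class TestSubsetSearch:
    def test_seven_shortlist_gives_127_models(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        shortlist = ["Angle 3", "Torsion 3", "Torsion 12", "Torsion 9",
                     "Torsion 10", "Torsion 11", "Angle 1"]
        res = exhaustive_subset_search(dataset, shortlist)
        assert len(res.models) == 127
        assert res.best in res.window
        assert all(m.bic <= res.best.bic + 2.0 for m in res.window)

    @pytest.mark.parametrize("k", [4, 6, 7])
    def test_best_matches_brute_force_loop(self, rng, k):
        """Enumeration exactness on random instances."""
        for _ in range(5):
            n = 11
            x = rng.normal(size=(n, k))
            y = rng.normal(440, 25, size=n)
            ds = make_dataset(x, y)
            shortlist = ds.medians_frame().columns.tolist()
            res = exhaustive_subset_search(ds, shortlist)
            assert tuple(sorted(res.best.terms)) == tuple(
                sorted(brute_force_best(ds, shortlist, n))
            )

    def test_inert_column_does_not_change_selection(self, noisy_dataset, rng):
        dataset, _, _ = noisy_dataset
        shortlist = ["Angle 3", "Torsion 3", "Torsion 12"]
        before = exhaustive_subset_search(dataset, shortlist).best.terms
        # augment every record with an unrelated constant-free column
        extra = rng.normal(size=len(dataset))
        for r, v in zip(dataset, extra):
            r.feature_summary.medians["Torsion 99"] = float(v)
        try:
            after = exhaustive_subset_search(dataset, shortlist).best.terms
        finally:
            for r in dataset:
                r.feature_summary.medians.pop("Torsion 99")
        assert after == before

    def test_empty_shortlist_rejected(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        with pytest.raises(ModelFitError):
            exhaustive_subset_search(dataset, [])

    def test_parsimonious_window_pick_prefers_fewer_terms(self, noisy_dataset):
        dataset, _, _ = noisy_dataset
        res = exhaustive_subset_search(
            dataset, ["Angle 3", "Torsion 3", "Torsion 12"], bic_window=2.0
        )
        pick = res.select_parsimonious()
        assert pick in res.window
        assert all(
            len(pick.terms) <= len(m.terms)
            or (len(pick.terms) == len(m.terms) and pick.bic <= m.bic)
            for m in res.window
        )


def test_bic_convention():
    # 11 observations, RSS 100, 3 terms: n ln(RSS/n) + (k+1) ln n
    expected = 11 * np.log(100 / 11) + 4 * np.log(11)
    assert bic_score(11, 100.0, 3) == pytest.approx(expected, abs=1e-12)


def test_linear_model_json_round_trip(tmp_path):
    m = LinearModel(("Angle 3",), 2700.0, (-17.0,), n=11, rss=1.5, r_squared=0.9, bic=-3.2)
    path = tmp_path / "m.json"
    m.to_json(path)
    back = LinearModel.from_json(path)
    assert back == m
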
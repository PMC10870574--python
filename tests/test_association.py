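"""Variable transforms, GEE model objects, stratified fits, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actionreview.association import (
    ReviewOutcomeModel,
    build_design,
    fit_gee,
    fit_stratified,
    transform_change,
    transform_review,
)


class TestTransforms:
    def test_cube_root_examples(self):
        assert transform_change(0.0) == 0.0
        assert transform_change(-8.0) == pytest.approx(-2.0)
        assert transform_change(50.0) == pytest.approx(3.6840, abs=5e-5)

    def test_cube_root_is_odd_function(self):
        x = np.linspace(-90, 90, 31)
        assert transform_change(-x) == pytest.approx(-transform_change(x))

    def test_log1p_examples(self):
        assert transform_review(0.0) == 0.0
        assert transform_review(np.e - 1) == pytest.approx(1.0)
        assert transform_review(10.0) == pytest.approx(2.3979, abs=5e-5)

    def test_negative_review_rejected(self):
        with pytest.raises(ValueError):
            transform_review(-0.1)


def _toy_table(n_clients=40, rows_per_client=4, seed=0, beta=0.5,
               cluster_y=True, n_therapists=5):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clients):
        tid = f"t{c % n_therapists}"
        oid = f"o{(c % n_therapists) % 2}"
        init = int(rng.integers(5, 20))
        days = int(rng.integers(50, 71))
        x_c = float(rng.uniform(0, 3))
        nd_c, nr_c = int(rng.integers(15, 45)), int(rng.integers(1, 9))
        y_c = beta * x_c + 0.05 * init + rng.normal(0, 0.5)
        for s in range(rows_per_client):
            x = x_c if cluster_y else float(rng.uniform(0, 3))
            rows.append({
                "client_id": f"c{c}", "therapist_id": tid, "org_id": oid,
                "session_id": f"c{c}_s{s}", "review_percentage": np.expm1(x),
                "x_review": x,
                "n_dialogues": nd_c if cluster_y else int(rng.integers(15, 45)),
                "n_recs_prev": nr_c if cluster_y else int(rng.integers(1, 9)),
                "initial_score": init,
                "days_examined": days,
                "severity": ["mild", "moderate", "severe"][c % 3],
                "change_pct": y_c ** 3, "y": y_c,
            })
    return pd.DataFrame(rows)


class TestModelObjects:
    def test_gee_degenerates_to_ols_with_one_row_per_cluster(self):
        table = _toy_table(n_clients=60, rows_per_client=1, seed=3)
        res = fit_gee(table, interactions="none", cov_struct="independence")
        ols = sm.OLS(res.model.endog, res.model.exog).fit()
        assert np.allclose(res.params.values, ols.params.values, atol=1e-8)

    def test_single_cluster_rejected(self):
        table = _toy_table(n_clients=1)
        with pytest.raises(ValueError, match="two clusters"):
            ReviewOutcomeModel(table)

    def test_org_dummies_aliased_by_therapist_nesting_are_dropped(self):
        table = _toy_table(n_clients=30)
        with pytest.warns(UserWarning, match="aliased"):
            _, X, _, dropped = build_design(table, "none", fixed_effects=True)
        assert dropped and all(c.startswith("org_") for c in dropped)
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]

    def test_interaction_columns_present(self):
        table = _toy_table()
        _, X, _, _ = build_design(table, "review_x_initial+review_x_dialogues",
                                  fixed_effects=False)
        assert "log_review_pct:initial_score" in X.columns
        assert "log_review_pct:n_dialogues" in X.columns
        assert np.allclose(X["log_review_pct:initial_score"],
                           X.log_review_pct * X.initial_score)

    def test_results_expose_recomputable_inference(self):
        table = _toy_table()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_gee(table, interactions="none")
        ci = res.conf_int()
        z = res.params / res.bse
        from scipy import stats
        p = 2 * stats.norm.sf(np.abs(z))
        assert np.allclose(res.pvalues, p, atol=1e-10)
        assert np.allclose(ci.upper - res.params, res.params - ci.lower,
                           atol=1e-10)
        assert (ci.lower <= ci.upper).all()
        assert "Review-outcome GEE" in res.summary()

    def test_cluster_constant_design_invariant_to_working_correlation(self):
        table = _toy_table(cluster_y=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_gee(table, cov_struct="exchangeable")
            b = fit_gee(table, cov_struct="independence")
        assert np.allclose(a.params["log_review_pct"],
                           b.params["log_review_pct"], atol=1e-6)

    def test_marginal_review_association_decreases_with_initial_score(self):
        """With a positive main effect and negative interaction, the fitted
        marginal slope of review on change declines in the initial score."""
        rng = np.random.default_rng(8)
        table = _toy_table(n_clients=120, seed=8)
        table["y"] = (0.8 * table.x_review + 0.06 * table.initial_score
                      - 0.03 * table.x_review * table.initial_score
                      + rng.normal(0, 0.2, len(table)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_gee(table, interactions="review_x_initial")
        b_main = res.params["log_review_pct"]
        b_int = res.params["log_review_pct:initial_score"]
        assert b_main > 0 and b_int < 0
        slope_at = lambda s: b_main + b_int * s
        assert slope_at(5) > slope_at(15) > slope_at(25)


class TestStratified:
    def test_strata_partition_rows(self):
        table = _toy_table(n_clients=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata, skipped = fit_stratified(table)
        total = sum(r.nobs for r in strata.values())
        n_skipped_rows = sum((table.severity == s).sum() for s in skipped)
        assert total + n_skipped_rows == len(table)

    def test_single_stratum_matches_plain_fit(self):
        table = _toy_table(n_clients=40)
        table["severity"] = "mild"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata, skipped = fit_stratified(table)
            direct = fit_gee(table, interactions="none")
        assert list(strata) == ["mild"] and not skipped
        assert np.allclose(strata["mild"].params.values, direct.params.values)

    def test_too_small_stratum_skipped_not_errored(self):
        table = _toy_table(n_clients=9)
        table.loc[table.client_id == "c0", "severity"] = "lonely"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata, skipped = fit_stratified(table, min_clusters=4)
        assert "lonely" in skipped


class TestBootstrap:
    def _fit(self, **kw):
        table = _toy_table(n_clients=50, seed=5, **kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fit_gee(table, interactions="none", fixed_effects=False)

    def test_identical_seed_identical_intervals(self):
        res = self._fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = res.bootstrap(B=60, seed=4)
            b = res.bootstrap(B=60, seed=4)
        pd.testing.assert_frame_equal(a.conf_int, b.conf_int)

    def test_b_below_two_rejected(self):
        res = self._fit()
        with pytest.raises(ValueError):
            res.bootstrap(B=1)

    def test_bootstrap_and_wald_intervals_agree_on_well_behaved_fit(self):
        res = self._fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot = res.bootstrap(B=250, seed=9)
        wald = res.conf_int()
        for term in ("log_review_pct", "initial_score"):
            bw = boot.conf_int.upper[term] - boot.conf_int.lower[term]
            ww = wald.upper[term] - wald.lower[term]
            assert bw == pytest.approx(ww, rel=0.35)
            # intervals overlap
            assert boot.conf_int.lower[term] < wald.upper[term]
            assert wald.lower[term] < boot.conf_int.upper[term]
        assert boot.verified["log_review_pct"]

    def test_null_coefficient_interval_contains_zero_most_of_the_time(self):
        hits = 0
        n_outer = 10
        for r in range(n_outer):
            rng = np.random.default_rng(100 + r)
            table = _toy_table(n_clients=40, seed=200 + r, beta=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_gee(table, interactions="none", fixed_effects=False)
                boot = res.bootstrap(B=120, seed=300 + r)
            lo = boot.conf_int.lower["log_review_pct"]
            hi = boot.conf_int.upper["log_review_pct"]
            hits += lo <= 0.0 <= hi
        assert hits >= n_outer - 2
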
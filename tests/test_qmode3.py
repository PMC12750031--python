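"""Ranking error, robust covariance, Mahalanobis penalty, category ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from emakit.qmode3 import (
    CovarianceModel,
    ConfigurationError,
    ResolutionError,
    ScoreTable,
    best_selection_true_rank,
    evaluate_category,
    penalty_metrics,
    ranking_error,
    ranking_error_matrix,
    robust_covariance,
    weighted_penalty,
    zscore_crosscheck,
)
from emakit.rankstats import ZConfig
from emakit.synth import PredictorSpec, make_score_table, make_submissions


def _identity_cov(metrics):
    d = len(metrics)
    return CovarianceModel(np.eye(d), np.eye(d), tuple(metrics), "monomer", 0.975, (0, 0))


class TestRankingError:
    POOL = {f"m{i}": v for i, v in enumerate([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4])}

    def test_true_top5_any_order_is_zero(self):
        assert ranking_error(self.POOL, ["m4", "m0", "m2", "m1", "m3"]) == 0.0

    def test_hand_summed_offset_selection(self):
        """Selecting ranks 2–6 leaves a 0.1 gap in every slot → RE 0.5."""
        sel = ["m1", "m2", "m3", "m4", "m5"]
        assert ranking_error(self.POOL, sel) == pytest.approx(0.5)

    def test_tied_top_pool_any_selection_zero(self):
        """With ≥ 5 models tied at the best value, any choice of them is perfect."""
        pool = {f"m{i}": 0.9 for i in range(8)}
        pool.update({"w1": 0.2, "w2": 0.1})
        for sel in (["m0", "m1", "m2", "m3", "m4"], ["m3", "m5", "m6", "m7", "m0"]):
            assert ranking_error(pool, sel) == 0.0

    def test_lower_better_orientation(self):
        pool = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0, "f": 6.0}
        assert ranking_error(pool, ["a", "b", "c", "d", "e"], higher_better=False) == 0.0
        assert ranking_error(pool, ["b", "c", "d", "e", "f"], higher_better=False) == pytest.approx(5.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ResolutionError):
            ranking_error(self.POOL, ["m0", "m1", "m2", "m3", "nope"])

    def test_short_selection_needs_flag(self):
        with pytest.raises(ValueError):
            ranking_error(self.POOL, ["m0", "m1"])
        # permissive: empty slots charged true − worst
        got = ranking_error(self.POOL, ["m0", "m1"], allow_short=True)
        assert got == pytest.approx((0.8 - 0.4) + (0.7 - 0.4) + (0.6 - 0.4))

    def test_degrading_a_pick_never_reduces_error(self):
        sel = ["m0", "m1", "m2", "m3", "m4"]
        base = ranking_error(self.POOL, sel)
        for worse in ("m5", "m6"):
            degraded = sel[:4] + [worse]
            assert ranking_error(self.POOL, degraded) >= base


class TestRobustCovariance:
    def test_independent_metrics_near_identity(self):
        rng = np.random.default_rng(42)
        n = 4000
        rows = []
        for metric in ("a", "b"):
            vals = rng.normal(0.0, 1.0, size=n)
            rows += [("T0", f"m{i}", metric, float(v)) for i, v in enumerate(vals)]
        table = ScoreTable(pd.DataFrame(rows, columns=["target", "model", "metric", "value"]))
        cov = robust_covariance(table, metrics=("a", "b"))
        # the 97.5% screen trims the tail, so the diagonal shrinks slightly
        assert cov.sigma[0, 0] == pytest.approx(1.0, abs=0.15)
        assert cov.sigma[1, 1] == pytest.approx(1.0, abs=0.15)
        assert abs(cov.sigma[0, 1]) < 0.1

    def test_clean_data_survivor_fraction(self):
        rng = np.random.default_rng(7)
        n = 2000
        rows = []
        for metric in ("a", "b", "c"):
            rows += [("T0", f"m{i}", metric, float(v)) for i, v in enumerate(rng.normal(size=n))]
        table = ScoreTable(pd.DataFrame(rows, columns=["target", "model", "metric", "value"]))
        cov = robust_covariance(table, outlier_quantile=0.975)
        frac = cov.n_models_used[1] / cov.n_models_used[0]
        assert frac == pytest.approx(0.975, abs=0.02)  # binomial tolerance

    def test_planted_outliers_screened(self):
        rng = np.random.default_rng(3)
        n = 1000
        clean = {m: rng.normal(0, 1, size=n) for m in ("a", "b")}
        rows = []
        for metric in ("a", "b"):
            vals = clean[metric].copy()
            vals[:10] += 50.0  # gross outliers at 50σ
            rows += [("T0", f"m{i}", metric, float(v)) for i, v in enumerate(vals)]
        table = ScoreTable(pd.DataFrame(rows, columns=["target", "model", "metric", "value"]))
        cov = robust_covariance(table, metrics=("a", "b"))
        assert cov.n_models_used[0] - cov.n_models_used[1] >= 10
        # oracle: plain sample covariance of the uncontaminated rows; the
        # off-diagonal carries ~1/sqrt(n) sampling noise, so it is bounded
        # absolutely while the variances must agree within 5%
        clean_cov = np.cov(np.column_stack([clean["a"][10:], clean["b"][10:]]), rowvar=False)
        assert np.diag(cov.sigma) == pytest.approx(np.diag(clean_cov), rel=0.05)
        assert abs(cov.sigma[0, 1]) < 0.1 and abs(clean_cov[0, 1]) < 0.1

    def test_too_few_rows_rejected(self):
        rows = [("T0", f"m{i}", m, 0.5) for i in range(3) for m in ("a", "b")]
        table = ScoreTable(pd.DataFrame(rows, columns=["target", "model", "metric", "value"]))
        with pytest.raises(ValueError):
            robust_covariance(table, metrics=("a", "b"))


class TestWeightedPenalty:
    def test_zero_re_zero_penalty(self):
        cov = _identity_cov(("a", "b"))
        assert weighted_penalty({"a": 0.0, "b": 0.0}, cov) == 0.0

    def test_one_dimensional_closed_form(self):
        sigma2 = 4.0
        cov = CovarianceModel(np.array([[sigma2]]), np.array([[1 / sigma2]]),
                              ("a",), "monomer", 0.975, (0, 0))
        assert weighted_penalty({"a": 3.0}, cov) == pytest.approx((3.0 / 2.0) ** 2)

    def test_euclidean_case(self):
        assert weighted_penalty({"a": 3.0, "b": 4.0}, _identity_cov(("a", "b"))) == pytest.approx(25.0)

    def test_metric_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            weighted_penalty({"a": 1.0}, _identity_cov(("a", "b")))

    def test_affine_invariance_of_penalties(self):
        """Rescaling any metric's scores leaves every P_w unchanged."""
        table = make_score_table(4, 60, category="monomer", seed=2)
        spec = PredictorSpec(3, (0.02, 0.1, 0.3), seed=3)
        subs = make_submissions(table, spec, "qmode3")
        metrics = penalty_metrics("monomer")

        def penalties(tbl):
            cov = robust_covariance(tbl, metrics=metrics)
            re_long = ranking_error_matrix(subs, tbl, metrics=metrics)
            out = {}
            for (p, t), grp in re_long.groupby(["predictor", "target"]):
                out[(p, t)] = weighted_penalty(dict(zip(grp["metric"], grp["re"])), cov)
            return out

        base = penalties(table)
        scaled_df = table.values.copy()
        mask = scaled_df["metric"] == "lddt"
        scaled_df.loc[mask, "value"] = 7.0 * scaled_df.loc[mask, "value"] + 3.0
        scaled = penalties(ScoreTable(scaled_df, category="monomer"))
        for key in base:
            assert scaled[key] == pytest.approx(base[key], abs=1e-8, rel=1e-8)

    def test_duplicated_metric_with_ridge_preserves_order(self):
        table = make_score_table(4, 60, category="monomer", seed=4)
        spec = PredictorSpec(4, (0.0, 0.05, 0.15, 0.4), seed=5)
        subs = make_submissions(table, spec, "qmode3")
        metrics = penalty_metrics("monomer")

        dup = table.values.copy()
        clone = dup[dup["metric"] == "tm_score"].copy()
        clone["metric"] = "tm_clone"
        dup_table = ScoreTable(pd.concat([dup, clone], ignore_index=True), category="monomer")

        def order(tbl, mets, ridge):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov = robust_covariance(tbl, metrics=mets, ridge=ridge)
            res = evaluate_category(subs, tbl, cov)
            return list(res.ranking["predictor"])

        assert order(table, metrics, 0.0) == order(dup_table, metrics + ("tm_clone",), 1e-8)


class TestEvaluateCategory:
    def test_identical_selections_all_zero(self):
        table = make_score_table(3, 30, category="monomer", seed=6)
        spec = PredictorSpec(3, (0.0, 0.0, 0.0), seed=7)
        subs = make_submissions(table, spec, "qmode3")
        cov = robust_covariance(table)
        res = evaluate_category(subs, table, cov)
        assert np.allclose(res.normalized.to_numpy(dtype=float), 0.0)
        assert set(res.ranking["rank"]) == {1}

    def test_normalized_bounds_and_extremes(self):
        table = make_score_table(5, 50, category="monomer", seed=8)
        spec = PredictorSpec(4, (0.0, 0.05, 0.2, 0.5), seed=9)
        subs = make_submissions(table, spec, "qmode3")
        res = evaluate_category(subs, table, robust_covariance(table))
        arr = res.normalized.to_numpy(dtype=float)
        assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0
        for t in res.normalized.columns:
            col = res.normalized[t].dropna()
            if col.nunique() > 1:
                assert col.min() == 0.0 and col.max() == 1.0

    def test_skipped_target_carries_no_extra_penalty(self):
        table = make_score_table(10, 30, category="monomer", seed=10)
        spec = PredictorSpec(3, (0.05, 0.05, 0.05), seed=11)
        subs = make_submissions(table, spec, "qmode3")
        skipping = subs[~((subs["predictor"] == "pred_01") & (subs["target"] == "T009"))]
        res = evaluate_category(skipping, table, robust_covariance(table), coverage_min=0.8)
        assert "pred_01" in res.eligible_predictors
        row = res.normalized.loc["pred_01"]
        assert row.isna()["T009"]
        expect = row.drop("T009").mean()
        got = float(res.ranking.set_index("predictor").loc["pred_01", "mean_penalty"])
        assert got == pytest.approx(float(expect))

    def test_coverage_excludes_sparse_predictor(self):
        table = make_score_table(10, 30, category="monomer", seed=12)
        spec = PredictorSpec(2, (0.05, 0.05), seed=13)
        subs = make_submissions(table, spec, "qmode3")
        sparse = subs[(subs["predictor"] != "pred_01") | (subs["target"].isin(["T000", "T001"]))]
        res = evaluate_category(sparse, table, robust_covariance(table), coverage_min=0.8)
        assert res.excluded_predictors == ["pred_01"]

    def test_oracle_predictor_ranks_first(self):
        table = make_score_table(8, 80, category="monomer", seed=14)
        spec = PredictorSpec(5, (0.0, 0.05, 0.1, 0.2, 0.5), seed=15)
        subs = make_submissions(table, spec, "qmode3")
        res = evaluate_category(subs, table, robust_covariance(table))
        assert res.ranking.loc[0, "predictor"] == "pred_00"


class TestCrosscheck:
    def test_single_cell_reduces_to_two_pass_z(self):
        re_long = pd.DataFrame(
            [("a", "T0", "lddt", 0.0), ("b", "T0", "lddt", 0.3), ("c", "T0", "lddt", 0.9)],
            columns=["predictor", "target", "metric", "re"],
        )
        out = zscore_crosscheck(re_long, ZConfig(exclusion_sd=3.0))
        from emakit.rankstats import two_pass_z

        z = two_pass_z({"a": 0.0, "b": -0.3, "c": -0.9}, ZConfig(exclusion_sd=3.0))
        assert dict(zip(out["predictor"], out["z_sum"])) == pytest.approx(z)

    def test_zero_re_everywhere_tops_ranking(self):
        rng = np.random.default_rng(0)
        rows = []
        for t in range(4):
            for m in ("lddt", "tm_score"):
                rows.append(("perfect", f"T{t}", m, 0.0))
                for p in ("x", "y", "z"):
                    rows.append((p, f"T{t}", m, float(rng.uniform(0.1, 1.0))))
        out = zscore_crosscheck(pd.DataFrame(rows, columns=["predictor", "target", "metric", "re"]))
        assert out.loc[0, "predictor"] == "perfect"

    def test_agrees_with_weighted_penalty_on_fidelity_ladder(self):
        rhos = []
        for seed in range(5):
            table = make_score_table(6, 60, category="monomer", seed=100 + seed)
            spec = PredictorSpec(5, (0.0, 0.02, 0.05, 0.1, 0.3), seed=200 + seed)
            subs = make_submissions(table, spec, "qmode3")
            cov = robust_covariance(table)
            pen = evaluate_category(subs, table, cov).ranking.set_index("predictor")["rank"]
            re_long = ranking_error_matrix(subs, table, metrics=cov.metrics)
            cross = zscore_crosscheck(re_long).set_index("predictor")["rank"]
            preds = sorted(pen.index)
            rhos.append(spearmanr([pen[p] for p in preds], [cross[p] for p in preds]).statistic)
        assert np.mean(rhos) >= 0.9


class TestBestSelectionTrueRank:
    def _table(self):
        rows = [("T0", f"m{i}", "tm_score", v) for i, v in
                enumerate([0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60])]
        return ScoreTable(pd.DataFrame(rows, columns=["target", "model", "metric", "value"]))

    def _subs(self, models):
        return pd.DataFrame(
            [("p", "T0", r + 1, m) for r, m in enumerate(models)],
            columns=["predictor", "target", "rank", "model"],
        )

    def test_true_best_selected_rank_one(self):
        ranks = best_selection_true_rank(self._subs(["m0", "m4", "m5", "m6", "m7"]), self._table())
        assert ranks == {"T0": 1}

    def test_kth_best_rank_counted(self):
        ranks = best_selection_true_rank(self._subs(["m3", "m4", "m5", "m6", "m7"]), self._table())
        assert ranks == {"T0": 4}

    def test_all_tied_pool_rank_one(self):
        rows = [("T0", f"m{i}", "tm_score", 0.5) for i in range(8)]
        table = ScoreTable(pd.DataFrame(rows, columns=["target", "model", "metric", "value"]))
        ranks = best_selection_true_rank(self._subs(["m5", "m6", "m7", "m3", "m4"]), table)
        assert ranks == {"T0": 1}

    def test_unknown_selection_rejected(self):
        with pytest.raises(ResolutionError):
            best_selection_true_rank(self._subs(["m0", "m1", "m2", "m3", "zzz"]), self._table())
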
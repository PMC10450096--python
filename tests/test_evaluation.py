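import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from jitaema import (
    compare_conditions,
    confusion_counts,
    cutoff_rmse_by_day,
    fit_random_intercept_logistic,
    items_variance_decomposition,
    kappa_from_rates,
    summarize_condition,
)


def make_records(rng, n_persons=20, prompts=30, accuracy=1.0, prevalence=0.2,
                 n_items=None, condition="test"):
    """Synthetic classifiable records with controllable observer accuracy."""
    rows = []
    for i in range(n_persons):
        pid = f"p{i:02d}"
        for t in range(prompts):
            truth = "above" if rng.random() < prevalence else "below"
            correct = rng.random() < accuracy
            obs = truth if correct else ("below" if truth == "above" else "above")
            k = n_items if n_items is not None else int(rng.integers(1, 6))
            rows.append(
                (condition, pid, t // 5 + 1, 10.0, (t // 5) // 7 + 1, 0.0, 1.0,
                 truth, "", "", k, 0.0, 0.5, 1.0, obs, True, "confidence")
            )
    from jitaema.simulate import RECORD_COLUMNS

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def kappa_from_table(tp, fn, fp, tn):
    """Standard confusion-matrix kappa: the independent oracle."""
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    return (po - pe) / (1 - pe)


class TestConfusionCounts:
    def test_perfect_observer_has_no_errors(self, rng):
        cc = confusion_counts(make_records(rng, accuracy=1.0))
        assert cc.totals["fn"] == 0 and cc.totals["fp"] == 0

    def test_flipping_observed_swaps_cells(self, rng):
        rec = make_records(rng, accuracy=0.8)
        flipped = rec.copy()
        flipped["obs_class"] = np.where(rec["obs_class"] == "above", "below", "above")
        a, b = confusion_counts(rec).totals, confusion_counts(flipped).totals
        assert a["tp"] == b["fn"] and a["tn"] == b["fp"]

    def test_counts_conserve_records(self, rng):
        rec = make_records(rng, accuracy=0.9)
        assert sum(confusion_counts(rec).totals.values()) == int(rec["classifiable"].sum())


class TestKappaFromRates:
    def test_perfect_agreement(self):
        assert kappa_from_rates(1.0, 1.0, 0.3) == pytest.approx(1.0)

    @pytest.mark.parametrize("prev", [0.1, 0.3, 0.5, 0.9])
    def test_chance_level_when_se_plus_sp_is_one(self, prev):
        assert kappa_from_rates(0.7, 0.3, prev) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_example(self):
        # brute-force oracle: expected 2x2 table at P=.3, Se=.8, Sp=.9
        assert kappa_from_rates(0.8, 0.9, 0.3) == pytest.approx(0.6934, abs=1e-4)

    def test_identity_with_confusion_matrix_kappa(self, rng):
        # exact algebraic identity, checked numerically on random rates
        for _ in range(50):
            se, sp, p = rng.uniform(0.05, 0.95, size=3)
            n = 1e7
            tp, fn = n * p * se, n * p * (1 - se)
            tn, fp = n * (1 - p) * sp, n * (1 - p) * (1 - sp)
            assert kappa_from_rates(se, sp, p) == pytest.approx(
                kappa_from_table(tp, fn, fp, tn), abs=1e-12
            )

    def test_degenerate_chance_agreement_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kappa_from_rates(1.0, 0.0, 1.0)


class TestItemsVarianceDecomposition:
    def test_constant_counts(self, rng):
        d = items_variance_decomposition(make_records(rng, n_items=3))
        assert d["between_sd"] == 0.0 and d["within_sd"] == 0.0

    def test_pure_between_person_variation(self, rng):
        rec = make_records(rng, n_persons=6, n_items=1)
        rec["n_items"] = rec["person_id"].str[1:].astype(int) + 1
        d = items_variance_decomposition(rec)
        assert d["within_sd"] == 0.0 and d["between_sd"] > 0

    def test_matches_anova_oracle(self, rng):
        rec = make_records(rng, n_persons=8, prompts=12)
        d = items_variance_decomposition(rec)
        # direct unbalanced one-way ANOVA sums of squares
        g = rec.groupby("person_id")["n_items"]
        ni, mi = g.count().to_numpy(float), g.mean().to_numpy()
        N, k = ni.sum(), len(ni)
        grand = rec["n_items"].mean()
        msw = float(((rec["n_items"] - g.transform("mean")) ** 2).sum()) / (N - k)
        msb = float((ni * (mi - grand) ** 2).sum()) / (k - 1)
        n0 = (N - (ni**2).sum() / N) / (k - 1)
        var_b = max(0.0, (msb - msw) / n0)
        assert d["within_sd"] == pytest.approx(np.sqrt(msw), abs=1e-12)
        assert d["between_sd"] == pytest.approx(np.sqrt(var_b), abs=1e-12)
        assert d["within_share"] == pytest.approx(msw / (msw + var_b), abs=1e-12)


class TestRandomInterceptLogistic:
    @staticmethod
    def simulate(rng, mu, sd, k, n):
        rows = []
        for i in range(k):
            p = expit(mu + rng.normal(0, sd))
            rows += [(f"c{i:03d}", int(rng.random() < p)) for _ in range(n)]
        return pd.DataFrame(rows, columns=["person_id", "y"])

    def test_zero_variance_collapses_to_pooled_logit(self, rng):
        df = self.simulate(rng, 0.8, 0.0, 50, 40)
        fit = fit_random_intercept_logistic(df)
        pooled = np.log(df["y"].mean() / (1 - df["y"].mean()))
        assert fit.intercept_logit == pytest.approx(pooled, abs=0.05)
        assert fit.intercept_var < 0.05

    def test_matches_lme4_reference_fit(self):
        # frozen cross-check: lme4::glmer(y ~ 1 + (1|person_id), nAGQ=21)
        # on this exact dataset gives mu=0.717016, sd=0.808906
        rng = np.random.default_rng(2024)
        k, n = 60, 25
        u = rng.normal(0, 0.8, size=k)
        rows = []
        for i in range(k):
            p = expit(0.7 + u[i])
            y = (rng.random(n) < p).astype(int)
            rows += [(f"c{i:02d}", int(v)) for v in y]
        fit = fit_random_intercept_logistic(pd.DataFrame(rows, columns=["person_id", "y"]))
        assert fit.intercept_logit == pytest.approx(0.717016, abs=5e-3)
        assert np.sqrt(fit.intercept_var) == pytest.approx(0.808906, abs=5e-3)

    def test_quadrature_matches_dense_integration_oracle(self, rng):
        df = self.simulate(rng, 0.5, 0.7, 30, 20)
        fit = fit_random_intercept_logistic(df)
        mu, sd = fit.intercept_logit, np.sqrt(fit.intercept_var)
        # dense trapezoid integral of each cluster's marginal likelihood
        z = np.linspace(-8, 8, 10001)
        phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        g = df.groupby("person_id")["y"]
        s, n = g.sum().to_numpy(float), g.count().to_numpy(float)
        p = expit(mu + sd * z)[None, :]
        lik = (p ** s[:, None]) * ((1 - p) ** (n - s)[:, None]) * phi[None, :]
        dense = np.log(np.trapezoid(lik, z, axis=1))
        # quadrature per-cluster log-likelihood at the same parameters
        def gh_loglik(nodes):
            zq, wq = np.polynomial.hermite_e.hermegauss(nodes)
            wq = wq / wq.sum()
            pq = expit(mu + sd * zq)[None, :]
            return np.log(
                (wq[None, :] * pq ** s[:, None] * (1 - pq) ** (n - s)[:, None]).sum(axis=1)
            )

        # 21 fixed nodes carry only quadrature truncation error ...
        assert np.max(np.abs(dense - gh_loglik(21))) < 1e-3
        # ... and converge onto the dense integral as nodes increase
        assert np.max(np.abs(dense - gh_loglik(81))) < 1e-8

    def test_all_one_outcomes_flagged(self):
        df = pd.DataFrame({"person_id": ["a"] * 5 + ["b"] * 5, "y": [1] * 10})
        fit = fit_random_intercept_logistic(df)
        assert fit.boundary and 0.9 < fit.median_prob < 1.0

    def test_eb_intercepts_shrink_toward_zero(self, rng):
        df = self.simulate(rng, 0.0, 1.0, 40, 10)
        fit = fit_random_intercept_logistic(df)
        # posterior modes are pulled in relative to raw cluster logits
        assert fit.per_person_eb.abs().max() < 4.0


class TestSummarizeCondition:
    def test_perfect_observer_all_metrics_near_one(self, rng):
        # boundary clusters get a half-count continuity correction, so the
        # median rates sit just below 1 rather than exactly at it
        s = summarize_condition(make_records(rng, accuracy=1.0), n_boot=0)
        assert s.sensitivity > 0.99 and s.specificity > 0.99
        assert s.kappa > 0.97

    def test_coin_flip_observer_kappa_near_zero(self, rng):
        rec = make_records(rng, n_persons=40, prompts=60, accuracy=0.5, prevalence=0.5)
        s = summarize_condition(rec, n_boot=0)
        assert abs(s.kappa) < 0.05

    def test_weekly_summaries_partition_records(self, rng):
        rec = make_records(rng, prompts=28)
        s = summarize_condition(rec, weekly=True, n_boot=0)
        assert sum(w.n_classifiable for w in s.by_week.values()) == s.n_classifiable

    def test_bootstrap_interval_covers_point(self, rng):
        rec = make_records(rng, accuracy=0.85)
        s = summarize_condition(rec, n_boot=60, seed=3)
        lo, hi = s.ci["kappa"]
        assert lo <= s.kappa <= hi

    def test_empty_input_rejected(self):
        from jitaema.simulate import RECORD_COLUMNS

        with pytest.raises(ValueError):
            summarize_condition(pd.DataFrame(columns=RECORD_COLUMNS))


class TestCutoffRmse:
    def base(self, rng):
        rec = make_records(rng, n_persons=4, prompts=20)
        rec["true_cutoff"] = rng.normal(1.0, 0.2, size=len(rec))
        return rec

    def test_zero_when_exact(self, rng):
        rec = self.base(rng)
        rec["obs_cutoff"] = rec["true_cutoff"]
        assert (cutoff_rmse_by_day(rec)["rmse"] == 0).all()

    def test_constant_offset(self, rng):
        rec = self.base(rng)
        rec["obs_cutoff"] = rec["true_cutoff"] + 0.3
        assert cutoff_rmse_by_day(rec)["rmse"].to_numpy() == pytest.approx(0.3, abs=1e-12)

    def test_matches_arithmetic_oracle(self, rng):
        rec = self.base(rng).head(20)
        rec["obs_cutoff"] = rec["true_cutoff"] + rng.normal(0, 0.2, size=len(rec))
        out = cutoff_rmse_by_day(rec)
        for _, row in out.iterrows():
            sub = rec[rec["day"] == row["day"]]
            expected = np.sqrt(((sub["obs_cutoff"] - sub["true_cutoff"]) ** 2).mean())
            assert row["rmse"] == pytest.approx(expected, abs=1e-12)


class TestCompareConditions:
    def test_self_comparison_is_null(self, rng):
        rec = make_records(rng, accuracy=0.8)
        out = compare_conditions({"a": rec, "b": rec.copy()}, n_boot=30, seed=1)
        row = out.iloc[0]
        assert row["difference"] == pytest.approx(0.0, abs=1e-12)
        assert row["ci_lo"] <= 0 <= row["ci_hi"]

    def test_known_ordering_flagged(self, rng):
        good = make_records(rng, accuracy=0.97, n_persons=30, prompts=40)
        bad = make_records(rng, accuracy=0.6, n_persons=30, prompts=40)
        out = compare_conditions({"good": good, "bad": bad}, n_boot=60, seed=2)
        assert bool(out.iloc[0]["significant"])

    def test_single_draw_degenerates_gracefully(self, rng):
        rec = make_records(rng)
        out = compare_conditions({"a": rec, "b": rec.copy()}, n_boot=1)
        assert np.isnan(out.iloc[0]["ci_lo"]) and out.iloc[0]["significant"] is None

    def test_mismatched_persons_rejected(self, rng):
        a = make_records(rng, n_persons=5)
        b = make_records(rng, n_persons=6)
        with pytest.raises(ValueError, match="mismatched"):
            compare_conditions({"a": a, "b": b})
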
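"""Performance criteria for momentary classification methods.

Given per-prompt records (one condition at a time) this module computes:

* sensitivity and specificity as *median-person* rates from a logit-normal
  random-intercept model fitted by maximum likelihood with fixed 21-node
  Gauss-Hermite quadrature (momentary classifications are nested within
  persons, so pooled proportions would be biased toward heavy reporters);
* Cohen's kappa derived from sensitivity, specificity and prevalence;
* the mean number of items administered per prompt with a one-way
  between/within-person variance decomposition;
* weekly breakdowns, cutoff RMSE by study day, and paired between-condition
  contrasts with person-resampled (cluster) bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "ConfusionByPerson",
    "RandomInterceptFit",
    "EvalSummary",
    "confusion_counts",
    "fit_random_intercept_logistic",
    "kappa_from_rates",
    "items_variance_decomposition",
    "summarize_condition",
    "cutoff_rmse_by_day",
    "compare_conditions",
]


@dataclass
class ConfusionByPerson:
    """Per-person 2x2 confusion counts over classifiable prompts."""

    table: pd.DataFrame  # index person_id, columns tp, fn, fp, tn

    @property
    def totals(self) -> dict:
        s = self.table.sum()
        return {k: int(s[k]) for k in ("tp", "fn", "fp", "tn")}


def confusion_counts(records: pd.DataFrame) -> ConfusionByPerson:
    """Cross-tabulate true vs observed class per person (classifiable only)."""
    df = records[records["classifiable"]].copy()
    truth_above = df["true_class"] == "above"
    obs_above = df["obs_class"] == "above"
    df["cell"] = np.select(
        [truth_above & obs_above, truth_above & ~obs_above,
         ~truth_above & obs_above, ~truth_above & ~obs_above],
        ["tp", "fn", "fp", "tn"],
        default="",
    )
    tab = (
        df.groupby(["person_id", "cell"], sort=True).size().unstack(fill_value=0)
        .reindex(columns=["tp", "fn", "fp", "tn"], fill_value=0)
    )
    return ConfusionByPerson(table=tab)


# ---------------------------------------------------------------------------
# Logit-normal random-intercept model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomInterceptFit:
    """ML fit of y_ij ~ Bernoulli(expit(mu + u_i)), u_i ~ N(0, sigma^2)."""

    intercept_logit: float
    intercept_var: float
    median_prob: float
    per_person_eb: pd.Series
    boundary: bool = False


_GH_NODES = 21


def _gh_points():
    # probabilists' Hermite rule: integrates against the standard normal
    z, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return z, w / w.sum()


def _cluster_stats(outcomes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    grp = outcomes.groupby("person_id")["y"]
    s = grp.sum().to_numpy(dtype=float)
    n = grp.count().to_numpy(dtype=float)
    return s, n, grp.count().index


def fit_random_intercept_logistic(outcomes: pd.DataFrame) -> RandomInterceptFit:
    """Fit the logit-normal random-intercept model by quadrature ML.

    ``outcomes`` has columns ``person_id`` and binary ``y``.  The
    back-transformed intercept is the *median-person* probability.
    Degenerate all-0/all-1 data are flagged and handled with an
    Agresti-style half-count continuity correction.
    """
    if outcomes["person_id"].nunique() < 2:
        raise ValueError("need >= 2 persons (clusters) to fit a random-intercept model")
    s, n, idx = _cluster_stats(outcomes)
    boundary = False
    total_s = s.sum()
    if total_s == 0 or total_s == n.sum():
        boundary = True
        # continuity correction: half a success and half a failure overall
        p = (total_s + 0.5) / (n.sum() + 1.0)
        mu = float(logit(p))
        eb = pd.Series(np.zeros(len(idx)), index=idx, name="eb_intercept")
        return RandomInterceptFit(mu, 0.0, float(expit(mu)), eb, boundary=True)

    z, w = _gh_points()

    def nll(params):
        mu, log_sd = params
        sd = np.exp(log_sd)
        eta = mu + sd * z  # (Q,)
        # cluster log-likelihood via sufficient stats (all obs share p)
        logp = -np.logaddexp(0.0, -eta)   # log expit(eta)
        logq = -np.logaddexp(0.0, eta)    # log (1 - expit(eta))
        ll_zk = s[:, None] * logp[None, :] + (n - s)[:, None] * logq[None, :]
        m = ll_zk.max(axis=1, keepdims=True)
        lik = np.log((w[None, :] * np.exp(ll_zk - m)).sum(axis=1)) + m[:, 0]
        return -lik.sum()

    p_pool = np.clip(total_s / n.sum(), 1e-6, 1 - 1e-6)
    x0 = np.array([logit(p_pool), np.log(0.5)])
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, log_sd = res.x
    sd = float(np.exp(log_sd))

    # empirical-Bayes posterior modes per person (Newton on a concave target)
    u = np.zeros(len(s))
    if sd > 1e-8:
        for _ in range(50):
            p = expit(mu + u)
            g = s - n * p - u / sd**2
            h = -n * p * (1 - p) - 1 / sd**2
            step = -g / h
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
    eb = pd.Series(u, index=idx, name="eb_intercept")
    return RandomInterceptFit(
        intercept_logit=float(mu),
        intercept_var=sd**2,
        median_prob=float(expit(mu)),
        per_person_eb=eb,
        boundary=boundary,
    )


def kappa_from_rates(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Cohen's kappa as a function of sensitivity, specificity, prevalence.

    With ``P`` the prevalence, observed agreement ``p_o = P*Se +
    (1-P)*Sp``, the positive-call rate ``q = P*Se + (1-P)(1-Sp)`` and
    chance agreement ``p_e = P*q + (1-P)(1-q)``: ``kappa = (p_o - p_e) /
    (1 - p_e)``.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    p, se, sp = prevalence, sensitivity, specificity
    p_o = p * se + (1 - p) * sp
    q = p * se + (1 - p) * (1 - sp)
    p_e = p * q + (1 - p) * (1 - q)
    if p_e >= 1.0:
        raise ValueError("degenerate input: chance agreement is 1")
    return (p_o - p_e) / (1 - p_e)


def items_variance_decomposition(records: pd.DataFrame) -> dict:
    """One-way (method-of-moments) decomposition of items-per-prompt.

    Splits the variance of the number of items administered into a
    between-person and a within-person component; ``within_share`` is the
    within fraction of the total.  Uses the standard unbalanced one-way
    ANOVA estimator.
    """
    grp = records.groupby("person_id")["n_items"]
    counts = grp.count().to_numpy(dtype=float)
    means = grp.mean().to_numpy()
    y = records["n_items"].to_numpy(dtype=float)
    k = len(counts)
    N = counts.sum()
    grand = y.mean()
    if k < 2:
        return {"mean": float(grand), "between_sd": float("nan"),
                "within_sd": float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
                "within_share": float("nan"), "flag": "single_person"}
    sse = float(((records["n_items"] - grp.transform("mean")) ** 2).sum())
    ssb = float((counts * (means - grand) ** 2).sum())
    msw = sse / (N - k)
    n0 = (N - (counts**2).sum() / N) / (k - 1)
    var_b = max(0.0, (ssb / (k - 1) - msw) / n0)
    var_w = msw
    total = var_b + var_w
    return {
        "mean": float(grand),
        "between_sd": float(np.sqrt(var_b)),
        "within_sd": float(np.sqrt(var_w)),
        "within_share": float(var_w / total) if total > 0 else float("nan"),
        "flag": None,
    }


@dataclass
class EvalSummary:
    """Condition-level performance summary (optionally per week)."""

    condition: str
    n_prompts: int
    n_classifiable: int
    prevalence: float
    sensitivity: float
    specificity: float
    kappa: float
    mean_items: float
    items_between_sd: float
    items_within_sd: float
    items_within_share: float
    ci: dict = field(default_factory=dict)          # metric -> (lo, hi)
    by_week: dict = field(default_factory=dict)     # week -> EvalSummary

    def to_dict(self) -> dict:
        out = {
            "condition": self.condition,
            "n_prompts": self.n_prompts,
            "n_classifiable": self.n_classifiable,
            "prevalence": self.prevalence,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
            "mean_items": self.mean_items,
            "items_between_sd": self.items_between_sd,
            "items_within_sd": self.items_within_sd,
            "items_within_share": self.items_within_share,
        }
        for metric, (lo, hi) in self.ci.items():
            out[f"{metric}_ci_lo"] = lo
            out[f"{metric}_ci_hi"] = hi
        return out


def _rates(records: pd.DataFrame) -> tuple[float, float, float]:
    """Median-person sensitivity and specificity plus prevalence."""
    df = records[records["classifiable"]]
    above = df[df["true_class"] == "above"]
    below = df[df["true_class"] == "below"]
    prevalence = len(above) / len(df) if len(df) else float("nan")

    def median_rate(sub: pd.DataFrame, positive: str) -> float:
        if not len(sub):
            return float("nan")
        out = pd.DataFrame(
            {"person_id": sub["person_id"], "y": (sub["obs_class"] == positive).astype(int)}
        )
        if out["person_id"].nunique() < 2:
            return float(out["y"].mean())
        return fit_random_intercept_logistic(out).median_prob

    return median_rate(above, "above"), median_rate(below, "below"), prevalence


def summarize_condition(
    records: pd.DataFrame,
    weekly: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalSummary:
    """Assemble the full performance summary for one condition's records.

    Prevalence for kappa is the empirical rate of truly-above states among
    classifiable prompts.  Bootstrap confidence intervals (``n_boot`` > 0)
    resample persons with replacement (cluster bootstrap); ``n_boot = 1``
    degenerates to no interval.
    """
    if not len(records):
        raise ValueError("no records to summarize")
    conds = records["condition"].unique()
    condition = conds[0] if len(conds) == 1 else "mixed"

    def metrics(df: pd.DataFrame) -> dict:
        se, sp, prev = _rates(df)
        kap = (
            kappa_from_rates(se, sp, prev)
            if np.isfinite(se) and np.isfinite(sp) and 0 < prev < 1
            else float("nan")
        )
        dec = items_variance_decomposition(df)
        return {
            "sensitivity": se, "specificity": sp, "prevalence": prev, "kappa": kap,
            "mean_items": dec["mean"], "items_between_sd": dec["between_sd"],
            "items_within_sd": dec["within_sd"], "items_within_share": dec["within_share"],
        }

    m = metrics(records)
    ci: dict = {}
    if n_boot > 1:
        rng = np.random.default_rng(seed)
        persons = records["person_id"].unique()
        groups = {p: g for p, g in records.groupby("person_id")}
        draws: dict[str, list[float]] = {k: [] for k in
                                         ("sensitivity", "specificity", "kappa", "mean_items")}
        for _ in range(n_boot):
            pick = rng.choice(persons, size=len(persons), replace=True)
            boot = pd.concat(
                [groups[p].assign(person_id=f"{p}#{i}") for i, p in enumerate(pick)],
                ignore_index=True,
            )
            bm = metrics(boot)
            for k in draws:
                draws[k].append(bm[k])
        for k, vals in draws.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[np.isfinite(arr)]
            if len(arr):
                ci[k] = (float(np.quantile(arr, 0.025)), float(np.quantile(arr, 0.975)))

    by_week: dict[int, EvalSummary] = {}
    if weekly:
        for wk, sub in records.groupby("week"):
            by_week[int(wk)] = summarize_condition(sub, weekly=False, n_boot=0, seed=seed)

    ncls = int(records["classifiable"].sum())
    return EvalSummary(
        condition=condition,
        n_prompts=int(len(records)),
        n_classifiable=ncls,
        prevalence=m["prevalence"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        kappa=m["kappa"],
        mean_items=m["mean_items"],
        items_between_sd=m["items_between_sd"],
        items_within_sd=m["items_within_sd"],
        items_within_share=m["items_within_share"],
        ci=ci,
        by_week=by_week,
    )


def cutoff_rmse_by_day(records: pd.DataFrame, by_person: bool = False) -> pd.DataFrame:
    """RMSE of (observed - true) cutoff over classifiable prompts per day."""
    df = records[records["classifiable"] & records["obs_cutoff"].notna()].copy()
    df["sq_err"] = (df["obs_cutoff"] - df["true_cutoff"]) ** 2
    keys = ["person_id", "day"] if by_person else ["day"]
    out = df.groupby(keys)["sq_err"].mean().pow(0.5).rename("rmse").reset_index()
    return out


def compare_conditions(
    bundles: dict[str, pd.DataFrame],
    metric: str = "kappa",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired between-condition differences with cluster-bootstrap intervals.

    ``bundles`` maps condition name -> records sharing the same persons
    (the shared-truth design).  For each ordered pair, the metric
    difference is recomputed on person resamples drawn identically for
    both conditions; a difference is flagged when its 95% interval
    excludes zero.  ``n_boot <= 1`` yields point differences only.
    """
    names = list(bundles)
    person_sets = {n: frozenset(b["person_id"].unique()) for n, b in bundles.items()}
    base = person_sets[names[0]]
    for n in names[1:]:
        if person_sets[n] != base:
            raise ValueError(f"conditions {names[0]!r} and {n!r} have mismatched persons")
    persons = sorted(base)

    def metric_value(df: pd.DataFrame) -> float:
        s = summarize_condition(df, n_boot=0)
        return getattr(s, metric)

    point = {n: metric_value(b) for n, b in bundles.items()}
    grouped = {n: {p: g for p, g in b.groupby("person_id")} for n, b in bundles.items()}

    rows = []
    rng = np.random.default_rng(seed)
    boot_draws: dict[tuple[str, str], list[float]] = {}
    if n_boot > 1:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        boot_draws = {pr: [] for pr in pairs}
        for _ in range(n_boot):
            pick = rng.choice(persons, size=len(persons), replace=True)
            vals = {}
            for n in names:
                boot = pd.concat(
                    [grouped[n][p].assign(person_id=f"{p}#{i}") for i, p in enumerate(pick)],
                    ignore_index=True,
                )
                vals[n] = metric_value(boot)
            for a, b in pairs:
                boot_draws[(a, b)].append(vals[a] - vals[b])

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = point[a] - point[b]
            row = {"condition_a": a, "condition_b": b, "metric": metric, "difference": diff}
            if (a, b) in boot_draws and boot_draws[(a, b)]:
                arr = np.asarray(boot_draws[(a, b)], dtype=float)
                arr = arr[np.isfinite(arr)]
                lo, hi = float(np.quantile(arr, 0.025)), float(np.quantile(arr, 0.975))
                row.update({"ci_lo": lo, "ci_hi": hi, "significant": bool(lo > 0 or hi < 0)})
            else:
                row.update({"ci_lo": float("nan"), "ci_hi": float("nan"), "significant": None})
            rows.append(row)
    return pd.DataFrame(rows)
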
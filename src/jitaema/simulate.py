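"""End-to-end EMA study simulation under five item-selection conditions.

The generator emulates a multi-week momentary-fatigue study: a population
of persons, each with an idiographic diurnal (cosinor) cycle on the
z-standardized latent metric, day-to-day wobble of that cycle, and
within-person residual noise; a prompt schedule of 5-6 signals per day over
the waking window with configurable compliance; and "true" classification
cutoffs that are either uniform (one z-value for everyone) or tailored to
the person's generating cycle plus half a within-person SD.

Five item-selection conditions are run over *identical* ground truth:

* ``fixed2`` / ``fixed3`` / ``fixed5`` — 2, 3 or 5 randomly chosen items;
* ``variable`` — random items, stop once the 95% CI excludes the cutoff
  (max 5);
* ``jita`` — maximum-expected-information selection with the same
  classification-confidence stop, initialized from the previous prompt's
  estimate (uniform cutoffs) or from the person's estimated diurnal cycle
  (dynamic cutoffs).

Response streams are keyed per (prompt, item) so that two conditions
administering the same item at the same prompt observe the same answer,
sharpening between-condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bank import ItemBank, generate_synthetic_bank
from .cutoffs import (
    CutoffSpec,
    SingularFitError,
    dynamic_cutoff,
    fit_cosinor,
    is_classifiable,
    predict_cosinor,
)
from .engine import SelectorSpec, StoppingSpec, run_session, start_session
from .irt import (
    BankArrays,
    PriorSpec,
    _all_category_terms,
    _information_arrays,
    _map_newton,
    _se_from_information,
)

__all__ = [
    "PersonProfile",
    "PopulationHyper",
    "Schedule",
    "StudyConfig",
    "StudyResult",
    "CONDITIONS",
    "generate_population",
    "generate_schedule",
    "generate_true_thetas",
    "run_condition",
    "run_study",
    "study1_config",
    "study2_config",
]

CONDITIONS = ("fixed2", "fixed3", "fixed5", "variable", "jita")

RECORD_COLUMNS = [
    "condition", "person_id", "day", "hour", "week",
    "true_theta", "true_cutoff", "true_class",
    "items", "responses", "n_items", "theta", "se",
    "obs_cutoff", "obs_class", "classifiable", "stop_reason",
]


@dataclass(frozen=True)
class PersonProfile:
    """Generating truth for one person: cosinor cycle plus noise scales."""

    person_id: str
    beta0: float
    beta1: float
    beta2: float
    within_sd: float
    cycle_day_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.within_sd > 0):
            raise ValueError("within_sd must be > 0")
        if self.cycle_day_sd < 0:
            raise ValueError("cycle_day_sd must be >= 0")


@dataclass(frozen=True)
class PopulationHyper:
    """Hyperpriors for person profiles.

    Defaults are calibrated so the pooled marginal variance of true states
    is approximately 1 (the latent metric is z-standardized):
    Var(beta0) + E[amplitude^2]/2 + E[within_sd^2] + E[cycle_day_sd^2]
    = 0.49 + 0.11 + 0.39 + 0.05 which is approximately 1.04.
    """

    beta0_sd: float = 0.7
    amplitude_range: tuple[float, float] = (0.0, 0.8)
    within_sd_range: tuple[float, float] = (0.3, 0.9)
    cycle_day_sd_range: tuple[float, float] = (0.0, 0.4)


@dataclass
class Schedule:
    """Prompt schedule: rows (person_id, day, hour), sorted per person."""

    prompts: list[tuple[str, int, float]]
    compliance: float = 1.0

    def __len__(self) -> int:
        return len(self.prompts)

    def for_person(self, person_id: str) -> list[tuple[int, float]]:
        return [(d, h) for p, d, h in self.prompts if p == person_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prompts, columns=["person_id", "day", "hour"])


@dataclass
class StudyConfig:
    """Design of one simulated study (defaults mirror the reference design)."""

    n_persons: int = 106
    n_days: int = 28
    prompts_per_day_range: tuple[int, int] = (5, 6)
    compliance: float = 0.91
    waking_window: tuple[float, float] = (6.0, 22.0)
    cutoff: CutoffSpec = field(default_factory=CutoffSpec)
    conditions: tuple[str, ...] = CONDITIONS
    prior: PriorSpec = field(default_factory=PriorSpec)
    max_items: int = 5
    confidence: float = 0.95
    run_in_se: float = 0.3
    hyper: PopulationHyper = field(default_factory=PopulationHyper)
    bank: ItemBank | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        lo, hi = self.prompts_per_day_range
        if not (1 <= lo <= hi):
            raise ValueError("prompts_per_day_range must satisfy 1 <= min <= max")
        if not (0 <= self.compliance <= 1):
            raise ValueError("compliance must be in [0, 1]")
        if self.waking_window[1] <= self.waking_window[0]:
            raise ValueError("waking_window end must exceed start")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    def resolve_bank(self) -> ItemBank:
        if self.bank is not None:
            return self.bank
        return generate_synthetic_bank(seed=_seed_for(self.master_seed, "bank"))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        """Build a config from a plain mapping (e.g., parsed YAML).

        Unknown or ill-typed fields raise ``ValueError`` naming the field
        path (``cutoff.delta_sd`` etc.).
        """
        d = dict(d)
        kwargs: dict = {}
        simple = {
            "n_persons": int, "n_days": int, "compliance": float,
            "max_items": int, "confidence": float, "run_in_se": float,
            "master_seed": int,
        }
        pairs = {"prompts_per_day_range": int, "waking_window": float}
        for key, cast in simple.items():
            if key in d:
                try:
                    kwargs[key] = cast(d.pop(key))
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"config field {key}: {exc}") from exc
        for key, cast in pairs.items():
            if key in d:
                v = d.pop(key)
                try:
                    kwargs[key] = (cast(v[0]), cast(v[1]))
                except (TypeError, ValueError, IndexError) as exc:
                    raise ValueError(f"config field {key}: expected a pair, got {v!r}") from exc
        if "conditions" in d:
            kwargs["conditions"] = tuple(d.pop("conditions"))
        if "cutoff" in d:
            c = d.pop("cutoff")
            try:
                kwargs["cutoff"] = CutoffSpec(
                    kind=c.get("kind", "uniform"),
                    uniform_z=float(c.get("uniform_z", 1.0)),
                    delta_sd=float(c.get("delta_sd", 0.5)),
                    daytime=tuple(float(x) for x in c.get("daytime", (6.0, 18.0))),
                    run_in_days=int(c.get("run_in_days", 2)),
                )
            except (TypeError, ValueError, AttributeError) as exc:
                raise ValueError(f"config field cutoff: {exc}") from exc
        if "prior" in d:
            p = d.pop("prior")
            try:
                kwargs["prior"] = PriorSpec(
                    mean=float(p.get("mean", 0.0)), sd=float(p.get("sd", 1.0))
                )
            except (TypeError, ValueError, AttributeError) as exc:
                raise ValueError(f"config field prior: {exc}") from exc
        if "hyper" in d:
            h = d.pop("hyper")
            try:
                kwargs["hyper"] = PopulationHyper(
                    beta0_sd=float(h.get("beta0_sd", 0.7)),
                    amplitude_range=tuple(float(x) for x in h.get("amplitude_range", (0.0, 0.8))),
                    within_sd_range=tuple(float(x) for x in h.get("within_sd_range", (0.3, 0.9))),
                    cycle_day_sd_range=tuple(
                        float(x) for x in h.get("cycle_day_sd_range", (0.0, 0.4))
                    ),
                )
            except (TypeError, ValueError, AttributeError) as exc:
                raise ValueError(f"config field hyper: {exc}") from exc
        if d:
            raise ValueError(f"unknown config fields: {sorted(d)}")
        try:
            return cls(**kwargs)
        except ValueError as exc:
            raise ValueError(f"invalid config: {exc}") from exc


def study1_config(**overrides) -> StudyConfig:
    """Uniform-cutoff study: one z = 1.0 cutoff for everyone, all prompts."""
    cfg = StudyConfig(cutoff=CutoffSpec(kind="uniform", uniform_z=1.0))
    return replace(cfg, **overrides) if overrides else cfg


def study2_config(**overrides) -> StudyConfig:
    """Dynamic-cutoff study: person/time-tailored cutoffs, 2-day run-in,
    6 AM-6 PM classification window, +0.5 within-person SD margin."""
    cfg = StudyConfig(
        cutoff=CutoffSpec(kind="dynamic", delta_sd=0.5, daytime=(6.0, 18.0), run_in_days=2)
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Seeding: every stage draws from a named child of the master seed.
# ---------------------------------------------------------------------------

_STAGES = {"bank": 1, "population": 2, "schedule": 3, "truth": 4, "responses": 5, "sessions": 6}


def _seed_for(master_seed: int, stage: str, extra: int = 0) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGES[stage], extra))
    return int(ss.generate_state(1)[0] % (2**31))


def _rng_for(master_seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGES[stage], extra))
    )


# ---------------------------------------------------------------------------
# Ground-truth generation
# ---------------------------------------------------------------------------


def generate_population(
    n: int, hyper: PopulationHyper = PopulationHyper(), seed: int = 0
) -> list[PersonProfile]:
    """Draw ``n`` person profiles i.i.d. from the hyperpriors."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for name in ("amplitude_range", "within_sd_range", "cycle_day_sd_range"):
        lo, hi = getattr(hyper, name)
        if hi < lo or lo < 0:
            raise ValueError(f"invalid {name}: {(lo, hi)}")
    if hyper.within_sd_range[0] <= 0:
        raise ValueError("within_sd_range lower bound must be > 0")
    rng = np.random.default_rng(seed)
    beta0 = rng.normal(0.0, hyper.beta0_sd, size=n)
    amp = rng.uniform(*hyper.amplitude_range, size=n)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n)
    within = rng.uniform(*hyper.within_sd_range, size=n)
    wobble = rng.uniform(*hyper.cycle_day_sd_range, size=n)
    pad = len(str(n))
    return [
        PersonProfile(
            person_id=f"p{i + 1:0{pad}d}",
            beta0=float(beta0[i]),
            beta1=float(amp[i] * np.cos(phase[i])),
            beta2=float(amp[i] * np.sin(phase[i])),
            within_sd=float(within[i]),
            cycle_day_sd=float(wobble[i]),
        )
        for i in range(n)
    ]


def generate_schedule(
    config: StudyConfig, seed: int = 0, person_ids: list[str] | None = None
) -> Schedule:
    """Draw the prompt schedule: counts uniform on the configured range,
    hours stratified over the waking window with jitter, prompts kept
    independently with probability ``compliance`` (missing completely at
    random)."""
    rng = np.random.default_rng(seed)
    if person_ids is None:
        pad = len(str(config.n_persons))
        person_ids = [f"p{i + 1:0{pad}d}" for i in range(config.n_persons)]
    lo, hi = config.prompts_per_day_range
    w0, w1 = config.waking_window
    prompts: list[tuple[str, int, float]] = []
    for pid in person_ids:
        for day in range(1, config.n_days + 1):
            count = int(rng.integers(lo, hi + 1))
            edges = np.linspace(w0, w1, count + 1)
            hours = edges[:-1] + rng.random(count) * np.diff(edges)
            keep = rng.random(count) < config.compliance
            prompts.extend((pid, day, float(h)) for h in hours[keep])
    return Schedule(prompts=prompts, compliance=config.compliance)


def _day_cycles(profile: PersonProfile, days: np.ndarray, rng: np.random.Generator):
    """Per-day perturbed (beta1, beta2): the day-to-day cycle wobble."""
    uniq = np.unique(days)
    d1 = rng.normal(0.0, profile.cycle_day_sd, size=len(uniq))
    d2 = rng.normal(0.0, profile.cycle_day_sd, size=len(uniq))
    lookup = {int(d): (float(a), float(b)) for d, a, b in zip(uniq, d1, d2)}
    return lookup


def generate_true_thetas(
    profile: PersonProfile,
    schedule: Schedule,
    cutoff_spec: CutoffSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate true momentary states and true cutoffs for one person.

    The day-specific cycle is the person's cycle with Normal(0,
    cycle_day_sd) wobble on the sine/cosine coefficients; the momentary
    state adds Normal(0, within_sd) residual noise.  True dynamic cutoffs
    use the *person-level* cycle (the stable generating rhythm) plus
    ``delta_sd * within_sd``; uniform cutoffs are the configured z-value.
    The true class is "above" iff the state strictly exceeds the cutoff.
    """
    rng = np.random.default_rng(seed)
    own = schedule.for_person(profile.person_id)
    days = np.asarray([d for d, _ in own], dtype=int)
    hours = np.asarray([h for _, h in own], dtype=float)
    cycles = _day_cycles(profile, days, rng)
    ang = 2.0 * np.pi * hours / 24.0
    b1 = np.asarray([profile.beta1 + cycles[int(d)][0] for d in days])
    b2 = np.asarray([profile.beta2 + cycles[int(d)][1] for d in days])
    theta = profile.beta0 + b1 * np.sin(ang) + b2 * np.cos(ang)
    theta = theta + rng.normal(0.0, profile.within_sd, size=len(theta))
    if cutoff_spec.kind == "uniform":
        cut = np.full(len(theta), float(cutoff_spec.uniform_z))
    else:
        base = (
            profile.beta0
            + profile.beta1 * np.sin(ang)
            + profile.beta2 * np.cos(ang)
        )
        cut = base + cutoff_spec.delta_sd * profile.within_sd
    return pd.DataFrame(
        {
            "person_id": profile.person_id,
            "day": days,
            "hour": hours,
            "week": np.ceil(days / 7.0).astype(int),
            "true_theta": theta,
            "true_cutoff": cut,
            "true_class": np.where(theta > cut, "above", "below"),
        }
    )


def _truth_table(config: StudyConfig, population, schedule) -> pd.DataFrame:
    frames = [
        generate_true_thetas(
            prof, schedule, config.cutoff, seed=_seed_for(config.master_seed, "truth", i)
        )
        for i, prof in enumerate(population)
    ]
    return pd.concat(frames, ignore_index=True)


def _truth_from_external(config: StudyConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Build the truth table from externally supplied true states.

    ``table`` needs columns person_id, day, hour, theta.  True dynamic
    cutoffs are then *estimated* per person with a cosinor fit over all of
    that person's supplied states (the natural definition when the
    generating process is unknown)."""
    need = {"person_id", "day", "hour", "theta"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"external true-theta table missing columns: {sorted(missing)}")
    out = table.copy().sort_values(["person_id", "day", "hour"]).reset_index(drop=True)
    out = out.rename(columns={"theta": "true_theta"})
    out["week"] = np.ceil(out["day"] / 7.0).astype(int)
    if config.cutoff.kind == "uniform":
        out["true_cutoff"] = float(config.cutoff.uniform_z)
    else:
        cuts = np.empty(len(out))
        for pid, grp in out.groupby("person_id", sort=False):
            fit = fit_cosinor(grp["hour"].to_numpy(), grp["true_theta"].to_numpy())
            cuts[grp.index] = (
                predict_cosinor(fit, grp["hour"].to_numpy())
                + config.cutoff.delta_sd * fit.resid_sd
            )
        out["true_cutoff"] = cuts
    out["true_class"] = np.where(out["true_theta"] > out["true_cutoff"], "above", "below")
    return out


def _shared_responses(config: StudyConfig, bank: ItemBank, truth: pd.DataFrame) -> np.ndarray:
    """Pre-draw the response every bank item would receive at every prompt.

    One uniform variate per (prompt, item), inverted through the GRM CDF at
    the prompt's true state — conditions administering the same item at the
    same prompt therefore observe the same answer."""
    arrs = BankArrays.from_bank(bank)
    rng = _rng_for(config.master_seed, "responses")
    thetas = truth["true_theta"].to_numpy()
    u = rng.random((len(thetas), len(bank)))
    P, _ = _all_category_terms(arrs.a, arrs.b, thetas)  # (n, m, K)
    cum = np.cumsum(P, axis=-1)
    cats = (u[:, :, None] > cum).sum(axis=-1) + 1
    return np.minimum(cats, arrs.k[None, :]).astype(np.int64)


# ---------------------------------------------------------------------------
# Condition execution
# ---------------------------------------------------------------------------


def _condition_setup(condition: str, config: StudyConfig):
    if condition.startswith("fixed"):
        n = int(condition[len("fixed"):])
        selector_kind = "random"
        stopping = StoppingSpec(
            kind="fixed_length", fixed_n=n, max_items=max(n, config.max_items)
        )
        return selector_kind, stopping
    if condition == "variable":
        selector_kind = "random"
    elif condition == "jita":
        selector_kind = "mei"
    else:
        raise ValueError(f"unknown condition {condition!r}")
    stopping = StoppingSpec(
        kind="classification_confidence",
        max_items=config.max_items,
        confidence=config.confidence,
    )
    return selector_kind, stopping


def _cosinor_init(history: list[tuple[float, float]], hour: float, prior: PriorSpec) -> float:
    """Initialization for dynamic-cutoff adaptive sessions: the person's
    expected level at this time of day, from previously observed scores."""
    if len(history) >= 3:
        hs = np.asarray([h for h, _ in history])
        ts = np.asarray([t for _, t in history])
        try:
            return float(predict_cosinor(fit_cosinor(hs, ts), hour))
        except SingularFitError:
            pass
    if history:
        return float(np.mean([t for _, t in history]))
    return prior.mean


def _run_fixed_batch(
    condition: str,
    n_fix: int,
    bank: ItemBank,
    config: StudyConfig,
    truth: pd.DataFrame,
    responses: np.ndarray,
) -> pd.DataFrame:
    """Vectorized path for fixed-length conditions.

    Random selection is independent of the answers, so all prompts can be
    scored in one stacked Newton solve; the item-selection random streams
    are drawn exactly as the sequential engine would draw them.
    """
    arrs = BankArrays.cached(bank)
    m = len(bank)
    cond_idx = CONDITIONS.index(condition)
    n_prompts = len(truth)
    sel = np.empty((n_prompts, n_fix), dtype=np.int64)
    person_slices = []
    for pi, (pid, grp) in enumerate(truth.groupby("person_id", sort=False)):
        rng = _rng_for(config.master_seed, "sessions", cond_idx * 100003 + pi)
        person_slices.append((pid, grp))
        for ridx in grp.index:
            remaining = list(range(m))
            for k in range(n_fix):
                j = int(rng.choice(remaining))
                remaining.remove(j)
                sel[ridx, k] = j
    cats = np.take_along_axis(responses, sel, axis=1)
    theta = _map_newton(
        arrs.a[sel], arrs.b[sel], cats,
        config.prior.mean, config.prior.sd,
        np.full(n_prompts, config.prior.mean),
    )
    info = _information_arrays(arrs.a[sel], arrs.b[sel], theta).sum(axis=-1)
    se = _se_from_information(info, config.prior.sd)

    spec = config.cutoff
    item_ids = bank.item_ids
    rows = []
    for pid, grp in person_slices:
        history: list[tuple[float, float]] = []
        for ridx, rec in zip(grp.index, grp.itertuples(index=False)):
            day, hour = int(rec.day), float(rec.hour)
            classifiable = is_classifiable(day, hour, spec)
            if spec.kind == "uniform":
                obs_cutoff: float | None = float(spec.uniform_z)
            elif history:
                obs_cutoff = dynamic_cutoff(history, hour, spec)
            else:
                obs_cutoff = None
                classifiable = False
            th, s = float(theta[ridx]), float(se[ridx])
            if classifiable and obs_cutoff is not None:
                obs_class = "above" if th > obs_cutoff else "below"
            else:
                obs_class = None
            rows.append(
                (
                    condition, pid, day, hour, int(rec.week),
                    float(rec.true_theta), float(rec.true_cutoff), rec.true_class,
                    "|".join(item_ids[j] for j in sel[ridx]),
                    "|".join(str(c) for c in cats[ridx]),
                    n_fix, th, s,
                    obs_cutoff if obs_cutoff is not None else np.nan,
                    obs_class, classifiable, "fixed_length",
                )
            )
            history.append((hour, th))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_condition(
    condition: str,
    population: list[PersonProfile],
    schedule: Schedule,
    bank: ItemBank,
    config: StudyConfig,
    truth: pd.DataFrame | None = None,
    responses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Execute one item-selection condition over the whole study.

    Returns one row per prompt with ground truth, the administered items
    and responses, the final estimate, the cutoff applied, and both true
    and observed classifications.  ``truth`` and ``responses`` may be
    passed in so several conditions share identical ground truth.
    """
    if truth is None:
        truth = _truth_table(config, population, schedule)
    if responses is None:
        responses = _shared_responses(config, bank, truth)
    if condition.startswith("fixed"):
        return _run_fixed_batch(
            condition, int(condition[len("fixed"):]), bank, config, truth, responses
        )
    selector_kind, stopping = _condition_setup(condition, config)
    run_in_stopping = StoppingSpec(
        kind="se_threshold", se_threshold=config.run_in_se, max_items=config.max_items
    )
    spec = config.cutoff
    item_ids = bank.item_ids
    cond_idx = CONDITIONS.index(condition)

    rows = []
    for pi, (pid, grp) in enumerate(truth.groupby("person_id", sort=False)):
        rng = _rng_for(config.master_seed, "sessions", cond_idx * 100003 + pi)
        history: list[tuple[float, float]] = []
        prev_theta: float | None = None
        for ridx, rec in zip(grp.index, grp.itertuples(index=False)):
            day, hour = int(rec.day), float(rec.hour)
            classifiable = is_classifiable(day, hour, spec)
            if spec.kind == "uniform":
                obs_cutoff: float | None = float(spec.uniform_z)
            elif history:
                obs_cutoff = dynamic_cutoff(history, hour, spec)
            else:
                obs_cutoff = None
                classifiable = False

            if condition in ("variable", "jita"):
                use_stop = stopping if (classifiable and obs_cutoff is not None) else run_in_stopping
                if condition == "jita":
                    if spec.kind == "uniform":
                        init = prev_theta if prev_theta is not None else config.prior.mean
                    else:
                        init = _cosinor_init(history, hour, config.prior)
                else:
                    init = config.prior.mean
            else:
                use_stop = stopping
                init = config.prior.mean

            session = start_session(
                bank,
                prior=config.prior,
                selector=SelectorSpec(kind=selector_kind, rng_seed=0),
                stopping=use_stop,
                cutoff=obs_cutoff if use_stop.kind == "classification_confidence" else None,
                init_theta=init,
                rng=rng,
            )
            responder = dict(zip(item_ids, responses[ridx]))
            result = run_session(session, responder)
            est = result.estimate
            if classifiable and obs_cutoff is not None:
                obs_class = "above" if est.theta > obs_cutoff else "below"
            else:
                obs_class = None
            rows.append(
                (
                    condition, pid, day, hour, int(rec.week),
                    float(rec.true_theta), float(rec.true_cutoff), rec.true_class,
                    "|".join(result.items),
                    "|".join(str(c) for c in result.responses),
                    est.n_items, est.theta, est.se,
                    obs_cutoff if obs_cutoff is not None else np.nan,
                    obs_class, classifiable, result.stop_reason,
                )
            )
            history.append((hour, est.theta))
            prev_theta = est.theta
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass
class StudyResult:
    """Everything a study run produced, plus provenance for re-runs."""

    records: pd.DataFrame
    bank: ItemBank
    population: list[PersonProfile]
    schedule: Schedule
    truth: pd.DataFrame
    provenance: dict

    def condition(self, name: str) -> pd.DataFrame:
        return self.records[self.records["condition"] == name].reset_index(drop=True)


def run_study(config: StudyConfig, external_truth: pd.DataFrame | None = None) -> StudyResult:
    """Run all configured conditions over one shared synthetic ground truth.

    ``external_truth`` (columns person_id, day, hour, theta) replaces the
    generated true states: the schedule and person list are then taken
    from that table.
    """
    bank = config.resolve_bank()
    if external_truth is not None:
        truth = _truth_from_external(config, external_truth)
        population = []
        schedule = Schedule(
            prompts=[
                (str(r.person_id), int(r.day), float(r.hour))
                for r in truth.itertuples(index=False)
            ],
            compliance=float("nan"),
        )
    else:
        population = generate_population(
            config.n_persons, config.hyper, seed=_seed_for(config.master_seed, "population")
        )
        schedule = generate_schedule(
            config,
            seed=_seed_for(config.master_seed, "schedule"),
            person_ids=[p.person_id for p in population],
        )
        truth = _truth_table(config, population, schedule)
    responses = _shared_responses(config, bank, truth)
    frames = [
        run_condition(cond, population, schedule, bank, config, truth, responses)
        for cond in config.conditions
    ]
    records = pd.concat(frames, ignore_index=True)
    provenance = {
        "master_seed": config.master_seed,
        "conditions": list(config.conditions),
        "n_persons": config.n_persons,
        "n_days": config.n_days,
        "prompts_per_day_range": list(config.prompts_per_day_range),
        "compliance": config.compliance,
        "cutoff": {
            "kind": config.cutoff.kind,
            "uniform_z": config.cutoff.uniform_z,
            "delta_sd": config.cutoff.delta_sd,
            "daytime": list(config.cutoff.daytime),
            "run_in_days": config.cutoff.run_in_days,
        },
        "prior": {"mean": config.prior.mean, "sd": config.prior.sd},
        "max_items": config.max_items,
        "confidence": config.confidence,
        "run_in_se": config.run_in_se,
        "bank": bank.name,
        "n_prompts": int(len(truth)),
        "external_truth": external_truth is not None,
    }
    return StudyResult(
        records=records,
        bank=bank,
        population=population,
        schedule=schedule,
        truth=truth,
        provenance=provenance,
    )
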
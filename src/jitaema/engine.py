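"""Adaptive assessment sessions: item selection, stopping, classification.

One :class:`CATSession` covers a single EMA prompt.  Items are chosen by a
selector (uniform random, maximum Fisher information at the interim
estimate, or maximum expected information), the interim latent-state
estimate is rescored by MAP after every response, and a stopping rule ends
the session:

* ``fixed_length`` — stop after exactly ``fixed_n`` items (conventional EMA);
* ``se_threshold`` — stop once the standard error of measurement drops
  below a threshold (precision-oriented variable length);
* ``classification_confidence`` — stop as soon as the Wald confidence
  interval around the interim estimate excludes the classification cutoff
  (computerized classification testing), or at ``max_items``.

The maximum expected information (MEI) criterion scores a candidate item by
the information it would yield under each possible answer, weighted by the
predictive probability of that answer at the current MAP estimate, with the
hypothetical post-answer estimate recomputed per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .bank import ItemBank
from .irt import (
    BankArrays,
    PriorSpec,
    ThetaEstimate,
    _information_arrays,
    _all_category_terms,
    _map_newton,
    _se_from_information,
)

__all__ = [
    "SelectorSpec",
    "StoppingSpec",
    "CATSession",
    "ClassificationResult",
    "StopDecision",
    "SessionResult",
    "BankExhaustedError",
    "start_session",
    "select_next_item",
    "mei_score",
    "record_response",
    "check_stop",
    "classify",
    "run_session",
]


class BankExhaustedError(RuntimeError):
    """All bank items have been administered in this session."""


@dataclass(frozen=True)
class SelectorSpec:
    """Item-selection rule: ``random``, ``max_info`` or ``mei``."""

    kind: str = "mei"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random", "max_info", "mei"):
            raise ValueError(f"unknown selector kind {self.kind!r}")


@dataclass(frozen=True)
class StoppingSpec:
    """Stopping rule configuration; ``max_items`` always caps the session."""

    kind: str = "classification_confidence"
    max_items: int = 5
    fixed_n: int | None = None
    se_threshold: float | None = None
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_length", "se_threshold", "classification_confidence"):
            raise ValueError(f"unknown stopping kind {self.kind!r}")
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")
        if (self.kind == "fixed_length") != (self.fixed_n is not None):
            raise ValueError("fixed_n is required iff kind == 'fixed_length'")
        if (self.kind == "se_threshold") != (self.se_threshold is not None):
            raise ValueError("se_threshold is required iff kind == 'se_threshold'")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")
        if self.fixed_n is not None and self.fixed_n < 1:
            raise ValueError("fixed_n must be >= 1")


@dataclass(frozen=True)
class ClassificationResult:
    decision: str            # "above" or "below"
    confident: bool
    ci_lo: float
    ci_hi: float


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    reason: str | None = None


@dataclass
class CATSession:
    """State of one adaptive assessment at a single EMA prompt."""

    bank: ItemBank
    prior: PriorSpec
    selector: SelectorSpec
    stopping: StoppingSpec
    cutoff: float | None
    init_theta: float
    administered: list[tuple[str, int]] = field(default_factory=list)
    interim: ThetaEstimate = None  # type: ignore[assignment]
    selection_theta: float = 0.0
    _arrs: BankArrays = None  # type: ignore[assignment]
    _admin_idx: list[int] = field(default_factory=list)
    _rng: np.random.Generator = None  # type: ignore[assignment]

    def remaining_indices(self) -> list[int]:
        used = set(self._admin_idx)
        return [j for j in range(len(self.bank)) if j not in used]


@dataclass(frozen=True)
class SessionResult:
    """Outcome of a completed session at one prompt."""

    items: tuple[str, ...]
    responses: tuple[int, ...]
    estimate: ThetaEstimate
    stop_reason: str
    classification: ClassificationResult | None


def start_session(
    bank: ItemBank,
    prior: PriorSpec = PriorSpec(),
    selector: SelectorSpec = SelectorSpec(),
    stopping: StoppingSpec = StoppingSpec(),
    cutoff: float | None = None,
    init_theta: float | None = None,
    rng: np.random.Generator | None = None,
) -> CATSession:
    """Open a session.

    ``init_theta`` seeds only the *selection* state for the first item (the
    prior-information entry point: the previous prompt's estimate, or a
    diurnal-cycle prediction); the scoring prior is untouched, so with no
    responses the interim estimate is ``(prior.mean, prior.sd)``.
    """
    if len(bank) == 0:
        raise ValueError("item bank is empty")
    if init_theta is None:
        init_theta = prior.mean
    return CATSession(
        bank=bank,
        prior=prior,
        selector=selector,
        stopping=stopping,
        cutoff=cutoff,
        init_theta=float(init_theta),
        interim=ThetaEstimate(theta=prior.mean, se=prior.sd, n_items=0),
        selection_theta=float(init_theta),
        _arrs=BankArrays.cached(bank),
        _rng=rng if rng is not None else np.random.default_rng(selector.rng_seed),
    )


def _argmax_with_ties(scores: np.ndarray, rng: np.random.Generator) -> int:
    top = np.flatnonzero(scores >= scores.max() - 1e-12)
    if len(top) == 1:
        return int(top[0])
    return int(rng.choice(top))


def select_next_item(session: CATSession) -> str:
    """Choose the next unadministered item id per the session's selector."""
    remaining = session.remaining_indices()
    if not remaining:
        raise BankExhaustedError("no unadministered items left in the bank")
    kind = session.selector.kind
    if kind == "random":
        j = int(session._rng.choice(remaining))
    elif kind == "max_info":
        arrs = session._arrs
        info = _information_arrays(
            arrs.a[remaining], arrs.b[remaining], np.asarray(session.selection_theta)
        )
        j = remaining[_argmax_with_ties(info, session._rng)]
    else:  # mei
        scores = _mei_scores(session, remaining)
        j = remaining[_argmax_with_ties(scores, session._rng)]
    return session.bank.items[j].item_id


def _admin_arrays(session: CATSession):
    arrs = session._arrs
    idx = np.asarray(session._admin_idx, dtype=np.int64)
    cats = np.asarray([c for _, c in session.administered], dtype=np.int64)
    return arrs.a[idx], arrs.b[idx], cats


def _mei_scores(session: CATSession, candidates: list[int]) -> np.ndarray:
    """Vectorized MEI for all candidate indices at once.

    Builds one stacked Newton problem per (candidate, category) pair:
    current responses plus the hypothetical answer, solved jointly.
    """
    arrs = session._arrs
    cand = np.asarray(candidates, dtype=np.int64)
    theta_hat = session.interim.theta if session.administered else session.selection_theta

    # predictive category probabilities at the current point estimate
    P_pred, _ = _all_category_terms(arrs.a[cand], arrs.b[cand], np.asarray(float(theta_hat)))
    ncand, ncat = P_pred.shape

    a_r, b_r, cats_r = _admin_arrays(session)
    n_resp = len(cats_r)

    # stacked hypothetical response sets: one row per (candidate, category)
    rows = ncand * ncat
    cand_rep = np.repeat(cand, ncat)
    cat_rep = np.tile(np.arange(1, ncat + 1), ncand)
    a_st = np.concatenate(
        [np.broadcast_to(a_r, (rows, n_resp)), arrs.a[cand_rep, None]], axis=1
    )
    b_st = np.concatenate(
        [np.broadcast_to(b_r, (rows, n_resp, b_r.shape[-1] if n_resp else arrs.b.shape[-1])),
         arrs.b[cand_rep][:, None, :]],
        axis=1,
    )
    cats_st = np.concatenate(
        [np.broadcast_to(cats_r, (rows, n_resp)), cat_rep[:, None]], axis=1
    )
    valid = P_pred.reshape(rows) > 0  # padded categories of shorter items
    theta_k = np.full(rows, float(theta_hat))
    if valid.any():
        theta_k[valid] = _map_newton(
            a_st[valid], b_st[valid], cats_st[valid],
            session.prior.mean, session.prior.sd, theta_k[valid],
        )

    info_k = _information_arrays(
        arrs.a[cand_rep, None], arrs.b[cand_rep][:, None, :], theta_k
    )[:, 0]
    scores = (P_pred.reshape(rows) * info_k).reshape(ncand, ncat).sum(axis=1)
    return scores


def mei_score(session: CATSession, candidate_item_id: str) -> float:
    """Maximum-expected-information score for one candidate item (>= 0)."""
    try:
        j = session._arrs.item_ids.index(candidate_item_id)
    except ValueError:
        raise KeyError(candidate_item_id) from None
    if j in session._admin_idx:
        raise ValueError(f"item {candidate_item_id!r} already administered")
    return float(_mei_scores(session, [j])[0])


def record_response(session: CATSession, item_id: str, category: int) -> CATSession:
    """Append a response and rescore the interim MAP estimate (in place)."""
    try:
        j = session._arrs.item_ids.index(item_id)
    except ValueError:
        raise KeyError(item_id) from None
    if j in session._admin_idx:
        raise ValueError(f"item {item_id!r} already administered in this session")
    item = session.bank.items[j]
    category = int(category)
    if not (1 <= category <= item.n_categories):
        raise ValueError(
            f"category {category} outside 1..{item.n_categories} for item {item_id!r}"
        )
    session._admin_idx.append(j)
    session.administered.append((item_id, category))
    a_r, b_r, cats_r = _admin_arrays(session)
    theta = float(
        _map_newton(
            a_r, b_r, cats_r, session.prior.mean, session.prior.sd,
            np.asarray(session.interim.theta),
        )
    )
    info = float(_information_arrays(a_r, b_r, np.asarray(theta)).sum())
    session.interim = ThetaEstimate(
        theta=theta,
        se=float(_se_from_information(info, session.prior.sd)),
        n_items=len(session.administered),
    )
    session.selection_theta = theta
    return session


@lru_cache(maxsize=32)
def _wald_z(confidence: float) -> float:
    return float(norm.ppf(0.5 * (1.0 + confidence)))


def _wald_interval(theta: float, se: float, confidence: float) -> tuple[float, float]:
    z = _wald_z(confidence)
    return theta - z * se, theta + z * se


def check_stop(session: CATSession) -> StopDecision:
    """Apply the session's stopping rule to the current interim estimate."""
    n = session.interim.n_items
    rule = session.stopping
    if n >= len(session.bank):
        return StopDecision(True, "bank_exhausted")
    if rule.kind == "fixed_length":
        return StopDecision(n >= rule.fixed_n, "fixed_length" if n >= rule.fixed_n else None)
    if n >= rule.max_items:
        return StopDecision(True, "max_items")
    if rule.kind == "se_threshold":
        if session.interim.se < rule.se_threshold:
            return StopDecision(True, "se_threshold")
        return StopDecision(False)
    # classification_confidence
    if session.cutoff is None:
        raise ValueError("classification_confidence stopping requires a cutoff")
    lo, hi = _wald_interval(session.interim.theta, session.interim.se, rule.confidence)
    if session.cutoff < lo or session.cutoff > hi:
        return StopDecision(True, "confidence")
    return StopDecision(False)


def classify(
    estimate: ThetaEstimate, cutoff: float, confidence: float = 0.95
) -> ClassificationResult:
    """Classify an estimate against a cutoff ("above" iff theta > cutoff).

    The decision is forced at the point estimate even when the Wald
    interval straddles the cutoff; ``confident`` records whether the
    interval excludes it.
    """
    lo, hi = _wald_interval(estimate.theta, estimate.se, confidence)
    return ClassificationResult(
        decision="above" if estimate.theta > cutoff else "below",
        confident=bool(cutoff < lo or cutoff > hi),
        ci_lo=float(lo),
        ci_hi=float(hi),
    )


def replay_batch(
    bank: ItemBank,
    response_matrix,
    prior: PriorSpec = PriorSpec(),
    selector: SelectorSpec = SelectorSpec(),
    stopping: StoppingSpec = StoppingSpec(),
    cutoff: float | None = None,
    init_theta: float | None = None,
) -> list[dict]:
    """Replay adaptive sessions against recorded answers, one per row.

    ``response_matrix`` is a mapping/DataFrame-like of rows: each row has a
    ``person_id`` (or index label) and one recorded 1-based category per
    bank item column.  Items the session does not select are simply never
    revealed.  Returns one plain dict per row (JSON-serializable).
    """
    out = []
    for row_id, answers in _iter_response_rows(response_matrix, bank):
        session = start_session(
            bank, prior=prior, selector=selector, stopping=stopping,
            cutoff=cutoff, init_theta=init_theta,
        )
        res = run_session(session, answers)
        rec = {
            "person_id": row_id,
            "items": list(res.items),
            "responses": list(res.responses),
            "theta": res.estimate.theta,
            "se": res.estimate.se,
            "n_items": res.estimate.n_items,
            "stop_reason": res.stop_reason,
        }
        if res.classification is not None:
            rec["decision"] = res.classification.decision
            rec["confident"] = res.classification.confident
        out.append(rec)
    return out


def _iter_response_rows(matrix, bank: ItemBank):
    ids = set(bank.item_ids)
    if hasattr(matrix, "iterrows"):  # DataFrame
        for label, row in matrix.iterrows():
            d = {k: int(v) for k, v in row.items() if k in ids}
            rid = row.get("person_id", label)
            yield rid, d
    else:
        for i, row in enumerate(matrix):
            rid = row.get("person_id", i)
            yield rid, {k: int(v) for k, v in row.items() if k in ids}


def run_session(session: CATSession, responder) -> SessionResult:
    """Drive a session to completion against a response oracle.

    ``responder`` maps item_id -> category (a callable or a mapping).  At
    least one item is always administered; the loop alternates select /
    respond / rescore / stop-check.
    """
    answer = responder.__getitem__ if hasattr(responder, "__getitem__") else responder
    while True:
        item_id = select_next_item(session)
        record_response(session, item_id, answer(item_id))
        decision = check_stop(session)
        if decision.stop:
            break
    classification = (
        classify(session.interim, session.cutoff, session.stopping.confidence)
        if session.cutoff is not None
        else None
    )
    return SessionResult(
        items=tuple(i for i, _ in session.administered),
        responses=tuple(c for _, c in session.administered),
        estimate=session.interim,
        stop_reason=decision.reason,
        classification=classification,
    )
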
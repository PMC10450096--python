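"""Graded response model: probabilities, information, MAP scoring, simulation.

The mathematical substrate for adaptive momentary assessment.  The graded
response model (GRM) gives the probability of choosing ordered category
``k`` of an item with discrimination ``a`` and thresholds ``b_1 < ... <
b_{K-1}`` as

    P(X = k | theta) = P(X >= k | theta) - P(X >= k + 1 | theta),
    P(X >= k | theta) = logistic(a * (theta - b_k)),

with ``P(X >= 1) = 1`` and ``P(X >= K + 1) = 0``.  Latent states are scored
by maximum a posteriori (MAP) estimation under a normal prior; the standard
error of measurement is ``(prior precision + summed item information at the
mode)^(-1/2)``, the standard adaptive-testing convention, which makes the
standard error non-increasing in the number of items administered.

Internally everything is evaluated on stacked numpy arrays (thresholds
right-padded with a large constant so survivor probabilities vanish), which
lets session engines score many hypothetical response patterns in one
vectorized Newton solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bank import Item, ItemBank

__all__ = [
    "PriorSpec",
    "ThetaEstimate",
    "THETA_BOUNDS",
    "category_probabilities",
    "item_information",
    "log_posterior",
    "estimate_map",
    "sample_response",
]

#: Optimization bracket for MAP scoring; the latent metric is z-standardized
#: so values beyond +/-6 are numerically irrelevant.
THETA_BOUNDS = (-6.0, 6.0)

_PAD = 1e8  # threshold padding: survivor prob is exactly 0 there
_TINY = 1e-300


@dataclass(frozen=True)
class PriorSpec:
    """Normal prior for MAP scoring (default standard normal)."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"prior sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class ThetaEstimate:
    """Latent-state estimate: point value, standard error, item count."""

    theta: float
    se: float
    n_items: int
    method: str = "map"

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"se must be > 0, got {self.se}")
        if self.n_items < 0:
            raise ValueError("n_items must be >= 0")


# ---------------------------------------------------------------------------
# Stacked-array internals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BankArrays:
    """Bank parameters as padded arrays for vectorized evaluation."""

    a: np.ndarray          # (m,)
    b: np.ndarray          # (m, C) thresholds, right-padded with _PAD
    k: np.ndarray          # (m,) categories per item
    item_ids: tuple[str, ...]

    @classmethod
    def from_bank(cls, bank: ItemBank) -> "BankArrays":
        m = len(bank)
        c = max(it.n_categories for it in bank) - 1
        a = np.empty(m)
        b = np.full((m, c), _PAD)
        k = np.empty(m, dtype=np.int64)
        for j, it in enumerate(bank):
            a[j] = it.discrimination
            b[j, : it.n_categories - 1] = it.thresholds
            k[j] = it.n_categories
        return cls(a=a, b=b, k=k, item_ids=tuple(bank.item_ids))

    @classmethod
    def from_items(cls, items: list[Item]) -> "BankArrays":
        return cls.from_bank(ItemBank(items=list(items), name="_tmp"))

    @classmethod
    def cached(cls, bank: ItemBank) -> "BankArrays":
        """Arrays for ``bank``, memoized on the bank instance."""
        arrs = bank.__dict__.get("_bank_arrays")
        if arrs is None:
            arrs = cls.from_bank(bank)
            bank.__dict__["_bank_arrays"] = arrs
        return arrs


def _survivor(a: np.ndarray, b: np.ndarray, theta: np.ndarray):
    """Augmented survivor curves P(X>=c) and their complements.

    Returns ``(pf, qf)`` of shape ``(..., n, C + 2)`` where column ``c``
    holds ``P(X >= c)`` for ``c = 0..C+1`` (first column 1, last 0) and
    ``qf = 1 - pf`` computed stably via ``logistic(-z)``.
    """
    z = a[..., :, None] * (theta[..., None, None] - b)
    ps = expit(z)
    qs = expit(-z)
    shape = ps.shape[:-1] + (1,)
    one = np.ones(shape)
    zero = np.zeros(shape)
    pf = np.concatenate([one, ps, zero], axis=-1)
    qf = np.concatenate([zero, qs, one], axis=-1)
    return pf, qf


def _all_category_terms(a: np.ndarray, b: np.ndarray, theta: np.ndarray):
    """Category probabilities and first derivatives for all categories.

    Returns ``(P, dP)`` of shape ``(..., n, C + 1)``; padded categories have
    zero probability and derivative.
    """
    pf, qf = _survivor(a, b, theta)
    # adjacent-difference computed in whichever tail is numerically stable
    P = np.where(
        pf[..., :-1] + pf[..., 1:] > 1.0,
        qf[..., 1:] - qf[..., :-1],
        pf[..., :-1] - pf[..., 1:],
    )
    gf = a[..., :, None] * pf * qf
    dP = gf[..., :-1] - gf[..., 1:]
    return P, dP


def _response_bounds(a, b, cats):
    """Per-response category bounds gathered once per response set.

    For response category ``c`` the probability is ``P(X>=c) - P(X>=c+1)``;
    these survivor curves need thresholds ``b_{c-1}`` and ``b_c`` (with
    virtual thresholds at -inf / +inf for the boundary categories).
    Returns ``(b_up, b_lo)`` of shape ``cats.shape``; gathering them ahead
    of time keeps the Newton iterations purely elementwise.
    """
    pad = np.full(b.shape[:-1] + (1,), _PAD)
    b_aug = np.concatenate([b, pad], axis=-1)
    b_lo = np.take_along_axis(b_aug, (cats - 1)[..., None], -1)[..., 0]
    b_up = np.take_along_axis(b_aug, np.maximum(cats - 2, 0)[..., None], -1)[..., 0]
    b_up = np.where(cats == 1, -_PAD, b_up)
    return b_up, b_lo


def _response_terms_from_bounds(a, b_up, b_lo, theta):
    """P, dP, d2P for observed categories at ``theta`` (all elementwise)."""
    th = theta[..., None]
    zu = a * (th - b_up)
    zl = a * (th - b_lo)
    pu = expit(zu)
    qu = expit(-zu)
    pl = expit(zl)
    ql = expit(-zl)
    # adjacent difference in whichever tail is numerically stable
    P = np.where(pu + pl > 1.0, ql - qu, pu - pl)
    gu = pu * qu
    gl = pl * ql
    dP = a * (gu - gl)
    d2P = a * a * (gu * (qu - pu) - gl * (ql - pl))
    return P, dP, d2P


def _map_newton_bounds(a, b_up, b_lo, mean, sd, theta0):
    """Vectorized safeguarded Newton ascent of the log posterior.

    The posterior is strictly log-concave (GRM likelihood is concave in
    ``theta``; the normal prior caps the Hessian at ``-1/sd^2``), so the
    mode is unique, but raw Newton can still oscillate far from it.  A
    sign-based bracket is maintained per row and any Newton step leaving
    its bracket is replaced by bisection; iterate to |step| < 1e-9.
    """
    inv_var = 1.0 / (sd * sd)
    theta = np.clip(np.asarray(theta0, dtype=float), *THETA_BOUNDS).astype(float).copy()
    lo = np.full_like(theta, THETA_BOUNDS[0])
    hi = np.full_like(theta, THETA_BOUNDS[1])
    for _ in range(120):
        P, dP, d2P = _response_terms_from_bounds(a, b_up, b_lo, theta)
        P = np.maximum(P, _TINY)
        r = dP / P
        grad = r.sum(axis=-1) - (theta - mean) * inv_var
        hess = (d2P / P - r * r).sum(axis=-1) - inv_var
        lo = np.where(grad > 0, np.maximum(lo, theta), lo)
        hi = np.where(grad < 0, np.minimum(hi, theta), hi)
        new = theta - grad / hess
        outside = (new <= lo) | (new >= hi)
        new = np.where(outside, 0.5 * (lo + hi), new)
        moved = np.max(np.abs(new - theta))
        theta = new
        if moved < 1e-9:
            break
    return theta


def _map_newton(a, b, cats, mean, sd, theta0):
    b_up, b_lo = _response_bounds(a, b, cats)
    return _map_newton_bounds(a, b_up, b_lo, mean, sd, theta0)


def _information_arrays(a, b, theta):
    """Per-item Fisher information: shape ``(..., m)``."""
    P, dP = _all_category_terms(a, b, theta)
    return (dP**2 / np.maximum(P, _TINY)).sum(axis=-1)


def _se_from_information(info_sum, prior_sd):
    return 1.0 / np.sqrt(1.0 / prior_sd**2 + info_sum)


# ---------------------------------------------------------------------------
# Public item-level API
# ---------------------------------------------------------------------------


def _item_arrays(item: Item):
    return np.array([item.discrimination]), np.array([item.thresholds])


def category_probabilities(item: Item, theta: float) -> np.ndarray:
    """Probabilities of all ``K`` response categories at ``theta``.

    Entries lie in [0, 1] and sum to 1 (to within 1e-12).
    """
    a, b = _item_arrays(item)
    P, _ = _all_category_terms(a, b, np.asarray(float(theta)))
    return P[0]


def item_information(item: Item, theta) -> float | np.ndarray:
    """GRM Fisher information ``I(theta) = sum_k P'_k(theta)^2 / P_k(theta)``.

    Accepts a scalar or array ``theta``; nonnegative, vanishing as
    ``|theta| -> inf``.
    """
    a, b = _item_arrays(item)
    th = np.asarray(theta, dtype=float)
    out = _information_arrays(a, b, th)[..., 0]
    return float(out) if np.isscalar(theta) or th.ndim == 0 else out


def _validate_responses(responses) -> tuple[list[Item], np.ndarray]:
    items = []
    cats = []
    for item, cat in responses:
        cat = int(cat)
        if not (1 <= cat <= item.n_categories):
            raise ValueError(
                f"item {item.item_id!r}: category {cat} outside 1..{item.n_categories}"
            )
        items.append(item)
        cats.append(cat)
    return items, np.asarray(cats, dtype=np.int64)


def log_posterior(responses, theta: float, prior: PriorSpec = PriorSpec()) -> float:
    """Log posterior of ``theta``: response log likelihood + normal log prior."""
    items, cats = _validate_responses(responses)
    th = np.asarray(float(theta))
    lp = -0.5 * ((theta - prior.mean) / prior.sd) ** 2 - np.log(
        prior.sd * np.sqrt(2 * np.pi)
    )
    if items:
        arrs = BankArrays.from_items(items)
        b_up, b_lo = _response_bounds(arrs.a, arrs.b, cats)
        P, _, _ = _response_terms_from_bounds(arrs.a, b_up, b_lo, th)
        lp += float(np.log(np.maximum(P, _TINY)).sum())
    return float(lp)


def estimate_map(responses, prior: PriorSpec = PriorSpec()) -> ThetaEstimate:
    """MAP estimate of theta with its standard error of measurement.

    With no responses this is the prior: ``(prior.mean, prior.sd)``.  The
    posterior mode is located on the bracket ``THETA_BOUNDS`` to a
    tolerance well below 1e-6; ``se = (1/prior.sd^2 + sum_j I_j(theta))^(-1/2)``.
    """
    items, cats = _validate_responses(responses)
    if not items:
        return ThetaEstimate(theta=prior.mean, se=prior.sd, n_items=0)
    arrs = BankArrays.from_items(items)
    theta = float(_map_newton(arrs.a, arrs.b, cats, prior.mean, prior.sd, prior.mean))
    info = float(_information_arrays(arrs.a, arrs.b, np.asarray(theta)).sum())
    return ThetaEstimate(
        theta=theta,
        se=float(_se_from_information(info, prior.sd)),
        n_items=len(items),
    )


def reliability_from_se(se: float, population_sd: float = 1.0) -> float:
    """Reliability implied by a standard error of measurement.

    On a z-standardized latent metric (population SD 1), an assessment
    with standard error ``se`` has reliability ``1 - se^2 /
    population_sd^2``; e.g. the common SE < 0.3 stopping rule guarantees
    reliability above 0.91.
    """
    return 1.0 - (se / population_sd) ** 2


def sample_response(item: Item, theta: float, rng: np.random.Generator) -> int:
    """Draw a 1-based response category from the GRM at ``theta``."""
    probs = category_probabilities(item, theta)
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(probs), u, side="right"))
    return min(idx, item.n_categories - 1) + 1


def response_from_uniform(item_a: float, item_b: np.ndarray, theta: float, u: float) -> int:
    """Inverse-CDF response draw from a uniform variate (stream-keyed use)."""
    a = np.array([item_a])
    b = np.asarray(item_b, dtype=float)[None, :]
    P, _ = _all_category_terms(a, b, np.asarray(float(theta)))
    idx = int(np.searchsorted(np.cumsum(P[0]), u, side="right"))
    return min(idx, P.shape[-1] - 1) + 1
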
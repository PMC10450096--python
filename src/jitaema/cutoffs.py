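"""Classification cutoffs: uniform and dynamically tailored via cosinor fits.

A uniform cutoff applies one z-value (default 1.0, roughly the 85th
percentile of a standard-normal state distribution) to every person and
moment.  A dynamic cutoff is tailored to the person and time of day: a
cosinor regression

    theta_i = beta0 + beta1 * sin(2*pi/24 * hour_i)
            + beta2 * cos(2*pi/24 * hour_i) + r_i

is fitted by ordinary least squares to all of the person's previously
observed momentary scores, and the cutoff for the current prompt is the
model-predicted level at the current hour plus ``delta_sd`` (default 0.5,
a common minimally-important-difference benchmark) residual standard
deviations.  Early "run-in" days and night-time prompts contribute history
for the fit but are themselves never classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CosinorFit",
    "CutoffSpec",
    "SingularFitError",
    "fit_cosinor",
    "predict_cosinor",
    "dynamic_cutoff",
    "is_classifiable",
]

_OMEGA = 2.0 * np.pi / 24.0


class SingularFitError(ValueError):
    """The cosinor design matrix is rank deficient (too few distinct hours)."""


@dataclass(frozen=True)
class CosinorFit:
    """OLS cosinor coefficients with the residual SD (denominator n - 3)."""

    beta0: float
    beta1: float
    beta2: float
    resid_sd: float
    n_obs: int


@dataclass(frozen=True)
class CutoffSpec:
    """How classification cutoffs are formed and which prompts are gated.

    ``uniform`` applies ``uniform_z`` everywhere.  ``dynamic`` applies a
    person/time-tailored cutoff and restricts classification to daytime
    hours ``[start, end)`` after ``run_in_days`` initial days.
    """

    kind: str = "uniform"
    uniform_z: float = 1.0
    delta_sd: float = 0.5
    daytime: tuple[float, float] = (6.0, 18.0)
    run_in_days: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "dynamic"):
            raise ValueError(f"unknown cutoff kind {self.kind!r}")
        if self.daytime[1] <= self.daytime[0]:
            raise ValueError(f"daytime end must exceed start, got {self.daytime}")
        if self.run_in_days < 0:
            raise ValueError("run_in_days must be >= 0")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")


def _design(hours: np.ndarray) -> np.ndarray:
    ang = _OMEGA * hours
    return np.column_stack([np.ones_like(hours), np.sin(ang), np.cos(ang)])


def fit_cosinor(hours, thetas) -> CosinorFit:
    """OLS fit of the 24-hour cosinor model.

    Requires at least 3 observations at hours in general position; raises
    :class:`SingularFitError` when the design is rank deficient (e.g., only
    two distinct hours).
    """
    hours = np.asarray(hours, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if hours.shape != thetas.shape or hours.ndim != 1:
        raise ValueError("hours and thetas must be equal-length 1-D vectors")
    n = len(hours)
    if n < 3:
        raise ValueError(f"cosinor fit needs n >= 3 observations, got {n}")
    X = _design(hours)
    beta, _, rank, _ = np.linalg.lstsq(X, thetas, rcond=None)
    if rank < 3:
        raise SingularFitError(
            f"cosinor design is rank {rank} < 3 ({len(np.unique(hours))} distinct hours)"
        )
    resid = thetas - X @ beta
    dof = n - 3
    resid_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return CosinorFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        resid_sd=resid_sd,
        n_obs=n,
    )


def predict_cosinor(fit: CosinorFit, hour) -> float | np.ndarray:
    """Model-predicted level at clock ``hour`` (24-periodic)."""
    ang = _OMEGA * np.asarray(hour, dtype=float)
    out = fit.beta0 + fit.beta1 * np.sin(ang) + fit.beta2 * np.cos(ang)
    return float(out) if out.ndim == 0 else out


def dynamic_cutoff(history, current_hour: float, spec: CutoffSpec) -> float:
    """Person/time-tailored cutoff from all previously observed scores.

    ``history`` is a sequence of ``(hour, observed_theta)`` pairs from all
    prompts before the current one (run-in and night-time prompts
    included).  The cutoff is the cosinor prediction at ``current_hour``
    plus ``spec.delta_sd`` residual SDs; with too little history or a
    singular design it falls back to ``mean + delta_sd * SD`` of the
    observed scores.  Order of the history pairs is irrelevant.
    """
    pairs = list(history)
    if not pairs:
        raise ValueError("dynamic_cutoff requires a nonempty history (run-in period)")
    hours = np.asarray([h for h, _ in pairs], dtype=float)
    thetas = np.asarray([t for _, t in pairs], dtype=float)
    if len(pairs) >= 3:
        try:
            fit = fit_cosinor(hours, thetas)
            return float(predict_cosinor(fit, current_hour) + spec.delta_sd * fit.resid_sd)
        except SingularFitError:
            pass
    sd = float(np.std(thetas, ddof=1)) if len(pairs) > 1 else 0.0
    return float(np.mean(thetas) + spec.delta_sd * sd)


def is_classifiable(day: int, hour: float, spec: CutoffSpec) -> bool:
    """Whether a prompt at (day, hour) yields a classification decision.

    Uniform cutoffs classify every prompt.  Dynamic cutoffs classify only
    after the run-in period and within the daytime window, which is
    half-open ``[start, end)``.
    """
    if day < 1:
        raise ValueError("day is 1-based")
    if spec.kind == "uniform":
        return True
    return day > spec.run_in_days and spec.daytime[0] <= hour < spec.daytime[1]
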
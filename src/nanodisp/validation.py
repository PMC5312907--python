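"""External test-set evaluation and the r_m² acceptance metrics.

Roy's r_m² metrics penalise external predictions whose through-origin
regression deviates from the free regression of observed on predicted:

    r_m² = r² · (1 − sqrt(r² − r0²))

with ``r²`` the free squared correlation and ``r0²`` the through-origin
coefficient of determination; the "reverse" variant swaps the roles of the
two axes.  A model is conventionally acceptable when the average of the two
exceeds 0.5 and their absolute difference stays below 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .regression import MLRResults

__all__ = [
    "ValidationReport",
    "Rm2Metrics",
    "external_r2",
    "rm2_metrics",
    "acceptance_check",
    "validate_model",
]


class Rm2Metrics(NamedTuple):
    rm2: float
    rm2_reverse: float
    average: float
    delta: float


@dataclass(frozen=True)
class ValidationReport:
    """External-set statistics with the conventional pass/fail flags."""

    r2_test: float
    rm2: float
    rm2_reverse: float
    rm2_average: float
    rm2_delta: float
    pass_average: bool
    pass_delta: bool


def _check_vectors(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.size} vs {pred.size}")
    if obs.size < 3:
        raise ValueError(f"need >= 3 points, got {obs.size}")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("degenerate (zero-variance) input")
    return obs, pred


def external_r2(model: MLRResults, X, y, kind: str = "pearson") -> float:
    """Squared correlation between observed and predicted on an external set.

    ``kind="pearson"`` (default) is the plain squared Pearson correlation,
    invariant to affine transformation of the predictions.
    ``kind="predictive"`` is ``1 − PRESS_ext / TSS`` with the total sum of
    squares taken about the TRAINING-set mean — the stricter convention,
    shown side by side in the reproduction report.
    """
    obs = np.asarray(y, dtype=float).ravel()
    pred = np.asarray(model.predict(X), dtype=float).ravel()
    if obs.size < 3:
        raise ValueError(f"need >= 3 external rows, got {obs.size}")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("degenerate (zero-variance) observations or predictions")
    if kind == "pearson":
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if kind == "predictive":
        train_mean = float(model.model.endog.mean())
        press_ext = float(((obs - pred) ** 2).sum())
        tss = float(((obs - train_mean) ** 2).sum())
        return 1.0 - press_ext / tss
    raise ValueError(f"unknown kind {kind!r}")


def _r0_squared(x: np.ndarray, y: np.ndarray, variant: str) -> float:
    """Through-origin r0² of y regressed on x."""
    k = float((x * y).sum() / (x * x).sum())
    if variant == "roy":
        # coefficient of determination of the through-origin fit, about the mean
        return 1.0 - float(((y - k * x) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    if variant == "uncentered":
        # squared uncentered correlation
        return float((x @ y) ** 2 / ((x @ x) * (y @ y)))
    raise ValueError(f"unknown r0² variant {variant!r}")


def rm2_metrics(obs, pred, variant: str = "roy") -> Rm2Metrics:
    """Roy's r_m², its axis-swapped reverse, their average and delta.

    ``r² − r0²`` is clipped at zero before the square root, so
    ``r_m² <= r²`` always.  ``variant`` selects the through-origin r0²
    formula: ``"roy"`` (coefficient of determination about the mean, the
    original definition) or ``"uncentered"`` (squared uncentered
    correlation).
    """
    obs, pred = _check_vectors(obs, pred)
    r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)

    def one_direction(x, y):
        r0 = _r0_squared(x, y, variant)
        gap = max(r2 - r0, 0.0)
        return r2 * (1.0 - np.sqrt(gap))

    rm2 = one_direction(pred, obs)  # observed against predicted
    rm2_rev = one_direction(obs, pred)  # predicted against observed
    return Rm2Metrics(
        rm2=float(rm2),
        rm2_reverse=float(rm2_rev),
        average=float((rm2 + rm2_rev) / 2),
        delta=float(abs(rm2 - rm2_rev)),
    )


def acceptance_check(report: ValidationReport) -> tuple[bool, list[str]]:
    """Conventional acceptance: average r_m² > 0.5 and delta r_m² < 0.2."""
    reasons = []
    if not report.pass_average:
        reasons.append(f"average r_m² = {report.rm2_average:.3f} is not > 0.5")
    if not report.pass_delta:
        reasons.append(f"delta r_m² = {report.rm2_delta:.3f} is not < 0.2")
    return (not reasons), reasons


def validate_model(
    model: MLRResults, X_test, y_test, variant: str = "roy"
) -> ValidationReport:
    """Evaluate a fitted model on a held-out set and build the report."""
    obs = np.asarray(y_test, dtype=float).ravel()
    pred = np.asarray(model.predict(X_test), dtype=float).ravel()
    r2_test = external_r2(model, X_test, y_test, kind="pearson")
    m = rm2_metrics(obs, pred, variant=variant)
    return ValidationReport(
        r2_test=r2_test,
        rm2=m.rm2,
        rm2_reverse=m.rm2_reverse,
        rm2_average=m.average,
        rm2_delta=m.delta,
        pass_average=m.average > 0.5,
        pass_delta=m.delta < 0.2,
    )
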
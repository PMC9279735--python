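"""Linear trend forecasting of DP_sum and prediction-accuracy evaluation.

An ordinary-least-squares line through all observed fractions extrapolates a
monitored parameter up to four fractions ahead; the model refuses to predict
from fewer than five observed fractions.  Accuracy over a set of flagged
trajectories is the mean difference between the prediction anchored ``i``
fractions before the threshold-crossing fraction Fx and the value actually
reached at Fx, with a Student-t 95% confidence interval:

    ΔDP_sum[Fx−i] = (1/n) Σ_n ( pDP_sum[Fx−i, n] − DP_sum[Fx, n] ),  i = 4..1

Predictions are reported unclamped (a coverage extrapolation may exceed
100%); clamping would bias the accuracy evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MIN_OBSERVED = 5  # fractions required before the model will extrapolate
HORIZON = 4       # fractions predicted ahead

LOOKAHEADS = (4, 3, 2, 1)


@dataclass
class TrendSeries:
    """Observed DP_sum trajectory with (optional) 4-ahead predictions."""

    observed: np.ndarray                 # DP_sum for fractions 1..k
    structure: str = ""
    metric: str = ""
    predictions: np.ndarray | None = None  # fractions k+1..k+HORIZON
    slope: float | None = None             # per fraction
    intercept: float | None = None
    reason: str | None = None               # set when prediction was refused
    out_of_range: bool = False              # any prediction outside [0, 100] for % metrics

    @property
    def k(self) -> int:
        return len(self.observed)


@dataclass
class PredictionAccuracy:
    """Eq.-style mean prediction error by lookahead, with CI95 half-widths."""

    mean_difference: dict[int, float] = field(default_factory=dict)
    ci95_half_width: dict[int, float] = field(default_factory=dict)
    n: dict[int, int] = field(default_factory=dict)


def fit_predict(
    series: np.ndarray, structure: str = "", metric: str = "",
    percent_metric: bool = False,
) -> TrendSeries:
    """OLS line over fractions 1..k; predictions for k+1..k+4.

    Deterministic; with k < 5 the fit is refused and the returned series
    carries a ``reason`` code instead of predictions.
    """
    observed = np.asarray(series, dtype=float)
    if observed.ndim != 1 or observed.size == 0:
        raise ValueError("series must be a non-empty 1D trajectory")
    k = observed.size
    if k < MIN_OBSERVED:
        return TrendSeries(
            observed=observed, structure=structure, metric=metric,
            reason=f"need >= {MIN_OBSERVED} observed fractions, got {k}",
        )
    fractions = np.arange(1, k + 1, dtype=float)
    slope, intercept = np.polyfit(fractions, observed, 1)
    future = np.arange(k + 1, k + 1 + HORIZON, dtype=float)
    preds = intercept + slope * future
    out_of_range = bool(percent_metric and np.any((preds < 0) | (preds > 100)))
    return TrendSeries(
        observed=observed, structure=structure, metric=metric,
        predictions=preds, slope=float(slope), intercept=float(intercept),
        out_of_range=out_of_range,
    )


def predict_at(series: np.ndarray, target_fraction: int) -> float | None:
    """Prediction of DP_sum at ``target_fraction`` from the fit on ``series``.

    Returns ``None`` when the anchor has too few fractions or the target is
    beyond the 4-fraction horizon.
    """
    observed = np.asarray(series, dtype=float)
    k = observed.size
    if k < MIN_OBSERVED or not (0 < target_fraction - k <= HORIZON):
        return None
    ts = fit_predict(observed)
    assert ts.predictions is not None
    return float(ts.predictions[target_fraction - k - 1])


def eval_accuracy(
    flagged: list[tuple[np.ndarray, int]],
) -> PredictionAccuracy:
    """Prediction accuracy over flagged trajectories.

    ``flagged`` holds ``(trajectory, Fx)`` pairs: the observed DP_sum values
    covering at least fractions 1..Fx and the adaptation-crossing fraction.
    Series with Fx < 5 are excluded (the model cannot have predicted their
    crossing); for each lookahead ``i`` only series whose anchor Fx−i has at
    least five fractions contribute.
    """
    acc = PredictionAccuracy()
    for i in LOOKAHEADS:
        diffs = []
        for trajectory, fx in flagged:
            trajectory = np.asarray(trajectory, dtype=float)
            if fx < MIN_OBSERVED or fx > trajectory.size:
                continue
            anchor = fx - i
            pred = predict_at(trajectory[:anchor], fx) if anchor >= 1 else None
            if pred is None:
                continue
            diffs.append(pred - float(trajectory[fx - 1]))
        if not diffs:
            continue
        d = np.asarray(diffs)
        n = d.size
        acc.mean_difference[i] = float(d.mean())
        acc.n[i] = int(n)
        if n >= 2:
            half = float(
                stats.t.ppf(0.975, n - 1) * d.std(ddof=1) / np.sqrt(n)
            )
        else:
            half = float("nan")
        acc.ci95_half_width[i] = half
    return acc
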
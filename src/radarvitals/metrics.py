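"""Error metrics, percent-reduction summaries, and Kendall tau-b."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import stats

from .exceptions import ShapeError, UndefinedStatisticError


@dataclass
class MetricsReport:
    """MAE / MSE / MRE for one prediction set, plus optional reductions."""

    mae: float
    mse: float
    mre: float
    n: int
    reduction_pct: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"mae": self.mae, "mse": self.mse, "mre": self.mre, "n": self.n}
        if self.reduction_pct:
            out["reduction_pct"] = dict(self.reduction_pct)
        return out


def error_metrics(true, predicted) -> MetricsReport:
    """MAE, MSE and MRE of ``predicted`` against ``true``.

    MAE = mean |y - yhat|; MSE = mean (y - yhat)^2; MRE = mean |y - yhat|/y.
    True values must be nonzero (positive heart rates) for MRE.
    """
    y = np.asarray(true, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ShapeError(f"shape mismatch: true {y.shape} vs predicted {yhat.shape}")
    if y.size == 0:
        raise ShapeError("empty input")
    if np.any(y == 0):
        raise UndefinedStatisticError("MRE undefined: true values contain zero")
    err = y - yhat
    return MetricsReport(
        mae=float(np.mean(np.abs(err))),
        mse=float(np.mean(err**2)),
        mre=float(np.mean(np.abs(err) / np.abs(y))),
        n=int(y.size),
    )


def percent_reduction(before: MetricsReport, after: MetricsReport) -> Dict[str, float]:
    """Percent reduction 100*(before - after)/before per metric, 2 decimals."""
    out = {}
    for name in ("mae", "mse", "mre"):
        b = getattr(before, name)
        a = getattr(after, name)
        if b == 0:
            raise UndefinedStatisticError(f"reduction undefined: before {name} is 0")
        out[name] = round(100.0 * (b - a) / b, 2)
    return out


def kendall_tau_b(a, b) -> float:
    """Kendall tau-b rank correlation with tie correction.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where C/D count concordant and
    discordant pairs, n0 = n(n-1)/2 and n1/n2 are the within-ties pair counts
    of each argument.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ShapeError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("tau-b undefined when one argument is all ties")
    tau = stats.kendalltau(x, y, variant="b").statistic
    if not np.isfinite(tau):
        raise UndefinedStatisticError("tau-b undefined for this input")
    return float(tau)
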
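"""Evaluation metrics: RMSE, MSE, Pearson r, and fold-accuracy.

``F2acc`` / ``F3acc`` are the percentages of predicted rate constants
within two-fold / three-fold of the observed ones (strict symmetric
fold-change, computed in k-space); error metrics for rate constants are
computed in log₁₀ space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "MetricsError", "fkacc", "evaluate"]


class MetricsError(ValueError):
    """Structured error for invalid metric inputs."""


@dataclass
class EvalReport:
    rmse: float
    mse: float
    pearson_r: float
    n: int
    f2acc: float | None = None  # percent
    f3acc: float | None = None  # percent

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mse": self.mse,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "f2acc": self.f2acc,
            "f3acc": self.f3acc,
        }


def fkacc(pred, obs, fold: float) -> float:
    """Percentage of pairs within a symmetric ``fold``-change (strict).

    Both inputs must be positive rate constants (k, not log k).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise MetricsError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise MetricsError("fold accuracy requires strictly positive rate constants")
    ratio = np.maximum(pred / obs, obs / pred)
    return float(100.0 * np.mean(ratio < fold))


def evaluate(pred, obs, label_space: str = "free_energy") -> EvalReport:
    """Standard report for predictions against observations.

    ``label_space="free_energy"`` treats values as ΔG° (kcal/mol);
    ``label_space="log_rate"`` treats them as log₁₀(k): errors stay in
    log space while F2acc/F3acc are computed on 10**logk.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise MetricsError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if pred.size < 2:
        raise MetricsError("need at least 2 pairs")
    mse = float(np.mean((pred - obs) ** 2))
    rmse = float(np.sqrt(mse))
    if np.std(pred) == 0 or np.std(obs) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, obs).statistic)
    report = EvalReport(rmse=rmse, mse=mse, pearson_r=r, n=int(pred.size))
    if label_space == "log_rate":
        report.f2acc = fkacc(10.0**pred, 10.0**obs, 2.0)
        report.f3acc = fkacc(10.0**pred, 10.0**obs, 3.0)
    elif label_space != "free_energy":
        raise MetricsError(f"unknown label space {label_space!r}")
    return report
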
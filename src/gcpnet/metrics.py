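"""Evaluation metrics shared by every task.

Scalar regression reports RMSE plus Pearson, Spearman and Kendall-tau
correlations; vector (position) regression reports MSE over all components
and correlations computed independently per coordinate axis and then
averaged; classification reports accuracy.  A correlation against a
zero-variance series is undefined and reported as ``None`` (never silently
zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass
class MetricsReport:
    n: int
    rmse: float | None = None
    mse: float | None = None
    pearson: float | None = None
    spearman: float | None = None
    kendall_tau: float | None = None
    accuracy: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _corrs(pred: np.ndarray, truth: np.ndarray):
    if pred.std() == 0 or truth.std() == 0:
        return None, None, None
    pearson = float(stats.pearsonr(pred, truth).statistic)
    spearman = float(stats.spearmanr(pred, truth).statistic)
    kendall = float(stats.kendalltau(pred, truth).statistic)
    return pearson, spearman, kendall


def compute_metrics(pred, truth, task: str) -> MetricsReport:
    """Score predictions against ground truth.

    ``task`` is one of ``"scalar"``, ``"vector"`` or ``"classification"``.
    Vector inputs are (n, 3) or (n, m, 3); correlations are computed per
    coordinate axis and averaged, skipping axes where either side is
    constant (if all axes are degenerate the correlation is ``None``).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")

    if task == "classification":
        return MetricsReport(n=len(pred), accuracy=float(np.mean(pred == truth)))

    if task == "scalar":
        pred, truth = pred.ravel(), truth.ravel()
        if len(pred) < 2:
            raise ValueError("correlations need n >= 2")
        mse_val = float(np.mean((pred - truth) ** 2))
        pearson, spearman, kendall = _corrs(pred, truth)
        return MetricsReport(n=len(pred), mse=mse_val, rmse=float(np.sqrt(mse_val)),
                             pearson=pearson, spearman=spearman,
                             kendall_tau=kendall)

    if task == "vector":
        p3 = pred.reshape(-1, 3)
        t3 = truth.reshape(-1, 3)
        if p3.shape[0] < 2:
            raise ValueError("correlations need n >= 2")
        mse_val = float(np.mean((p3 - t3) ** 2))
        per_axis = [_corrs(p3[:, ax], t3[:, ax]) for ax in range(3)]
        means = []
        for idx in range(3):
            vals = [c[idx] for c in per_axis if c[idx] is not None]
            means.append(float(np.mean(vals)) if vals else None)
        return MetricsReport(n=p3.shape[0], mse=mse_val,
                             rmse=float(np.sqrt(mse_val)),
                             pearson=means[0], spearman=means[1],
                             kendall_tau=means[2])

    raise ValueError(f"unknown task {task!r}")
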
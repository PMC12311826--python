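"""Node-level regression metrics: MAPE, MSE, RMSE, MAE and R²."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import EPS_MAPE

__all__ = ["MetricReport", "metrics"]


@dataclass(frozen=True)
class MetricReport:
    mape: float
    mse: float
    rmse: float
    mae: float
    r2: float
    n_eval: int

    def as_dict(self) -> dict:
        return asdict(self)


def metrics(h_true: np.ndarray, h_pred: np.ndarray,
            eps: float = EPS_MAPE) -> MetricReport:
    """Compute all five evaluation metrics over paired vectors.

    MAPE denominators are |h_true| floored at `eps` so exactly-zero
    hesitancy cells stay finite. At least two pairs are required (R² is
    undefined for one).
    """
    y = np.asarray(h_true, dtype=np.float64).ravel()
    yhat = np.asarray(h_pred, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between truth and prediction")
    if y.size < 2:
        raise ValueError("need at least 2 pairs (R² undefined otherwise)")
    err = y - yhat
    mape = float(np.mean(np.abs(err) / np.maximum(np.abs(y), eps)))
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y - y.mean())**2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    return MetricReport(mape=mape, mse=mse, rmse=float(np.sqrt(mse)),
                        mae=mae, r2=r2, n_eval=int(y.size))
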
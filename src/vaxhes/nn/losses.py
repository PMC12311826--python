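"""Training losses shared by the spatial and temporal modules."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["mape_loss", "EPS_MAPE"]

# Floor on |y_true| inside MAPE denominators; hesitancy targets can be
# exactly zero (no refusals in a quarter) and a raw percentage error would
# then be infinite.
EPS_MAPE = 1e-3


def mape_loss(y_true: np.ndarray, y_pred: Tensor, eps: float = EPS_MAPE) -> Tensor:
    """Mean absolute percentage error of predictions vs. constant targets.

    `y_true` is plain data (never differentiated through); `y_pred` is a
    Tensor on the autodiff graph. Denominators are |y_true| floored at eps.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_true.size == 0:
        raise ValueError("MAPE over an empty target set")
    denom = np.maximum(np.abs(y_true), eps)
    return ((y_pred - Tensor(y_true)) / Tensor(denom)).abs().mean()
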
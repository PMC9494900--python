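"""Objective functions over model vs wish distances.

Four selectable losses over the residuals ``r_k = d_model_k - d_wish_k``:

* ``sse``  — sum of squared errors, ``sum r^2`` (the default objective),
* ``mse``  — ``sse / n``,
* ``rmse`` — ``sqrt(mse)``,
* ``huber`` — summed Huber loss, quadratic ``r^2/2`` for ``|r| <= delta`` and
  linear ``delta * (|r| - delta/2)`` beyond the transition point ``delta``.

SSE, MSE and RMSE are monotone transforms of each other for a fixed pair
count, so they rank candidate structures identically; Huber differs by
down-weighting large residuals. All four operate on whatever scale the wish
distances carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossSpec", "LOSS_NAMES", "loss", "batch_loss"]

LOSS_NAMES = ("sse", "mse", "rmse", "huber")


@dataclass(frozen=True)
class LossSpec:
    """Loss selection: name plus the Huber transition point ``huber_delta``."""

    name: str = "sse"
    huber_delta: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; expected one of {LOSS_NAMES}")
        if self.huber_delta <= 0:
            raise ValueError("huber_delta must be positive")


def loss(model_d: np.ndarray, wish_d: np.ndarray, spec: LossSpec) -> float:
    """Evaluate the selected loss on aligned model/wish distance vectors."""
    model_d = np.asarray(model_d, dtype=float)
    wish_d = np.asarray(wish_d, dtype=float)
    if model_d.shape != wish_d.shape:
        raise ValueError(
            f"length mismatch: model {model_d.shape} vs wish {wish_d.shape}"
        )
    if model_d.size == 0:
        raise ValueError("loss undefined for empty distance vectors")
    return float(batch_loss(model_d[None, :], wish_d, spec)[0])


def batch_loss(model_d: np.ndarray, wish_d: np.ndarray, spec: LossSpec) -> np.ndarray:
    """Vectorized loss for a stack of candidates.

    ``model_d`` has shape ``(n_candidates, n_pairs)``; returns one loss per
    candidate. This is the hot path of the swarm update.
    """
    r = model_d - wish_d
    if spec.name == "huber":
        a = np.abs(r)
        d = spec.huber_delta
        per = np.where(a <= d, 0.5 * r * r, d * (a - 0.5 * d))
        return per.sum(axis=-1)
    sse = np.einsum("...i,...i->...", r, r)
    if spec.name == "sse":
        return sse
    mse = sse / r.shape[-1]
    return mse if spec.name == "mse" else np.sqrt(mse)
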
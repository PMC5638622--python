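"""Static transfer functions mapping population activity to firing rate."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["TransferFunction", "sigmoid_transfer", "eval_transfer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh((x - 0.5) / 0.1))


@dataclass(frozen=True)
class TransferFunction:
    """Monotone mapping F from activity to firing rate.

    The default (``kind="sigmoid"``) is F(X) = (1 + tanh((X - 0.5)/0.1))/2,
    a saturating nonlinearity bounded in [0, 1] with F(0.5) = 0.5 exactly.
    A custom callable must be monotone non-decreasing and bounded in
    [0, rmax] on the range where it is evaluated.
    """

    kind: str = "sigmoid"
    func: Callable[[np.ndarray], np.ndarray] = field(default=_sigmoid)
    rmax: float = 1.0

    def __call__(self, x):
        return eval_transfer(self, x)


def sigmoid_transfer() -> TransferFunction:
    """The standard sigmoidal transfer function F(X) = (1 + tanh((X-0.5)/0.1))/2."""
    return TransferFunction(kind="sigmoid", func=_sigmoid, rmax=1.0)


def eval_transfer(tf: TransferFunction, x) -> np.ndarray:
    """Evaluate F element-wise, rejecting non-finite input."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("transfer function input must be finite")
    return tf.func(x)
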
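"""Exact-design Gaussian radial-basis-function (RBF) regression.

Every training sample becomes one hidden unit (center); the hidden
activation for a query p is

    a_i = exp(-(b1 * ||c_i - p||)^2),     b1 = 0.8326 / spread,

so that a unit's activation is exactly 0.5 when the query sits one
``spread`` away from its center (0.8326 ~ sqrt(ln 2)).  The linear output
layer [W b2] is obtained from the training design

    [W b2] . [A; 1] = T

which has Q equations and Q+1 unknowns per output; the minimum-norm
least-squares solution is used, giving exact interpolation of the training
targets whenever the centers are distinct.  There is no iterative training.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

__all__ = ["RBFConfig", "RBFModel", "bias_from_spread", "activations", "fit_exact", "predict"]

logger = logging.getLogger(__name__)

#: Half-activation constant: exp(-(0.8326)^2) = 0.4999…, i.e. sqrt(ln 2) to
#: four decimals.
HALF_ACTIVATION_CONSTANT = 0.8326

#: Pairwise center distance below which two training inputs are reported as
#: duplicates (the design matrix then loses rank).
DUPLICATE_DISTANCE = 1e-12

CONDITION_WARN_THRESHOLD = 1e12


@dataclass(frozen=True)
class RBFConfig:
    """Kernel width: larger ``spread`` means wider, smoother basis functions."""

    spread: float = 0.8

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValueError("spread must be positive")


def bias_from_spread(spread: float) -> float:
    """Kernel bias b1 = 0.8326 / spread (activation 0.5 at distance = spread)."""
    if not spread > 0:
        raise ValueError("spread must be positive")
    return HALF_ACTIVATION_CONSTANT / spread


@dataclass(frozen=True)
class RBFModel:
    """Fitted network: centers (Q x M), kernel bias b1, output layer (W, b2)."""

    centers: np.ndarray
    b1: float
    W: np.ndarray  # (N, Q)
    b2: np.ndarray  # (N,)
    spread: float
    condition_number: float = field(default=float("nan"), compare=False)

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    @property
    def input_dim(self) -> int:
        return self.centers.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "spread": self.spread,
            "b1": self.b1,
            "centers": self.centers.tolist(),
            "W": self.W.tolist(),
            "b2": self.b2.tolist(),
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "RBFModel":
        payload = json.loads(text)
        return cls(
            centers=np.asarray(payload["centers"], dtype=float),
            b1=float(payload["b1"]),
            W=np.asarray(payload["W"], dtype=float),
            b2=np.asarray(payload["b2"], dtype=float),
            spread=float(payload["spread"]),
        )


def _kernel_matrix(centers: np.ndarray, samples: np.ndarray, b1: float) -> np.ndarray:
    """(n_centers x n_samples) Gaussian activations."""
    d = cdist(centers, samples)
    return np.exp(-((b1 * d) ** 2))


def activations(model: RBFModel, sample: np.ndarray) -> np.ndarray:
    """Hidden-layer activations a_i for a single query vector."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (model.input_dim,):
        raise ValueError(f"sample has shape {sample.shape}, expected ({model.input_dim},)")
    return _kernel_matrix(model.centers, sample[None, :], model.b1)[:, 0]


def fit_exact(inputs: np.ndarray, targets: np.ndarray, config: RBFConfig) -> RBFModel:
    """Solve the exact-design system for the output layer.

    ``inputs`` is Q x M (one training sample per row); ``targets`` is a
    length-Q vector or an N x Q matrix.  All training inputs become
    centers.  Near-duplicate inputs (pairwise distance < 1e-12) are
    reported with a warning: the design matrix is then rank-deficient and
    the least-squares solution fits the duplicates in the mean.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[None, :]
    q = inputs.shape[0]
    if q < 1:
        raise ValueError("need at least one training sample")
    if targets.shape[1] != q:
        raise ValueError(f"targets have {targets.shape[1]} columns, expected {q}")
    if not np.all(np.isfinite(inputs)):
        raise ValueError("non-finite training inputs")
    if not np.all(np.isfinite(targets)):
        raise ValueError("non-finite training targets")

    d = cdist(inputs, inputs)
    dup = np.argwhere(np.triu(d < DUPLICATE_DISTANCE, k=1))
    if len(dup):
        i, j = dup[0]
        warnings.warn(
            f"{len(dup)} near-duplicate training input pair(s), e.g. rows {i} and {j}; "
            "the design matrix is rank-deficient and targets are fitted in the "
            "least-squares sense",
            RuntimeWarning,
            stacklevel=2,
        )

    b1 = bias_from_spread(config.spread)
    a = np.exp(-((b1 * d) ** 2))  # Q x Q, symmetric
    design = np.vstack([a, np.ones((1, q))])  # (Q+1) x Q

    cond = float(np.linalg.cond(a))
    if cond > CONDITION_WARN_THRESHOLD:
        logger.warning("RBF design matrix condition number %.3e exceeds %.0e", cond, CONDITION_WARN_THRESHOLD)

    # [W b2] . design = T  <=>  design' x' = T' ; gelsd gives the minimum-norm
    # least-squares solution of the underdetermined system.
    solution, *_ = scipy.linalg.lstsq(design.T, targets.T, lapack_driver="gelsd")
    solution = solution.T  # N x (Q+1)
    return RBFModel(
        centers=inputs.copy(),
        b1=b1,
        W=solution[:, :q],
        b2=solution[:, q],
        spread=config.spread,
        condition_number=cond,
    )


def predict(model: RBFModel, samples: np.ndarray) -> np.ndarray:
    """Network output for each sample row: W a(p) + b2.

    Returns a length-n vector for single-output models, else an n x N
    matrix.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != model.input_dim:
        raise ValueError(f"samples have dimension {samples.shape[1]}, expected {model.input_dim}")
    a = _kernel_matrix(model.centers, samples, model.b1)  # Q x n
    out = model.W @ a + model.b2[:, None]  # N x n
    if out.shape[0] == 1:
        return out[0]
    return out.T
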
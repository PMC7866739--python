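"""General regression neural network (GRNN) core.

A GRNN is a one-pass kernel regressor (Nadaraya–Watson regression with a
Gaussian kernel) organised as four layers: the input layer distributes
the query vector, each pattern neuron ``i`` fires

    p_i = exp(−‖x − x_i‖² / (2σ²)),

the summation layer forms the simple sum ``S_s = Σ p_i`` and the
weighted sum ``S_w = Σ w_i p_i`` (with ``w_i`` the training target of
pattern ``i``), and the output layer returns ``Y = S_w / S_s``.  The
prediction is therefore a convex combination of the training targets and
always lies within their range.  The smoothing parameter σ — the kernel
bandwidth, shared across dimensions — is the network's only free
parameter: σ → 0 recovers nearest-neighbour interpolation, σ → ∞ the
target mean.

Fitting is storage only (a lazy learner); distances are meant to be
computed on standardized inputs, so a model can carry references to the
input scaling and the response transform used upstream to allow
predictions on the original units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import BoxCoxState, ScalingState

__all__ = ["GRNNModel", "grnn_fit", "grnn_predict"]

# exp underflows to 0 below roughly -745; beyond that every raw pattern
# activation is numerically zero and the stabilized prediction degrades
# to the nearest pattern's target
_UNDERFLOW_EXPONENT = -745.0


@dataclass
class GRNNModel:
    """Stored training patterns, targets and bandwidth.

    Attributes
    ----------
    X : ndarray, shape (n, d)
        Training patterns on the standardized input scale.
    w : ndarray, shape (n,)
        Pattern-neuron interconnection weights, i.e. the training
        targets (possibly on a transformed response scale).
    sigma : float
        Smoothing parameter σ > 0.
    scaling, transform :
        Optional preprocessing states recorded for provenance; the
        pipeline layer uses them to map raw inputs and to invert the
        response transform.
    """

    X: np.ndarray
    w: np.ndarray
    sigma: float
    scaling: "ScalingState | None" = None
    transform: "BoxCoxState | None" = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.X.shape[0] != self.w.shape[0]:
            raise ValueError("X and w must have the same number of rows")
        if self.X.shape[0] < 1:
            raise ValueError("at least one training pattern is required")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite values in training data")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def predict(self, query: np.ndarray) -> np.ndarray | float:
        return grnn_predict(self, query)

    def to_dict(self) -> dict:
        d = {
            "X": self.X.tolist(),
            "w": self.w.tolist(),
            "sigma": self.sigma,
        }
        if self.scaling is not None:
            d["scaling"] = self.scaling.to_dict()
        if self.transform is not None:
            d["transform"] = self.transform.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GRNNModel":
        from .preprocess import BoxCoxState, ScalingState

        return cls(
            X=np.asarray(d["X"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            sigma=float(d["sigma"]),
            scaling=ScalingState.from_dict(d["scaling"]) if "scaling" in d else None,
            transform=BoxCoxState.from_dict(d["transform"])
            if "transform" in d
            else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GRNNModel":
        return cls.from_dict(json.loads(s))


def grnn_fit(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float,
    scaling: "ScalingState | None" = None,
    transform: "BoxCoxState | None" = None,
) -> GRNNModel:
    """Store the training set as a GRNN (lazy learner; no optimization)."""
    return GRNNModel(X=X, w=y, sigma=sigma, scaling=scaling, transform=transform)


def grnn_predict(model: GRNNModel, query: np.ndarray) -> np.ndarray | float:
    """Evaluate the network at one query vector or a batch of them.

    Pattern activations are normalized after subtracting the largest
    exponent (log-sum-exp style), so the convex-combination output is
    computed stably even for tiny σ.  If every raw activation underflows
    — the query is far from all patterns at a small bandwidth — the
    stabilized result equals the nearest pattern's target and a warning
    is emitted.

    Returns a scalar for a single query vector, else an array of
    predictions.
    """
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != model.n_features:
        raise ValueError(
            f"query has {q.shape[1]} features, model expects {model.n_features}"
        )
    d2 = cdist(q, model.X, metric="sqeuclidean")
    expo = -d2 / (2.0 * model.sigma**2)
    emax = expo.max(axis=1, keepdims=True)
    if np.any(emax < _UNDERFLOW_EXPONENT):
        warnings.warn(
            "all pattern activations underflow for some queries; "
            "falling back to the nearest pattern's target",
            RuntimeWarning,
            stacklevel=2,
        )
    p = np.exp(expo - emax)
    s_simple = p.sum(axis=1)
    s_weighted = p @ model.w
    out = s_weighted / s_simple
    return float(out[0]) if single else out
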
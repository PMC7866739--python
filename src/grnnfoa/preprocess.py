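"""Response normalization, outlier screening, input scaling and CV plans.

Responses are normalized with a Box-Cox power transform (maximum
likelihood λ on a bounded interval, with an automatic positive shift for
non-positive data).  Inputs are design variables on meaningful physical
scales, so they are only standardized (zero mean, unit variance on the
training statistics) — the Gaussian pattern distance of the regressor is
scale-sensitive.  Outliers are screened with a PCA score distance; the
screen is advisory (it reports indices, dropping is the caller's call).
Model assessment uses repeated k-fold cross-validation plans that are
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from sklearn.model_selection import RepeatedKFold

__all__ = [
    "BoxCoxState",
    "ScalingState",
    "CVPlan",
    "boxcox_fit",
    "boxcox_apply",
    "boxcox_invert",
    "pca_outliers",
    "make_cv_plan",
]


@dataclass
class BoxCoxState:
    """Fitted power parameter and additive shift for one response.

    The transform is ``((y + shift)**lam − 1) / lam`` (natural log at
    λ = 0); the shift makes all values strictly positive before the
    power is applied.
    """

    lam: float
    shift: float = 0.0

    def to_dict(self) -> dict:
        return {"lam": self.lam, "shift": self.shift}

    @classmethod
    def from_dict(cls, d: dict) -> "BoxCoxState":
        return cls(lam=float(d["lam"]), shift=float(d["shift"]))


def boxcox_fit(values: np.ndarray, lam_bounds: tuple[float, float] = (-5.0, 5.0)) -> BoxCoxState:
    """Fit λ by profile maximum likelihood on ``lam_bounds``.

    A shift of ``1 − min(values)`` is applied first when the minimum is
    non-positive.  Raises for fewer than 3 distinct values (the
    likelihood carries no information about λ).
    """
    v = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    if np.unique(v).size < 3:
        raise ValueError("need at least 3 distinct values to fit lambda")
    shift = 1.0 - v.min() if v.min() <= 0 else 0.0
    shifted = v + shift
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, shifted),
        bounds=lam_bounds,
        method="bounded",
    )
    return BoxCoxState(lam=float(res.x), shift=float(shift))


def boxcox_apply(state: BoxCoxState, values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float) + state.shift
    if np.any(v <= 0):
        raise ValueError("values must exceed -shift for the Box-Cox transform")
    return special.boxcox(v, state.lam)


def boxcox_invert(state: BoxCoxState, values: np.ndarray) -> np.ndarray:
    """Inverse transform; errors on values outside the transform range."""
    t = np.asarray(values, dtype=float)
    if state.lam != 0.0 and np.any(state.lam * t + 1.0 <= 0):
        raise ValueError("values outside the range of the Box-Cox transform")
    return special.inv_boxcox(t, state.lam) - state.shift


@dataclass
class ScalingState:
    """Per-column mean and standard deviation from the training subset."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if np.any(self.sd <= 0):
            raise ValueError("standard deviation must be > 0 for every column")

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalingState":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0))

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def invert(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean

    def drop(self, index: int) -> "ScalingState":
        keep = np.arange(self.mean.size) != index
        return ScalingState(mean=self.mean[keep], sd=self.sd[keep])

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingState":
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]))


def pca_outliers(
    table: np.ndarray, var_frac: float = 0.95, alpha: float = 0.05
) -> np.ndarray:
    """Flag rows with an extreme PCA score distance.

    Columns are standardized, a PCA is taken, and each row's squared
    score distance is computed over the leading components that cover
    ``var_frac`` of the variance (scores divided by the component
    standard deviations), i.e. a Mahalanobis distance in the retained
    subspace.  Under approximate normality that statistic is chi-square
    with q degrees of freedom, so a row is flagged when it exceeds the
    ``1 − alpha/n`` quantile — a family-wise cutoff under which a clean
    dataset is expected to produce no flags.  Returns flagged row
    indices.
    """
    X = np.atleast_2d(np.asarray(table, dtype=float))
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows to screen for outliers")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0  # constant columns carry no outlier information
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, _vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    q = int(np.searchsorted(frac, var_frac) + 1)
    # u * s are the scores; dividing by s normalizes each retained
    # component to unit variance
    d2 = (u[:, :q] ** 2).sum(axis=1) * n
    cutoff = stats.chi2.ppf(1.0 - alpha / n, df=q)
    return np.flatnonzero(d2 > cutoff)


@dataclass
class CVPlan:
    """Row-to-fold assignments for repeated k-fold cross-validation.

    ``assignments[r, i]`` is the fold index of row ``i`` in repeat
    ``r``; each row appears in exactly one test fold per repeat and fold
    sizes differ by at most one.
    """

    k: int
    repeats: int
    seed: int | None
    assignments: np.ndarray  # (repeats, n) int fold indices

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def split(self):
        """Yield (repeat, fold, train_idx, test_idx) for all 50-style splits."""
        for r in range(self.repeats):
            for f in range(self.k):
                test = np.flatnonzero(self.assignments[r] == f)
                train = np.flatnonzero(self.assignments[r] != f)
                yield r, f, train, test

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "assignments": self.assignments.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVPlan":
        return cls(
            k=int(d["k"]),
            repeats=int(d["repeats"]),
            seed=d["seed"],
            assignments=np.asarray(d["assignments"], dtype=int),
        )


def make_cv_plan(n: int, k: int = 5, repeats: int = 10, seed: int | None = 0) -> CVPlan:
    """Build a repeated k-fold plan (deterministic under ``seed``)."""
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rkf = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    assignments = np.empty((repeats, n), dtype=int)
    for s, (_train, test) in enumerate(rkf.split(np.empty((n, 1)))):
        r, f = divmod(s, k)
        assignments[r, test] = f
    return CVPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)
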
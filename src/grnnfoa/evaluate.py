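"""Model metrics, bandwidth tuning and the GRNN-FOA training pipeline.

The fit of each response model is judged by three criteria on the
original response units:

    RMSE = sqrt(mean((y_est − y_act)²))
    MBE  = mean(y_est − y_act)
    R²   = 1 − SSE / SST

The smoothing parameter σ is tuned per response by running the fruit-fly
optimizer on the negative mean cross-validated RMSE over a repeated
k-fold plan (5 folds × 10 repeats by default), and the tuned σ is then
held fixed while the 50 per-split training/testing metrics are
collected.  The deployment model is refit on all rows.

Implementation note: because the GRNN is a lazy learner over a fixed row
set, the full pairwise squared-distance matrix is computed once and all
fold fits and bandwidth evaluations reuse it, which keeps the repeated
tuning loops fast.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import __version__
from .foa import FOAConfig, foa_maximize
from .grnn import GRNNModel, grnn_fit
from .io import INPUT_COLUMNS, RESPONSE_COLUMNS, validate_dataset
from .preprocess import (
    BoxCoxState,
    CVPlan,
    ScalingState,
    boxcox_apply,
    boxcox_fit,
    boxcox_invert,
    make_cv_plan,
)

__all__ = [
    "compute_metrics",
    "tune_sigma_foa",
    "fit_pipeline",
    "evaluate_pipeline",
    "FittedPipeline",
    "PipelineConfig",
]


def compute_metrics(y_act: np.ndarray, y_est: np.ndarray) -> dict[str, float]:
    """RMSE, MBE and R² of predictions against actual values.

    Raises when the actual values have zero variance (R² undefined) or
    the arrays have mismatched lengths or fewer than 2 entries.
    """
    y_act = np.asarray(y_act, dtype=float).ravel()
    y_est = np.asarray(y_est, dtype=float).ravel()
    if y_act.shape != y_est.shape or y_act.size < 2:
        raise ValueError("need two equal-length arrays with at least 2 values")
    sst = float(np.sum((y_act - y_act.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("zero variance in actual values; R^2 undefined")
    resid = y_est - y_act
    sse = float(np.sum(resid**2))
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mbe": float(np.mean(resid)),
        "r2": 1.0 - sse / sst,
    }


class _CVObjective:
    """Mean cross-validated RMSE as a function of σ over a fixed plan.

    Predictions are made on the transformed response scale and inverted
    before the residuals are taken, so the objective is in original
    units.  The pairwise distance matrix is shared across σ values.
    """

    def __init__(
        self,
        Xs: np.ndarray,
        y: np.ndarray,
        plan: CVPlan,
        transform: BoxCoxState | None,
    ) -> None:
        self.d2 = cdist(Xs, Xs, metric="sqeuclidean")
        self.y = np.asarray(y, dtype=float)
        self.yt = boxcox_apply(transform, y) if transform is not None else self.y
        self.transform = transform
        self.splits = [(tr, te) for _r, _f, tr, te in plan.split()]
        for _tr, te in self.splits:
            if te.size == 0:
                raise ValueError("degenerate fold with no test rows")

    def fold_predictions(self, sigma: float, fold_sigmas: list[float] | None = None):
        """Yield (train_idx, test_idx, in-fold preds, held-out preds).

        ``fold_sigmas`` overrides σ per split (per-fold retuning).
        """
        for s_idx, (tr, te) in enumerate(self.splits):
            s = fold_sigmas[s_idx] if fold_sigmas is not None else sigma
            expo = -self.d2 / (2.0 * s**2)
            sub_te = expo[np.ix_(te, tr)]
            p = np.exp(sub_te - sub_te.max(axis=1, keepdims=True))
            pred_te = (p @ self.yt[tr]) / p.sum(axis=1)
            sub_tr = expo[np.ix_(tr, tr)]
            p = np.exp(sub_tr - sub_tr.max(axis=1, keepdims=True))
            pred_tr = (p @ self.yt[tr]) / p.sum(axis=1)
            if self.transform is not None:
                pred_te = boxcox_invert(self.transform, pred_te)
                pred_tr = boxcox_invert(self.transform, pred_tr)
            yield tr, te, pred_tr, pred_te

    def mean_rmse(self, sigma: float) -> float:
        expo = -self.d2 / (2.0 * sigma**2)
        total = 0.0
        for tr, te in self.splits:
            sub = expo[np.ix_(te, tr)]
            p = np.exp(sub - sub.max(axis=1, keepdims=True))
            pred = (p @ self.yt[tr]) / p.sum(axis=1)
            if self.transform is not None:
                pred = boxcox_invert(self.transform, pred)
            total += float(np.sqrt(np.mean((pred - self.y[te]) ** 2)))
        return total / len(self.splits)


def tune_sigma_foa(
    Xs: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    foa_config: FOAConfig | None = None,
    sigma_bounds: tuple[float, float] = (1e-3, 10.0),
    transform: BoxCoxState | None = None,
) -> float:
    """Choose σ by FOA-maximizing the negative mean CV RMSE.

    ``Xs`` are standardized inputs; ``y`` the original-scale targets
    (transformed internally when ``transform`` is given).  Deterministic
    under the FOA config's seed.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    if Xs.shape[0] < 2 * plan.k:
        raise ValueError("need at least 2k training rows to tune sigma")
    obj = _CVObjective(Xs, y, plan, transform)
    cfg = foa_config or FOAConfig()
    result = foa_maximize(
        lambda c: -obj.mean_rmse(float(c[0])), [sigma_bounds], cfg
    )
    return float(result.x[0])


@dataclass
class PipelineConfig:
    """Everything needed to re-run a fit bit-for-bit."""

    cv_k: int = 5
    cv_repeats: int = 10
    seed: int = 0
    sigma_bounds: tuple[float, float] = (1e-3, 10.0)
    boxcox: bool = True
    foa_sizepop: int = 10
    foa_maxgen: int = 100
    retune_per_fold: bool = False

    def foa_config(self, seed: int) -> FOAConfig:
        return FOAConfig(sizepop=self.foa_sizepop, maxgen=self.foa_maxgen, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_bounds"] = list(self.sigma_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["sigma_bounds"] = tuple(d.get("sigma_bounds", (1e-3, 10.0)))
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FittedPipeline:
    """Per-response GRNN models plus the shared preprocessing state."""

    inputs: list[str]
    responses: list[str]
    scaling: ScalingState
    transforms: dict[str, BoxCoxState | None]
    sigmas: dict[str, float]
    models: dict[str, GRNNModel]
    plan: CVPlan
    config: PipelineConfig
    metrics: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def predict(self, response: str, X: np.ndarray | pd.DataFrame) -> np.ndarray | float:
        """Predict one response on the original units from raw inputs."""
        if response not in self.models:
            raise KeyError(f"no fitted model for response {response!r}")
        if isinstance(X, pd.DataFrame):
            X = X[self.inputs].to_numpy()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        pred = self.models[response].predict(self.scaling.apply(np.atleast_2d(X)))
        pred = np.atleast_1d(pred)
        tf = self.transforms.get(response)
        if tf is not None:
            pred = boxcox_invert(tf, pred)
        return float(pred[0]) if single else pred

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "responses": self.responses,
            "scaling": self.scaling.to_dict(),
            "transforms": {
                k: (v.to_dict() if v is not None else None)
                for k, v in self.transforms.items()
            },
            "sigmas": self.sigmas,
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "plan": self.plan.to_dict(),
            "config": self.config.to_dict(),
            "metrics": self.metrics.to_dict(orient="list")
            if self.metrics is not None
            else None,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedPipeline":
        return cls(
            inputs=list(d["inputs"]),
            responses=list(d["responses"]),
            scaling=ScalingState.from_dict(d["scaling"]),
            transforms={
                k: (BoxCoxState.from_dict(v) if v is not None else None)
                for k, v in d["transforms"].items()
            },
            sigmas={k: float(v) for k, v in d["sigmas"].items()},
            models={k: GRNNModel.from_dict(v) for k, v in d["models"].items()},
            plan=CVPlan.from_dict(d["plan"]),
            config=PipelineConfig.from_dict(d["config"]),
            metrics=pd.DataFrame(d["metrics"]) if d["metrics"] is not None else None,
            provenance=dict(d.get("provenance", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FittedPipeline":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _response_seed(base_seed: int, response: str) -> int:
    # stable per-response sub-seed, kept below 2**31
    digest = hashlib.sha256(f"{base_seed}:{response}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def fit_pipeline(
    dataset: pd.DataFrame,
    config: PipelineConfig | None = None,
    responses: list[str] | None = None,
) -> FittedPipeline:
    """Normalize, standardize, tune σ per response and refit on all rows.

    Like :func:`evaluate_pipeline` but without collecting the repeated
    cross-validation metrics.
    """
    return _run_pipeline(dataset, config, responses, with_metrics=False)


def evaluate_pipeline(
    dataset: pd.DataFrame,
    config: PipelineConfig | None = None,
    responses: list[str] | None = None,
) -> FittedPipeline:
    """Full model development: Box-Cox → standardize → FOA-tuned σ →
    repeated k-fold training/testing metrics → deployment refit.

    The metrics table has one row per (response, subset) with the mean
    and standard deviation of each criterion over all (repeat, fold)
    splits, on the original response units.
    """
    return _run_pipeline(dataset, config, responses, with_metrics=True)


def _run_pipeline(
    dataset: pd.DataFrame,
    config: PipelineConfig | None,
    responses: list[str] | None,
    with_metrics: bool,
) -> FittedPipeline:
    cfg = config or PipelineConfig()
    responses = list(responses) if responses is not None else list(RESPONSE_COLUMNS)
    df = validate_dataset(dataset)
    X = df[INPUT_COLUMNS].to_numpy()
    scaling = ScalingState.fit(X)
    Xs = scaling.apply(X)
    plan = make_cv_plan(len(df), k=cfg.cv_k, repeats=cfg.cv_repeats, seed=cfg.seed)

    transforms: dict[str, BoxCoxState | None] = {}
    sigmas: dict[str, float] = {}
    models: dict[str, GRNNModel] = {}
    records: list[dict] = []

    for resp in responses:
        y = df[resp].to_numpy()
        tf = boxcox_fit(y) if cfg.boxcox else None
        transforms[resp] = tf
        obj = _CVObjective(Xs, y, plan, tf)
        foa_cfg = cfg.foa_config(_response_seed(cfg.seed, resp))
        res = foa_maximize(
            lambda c: -obj.mean_rmse(float(c[0])), [cfg.sigma_bounds], foa_cfg
        )
        sigma = float(res.x[0])
        sigmas[resp] = sigma
        yt = boxcox_apply(tf, y) if tf is not None else y
        models[resp] = grnn_fit(Xs, yt, sigma, scaling=scaling, transform=tf)

        if with_metrics:
            fold_sigmas = None
            if cfg.retune_per_fold:
                fold_sigmas = []
                for s_idx, (tr, _te) in enumerate(obj.splits):
                    inner_plan = make_cv_plan(
                        tr.size, k=cfg.cv_k, repeats=1, seed=cfg.seed
                    )
                    inner = _CVObjective(Xs[tr], y[tr], inner_plan, tf)
                    inner_res = foa_maximize(
                        lambda c: -inner.mean_rmse(float(c[0])),
                        [cfg.sigma_bounds],
                        cfg.foa_config(_response_seed(cfg.seed, f"{resp}:{s_idx}")),
                    )
                    fold_sigmas.append(float(inner_res.x[0]))
            per_split = {"training": [], "testing": []}
            for s_idx, (tr, te, pred_tr, pred_te) in enumerate(
                obj.fold_predictions(sigma, fold_sigmas)
            ):
                per_split["training"].append(compute_metrics(y[tr], pred_tr))
                per_split["testing"].append(compute_metrics(y[te], pred_te))
            for subset, rows in per_split.items():
                agg = pd.DataFrame(rows)
                rec = {"response": resp, "subset": subset, "sigma": sigma}
                for m in ("r2", "rmse", "mbe"):
                    rec[m] = float(agg[m].mean())
                    rec[f"{m}_sd"] = float(agg[m].std(ddof=1))
                records.append(rec)

    metrics = pd.DataFrame(records) if with_metrics else None
    provenance = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_rows": int(len(df)),
        "version": __version__,
    }
    return FittedPipeline(
        inputs=list(INPUT_COLUMNS),
        responses=responses,
        scaling=scaling,
        transforms=transforms,
        sigmas=sigmas,
        models=models,
        plan=plan,
        config=cfg,
        metrics=metrics,
        provenance=provenance,
    )
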
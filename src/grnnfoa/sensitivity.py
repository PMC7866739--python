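"""Leave-one-covariate-out variable importance (VSE / VSR).

The variable sensitivity error (VSE) of an input is the RMSE of the
model retrained without that input, evaluated over the entire dataset
(training and testing rows pooled); the variable sensitivity ratio
(VSR) divides it by the full model's RMSE.  A higher VSR means the
model loses more accuracy without the input, i.e. the input matters
more.  For readability the VSRs are additionally min-max rescaled to
[0, 1] within each response; rescaling is monotone, so the ranking by
rescaled values equals the ranking by raw VSR.

"Unavailable" is implemented as retraining without the column, not as
mean substitution: the GRNN is a lazy learner, so retraining is cheap,
and the reduced model's bandwidth is retuned with the same seeded
procedure as the full model (set ``retune_sigma=False`` to keep the
full model's σ instead).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import FittedPipeline, _CVObjective, _response_seed, compute_metrics
from .foa import foa_maximize
from .io import INPUT_COLUMNS, validate_dataset

__all__ = ["sensitivity_analysis"]


def sensitivity_analysis(
    pipeline: FittedPipeline,
    dataset: pd.DataFrame,
    responses: list[str] | None = None,
    retune_sigma: bool = True,
) -> pd.DataFrame:
    """VSE, VSR, rescaled VSR and rank per (response, input).

    The report is sorted by response (pipeline order) and rank; rank 1
    is the most important input.
    """
    if len(pipeline.inputs) < 2:
        raise ValueError("sensitivity analysis needs at least 2 inputs")
    df = validate_dataset(dataset)
    responses = list(responses) if responses is not None else list(pipeline.responses)
    X = df[INPUT_COLUMNS].to_numpy()
    Xs = pipeline.scaling.apply(X)
    cfg = pipeline.config

    records = []
    for resp in responses:
        y = df[resp].to_numpy()
        full_pred = np.atleast_1d(pipeline.predict(resp, X))
        rmse_full = compute_metrics(y, full_pred)["rmse"]
        tf = pipeline.transforms.get(resp)

        vses = []
        for j, _input in enumerate(pipeline.inputs):
            keep = np.arange(len(pipeline.inputs)) != j
            Xr = Xs[:, keep]
            if retune_sigma:
                obj = _CVObjective(Xr, y, pipeline.plan, tf)
                res = foa_maximize(
                    lambda c: -obj.mean_rmse(float(c[0])),
                    [cfg.sigma_bounds],
                    cfg.foa_config(_response_seed(cfg.seed, resp)),
                )
                sigma = float(res.x[0])
                d2 = obj.d2
                yt = obj.yt
            else:
                sigma = pipeline.sigmas[resp]
                obj = _CVObjective(Xr, y, pipeline.plan, tf)
                d2 = obj.d2
                yt = obj.yt
            # reduced model refit on all rows, evaluated on all rows
            expo = -d2 / (2.0 * sigma**2)
            p = np.exp(expo - expo.max(axis=1, keepdims=True))
            pred = (p @ yt) / p.sum(axis=1)
            if tf is not None:
                from .preprocess import boxcox_invert

                pred = boxcox_invert(tf, pred)
            vses.append(compute_metrics(y, pred)["rmse"])

        vses = np.asarray(vses)
        vsr = vses / rmse_full
        span = vsr.max() - vsr.min()
        rescaled = (vsr - vsr.min()) / span if span > 0 else np.zeros_like(vsr)
        # rank 1 = highest VSR; ties broken by input order
        order = np.argsort(-vsr, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        for j, name in enumerate(pipeline.inputs):
            records.append(
                {
                    "response": resp,
                    "input": name,
                    "vse": float(vses[j]),
                    "vsr": float(vsr[j]),
                    "rescaled": float(rescaled[j]),
                    "rank": int(rank[j]),
                }
            )
    return pd.DataFrame(records)
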
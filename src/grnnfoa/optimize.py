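"""Culture-input optimization over the trained response models.

Each response model defines a predicted surface over the culture-input
box (CE %, CF %, elicitor adding day, harvest day).  The optimizers
maximize that surface subject to the feasibility constraint that the
harvest must come after elicitation; infeasible candidates receive −∞
fitness.  Because the GRNN prediction is a convex combination of the
training targets, the reported optimum can never exceed the largest
observed training response.

Besides the optimal input vector, the report carries the derived
quantities the bioprocess literature communicates: total elicitor dose
(ce + cf, % v/v), the CE:CF ratio as whole percentages, and the
exposure time in hours post-elicitation, (harvest − adding) × 24.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .evaluate import FittedPipeline, _response_seed
from .foa import FOAConfig, foa_maximize
from .ga import GAConfig, ga_maximize
from .io import INPUT_COLUMNS
from .synthetic import DEFAULT_BOUNDS

__all__ = ["OptimizationProblem", "optimize_response", "derived_quantities"]


@dataclass
class OptimizationProblem:
    """One response to maximize over a bounded culture-input box."""

    response: str
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    optimizer: str = "both"  # "foa" | "ga" | "both"
    seed: int = 0
    foa: FOAConfig | None = None
    ga: GAConfig | None = None
    # a GRNN extrapolates as a plateau at the nearest pattern's value, so
    # by default the search is confined to the training data's convex
    # hull, where the model's maximum is actually determined by data
    allow_extrapolation: bool = False

    def validate(self) -> None:
        if self.optimizer not in ("foa", "ga", "both"):
            raise ValueError("optimizer must be 'foa', 'ga' or 'both'")
        missing = [c for c in INPUT_COLUMNS if c not in self.bounds]
        if missing:
            raise ValueError(f"bounds missing for input(s): {', '.join(missing)}")
        lo_h, hi_h = self.bounds["harvest_day"]
        lo_a, _hi_a = self.bounds["adding_day"]
        if hi_h <= lo_a:
            raise ValueError("feasible box is empty: no harvest after adding day")


def derived_quantities(
    ce: float, cf: float, adding_day: float, harvest_day: float
) -> dict[str, object]:
    """Dose, CE:CF ratio and exposure hours for an optimal input vector."""
    dose = ce + cf
    if dose > 0:
        r_ce = round(100.0 * ce / dose)
        ratio = f"{r_ce}:{100 - r_ce}"
    else:
        ratio = None
    return {
        "dose_pct": dose,
        "ratio": ratio,
        "hours_post_elicitation": (harvest_day - adding_day) * 24.0,
    }


def optimize_response(
    pipeline: FittedPipeline, problem: OptimizationProblem
) -> pd.DataFrame:
    """Maximize one trained response model with FOA and/or GA.

    Returns one row per optimizer with the optimal inputs, the
    predicted response at the optimum (original units) and the derived
    dose/ratio/exposure quantities.  Deterministic under the problem's
    seed.
    """
    problem.validate()
    if problem.response not in pipeline.models:
        raise KeyError(f"no fitted model for response {problem.response!r}")
    bounds = [problem.bounds[c] for c in INPUT_COLUMNS]

    hull = None
    if not problem.allow_extrapolation:
        X_train = pipeline.scaling.invert(pipeline.models[problem.response].X)
        try:
            hull = Delaunay(X_train)
        except QhullError:
            try:
                hull = Delaunay(X_train, qhull_options="QJ")
            except QhullError:
                warnings.warn(
                    "training inputs are degenerate; convex-hull constraint "
                    "disabled for this problem",
                    RuntimeWarning,
                    stacklevel=2,
                )

    def fitness(x: np.ndarray) -> float:
        if x[3] <= x[2]:  # harvest on or before elicitor addition
            return -np.inf
        if hull is not None and hull.find_simplex(x) < 0:
            return -np.inf
        return float(pipeline.predict(problem.response, x))

    runs = {}
    seed = _response_seed(problem.seed, problem.response)
    if problem.optimizer in ("foa", "both"):
        cfg = problem.foa or FOAConfig()
        cfg.seed = seed
        runs["foa"] = foa_maximize(fitness, bounds, cfg)
    if problem.optimizer in ("ga", "both"):
        cfg = problem.ga or GAConfig()
        cfg.seed = seed
        runs["ga"] = ga_maximize(fitness, bounds, cfg)

    records = []
    for name, res in runs.items():
        ce, cf, adding, harvest = (float(v) for v in res.x)
        rec = {
            "response": problem.response,
            "optimizer": name,
            "ce_pct": ce,
            "cf_pct": cf,
            "adding_day": adding,
            "harvest_day": harvest,
            "predicted": float(res.fun),
        }
        rec.update(derived_quantities(ce, cf, adding, harvest))
        records.append(rec)
    return pd.DataFrame(records)
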
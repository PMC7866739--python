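"""Fruit-fly optimization algorithm (FOA) as a generic bounded maximizer.

FOA is a swarm metaheuristic modeled on the foraging behaviour of fruit
flies.  A group of flies shares a pair of location coordinates ``(X, Y)``
per search dimension.  Each generation every fly makes a random flight
away from the group, the flight geometry yields a "smell concentration
judgment value" ``S = 1 / Dist``, the resulting candidate is scored by
the fitness ("smell concentration") function, and the group relocates to
the best fly whenever that fly improves on the incumbent.  The incumbent
is elitist, so its fitness trace is non-decreasing.

Candidate generation — the map from flight geometry to a point of the
problem's box — is the one step the classical recipe leaves open for
box-constrained multi-dimensional problems, because ``S`` is positive,
unbounded, and heavily right-skewed.  Three schemes are provided:

``"scale_free"`` (default)
    Candidates are steps away from the incumbent,
    ``c_j = clip(x_best_j ± (hi_j − lo_j) · exp(−L_j))``, where ``L_j``
    is the fly's flight length in dimension ``j``.  Because the flight
    length is uniform over the flight-distance range, the step sizes are
    log-uniform: every spatial scale from the full box width down to
    ``exp(−|FDR|·√2)`` of it is sampled equally often, which gives the
    swarm both global coverage and unlimited local refinement without
    any adaptive schedule.
``"minmax"``
    The swarm's raw ``S`` values are affinely squashed onto the bounds
    dimension-by-dimension (min-max over the generation), preserving the
    within-generation ordering.  See :func:`smell_to_box`.
``"clip"``
    The literal classical form: ``c = clip(S, lo, hi)``.  Appropriate
    when the search variable is itself a small positive quantity, such
    as a kernel bandwidth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["FOAConfig", "FOAResult", "foa_maximize", "smell_to_box"]

_SCHEMES = ("scale_free", "minmax", "clip")


@dataclass
class FOAConfig:
    """Swarm-size, budget and flight-scale settings.

    Attributes
    ----------
    sizepop : int
        Flies evaluated per generation (default 10).
    maxgen : int
        Number of generations (default 100).
    lc_range : tuple of float
        Interval for the random initial location coordinates.
    fdr : tuple of float
        Flight distance range; each flight perturbs a coordinate by a
        uniform draw from this interval.  Must contain 0.
    seed : int or None
        Seed for the generator; fixes the run bit-for-bit.
    candidate_scheme : str
        One of ``"scale_free"`` (default), ``"minmax"``, ``"clip"``;
        see the module docstring.
    """

    sizepop: int = 10
    maxgen: int = 100
    lc_range: tuple[float, float] = (0.0, 1.0)
    fdr: tuple[float, float] = (-10.0, 10.0)
    seed: int | None = None
    candidate_scheme: str = "scale_free"

    def validate(self) -> None:
        if self.sizepop < 2:
            raise ValueError("sizepop must be >= 2")
        if self.maxgen < 1:
            raise ValueError("maxgen must be >= 1")
        if not (self.fdr[0] <= 0.0 <= self.fdr[1]):
            raise ValueError("flight distance range must contain 0")
        if self.candidate_scheme not in _SCHEMES:
            raise ValueError(f"candidate_scheme must be one of {_SCHEMES}")


@dataclass
class FOAResult:
    """Outcome of one FOA run."""

    x: np.ndarray
    fun: float
    trace: np.ndarray  # incumbent best fitness per generation
    n_evals: int


def smell_to_box(
    s: np.ndarray, bounds: np.ndarray, mapped: bool = True
) -> np.ndarray:
    """Convert a generation's judgment values to in-box candidates.

    Parameters
    ----------
    s : ndarray, shape (sizepop, d)
        Positive smell-concentration judgment values for one generation.
    bounds : ndarray, shape (d, 2)
        Per-dimension ``[lo, hi]``.
    mapped : bool
        If True, min-max squash each column of ``s`` onto ``[lo, hi]``;
        a degenerate column (all values equal) maps to the midpoint.
        If False, clip the raw values to the bounds.
    """
    s = np.asarray(s, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not mapped:
        return np.clip(s, lo, hi)
    smin = s.min(axis=0)
    smax = s.max(axis=0)
    span = smax - smin
    out = np.empty_like(s)
    for j in range(s.shape[1]):
        if span[j] < 1e-300:
            out[:, j] = 0.5 * (lo[j] + hi[j])
        else:
            out[:, j] = lo[j] + (s[:, j] - smin[j]) / span[j] * (hi[j] - lo[j])
    return np.clip(out, lo, hi)


def foa_maximize(
    fitness: Callable[[np.ndarray], float],
    bounds: Sequence[Sequence[float]],
    config: FOAConfig | None = None,
) -> FOAResult:
    """Maximize ``fitness`` over a box with the fruit-fly algorithm.

    One independent ``(X, Y)`` coordinate pair is maintained per search
    dimension, so the algorithm applies unchanged to multi-dimensional
    problems.  Exactly ``sizepop × maxgen`` fitness evaluations are made;
    flies whose fitness is non-finite are discarded for their generation
    with a warning.

    Parameters
    ----------
    fitness : callable
        Maps a candidate vector (length d) to a scalar.
    bounds : sequence of (lo, hi)
        Finite box, ``lo < hi`` per dimension.
    config : FOAConfig, optional

    Returns
    -------
    FOAResult
    """
    cfg = config or FOAConfig()
    cfg.validate()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a (d, 2) array of [lo, hi] rows")
    if not np.all(np.isfinite(bounds)) or not np.all(bounds[:, 0] < bounds[:, 1]):
        raise ValueError("bounds must be finite with lo < hi")
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(cfg.seed)

    # group location coordinates, one (X, Y) pair per dimension
    gx = rng.uniform(cfg.lc_range[0], cfg.lc_range[1], size=d)
    gy = rng.uniform(cfg.lc_range[0], cfg.lc_range[1], size=d)

    best_f = -np.inf
    best_x: np.ndarray | None = None
    center = 0.5 * (lo + hi)  # pre-incumbent center for the first flights
    trace = np.empty(cfg.maxgen)
    n_evals = 0

    for _gen in range(cfg.maxgen):
        dx = rng.uniform(cfg.fdr[0], cfg.fdr[1], size=(cfg.sizepop, d))
        dy = rng.uniform(cfg.fdr[0], cfg.fdr[1], size=(cfg.sizepop, d))
        fx, fy = gx + dx, gy + dy

        if cfg.candidate_scheme == "scale_free":
            flight = np.sqrt(dx**2 + dy**2)
            step = (hi - lo) * np.exp(-flight)
            sign = rng.choice([-1.0, 1.0], size=(cfg.sizepop, d))
            cand = np.clip(center + sign * step, lo, hi)
        else:
            dist = np.sqrt(fx**2 + fy**2)
            s = 1.0 / np.maximum(dist, 1e-300)
            cand = smell_to_box(
                s, bounds, mapped=(cfg.candidate_scheme == "minmax")
            )

        smell = np.full(cfg.sizepop, -np.inf)
        for i in range(cfg.sizepop):
            val = float(fitness(cand[i]))
            n_evals += 1
            if np.isfinite(val):
                smell[i] = val
            else:
                warnings.warn(
                    "non-finite fitness; fly discarded for this generation",
                    RuntimeWarning,
                    stacklevel=2,
                )
        best_i = int(np.argmax(smell))  # ties: lowest index
        if smell[best_i] > best_f:
            best_f = smell[best_i]
            best_x = cand[best_i].copy()
            center = best_x
            gx = fx[best_i].copy()
            gy = fy[best_i].copy()
        trace[_gen] = best_f

    if best_x is None:
        raise RuntimeError("fitness was non-finite at every evaluated candidate")
    return FOAResult(x=best_x, fun=best_f, trace=trace, n_evals=n_evals)
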
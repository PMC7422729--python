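"""Maximum-likelihood ability scoring for a single examinee.

Given calibrated item parameters, the ability estimate maximizes the
Bernoulli log-likelihood of the observed response vector, with the
response probability taken from either the plain 3PL curve or the
time-aware G3PLT curve at supplied transformed times.  Because the
guessing floor can create shoulder local maxima, the optimizer scans a
coarse grid first and refines the grid winner with a bounded scalar
search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .model import ItemParams, cell_log_likelihood

__all__ = ["ScoringProblem", "estimate_ability_mle", "ability_profile"]

_GRID_STEP = 0.01
_XTOL = 1e-10
_BOUNDARY_TOL = 1e-6


@dataclass
class ScoringProblem:
    """One examinee's responses, the item bank and (optionally) times.

    ``t_star`` may be a scalar (one transformed time applied to every
    item), a length-J vector, or None for plain-3PL scoring.
    """

    y: np.ndarray
    items: ItemParams
    t_star: Optional[object] = None
    search_bounds: tuple = (-6.0, 6.0)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.y.ndim != 1 or self.y.size != self.items.J:
            raise ValueError("response vector length must equal item count")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("responses must be 0/1 (1 = correct)")
        lo, hi = self.search_bounds
        if not lo < hi:
            raise ValueError("invalid search bounds")


def _neg_loglik(theta: float, problem: ScoringProblem) -> float:
    t = problem.t_star
    if t is not None and np.ndim(t) == 0:
        t = np.full(problem.items.J, float(t))
    ll = cell_log_likelihood(problem.y[None, :], [theta], problem.items, t)
    return -float(ll.sum())


def estimate_ability_mle(problem: ScoringProblem):
    """Maximize the response log-likelihood over ability.

    Returns
    -------
    (theta_hat, loglik, boundary_flag)
        ``boundary_flag`` is True when the maximizer sits at a search
        bound (e.g. an all-correct or all-incorrect response vector).
    """
    lo, hi = problem.search_bounds
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    vals = np.array([_neg_loglik(g, problem) for g in grid])
    g0 = float(grid[int(np.argmin(vals))])
    res = minimize_scalar(
        _neg_loglik,
        bounds=(max(lo, g0 - 2 * _GRID_STEP), min(hi, g0 + 2 * _GRID_STEP)),
        args=(problem,),
        method="bounded",
        options={"xatol": _XTOL},
    )
    theta_hat = float(res.x)
    boundary = min(theta_hat - lo, hi - theta_hat) < _BOUNDARY_TOL
    return theta_hat, -float(res.fun), boundary


def ability_profile(y, items: ItemParams, tstar_grid: Sequence[float],
                    search_bounds=(-6.0, 6.0)):
    """Ability estimate for one response vector at each scalar transformed time.

    Returns a list of ``theta_hat`` aligned with ``tstar_grid``.  For a
    fixed response vector the estimates are non-increasing in ``t*``:
    the shorter the (transformed) time in which the same answers were
    produced, the higher the inferred ability.
    """
    out = []
    for t in tstar_grid:
        prob = ScoringProblem(y=y, items=items, t_star=float(t),
                              search_bounds=search_bounds)
        out.append(estimate_ability_mle(prob)[0])
    return out
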
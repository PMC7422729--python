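"""Seeded synthetic-data generation for recovery and model-comparison studies.

The generator emulates a timed power test:

* item discriminations from a positive-truncated normal (mean 1,
  variance 0.2), difficulties standard normal, guessing Beta(2, 10);
* abilities standard normal (the identification scale of the model);
* item-level mean transformed times obtained by standardizing log-normal
  average times (log t_j ~ N(0.5, 0.25), so t*_j ~ N(0, 1)), then paired
  with difficulty by rank: harder items take longer;
* person-by-item transformed times drawn around the item mean with
  variance 0.5 and paired with ability by rank within each item: more
  able examinees answer faster (Spearman correlation exactly -1 by
  construction);
* responses Bernoulli under the G3PLT probability evaluated at
  ``t* + W``, where W is the test-level time weight.

Normal distributions are parameterized as N(mean, variance) throughout,
matching the convention under which standardizing N(0.5, 0.25) log-times
divides by 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ItemParams, ResponseMatrix, _prob_matrix

__all__ = [
    "SimulationDesign",
    "generate_item_parameters",
    "generate_abilities",
    "generate_structured_times",
    "generate_responses",
    "generate_dataset",
]


@dataclass
class SimulationDesign:
    """A simulation condition: size, time weight, seed and replication count."""

    N: int = 500
    J: int = 20
    W: float = 1.0
    seed: int = 0
    reps: int = 200
    # generator hyperparameters (variances, not SDs)
    a_mean: float = 1.0
    a_var: float = 0.2
    c_shape: tuple = (2.0, 10.0)
    log_time_mean: float = 0.5
    log_time_var: float = 0.25
    within_item_time_var: float = 0.5
    D: float = 1.7

    def __post_init__(self) -> None:
        if self.N < 1 or self.J < 1 or self.reps < 1:
            raise ValueError("N, J and reps must be >= 1")
        if not (0.0 <= self.W <= 8.0):
            raise ValueError("time weight W must lie in [0, 8]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_item_parameters(J: int, seed, design: SimulationDesign | None = None) -> ItemParams:
    """Draw item triples: a ~ N(1, 0.2) truncated to a > 0 (by rejection),
    b ~ N(0, 1), c ~ Beta(2, 10)."""
    d = design or SimulationDesign(J=J)
    rng = _rng(seed)
    sd = np.sqrt(d.a_var)
    a = rng.normal(d.a_mean, sd, size=J)
    while np.any(a <= 0):
        bad = a <= 0
        a[bad] = rng.normal(d.a_mean, sd, size=int(bad.sum()))
    b = rng.normal(0.0, 1.0, size=J)
    c = rng.beta(*d.c_shape, size=J)
    return ItemParams(a=a, b=b, c=c, D=d.D)


def generate_abilities(N: int, seed) -> np.ndarray:
    """Standard-normal abilities (the model's identification scale)."""
    return _rng(seed).normal(0.0, 1.0, size=N)


def generate_structured_times(items: ItemParams, theta: np.ndarray, seed,
                              design: SimulationDesign | None = None,
                              return_item_means: bool = False):
    """Transformed times (without the weight) with the study's dependence
    structure.

    Item-level means t*_j come from standardized log-normal average times
    and are rank-paired with difficulty (b ascending <-> t*_j ascending).
    Within each item, N draws around t*_j are rank-paired with ability
    (theta descending <-> t* ascending), so per item the Spearman
    correlation of ability with time is exactly -1.
    """
    d = design or SimulationDesign(N=theta.size, J=items.J)
    rng = _rng(seed)
    J, N = items.J, np.asarray(theta).size

    log_tj = rng.normal(d.log_time_mean, np.sqrt(d.log_time_var), size=J)
    tj_star = np.sort((log_tj - d.log_time_mean) / np.sqrt(d.log_time_var))
    # assign ascending t*_j to items in ascending-difficulty order
    item_order = np.argsort(items.b, kind="stable")
    tj_by_item = np.empty(J)
    tj_by_item[item_order] = tj_star

    # within each item: sorted draws to examinees in descending-ability order
    ability_rank = np.argsort(np.argsort(-np.asarray(theta), kind="stable"), kind="stable")
    t_star = np.empty((N, J))
    sd_w = np.sqrt(d.within_item_time_var)
    for j in range(J):
        draws = np.sort(rng.normal(tj_by_item[j], sd_w, size=N))
        t_star[:, j] = draws[ability_rank]
    if return_item_means:
        return t_star, tj_by_item
    return t_star


def generate_responses(theta, items: ItemParams, t_star, W: float, seed) -> ResponseMatrix:
    """Bernoulli responses under the G3PLT probability at ``t* + W``."""
    rng = _rng(seed)
    p = _prob_matrix(theta, items, np.asarray(t_star) + float(W))
    y = (rng.random(p.shape) < p).astype(np.int8)
    return ResponseMatrix(y=y)


def generate_dataset(design: SimulationDesign, seed=None):
    """One full replication: items, abilities, structured times, responses.

    Returns a dict with keys ``items``, ``theta``, ``t_star`` (weight not
    yet added), ``responses`` and the design.  Deterministic given
    ``seed`` (defaults to ``design.seed``).
    """
    rng = _rng(design.seed if seed is None else seed)
    items = generate_item_parameters(design.J, rng, design)
    theta = generate_abilities(design.N, rng)
    t_star = generate_structured_times(items, theta, rng, design)
    responses = generate_responses(theta, items, t_star, design.W, rng)
    return {
        "items": items,
        "theta": theta,
        "t_star": t_star,
        "responses": responses,
        "design": design,
    }
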
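"""Metropolis–Hastings-within-Gibbs estimation of the G3PLT model.

One Gibbs sweep updates four blocks in turn, each with a Metropolis
accept/reject step against the Bernoulli likelihood and the block's prior:

1. abilities ``theta_i`` — normal random-walk proposal;
2. difficulties ``b_j`` — normal random-walk proposal;
3. discriminations ``a_j`` — lognormal random-walk proposal, whose
   asymmetry contributes the Jacobian factor ``a*_j / a_j`` to the
   acceptance ratio;
4. guessing ``c_j`` — uniform proposal of half-width 0.01, auto-rejected
   outside (0, 1).

Priors default to theta ~ N(0,1) (which also fixes the latent scale and
identifies the model), b ~ N(0,1), a ~ logN(0,1), c ~ Beta(2,10).
Random-walk scales for the theta/b/a blocks are adapted toward a 20-50%
acceptance rate during burn-in and frozen afterwards so the retained
draws target the exact posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import ItemParams, ResponseMatrix, _P_EPS

__all__ = [
    "PriorConfig",
    "ProposalConfig",
    "ChainConfig",
    "PosteriorDraws",
    "run_mcmc",
    "psrf",
    "hpd_interval",
]

_ALL_BLOCKS = ("theta", "b", "a", "c")


@dataclass
class PriorConfig:
    """Prior hyperparameters; normal laws are (mean, variance)."""

    theta: tuple = (0.0, 1.0)
    b: tuple = (0.0, 1.0)
    a: tuple = (0.0, 1.0)   # lognormal: (mean, variance) of log a
    c: tuple = (2.0, 10.0)  # Beta shapes

    def __post_init__(self) -> None:
        if self.theta[1] <= 0 or self.b[1] <= 0 or self.a[1] <= 0:
            raise ValueError("prior variances must be positive")
        if self.c[0] <= 0 or self.c[1] <= 0:
            raise ValueError("Beta shapes must be positive")


@dataclass
class ProposalConfig:
    """Random-walk proposal scales (SDs; c uses a uniform half-width)."""

    v_theta: float = 1.0
    v_b: float = 0.5
    v_a: float = 0.3
    c_halfwidth: float = 0.01
    adapt: bool = True
    adapt_window: int = 50
    target_low: float = 0.2
    target_high: float = 0.5

    def __post_init__(self) -> None:
        if min(self.v_theta, self.v_b, self.v_a, self.c_halfwidth) <= 0:
            raise ValueError("proposal scales must be positive")


@dataclass
class ChainConfig:
    """MCMC run lengths and bookkeeping."""

    iterations: int = 10_000
    burn_in: int = 5_000
    n_chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorDraws:
    """Post-burn-in draws (chains concatenated) with chain bookkeeping."""

    theta: np.ndarray          # R x N
    a: np.ndarray              # R x J
    b: np.ndarray              # R x J
    c: np.ndarray              # R x J
    chain: np.ndarray          # R, chain label per draw
    acceptance: dict = field(default_factory=dict)
    D: float = 1.7

    @property
    def R(self) -> int:
        return self.theta.shape[0]

    def block(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def eap(self, name: str) -> np.ndarray:
        return self.block(name).mean(axis=0)

    def post_sd(self, name: str) -> np.ndarray:
        return self.block(name).std(axis=0, ddof=1)

    def hpd(self, name: str, prob: float = 0.95) -> np.ndarray:
        draws = self.block(name)
        return np.array([hpd_interval(draws[:, k], prob)
                         for k in range(draws.shape[1])])

    def split_by_chain(self, name: str) -> np.ndarray:
        """(n_chains, n_kept, P) view for convergence diagnostics."""
        labels = np.unique(self.chain)
        per = [self.block(name)[self.chain == l] for l in labels]
        n = min(p.shape[0] for p in per)
        return np.stack([p[:n] for p in per])

    def summary(self, prob: float = 0.95):
        """Tidy per-parameter table: EAP, posterior SD, HPD bounds."""
        import pandas as pd

        rows = []
        for name in ("theta", "a", "b", "c"):
            draws = self.block(name)
            if draws.shape[1] == 0:
                continue
            hpd = self.hpd(name, prob)
            for k in range(draws.shape[1]):
                rows.append({
                    "parameter": f"{name}[{k}]", "block": name, "index": k,
                    "eap": draws[:, k].mean(), "sd": draws[:, k].std(ddof=1),
                    "hpd_lower": hpd[k, 0], "hpd_upper": hpd[k, 1],
                })
        return pd.DataFrame(rows)


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple:
    """Shortest interval containing ``prob`` posterior mass among sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = max(1, int(np.ceil(prob * n)))  # points inside the interval
    if k >= n:
        return (float(x[0]), float(x[-1]))
    widths = x[k - 1:] - x[:n - k + 1]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + k - 1]))


# ---------------------------------------------------------------------------
# likelihood kernels (arrays only; hot path)

def _cell_ll(theta, a, b, c, D, Et, y):
    """N x J Bernoulli log-pmf matrix. Et is exp(-t*) (matrix or 0.0)."""
    with np.errstate(over="ignore"):
        denom = 1.0 + np.exp(-D * a * (theta[:, None] - b)) + Et
    p = np.clip(c + (1.0 - c) / denom, _P_EPS, 1.0 - _P_EPS)
    return np.where(y == 1, np.log(p), np.log1p(-p))


def _log_norm_pdf(x, mean, var):
    return -0.5 * (x - mean) ** 2 / var


# ---------------------------------------------------------------------------
# block updates (operate in place on state arrays; return acceptance mask)

def mh_step_theta(theta, L, y, Et, a, b, c, D, prior, v, rng):
    """Person-wise MH update of abilities; mutates ``theta`` and ``L``."""
    prop = theta + rng.normal(size=theta.size) * v
    Lp = _cell_ll(prop, a, b, c, D, Et, y)
    mu, var = prior
    logr = (Lp.sum(axis=1) - L.sum(axis=1)
            + _log_norm_pdf(prop, mu, var) - _log_norm_pdf(theta, mu, var))
    acc = np.log(rng.random(theta.size)) < logr
    theta[acc] = prop[acc]
    L[acc] = Lp[acc]
    return acc


def mh_step_b(theta, L, y, Et, a, b, c, D, prior, v, rng):
    """Item-wise MH update of difficulties; mutates ``b`` and ``L``."""
    prop = b + rng.normal(size=b.size) * v
    Lp = _cell_ll(theta, a, prop, c, D, Et, y)
    mu, var = prior
    logr = (Lp.sum(axis=0) - L.sum(axis=0)
            + _log_norm_pdf(prop, mu, var) - _log_norm_pdf(b, mu, var))
    acc = np.log(rng.random(b.size)) < logr
    b[acc] = prop[acc]
    L[:, acc] = Lp[:, acc]
    return acc


def mh_step_a(theta, L, y, Et, a, b, c, D, prior, v, rng):
    """Item-wise MH update of discriminations.

    The proposal is a lognormal random walk, ``log a* ~ N(log a, v^2)``.
    Its asymmetry contributes the factor ``a*/a`` to the acceptance
    ratio, carried here in log space as ``log a* - log a`` alongside the
    lognormal prior density evaluated at both points.
    """
    la = np.log(a)
    la_prop = la + rng.normal(size=a.size) * v
    prop = np.exp(la_prop)
    Lp = _cell_ll(theta, prop, b, c, D, Et, y)
    mu, var = prior
    # lognormal prior log-density: -log a - (log a - mu)^2 / (2 var) + const
    prior_diff = (-la_prop + _log_norm_pdf(la_prop, mu, var)
                  - (-la + _log_norm_pdf(la, mu, var)))
    jacobian = la_prop - la  # log(a*/a)
    logr = Lp.sum(axis=0) - L.sum(axis=0) + prior_diff + jacobian
    acc = np.log(rng.random(a.size)) < logr
    a[acc] = prop[acc]
    L[:, acc] = Lp[:, acc]
    return acc


def mh_step_c(theta, L, y, Et, a, b, c, D, prior, halfwidth, rng):
    """Item-wise MH update of guessing floors.

    Uniform symmetric proposal ``c* ~ U(c - h, c + h)``; proposals outside
    (0, 1) have zero prior density and are rejected outright.
    """
    prop = c + rng.uniform(-halfwidth, halfwidth, size=c.size)
    valid = (prop > 0.0) & (prop < 1.0)
    safe = np.where(valid, prop, 0.5)
    Lp = _cell_ll(theta, a, b, safe, D, Et, y)
    u1, u2 = prior
    prior_diff = ((u1 - 1) * (np.log(safe) - np.log(c))
                  + (u2 - 1) * (np.log1p(-safe) - np.log1p(-c)))
    logr = np.where(valid, Lp.sum(axis=0) - L.sum(axis=0) + prior_diff, -np.inf)
    acc = np.log(rng.random(c.size)) < logr
    c[acc] = prop[acc]
    L[:, acc] = Lp[:, acc]
    return acc


# ---------------------------------------------------------------------------

def _default_init(y: np.ndarray, priors: PriorConfig):
    """Moment-based starting point: standardized person/item logits."""
    N, J = y.shape
    if J > 0:
        s = (y.mean(axis=1) * J + 0.5) / (J + 1.0)
        theta = np.log(s / (1 - s))
        sd = theta.std()
        theta = (theta - theta.mean()) / (sd if sd > 0 else 1.0)
    else:
        theta = np.zeros(N)
    if J > 0 and N > 0:
        q = (y.mean(axis=0) * N + 0.5) / (N + 1.0)
        b = -np.log(q / (1 - q))
        sdb = b.std()
        b = (b - b.mean()) / (sdb if sdb > 0 else 1.0)
    else:
        b = np.zeros(J)
    a = np.ones(J)
    u1, u2 = priors.c
    c = np.full(J, u1 / (u1 + u2))
    return theta, a, b, c


def _jitter_init(state, rng, priors: PriorConfig):
    """Overdispersed start for multi-chain runs."""
    theta, a, b, c = (s.copy() for s in state)
    theta += rng.normal(0.0, 1.0, size=theta.size)
    b += rng.normal(0.0, 1.0, size=b.size)
    a *= np.exp(rng.normal(0.0, 0.5, size=a.size))
    c = rng.beta(*priors.c, size=c.size)
    return theta, a, b, c


def _run_chain(y, Et, D, priors, proposals, n_iter, burn_in, rng, init,
               sample_blocks):
    N, J = y.shape
    theta, a, b, c = (np.asarray(x, dtype=float).copy() for x in init)
    L = _cell_ll(theta, a, b, c, D, Et, y)

    v_theta = np.full(N, proposals.v_theta)
    v_b = np.full(J, proposals.v_b)
    v_a = np.full(J, proposals.v_a)

    kept = n_iter - burn_in
    out = {
        "theta": np.empty((kept, N)), "a": np.empty((kept, J)),
        "b": np.empty((kept, J)), "c": np.empty((kept, J)),
    }
    acc_tot = {k: 0.0 for k in _ALL_BLOCKS}
    win = {"theta": np.zeros(N), "b": np.zeros(J), "a": np.zeros(J)}
    wlen = proposals.adapt_window

    for r in range(n_iter):
        if "theta" in sample_blocks:
            acc = mh_step_theta(theta, L, y, Et, a, b, c, D, priors.theta,
                                v_theta, rng)
            win["theta"] += acc
            if r >= burn_in:
                acc_tot["theta"] += acc.mean() if N else 0.0
        if "b" in sample_blocks:
            acc = mh_step_b(theta, L, y, Et, a, b, c, D, priors.b, v_b, rng)
            win["b"] += acc
            if r >= burn_in:
                acc_tot["b"] += acc.mean() if J else 0.0
        if "a" in sample_blocks:
            acc = mh_step_a(theta, L, y, Et, a, b, c, D, priors.a, v_a, rng)
            win["a"] += acc
            if r >= burn_in:
                acc_tot["a"] += acc.mean() if J else 0.0
        if "c" in sample_blocks:
            acc = mh_step_c(theta, L, y, Et, a, b, c, D, priors.c,
                            proposals.c_halfwidth, rng)
            if r >= burn_in:
                acc_tot["c"] += acc.mean() if J else 0.0

        # proposal adaptation, burn-in only (frozen afterwards)
        if proposals.adapt and r < burn_in and (r + 1) % wlen == 0:
            for key, v in (("theta", v_theta), ("b", v_b), ("a", v_a)):
                if key not in sample_blocks:
                    continue
                rate = win[key] / wlen
                v *= np.where(rate < proposals.target_low, 0.7,
                              np.where(rate > proposals.target_high, 1.4, 1.0))
                win[key][:] = 0.0

        if r >= burn_in:
            k = r - burn_in
            out["theta"][k] = theta
            out["a"][k] = a
            out["b"][k] = b
            out["c"][k] = c

    rates = {k: (acc_tot[k] / kept if kept else np.nan) for k in _ALL_BLOCKS}
    return out, rates


def run_mcmc(y, t_star=None, priors: Optional[PriorConfig] = None,
             proposals: Optional[ProposalConfig] = None,
             chains: Optional[ChainConfig] = None, D: float = 1.7,
             sample_blocks: Iterable[str] = _ALL_BLOCKS,
             init_state=None) -> PosteriorDraws:
    """Fit the G3PLT (or, with ``t_star=None``, the plain 3PL) by
    MH-within-Gibbs.

    Parameters
    ----------
    y : ResponseMatrix or (N, J) array of 0/1
    t_star : None, scalar, or (N, J) array
        Final transformed times including any weight; ``None`` drops the
        time term entirely (3PL likelihood).
    sample_blocks : iterable of {"theta", "a", "b", "c"}
        Blocks to update; omitted blocks stay at their initial values
        (useful for oracle checks with parameters fixed at truth).
    init_state : optional (theta, a, b, c) starting point.

    Returns post-burn-in draws of all chains concatenated, with per-block
    acceptance rates. Fully reproducible given ``chains.seed``.
    """
    if isinstance(y, ResponseMatrix):
        y = y.y
    y = np.asarray(y)
    if y.ndim != 2:
        raise ValueError("y must be a 2-D 0/1 matrix")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("responses must be 0/1 (1 = correct)")
    N, J = y.shape
    if N == 0:
        raise ValueError("need at least one examinee")
    y = y.astype(np.int8)

    if t_star is None:
        Et = 0.0
    else:
        t_star = np.asarray(t_star, dtype=float)
        if t_star.ndim == 0:
            t_star = np.full((N, J), float(t_star))
        if t_star.shape != y.shape:
            raise ValueError("t_star shape does not match responses")
        with np.errstate(over="ignore"):
            Et = np.exp(-t_star)

    priors = priors or PriorConfig()
    proposals = proposals or ProposalConfig()
    chains = chains or ChainConfig()
    sample_blocks = frozenset(sample_blocks)
    if not sample_blocks <= set(_ALL_BLOCKS):
        raise ValueError(f"unknown blocks: {sample_blocks - set(_ALL_BLOCKS)}")

    base_init = init_state or _default_init(y, priors)
    ss = np.random.SeedSequence(chains.seed)
    blocks_out = {k: [] for k in ("theta", "a", "b", "c")}
    labels, rate_acc = [], []
    for ci, child in enumerate(ss.spawn(chains.n_chains)):
        rng = np.random.default_rng(child)
        init = base_init if ci == 0 else _jitter_init(base_init, rng, priors)
        out, rates = _run_chain(y, Et, D, priors, proposals,
                                chains.iterations, chains.burn_in, rng, init,
                                sample_blocks)
        for k in blocks_out:
            blocks_out[k].append(out[k])
        labels.append(np.full(out["theta"].shape[0], ci))
        rate_acc.append(rates)

    acceptance = {k: float(np.mean([r[k] for r in rate_acc]))
                  for k in _ALL_BLOCKS}
    return PosteriorDraws(
        theta=np.concatenate(blocks_out["theta"]),
        a=np.concatenate(blocks_out["a"]),
        b=np.concatenate(blocks_out["b"]),
        c=np.concatenate(blocks_out["c"]),
        chain=np.concatenate(labels),
        acceptance=acceptance,
        D=D,
    )


def psrf(chain_draws: np.ndarray) -> np.ndarray:
    """Gelman–Rubin potential scale reduction factor.

    Parameters
    ----------
    chain_draws : (m, n) or (m, n, P) array
        ``m`` chains of ``n`` draws (optionally for P parameters).

    Returns the between/within variance ratio per scalar parameter;
    values below 1.2 are conventionally taken as converged.
    """
    x = np.asarray(chain_draws, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n, _ = x.shape
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    W = x.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = x.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_plus / W)
    r = np.where(W == 0, 1.0, r)
    return float(r[0]) if squeeze else r
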
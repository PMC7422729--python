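"""Replication-level accuracy indices for simulation studies.

Given M replications of posterior estimates for P parameters, computes
per-parameter bias, mean squared error, simulation SE (the square root
of the 1/M-normalized sample variance of the estimates), the average
posterior SD, and 95% HPD coverage probability, plus averages of these
within parameter classes (all discriminations, all difficulties, all
guessing floors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = ["RecoveryReport", "recovery_metrics", "truth_vs_estimate_scatter"]


@dataclass
class RecoveryReport:
    per_parameter: pd.DataFrame   # one row per parameter
    by_class: pd.DataFrame        # one row per parameter class
    M: int


def recovery_metrics(estimates, truth, post_sds=None, hpd_intervals=None,
                     classes=None) -> RecoveryReport:
    """Accuracy indices over M replications.

    Parameters
    ----------
    estimates : (M, P) array
        Posterior-mean estimates per replication.
    truth : (P,) array
        True generating values.
    post_sds : (M, P) array, optional
        Posterior SDs per replication.
    hpd_intervals : (M, P, 2) array, optional
        95% HPD bounds per replication; coverage counts intervals whose
        closed range contains the truth.
    classes : (P,) sequence of str, optional
        Class label per parameter for the class-averaged table.

    Notes
    -----
    The simulation SE uses the 1/M (not 1/(M-1)) normalization of the
    sample variance, so for M replications with estimates
    ``{truth+1, truth-1}`` the simulation SE is exactly 1.
    """
    est = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.ndim != 2 or est.shape[1] != truth.size:
        raise ValueError("estimates must be (M, P) matching truth length")
    M, P = est.shape

    err = est - truth
    bias = err.mean(axis=0)
    mse = (err ** 2).mean(axis=0)
    sim_se = np.sqrt(((est - est.mean(axis=0)) ** 2).mean(axis=0))

    avg_sd = np.full(P, np.nan)
    if post_sds is not None:
        post_sds = np.asarray(post_sds, dtype=float)
        if post_sds.shape != est.shape:
            raise ValueError("post_sds shape mismatch")
        avg_sd = post_sds.mean(axis=0)

    cp = np.full(P, np.nan)
    if hpd_intervals is not None:
        hpd = np.asarray(hpd_intervals, dtype=float)
        if hpd.shape != (M, P, 2):
            raise ValueError("hpd_intervals must be (M, P, 2)")
        inside = (hpd[:, :, 0] <= truth) & (truth <= hpd[:, :, 1])
        cp = inside.mean(axis=0)

    per = pd.DataFrame({
        "truth": truth, "bias": bias, "mse": mse,
        "sim_se": sim_se, "avg_sd": avg_sd, "cp": cp,
    })
    if classes is None:
        classes = ["all"] * P
    per["class"] = list(classes)
    by_class = (per.groupby("class")[["bias", "mse", "sim_se", "avg_sd", "cp"]]
                .mean().reset_index())
    return RecoveryReport(per_parameter=per, by_class=by_class, M=M)


def truth_vs_estimate_scatter(truth, estimates, ax=None, label=None):
    """Plain truth-vs-estimate scatter with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    truth = np.asarray(truth, dtype=float)
    est = np.asarray(estimates, dtype=float)
    ax.scatter(truth, est, s=8, alpha=0.6, label=label)
    lo = min(truth.min(), est.min())
    hi = max(truth.max(), est.max())
    ax.plot([lo, hi], [lo, hi], color="k", lw=0.8)
    ax.set_xlabel("true value")
    ax.set_ylabel("estimate")
    return ax
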
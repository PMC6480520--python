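"""Accuracy and detection experiments for the introgression statistics.

Simulates grids of loci with known introgression fraction f, computes
D, f_hom, f_d and d_f per locus and scores each statistic with

* adjusted R^2 of an OLS fit of the statistic on the true fraction
  ("goodness of fit"; an identity-line variant is available),
* SSLF, the lack-of-fit sum of squares sum_j n_j (ybar_j - f_j)^2,
  reported divided by the per-fraction sample size,
* SSPE, the pure-error sum of squares sum_ij (y_ij - ybar_j)^2,

plus ROC AUC for the neutral-vs-introgressed detection experiment and
Monte-Carlo curves of the pairwise distances d_12, d_13, d_23 against f
(whose direction-dependent slopes carry information about the donor).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .core_stats import compute_window_stats, site_dxy
from .io import frequency_table
from .simulator import (SimulationConfig, simulate_detection_set,
                        simulate_grid)

logger = logging.getLogger(__name__)

__all__ = ["FitMetrics", "EvalReport", "fit_metrics", "statistic_table",
           "run_accuracy_experiment", "run_detection_experiment",
           "dxy_vs_f_curves", "slope_on_f"]

STATISTICS = ("D", "f_hom", "f_d", "d_f")


class FitMetrics(NamedTuple):
    adj_r2: float
    sslf_over_n: float
    sspe: float
    n_used: int
    n_excluded: int


@dataclass
class EvalReport:
    """Per-statistic accuracy metrics over an introgression-fraction grid."""

    metrics: dict
    f_values: list
    reps: int
    config: SimulationConfig
    seed: int | None = None
    auc: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s: m._asdict() for s, m in self.metrics.items()}).T

    def to_json(self, path=None):
        payload = {
            "metrics": {s: m._asdict() for s, m in self.metrics.items()},
            "auc": self.auc,
            "f_values": list(map(float, self.f_values)),
            "reps": self.reps,
            "seed": self.seed,
            "config": {k: v for k, v in vars(self.config).items()},
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_metrics(f_true, values, n_per_f=None, model="ols") -> FitMetrics:
    """Score one statistic against the true introgression fractions.

    NaN values (undefined statistics) are excluded with a logged count.
    SSLF is divided by ``n_per_f`` (default: the largest per-fraction
    group size, i.e. the number of replicates).  ``model="ols"`` fits
    value ~ a + b f and reports the standard adjusted R^2;
    ``model="identity"`` scores deviation from the line y = f instead.
    """
    f_true = np.asarray(f_true, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("fit_metrics: excluded %d undefined values", n_excluded)
    f_true, values = f_true[ok], values[ok]
    if len(values) == 0:
        raise ValueError("all values undefined")
    groups = np.unique(f_true)
    if len(groups) < 2:
        raise ValueError("need at least two distinct true fractions")

    sslf_raw = 0.0
    sspe = 0.0
    max_group = 0
    for fj in groups:
        y = values[f_true == fj]
        max_group = max(max_group, len(y))
        sslf_raw += len(y) * (y.mean() - fj) ** 2
        sspe += float(((y - y.mean()) ** 2).sum())
    if n_per_f is None:
        n_per_f = max_group

    if model == "ols":
        if np.ptp(values) == 0:  # constant estimator: nothing to explain
            adj_r2 = 0.0
        else:
            fit = sm.OLS(values, sm.add_constant(f_true)).fit()
            adj_r2 = float(fit.rsquared_adj)
    elif model == "identity":
        ss_res = float(((values - f_true) ** 2).sum())
        ss_tot = float(((values - values.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        n = len(values)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    else:
        raise ValueError("model must be 'ols' or 'identity'")
    return FitMetrics(adj_r2, sslf_raw / n_per_f, sspe, len(values), n_excluded)


def statistic_table(config, f_values, reps, seed=None, smooth=False):
    """Simulate a grid and tabulate the four statistics per locus."""
    rows = []
    for f, rep, matrix in simulate_grid(config, f_values, reps, seed=seed):
        w = compute_window_stats(frequency_table(matrix), smooth=smooth)
        rows.append({"f": f, "rep": rep, "n_snps": w.n_snps, "D": w.D,
                     "f_hom": w.f_hom, "f_d": w.f_d, "d_f": w.d_f})
    return pd.DataFrame(rows)


def run_accuracy_experiment(config, f_values=None, reps=100, seed=None,
                            smooth=False, model="ols") -> EvalReport:
    """Grid simulation scored per statistic (the Table-1 style experiment)."""
    if f_values is None:
        f_values = np.round(np.arange(0.0, 1.01, 0.1), 1)
    table = statistic_table(config, f_values, reps, seed=seed, smooth=smooth)
    metrics = {s: fit_metrics(table["f"], table[s], n_per_f=reps, model=model)
               for s in STATISTICS}
    return EvalReport(metrics, list(f_values), reps, config, seed)


def run_detection_experiment(config, n_neutral=10_000, n_introgressed=1_000,
                             seed=None, smooth=False):
    """ROC AUC of each statistic separating introgressed from neutral loci.

    Loci with an undefined statistic are excluded from that statistic's
    AUC (logged); raises if either class becomes empty.
    """
    loci, labels = simulate_detection_set(config, config, n_neutral,
                                          n_introgressed, seed=seed)
    values = {s: [] for s in STATISTICS}
    for m in loci:
        w = compute_window_stats(frequency_table(m), smooth=smooth)
        for s in STATISTICS:
            values[s].append(getattr(w, s))
    auc = {}
    for s in STATISTICS:
        y = np.asarray(values[s], dtype=float)
        ok = np.isfinite(y)
        if (~ok).sum():
            logger.info("detection: excluded %d undefined %s loci",
                        int((~ok).sum()), s)
        lab = labels[ok]
        if len(np.unique(lab)) < 2:
            raise ValueError(f"single-class data after exclusions for {s}")
        auc[s] = float(roc_auc_score(lab, y[ok]))
    return auc


def dxy_vs_f_curves(config, f_values=None, reps=100, seed=None) -> pd.DataFrame:
    """Monte-Carlo mean per-bp pairwise distances d_12, d_13, d_23 per f."""
    if f_values is None:
        f_values = np.round(np.arange(0.0, 1.01, 0.1), 1)
    acc = {f: np.zeros(3) for f in map(float, f_values)}
    counts = {f: 0 for f in acc}
    for f, rep, matrix in simulate_grid(config, f_values, reps, seed=seed):
        p = frequency_table(matrix).p
        L = matrix.length
        d12 = site_dxy(p[:, 0], p[:, 1]).sum() / L
        d13 = site_dxy(p[:, 0], p[:, 2]).sum() / L
        d23 = site_dxy(p[:, 1], p[:, 2]).sum() / L
        acc[f] += (d12, d13, d23)
        counts[f] += 1
    rows = [{"f": f, "d12": a[0] / counts[f], "d13": a[1] / counts[f],
             "d23": a[2] / counts[f]} for f, a in acc.items()]
    return pd.DataFrame(rows).sort_values("f").reset_index(drop=True)


def slope_on_f(curves: pd.DataFrame, column: str) -> float:
    """OLS slope of one mean-distance column against f."""
    fit = sm.OLS(curves[column].to_numpy(),
                 sm.add_constant(curves["f"].to_numpy())).fit()
    return float(fit.params[1])
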
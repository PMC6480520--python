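"""Window-based genome scan with weighted block-jackknife Z values.

The scan tiles a chromosome with half-open windows, computes the four
statistics per window (d_f Laplace-smoothed by default, as recommended
for genomic scans), attaches jackknife standard errors and Z values,
converts Z to two-sided normal p-values, adjusts them with the
Benjamini-Hochberg step-up rule and reports significant outlier
windows.

The jackknife treats the scan windows themselves as blocks (delete one
block, recompute the pooled region-wide ratio statistic from the summed
numerators and denominators).  Block weights are proportional to SNP
counts following Busing et al. (1999); with equal weights the formula
reduces to the textbook delete-one jackknife variance.  Each window's
standard error is the implied per-block standard deviation
``sqrt(g * var_jack)`` rescaled by ``sqrt(mean_weight / weight_i)`` so
SNP-rich windows get tighter errors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_stats import compute_window_stats
from .io import HaplotypeMatrix, frequency_table

logger = logging.getLogger(__name__)

__all__ = ["window_scan", "jackknife_z", "bh_fdr", "call_outliers",
           "run_scan", "write_scan_tsv", "write_outlier_bed"]

_DEN_OF = {"D": "den_D", "f_hom": "den_fhom", "f_d": "den_fd", "d_f": "den_df"}


def window_scan(matrix: HaplotypeMatrix, width_bp: int, step_bp: int | None = None,
                smooth: bool = True, chrom_length: int | None = None) -> pd.DataFrame:
    """Per-window statistics over a tiling of [0, chrom_length).

    ``step_bp`` defaults to ``width_bp`` (consecutive windows).  Windows
    are half-open ``[start, start + width)``; those without usable SNPs
    carry NaN statistics and ``n_snps = 0``.
    """
    step_bp = width_bp if step_bp is None else step_bp
    if not (width_bp >= step_bp >= 1):
        raise ValueError("need width >= step >= 1")
    span = chrom_length if chrom_length is not None else matrix.length
    freqs = frequency_table(matrix)
    rows = []
    # at least one window even when the region is shorter than the width
    for start in range(0, max(span - width_bp, 0) + 1, step_bp):
        end = start + width_bp
        sel = (freqs.positions >= start) & (freqs.positions < end)
        w = compute_window_stats(freqs.select(sel), smooth=smooth,
                                 window_start=start, window_end=end)
        rows.append({"start": start, "end": end, "n_snps": w.n_snps,
                     "D": w.D, "f_hom": w.f_hom, "f_d": w.f_d, "d_f": w.d_f,
                     "num": w.num, "den_D": w.den_D, "den_fhom": w.den_fhom,
                     "den_fd": w.den_fd, "den_df": w.den_df})
    columns = ["start", "end", "n_snps", "D", "f_hom", "f_d", "d_f", "num",
               "den_D", "den_fhom", "den_fd", "den_df"]
    return pd.DataFrame(rows, columns=columns)


def _busing_variance(theta_hat, theta_del, weights):
    """Weighted delete-one-block jackknife variance (Busing et al. 1999)."""
    g = len(theta_del)
    n = weights.sum()
    h = n / weights
    theta_j = g * theta_hat - np.sum((1.0 - weights / n) * theta_del)
    pseudo = h * theta_hat - (h - 1.0) * theta_del
    return float(np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / g)


def jackknife_z(scan: pd.DataFrame, statistic: str = "d_f",
                null_value=0.0, equal_weights: bool = False,
                block_size_bp: int | None = None) -> pd.DataFrame:
    """Attach jackknife SE and Z columns for one statistic.

    ``null_value`` is a scalar or per-window array.  Jackknife blocks
    default to the scan windows themselves; ``block_size_bp`` instead
    aggregates consecutive windows into blocks of that span.  Windows
    whose denominator is zero (undefined statistic) are excluded from
    the blocks and get NaN Z.  Fewer than two usable blocks, or a zero
    jackknife variance, also yield NaN Z (with a warning).
    """
    den_col = _DEN_OF[statistic]
    out = scan.copy()
    num = scan["num"].to_numpy(dtype=float)
    den = scan[den_col].to_numpy(dtype=float)
    usable = (den > 0) & np.isfinite(scan[statistic].to_numpy(dtype=float))
    out["se"] = np.nan
    out["z"] = np.nan
    nb, db = num[usable], den[usable]
    snps = scan["n_snps"].to_numpy(dtype=float)[usable]
    if block_size_bp is not None:
        block_of = (scan["start"].to_numpy()[usable] // block_size_bp)
        _, inverse = np.unique(block_of, return_inverse=True)
        nb = np.bincount(inverse, weights=nb)
        db = np.bincount(inverse, weights=db)
        snps = np.bincount(inverse, weights=snps)
    g = len(nb)
    if g < 2:
        logger.warning("jackknife: only %d usable blocks, Z undefined", g)
        return out
    theta_hat = nb.sum() / db.sum()
    theta_del = (nb.sum() - nb) / (db.sum() - db)
    m = np.ones(g) if equal_weights else snps
    var = _busing_variance(theta_hat, theta_del, m)
    if var <= 0:
        logger.warning("jackknife: zero variance (statistic constant across "
                       "blocks), Z undefined")
        return out
    block_sd = np.sqrt(g * var)
    se = np.full(len(scan), np.nan)
    win_w = (np.ones(int(usable.sum())) if equal_weights
             else scan["n_snps"].to_numpy(dtype=float)[usable])
    se[usable] = block_sd * np.sqrt(m.mean() / win_w)
    null = np.broadcast_to(np.asarray(null_value, dtype=float), (len(scan),))
    out["se"] = se
    out["z"] = (scan[statistic].to_numpy(dtype=float) - null) / se
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_outliers(scan: pd.DataFrame, alpha_levels=(0.05, 0.01),
                  statistic: str = "d_f") -> pd.DataFrame:
    """Windows with q below the loosest level, tiered by significance.

    The returned table mirrors a genome-scan outlier report: window
    coordinates, the statistic, Z and the strictest level passed.
    """
    levels = sorted(alpha_levels, reverse=True)
    hits = scan[scan["q"] < levels[0]].copy()
    tier = []
    for q in hits["q"]:
        passed = [a for a in levels if q < a]
        tier.append(min(passed))
    hits["alpha"] = tier
    return hits[["start", "end", statistic, "z", "p", "q", "alpha"]] \
        .reset_index(drop=True)


def run_scan(matrix: HaplotypeMatrix, width_bp: int = 50_000,
             step_bp: int | None = None, smooth: bool = True,
             statistic: str = "d_f", null: str = "zero",
             region: tuple | None = None, equal_weights: bool = False,
             alpha_levels=(0.05, 0.01), chrom_length: int | None = None):
    """Full scan pipeline: windows -> jackknife Z -> BH q -> outliers.

    ``null="zero"`` tests every window against 0.  ``null="mean"``
    with ``region=(start, end)`` tests windows inside the region
    against the region's mean statistic (the inside-the-inversion null)
    and the remainder against 0.
    """
    scan = window_scan(matrix, width_bp, step_bp, smooth=smooth,
                       chrom_length=chrom_length)
    null_arr = np.zeros(len(scan))
    if null == "mean":
        if region is None:
            null_arr[:] = np.nanmean(scan[statistic])
        else:
            inside = (scan["start"] >= region[0]) & (scan["end"] <= region[1])
            null_arr[inside.to_numpy()] = np.nanmean(scan.loc[inside, statistic])
    elif null != "zero":
        raise ValueError("null must be 'zero' or 'mean'")
    scan = jackknife_z(scan, statistic=statistic, null_value=null_arr,
                       equal_weights=equal_weights)
    scan["p"] = 2.0 * sps.norm.sf(np.abs(scan["z"]))
    scan["q"] = bh_fdr(scan["p"])
    outliers = call_outliers(scan, alpha_levels=alpha_levels,
                             statistic=statistic)
    return scan, outliers


def write_scan_tsv(scan: pd.DataFrame, path):
    scan.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_outlier_bed(outliers: pd.DataFrame, path, chrom="chr"):
    with open(path, "w") as fh:
        for _, row in outliers.iterrows():
            fh.write(f"{chrom}\t{int(row.start)}\t{int(row.end)}\t"
                     f"q={row.q:.4g};alpha={row.alpha}\n")
    return path
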
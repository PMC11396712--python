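"""Simplified differential-expression screen for targeted count panels.

This is a deliberately simple, fully documented stand-in for vendor count
pipelines: housekeeping geometric-mean normalization, Welch t-tests on
log2(x+1) counts, Benjamini-Hochberg adjustment, and the conventional
significance cut (|fold change| >= 1.5 and adjusted p <= 0.05).  Fold
changes below 1 are reported as negative reciprocals (a halving is -2.0).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FC_CUT = 1.5
ALPHA = 0.05


def _split_counts(raw: pd.DataFrame):
    if "housekeeping" not in raw.columns:
        raise ValueError("count table needs a 'housekeeping' column")
    hk = raw["housekeeping"].astype(bool)
    counts = raw.drop(columns="housekeeping")
    return counts, hk


def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Housekeeping geometric-mean scaling (genes x samples).

    Per-sample factor = (cohort geometric mean of the per-sample
    housekeeping geometric means) / (sample housekeeping geometric mean);
    all counts in a sample are multiplied by its factor.  A housekeeping
    zero anywhere triggers a +0.5 pseudocount (logged) for the factor
    computation.  This is a documented simplification of proprietary panel
    normalizers.
    """
    counts, hk = _split_counts(raw)
    if hk.sum() < 1:
        raise ValueError("need at least one housekeeping gene")
    hk_counts = counts.loc[hk].to_numpy(dtype=float)
    if (hk_counts == 0).any():
        log.warning("housekeeping zeros found; using +0.5 pseudocount")
        hk_counts = hk_counts + 0.5
    sample_gm = np.exp(np.log(hk_counts).mean(axis=0))
    cohort_gm = np.exp(np.log(sample_gm).mean())
    factors = cohort_gm / sample_gm
    out = counts.astype(float) * factors[None, :]
    out.insert(0, "housekeeping", hk)
    return out


def de_test(
    norm: pd.DataFrame, groups, group_a, group_b, exclude_housekeeping: bool = True
) -> pd.DataFrame:
    """Per-gene Welch t-test of group A vs B on log2(x+1) normalized counts.

    log2fc = mean log2(A) - mean log2(B); zero variance in both groups with
    equal means gives p = 1.  Returns a tidy frame (gene, log2fc,
    fold_change, p) before multiplicity adjustment.
    """
    counts, hk = _split_counts(norm) if "housekeeping" in norm.columns else (norm, None)
    groups = np.asarray(groups)
    a = counts.loc[:, groups == group_a].to_numpy(dtype=float)
    b = counts.loc[:, groups == group_b].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fc = np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))
    out = pd.DataFrame(
        {"gene": counts.index, "log2fc": log2fc, "fold_change": fc, "p": p}
    )
    if exclude_housekeeping and hk is not None:
        out = out[~hk.to_numpy()].reset_index(drop=True)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_de(
    results: pd.DataFrame, fc_cut: float = FC_CUT, alpha: float = ALPHA
) -> pd.DataFrame:
    """Apply the significance conjunction |fold change| >= fc_cut and
    p_adj <= alpha (both inclusive); adds p_adj/significant columns."""
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (np.abs(out["fold_change"]) >= fc_cut) & (
        out["p_adj"] <= alpha
    )
    return out


def run_de_screen(
    raw: pd.DataFrame,
    groups,
    group_a,
    group_b,
    fc_cut: float = FC_CUT,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """normalize -> Welch t -> BH -> threshold, in one call."""
    norm = normalize_counts(raw)
    return threshold_de(de_test(norm, groups, group_a, group_b), fc_cut, alpha)


def hcluster_order(matrix: pd.DataFrame, method: str = "average") -> list:
    """Deterministic leaf order of columns under average-linkage clustering
    with 1 - Pearson distance (for heatmap export).

    A constant column has undefined correlation; its distance to every
    other column is set to 1 by convention.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.where(np.isnan(corr), 0.0, corr)
    const = sd == 0
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaves = hierarchy.leaves_list(z)
    return [matrix.columns[i] for i in leaves]
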
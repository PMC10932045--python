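"""Count filtering, normalization, and two-group differential expression.

The cohort-level DEG screen uses median-of-ratios size factors, a log2
(normalized + 1) transform, Welch's t test per gene and Benjamini-Hochberg
adjustment; a gene is called differentially expressed when
|log2FC| > lfc_threshold and adjusted p < alpha.  The pair-member filter of
the ceRNA screen uses the Kruskal-Wallis rank test instead, which is also
housed here, together with the 2^-ddCt qPCR utility.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger("cerna")

__all__ = [
    "DEResult",
    "KWResult",
    "filter_low_counts",
    "normalize_counts",
    "log2_expression",
    "de_test",
    "bh_adjust",
    "kruskal_wallis",
    "fold_change_ddct",
]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    adjusted_p: float
    is_deg: bool


@dataclass(frozen=True)
class KWResult:
    gene_id: str
    H: float
    p_value: float
    significant: bool


def filter_low_counts(m: CountMatrix, min_total: int = 1) -> CountMatrix:
    """Drop genes whose total count across samples is below ``min_total``."""
    totals = m.counts.sum(axis=1)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("all genes removed by the low-count filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("low-count filter removed %d gene(s)", dropped)
    return CountMatrix(m.counts.loc[keep], m.groups.copy())


def normalize_counts(m: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization.

    The geometric mean of each gene expressed in every sample is the
    reference; the size factor of a sample is the median ratio of its counts
    to that reference, and normalized counts are counts divided by the size
    factor.  If no gene is expressed in all samples, falls back to
    total-count scaling with a warning.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        logmeans = np.log(counts[all_pos]).mean(axis=1)
        ratios = np.log(counts[all_pos]) - logmeans[:, None]
        size = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene expressed in all samples; falling back to total-count scaling",
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        size = totals / totals.mean()
    factors = pd.Series(size, index=m.sample_ids, name="size_factor")
    normalized = m.counts / factors
    return normalized, factors


def log2_expression(m: CountMatrix) -> pd.DataFrame:
    """log2(normalized count + 1) expression matrix."""
    normalized, _ = normalize_counts(m)
    return np.log2(normalized + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    log2_expr: pd.DataFrame,
    groups: pd.Series,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> list[DEResult]:
    """Welch two-sample t test per gene on log2 expression.

    log2FC is mean(CASE) - mean(CTRL).  A gene with zero variance in both
    groups gets p = 1 when the means agree, p = 0 otherwise.
    """
    groups = groups.reindex(log2_expr.columns)
    case = log2_expr.loc[:, (groups == "CASE").to_numpy()].to_numpy()
    ctrl = log2_expr.loc[:, (groups == "CTRL").to_numpy()].to_numpy()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(case, ctrl, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (lfc == 0.0), 1.0, p)
    p = np.where(degenerate & (lfc != 0.0), 0.0, p)
    lfc = np.where(degenerate & (p == 1.0), 0.0, lfc)
    adj = bh_adjust(p)
    return [
        DEResult(
            gene_id=g,
            log2_fold_change=float(lfc[i]),
            p_value=float(p[i]),
            adjusted_p=float(adj[i]),
            is_deg=bool(abs(lfc[i]) > lfc_threshold and adj[i] < alpha),
        )
        for i, g in enumerate(log2_expr.index)
    ]


def kruskal_wallis(values, group_labels, alpha: float = 0.05, gene_id: str = "") -> KWResult:
    """Kruskal-Wallis H with midrank tie correction, chi-square p (k-1 df).

    The two-group case is permitted (rank-sum equivalent).  All-identical
    values give H = 0, p = 1.  The chi-square approximation is used for all
    sample sizes; it is anticonservative below ~5 observations per group.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    levels = pd.unique(group_labels)
    if len(levels) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    samples = [values[group_labels == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("kruskal_wallis groups must be non-empty")
    if np.all(values == values[0]):
        return KWResult(gene_id=gene_id, H=0.0, p_value=1.0, significant=False)
    H, p = sps.kruskal(*samples)
    return KWResult(
        gene_id=gene_id, H=float(H), p_value=float(p), significant=bool(p < alpha)
    )


def fold_change_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative abundance by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
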
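"""Signature-matrix deconvolution of bulk expression into cell-type fractions.

Follows the published support-vector-regression deconvolution sketch: mixture
and signature are z-scored, a linear nu-SVR is fitted for each nu in a small
grid, the fit with the lowest reconstruction RMSE wins, negative coefficients
are clipped and the rest renormalized to proportions.  An empirical p-value
comes from refitting gene-label-shuffled mixtures.  A plain non-negative
least-squares mode is available as a dependency-light alternative; both are
scale-invariant in the mixture.

Downstream, fractions are compared between groups with the Kruskal-Wallis
test and correlated gene-by-gene with expression (the infiltration analysis).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from .diffexpr import kruskal_wallis
from .stats import ZeroVarianceError, pearson

logger = logging.getLogger("cerna")

__all__ = [
    "FractionEstimate",
    "estimate_fractions",
    "compare_fractions",
    "correlate_expression_fractions",
]


@dataclass
class FractionEstimate:
    """Per-sample cell-type proportions with fit diagnostics."""

    fractions: pd.DataFrame          # samples x cell types, rows sum to 1
    fit_rmse: pd.Series
    fit_correlation: pd.Series
    permutation_p: pd.Series | None
    method: str


def _svr_fit(
    sz: np.ndarray, yz: np.ndarray, nu_grid, cost: float = 100.0
) -> tuple[np.ndarray, float, float]:
    # a high cost keeps the weakly identified coefficient direction that the
    # default slack penalty would shrink away when signature columns are
    # nearly collinear with the intercept (pronounced for few cell types)
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=cost)
        model.fit(sz, yz)
        w = model.coef_.ravel()
        recon = sz @ w + model.intercept_
        rmse = float(np.sqrt(np.mean((recon - yz) ** 2)))
        if best is None or rmse < best[1]:
            corr = float(np.corrcoef(recon, yz)[0, 1]) if np.std(recon) > 0 else 0.0
            best = (w, rmse, corr)
    return best


def _nnls_fit(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    w, _ = nnls(s, y)
    recon = s @ w
    rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
    corr = float(np.corrcoef(recon, y)[0, 1]) if np.std(recon) > 0 and np.std(y) > 0 else 0.0
    return w, rmse, corr


def _to_fractions(w: np.ndarray) -> np.ndarray:
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total == 0.0:
        logger.warning("all coefficients non-positive; returning uniform fractions")
        return np.full(w.size, 1.0 / w.size)
    return w / total


def estimate_fractions(
    mixture_expr: pd.DataFrame,
    signature: pd.DataFrame,
    method: str = "svr_ensemble",
    nu_grid=(0.25, 0.5, 0.75),
    n_permutations: int = 0,
    seed: int = 0,
    svr_cost: float = 100.0,
) -> FractionEstimate:
    """Estimate cell-type proportions of each mixture sample.

    ``mixture_expr`` is genes x samples on linear (non-log) scale;
    ``signature`` is marker genes x cell types.  Only shared genes are used;
    at least as many shared genes as cell types are required.  With
    ``n_permutations`` > 0 an empirical null of best-fit correlations is
    built from gene-label-shuffled mixtures (one shared null across samples)
    and each sample's p-value is the fraction of null fits at least as good
    as its observed fit.
    """
    if method not in ("svr_ensemble", "nnls"):
        raise ValueError(f"unknown method {method!r}")
    shared = [g for g in signature.index if g in set(mixture_expr.index)]
    k = signature.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} genes shared between mixture and signature; need >= {k}"
        )
    s = signature.loc[shared].to_numpy(dtype=float)
    m = mixture_expr.loc[shared].to_numpy(dtype=float)
    zero_cols = np.flatnonzero(m.std(axis=0) == 0)
    if zero_cols.size:
        bad = mixture_expr.columns[zero_cols[0]]
        raise ValueError(f"mixture sample {bad!r} is constant/all-zero over shared genes")
    sz = (s - s.mean()) / s.std()

    def fit_one(y: np.ndarray) -> tuple[np.ndarray, float, float]:
        if method == "svr_ensemble":
            yz = (y - y.mean()) / y.std()
            return _svr_fit(sz, yz, nu_grid, cost=svr_cost)
        return _nnls_fit(s, y / y.mean())

    frac, rmse, corr = [], [], []
    for j in range(m.shape[1]):
        w, e, c = fit_one(m[:, j])
        frac.append(_to_fractions(w))
        rmse.append(e)
        corr.append(c)
    samples = list(mixture_expr.columns)
    fractions = pd.DataFrame(frac, index=samples, columns=list(signature.columns))

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            y = m[:, i % m.shape[1]].copy()
            rng.shuffle(y)
            if y.std() == 0:
                null[i] = 1.0
                continue
            _, _, c = fit_one(y)
            null[i] = c
        pvals = [(1 + int(np.sum(null >= c))) / (n_permutations + 1) for c in corr]
        perm_p = pd.Series(pvals, index=samples, name="permutation_p")

    return FractionEstimate(
        fractions=fractions,
        fit_rmse=pd.Series(rmse, index=samples, name="fit_rmse"),
        fit_correlation=pd.Series(corr, index=samples, name="fit_correlation"),
        permutation_p=perm_p,
        method=method,
    )


def compare_fractions(fractions: pd.DataFrame, groups: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis group comparison per cell type.

    ``direction`` is median(CASE) - median(CTRL) of the fraction values.
    """
    groups = groups.reindex(fractions.index)
    labels = groups.to_numpy()
    if min(int((labels == "CASE").sum()), int((labels == "CTRL").sum())) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for ct in fractions.columns:
        vals = fractions[ct].to_numpy(dtype=float)
        res = kruskal_wallis(vals, labels, alpha=alpha, gene_id=str(ct))
        direction = float(
            np.median(vals[labels == "CASE"]) - np.median(vals[labels == "CTRL"])
        )
        rows.append(
            {"cell_type": ct, "H": res.H, "p": res.p_value,
             "direction": direction, "significant": res.significant}
        )
    return pd.DataFrame(rows).set_index("cell_type")


def correlate_expression_fractions(
    log2_expr: pd.DataFrame, fractions: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each (gene, cell type) expression-fraction pair.

    Zero-variance genes or fraction columns are reported as missing with a
    reason instead of a silent value.
    """
    if list(log2_expr.columns) != list(fractions.index):
        fractions = fractions.reindex(log2_expr.columns)
        if fractions.isna().any().any():
            raise ValueError("expression and fractions must cover the same samples")
    rows = []
    for gene in log2_expr.index:
        x = log2_expr.loc[gene].to_numpy(dtype=float)
        for ct in fractions.columns:
            y = fractions[ct].to_numpy(dtype=float)
            try:
                res = pearson(x, y)
                rows.append({"gene": gene, "cell_type": ct, "r": res.r, "p": res.p,
                             "significant": res.p < alpha, "note": ""})
            except ZeroVarianceError as exc:
                rows.append({"gene": gene, "cell_type": ct, "r": np.nan, "p": np.nan,
                             "significant": False, "note": str(exc)})
    return pd.DataFrame(rows)
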
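"""Weighted co-expression network core.

Implements the standard unsigned pipeline: the most-variable genes by median
absolute deviation are kept, |Pearson r|^beta adjacencies are scanned for the
smallest power giving an approximately scale-free connectivity distribution,
topological overlap is computed from the chosen adjacency, modules come from
average-linkage clustering of 1 - TOM with a static tree cut and a minimum
size, each module is summarized by its eigengene (first principal component
of the standardized member expression), and modules are related to the 0/1
disease trait by the Pearson/Student correlation test.  Modules are named by
the conventional color sequence in decreasing size order.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import corr_pvalue

logger = logging.getLogger("cerna")

UNASSIGNED = "unassigned"

# conventional module color sequence, assigned in decreasing size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

__all__ = [
    "ModuleSet",
    "select_top_mad",
    "scale_free_fit",
    "scan_soft_threshold",
    "pick_beta",
    "adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "select_key_modules",
    "UNASSIGNED",
]


@dataclass
class ModuleSet:
    """Gene -> module assignment with optional eigengene summaries.

    ``eigengenes`` is samples x modules with unit-variance columns oriented
    so the mean correlation with member genes is non-negative;
    ``variance_explained`` is the leading-eigenvalue share per module.
    """

    assignment: dict[str, str]
    eigengenes: pd.DataFrame | None = None
    variance_explained: dict[str, float] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        out: list[str] = []
        for label in self.assignment.values():
            if label != UNASSIGNED and label not in out:
                out.append(label)
        return out

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.assignment.items() if m == module]

    @property
    def sizes(self) -> dict[str, int]:
        return {m: len(self.genes_in(m)) for m in self.modules}


def select_top_mad(log2_expr: pd.DataFrame, k: int = 5000, statistic: str = "median") -> pd.DataFrame:
    """Keep the top-k genes by (median or mean) absolute deviation.

    Ties in the deviation are broken by gene id, lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = log2_expr.to_numpy(dtype=float)
    if statistic == "median":
        dev = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    elif statistic == "mean":
        dev = np.mean(np.abs(x - np.mean(x, axis=1, keepdims=True)), axis=1)
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    order = sorted(
        range(len(dev)), key=lambda i: (-dev[i], str(log2_expr.index[i]))
    )
    keep = sorted(order[: min(k, len(order))])
    return log2_expr.iloc[keep]


def _gene_correlation(expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} zero-variance gene(s) before correlation",
            stacklevel=3,
        )
    sub = expr.loc[ok]
    r = np.corrcoef(sub.to_numpy(dtype=float))
    return sub, np.clip(r, -1.0, 1.0)


def scale_free_fit(connectivity, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity vector.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    log10(proportion per bin) is regressed on log10(mean connectivity per
    bin) over non-empty bins.  Returns (R^2 x -sign(slope), slope).
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        n_in = int(mask.sum())
        if n_in == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(n_in / k.size))
    if len(xs) < 2:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = float(np.sum((ys - fitted) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(r2 * -np.sign(slope)), float(slope)


def scan_soft_threshold(expr: pd.DataFrame, beta_range=tuple(range(1, 21))) -> pd.DataFrame:
    """Scale-free fit index and connectivity summaries per candidate power."""
    if expr.shape[0] < 3:
        raise ValueError("soft-threshold scan needs >= 3 genes")
    _, r = _gene_correlation(expr)
    absr = np.abs(r)
    np.fill_diagonal(absr, 0.0)
    rows = []
    for beta in beta_range:
        a = absr**beta
        k = a.sum(axis=1)
        r2s, slope = scale_free_fit(k)
        rows.append(
            {
                "beta": int(beta),
                "scale_free_r2_signed": r2s,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
                "max_connectivity": float(k.max()),
            }
        )
    return pd.DataFrame(rows).set_index("beta")


def pick_beta(scan: pd.DataFrame, r2_target: float = 0.85) -> tuple[int, bool]:
    """Smallest power whose signed fit index reaches the target.

    Falls back to the power maximizing the index (``warned`` True) when no
    power reaches it.
    """
    if scan.empty:
        raise ValueError("empty soft-threshold scan")
    ok = scan.index[scan["scale_free_r2_signed"] >= r2_target]
    if len(ok):
        return int(ok.min()), False
    best = int(scan["scale_free_r2_signed"].idxmax())
    warnings.warn(
        f"no power reached scale-free R^2 {r2_target}; using beta={best} "
        f"(R^2={scan.loc[best, 'scale_free_r2_signed']:.3f})",
        stacklevel=2,
    )
    return best, True


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned power adjacency a_ij = |r_ij|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.to_numpy(dtype=float)
    if np.any(x.std(axis=1) == 0):
        bad = expr.index[x.std(axis=1) == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}; filter before adjacency")
    r = np.clip(np.corrcoef(x), -1.0, 1.0)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(a: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the whole-network connectivity of gene i; TOM_ii = 1.
    """
    av = a.to_numpy(dtype=float)
    if av.shape[0] != av.shape[1] or not np.allclose(av, av.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    if av.min() < -1e-12 or av.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    n = av.shape[0]
    k = av.sum(axis=1) - np.diag(av)
    shared = av @ av - np.diag(av)[:, None] * av - av * np.diag(av)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - av
    np.fill_diagonal(denom, 1.0)
    tom = (shared + av) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def cluster_modules(tom_dissimilarity: pd.DataFrame, min_module_size: int = 30) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    The tree is cut at 0.99 x the maximum merge height; resulting clusters
    of at least ``min_module_size`` genes become modules named by the color
    sequence in decreasing size order (ties broken by the lexicographically
    smallest member), everything else is unassigned.
    """
    d = tom_dissimilarity.to_numpy(dtype=float)
    genes = list(tom_dissimilarity.index)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned", stacklevel=2)
        return ModuleSet({g: UNASSIGNED for g in genes})
    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    z = linkage(squareform(dsym, checks=False), method="average")
    cut = 0.99 * z[:, 2].max()
    flat = fcluster(z, t=cut, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gene, c in zip(genes, flat):
        clusters.setdefault(int(c), []).append(gene)
    big = [m for m in clusters.values() if len(m) >= min_module_size]
    big.sort(key=lambda m: (-len(m), min(m)))
    assignment = {g: UNASSIGNED for g in genes}
    for i, members in enumerate(big):
        label = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        for g in members:
            assignment[g] = label
    return ModuleSet(assignment)


def module_eigengenes(log2_expr: pd.DataFrame, assignment: dict[str, str]) -> ModuleSet:
    """First-principal-component eigengene per module.

    Member genes are standardized across samples; the eigengene is the
    leading PC score vector scaled to unit variance and oriented so its mean
    correlation with member genes is non-negative (tie: positive correlation
    with the lexicographically first member).  Constant genes are excluded
    from the PC with a warning.
    """
    samples = list(log2_expr.columns)
    modules: list[str] = []
    for label in assignment.values():
        if label != UNASSIGNED and label not in modules:
            modules.append(label)
    eig = {}
    var_exp = {}
    for module in modules:
        members = sorted(g for g, m in assignment.items() if m == module)
        if len(members) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 genes")
        x = log2_expr.loc[members].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.all():
            warnings.warn(
                f"module {module!r}: excluding {int((~ok).sum())} constant gene(s) from PC",
                stacklevel=2,
            )
            x = x[ok]
            members = [g for g, keep in zip(members, ok) if keep]
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        pc = pc / pc.std(ddof=1)
        corrs = np.array([np.corrcoef(pc, row)[0, 1] for row in z])
        mean_corr = corrs.mean()
        if mean_corr < 0 or (mean_corr == 0 and corrs[0] < 0):
            pc = -pc
        eig[module] = pc
        var_exp[module] = float(s[0] ** 2 / np.sum(s**2))
    eigdf = pd.DataFrame(eig, index=samples)
    return ModuleSet(dict(assignment), eigengenes=eigdf, variance_explained=var_exp)


def module_trait_correlation(eigengenes: pd.DataFrame, trait) -> pd.DataFrame:
    """Pearson r and Student-test p of each eigengene against the 0/1 trait."""
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    if n < 3:
        raise ValueError("module-trait correlation needs >= 3 samples")
    rows = []
    for module in eigengenes.columns:
        r = float(np.corrcoef(eigengenes[module].to_numpy(), trait)[0, 1])
        r = max(-1.0, min(1.0, r))
        if abs(r) > 1.0 - 1e-12:
            r = float(np.sign(r))
        rows.append({"module": module, "r": r, "p": corr_pvalue(r, n)})
    return pd.DataFrame(rows).set_index("module")


def select_key_modules(table: pd.DataFrame) -> tuple[str | None, str | None]:
    """Strongest positively and negatively trait-correlated modules.

    Ties are broken lexicographically; if every module correlates with the
    trait in the same direction, the other slot is empty (None).
    """
    if table.empty:
        raise ValueError("no modules to select from")
    r = table["r"]
    max_r, min_r = r.max(), r.min()
    pos = min(r.index[r == max_r]) if max_r > 0 else None
    neg = min(r.index[r == min_r]) if min_r < 0 else None
    return pos, neg
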
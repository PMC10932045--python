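"""Synthetic two-cohort study generator with planted, recoverable truth.

Counts are negative binomial around log-normal baselines.  Co-expression
modules come from a one-factor model per module (within-module latent
correlation = loading^2); two modules carry opposite-sign group effects so
they become the trait-associated key modules.  Planted ceRNA pairs are key
module members that share an extra dedicated latent factor, whose loading is
calibrated against pilot cohorts so the population correlation of log2
normalized expression equals ``pair_target_corr``.
Decoy pair classes fail exactly one screening criterion each: no shared
miRNA, low correlation (members straddle the two oppositely-regulated
modules), no differential expression, or no group effect in the validation
cohort.  Cell-type mixtures from a block signature are embedded as extra
marker genes so the deconvolution stage is exercised end to end.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneAnnotation,
    InteractionCatalog,
    write_annotation,
    write_catalog,
    write_count_matrix,
    write_gene_list,
    write_signature,
)

__all__ = [
    "SynthParams",
    "CohortTruth",
    "SyntheticStudy",
    "generate_cohorts",
    "generate_interaction_catalog",
    "generate_mixtures",
    "generate_study",
    "write_study",
]

# generator design constants (see docs/methods.md)
SIGNAL_SD = 1.25            # sd of the latent log2 signal, log2 units
PAIR_BASELINE_RANGE = (6.0, 9.0)   # planted pair members are abundant genes
DE_FRACTION = 1.0           # share of regular key-module genes carrying the group effect
SIZE_FACTOR_RANGE = (0.5, 2.0)     # per-sample library-size factor, log-uniform
SIGNATURE_HIGH = 10.0       # marker expression in its own cell type
MARKER_COUNT_SCALE = 30.0   # mixture expression -> expected marker counts
DIRICHLET_ALPHA = 2.0       # fraction prior per cell type
TILT_ALPHA = 6.0            # boosted alpha of the group-shifted cell type in CASE
IMMUNE_MODULE_FRACTION = 0.2
IMMUNE_BACKGROUND_FRACTION = 0.1
OTHER_BIOTYPE_FRACTION = 0.05
_E_INV_SIZE = 1.08          # E[1/s] for the log-uniform size factor
_LN2_SQ = np.log(2.0) ** 2

PAIR_CLASSES = ("true", "no_mirna", "low_corr", "no_de", "no_replication")


@dataclass
class SynthParams:
    """Study conditions of the synthetic cohorts."""

    n_genes: int = 1200
    n_lnc: int = 250
    n_samples_per_group: tuple[int, int] = (20, 20)  # (train, valid), per group
    n_modules: int = 4
    module_size: int = 60
    factor_loading: float = 0.9
    group_effect: float = 2.0          # log2 units
    nb_dispersion: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)
    n_true_pairs: int = 5
    n_decoy_no_mirna: int = 3
    n_decoy_low_corr: int = 3
    n_decoy_no_de: int = 3
    n_decoy_no_replication: int = 3
    pair_target_corr: float = 0.85
    n_celltypes: int = 8
    markers_per_type: int = 25
    mixture_noise_sd: float = 1.0      # 0.1 x the in-type signature expression
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_lnc", "module_size", "n_celltypes", "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules < 0 or min(self.n_samples_per_group) < 2:
            raise ValueError("need n_modules >= 0 and >= 2 samples per group")
        if not (0.0 < self.pair_target_corr < 1.0):
            raise ValueError("pair_target_corr must be in (0, 1)")
        if not (0.0 <= self.factor_loading <= 1.0):
            raise ValueError("factor_loading must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_pairs_total > 0 and self.n_modules < 1:
            raise ValueError("planted pairs require at least one module")
        if self.n_decoy_low_corr > 0 and self.n_modules < 2:
            raise ValueError("low-correlation decoys require at least two modules")
        if self.n_modules * self.module_size + 2 * self.n_pairs_total > self.n_genes:
            raise ValueError(
                "infeasible layout: n_modules x module_size plus pair genes exceeds n_genes"
            )

    @property
    def n_pairs_total(self) -> int:
        return (self.n_true_pairs + self.n_decoy_no_mirna + self.n_decoy_low_corr
                + self.n_decoy_no_de + self.n_decoy_no_replication)

    def to_dict(self) -> dict:
        return {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }


@dataclass
class CohortTruth:
    """Planted ground truth emitted alongside the synthetic cohorts."""

    module_of_gene: dict[str, int | None]
    true_pairs: set[tuple[str, str]]
    decoys: dict[str, set[tuple[str, str]]]
    de_genes: set[str]
    de_genes_valid: set[str]
    shared_mirnas_of_pair: dict[tuple[str, str], frozenset] = field(default_factory=dict)
    true_fractions: pd.DataFrame | None = None
    immune_genes: set[str] = field(default_factory=set)
    biotype_of_gene: dict[str, str] = field(default_factory=dict)
    train_groups: pd.Series | None = None

    def all_pairs(self) -> dict[str, set[tuple[str, str]]]:
        out = {"true": set(self.true_pairs)}
        out.update({k: set(v) for k, v in self.decoys.items()})
        return out


@dataclass
class SyntheticStudy:
    train: CountMatrix
    valid: CountMatrix
    annotation: GeneAnnotation
    truth: CohortTruth
    immune_genes: set[str]
    catalog: InteractionCatalog
    signature: pd.DataFrame
    mixture: pd.DataFrame        # continuous marker expression, train samples
    params: SynthParams


# ---------------------------------------------------------------------------
# gene layout
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    baseline: float
    module: int | None
    a_m: float
    a_p: float
    u: float
    pair_factor: int | None
    de_train: int       # -1, 0, +1
    de_valid: int
    biotype: str = "mRNA"


def _pair_loadings(
    p: SynthParams, b1: float, b2: float, shared_group_effect: bool,
) -> tuple[float, float, float]:
    """Initial module/pair loadings targeting the pair correlation.

    Delta-method start: solves rho* = (tau^2 c + E) / (tau^2 + E + v) for
    the shared latent-variance fraction c, with E the shared group-effect
    variance and v a first-order count-noise variance.  The loadings are
    then refined against pilot cohorts (see ``_calibrate_pair_loadings``),
    because counting noise, the log pseudocount and the median-of-ratios
    normalization all attenuate the planted correlation nonlinearly.
    """
    tau2 = SIGNAL_SD**2
    mu_min = 2.0 ** min(b1, b2)
    v0 = (_E_INV_SIZE / mu_min + p.nb_dispersion) / _LN2_SQ
    e = (p.group_effect**2) / 4.0 if shared_group_effect else 0.0
    a_m2 = p.factor_loading**2
    c = float(np.clip((p.pair_target_corr * (tau2 + e + v0) - e) / tau2, a_m2, 0.995))
    a_p = float(np.sqrt(max(c - a_m2, 0.0)))
    u = float(max(1.0 - c, 0.005))
    return p.factor_loading, a_p, u


def _calibrate_pair_loadings(
    p: SynthParams,
    plans: list["_GenePlan"],
    rng: np.random.Generator,
    n_pilot_per_group: int = 300,
    n_iterations: int = 4,
) -> None:
    """Refine pair-factor loadings so the pair correlation measured on a
    pilot cohort -- after the pipeline's own median-of-ratios normalization
    and log2(x+1) transform -- hits ``pair_target_corr``.

    Each iteration samples a fresh pilot cohort at large n, measures every
    factor-sharing pair's realized correlation, and takes a damped secant
    step on its shared-variance fraction c (bounded by the module loading
    below and 0.995 above).
    """
    from .diffexpr import filter_low_counts, log2_expression

    by_factor: dict[int, list[_GenePlan]] = {}
    for pl in plans:
        if pl.pair_factor is not None:
            by_factor.setdefault(pl.pair_factor, []).append(pl)
    if not by_factor:
        return
    a_m2 = p.factor_loading**2
    for _ in range(n_iterations):
        pilot = _sample_cohort(p, plans, n_pilot_per_group, "P", rng, valid=False)
        le = log2_expression(filter_low_counts(pilot))
        for members in by_factor.values():
            g1, g2 = members[0], members[1]
            r_obs = float(np.corrcoef(le.loc[g1.gene_id], le.loc[g2.gene_id])[0, 1])
            c_old = g1.a_m**2 + g1.a_p**2
            c_new = float(np.clip(c_old + (p.pair_target_corr - r_obs) * 1.6, a_m2, 0.995))
            for pl in members:
                pl.a_p = float(np.sqrt(max(c_new - a_m2, 0.0)))
                pl.u = float(max(1.0 - c_new, 0.005))


def _plan_genes(p: SynthParams, rng: np.random.Generator) -> tuple[list[_GenePlan], CohortTruth]:
    lo, hi = p.baseline_log_mean_range
    plans: list[_GenePlan] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        gid = f"G{idx:04d}"
        idx += 1
        return gid

    module_of: dict[str, int | None] = {}
    de_train: set[str] = set()
    de_valid: set[str] = set()

    # regular module members; modules 0 (+) and 1 (-) carry partial group effects
    for m in range(p.n_modules):
        sign = +1 if m == 0 else (-1 if m == 1 else 0)
        for _ in range(p.module_size):
            gid = next_id()
            de = sign if (sign != 0 and rng.random() < DE_FRACTION) else 0
            plans.append(_GenePlan(
                gene_id=gid, baseline=float(rng.uniform(lo, hi)), module=m,
                a_m=p.factor_loading, a_p=0.0, u=1.0 - p.factor_loading**2,
                pair_factor=None, de_train=de, de_valid=de,
            ))
            module_of[gid] = m
            if de:
                de_train.add(gid)
                de_valid.add(gid)

    # planted pairs and decoy pairs
    pair_counts = {
        "true": p.n_true_pairs,
        "no_mirna": p.n_decoy_no_mirna,
        "low_corr": p.n_decoy_low_corr,
        "no_de": p.n_decoy_no_de,
        "no_replication": p.n_decoy_no_replication,
    }
    pairs: dict[str, set[tuple[str, str]]] = {c: set() for c in PAIR_CLASSES}
    pf = 0
    blo, bhi = PAIR_BASELINE_RANGE
    for cls in PAIR_CLASSES:
        for _ in range(pair_counts[cls]):
            b1, b2 = rng.uniform(blo, bhi, size=2)
            lnc, mrna = next_id(), next_id()
            if cls == "low_corr":
                # members straddle the two oppositely regulated key modules
                for gid, b, mod, sign in ((lnc, b1, 0, +1), (mrna, b2, 1, -1)):
                    plans.append(_GenePlan(
                        gene_id=gid, baseline=float(b), module=mod,
                        a_m=p.factor_loading, a_p=0.0, u=1.0 - p.factor_loading**2,
                        pair_factor=None, de_train=sign, de_valid=sign,
                    ))
                    module_of[gid] = mod
                    de_train.add(gid)
                    de_valid.add(gid)
            else:
                de_t = 0 if cls == "no_de" else +1
                de_v = 0 if cls in ("no_de", "no_replication") else +1
                a_m, a_p, u = _pair_loadings(p, b1, b2, de_t != 0)
                for gid, b in ((lnc, b1), (mrna, b2)):
                    plans.append(_GenePlan(
                        gene_id=gid, baseline=float(b), module=0,
                        a_m=a_m, a_p=a_p, u=u, pair_factor=pf,
                        de_train=de_t, de_valid=de_v,
                    ))
                    module_of[gid] = 0
                    if de_t:
                        de_train.add(gid)
                    if de_v:
                        de_valid.add(gid)
                pf += 1
            plans[-2].biotype = "lncRNA"
            plans[-1].biotype = "mRNA"
            pairs[cls].add((lnc, mrna))

    # background genes: independent noise, no group effect
    while idx < p.n_genes:
        plans.append(_GenePlan(
            gene_id=next_id(), baseline=float(rng.uniform(lo, hi)), module=None,
            a_m=0.0, a_p=0.0, u=1.0, pair_factor=None, de_train=0, de_valid=0,
        ))
        module_of[plans[-1].gene_id] = None

    # biotypes: pair members are fixed; fill the rest to n_lnc lncRNAs,
    # a small share of "other", mRNA otherwise
    pair_members = {g for prs in pairs.values() for pr in prs for g in pr}
    unpaired = [pl for pl in plans if pl.gene_id not in pair_members]
    n_pair_lnc = sum(len(v) for v in pairs.values())
    n_extra_lnc = max(p.n_lnc - n_pair_lnc, 0)
    shuffled = list(unpaired)
    rng.shuffle(shuffled)
    for pl in shuffled[:n_extra_lnc]:
        pl.biotype = "lncRNA"
    rest = shuffled[n_extra_lnc:]
    n_other = int(OTHER_BIOTYPE_FRACTION * len(rest))
    for pl in rest[:n_other]:
        pl.biotype = "other"

    # immune list: every pair member plus random module/background genes
    immune: set[str] = set(pair_members)
    module_regular = [pl.gene_id for pl in unpaired if pl.module is not None]
    background = [pl.gene_id for pl in unpaired if pl.module is None]
    if module_regular:
        immune.update(rng.choice(module_regular,
                                 size=int(IMMUNE_MODULE_FRACTION * len(module_regular)),
                                 replace=False))
    if background:
        immune.update(rng.choice(background,
                                 size=int(IMMUNE_BACKGROUND_FRACTION * len(background)),
                                 replace=False))

    truth = CohortTruth(
        module_of_gene=module_of,
        true_pairs=pairs["true"],
        decoys={c: pairs[c] for c in PAIR_CLASSES if c != "true"},
        de_genes=de_train,
        de_genes_valid=de_valid,
        immune_genes=immune,
        biotype_of_gene={pl.gene_id: pl.biotype for pl in plans},
    )
    return plans, truth


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def _sample_cohort(
    p: SynthParams,
    plans: list[_GenePlan],
    n_per_group: int,
    prefix: str,
    rng: np.random.Generator,
    valid: bool,
) -> CountMatrix:
    n_samples = 2 * n_per_group
    sample_ids = [f"{prefix}{i:02d}" for i in range(n_samples)]
    groups = pd.Series(["CTRL"] * n_per_group + ["CASE"] * n_per_group, index=sample_ids)
    z = (groups.to_numpy() == "CASE").astype(float)
    size = np.exp(rng.uniform(np.log(SIZE_FACTOR_RANGE[0]), np.log(SIZE_FACTOR_RANGE[1]),
                              size=n_samples))
    n_pf = max([pl.pair_factor for pl in plans if pl.pair_factor is not None] + [-1]) + 1
    f_mod = rng.normal(size=(max(p.n_modules, 1), n_samples))
    f_pair = rng.normal(size=(max(n_pf, 1), n_samples))
    log2_mean = np.empty((len(plans), n_samples))
    for i, pl in enumerate(plans):
        signal = np.sqrt(pl.u) * rng.normal(size=n_samples)
        if pl.module is not None and pl.a_m > 0:
            signal = signal + pl.a_m * f_mod[pl.module]
        if pl.pair_factor is not None and pl.a_p > 0:
            signal = signal + pl.a_p * f_pair[pl.pair_factor]
        de = pl.de_valid if valid else pl.de_train
        log2_mean[i] = pl.baseline + SIGNAL_SD * signal + de * p.group_effect * z
    mu = (2.0**log2_mean) * size[None, :]
    r = 1.0 / p.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=[pl.gene_id for pl in plans], columns=sample_ids)
    return CountMatrix(df, groups)


def generate_cohorts(
    params: SynthParams,
) -> tuple[CountMatrix, CountMatrix, GeneAnnotation, CohortTruth]:
    """Training and validation count matrices with shared planted truth.

    Both cohorts are drawn independently from the same gene plan; the
    no-replication decoy class loses its group effect in the validation
    cohort only.
    """
    rng_plan = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    plans, truth = _plan_genes(params, rng_plan)
    rng_cal = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    _calibrate_pair_loadings(params, plans, rng_cal)
    rng_train = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    rng_valid = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    train = _sample_cohort(params, plans, params.n_samples_per_group[0], "T", rng_train, valid=False)
    valid = _sample_cohort(params, plans, params.n_samples_per_group[1], "V", rng_valid, valid=True)
    annotation = GeneAnnotation(dict(truth.biotype_of_gene))
    truth.train_groups = train.groups.copy()
    return train, valid, annotation, truth


# ---------------------------------------------------------------------------
# interaction catalog
# ---------------------------------------------------------------------------

def generate_interaction_catalog(
    truth: CohortTruth,
    params: SynthParams,
    n_background_mirnas: int = 30,
    n_background_edges: int = 300,
) -> InteractionCatalog:
    """miRNA-target catalog honouring the planted pair classes.

    Every planted pair except the no-shared-miRNA decoys gets 1-2 dedicated
    shared miRNAs; no-shared-miRNA decoy members get private, disjoint
    miRNAs; random background edges are added but never in a way that gives
    a no-shared-miRNA decoy a shared miRNA.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 4]))
    edges: set[tuple[str, str, str]] = set()
    neighbors: dict[str, set[str]] = {}

    def add_edge(mirna: str, gene: str) -> None:
        biotype = truth.biotype_of_gene.get(gene, "mRNA")
        if biotype == "other":
            return
        edges.add((mirna, gene, biotype))
        neighbors.setdefault(gene, set()).add(mirna)

    pair_classes = truth.all_pairs()
    mi = 0
    for cls in PAIR_CLASSES:
        for lnc, mrna in sorted(pair_classes.get(cls, set())):
            if cls == "no_mirna":
                for gene in (lnc, mrna):
                    for _ in range(2):
                        add_edge(f"miR-X{mi:03d}", gene)
                        mi += 1
                truth.shared_mirnas_of_pair[(lnc, mrna)] = frozenset()
            else:
                shared = []
                for _ in range(int(rng.integers(1, 3))):
                    mirna = f"miR-P{mi:03d}"
                    mi += 1
                    add_edge(mirna, lnc)
                    add_edge(mirna, mrna)
                    shared.append(mirna)
                truth.shared_mirnas_of_pair[(lnc, mrna)] = frozenset(shared)

    forbidden = sorted(pair_classes.get("no_mirna", set()))
    targets = sorted(g for g, b in truth.biotype_of_gene.items() if b in ("mRNA", "lncRNA"))
    pool = [f"miR-B{i:03d}" for i in range(n_background_mirnas)]
    attempts = 0
    added = 0
    while added < n_background_edges and attempts < 20 * n_background_edges:
        attempts += 1
        mirna = pool[int(rng.integers(len(pool)))]
        gene = targets[int(rng.integers(len(targets)))]
        clash = any(
            (gene == a and mirna in neighbors.get(b, set()))
            or (gene == b and mirna in neighbors.get(a, set()))
            for a, b in forbidden
        )
        if clash:
            continue
        before = len(edges)
        add_edge(mirna, gene)
        added += len(edges) - before
    return InteractionCatalog(edges)


# ---------------------------------------------------------------------------
# signature and mixtures
# ---------------------------------------------------------------------------

def generate_mixtures(
    params: SynthParams,
    truth: CohortTruth,
    groups: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Block signature, noisy linear mixtures, and the true fractions.

    Markers are high (``SIGNATURE_HIGH``) in their own cell type and low
    elsewhere; fractions are Dirichlet with the first cell type up-tilted in
    CASE samples, so a group difference and a correlation with the planted
    disease signal exist; mixtures are signature x fractions plus truncated
    Gaussian noise.
    """
    if groups is None:
        groups = truth.train_groups
    if groups is None:
        raise ValueError("sample groups required to generate mixtures")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 5]))
    k, m = params.n_celltypes, params.markers_per_type
    genes = [f"MK{t:02d}_{j:02d}" for t in range(k) for j in range(m)]
    celltypes = [f"CT{t:02d}" for t in range(k)]
    sig = rng.uniform(0.0, 1.0, size=(k * m, k))
    for t in range(k):
        sig[t * m:(t + 1) * m, t] = SIGNATURE_HIGH
    signature = pd.DataFrame(sig, index=genes, columns=celltypes)

    alpha = np.full(k, DIRICHLET_ALPHA)
    fracs = np.empty((len(groups), k))
    for i, g in enumerate(groups):
        a = alpha.copy()
        if g == "CASE":
            a[0] = TILT_ALPHA
        fracs[i] = rng.dirichlet(a)
    fractions = pd.DataFrame(fracs, index=list(groups.index), columns=celltypes)

    clean = sig @ fracs.T
    noisy = np.clip(clean + rng.normal(0.0, params.mixture_noise_sd, size=clean.shape), 0.0, None)
    mixture = pd.DataFrame(noisy, index=genes, columns=list(groups.index))
    return signature, mixture, fractions


def _embed_markers(
    cohort: CountMatrix, mixture: pd.DataFrame, rng: np.random.Generator
) -> CountMatrix:
    size = np.exp(rng.uniform(np.log(SIZE_FACTOR_RANGE[0]), np.log(SIZE_FACTOR_RANGE[1]),
                              size=cohort.counts.shape[1]))
    mu = mixture.to_numpy() * MARKER_COUNT_SCALE * size[None, :]
    counts = rng.poisson(mu)
    marker_df = pd.DataFrame(counts, index=mixture.index, columns=cohort.sample_ids)
    return CountMatrix(pd.concat([cohort.counts, marker_df]), cohort.groups.copy())


def generate_study(params: SynthParams) -> SyntheticStudy:
    """Full synthetic study: cohorts, annotation, immune list, catalog,
    signature, and cell-type marker genes embedded in both count matrices."""
    train, valid, annotation, truth = generate_cohorts(params)
    catalog = generate_interaction_catalog(truth, params)
    signature, mixture_train, fractions = generate_mixtures(params, truth, train.groups)
    _, mixture_valid, _ = generate_mixtures(params, truth, valid.groups)
    truth.true_fractions = fractions
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 6]))
    train = _embed_markers(train, mixture_train, rng)
    valid = _embed_markers(valid, mixture_valid, rng)
    for g in mixture_train.index:
        annotation.biotype[g] = "other"
        truth.biotype_of_gene[g] = "other"
        truth.module_of_gene[g] = None
    return SyntheticStudy(
        train=train, valid=valid, annotation=annotation, truth=truth,
        immune_genes=set(truth.immune_genes), catalog=catalog,
        signature=signature, mixture=mixture_train, params=params,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write every pipeline input plus truth.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(study.train, out / "counts_train.tsv", out / "groups_train.tsv")
    write_count_matrix(study.valid, out / "counts_valid.tsv", out / "groups_valid.tsv")
    write_annotation(study.annotation, out / "annotation.tsv")
    write_gene_list(study.immune_genes, out / "immune.txt")
    write_catalog(study.catalog, out / "catalog.tsv")
    write_signature(study.signature, out / "signature.tsv")
    truth = study.truth
    payload = {
        "params": study.params.to_dict(),
        "module_of_gene": {g: m for g, m in sorted(truth.module_of_gene.items())},
        "true_pairs": sorted(map(list, truth.true_pairs)),
        "decoys": {c: sorted(map(list, v)) for c, v in sorted(truth.decoys.items())},
        "de_genes": sorted(truth.de_genes),
        "de_genes_valid": sorted(truth.de_genes_valid),
        "shared_mirnas_of_pair": {
            f"{a}|{b}": sorted(v) for (a, b), v in sorted(truth.shared_mirnas_of_pair.items())
        },
        "true_fractions": (
            truth.true_fractions.round(10).to_dict(orient="index")
            if truth.true_fractions is not None else None
        ),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
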
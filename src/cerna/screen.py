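"""Immune-related ceRNA pair screening.

Genes of the trait-associated key modules are intersected with the
immune-related gene list and split by biotype; every immune lncRNA x immune
mRNA combination is then pushed through the three pair criteria: positive
expression correlation above the cutoff, at least one shared miRNA in the
interaction catalog, and Kruskal-Wallis differential expression of both
members between CASE and CTRL.  Dropped pairs are kept with machine-readable
drop reasons so the cascade is auditable, and the surviving pairs form a
typed lncRNA-miRNA-mRNA network.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

from .diffexpr import kruskal_wallis
from .io import GeneAnnotation, InteractionCatalog
from .stats import pearson

logger = logging.getLogger("cerna")

__all__ = [
    "CandidatePair",
    "CeRNANetwork",
    "split_immune_genes",
    "correlate_pairs",
    "shared_mirna_filter",
    "de_filter",
    "summarize_pairs",
    "build_cerna_network",
    "load_table1_pairs",
]


@dataclass(frozen=True)
class CandidatePair:
    lncRNA_id: str
    mRNA_id: str
    r_train: float
    p_corr_train: float
    shared_mirnas: frozenset[str] = frozenset()
    kw_p_lnc: float | None = None
    kw_p_mrna: float | None = None
    status: str = "candidate"

    @property
    def key(self) -> tuple[str, str]:
        return (self.lncRNA_id, self.mRNA_id)


@dataclass
class CeRNANetwork:
    """Typed ceRNA graph: lncRNA-miRNA and miRNA-mRNA edges of passing pairs."""

    pairs: list[CandidatePair]
    nodes: list[tuple[str, str]] = field(default_factory=list)  # (id, type)
    edges: list[tuple[str, str]] = field(default_factory=list)


def split_immune_genes(
    key_module_genes, annotation: GeneAnnotation, immune_list
) -> tuple[set[str], set[str]]:
    """Intersect key-module genes with the immune list, split by biotype."""
    overlap = set(key_module_genes) & set(immune_list)
    lnc = {g for g in overlap if annotation.of(g) == "lncRNA"}
    mrna = {g for g in overlap if annotation.of(g) == "mRNA"}
    logger.info("immune intersection: %d lncRNAs, %d mRNAs", len(lnc), len(mrna))
    return lnc, mrna


def correlate_pairs(
    log2_expr: pd.DataFrame,
    lncRNAs,
    mRNAs,
    cutoff: float = 0.75,
    absolute: bool = False,
) -> list[CandidatePair]:
    """Evaluate all lncRNA x mRNA combinations; keep r > cutoff.

    The criterion is a strict inequality on the positive correlation (set
    ``absolute`` to screen on |r| instead).  All combinations are recorded;
    failures carry status ``dropped:low_correlation``.
    """
    missing = (set(lncRNAs) | set(mRNAs)) - set(log2_expr.index)
    if missing:
        raise KeyError(f"gene(s) missing from expression: {sorted(missing)}")
    out = []
    for lnc in sorted(lncRNAs):
        x = log2_expr.loc[lnc].to_numpy()
        for mrna in sorted(mRNAs):
            if lnc == mrna:
                continue
            res = pearson(x, log2_expr.loc[mrna].to_numpy())
            stat = abs(res.r) if absolute else res.r
            status = "candidate" if stat > cutoff else "dropped:low_correlation"
            out.append(
                CandidatePair(
                    lncRNA_id=lnc, mRNA_id=mrna, r_train=res.r,
                    p_corr_train=res.p, status=status,
                )
            )
    return out


def _live(pairs) -> list[CandidatePair]:
    return [p for p in pairs if not p.status.startswith("dropped")]


def shared_mirna_filter(pairs, catalog: InteractionCatalog) -> list[CandidatePair]:
    """Populate shared miRNA sets; drop pairs with a disjoint neighbourhood."""
    out = []
    for p in pairs:
        if p.status.startswith("dropped"):
            out.append(p)
            continue
        shared = frozenset(catalog.mirnas_of(p.lncRNA_id) & catalog.mirnas_of(p.mRNA_id))
        if shared:
            out.append(replace(p, shared_mirnas=shared, status="passed_mirna"))
        else:
            out.append(replace(p, shared_mirnas=frozenset(), status="dropped:no_shared_mirna"))
    return out


def de_filter(pairs, log2_expr: pd.DataFrame, groups: pd.Series, alpha: float = 0.05) -> list[CandidatePair]:
    """Keep pairs whose members are both Kruskal-Wallis significant."""
    labels = groups.reindex(log2_expr.columns).to_numpy()
    cache: dict[str, float] = {}

    def kw_p(gene: str) -> float:
        if gene not in cache:
            cache[gene] = kruskal_wallis(
                log2_expr.loc[gene].to_numpy(), labels, alpha=alpha, gene_id=gene
            ).p_value
        return cache[gene]

    out = []
    for p in pairs:
        if p.status.startswith("dropped"):
            out.append(p)
            continue
        pl, pm = kw_p(p.lncRNA_id), kw_p(p.mRNA_id)
        status = "passed_de" if (pl < alpha and pm < alpha) else "dropped:not_de"
        out.append(replace(p, kw_p_lnc=pl, kw_p_mrna=pm, status=status))
    return out


def summarize_pairs(pairs) -> tuple[int, int, int]:
    """(number of pairs, distinct lncRNAs, distinct mRNAs)."""
    keys = [(p.lncRNA_id, p.mRNA_id) if isinstance(p, CandidatePair) else tuple(p) for p in pairs]
    return (len(keys), len({k[0] for k in keys}), len({k[1] for k in keys}))


def build_cerna_network(pairs, catalog: InteractionCatalog | None = None) -> CeRNANetwork:
    """Assemble the typed network from surviving pairs.

    For each pair and each shared miRNA mu, the edges (lncRNA, mu) and
    (mu, mRNA) are added; nodes and edges are deduplicated and ordered
    deterministically.
    """
    live = _live(pairs)
    for p in live:
        if not p.shared_mirnas:
            raise ValueError(
                f"pair ({p.lncRNA_id}, {p.mRNA_id}) has no shared miRNA; "
                "run shared_mirna_filter first"
            )
    nodes: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    for p in live:
        nodes[p.lncRNA_id] = "lncRNA"
        nodes[p.mRNA_id] = "mRNA"
        for mu in p.shared_mirnas:
            nodes[mu] = "miRNA"
            edges.add((p.lncRNA_id, mu))
            edges.add((mu, p.mRNA_id))
    return CeRNANetwork(
        pairs=list(live),
        nodes=sorted(nodes.items()),
        edges=sorted(edges),
    )


def load_table1_pairs() -> list[CandidatePair]:
    """Bundled transcription of the published 26-pair screening table."""
    with resources.files("cerna.data").joinpath("table1_pairs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        CandidatePair(
            lncRNA_id=row["lncRNA"], mRNA_id=row["mRNA"],
            r_train=float(row["correlation"]), p_corr_train=float("nan"),
        )
        for _, row in df.iterrows()
    ]
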
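"""Validation-cohort replication of candidate ceRNA pairs.

The validation cohort only vetoes: every member of a surviving pair must be
Kruskal-Wallis differentially expressed there, and the pair must show a
significant positive Pearson correlation there.  No new pairs are screened
in from the validation cohort.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .diffexpr import kruskal_wallis
from .screen import CandidatePair
from .stats import ZeroVarianceError, pearson

logger = logging.getLogger("cerna")

__all__ = ["PairReplication", "replicate_de", "replicate_correlation"]


@dataclass(frozen=True)
class PairReplication:
    pair: CandidatePair
    kw_p_lnc_valid: float | None = None
    kw_p_mrna_valid: float | None = None
    r_valid: float | None = None
    p_corr_valid: float | None = None
    final_status: str = "replicated"


def replicate_de(
    pairs, valid_expr: pd.DataFrame, valid_groups: pd.Series, alpha: float = 0.05
) -> list[PairReplication]:
    """Drop pairs with a member not differentially expressed in validation.

    A member absent from the validation matrix drops the pair with reason
    ``absent_in_validation`` (warning, not a crash).
    """
    labels = valid_groups.reindex(valid_expr.columns).to_numpy()
    present = set(valid_expr.index)
    cache: dict[str, float] = {}

    def kw_p(gene: str) -> float:
        if gene not in cache:
            cache[gene] = kruskal_wallis(
                valid_expr.loc[gene].to_numpy(), labels, alpha=alpha, gene_id=gene
            ).p_value
        return cache[gene]

    out = []
    for p in pairs:
        members = (p.lncRNA_id, p.mRNA_id)
        missing = [g for g in members if g not in present]
        if missing:
            logger.warning("pair (%s, %s): member(s) %s absent from validation cohort",
                           p.lncRNA_id, p.mRNA_id, missing)
            out.append(PairReplication(pair=p, final_status="dropped:absent_in_validation"))
            continue
        pl, pm = kw_p(p.lncRNA_id), kw_p(p.mRNA_id)
        status = "member_de_ok" if (pl < alpha and pm < alpha) else "dropped_member_de"
        out.append(PairReplication(pair=p, kw_p_lnc_valid=pl, kw_p_mrna_valid=pm,
                                   final_status=status))
    return out


def replicate_correlation(
    reports, valid_expr: pd.DataFrame, alpha: float = 0.05
) -> list[PairReplication]:
    """Require a significant positive validation correlation to replicate."""
    out = []
    for rep in reports:
        if rep.final_status != "member_de_ok":
            out.append(rep)
            continue
        p = rep.pair
        try:
            res = pearson(
                valid_expr.loc[p.lncRNA_id].to_numpy(),
                valid_expr.loc[p.mRNA_id].to_numpy(),
            )
        except ZeroVarianceError:
            out.append(PairReplication(
                pair=p, kw_p_lnc_valid=rep.kw_p_lnc_valid,
                kw_p_mrna_valid=rep.kw_p_mrna_valid,
                final_status="dropped:zero_variance_in_validation"))
            continue
        ok = res.p < alpha and res.r > 0
        out.append(PairReplication(
            pair=p, kw_p_lnc_valid=rep.kw_p_lnc_valid,
            kw_p_mrna_valid=rep.kw_p_mrna_valid,
            r_valid=res.r, p_corr_valid=res.p,
            final_status="replicated" if ok else "dropped_corr"))
    return out
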
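"""End-to-end orchestration of the immune-related ceRNA screening cascade.

Stage order: DEG screen -> module detection -> key-module selection ->
immune intersection -> pair screen (correlation, shared miRNA, member DE) ->
validation-cohort replication -> deconvolution and fraction correlation.
Every stage writes its table when an output directory is given, and the
machine-readable summary is deterministic for a fixed config and inputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import deconv, diffexpr, replicate, screen, wgcna
from .io import (
    CountMatrix,
    GeneAnnotation,
    InteractionCatalog,
    PipelineConfig,
    write_edge_table,
)

logger = logging.getLogger("cerna")

__all__ = ["run_pipeline", "candidate_table", "replication_table"]


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def candidate_table(pairs) -> pd.DataFrame:
    rows = [
        {
            "lncRNA": p.lncRNA_id,
            "mRNA": p.mRNA_id,
            "r_train": p.r_train,
            "p_corr_train": p.p_corr_train,
            "shared_mirnas": ";".join(sorted(p.shared_mirnas)),
            "kw_p_lnc": p.kw_p_lnc,
            "kw_p_mrna": p.kw_p_mrna,
            "status": p.status,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["lncRNA", "mRNA", "r_train", "p_corr_train",
                                       "shared_mirnas", "kw_p_lnc", "kw_p_mrna", "status"])


def replication_table(reports) -> pd.DataFrame:
    rows = [
        {
            "lncRNA": rep.pair.lncRNA_id,
            "mRNA": rep.pair.mRNA_id,
            "kw_p_lnc_valid": rep.kw_p_lnc_valid,
            "kw_p_mrna_valid": rep.kw_p_mrna_valid,
            "r_valid": rep.r_valid,
            "p_corr_valid": rep.p_corr_valid,
            "final_status": rep.final_status,
        }
        for rep in reports
    ]
    return pd.DataFrame(rows, columns=["lncRNA", "mRNA", "kw_p_lnc_valid",
                                       "kw_p_mrna_valid", "r_valid", "p_corr_valid",
                                       "final_status"])


def run_pipeline(
    config: PipelineConfig,
    training: CountMatrix,
    validation: CountMatrix,
    annotation: GeneAnnotation,
    immune_list,
    catalog: InteractionCatalog,
    signature: pd.DataFrame | None = None,
    out_dir=None,
) -> dict:
    """Run the whole cascade; returns the machine-readable run report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        if out is not None:
            df.to_csv(out / name, sep="\t", **kwargs)

    report: dict = {"config": config.to_dict(), "stages": {}}

    # ------------------------------------------------------------------ DEG
    @_stage("deg_screen")
    def stage_deg():
        filtered = diffexpr.filter_low_counts(training, min_total=1)
        log2_expr = diffexpr.log2_expression(filtered)
        results = diffexpr.de_test(log2_expr, filtered.groups,
                                   lfc_threshold=config.lfc_threshold, alpha=config.alpha)
        df = pd.DataFrame([r.__dict__ for r in results])
        save(df, "deg.tsv", index=False)
        up = int(sum(r.is_deg and r.log2_fold_change > 0 for r in results))
        down = int(sum(r.is_deg and r.log2_fold_change < 0 for r in results))
        report["stages"]["deg_screen"] = {
            "n_genes_tested": len(results), "n_deg_up": up, "n_deg_down": down,
        }
        return log2_expr

    log2_train = stage_deg()

    # -------------------------------------------------------------- modules
    @_stage("module_detection")
    def stage_modules():
        top = wgcna.select_top_mad(log2_train, k=config.top_k_mad,
                                   statistic=config.mad_statistic)
        scan = wgcna.scan_soft_threshold(top, config.beta_range)
        save(scan, "soft_threshold_scan.tsv")
        beta, warned = wgcna.pick_beta(scan, config.r2_target)
        adj = wgcna.adjacency(top, beta)
        tom = wgcna.tom_similarity(adj)
        modules = wgcna.cluster_modules(1.0 - tom, config.min_module_size)
        modules = wgcna.module_eigengenes(top, modules.assignment) if modules.modules \
            else modules
        save(pd.DataFrame({"gene": list(modules.assignment),
                           "module": list(modules.assignment.values())}),
             "modules.tsv", index=False)
        if modules.eigengenes is not None:
            save(modules.eigengenes, "eigengenes.tsv", index_label="sample")
        report["stages"]["module_detection"] = {
            "beta": beta, "beta_fallback": bool(warned),
            "n_genes_clustered": top.shape[0],
            "module_sizes": dict(sorted(modules.sizes.items())),
        }
        return modules

    modules = stage_modules()

    # ----------------------------------------------------------- key modules
    @_stage("key_module_selection")
    def stage_key():
        if not modules.modules:
            report["stages"]["key_modules"] = {
                "positive": None, "negative": None, "note": "no modules detected",
            }
            return []
        trait = training.trait
        table = wgcna.module_trait_correlation(modules.eigengenes, trait)
        save(table, "module_trait.tsv")
        pos, neg = wgcna.select_key_modules(table)
        genes: list[str] = []
        for key in (pos, neg):
            if key is not None:
                genes.extend(modules.genes_in(key))
        report["stages"]["key_modules"] = {
            "positive": pos, "negative": neg, "n_key_module_genes": len(genes),
            "trait_correlation": {m: round(float(table.loc[m, "r"]), 6)
                                  for m in table.index},
        }
        return genes

    key_genes = stage_key()

    # ------------------------------------------------------------ pair screen
    @_stage("pair_screen")
    def stage_pairs():
        lnc, mrna = screen.split_immune_genes(key_genes, annotation, immune_list)
        pairs = screen.correlate_pairs(log2_train, lnc, mrna,
                                       cutoff=config.corr_cutoff,
                                       absolute=config.abs_correlation)
        pairs = screen.shared_mirna_filter(pairs, catalog)
        pairs = screen.de_filter(pairs, log2_train, training.groups, alpha=config.alpha)
        save(candidate_table(pairs), "candidates.tsv", index=False)
        live = [p for p in pairs if not p.status.startswith("dropped")]
        n, nl, nm = screen.summarize_pairs(live)
        report["stages"]["pair_screen"] = {
            "n_immune_lncRNAs": len(lnc), "n_immune_mRNAs": len(mrna),
            "n_combinations": len(pairs), "n_candidate_pairs": n,
            "n_distinct_lncRNAs": nl, "n_distinct_mRNAs": nm,
        }
        if live:
            network = screen.build_cerna_network(live, catalog)
            if out is not None:
                write_edge_table(network, out / "network_train.tsv", "tsv")
                write_edge_table(network, out / "network_train.sif", "sif")
        return pairs, live

    all_pairs, live_pairs = stage_pairs()

    # ------------------------------------------------------------ replication
    @_stage("replication")
    def stage_replication():
        filtered = diffexpr.filter_low_counts(validation, min_total=1)
        log2_valid = diffexpr.log2_expression(filtered)
        reports = replicate.replicate_de(live_pairs, log2_valid, filtered.groups,
                                         alpha=config.alpha)
        reports = replicate.replicate_correlation(reports, log2_valid, alpha=config.alpha)
        save(replication_table(reports), "replication.tsv", index=False)
        final = [r.pair for r in reports if r.final_status == "replicated"]
        if final:
            network = screen.build_cerna_network(final, catalog)
            if out is not None:
                write_edge_table(network, out / "network_final.tsv", "tsv")
                write_edge_table(network, out / "network_final.sif", "sif")
        report["stages"]["replication"] = {
            "n_tested": len(reports),
            "n_replicated": len(final),
            "final_pairs": sorted([r.pair.lncRNA_id, r.pair.mRNA_id]
                                  for r in reports if r.final_status == "replicated"),
        }
        return final

    final_pairs = stage_replication()

    # ---------------------------------------------------------- deconvolution
    if signature is not None:
        @_stage("deconvolution")
        def stage_deconv():
            normalized, _ = diffexpr.normalize_counts(training)
            est = deconv.estimate_fractions(
                normalized, signature, method="svr_ensemble",
                nu_grid=config.deconv_nu_grid,
                n_permutations=config.n_permutations, seed=config.rng_seed,
            )
            frac_out = est.fractions.copy()
            frac_out["fit_rmse"] = est.fit_rmse
            frac_out["fit_correlation"] = est.fit_correlation
            if est.permutation_p is not None:
                frac_out["permutation_p"] = est.permutation_p
            save(frac_out, "fractions.tsv", index_label="sample")
            comparison = deconv.compare_fractions(est.fractions, training.groups,
                                                  alpha=config.alpha)
            save(comparison, "fraction_group_test.tsv")
            genes = sorted({g for p in final_pairs for g in (p.lncRNA_id, p.mRNA_id)})
            infil = None
            if genes:
                infil = deconv.correlate_expression_fractions(
                    log2_train.loc[genes], est.fractions, alpha=config.alpha)
                save(infil, "infiltration_correlation.tsv", index=False)
            report["stages"]["deconvolution"] = {
                "n_celltypes": est.fractions.shape[1],
                "significant_celltypes": sorted(
                    comparison.index[comparison["significant"]].tolist()),
                "n_infiltration_tests": 0 if infil is None else len(infil),
                "n_significant_infiltration": 0 if infil is None
                    else int(infil["significant"].sum()),
            }

        stage_deconv()

    report["final_pairs"] = sorted([p.lncRNA_id, p.mRNA_id] for p in final_pairs)
    report["n_final_pairs"] = len(final_pairs)
    if out is not None:
        (out / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
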
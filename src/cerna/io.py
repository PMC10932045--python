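"""Data containers, configuration and tabular I/O for the screening pipeline.

All tabular files are plain TSV with a single header line; gene, sample,
miRNA and cell-type identifiers are opaque strings.  Group labels are the
disease-agnostic pair {CTRL, CASE}; CASE is coded 1 wherever a 0/1 trait
vector is needed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cerna")

GROUPS = ("CTRL", "CASE")
BIOTYPES = ("mRNA", "lncRNA", "other")

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "InteractionCatalog",
    "PipelineConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "read_catalog",
    "write_catalog",
    "read_signature",
    "write_signature",
    "write_edge_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer counts with group labels.

    ``counts`` is a DataFrame indexed by gene id with sample-id columns;
    ``groups`` maps every sample id to CTRL or CASE.  File order of genes and
    samples is preserved.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("counts must be finite and non-negative")
        if np.any(vals != np.round(vals)):
            raise ValueError("counts must be integers")
        self.groups = self.groups.reindex(self.counts.columns)
        missing = self.groups.index[self.groups.isna()]
        if len(missing):
            raise ValueError(f"sample without group label: {missing[0]!r}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if int((self.groups == g).sum()) < 2:
                raise ValueError(f"need at least 2 samples in group {g}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def trait(self) -> np.ndarray:
        """0/1 trait vector over samples (CASE = 1)."""
        return (self.groups.to_numpy() == "CASE").astype(float)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.groups.copy())


@dataclass
class GeneAnnotation:
    """gene id -> biotype lookup (mRNA / lncRNA / other)."""

    biotype: dict[str, str]

    def __post_init__(self) -> None:
        bad = {b for b in self.biotype.values()} - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotype(s): {sorted(bad)}")

    def of(self, gene_id: str) -> str:
        return self.biotype.get(gene_id, "other")

    def genes_of_biotype(self, biotype: str) -> set[str]:
        return {g for g, b in self.biotype.items() if b == biotype}


@dataclass
class InteractionCatalog:
    """Unique (miRNA, target gene, target biotype) edges.

    Emulates a miRNA-target interaction database: the neighbourhood of a
    gene is the set of miRNAs predicted or validated to bind it.
    """

    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._neighbors: dict[str, set[str]] = {}
        for mirna, target, biotype in self.edges:
            if biotype not in ("mRNA", "lncRNA"):
                raise ValueError(f"catalog target biotype must be mRNA or lncRNA, got {biotype!r}")
            self._neighbors.setdefault(target, set()).add(mirna)

    def mirnas_of(self, gene_id: str) -> set[str]:
        return self._neighbors.get(gene_id, set())

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PipelineConfig:
    """Tunable constants of the screening cascade.

    Defaults are the printed constants of the study design: correlation
    cutoff 0.75, |log2FC| threshold 1, alpha 0.05, top 5000 MAD genes,
    soft-threshold scan over powers 1..20 targeting scale-free R^2 0.85,
    minimum module size 30, nu-SVR grid {0.25, 0.5, 0.75}, 1000 permutations.
    """

    corr_cutoff: float = 0.75
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    top_k_mad: int = 5000
    beta_range: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.85
    min_module_size: int = 30
    deconv_nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    n_permutations: int = 1000
    rng_seed: int = 0
    # extension points (documented alternatives to the defaults)
    abs_correlation: bool = False      # |r| > cutoff instead of r > cutoff
    mad_statistic: str = "median"      # "median" or "mean" absolute deviation

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.corr_cutoff < 1.0):
            raise ValueError("corr_cutoff must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        br = tuple(self.beta_range)
        if not br or list(br) != sorted(br) or len(set(br)) != len(br):
            raise ValueError("beta_range must be non-empty strictly ascending")
        self.beta_range = br
        self.deconv_nu_grid = tuple(self.deconv_nu_grid)
        if self.mad_statistic not in ("median", "mean"):
            raise ValueError("mad_statistic must be 'median' or 'mean'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Flat key/value YAML file; keyword overrides win over the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})

    def to_dict(self) -> dict:
        return {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})


def read_count_matrix(path, groups_path) -> CountMatrix:
    """Read a genes x samples count TSV plus a sample -> group TSV.

    The count file has a header row of sample ids and gene ids in the first
    column; the groups file has columns (sample, group).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    gdf = pd.read_csv(groups_path, sep="\t")
    if gdf.shape[1] < 2:
        raise ValueError("groups file needs columns (sample, group)")
    groups = pd.Series(gdf.iloc[:, 1].values, index=gdf.iloc[:, 0].astype(str).values)
    if groups.index.duplicated().any():
        dup = groups.index[groups.index.duplicated()][0]
        raise ValueError(f"duplicate sample in groups file: {dup!r}")
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric count in {path}: {exc}") from exc
    return CountMatrix(num, groups)


def write_count_matrix(m: CountMatrix, path, groups_path=None) -> None:
    m.counts.to_csv(path, sep="\t", index_label="gene")
    if groups_path is not None:
        pd.DataFrame({"sample": m.sample_ids, "group": m.groups.values}).to_csv(
            groups_path, sep="\t", index=False
        )


def read_annotation(path) -> GeneAnnotation:
    """TSV with columns (gene, biotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = df.iloc[:, 0]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene in annotation: {dup!r}")
    return GeneAnnotation(dict(zip(genes, df.iloc[:, 1])))


def write_annotation(ann: GeneAnnotation, path) -> None:
    pd.DataFrame(
        {"gene": list(ann.biotype), "biotype": list(ann.biotype.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """One gene id per line (e.g. the immune-related gene list)."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_catalog(path) -> InteractionCatalog:
    """TSV with columns (miRNA, target, target_biotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = set(map(tuple, df.iloc[:, :3].itertuples(index=False)))
    return InteractionCatalog(edges)


def write_catalog(catalog: InteractionCatalog, path) -> None:
    rows = sorted(catalog.edges)
    pd.DataFrame(rows, columns=["miRNA", "target", "target_biotype"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path) -> pd.DataFrame:
    """Marker genes x cell types signature TSV (expression >= 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("signature has duplicate genes or cell types")
    if df.shape[1] < 2:
        raise ValueError("signature needs at least 2 cell types")
    if (df.to_numpy() < 0).any():
        raise ValueError("signature values must be >= 0")
    return df


def write_signature(sig: pd.DataFrame, path) -> None:
    sig.to_csv(path, sep="\t", index_label="gene")


def write_edge_table(network, path, dialect: str = "tsv") -> None:
    """Export a ceRNA network as an edge list for graph viewers.

    ``tsv`` writes (source, interaction, target, node_type_source,
    node_type_target); ``sif`` writes "source interaction target" lines.
    Edges are emitted once each in lexicographic order, so output is
    deterministic.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    node_type = dict(network.nodes)
    rows = sorted(
        (src, "ceRNA", dst, node_type[src], node_type[dst])
        for src, dst in network.edges
    )
    path = Path(path)
    if dialect == "tsv":
        lines = ["source\tinteraction\ttarget\tnode_type_source\tnode_type_target"]
        lines += ["\t".join(r) for r in rows]
    else:
        lines = [f"{r[0]} {r[1]} {r[2]}" for r in rows]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
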
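import numpy as np
import pandas as pd
import pytest

from cerna.io import GeneAnnotation, InteractionCatalog
from cerna.screen import (
    CandidatePair,
    build_cerna_network,
    correlate_pairs,
    de_filter,
    load_table1_pairs,
    shared_mirna_filter,
    split_immune_genes,
    summarize_pairs,
)


def _expr(rows: dict, n=12):
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T


class TestSplitImmuneGenes:
    ANN = GeneAnnotation({"L1": "lncRNA", "L2": "lncRNA", "M1": "mRNA",
                          "M2": "mRNA", "X1": "other"})

    def test_empty_immune_list(self):
        assert split_immune_genes({"L1", "M1"}, self.ANN, set()) == (set(), set())

    def test_biotype_routing(self):
        lnc, mrna = split_immune_genes({"L1", "M1", "X1"}, self.ANN,
                                       {"L1", "M1", "X1"})
        assert lnc == {"L1"} and mrna == {"M1"}  # "other" excluded

    def test_planted_counts(self):
        ann = GeneAnnotation(
            {f"L{i}": "lncRNA" for i in range(3)} | {f"M{i}": "mRNA" for i in range(5)}
        )
        module = {f"L{i}" for i in range(3)} | {f"M{i}" for i in range(5)} | {"bg"}
        immune = set(module) - {"bg"}
        lnc, mrna = split_immune_genes(module, ann, immune)
        assert (len(lnc), len(mrna)) == (3, 5)


class TestCorrelatePairs:
    def test_duplicated_profile_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        expr = _expr({"L1": x, "M1": x})
        (pair,) = correlate_pairs(expr, {"L1"}, {"M1"})
        assert pair.r_train == pytest.approx(1.0)
        assert pair.status == "candidate"

    def test_negative_correlation_excluded(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        expr = _expr({"L1": x, "M1": -x + rng.normal(0, 0.1, 12)})
        (pair,) = correlate_pairs(expr, {"L1"}, {"M1"})
        assert pair.r_train < -0.9
        assert pair.status == "dropped:low_correlation"

    def test_exact_cutoff_excluded(self):
        # orthonormal construction: sample r exactly 0.75
        z1 = np.array([1.0, 1, -1, -1])
        z2 = np.array([1.0, -1, 1, -1])
        expr = pd.DataFrame([z1, 0.75 * z1 + np.sqrt(1 - 0.75**2) * z2],
                            index=["L1", "M1"])
        (pair,) = correlate_pairs(expr, {"L1"}, {"M1"}, cutoff=0.75)
        assert pair.r_train == pytest.approx(0.75, abs=1e-12)
        assert pair.status == "dropped:low_correlation"

    def test_absolute_mode_keeps_negative(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        expr = _expr({"L1": x, "M1": -x})
        (pair,) = correlate_pairs(expr, {"L1"}, {"M1"}, absolute=True)
        assert pair.status == "candidate"

    def test_missing_gene_named(self):
        expr = _expr({"L1": np.arange(12.0)})
        with pytest.raises(KeyError, match="M9"):
            correlate_pairs(expr, {"L1"}, {"M9"})


class TestSharedMirnaFilter:
    P = CandidatePair("L1", "M1", 0.9, 0.001)

    def test_empty_catalog_drops_all(self):
        out = shared_mirna_filter([self.P], InteractionCatalog(set()))
        assert out[0].status == "dropped:no_shared_mirna"

    def test_intersection_by_hand(self):
        cat = InteractionCatalog({
            ("m1", "L1", "lncRNA"), ("m2", "L1", "lncRNA"),
            ("m2", "M1", "mRNA"), ("m3", "M1", "mRNA"),
        })
        (out,) = shared_mirna_filter([self.P], cat)
        assert out.shared_mirnas == {"m2"} and out.status == "passed_mirna"

    def test_disjoint_sets_dropped_with_reason(self):
        cat = InteractionCatalog({("m1", "L1", "lncRNA"), ("m2", "M1", "mRNA")})
        (out,) = shared_mirna_filter([self.P], cat)
        assert out.status == "dropped:no_shared_mirna"
        assert out.shared_mirnas == frozenset()


class TestDeFilter:
    @staticmethod
    def _setup(lnc_vals, mrna_vals):
        expr = pd.DataFrame([lnc_vals, mrna_vals], index=["L1", "M1"],
                            columns=[f"s{i}" for i in range(len(lnc_vals))])
        groups = pd.Series(["CTRL"] * (len(lnc_vals) // 2)
                           + ["CASE"] * (len(lnc_vals) - len(lnc_vals) // 2),
                           index=expr.columns)
        pair = CandidatePair("L1", "M1", 0.9, 0.001, frozenset({"m"}),
                             status="passed_mirna")
        return [pair], expr, groups

    def test_constant_member_dropped(self):
        pairs, expr, groups = self._setup([1.0] * 10, list(range(10)))
        (out,) = de_filter(pairs, expr, groups)
        assert out.kw_p_lnc == 1.0 and out.status == "dropped:not_de"

    def test_alpha_one_keeps_everything(self):
        rng = np.random.default_rng(3)
        pairs, expr, groups = self._setup(rng.normal(size=10), rng.normal(size=10))
        (out,) = de_filter(pairs, expr, groups, alpha=1.0)
        assert out.status == "passed_de"

    def test_strong_shift_retained(self):
        shift = [0.0] * 5 + [10.0] * 5
        noise = np.random.default_rng(4).normal(0, 0.1, 10)
        pairs, expr, groups = self._setup(shift + noise, shift + noise * 2)
        (out,) = de_filter(pairs, expr, groups)
        assert out.status == "passed_de"
        assert out.kw_p_lnc < 0.05 and out.kw_p_mrna < 0.05


class TestSummarizePairs:
    def test_empty_and_singleton(self):
        assert summarize_pairs([]) == (0, 0, 0)
        assert summarize_pairs([("L1", "M1")]) == (1, 1, 1)

    def test_matches_brute_force_cardinalities(self):
        rng = np.random.default_rng(5)
        pairs = {(f"L{rng.integers(6)}", f"M{rng.integers(9)}") for _ in range(40)}
        pairs = sorted(pairs)
        n, nl, nm = summarize_pairs(pairs)
        assert n == len(pairs)
        assert nl == len({p[0] for p in pairs})
        assert nm == len({p[1] for p in pairs})

    def test_published_table_counts(self):
        pairs = load_table1_pairs()
        assert summarize_pairs(pairs) == (26, 9, 17)


class TestBuildNetwork:
    def test_single_pair_three_nodes_two_edges(self):
        net = build_cerna_network(
            [CandidatePair("L1", "M1", 0.9, 0.01, frozenset({"m1"}), status="passed_de")]
        )
        assert len(net.nodes) == 3 and len(net.edges) == 2
        assert ("L1", "m1") in net.edges and ("m1", "M1") in net.edges

    def test_two_pairs_sharing_mirna(self):
        net = build_cerna_network([
            CandidatePair("L1", "M1", 0.9, 0.01, frozenset({"m1"}), status="passed_de"),
            CandidatePair("L2", "M2", 0.8, 0.01, frozenset({"m1"}), status="passed_de"),
        ])
        assert len(net.edges) == 4
        assert [n for n, t in net.nodes if t == "miRNA"] == ["m1"]

    def test_empty_input(self):
        net = build_cerna_network([])
        assert net.nodes == [] and net.edges == []

    def test_pair_without_shared_mirna_rejected(self):
        with pytest.raises(ValueError, match="no shared miRNA"):
            build_cerna_network(
                [CandidatePair("L1", "M1", 0.9, 0.01, status="candidate")]
            )


class TestFilterCascadeOrderEquivalence:
    def test_cascade_equals_conjunction_of_predicates(self):
        """The surviving set equals the order-free conjunction of the three
        criteria evaluated independently (correlation, shared miRNA, DE)."""
        rng = np.random.default_rng(6)
        n = 16
        lncs = [f"L{i}" for i in range(4)]
        mrnas = [f"M{i}" for i in range(4)]
        shift = np.array([0.0] * (n // 2) + [2.0] * (n // 2))
        rows = {}
        base = rng.normal(size=n)
        for g in lncs + mrnas:
            mix = rng.uniform(0, 1)
            rows[g] = mix * base + (1 - mix) * rng.normal(size=n) \
                + (shift if rng.random() < 0.5 else 0)
        expr = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T
        groups = pd.Series(["CTRL"] * (n // 2) + ["CASE"] * (n // 2),
                           index=expr.columns)
        edges = set()
        for g in lncs + mrnas:
            for m in rng.choice(["x1", "x2", "x3", "x4"], size=2, replace=False):
                edges.add((str(m), g, "lncRNA" if g.startswith("L") else "mRNA"))
        catalog = InteractionCatalog(edges)

        pairs = correlate_pairs(expr, lncs, mrnas, cutoff=0.5)
        pairs = shared_mirna_filter(pairs, catalog)
        pairs = de_filter(pairs, expr, groups, alpha=0.05)
        survivors = {p.key for p in pairs if not p.status.startswith("dropped")}

        from cerna.diffexpr import kruskal_wallis
        from cerna.stats import pearson
        expected = set()
        for l in lncs:
            for m in mrnas:
                r = pearson(expr.loc[l], expr.loc[m]).r
                shared = catalog.mirnas_of(l) & catalog.mirnas_of(m)
                kwl = kruskal_wallis(expr.loc[l], groups.values).p_value
                kwm = kruskal_wallis(expr.loc[m], groups.values).p_value
                if r > 0.5 and shared and kwl < 0.05 and kwm < 0.05:
                    expected.add((l, m))
        assert survivors == expected
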
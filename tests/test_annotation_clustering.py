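"""Kappa matrix, seed formation, deterministic merging, pruning and treemap."""

import itertools
import math

import numpy as np
import pytest

from growthnet import (
    ClusteringParams,
    EnrichmentResult,
    TermAnnotation,
    cluster_terms,
    cohen_kappa,
    form_seeds,
    kappa_matrix,
    merge_clusters,
    prune_and_summarize,
    treemap_table,
)
from growthnet.annotation_clustering import squarify_layout


def make_terms(gene_sets, prefix="T"):
    return [
        TermAnnotation(f"{prefix}{i}", "GO_BP", frozenset(g))
        for i, g in enumerate(gene_sets)
    ]


def kappa_oracle(genes_i, genes_j, universe):
    """Scalar recomputation of kappa from the 2x2 agreement table."""
    a = len(genes_i & genes_j)
    b = len(genes_i - genes_j)
    c = len(genes_j - genes_i)
    d = len(universe) - a - b - c
    total = len(universe)
    po = (a + d) / total
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / total**2
    return (po - pe) / (1 - pe)


class TestKappaMatrix:
    def test_identical_sets_reach_one(self):
        universe = [f"G{i}" for i in range(100)]
        terms = make_terms([universe[:10], universe[:10]])
        k = kappa_matrix(terms, universe)
        assert k.loc["T0", "T1"] == pytest.approx(1.0)

    def test_overlap_gate_zeroes_small_intersections(self):
        universe = [f"G{i}" for i in range(100)]
        # 3 shared genes: high agreement but below the overlap threshold of 5
        terms = make_terms([universe[:10], universe[7:17]])
        k = kappa_matrix(terms, universe)
        assert k.loc["T0", "T1"] == 0.0

    def test_hand_arithmetic_example(self):
        # a=10, b=5, c=5, d=980: Po and Pe recomputed by hand
        po = (10 + 980) / 1000
        pe = (15 * 15 + 985 * 985) / 1000**2
        expected = (po - pe) / (1 - pe)
        assert cohen_kappa(10, 5, 5, 980) == pytest.approx(expected)

    def test_matrix_equals_scalar_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        universe = [f"G{i}" for i in range(300)]
        sets = [
            frozenset(rng.choice(universe, size=rng.integers(10, 40), replace=False))
            for _ in range(12)
        ]
        terms = make_terms(sets)
        k = kappa_matrix(terms, universe, ClusteringParams(min_gene_overlap=2))
        uni = set(universe)
        assert np.allclose(k.values, k.values.T)
        assert np.all(np.diag(k.values) == 1.0)
        assert np.all((k.values >= -1 - 1e-12) & (k.values <= 1 + 1e-12))
        for i, j in itertools.combinations(range(12), 2):
            expected = (
                kappa_oracle(sets[i], sets[j], uni)
                if len(sets[i] & sets[j]) >= 2
                else 0.0
            )
            assert k.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_constant_annotation_warns_and_zeroes(self):
        universe = [f"G{i}" for i in range(10)]
        terms = make_terms([universe, universe])  # both cover everything: Pe = 1
        with pytest.warns(UserWarning, match="degenerate"):
            k = kappa_matrix(terms, universe)
        assert k.loc["T0", "T1"] == 0.0


class TestSeeds:
    def test_clique_collapses_to_one_seed(self):
        universe = [f"G{i}" for i in range(50)]
        terms = make_terms([universe[:10]] * 6)
        k = kappa_matrix(terms, universe)
        seeds = form_seeds(k)
        assert seeds == [frozenset(f"T{i}" for i in range(6))]

    def test_star_topology_rejected_by_membership_fraction(self):
        # hub tied to 5 leaves, leaves mutually unrelated: 5 of 15 pairs tight
        import pandas as pd

        ids = ["HUB"] + [f"L{i}" for i in range(5)]
        m = np.zeros((6, 6))
        m[0, 1:] = m[1:, 0] = 0.9
        np.fill_diagonal(m, 1.0)
        k = pd.DataFrame(m, index=ids, columns=ids)
        assert form_seeds(k) == []

    def test_no_tight_pairs_no_seeds(self):
        universe = [f"G{i}" for i in range(100)]
        sets = [universe[i * 10:(i + 1) * 10] for i in range(6)]
        k = kappa_matrix(make_terms(sets), universe)
        assert form_seeds(k) == []


class TestMerge:
    def test_linkage_threshold_definition(self):
        a = frozenset("ABCDE")
        b = frozenset("ABCXY")  # shares 3 of the smaller's 5 members: 0.6 >= 0.5
        merged = merge_clusters([a, b], ClusteringParams(final_cluster_size=2))
        assert merged == [a | b]

    def test_disjoint_seeds_unchanged(self):
        a = frozenset("ABCDE")
        b = frozenset("VWXYZ")
        assert set(merge_clusters([a, b], ClusteringParams(final_cluster_size=2))) == {a, b}

    def test_small_final_clusters_discarded(self):
        a = frozenset("ABC")
        assert merge_clusters([a], ClusteringParams(final_cluster_size=5)) == []

    def test_matches_exhaustive_merge_oracle_on_bridged_blocks(self):
        # two 5-term blocks plus a bridge overlapping both; the oracle tries
        # every merge order and checks the final partition is order-free
        block1 = frozenset(f"A{i}" for i in range(5))
        block2 = frozenset(f"B{i}" for i in range(5))
        bridge = frozenset(["A0", "A1", "A2", "B0", "B1"])
        seeds = [block1, block2, bridge]
        params = ClusteringParams(final_cluster_size=2)

        def oracle(groups):
            outcomes = set()
            frontier = [tuple(sorted(groups, key=sorted))]
            while frontier:
                state = frontier.pop()
                pairs = [
                    (x, y)
                    for x, y in itertools.combinations(state, 2)
                    if len(x & y) / min(len(x), len(y)) >= params.linkage_threshold
                ]
                if not pairs:
                    outcomes.add(frozenset(state))
                    continue
                for x, y in pairs:
                    nxt = [g for g in state if g not in (x, y)] + [x | y]
                    frontier.append(tuple(sorted(set(nxt), key=sorted)))
            return outcomes

        outcomes = oracle(seeds)
        assert len(outcomes) == 1  # order-independent end state on this instance
        assert frozenset(merge_clusters(seeds, params)) == next(iter(outcomes))

    def test_permutation_invariance_of_full_clustering(self, planted_corpus):
        config, terms, growth, blocks, universe = planted_corpus
        from growthnet import enrich_terms

        results = {r.term_id: r for r in enrich_terms(growth, terms, universe)}
        forward = cluster_terms(terms, results, universe)
        backward = cluster_terms(list(reversed(terms)), results, universe)
        assert [c.member_terms for c in forward] == [c.member_terms for c in backward]


def result(term_id, p, fold=2.0, fdr=None):
    return EnrichmentResult(
        term_id=term_id, a=5, A=50, b=10, B=950, p_raw=p,
        odds_ratio=3.0, fold_enrichment=fold, fdr=p if fdr is None else fdr,
    )


class TestPruneAndSummarize:
    def make_inputs(self, n=6):
        universe = [f"G{i}" for i in range(60)]
        terms = {
            f"T{i}": TermAnnotation(f"T{i}", "GO_BP", frozenset(universe[i: i + 10]))
            for i in range(n)
        }
        return terms

    def test_pruned_member_leaves_cluster_intact_at_threshold(self):
        terms = self.make_inputs(6)
        results = {t: result(t, 1e-4) for t in terms}
        results["T5"] = result("T5", 0.5, fdr=0.2)
        clusters = prune_and_summarize(
            [frozenset(terms)], results, terms, alpha=0.05
        )
        assert len(clusters) == 1 and clusters[0].n_terms == 5
        assert "T5" not in clusters[0].member_terms
        assert clusters[0].gene_union == frozenset().union(
            *(terms[t].genes for t in clusters[0].member_terms)
        )

    def test_enrichment_score_is_neglog_geometric_mean(self):
        terms = self.make_inputs(5)
        ids = sorted(terms)
        results = {t: result(t, 1e-4) for t in ids}
        results[ids[0]] = result(ids[0], 1e-6)
        clusters = prune_and_summarize(
            [frozenset(ids)], results, terms,
            ClusteringParams(final_cluster_size=2), alpha=1.0,
        )
        expected = -math.log10((1e-6 * (1e-4) ** 4) ** (1 / 5))
        assert clusters[0].enrichment_score == pytest.approx(expected)

    def test_mean_fold_enrichment_is_arithmetic(self):
        terms = self.make_inputs(3)
        ids = sorted(terms)
        results = {
            t: result(t, 1e-4, fold=f) for t, f in zip(ids, (2.0, 4.0, 6.0))
        }
        clusters = prune_and_summarize(
            [frozenset(ids)], results, terms,
            ClusteringParams(final_cluster_size=2), alpha=1.0,
        )
        assert clusters[0].mean_fold_enrichment == pytest.approx(4.0)

    def test_missing_enrichment_names_term(self):
        terms = self.make_inputs(5)
        results = {t: result(t, 1e-4) for t in list(terms)[:-1]}
        with pytest.raises(KeyError, match="T4"):
            prune_and_summarize([frozenset(terms)], results, terms)

    def test_pruning_never_grows_clusters(self):
        terms = self.make_inputs(6)
        results = {t: result(t, 1e-3, fdr=0.01 if t < "T3" else 0.2) for t in terms}
        full = prune_and_summarize([frozenset(terms)], results, terms, alpha=1.0)
        pruned = prune_and_summarize(
            [frozenset(terms)], results, terms,
            ClusteringParams(final_cluster_size=2), alpha=0.05,
        )
        for p in pruned:
            assert p.n_terms <= full[0].n_terms


class TestTreemap:
    def make_cluster(self, label, n_genes, cid="C01"):
        from growthnet import TermCluster

        return TermCluster(
            cluster_id=cid, member_terms=frozenset({label}),
            representative_label=label,
            gene_union=frozenset(f"{label}_G{i}" for i in range(n_genes)),
            enrichment_score=1.0, mean_fold_enrichment=1.0,
        )

    def test_single_cluster_fills_canvas(self):
        table = treemap_table([self.make_cluster("only", 12)])
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.x, row.y, row.dx, row.dy) == (0.0, 0.0, 100.0, 100.0)

    def test_area_proportional_to_gene_union(self):
        t = treemap_table([
            self.make_cluster("big", 30, "C01"), self.make_cluster("small", 10, "C02")
        ])
        areas = (t.dx * t.dy).to_numpy()
        assert areas[0] / areas[1] == pytest.approx(3.0)

    def test_layout_partitions_canvas(self):
        rng = np.random.default_rng(1)
        sizes = rng.integers(5, 60, size=12).astype(float)
        scaled = sizes / sizes.sum() * 100 * 100
        rects = squarify_layout(list(scaled), 0, 0, 100.0, 100.0)
        assert sum(dx * dy for _, _, dx, dy in rects) == pytest.approx(100 * 100)
        for (x, y, dx, dy), s in zip(rects, scaled):
            assert dx * dy == pytest.approx(s)
            assert 0 <= x <= 100 and 0 <= y <= 100

    def test_published_cluster_fixture_renders_29_rectangles(self):
        from growthnet import load_published_clusters
        from growthnet.annotation_clustering import TermCluster

        df, _ = load_published_clusters()
        clusters = [
            TermCluster(
                cluster_id=f"P{i:02d}", member_terms=frozenset({r.cluster_name}),
                representative_label=r.cluster_name,
                gene_union=frozenset(f"G{j}" for j in range(int(r.n_growth_genes))),
                enrichment_score=1.0,
                mean_fold_enrichment=float(r.growth_fold_enrichment),
            )
            for i, r in enumerate(df.itertuples())
        ]
        table = treemap_table(clusters)
        assert len(table) == 29
        assert table.iloc[0].label == "Skeletal system development"
        assert table.iloc[0].gene_union_size == 996
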
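from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fugue.data_io import GeneAnnotation, TadSet
from fugue.downstream import (
    genomic_cluster_test,
    genomic_clusters,
    map_snps_to_genes,
    permutation_null,
    select_top_fraction,
    set_enrichment,
    tad_coverage,
    tissue_tf_dendrogram,
)


def _ann(starts, chroms=None, length=10_000):
    genes = [f"g{i}" for i in range(len(starts))]
    chroms = chroms or ["chr1"] * len(starts)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": [s + length for s in starts],
            "strand": "+",
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneAnnotation(table=df), genes


def brute_cluster_fraction(genes, ann, min_genes, max_gap):
    """Mark genes inside any qualifying contiguous window (O(n^2) oracle)."""
    covered = set()
    sub = ann.table.loc[[g for g in genes if g in ann.table.index]]
    for chrom, grp in sub.groupby("chrom"):
        ordered = grp.sort_values("start")
        ids = ordered.index.tolist()
        starts = ordered["start"].tolist()
        for i in range(len(ids)):
            for j in range(i + min_genes - 1, len(ids)):
                gaps_ok = all(
                    starts[k + 1] - starts[k] <= max_gap for k in range(i, j)
                )
                if gaps_ok:
                    covered.update(ids[i : j + 1])
    return len(covered) / len(sub) if len(sub) else 0.0


class TestSelectTopFraction:
    def _table(self, n=100):
        return pd.DataFrame(
            {
                "gene": [f"g{i:03d}" for i in range(n)],
                "tissue": "T1",
                "label": "U",
                "score": np.linspace(1, 0, n),
                "normalized_rank": np.linspace(1, 0, n),
            }
        )

    def test_ten_percent_of_hundred(self):
        assert len(select_top_fraction(self._table(), "T1", 0.10)) == 10

    def test_all_at_frac_one(self):
        assert len(select_top_fraction(self._table(), "T1", 1.0)) == 100

    def test_tie_at_cutoff_broken_by_gene_id(self):
        t = self._table(4)
        t["score"] = [0.9, 0.5, 0.5, 0.1]
        top = select_top_fraction(t, "T1", 0.5)
        assert top == ["g000", "g001"]

    def test_invalid_frac_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(self._table(), "T1", 0.0)


class TestSnpMapping:
    def test_boundary_and_threshold_conventions(self):
        ann, _ = _ann([100], length=100)  # g0 spans [100, 200)
        snps = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [150, 150, 200],
                "p": [1e-12, 1e-8, 1e-12],
                "trait": ["t_in", "t_weak", "t_edge"],
            }
        )
        out = map_snps_to_genes(snps, ann, min_genes=1)
        assert out == {"t_in": {"g0"}}  # weak p and half-open end excluded

    def test_min_genes_filter(self):
        ann, genes = _ann([i * 1_000_000 for i in range(6)])
        snps = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [i * 1_000_000 + 10 for i in range(6)],
                "p": [1e-12] * 6,
                "trait": ["big"] * 5 + ["small"],
            }
        )
        out = map_snps_to_genes(snps, ann, min_genes=5)
        assert set(out) == {"big"} and len(out["big"]) == 5


class TestSetEnrichment:
    def test_hand_arithmetic_odds_ratios(self):
        uni = {f"g{i}" for i in range(1000)}
        top = {f"g{i}" for i in range(100)}
        trait = {f"g{i}" for i in range(92, 112)}  # overlap 8
        r = set_enrichment(top, trait, uni)
        assert (r.a, r.b, r.c, r.d) == (8, 92, 12, 888)
        assert r.odds_ratio == pytest.approx((8 * 888) / (92 * 12))

    def test_deg_style_table(self):
        uni = {f"g{i}" for i in range(1000)}
        trg = {f"g{i}" for i in range(50)}
        deg = {f"g{i}" for i in range(30, 130)}  # overlap 20
        r = set_enrichment(trg, deg, uni)
        assert r.odds_ratio == pytest.approx((20 * 870) / (30 * 80))  # 7.25

    def test_independence_gives_or_near_one(self):
        uni = {f"g{i}" for i in range(1000)}
        top = {f"g{i}" for i in range(100)}
        trait = {f"g{i}" for i in range(0, 1000, 10)}  # 10% everywhere
        r = set_enrichment(top, trait, uni)
        assert 0.5 < r.odds_ratio < 2.0
        assert not r.passed

    def test_zero_cell_reports_inf(self):
        uni = {f"g{i}" for i in range(100)}
        top = {f"g{i}" for i in range(10)}
        r = set_enrichment(top, top, uni)
        assert np.isinf(r.odds_ratio)

    @pytest.mark.parametrize("seed", range(5))
    def test_fisher_agrees_with_hypergeometric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        uni = {f"g{i}" for i in range(n)}
        top = set(rng.choice(sorted(uni), size=int(rng.integers(1, n)), replace=False))
        trait = set(rng.choice(sorted(uni), size=int(rng.integers(1, n)), replace=False))
        r = set_enrichment(top, trait, uni)
        # two-sided Fisher p: sum of hypergeometric pmf over tables at
        # fixed margins with probability <= observed table's
        M, K, N = n, len(trait), len(top)
        pmf = lambda k: stats.hypergeom.pmf(k, M, K, N)
        p_obs = pmf(r.a)
        oracle = sum(
            pmf(k)
            for k in range(max(0, K + N - M), min(K, N) + 1)
            if pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert r.fisher_p == pytest.approx(oracle, rel=1e-6)


class TestGenomicClusters:
    def test_five_genes_within_gap_rule(self):
        ann, genes = _ann([i * 400_000 for i in range(5)])
        clusters, f = genomic_clusters(genes, ann, min_genes=5)
        assert f == 1.0 and len(clusters) == 1

    def test_genes_on_different_chromosomes_do_not_cluster(self):
        ann, genes = _ann([0] * 5, chroms=[f"chr{i}" for i in range(5)])
        _, f = genomic_clusters(genes, ann, min_genes=5)
        assert f == 0.0

    def test_large_gap_splits_run(self):
        starts = [0, 400_000, 800_000, 1_400_000, 1_800_000, 2_200_000]
        ann, genes = _ann(starts)  # one 600 kb gap splits 3 + 3
        _, f5 = genomic_clusters(genes, ann, min_genes=5)
        _, f3 = genomic_clusters(genes, ann, min_genes=3)
        assert f5 == 0.0 and f3 == 1.0

    def test_max_gap_monotonicity(self, rng):
        starts = sorted(rng.integers(0, 20_000_000, size=20).tolist())
        ann, genes = _ann(starts)
        prev = -1.0
        for gap in (100_000, 300_000, 500_000, 1_000_000, 5_000_000):
            _, f = genomic_clusters(genes, ann, min_genes=3, max_gap=gap)
            assert f >= prev
            prev = f

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_window_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        starts = sorted(rng.integers(0, 5_000_000, size=n).tolist())
        chroms = rng.choice(["chr1", "chr2"], size=n).tolist()
        ann, genes = _ann(starts, chroms=chroms)
        for min_genes in (3, 5):
            _, f = genomic_clusters(genes, ann, min_genes=min_genes)
            assert f == pytest.approx(
                brute_cluster_fraction(genes, ann, min_genes, 500_000), abs=1e-12
            )


class TestPermutationNull:
    def test_seed_reproducible(self, study):
        obs = study.clustered_genes + study.positives["T2"][:5]
        a = genomic_cluster_test(obs, study.annotation, n_resamples=100, seed=3)
        b = genomic_cluster_test(obs, study.annotation, n_resamples=100, seed=3)
        assert a.z == b.z and a.empirical_p == b.empirical_p

    def test_planted_cluster_z_above_two(self, study):
        obs = study.clustered_genes + study.positives["T2"][:10]
        r = genomic_cluster_test(obs, study.annotation, n_resamples=500, seed=4)
        assert r.z > 2
        assert r.empirical_p <= 0.05

    def test_unplanted_controls_mostly_null(self, study, rng):
        zs = []
        pool = study.annotation.table.index
        for i in range(10):
            ctrl = list(rng.choice(pool, size=20, replace=False))
            r = genomic_cluster_test(ctrl, study.annotation, n_resamples=200, seed=50 + i)
            zs.append(r.z)
        assert np.mean(np.abs(zs) < 2) >= 0.9

    def test_empirical_p_never_zero_and_add_one_rule(self, study):
        obs = study.clustered_genes
        r = genomic_cluster_test(obs, study.annotation, n_resamples=50, seed=1)
        assert r.empirical_p >= 1 / 51

    def test_chromosome_composition_preserved(self, study):
        # a statistic that records per-chromosome counts must see the same
        counts = {}

        def spy(genes):
            c = study.annotation.table.loc[list(genes), "chrom"].value_counts()
            counts.setdefault("draws", []).append(tuple(sorted(c.items())))
            return 0.0

        obs = study.clustered_genes + study.positives["T2"][:5]
        permutation_null(spy, obs, study.annotation, n_resamples=5, seed=0)
        assert len(set(counts["draws"])) == 1


class TestTadCoverage:
    def _tads(self, bounds):
        return TadSet(
            intervals=pd.DataFrame(bounds, columns=["chrom", "start", "end"])
        )

    def test_two_tads_two_genes_each(self):
        ann, genes = _ann([100, 200, 1_100, 1_200], length=50)
        tads = self._tads([("chr1", 0, 1000), ("chr1", 1000, 2000)])
        n_tads, n_uncovered = tad_coverage(genes, tads, ann)
        assert (n_tads, n_uncovered) == (2, 0)

    def test_all_genes_outside_tads(self):
        ann, genes = _ann([10_000, 20_000], length=50)
        tads = self._tads([("chr2", 0, 1000)])
        n_tads, n_uncovered = tad_coverage(genes, tads, ann)
        assert (n_tads, n_uncovered) == (0, 2)

    def test_min_genes_threshold_semantics(self):
        ann, genes = _ann([100, 1_100, 1_200], length=50)
        tads = self._tads([("chr1", 0, 1000), ("chr1", 1000, 2000)])
        n1, _ = tad_coverage(genes, tads, ann, min_genes_per_tad=1)
        n2, _ = tad_coverage(genes, tads, ann, min_genes_per_tad=2)
        assert n1 - n2 == 1

    def test_planted_genes_span_few_tads(self, study):
        from fugue.downstream import tad_coverage_test

        obs = study.clustered_genes + study.positives["T2"][:10]
        r = tad_coverage_test(
            obs, study.tads, study.annotation, min_genes_per_tad=1,
            n_resamples=300, seed=6,
        )
        assert r.z < 0


class TestDendrogram:
    def _scores(self, top_sets):
        rows = []
        for tissue, genes in top_sets.items():
            for i, g in enumerate(genes):
                rows.append((g, tissue, "U", 1.0 - i * 0.01, 1.0))
        return pd.DataFrame(
            rows, columns=["gene", "tissue", "label", "score", "normalized_rank"]
        )

    def test_identical_sets_distance_zero(self):
        tfs = [f"tf{i}" for i in range(20)]
        table = self._scores({"A": tfs, "B": tfs, "C": tfs})
        d = tissue_tf_dendrogram(table, set(tfs), top_k=20)
        assert np.allclose(d.distances.values, 0)

    def test_half_shared_jaccard(self):
        a = [f"tf{i}" for i in range(20)]
        b = a[:10] + [f"x{i}" for i in range(10)]
        table = self._scores({"A": a, "B": b})
        d = tissue_tf_dendrogram(table, set(a) | set(b), top_k=20)
        assert d.distances.loc["A", "B"] == pytest.approx(1 - 10 / 30)

    def test_disjoint_sets_distance_one(self):
        a = [f"a{i}" for i in range(20)]
        b = [f"b{i}" for i in range(20)]
        table = self._scores({"A": a, "B": b})
        d = tissue_tf_dendrogram(table, set(a) | set(b), top_k=20)
        assert d.distances.loc["A", "B"] == 1.0

    def test_jaccard_metric_properties(self, rng):
        universe = [f"tf{i}" for i in range(30)]
        sets = {
            t: list(rng.choice(universe, size=15, replace=False))
            for t in ("A", "B", "C", "D")
        }
        table = self._scores(sets)
        d = tissue_tf_dendrogram(table, set(universe), top_k=15).distances
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        for a, b, c in combinations(d.index, 3):
            assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-12

    def test_newick_export_contains_all_tissues(self):
        tfs = [f"tf{i}" for i in range(25)]
        rng = np.random.default_rng(2)
        sets = {t: list(rng.choice(tfs, size=20, replace=False)) for t in "ABCD"}
        table = self._scores(sets)
        nwk = tissue_tf_dendrogram(table, set(tfs), top_k=20).to_newick()
        assert nwk.endswith(";")
        for t in "ABCD":
            assert t in nwk
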
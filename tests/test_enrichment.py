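import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoidbench import de, enrichment
from organoidbench.enrichment import RankedList, _es_from_hits
from organoidbench.io import GeneSet, SampleSheet
from organoidbench.simulate import SimulationConfig, generate_design


def brute_force_es(ranked, gene_set, weight_exponent=1.0):
    """Independent oracle: explicit walk over every prefix."""
    members = set(gene_set.genes)
    n = len(ranked)
    m = sum(1 for g in ranked.genes if g in members)
    wsum = sum(
        abs(s) ** weight_exponent
        for g, s in zip(ranked.genes, ranked.stats)
        if g in members
    )
    run, best = 0.0, 0.0
    for g, s in zip(ranked.genes, ranked.stats):
        if g in members:
            run += (abs(s) ** weight_exponent) / wsum if wsum else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        if abs(run) > abs(best):
            best = run
    return best


class TestRankGenes:
    def _table(self, stats, genes=None):
        genes = genes or [f"g{i}" for i in range(len(stats))]
        return pd.DataFrame({"stat": stats}, index=genes)

    def test_sign_reversal_reverses_order(self):
        t = self._table([3.0, -1.0, 2.0])
        fwd = enrichment.rank_genes(t)
        rev = enrichment.rank_genes(self._table([-3.0, 1.0, -2.0]))
        assert rev.genes == fwd.genes[::-1]

    def test_ties_broken_by_gene_id(self):
        t = self._table([1.0, 1.0], genes=["zeta", "alpha"])
        assert enrichment.rank_genes(t).genes == ["alpha", "zeta"]

    def test_planted_top_gene_ranks_first(self, default_study):
        _, design, truth, bulk, _, _ = default_study
        table = de.nb_wald_test(bulk, design, de.Contrast("sample_type", "organoid", "crypt"))
        ranked = enrichment.rank_genes(table)
        # the strongest planted up-regulated gene should top the list
        assert ranked.genes[0] in set(truth.affected_gene_sets["sample_type"]) | {
            g for gs in truth.marker_genes.values() for g in gs
        }

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            enrichment.rank_genes(pd.DataFrame({"stat": []}))


class TestEnrichmentScore:
    def test_hand_walked_top_pair(self):
        # set at positions 1-2 with equal |r|: running sum peaks at exactly 1
        ranked = RankedList([f"g{i}" for i in range(10)], np.ones(10))
        es, running = enrichment.enrichment_score(ranked, GeneSet("S", ("g0", "g1")))
        assert es == pytest.approx(1.0)
        assert running[1] == pytest.approx(1.0)

    def test_set_at_bottom_gives_negative_es(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.linspace(5, -5, 10))
        es, _ = enrichment.enrichment_score(ranked, GeneSet("S", ("g8", "g9")))
        assert es < 0

    def test_streaming_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            genes = [f"g{i}" for i in range(n)]
            stats = np.sort(rng.normal(0, 2, n))[::-1]
            members = tuple(rng.choice(genes, size=int(rng.integers(3, 10)), replace=False))
            ranked = RankedList(genes, stats)
            gs = GeneSet("S", members)
            for w in (0.0, 1.0):
                es, _ = enrichment.enrichment_score(ranked, gs, weight_exponent=w)
                assert es == pytest.approx(brute_force_es(ranked, gs, w), abs=1e-12)

    def test_hit_position_shortcut_matches_walk(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 50
            stats = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            pos = np.sort(rng.choice(n, size=8, replace=False))
            gs = GeneSet("S", tuple(genes[i] for i in pos))
            ranked = RankedList(genes, stats)
            es, _ = enrichment.enrichment_score(ranked, gs)
            weights = np.abs(stats)
            assert abs(_es_from_hits(pos, weights[pos], n)) == pytest.approx(abs(es), abs=1e-12)

    def test_unweighted_mode_equals_ks_statistic(self):
        # weight_exponent = 0 reduces the walk to the two-sample KS statistic
        # between hit and miss rank distributions
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 40
            genes = [f"g{i}" for i in range(n)]
            ranked = RankedList(genes, np.ones(n))
            pos = np.sort(rng.choice(n, size=10, replace=False))
            gs = GeneSet("S", tuple(genes[i] for i in pos))
            es, _ = enrichment.enrichment_score(ranked, gs, weight_exponent=0.0)
            hits = np.zeros(n, dtype=bool)
            hits[pos] = True
            d = np.cumsum(hits) / hits.sum() - np.cumsum(~hits) / (~hits).sum()
            assert abs(es) == pytest.approx(np.abs(d).max(), abs=1e-12)

    @given(
        st.integers(10, 40),
        st.integers(1, 8),
        st.integers(0, 2**31 - 1),
        st.sampled_from([0.0, 0.5, 1.0]),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_walk_extremum_property(self, n, m, seed, w):
        # the streaming walk equals an explicit prefix recomputation for any
        # list size, set size, statistic draw and weight exponent
        m = min(m, n - 1)
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        stats_ = np.sort(rng.normal(0, 1.5, n))[::-1]
        members = tuple(rng.choice(genes, size=m, replace=False))
        ranked = RankedList(genes, stats_)
        gs = GeneSet("S", members)
        es, running = enrichment.enrichment_score(ranked, gs, weight_exponent=w)
        assert es == pytest.approx(brute_force_es(ranked, gs, w), abs=1e-12)
        assert abs(es) == pytest.approx(np.abs(running).max(), abs=1e-12)

    @pytest.mark.parametrize("members", [(), tuple(f"g{i}" for i in range(5))])
    def test_degenerate_sets_rejected(self, members):
        ranked = RankedList([f"g{i}" for i in range(5)], np.ones(5))
        if not members:
            with pytest.raises(Exception):
                enrichment.enrichment_score(ranked, GeneSet("S", members))
        else:
            with pytest.raises(ValueError, match="whole ranked list"):
                enrichment.enrichment_score(ranked, GeneSet("S", members))


@pytest.fixture(scope="module")
def null_ranked():
    rng = np.random.default_rng(12)
    genes = [f"g{i}" for i in range(1000)]
    stats = np.sort(rng.normal(0, 1, 1000))[::-1]
    return RankedList(genes, stats)


class TestGSEA:
    def test_null_permutation_p_calibrated(self, null_ranked):
        rng = np.random.default_rng(13)
        sets = [
            GeneSet(f"null{i}", tuple(rng.choice(null_ranked.genes, 25, replace=False)))
            for i in range(200)
        ]
        table = enrichment.gsea(null_ranked, sets, n_permutations=199, seed=14)
        frac = (table["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_stem_markers_enriched_in_organoids(self, default_study):
        _, design, truth, bulk, _, _ = default_study
        deg = de.nb_wald_test(bulk, design, de.Contrast("sample_type", "organoid", "crypt"))
        ranked = enrichment.rank_genes(deg)
        sets = [GeneSet(t, tuple(g)) for t, g in truth.marker_genes.items()]
        table = enrichment.gsea(ranked, sets, n_permutations=999, seed=0)
        # organoids are stem/TA-enriched by construction (composition shift)
        assert table.loc["Stem", "es"] > 0
        assert table.loc["Stem", "padj"] < 0.01
        assert table.loc["Enterocyte", "es"] < 0

    def test_identical_seed_identical_p(self, null_ranked):
        sets = [GeneSet("S", tuple(null_ranked.genes[100:120]))]
        a = enrichment.gsea(null_ranked, sets, n_permutations=201, seed=3)
        b = enrichment.gsea(null_ranked, sets, n_permutations=201, seed=3)
        assert (a["pvalue"] == b["pvalue"]).all()

    def test_p_never_zero(self, null_ranked):
        sets = [GeneSet("top", tuple(null_ranked.genes[:20]))]
        table = enrichment.gsea(null_ranked, sets, n_permutations=101, seed=4)
        assert table["pvalue"].iloc[0] >= 1.0 / 102


class TestZScoreSignature:
    @pytest.fixture()
    def small(self):
        rng = np.random.default_rng(30)
        cfg = SimulationConfig(
            factor_levels={"sample_type": ("crypt", "organoid")}, n_replicates=4
        )
        design = generate_design(cfg)
        data = pd.DataFrame(
            rng.normal(10, 2, size=(6, len(design))),
            index=[f"g{i}" for i in range(6)],
            columns=design.sample_ids,
        )
        return design, data

    def test_group_means_balance_to_zero(self, small):
        design, data = small
        gs = GeneSet("S", ("g0", "g1"), directions={"g0": 1, "g1": 1})
        means = enrichment.zscore_signature(data, gs, design)
        # per-gene z-scores sum to zero over all samples, so equal-sized
        # groups have opposite means
        assert means.sum() == pytest.approx(0.0, abs=1e-10)

    def test_planted_up_set_separates_groups(self, small):
        design, data = small
        up = data.columns[design.mask(sample_type="organoid")]
        data = data.copy()
        data.loc[["g0", "g1"], up] += 5
        gs = GeneSet("S", ("g0", "g1"), directions={"g0": 1, "g1": 1})
        means = enrichment.zscore_signature(data, gs, design)
        assert means["organoid"] > 0 > means["crypt"]

    def test_flipping_directions_negates_means(self, small):
        design, data = small
        gs = GeneSet("S", ("g0", "g1", "g2"), directions={"g0": 1, "g1": -1, "g2": 1})
        flipped = GeneSet("S", ("g0", "g1", "g2"), directions={"g0": -1, "g1": 1, "g2": -1})
        a = enrichment.zscore_signature(data, gs, design)
        b = enrichment.zscore_signature(data, flipped, design)
        assert b.to_numpy() == pytest.approx(-a.to_numpy(), abs=1e-12)

    def test_zero_variance_gene_excluded_with_warning(self, small):
        design, data = small
        data = data.copy()
        data.loc["g0"] = 7.0
        gs = GeneSet("S", ("g0", "g1"), directions={"g0": 1, "g1": 1})
        with pytest.warns(UserWarning, match="zero-variance"):
            enrichment.zscore_signature(data, gs, design)
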
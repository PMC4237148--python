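"""SNP-to-gene linkage windows and Fisher term enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdiff.annotation_enrichment import (
    AnnotationTrack,
    fisher_enrichment,
    genes_linked,
    link_snps_to_genes,
    neutral_control_summary,
    random_neutral_control,
)
from popdiff.synthetic_data import simulate_annotation

from ._oracles import fisher_two_tailed_enum, interval_links_bruteforce


def _loci(positions, contig="chr1"):
    return pd.DataFrame(
        {"id": [f"{contig}_{p}" for p in positions], "contig": contig, "pos": positions}
    )


def _track(spans, terms=None):
    genes = pd.DataFrame(
        [
            {"gene": f"g{i}", "contig": c, "start": s, "end": e}
            for i, (c, s, e) in enumerate(spans)
        ]
    )
    g2t = pd.DataFrame(terms or [], columns=["gene", "term"])
    return AnnotationTrack(genes=genes, gene2term=g2t)


class TestLinkage:
    def test_inclusive_window_boundary(self):
        # gene starting exactly window bp downstream is linked ...
        track = _track([("chr1", 15_001, 20_000)])
        links = link_snps_to_genes(_loci([10_000]), track, window=5000)
        assert links["chr1_10000"] == {"g0"}

    def test_beyond_window_not_linked(self):
        # ... one bp further is not
        track = _track([("chr1", 15_002, 20_000)])
        links = link_snps_to_genes(_loci([10_000]), track, window=5000)
        assert links["chr1_10000"] == set()

    def test_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(5)
        positions = np.sort(rng.choice(100_000, size=40, replace=False)) + 1
        spans = []
        for _ in range(25):
            start = int(rng.integers(1, 95_000))
            spans.append(("chr1", start, start + int(rng.integers(100, 8000))))
        track = _track(spans)
        loci = _loci(positions)
        got = link_snps_to_genes(loci, track, window=5000)
        expected = interval_links_bruteforce(loci, track.genes, 5000)
        assert got == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=20))
    def test_window_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(50_000, size=15, replace=False)) + 1
        spans = []
        for _ in range(8):
            start = int(rng.integers(1, 45_000))
            spans.append(("chr1", start, start + int(rng.integers(50, 4000))))
        track = _track(spans)
        loci = _loci(positions)
        small = link_snps_to_genes(loci, track, window=1000)
        large = link_snps_to_genes(loci, track, window=6000)
        for lid in small:
            assert small[lid] <= large[lid]

    def test_invalid_track_rejected(self):
        with pytest.raises(ValueError):
            _track([("chr1", 100, 50)])
        genes = pd.DataFrame(
            [
                {"gene": "g0", "contig": "chr1", "start": 1, "end": 10},
                {"gene": "g0", "contig": "chr1", "start": 5, "end": 20},
            ]
        )
        with pytest.raises(ValueError):
            AnnotationTrack(genes=genes, gene2term=pd.DataFrame(columns=["gene", "term"]))


class TestFisherEnrichment:
    def test_uniform_term_gives_p_one(self):
        # term carried by every gene: candidate and background proportions equal
        terms = [("g0", "T"), ("g1", "T"), ("g2", "T"), ("g3", "T")]
        track = _track([("chr1", i * 100, i * 100 + 10) for i in range(4)], terms)
        res = fisher_enrichment(["g0", "g1"], ["g0", "g1", "g2", "g3"], track)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        # k=5 of n=10 candidates carry the term, K=10 of N=100 background
        genes = [f"g{i}" for i in range(100)]
        carriers = genes[:5] + genes[10:15]  # 5 candidate carriers + 5 others
        terms = [(g, "T") for g in carriers]
        track = _track([("chr1", i * 100 + 1, i * 100 + 10) for i in range(100)], terms)
        res = fisher_enrichment(genes[:10], genes, track)
        expected = fisher_two_tailed_enum(5, 10, 10, 100)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_gene_list_order_invariance(self):
        genes = [f"g{i}" for i in range(30)]
        terms = [(g, "T") for g in genes[:8]] + [(g, "U") for g in genes[5:20]]
        track = _track([("chr1", i * 100 + 1, i * 100 + 10) for i in range(30)], terms)
        r1 = fisher_enrichment(genes[:10], genes, track)
        r2 = fisher_enrichment(genes[9::-1], genes[::-1], track)
        pd.testing.assert_frame_equal(r1, r2)

    def test_candidates_must_be_subset_of_background(self):
        track = _track([("chr1", 1, 10)])
        with pytest.raises(ValueError):
            fisher_enrichment(["gX"], ["g0"], track)
        with pytest.raises(ValueError):
            fisher_enrichment([], ["g0"], track)

    def test_adjusted_p_at_least_raw(self):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        terms = [(g, f"T{rng.integers(5)}") for g in genes]
        track = _track([("chr1", i * 100 + 1, i * 100 + 10) for i in range(40)], terms)
        res = fisher_enrichment(genes[:12], genes, track)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_planted_term_detected(self, planted_dataset):
        _, matrix, _, truth = planted_dataset
        track = simulate_annotation(
            matrix,
            truth,
            fraction_near_gene=1.0,
            enriched_terms_for_selected=("T_PLANTED",),
            p_enriched_selected=0.8,
            p_enriched_background=0.1,
            seed=3,
        )
        links = link_snps_to_genes(matrix.loci, track, window=5000)
        selected = truth[truth.isin(["positive", "fixed"])].index
        cand = genes_linked(links, selected)
        background = genes_linked(links, matrix.loci["id"])
        res = fisher_enrichment(cand, background, track)
        assert res["term"].iloc[0] == "T_PLANTED"
        assert res["p_adj"].iloc[0] < 0.001


class TestRandomNeutralControl:
    def test_seed_reproducible(self):
        pool = [f"g{i}" for i in range(50)]
        l1 = random_neutral_control(pool, 10, n_lists=5, seed=4)
        l2 = random_neutral_control(pool, 10, n_lists=5, seed=4)
        assert l1 == l2

    def test_full_pool_draw_is_whole_pool(self):
        pool = [f"g{i}" for i in range(12)]
        lists = random_neutral_control(pool, 12, n_lists=3, seed=0)
        assert all(lst == sorted(pool) for lst in lists)

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValueError):
            random_neutral_control(["g0", "g1"], 5)

    def test_null_annotation_rarely_significant(self, planted_dataset):
        # no planted signal: random neutral lists should almost never
        # produce a significant term after BH
        _, matrix, _, truth = planted_dataset
        track = simulate_annotation(
            matrix,
            truth,
            fraction_near_gene=1.0,
            enriched_terms_for_selected=(),
            p_enriched_selected=0.0,
            p_enriched_background=0.0,
            seed=8,
        )
        links = link_snps_to_genes(matrix.loci, track, window=5000)
        neutral_genes = genes_linked(links, truth[truth == "neutral"].index)
        background = genes_linked(links, matrix.loci["id"])
        n_sig, _ = neutral_control_summary(
            neutral_genes, 40, background, track, n_lists=10, seed=11, alpha=0.05
        )
        assert n_sig <= 2
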
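"""Window geometry, the binomial statistic, and the genome-wide scan."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoscan.core import GeneRecord, GeneStat, join_annotation
from genoscan.scan import (
    ScanParams,
    bin_genes,
    binomial_tail,
    regions_from_scan_frame,
    scan_genome,
    score_transform,
    significant_regions,
    window_centers,
)
from _oracles import (
    brute_merge_intervals,
    brute_window_members,
    exact_binomial_tails,
)

DEFAULTS = ScanParams()


def genes_frame(positions, dys, chrom="chr1"):
    """Positioned gene table straight from (rep_point, dysregulated) pairs."""
    pos = np.asarray(positions, dtype=np.int64)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(len(pos))],
            "chrom": chrom,
            "start": pos,
            "end": pos,
            "rep_point": pos,
            "p_value": [0.001 if d else 0.5 for d in dys],
            "t_stat": 0.0,
            "dysregulated": list(dys),
        }
    ).sort_values(["chrom", "rep_point"]).reset_index(drop=True)


class TestWindowCenters:
    def test_walk_extends_past_chromosome_end(self):
        assert window_centers(3_000_000, DEFAULTS).tolist() == [
            0, 1_250_000, 2_500_000, 3_750_000,
        ]

    def test_degenerate_chromosome_keeps_double_coverage(self):
        # both windows reaching bp 1 are emitted, so even a 1 bp
        # chromosome is covered by exactly two windows
        assert window_centers(1, DEFAULTS).tolist() == [0, 1_250_000]

    def test_ten_megabase_chromosome(self):
        centers = window_centers(10_000_000, DEFAULTS)
        assert len(centers) == 9
        assert centers[-1] == 10_000_000

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            window_centers(0, DEFAULTS)

    def test_spacing_is_exactly_step(self):
        centers = window_centers(77_000_000, DEFAULTS)
        assert set(np.diff(centers)) == {DEFAULTS.step_bp}

    def test_radius_below_step_rejected(self):
        with pytest.raises(ValueError, match="staggered"):
            ScanParams(step_bp=1_250_000, radius_bp=1_000_000)


class TestBinGenes:
    def test_right_edge_excluded(self):
        genes = genes_frame([1_250_000], [True])
        assert bin_genes(genes, 0, DEFAULTS) == (0, 0)

    def test_left_edge_included(self):
        genes = genes_frame([1_250_000], [True])
        assert bin_genes(genes, 2_500_000, DEFAULTS) == (1, 1)

    def test_counts_match_brute_force_membership(self, rng):
        pos = np.sort(rng.integers(1, 10_000_000, size=200))
        dys = rng.random(200) < 0.3
        genes = genes_frame(pos, dys)
        for center in (0, 1_250_000, 2_500_000, 5_000_000, 10_000_000):
            mask = brute_window_members(pos, center, DEFAULTS.radius_bp)
            n, k = bin_genes(genes, center, DEFAULTS)
            assert n == int(mask.sum())
            assert k == int(dys[mask].sum())


class TestBinomialTail:
    def test_tail_from_zero_is_total_mass(self):
        assert binomial_tail(50, 0, 0.01) == 1.0

    def test_all_successes_is_p_to_the_n(self):
        assert binomial_tail(10, 10, 0.01) == pytest.approx(1e-20, rel=1e-12)

    def test_against_exact_summation_oracle(self):
        tails = exact_binomial_tails(100, 0.01)
        got = binomial_tail(100, 5, 0.01)
        assert got == pytest.approx(tails[5], rel=1e-12)
        assert got == pytest.approx(3.4e-3, rel=0.05)

    def test_deep_tail_uses_exact_arithmetic(self):
        # far below scipy's underflow point, still correctly rounded
        tails = exact_binomial_tails(144, 0.001)
        assert binomial_tail(144, 108, 0.001) == pytest.approx(
            tails[108], rel=1e-12
        )

    @pytest.mark.parametrize("n,k,p", [(5, 6, 0.01), (5, -1, 0.01),
                                       (5, 2, 0.0), (5, 2, 1.0)])
    def test_invalid_arguments_rejected(self, n, k, p):
        with pytest.raises(ValueError):
            binomial_tail(n, k, p)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(1, 200), st.data())
    def test_tail_nonincreasing_in_k(self, n, data):
        k = data.draw(st.integers(1, n))
        assert binomial_tail(n, k, 0.01) <= binomial_tail(n, k - 1, 0.01)


class TestScoreTransform:
    def test_one_in_a_thousand_maps_to_three(self):
        assert score_transform(0.001, DEFAULTS) == pytest.approx(3.0)

    def test_extreme_probabilities_collapse_to_cap(self):
        assert score_transform(1e-12, DEFAULTS) == 9.0

    def test_probability_one_maps_to_zero(self):
        assert score_transform(1.0, DEFAULTS) == 0.0

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_probability_rejected(self, p):
        with pytest.raises(ValueError):
            score_transform(p, DEFAULTS)


class TestScanGenome:
    def test_null_table_scores_zero_everywhere(self):
        genes = genes_frame(
            np.arange(1, 20) * 500_000, [False] * 19
        )
        res = scan_genome(genes, {"chr1": 10_000_000}, DEFAULTS)
        assert all(w.k_dysregulated == 0 for w in res.windows)
        assert all(w.raw_p == 1.0 for w in res.windows)
        assert all(w.score == 0.0 for w in res.windows)

    def test_single_tested_window_makes_bonferroni_identity(self):
        # min_genes=2: only the middle window holds two genes, so M = 1
        # and the corrected probability equals the raw one
        params = ScanParams(min_genes=2)
        genes = genes_frame([100, 1_300_000], [True, True])
        res = scan_genome(genes, {"chr1": 2_000_000}, params)
        assert res.M == 1
        tested = [w for w in res.windows if w.tested]
        assert len(tested) == 1
        w = tested[0]
        assert w.corrected_p == w.raw_p
        assert w.score == pytest.approx(math.log10(1 / w.raw_p))

    def test_missing_chromosome_length_rejected(self):
        genes = genes_frame([100], [False])
        with pytest.raises(ValueError, match="chr1"):
            scan_genome(genes, {"chr2": 1_000_000}, DEFAULTS)

    def test_corrected_p_is_raw_times_m_clamped(self, planted_genes):
        genes, lengths = planted_genes
        res = scan_genome(genes, lengths, DEFAULTS)
        for w in res.windows:
            if w.tested:
                assert w.corrected_p == pytest.approx(
                    min(1.0, w.raw_p * res.M)
                )
            assert 0 < w.corrected_p <= 1.0
            assert 0.0 <= w.score <= DEFAULTS.score_cap

    def test_planted_cluster_scores_high_null_chromosomes_do_not(
        self, planted_genes
    ):
        genes, lengths = planted_genes
        res = scan_genome(genes, lengths, DEFAULTS)
        covering = [
            w for w in res.windows
            if w.chrom == "chr1" and w.center_bp == 11_250_000
        ]
        assert covering[0].score >= 3.0
        null_max = max(
            w.score for w in res.windows if w.chrom != "chr1"
        )
        assert null_max < 3.0

    def test_every_gene_lies_in_exactly_two_windows(self, rng):
        # staggered geometry: radius == step doubles-covers the genome
        pos = np.sort(rng.integers(1, 60_000_000, size=300))
        genes = genes_frame(pos, rng.random(300) < 0.5)
        length = 60_000_000
        centers = window_centers(length, DEFAULTS)
        counts = np.zeros(len(pos), dtype=int)
        for c in centers:
            counts += brute_window_members(pos, c, DEFAULTS.radius_bp)
        assert (counts == 2).all()

    def test_window_k_sums_to_twice_total_dysregulated(self, planted_genes):
        genes, lengths = planted_genes
        res = scan_genome(genes, lengths, DEFAULTS)
        assert (
            sum(w.k_dysregulated for w in res.windows)
            == 2 * res.n_dysregulated_total
        )

    def test_windows_ordered_with_step_spacing(self, planted_genes):
        genes, lengths = planted_genes
        res = scan_genome(genes, lengths, DEFAULTS)
        df = res.to_frame()
        for _, sub in df.groupby("chrom"):
            assert set(np.diff(sub["center_bp"])) == {DEFAULTS.step_bp}

    def test_empirical_rate_option_changes_null(self, planted_genes):
        genes, lengths = planted_genes
        res = scan_genome(
            genes, lengths, ScanParams(use_empirical_rate=True)
        )
        # empirical dysregulated fraction > 0.01 here (cluster planted),
        # so tails are larger and scores weakly smaller
        base = scan_genome(genes, lengths, DEFAULTS)
        assert max(w.score for w in res.windows) <= max(
            w.score for w in base.windows
        )


class TestSignificantRegions:
    def _result(self, scores, chrom="chr1"):
        genes = genes_frame([1], [False])
        res = scan_genome(
            genes, {chrom: (len(scores) - 2) * 1_250_000 or 1}, DEFAULTS
        )
        # rebuild windows with the requested scores
        from genoscan.scan import ScanResult, WindowResult

        windows = tuple(
            WindowResult(
                chrom=chrom,
                center_bp=i * 1_250_000,
                n_assayed=10,
                k_dysregulated=0,
                raw_p=1.0,
                corrected_p=10.0 ** -s if s > 0 else 1.0,
                score=float(s),
                tested=True,
            )
            for i, s in enumerate(scores)
        )
        return ScanResult(
            windows=windows,
            M=len(windows),
            params=DEFAULTS,
            n_genes_total=10,
            n_dysregulated_total=0,
        )

    def test_no_significant_window_gives_empty_list(self):
        assert significant_regions(self._result([0, 1, 2.9])) == []

    def test_consecutive_windows_merge_into_one_region(self):
        regs = significant_regions(self._result([0, 4, 5, 0]))
        assert len(regs) == 1
        assert regs[0].start == 1_250_000 - 1_250_000
        assert regs[0].end == 2 * 1_250_000 + 1_250_000
        assert regs[0].peak_score == 5.0
        assert regs[0].peak_center == 2 * 1_250_000
        assert regs[0].n_windows == 2

    def test_gap_splits_regions_like_interval_union(self):
        scores = [4, 0, 0, 5, 0, 6]
        regs = significant_regions(self._result(scores))
        expected = brute_merge_intervals(
            [
                (i * 1_250_000 - 1_250_000, i * 1_250_000 + 1_250_000)
                for i, s in enumerate(scores)
                if s >= 3
            ]
        )
        assert [(r.start, r.end) for r in regs] == expected

    def test_frame_rebuild_matches_in_memory_merge(self, planted_genes):
        genes, lengths = planted_genes
        res = scan_genome(genes, lengths, DEFAULTS)
        from_frame = regions_from_scan_frame(res.to_frame(), 3.0)
        assert from_frame == significant_regions(res, 3.0)
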
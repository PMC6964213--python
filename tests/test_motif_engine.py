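import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from summit_topology.io_formats import (
    GenomicInterval,
    MotifMatrix,
    reverse_complement,
)
from summit_topology.motif_engine import (
    DEFAULT_SCANNERS,
    MotifSite,
    ScannerConfig,
    consensus_sites,
    merge_peak_regions,
    optimize_pwm,
    scan,
    score_window,
)

from oracles import brute_consensus, brute_scan, brute_score


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def random_genome(rng, length, chrom="chr1"):
    return {chrom: "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])}


def sharp_matrix(consensus, weight=997.0):
    counts = np.ones((len(consensus), 4))
    for i, base in enumerate(consensus):
        counts[i, "ACGT".index(base)] = weight
    return MotifMatrix("sharp", counts)


class TestMergePeakRegions:
    def test_overlap_union(self):
        merged = merge_peak_regions([[iv("c", 0, 10)], [iv("c", 5, 15)]])
        assert merged == [iv("c", 0, 15)]

    def test_touching_intervals_merge(self):
        merged = merge_peak_regions([[iv("c", 0, 5)], [iv("c", 5, 9)]])
        assert merged == [iv("c", 0, 9)]

    def test_union_base_count_matches_boolean_oracle(self, rng):
        intervals = []
        for _ in range(100):
            start = int(rng.integers(0, 900))
            intervals.append(iv("c", start, start + int(rng.integers(1, 60))))
        merged = merge_peak_regions([intervals])
        mask = np.zeros(1000, dtype=bool)
        for interval in intervals:
            mask[interval.start : interval.end] = True
        assert sum(len(m) for m in merged) == int(mask.sum())
        starts = [m.start for m in merged]
        assert starts == sorted(starts)

    @given(st.data())
    def test_invariant_to_input_order_and_presplitting(self, data):
        spans = data.draw(
            st.lists(
                st.tuples(st.integers(0, 200), st.integers(1, 50)),
                min_size=1,
                max_size=15,
            )
        )
        intervals = [iv("c", s, s + l) for s, l in spans]
        merged = merge_peak_regions([intervals])
        shuffled = data.draw(st.permutations(intervals))
        assert merge_peak_regions([shuffled]) == merged
        # split every interval longer than 1 into two touching halves
        split = []
        for interval in intervals:
            if len(interval) > 1:
                mid = interval.start + len(interval) // 2
                split.append(iv("c", interval.start, mid))
                split.append(iv("c", mid, interval.end))
            else:
                split.append(interval)
        assert merge_peak_regions([split]) == merged


class TestScoreWindow:
    def test_hand_evaluated_two_position_matrix(self):
        # counts 10/0/0/0 with pseudocount 0.1 give p = 10.1/10.4 ~ 0.971;
        # score for the consensus is 2 * log2(p / 0.25) ~ 3.91
        matrix = MotifMatrix(
            "aa", np.array([[10.0, 0, 0, 0], [10.0, 0, 0, 0]])
        )
        expected = 2 * math.log2((10.1 / 10.4) / 0.25)
        assert score_window("AA", matrix) == pytest.approx(expected)
        assert expected == pytest.approx(3.91, abs=0.02)

    def test_uniform_matrix_scores_zero(self):
        matrix = MotifMatrix("u", np.ones((4, 4)))
        assert score_window("ACGT", matrix) == pytest.approx(0.0)

    def test_minus_strand_equals_reverse_complement_on_plus(self):
        matrix = sharp_matrix("ACGGT", weight=12.0)
        seq = "GTACC"
        assert score_window(seq, matrix, "-") == pytest.approx(
            score_window(reverse_complement(seq), matrix, "+")
        )

    def test_n_contributes_background_weighted_mean(self):
        matrix = MotifMatrix("u", np.ones((2, 4)))
        # uniform matrix: every base and N scores 0
        assert score_window("NN", matrix) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        matrix = MotifMatrix("m", np.ones((3, 4)))
        with pytest.raises(ValueError, match="length"):
            score_window("ACGT", matrix)

    def test_agrees_with_biopython_pssm(self):
        motifs = pytest.importorskip("Bio.motifs")
        counts = np.array(
            [[8.0, 2, 1, 1], [1, 9, 1, 1], [3, 3, 3, 3], [1, 1, 1, 9]]
        )
        matrix = MotifMatrix("bp", counts, pseudocount=0.5)
        motif = motifs.Motif(
            counts={
                base: counts[:, i].tolist()
                for i, base in enumerate("ACGT")
            }
        )
        pwm = motif.counts.normalize(pseudocounts=0.5)
        pssm = pwm.log_odds()  # log2 odds vs uniform background
        for seq in ("ACGT", "TTTT", "GCAT"):
            expected = sum(pssm[base][i] for i, base in enumerate(seq))
            assert score_window(seq, matrix) == pytest.approx(expected)


class TestScan:
    def test_planted_consensus_site_recovered(self, rng):
        genome = random_genome(rng, 1000)
        matrix = sharp_matrix("TGACGTCATCGC")
        seq = genome["chr1"]
        genome["chr1"] = seq[:137] + matrix.consensus + seq[149:]
        hits = scan(
            [iv("chr1", 0, 1000)],
            genome,
            matrix,
            ScannerConfig("s", 0.9),
        )
        assert any(
            h.interval.start == 137 and h.strand == "+" for h in hits
        )

    def test_uniform_matrix_at_threshold_one_reports_every_window(self, rng):
        genome = random_genome(rng, 50)
        matrix = MotifMatrix("u", np.ones((4, 4)))
        hits = scan(
            [iv("chr1", 0, 50)], genome, matrix, ScannerConfig("s", 1.0)
        )
        assert len(hits) == 2 * (50 - 4 + 1)  # both strands

    def test_region_outside_genome_rejected(self, rng):
        genome = random_genome(rng, 100)
        matrix = MotifMatrix("m", np.ones((4, 4)))
        with pytest.raises(ValueError, match="chr1"):
            scan([iv("chr1", 50, 200)], genome, matrix,
                 ScannerConfig("s", 0.5))

    def test_agrees_with_exhaustive_window_scoring(self, rng):
        genome = random_genome(rng, 600)
        counts = rng.integers(0, 20, size=(12, 4)).astype(float)
        matrix = MotifMatrix("r", counts)
        regions = [iv("chr1", 0, 200), iv("chr1", 250, 450)]
        config = ScannerConfig("s", 0.6, pseudocount=0.5)
        hits = scan(regions, genome, matrix, config)
        expected = brute_scan(
            regions, genome, counts.tolist(), 0.5, [0.25] * 4, 0.6
        )
        got = [
            (h.interval.chrom, h.interval.start, h.strand, h.score)
            for h in hits
        ]
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[:3] == e[:3]
            assert g[3] == pytest.approx(e[3])

    def test_monotone_containment_across_thresholds(self, rng):
        genome = random_genome(rng, 400)
        matrix = MotifMatrix(
            "r", rng.integers(0, 20, size=(10, 4)).astype(float)
        )
        keys = {}
        for frac in (0.75, 0.85, 0.95):
            hits = scan(
                [iv("chr1", 0, 400)], genome, matrix,
                ScannerConfig("s", frac),
            )
            keys[frac] = {(h.interval.start, h.strand) for h in hits}
        assert keys[0.95] <= keys[0.85] <= keys[0.75]

    def test_minus_strand_center_projection(self, rng):
        genome = random_genome(rng, 100)
        matrix = sharp_matrix("ACGTA")  # L=5, center_index=2
        genome["chr1"] = (
            genome["chr1"][:40]
            + reverse_complement(matrix.consensus)
            + genome["chr1"][45:]
        )
        hits = scan(
            [iv("chr1", 0, 100)], genome, matrix, ScannerConfig("s", 0.95)
        )
        minus = [h for h in hits if h.strand == "-"]
        assert minus and minus[0].center == 40 + (5 - 1 - 2)


def make_site(start, strand="+", score=1.0, chrom="c", L=10):
    return MotifSite(
        interval=GenomicInterval(chrom, start, start + L),
        strand=strand,
        score=score,
        center=start + (L - 1) // 2 if strand == "+" else start + L // 2,
        motif_name="m",
    )


class TestConsensusSites:
    def test_two_of_three_kept(self):
        result = consensus_sites(
            [[make_site(100)], [make_site(100)], []]
        )
        assert len(result) == 1
        assert result[0].supporting_scanners == 2

    def test_single_scanner_hit_dropped(self):
        assert consensus_sites([[make_site(100)], [], []]) == []

    def test_tolerance_grouping(self):
        result = consensus_sites(
            [[make_site(100)], [make_site(101)], [make_site(250)]]
        )
        assert [s.interval.start for s in result] == [100]

    def test_strand_mismatch_not_grouped(self):
        result = consensus_sites(
            [[make_site(100, "+")], [make_site(100, "-")], []]
        )
        assert result == []

    def test_wrong_list_count_rejected(self):
        with pytest.raises(ValueError, match="3"):
            consensus_sites([[], []])

    def test_representative_is_highest_scoring_member(self):
        result = consensus_sites(
            [
                [make_site(100, score=1.0)],
                [make_site(101, score=5.0)],
                [make_site(102, score=2.0)],
            ]
        )
        assert result[0].interval.start == 101
        assert result[0].supporting_scanners == 3

    @given(st.data())
    def test_invariant_under_scanner_list_permutation(self, data):
        lists = [
            [
                make_site(
                    data.draw(st.integers(0, 60)),
                    data.draw(st.sampled_from("+-")),
                    float(data.draw(st.integers(1, 9))),
                )
                for _ in range(data.draw(st.integers(0, 6)))
            ]
            for _ in range(3)
        ]
        baseline = consensus_sites(lists)
        permuted = consensus_sites(data.draw(st.permutations(lists)))
        key = lambda s: (s.interval.start, s.strand)
        assert {key(s) for s in baseline} == {key(s) for s in permuted}

    def test_agrees_with_all_pairs_union_find_oracle(self, rng):
        lists = []
        for scanner in range(3):
            hits = []
            for _ in range(300):
                start = int(rng.integers(0, 2000))
                strand = "+" if rng.random() < 0.5 else "-"
                hits.append(make_site(start, strand, float(rng.random())))
            lists.append(hits)
        got = consensus_sites(lists, tolerance=2)
        expected = brute_consensus(
            [
                [
                    (s.interval.chrom, s.interval.start, s.strand, s.score)
                    for s in hits
                ]
                for hits in lists
            ],
            tolerance=2,
        )
        got_tuples = [
            (
                s.interval.chrom,
                s.interval.start,
                s.strand,
                s.score,
                s.supporting_scanners,
            )
            for s in got
        ]
        assert got_tuples == expected


class TestOptimizePwm:
    def test_fixed_point_on_exact_consensus_sites(self, rng):
        matrix = sharp_matrix("ACGTACGTAC")
        genome = random_genome(rng, 5000)
        seq = genome["chr1"]
        regions = []
        for k in range(20):
            start = 40 + k * 200
            seq = seq[:start] + matrix.consensus + seq[start + 10 :]
            regions.append(iv("chr1", start - 20, start + 30))
        genome["chr1"] = seq
        result = optimize_pwm(regions, genome, matrix, max_iter=5)
        assert not result.no_sites
        assert result.matrix.consensus == matrix.consensus

    def test_information_content_grows_on_sharper_sites(self, rng):
        # seed matrix is fuzzy; the planted sites are exact consensus
        consensus = "ACGTACGTAC"
        fuzzy = sharp_matrix(consensus, weight=4.0)
        genome = random_genome(rng, 5000)
        seq = genome["chr1"]
        regions = []
        for k in range(20):
            start = 40 + k * 200
            seq = seq[:start] + consensus + seq[start + 10 :]
            regions.append(iv("chr1", start - 20, start + 30))
        genome["chr1"] = seq
        result = optimize_pwm(regions, genome, fuzzy, max_iter=10)
        assert not result.no_sites
        assert (
            result.matrix.information_content()
            >= fuzzy.information_content()
        )

    def test_empty_region_list_rejected(self, rng):
        with pytest.raises(ValueError, match="regions"):
            optimize_pwm([], random_genome(rng, 100), sharp_matrix("ACGT"))

    def test_probability_cells_stay_valid(self, rng):
        genome = random_genome(rng, 2000)
        matrix = sharp_matrix("ACGTAC", weight=5.0)
        result = optimize_pwm(
            [iv("chr1", 0, 2000)], genome, matrix, max_iter=3
        )
        probs = result.matrix.probabilities()
        assert np.all((probs > 0) & (probs < 1))
        assert np.allclose(probs.sum(axis=1), 1.0)


def test_default_scanners_are_three_distinct_parameterizations():
    assert len(DEFAULT_SCANNERS) == 3
    assert len({c.score_threshold_fraction for c in DEFAULT_SCANNERS}) == 3
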
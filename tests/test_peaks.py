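"""Peak segmentation, window refinement vs a literal oracle, consensus, distal calls."""

import numpy as np
import pytest

from ernascape.intervals import GenomicInterval, GenomeAnnotation
from ernascape.peaks import (
    RefinedPeak,
    classify_distal,
    refine_peak,
    replicate_consensus,
    segment_candidates,
)


def make_cov(length=50_000, background=0.02, peaks=(), fold=20, seed=0):
    rng = np.random.default_rng(seed)
    rate = np.full(length, background)
    for s, e in peaks:
        rate[s:e] = background * fold
    return {"chr1": rng.poisson(rate).astype(np.int32)}


class TestSegmentCandidates:
    def test_uniform_coverage_yields_nothing(self):
        cov = {"chr1": np.ones(20_000, dtype=np.int32)}
        assert segment_candidates(cov) == []

    def test_single_planted_region_found(self):
        cov = make_cov(peaks=[(10_000, 10_500)], seed=3)
        cands = segment_candidates(cov)
        assert len(cands) == 1
        assert cands[0].start <= 10_000 and cands[0].end >= 10_500

    def test_two_distant_peaks_stay_separate(self):
        cov = make_cov(peaks=[(10_000, 10_500), (15_500, 16_000)], seed=4)
        cands = segment_candidates(cov)
        assert len(cands) == 2

    def test_all_zero_coverage(self):
        assert segment_candidates({"chr1": np.zeros(10_000, dtype=np.int32)}) == []


def refine_oracle(candidate, arr, genome_rate, freq_cutoff=2.0):
    """Literal step-by-step re-execution of the refinement recipe."""
    expected = genome_rate * 50
    windows = []
    s = candidate.start
    while s + 50 <= candidate.end:
        freq = arr[s:s + 50].sum() / expected
        if freq >= freq_cutoff:
            windows.append((s, s + 50, freq))
        s += 25
    # merge kept windows across gaps of up to 150 bp
    regions = []
    for ws, we, _ in windows:
        if regions and ws - regions[-1][1] <= 150:
            regions[-1][1] = max(regions[-1][1], we)
        else:
            regions.append([ws, we])
    out = []
    for rs, re_ in regions:
        n = sum(1 for ws, we, _ in windows if rs <= ws and we <= re_)
        if n < 2:
            continue
        summit = rs + int(np.argmax(arr[rs:re_]))
        out.append((rs, re_, summit, n))
    return out


class TestRefinePeak:
    def test_single_passing_window_dropped(self):
        arr = np.zeros(100_000, dtype=np.int32)
        arr[1000:1050] = 10
        cov = {"chr1": arr}
        # expected per window = 2 * 50 = 100: only the fully covered window
        # (sum 500, freq 5) clears cutoff 4; its flanks reach freq 2.5
        got = refine_peak(GenomicInterval("chr1", 975, 1075), cov,
                          freq_cutoff=4.0, genome_rate=2.0, merge_gap=0)
        assert got == []

    def test_all_windows_passing_single_region_with_summit(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(0.02, 200_000).astype(np.int32)
        arr[5000:5400] += 8
        arr[5200] += 50  # unambiguous summit
        cov = {"chr1": arr}
        (peak,) = refine_peak(GenomicInterval("chr1", 5000, 5400), cov)
        assert peak.interval.start == 5000 and peak.interval.end >= 5350
        assert peak.summit == 5200
        assert peak.n_windows >= 2

    def test_matches_literal_oracle_on_random_coverage(self, rng):
        arr = rng.poisson(1.0, 30_000).astype(np.int32)
        arr[rng.integers(0, 30_000, 40)] += 20
        cov = {"chr1": arr}
        genome_rate = arr.mean()
        for _ in range(30):
            s = int(rng.integers(0, 28_000))
            cand = GenomicInterval("chr1", s, s + int(rng.integers(100, 2000)))
            got = refine_peak(cand, cov, freq_cutoff=2.0, genome_rate=genome_rate)
            want = refine_oracle(cand, arr, genome_rate)
            assert [(p.interval.start, p.interval.end, p.summit, p.n_windows)
                    for p in got] == want

    def test_organellar_chromosome_excluded(self):
        cov = {"Mt": np.full(1000, 50, dtype=np.int32)}
        assert refine_peak(GenomicInterval("Mt", 0, 1000), cov, genome_rate=0.02) == []

    def test_summit_must_lie_inside(self):
        with pytest.raises(ValueError):
            RefinedPeak(GenomicInterval("chr1", 10, 60), summit=100,
                        mean_norm_freq=2.0, n_windows=2)


class TestReplicateConsensus:
    def test_identical_sets_pass_through(self):
        x = [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 700)]
        assert replicate_consensus(x, x) == x

    def test_twenty_percent_overlap_dropped(self):
        assert replicate_consensus([GenomicInterval("c", 0, 100)],
                                   [GenomicInterval("c", 80, 180)]) == []

    def test_matches_brute_force_on_random_pairs(self, rng):
        def random_set(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 20_000))
                out.append(GenomicInterval("c", s, s + int(rng.integers(50, 600))))
            return out

        r1, r2 = random_set(200), random_set(200)
        got = replicate_consensus(r1, r2)
        want = []
        for a in r1:
            for b in r2:
                inter = a.intersection_length(b)
                if inter >= 0.5 * a.length and inter >= 0.5 * b.length:
                    want.append(a)
                    break
        assert got == want


@pytest.fixture()
def toy_annotation():
    # one plus-strand gene: TSS at 50_000
    return GenomeAnnotation(
        chrom_sizes={"chr1": 200_000},
        genes=[GenomicInterval("chr1", 50_000, 53_000, "+", "g1")],
    )


class TestClassifyDistal:
    def test_exactly_1500_bp_is_not_distal(self, toy_annotation):
        # center at 48_500, exactly 1500 from the TSS: strict > fails
        peak = GenomicInterval("chr1", 48_400, 48_600)
        distal, other = classify_distal([peak], toy_annotation)
        assert distal == [] and other == [peak]

    def test_1501_bp_away_is_distal(self, toy_annotation):
        peak = GenomicInterval("chr1", 48_399, 48_599)  # center 48_499
        distal, other = classify_distal([peak], toy_annotation)
        assert distal == [peak] and other == []

    def test_gene_body_overlap_is_not_distal(self, toy_annotation):
        peak = GenomicInterval("chr1", 52_900, 56_000)  # center far from TSS
        distal, _ = classify_distal([peak], toy_annotation)
        assert distal == []

    def test_partition_is_exhaustive(self, toy_annotation, rng):
        peaks = [GenomicInterval("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 199_000, 100)]
        distal, other = classify_distal(peaks, toy_annotation)
        assert len(distal) + len(other) == len(peaks)
        assert set(map(id, distal)).isdisjoint(map(id, other))
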
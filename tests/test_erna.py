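"""Transcript regions, TPM closed forms, eRNA calling, directionality vs enumeration."""

import math

import numpy as np
import pytest

from ernascape.erna import (
    annotate_polya_support,
    blacklist_filter,
    call_ernas,
    classify_directionality,
    classify_transcribed,
    define_transcript_region,
    tpm,
)
from ernascape.intervals import GenomicInterval, GenomeAnnotation


class TestDefineTranscriptRegion:
    def test_short_enhancer_center_plus_minus_500(self):
        r = define_transcript_region(GenomicInterval("c", 10_000, 10_300))
        assert (r.start, r.end) == (9_650, 10_650)

    def test_clamped_at_chromosome_start(self):
        r = define_transcript_region(GenomicInterval("c", 0, 300), chrom_len=100_000)
        assert (r.start, r.end) == (0, 650)

    def test_long_enhancer_keeps_own_coordinates(self):
        r = define_transcript_region(GenomicInterval("c", 5_000, 6_600))
        assert (r.start, r.end) == (5_000, 6_600)


def paint_filter_oracle(regions, features, length=100_000, extension=0):
    bad = np.zeros(length, dtype=bool)
    for f, ext in features:
        bad[max(0, f.start - ext):f.end + ext] = True
    return [r for r in regions if not bad[r.start:r.end].any()]


class TestBlacklistFilter:
    @pytest.fixture()
    def annotation(self):
        return GenomeAnnotation(
            chrom_sizes={"c": 100_000},
            genes=[GenomicInterval("c", 20_000, 23_000, "+", "g1")],
            lncrnas=[GenomicInterval("c", 60_000, 61_000, "+", "l1")],
            blacklist=[GenomicInterval("c", 80_000, 80_100, ".", "t1")],
        )

    def test_inside_1kb_extension_removed(self, annotation):
        region = GenomicInterval("c", 23_999, 24_999)  # 999 bp downstream of gene end
        assert blacklist_filter([region], annotation) == []

    def test_beyond_1kb_extension_retained(self, annotation):
        region = GenomicInterval("c", 24_001, 25_001)  # 1001 bp downstream
        assert blacklist_filter([region], annotation) == [region]

    def test_blacklist_features_not_extended(self, annotation):
        near = GenomicInterval("c", 79_500, 80_000)   # touches nothing
        inside = GenomicInterval("c", 80_050, 80_550)
        assert blacklist_filter([near, inside], annotation) == [near]

    def test_matches_per_base_painting_oracle(self, annotation, rng):
        regions = [GenomicInterval("c", int(s), int(s) + 1000)
                   for s in rng.integers(0, 99_000, 300)]
        got = blacklist_filter(regions, annotation)
        features = ([(g, 1000) for g in annotation.genes]
                    + [(l, 1000) for l in annotation.lncrnas]
                    + [(b, 0) for b in annotation.blacklist])
        assert got == paint_filter_oracle(regions, features)


class TestTpm:
    def test_single_region_gets_the_million(self):
        assert tpm({"a": 7}, {"a": 100}) == {"a": 1e6}

    def test_two_regions_length_normalized(self):
        got = tpm({"a": 10, "b": 10}, {"a": 500, "b": 1000})
        assert got["a"] == pytest.approx(666_666.67, abs=0.5)
        assert got["b"] == pytest.approx(333_333.33, abs=0.5)

    def test_all_zero_counts_no_error(self):
        assert tpm({"a": 0, "b": 0}, {"a": 100, "b": 200}) == {"a": 0.0, "b": 0.0}

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            tpm({"a": -1}, {"a": 100})

    def test_sums_to_one_million(self, rng):
        counts = {f"r{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 50))}
        lengths = {f"r{i}": int(l) for i, l in enumerate(rng.integers(100, 2000, 50))}
        assert sum(tpm(counts, lengths).values()) == pytest.approx(1e6)


class TestClassifyTranscribed:
    def test_all_zero_is_nontranscribed(self):
        assert classify_transcribed({"mock": 0}, {"mock": 0.0}) == "nontranscribed"

    def test_thresholds_inclusive(self):
        assert classify_transcribed({"mock": 5}, {"mock": 0.1}) == "transcribed"
        assert classify_transcribed({"mock": 4}, {"mock": 0.1}) == "nontranscribed"

    def test_count_and_tpm_must_coincide_in_one_condition(self):
        got = classify_transcribed({"mock": 5, "flg22": 2},
                                   {"mock": 0.01, "flg22": 5.0})
        assert got == "nontranscribed"


def binomial_direction_oracle(s, a, alpha=0.05, max_minority=0.25):
    """Direction decision with the two-sided binomial p-value fully enumerated."""
    n = s + a
    if n == 0:
        return "none"
    pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
    p = sum(q for q in pmf if q <= pmf[s] * (1 + 1e-9))
    if p < alpha and min(s, a) / n <= max_minority:
        return "uni+" if s > a else "uni-"
    if s > 0 and a > 0:
        return "bi"
    return "none"


class TestDirectionality:
    @pytest.mark.parametrize("s,a,want", [
        (50, 50, "bi"),
        (10, 0, "uni+"),   # p = 2 * 0.5^10 ~ 0.00195
        (0, 10, "uni-"),
        (5, 2, "bi"),      # two-sided exact p ~ 0.453
        (0, 0, "none"),
        (3, 0, "none"),    # one silent strand, not significant
        (580, 420, "bi"),  # p < 0.05 but both strands clearly active
    ])
    def test_examples(self, s, a, want):
        assert classify_directionality(s, a) == want

    def test_agrees_with_enumeration_for_all_small_totals(self):
        for n in range(0, 201):
            for s in range(0, n + 1):
                assert classify_directionality(s, n - s) == \
                    binomial_direction_oracle(s, n - s), (s, n - s)


class TestCallErnas:
    def test_zero_coverage_no_calls(self):
        rna = {s: {"c": np.zeros(10_000, dtype=np.int32)} for s in "+-"}
        regions = [GenomicInterval("c", 4_000, 5_000, ".", "e1")]
        assert call_ernas(rna, regions, background_rate=0.01) == []

    def test_nonpositive_background_rejected(self):
        rna = {s: {"c": np.zeros(1_000, dtype=np.int32)} for s in "+-"}
        with pytest.raises(ValueError):
            call_ernas(rna, [GenomicInterval("c", 0, 500, ".", "e")],
                       background_rate=0.0)

    def test_planted_erna_recovered_within_window_resolution(self, rng):
        background = 0.01
        arr = rng.poisson(background, 20_000).astype(np.int32)
        arr[5_400:5_600] += rng.poisson(background * 20, 200)  # 200 bp at 20x
        rna = {"+": {"c": arr}, "-": {"c": rng.poisson(background, 20_000).astype(np.int32)}}
        region = GenomicInterval("c", 5_000, 6_000, ".", "e1")
        calls = [c for c in call_ernas(rna, [region], background_rate=background)
                 if c.interval.strand == "+"]
        assert len(calls) == 1
        assert abs(calls[0].interval.start - 5_400) <= 50
        assert abs(calls[0].interval.end - 5_600) <= 50

    def test_polya_support_flag(self, rng):
        arr = np.zeros(10_000, dtype=np.int32)
        arr[2_000:2_300] = 3
        rna = {"+": {"c": arr}, "-": {"c": np.zeros(10_000, dtype=np.int32)}}
        calls = call_ernas(rna, [GenomicInterval("c", 1_800, 2_800, ".", "enhX")],
                           background_rate=0.01)
        flagged = annotate_polya_support(calls, {"enhX": 12}, min_count=5)
        assert all(c.polya_supported for c in flagged)
        unflagged = annotate_polya_support(calls, {"enhX": 4}, min_count=5)
        assert not any(c.polya_supported for c in unflagged)

    def test_call_carries_parent_and_strand(self, rng):
        arr = np.zeros(10_000, dtype=np.int32)
        arr[2_000:2_300] = 3
        rna = {"+": {"c": np.zeros(10_000, dtype=np.int32)}, "-": {"c": arr}}
        region = GenomicInterval("c", 1_800, 2_800, ".", "enhX")
        (call,) = call_ernas(rna, [region], background_rate=0.01)
        assert call.parent_enhancer == "enhX"
        assert call.interval.strand == "-"
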
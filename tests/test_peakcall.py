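"""Coverage, candidate calling, summit location and the knockout filter."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kochip.genomic_io import Tag
from kochip.params import PipelineParams
from kochip.peakcall import (
    Peak,
    annotate_interval,
    call_candidates,
    extended_coverage,
    knockout_filter,
    locate_summit_interval,
)
from kochip.synthetic_data import SimConfig, generate_truth, simulate_sample_tags
from kochip.synthetic_data import ALWAYS_MGA


def brute_force_pileup(tags, chrom_length, L):
    cov = np.zeros(chrom_length, dtype=np.int64)
    for t in tags:
        if t.strand == "+":
            cov[t.pos:min(t.pos + L, chrom_length)] += 1
        else:
            cov[max(t.pos - L + 1, 0):t.pos + 1] += 1
    return cov


class TestExtendedCoverage:
    def test_plus_tag_covers_forward(self):
        track = extended_coverage([Tag("c", 100, "+")], 1000, 200)
        expected = np.zeros(1000, dtype=np.int64)
        expected[100:300] = 1
        np.testing.assert_array_equal(track.values, expected)

    def test_minus_tag_covers_backward(self):
        track = extended_coverage([Tag("c", 499, "-")], 1000, 200)
        expected = np.zeros(1000, dtype=np.int64)
        expected[300:500] = 1
        np.testing.assert_array_equal(track.values, expected)

    def test_truncation_at_chromosome_ends(self):
        track = extended_coverage([Tag("c", 950, "+"), Tag("c", 10, "-")], 1000, 200)
        assert track.values[:11].sum() == 11  # - tag truncated to [0, 11)
        assert track.values[950:].sum() == 50
        # pileup mass = sum of truncated extension lengths
        assert track.values.sum() == 50 + 11

    def test_random_tags_match_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            tags = [
                Tag("c", int(rng.integers(0, 3000)), "+" if rng.random() < 0.5 else "-")
                for _ in range(n)
            ]
            track = extended_coverage(tags, 3000, 200)
            np.testing.assert_array_equal(
                track.values, brute_force_pileup(tags, 3000, 200)
            )

    def test_tag_beyond_chromosome_end_fails(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            extended_coverage([Tag("c", 1000, "+")], 1000, 200)

    def test_overlap_counts_match_brute_force(self):
        rng = np.random.default_rng(11)
        tags = [
            Tag("c", int(rng.integers(0, 5000)), "+" if rng.random() < 0.5 else "-")
            for _ in range(200)
        ]
        track = extended_coverage(tags, 5000, 200)
        for _ in range(100):
            a = int(rng.integers(0, 4900))
            b = int(a + rng.integers(1, 100))
            expected = sum(
                1
                for t in tags
                for s, e in [
                    (t.pos, min(t.pos + 200, 5000))
                    if t.strand == "+"
                    else (max(t.pos - 199, 0), t.pos + 1)
                ]
                if s < b and e > a
            )
            assert track.count_overlapping(a, b) == expected


class TestLocateSummit:
    def test_leftmost_tie(self):
        assert locate_summit_interval(np.array([1, 3, 3, 2]), 0, 4) == 1

    def test_single_extended_tag_summit_at_start(self):
        track = extended_coverage([Tag("c", 120, "+")], 1000, 200)
        assert locate_summit_interval(track.values, 100, 400) == 120

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            values = rng.integers(0, 10, size=200)
            values[rng.integers(0, 200)] += 1  # ensure non-zero
            lo = int(rng.integers(0, 100))
            hi = int(lo + rng.integers(1, 100))
            if values[lo:hi].max() == 0:
                continue
            got = locate_summit_interval(values, lo, hi)
            best = max(range(lo, hi), key=lambda i: (values[i], -i))
            assert got == best

    def test_zero_coverage_is_malformed(self):
        with pytest.raises(ValueError, match="malformed"):
            locate_summit_interval(np.zeros(10, dtype=int), 2, 8)


class TestKnockoutFilter:
    @pytest.mark.parametrize(
        "tag_count,ratio,kept",
        [
            (29, 10.0, False),  # below the 30-tag floor despite huge ratio
            (100, 2.99, False),  # just below 3x
            (30, 3.0, True),  # both boundaries inclusive
            (30, 2.9999, False),
            (1000, 1.0, False),  # the artifact signature
        ],
    )
    def test_boundaries(self, tag_count, ratio, kept):
        peak = Peak("c", 0, 100, 50, tag_count, ratio, float(tag_count))
        result = knockout_filter([peak], PipelineParams())
        assert (len(result) == 1) is kept

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=200),
                st.floats(min_value=0, max_value=20, allow_nan=False),
            ),
            max_size=30,
        ),
        st.integers(min_value=1, max_value=100),
        st.floats(min_value=0.5, max_value=10),
    )
    def test_monotonicity(self, entries, min_tags, min_ratio):
        """Raising either threshold never adds peaks."""
        peaks = [
            Peak("c", i * 10, i * 10 + 5, i * 10, tc, r, float(tc))
            for i, (tc, r) in enumerate(entries)
        ]
        base = PipelineParams(min_tags=min_tags, min_ratio=min_ratio)
        kept = set(p.start for p in knockout_filter(peaks, base))
        stricter = PipelineParams(min_tags=min_tags + 5, min_ratio=min_ratio + 0.5)
        kept_strict = set(p.start for p in knockout_filter(peaks, stricter))
        assert kept_strict <= kept


def _background_tags(rng, n, length):
    return [
        Tag("c", int(rng.integers(0, length)), "+" if rng.random() < 0.5 else "-")
        for _ in range(n)
    ]


class TestCallCandidates:
    def test_flat_equal_background_gives_no_candidates(self):
        """Type-I control: treat == control in distribution -> nothing called."""
        params = PipelineParams()
        false_runs = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            length = 200_000
            treat = extended_coverage(
                _background_tags(rng, 1000, length), length, 200, chrom="c"
            )
            control = extended_coverage(
                _background_tags(rng, 1000, length), length, 200, chrom="c"
            )
            if call_candidates(treat, control, params):
                false_runs += 1
        assert false_runs <= 1

    def test_single_strong_site_yields_one_candidate_with_summit(self):
        cfg = SimConfig(
            chrom_lengths={"c": 200_000},
            sites_per_class={ALWAYS_MGA: 1},
            lambda_bg=0.005,
            depth=1e7,
            strength_range=(100.0, 100.0),
            n_background_genes=0,
            seed=1,
        )
        truth, _ = generate_truth(cfg)
        treat_tags = simulate_sample_tags(truth, cfg, "MGA", "WT")
        ctrl_tags = simulate_sample_tags(truth, cfg, "MGA", "MGAko")
        params = PipelineParams()
        treat = extended_coverage(treat_tags, 200_000, 200, chrom="c")
        control = extended_coverage(ctrl_tags, 200_000, 200, chrom="c")
        candidates = call_candidates(treat, control, params)
        assert len(candidates) == 1
        peak = candidates[0]
        assert peak.start <= truth[0].summit < peak.end
        assert abs(peak.summit - truth[0].summit) <= 100

    def test_control_identical_to_treatment_ratio_one(self):
        rng = np.random.default_rng(3)
        length = 10_000
        tags = _background_tags(rng, 300, length)
        track = extended_coverage(tags, length, 200, chrom="c")
        peak = annotate_interval(track, track, 4000, 5000, PipelineParams())
        assert peak.ratio == pytest.approx(1.0)

    def test_zero_depth_treatment_fails(self):
        params = PipelineParams()
        empty = extended_coverage([], 1000, 200, chrom="c")
        full = extended_coverage([Tag("c", 10, "+")], 1000, 200, chrom="c")
        with pytest.raises(ValueError, match="zero-depth"):
            call_candidates(empty, full, params)

    def test_depth_correction_invariance(self):
        """Doubling every control tag and the control depth leaves ratios
        unchanged (wherever the control count is >= 1)."""
        rng = np.random.default_rng(4)
        length = 50_000
        treat = extended_coverage(
            _background_tags(rng, 2000, length), length, 200, chrom="c"
        )
        ctrl_tags = _background_tags(rng, 800, length)
        params = PipelineParams()
        c1 = extended_coverage(ctrl_tags, length, 200, chrom="c")
        c2 = extended_coverage(ctrl_tags * 2, length, 200, chrom="c")
        for start in range(0, 45_000, 1500):
            end = start + 1000
            if treat.count_overlapping(start, end) == 0:
                continue
            if c1.count_overlapping(start, end) == 0:
                continue
            p1 = annotate_interval(treat, c1, start, end, params)
            p2 = annotate_interval(treat, c2, start, end, params)
            assert p1.ratio == pytest.approx(p2.ratio)
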
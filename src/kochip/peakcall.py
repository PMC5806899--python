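"""Candidate peak calling and the knockout-control filter.

The caller is deliberately simple and pluggable: single-end tags are
extended to 200 bp, a sliding window is tested against a Poisson null
whose rate is the depth-scaled control density (max of the global
chromosome rate and a local +-5 kb rate), significant windows are
merged, and each candidate is annotated with its tag count,
depth-corrected treatment/control ratio and summit. The scientific
filter on top — at least 30 tags and a depth-corrected ratio over the
knockout (or IgG) control of at least 3x — is what removes antibody
artifacts, which by construction appear in both libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_io import Tag
from .params import PipelineParams


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base pileup of 200-bp-extended tags on one chromosome.

    Carries the sorted extended-interval bounds so that exact
    tags-overlapping-interval counts remain available downstream.
    ``depth`` is the full library tag total (all chromosomes), used for
    depth normalisation.
    """

    chrom: str
    values: np.ndarray  # int per-base pileup
    depth: int
    ext_starts: np.ndarray  # sorted extended-interval starts
    ext_ends: np.ndarray  # sorted extended-interval ends

    @property
    def n_tags(self) -> int:
        return int(self.ext_starts.size)

    def count_overlapping(self, start: int, end: int) -> int:
        """Number of extended tags overlapping [start, end)."""
        lo = np.searchsorted(self.ext_starts, end, side="left")
        hi = np.searchsorted(self.ext_ends, start, side="right")
        return int(lo - hi)


@dataclass(frozen=True)
class Peak:
    """A candidate or filtered binding site."""

    chrom: str
    start: int
    end: int
    summit: int
    tag_count: int
    ratio: float
    rank_score: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty peak interval [{self.start},{self.end})")
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak interval")
        if self.tag_count < 0 or self.ratio < 0:
            raise ValueError("tag_count and ratio must be non-negative")


def extend_intervals(
    tags: Sequence[Tag], chrom_length: int, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extended-read intervals, truncated at chromosome ends.

    A + tag at p covers [p, min(p+L, len)); a - tag at p covers
    [max(p-L+1, 0), p+1).
    """
    starts = np.empty(len(tags), dtype=np.int64)
    ends = np.empty(len(tags), dtype=np.int64)
    for i, t in enumerate(tags):
        if t.pos < 0 or t.pos >= chrom_length:
            raise ValueError(
                f"tag at {t.chrom}:{t.pos} outside chromosome of length {chrom_length}"
            )
        if t.strand == "+":
            starts[i] = t.pos
            ends[i] = min(t.pos + L, chrom_length)
        else:
            starts[i] = max(t.pos - L + 1, 0)
            ends[i] = t.pos + 1
    return starts, ends


def extended_coverage(
    tags: Sequence[Tag],
    chrom_length: int,
    L: int = 200,
    depth: int | None = None,
    chrom: str | None = None,
) -> CoverageTrack:
    """Pileup of tags extended to ``L`` bp on one chromosome.

    ``depth`` defaults to the number of tags given; pass the library
    total when tags span several chromosomes.
    """
    chroms = {t.chrom for t in tags}
    if len(chroms) > 1:
        raise ValueError(f"tags span multiple chromosomes: {sorted(chroms)}")
    name = chrom if chrom is not None else (chroms.pop() if chroms else "")
    starts, ends = extend_intervals(tags, chrom_length, L)
    diff = np.zeros(chrom_length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    values = np.cumsum(diff[:-1])
    return CoverageTrack(
        chrom=name,
        values=values,
        depth=int(depth if depth is not None else len(tags)),
        ext_starts=np.sort(starts),
        ext_ends=np.sort(ends),
    )


def _window_counts(track: CoverageTrack, starts: np.ndarray, width: int) -> np.ndarray:
    """Extended tags overlapping each [s, s+width), vectorised."""
    lo = np.searchsorted(track.ext_starts, starts + width, side="left")
    hi = np.searchsorted(track.ext_ends, starts, side="right")
    return lo - hi


def call_candidates(
    treat: CoverageTrack, control: CoverageTrack, params: PipelineParams
) -> list[Peak]:
    """Windowed Poisson caller against the depth-scaled control.

    Windows of ``params.window`` bp every ``params.step`` bp are kept
    when their treatment tag count beats a Poisson upper tail at
    ``params.p_cutoff`` under lambda = max(global, local +-5 kb) control
    density scaled to treatment depth; kept windows closer than
    ``params.merge_gap`` are merged and annotated.
    """
    if treat.chrom != control.chrom:
        raise ValueError(f"chromosome mismatch: {treat.chrom} vs {control.chrom}")
    if treat.depth <= 0 or treat.n_tags == 0:
        raise ValueError("zero-depth treatment library")
    if control.depth <= 0:
        raise ValueError("zero-depth control library")

    w, L = params.window, params.extension
    chrom_len = treat.values.size
    starts = np.arange(0, max(chrom_len - w + 1, 1), params.step, dtype=np.int64)
    k = _window_counts(treat, starts, w)

    depth_scale = treat.depth / control.depth
    # an extended L-bp control interval overlaps a w-bp window iff its
    # start falls in a (w + L)-bp span; rates below are per such span
    ctrl_rate = control.n_tags / chrom_len
    lam_global = ctrl_rate * (w + L)
    half = params.local_half_width
    local_counts = _window_counts(
        control, np.maximum(starts + w // 2 - half, 0), 2 * half
    )
    lam_local = local_counts * (w + L) / (2 * half + L)
    lam = np.maximum(np.maximum(lam_global, lam_local), params.min_lambda) * depth_scale

    pvals = stats.poisson.sf(k - 1, lam)
    sig = np.flatnonzero(pvals < params.p_cutoff)
    if sig.size == 0:
        return []

    intervals = _merge_windows(starts[sig], w, chrom_len, params.merge_gap)
    peaks = []
    for s, e in intervals:
        peaks.append(annotate_interval(treat, control, int(s), int(e), params))
    return peaks


def _merge_windows(
    win_starts: np.ndarray, width: int, chrom_len: int, gap: int
) -> list[tuple[int, int]]:
    intervals: list[tuple[int, int]] = []
    cur_s = int(win_starts[0])
    cur_e = min(cur_s + width, chrom_len)
    for s in win_starts[1:]:
        s = int(s)
        if s <= cur_e + gap:
            cur_e = min(s + width, chrom_len)
        else:
            intervals.append((cur_s, cur_e))
            cur_s, cur_e = s, min(s + width, chrom_len)
    intervals.append((cur_s, cur_e))
    return intervals


def annotate_interval(
    treat: CoverageTrack,
    control: CoverageTrack,
    start: int,
    end: int,
    params: PipelineParams,
) -> Peak:
    """Build a Peak for [start, end): tag count, ratio, summit, rank score.

    ratio = (treat count / treat depth) / (max(control count, c0) /
    control depth) with pseudo-count c0 because knockout controls can
    have zero local tags; rank_score = treat count per
    ``params.depth_scale`` tags of depth.
    """
    tag_count = treat.count_overlapping(start, end)
    ctrl_count = control.count_overlapping(start, end)
    ratio = (tag_count / treat.depth) / (
        max(ctrl_count, params.pseudo_control_tags) / control.depth
    )
    summit = locate_summit_interval(treat.values, start, end)
    return Peak(
        chrom=treat.chrom,
        start=start,
        end=end,
        summit=summit,
        tag_count=tag_count,
        ratio=float(ratio),
        rank_score=float(tag_count * params.depth_scale / treat.depth),
    )


def locate_summit_interval(values: np.ndarray, start: int, end: int) -> int:
    """Leftmost argmax of the pileup within [start, end)."""
    window = values[start:end]
    if window.size == 0 or window.max() == 0:
        raise ValueError(f"no coverage inside [{start},{end}): malformed peak")
    return start + int(np.argmax(window))


def locate_summit(peak: Peak, coverage: CoverageTrack) -> int:
    """Summit of a peak: the point of highest extended-read overlap."""
    return locate_summit_interval(coverage.values, peak.start, peak.end)


def knockout_filter(peaks: Iterable[Peak], params: PipelineParams) -> list[Peak]:
    """Keep peaks with >= min_tags tags and ratio >= min_ratio (inclusive)."""
    return [
        p
        for p in peaks
        if p.tag_count >= params.min_tags and p.ratio >= params.min_ratio
    ]


def call_peaks_genome(
    treat_tags: Sequence[Tag],
    control_tags: Sequence[Tag],
    chrom_lengths: dict[str, int],
    params: PipelineParams,
    apply_filter: bool = True,
) -> list[Peak]:
    """Whole-genome convenience wrapper: per-chromosome call + filter.

    Library depths are the genome-wide tag totals. Peaks are named
    sequentially in genomic order.
    """
    depth_t, depth_c = len(treat_tags), len(control_tags)
    by_chrom_t: dict[str, list[Tag]] = {c: [] for c in chrom_lengths}
    by_chrom_c: dict[str, list[Tag]] = {c: [] for c in chrom_lengths}
    for t in treat_tags:
        by_chrom_t[t.chrom].append(t)
    for t in control_tags:
        by_chrom_c[t.chrom].append(t)

    peaks: list[Peak] = []
    for chrom in sorted(chrom_lengths):
        clen = chrom_lengths[chrom]
        if not by_chrom_t[chrom]:
            continue
        treat = extended_coverage(
            by_chrom_t[chrom], clen, params.extension, depth=depth_t, chrom=chrom
        )
        control = extended_coverage(
            by_chrom_c[chrom], clen, params.extension, depth=depth_c, chrom=chrom
        )
        peaks.extend(call_candidates(treat, control, params))
    if apply_filter:
        peaks = knockout_filter(peaks, params)
    return [replace(p, name=f"peak_{i:05d}") for i, p in enumerate(peaks)]


def top_ranked(peaks: Sequence[Peak], n: int) -> list[Peak]:
    """Top-``n`` peaks by rank score (depth-normalised tag count), stable."""
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i].rank_score)
    return [peaks[i] for i in order[:n]]
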
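"""Summit-centred signal matrices and normalized per-region counts.

Heatmap data: one row per summit window, one column per base, values =
depth-normalised extended-read pileup, capped at each sample's own 99th
percentile for contrast, rows ordered by the signal sum of the first
sample and that order applied identically to every sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import Tag
from .params import PipelineParams
from .peakcall import CoverageTrack, extended_coverage


@dataclass
class SignalMatrix:
    """Depth-normalised, percentile-truncated signal around summits."""

    sample: str
    values: np.ndarray  # rows = regions, cols = base positions
    row_order: np.ndarray  # permutation applied to the input region list
    cap: float  # the percentile cap actually applied
    clipped_rows: list[int]  # input rows that hit a chromosome edge


def _coverage_by_chrom(
    tags: Sequence[Tag],
    chrom_lengths: dict[str, int],
    extension: int,
) -> tuple[dict[str, CoverageTrack], int]:
    depth = len(tags)
    by_chrom: dict[str, list[Tag]] = {}
    for t in tags:
        by_chrom.setdefault(t.chrom, []).append(t)
    tracks = {
        chrom: extended_coverage(
            ts, chrom_lengths[chrom], extension, depth=depth, chrom=chrom
        )
        for chrom, ts in by_chrom.items()
    }
    return tracks, depth


def summit_signal_matrix(
    summits: Sequence[tuple[str, int]],
    tags_by_sample: dict[str, Sequence[Tag]],
    chrom_lengths: dict[str, int],
    flank: int = 2000,
    params: PipelineParams | None = None,
) -> dict[str, SignalMatrix]:
    """Summit +- flank matrices for every sample, consistently ordered.

    Values are per-base extended-tag pileup scaled by
    ``depth_scale / depth``; each sample is truncated at its own
    ``truncate_percentile`` computed over all of its matrix entries.
    Row order is the descending row-sum order of the first sample
    (stable: ties keep input order) and is applied to all samples.
    Windows reaching past a chromosome edge are zero-padded and
    reported in ``clipped_rows``.
    """
    params = params or PipelineParams()
    width = 2 * flank + 1
    sample_names = list(tags_by_sample)
    if not sample_names:
        return {}

    raw: dict[str, np.ndarray] = {}
    clipped: list[int] = []
    for si, sample in enumerate(sample_names):
        tracks, depth = _coverage_by_chrom(
            tags_by_sample[sample], chrom_lengths, params.extension
        )
        mat = np.zeros((len(summits), width), dtype=float)
        # a tag-less sample yields an all-zero matrix rather than an error
        scale = params.depth_scale / depth if depth else 0.0
        for ri, (chrom, summit) in enumerate(summits):
            clen = chrom_lengths[chrom]
            lo, hi = summit - flank, summit + flank + 1
            clo, chi = max(lo, 0), min(hi, clen)
            if (clo != lo or chi != hi) and si == 0:
                clipped.append(ri)
            track = tracks.get(chrom)
            if track is None or clo >= chi:
                continue
            mat[ri, clo - lo: chi - lo] = track.values[clo:chi] * scale
        raw[sample] = mat

    order = np.argsort(-raw[sample_names[0]].sum(axis=1), kind="stable")
    out: dict[str, SignalMatrix] = {}
    for sample in sample_names:
        mat = raw[sample]
        cap = float(np.percentile(mat, params.truncate_percentile))
        out[sample] = SignalMatrix(
            sample=sample,
            values=np.minimum(mat, cap)[order],
            row_order=order,
            cap=cap,
            clipped_rows=list(clipped),
        )
    return out


def peak_region_counts(
    peaks: Sequence,
    tags: Sequence[Tag],
    chrom_lengths: dict[str, int],
    depth: int | None = None,
    scale: float = 1e7,
    extension: int = 200,
) -> np.ndarray:
    """Depth-normalised extended-tag counts per fixed peak region.

    The same (wild-type-defined) regions are reused across genotypes so
    per-site occupancy is comparable; count = number of extended tags
    overlapping [start, end), times ``scale / depth``.
    """
    depth = len(tags) if depth is None else depth
    if depth <= 0:
        raise ValueError("library depth must be positive")
    tracks, _ = _coverage_by_chrom(tags, chrom_lengths, extension)
    out = np.zeros(len(peaks), dtype=float)
    for i, p in enumerate(peaks):
        track = tracks.get(p.chrom)
        if track is not None:
            out[i] = track.count_overlapping(p.start, p.end) * scale / depth
    return out


def write_matrix_tsv(matrix: SignalMatrix, path) -> None:
    header = f"# sample={matrix.sample}\tcap={matrix.cap!r}"
    np.savetxt(path, matrix.values, fmt="%.6g", delimiter="\t", header=header)
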
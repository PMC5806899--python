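"""Genomic interval set algebra.

Overlaps and unions are computed on an at-least-1-bp basis with
half-open intervals (abutting intervals do not overlap). Venn counting
is region-based: the counting unit is a maximal merged region of the
union of all sets, and a set is a member of a union region if any of
its intervals overlaps it — this is what makes a single "union n"
statistic across several factors well-defined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genomic_io import GeneModel


@dataclass
class RegionSet:
    """A named collection of genomic intervals (not necessarily disjoint)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"invalid interval {chrom}:[{start},{end})")
        self._trees: dict[str, IntervalTree] | None = None

    @classmethod
    def from_peaks(cls, name: str, peaks: Iterable) -> "RegionSet":
        return cls(name, [(p.chrom, p.start, p.end) for p in peaks])

    def sorted_intervals(self) -> list[tuple[str, int, int]]:
        return sorted(self.intervals)

    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end in self.intervals:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._trees = trees
        return self._trees

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees().get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def __len__(self) -> int:
        return len(self.intervals)


def overlap_pairs(
    a: RegionSet, b: RegionSet
) -> list[tuple[tuple[str, int, int], tuple[str, int, int]]]:
    """All (interval-of-a, interval-of-b) pairs sharing >= 1 bp."""
    pairs = []
    b_trees = b.trees()
    for chrom, start, end in a.sorted_intervals():
        tree = b_trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(start, end)):
            pairs.append(((chrom, start, end), (chrom, hit.begin, hit.end)))
    return pairs


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Maximal merged intervals (union); abutting intervals stay separate."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def venn_membership(sets: Sequence[RegionSet]):
    """Region-based Venn decomposition of 2-4 interval sets.

    Returns ``(union_regions, memberships, counts)`` where
    ``union_regions`` are the maximal merged intervals over all sets,
    ``memberships[i]`` is the frozenset of set names overlapping union
    region ``i`` by >= 1 bp, and ``counts`` maps each membership
    category to its number of union regions. ``sum(counts.values())``
    equals ``len(union_regions)``.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_membership supports 2-4 sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    union_regions = merge_intervals(
        iv for s in sets for iv in s.intervals
    )
    memberships = []
    for chrom, start, end in union_regions:
        member = frozenset(s.name for s in sets if s.overlaps(chrom, start, end))
        memberships.append(member)
    counts = dict(Counter(memberships))
    return union_regions, memberships, counts


def gene_window(gene: GeneModel, upstream: int = 2500) -> tuple[str, int, int]:
    """Half-open association window: ``upstream`` bp 5' of the TSS
    (in transcription direction) through the TES."""
    if gene.strand == "+":
        return (gene.chrom, max(gene.tss - upstream, 0), gene.tes + 1)
    return (gene.chrom, gene.tes, gene.tss + upstream + 1)


def associate_peaks_to_genes(
    peaks: Sequence, genes: Sequence[GeneModel], upstream: int = 2500
) -> list[tuple[str, str]]:
    """(peak name, gene id) pairs where the peak overlaps the gene window.

    A peak may hit several genes and a gene several peaks.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        chrom, start, end = gene_window(g, upstream)
        trees.setdefault(chrom, IntervalTree()).addi(start, end, g.gene_id)
    out: list[tuple[str, str]] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        hits = sorted(
            (hit.begin, hit.end, hit.data) for hit in tree.overlap(p.start, p.end)
        )
        out.extend((p.name, gid) for _, _, gid in hits)
    return out


def bound_gene_ids(
    peaks: Sequence, genes: Sequence[GeneModel], upstream: int = 2500
) -> set[str]:
    """Genes associated with at least one peak."""
    return {gid for _, gid in associate_peaks_to_genes(peaks, genes, upstream)}


def metagene_profile(
    summits: Sequence[tuple[str, int]],
    genes: Sequence[GeneModel],
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin_width: int = 50,
) -> np.ndarray:
    """Peak-summit density around scaled gene bodies.

    Coordinates run from ``-flank`` bp upstream of the TSS, through the
    gene body rescaled to ``body_bins`` bins, to ``flank`` bp downstream
    of the TES, respecting gene orientation. Each summit inside the span
    of a gene contributes one count (to every gene whose span contains
    it); the profile is normalised to sum to 1 when any summit maps,
    otherwise returned as zeros.
    """
    n_flank = flank // flank_bin_width
    profile = np.zeros(2 * n_flank + body_bins, dtype=float)
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in summits:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in by_chrom:
        by_chrom[chrom] = sorted(by_chrom[chrom])

    for g in genes:
        positions = by_chrom.get(g.chrom)
        if not positions:
            continue
        lo, hi = (g.tss, g.tes) if g.strand == "+" else (g.tes, g.tss)
        length = hi - lo
        if length <= 0:
            continue
        arr = np.asarray(positions)
        sel = arr[(arr >= lo - flank) & (arr <= hi + flank)]
        for pos in sel:
            # signed offset in transcription direction
            if g.strand == "+":
                rel = pos - g.tss
                body_len = g.tes - g.tss
            else:
                rel = g.tss - pos
                body_len = g.tss - g.tes
            if rel < 0:
                b = max(n_flank + rel // flank_bin_width, 0)
            elif rel < body_len:
                b = n_flank + int(body_bins * rel / body_len)
            else:
                b = n_flank + body_bins + min(
                    (rel - body_len) // flank_bin_width, n_flank - 1
                )
            profile[int(b)] += 1
    total = profile.sum()
    return profile / total if total > 0 else profile
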
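"""Readers and writers for the plain-text formats the pipeline touches.

Formats: tag BED6 (one aligned read reduced to its 5' base), gene-model
TSV, peak BED6+, bedGraph coverage, FASTA genomes, and TSV count
matrices. All coordinates are 0-based half-open; chromosome names are
compared as exact strings. Readers and writers are exact inverses on
valid files.
"""

from __future__ import annotations

import os
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta


class Tag(NamedTuple):
    """One aligned sequencing read: chromosome, 0-based 5' position, strand."""

    chrom: str
    pos: int
    strand: str  # "+" or "-"


class GeneModel(NamedTuple):
    """Gene with oriented TSS/TES in genomic coordinates.

    For a + strand gene tss < tes; for a - strand gene tss > tes (the
    TSS is where transcription starts, in genomic coordinates).
    """

    chrom: str
    tss: int
    tes: int
    strand: str
    gene_id: str


class BedFormatError(ValueError):
    """A malformed line in a BED/TSV input, reported with its line number."""


def _check_strand(strand: str, path: str, lineno: int) -> None:
    if strand not in ("+", "-"):
        raise BedFormatError(
            f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
        )


# ---------------------------------------------------------------------------
# tags


def read_tags_bed(path: str | os.PathLike) -> list[Tag]:
    """Read tags from a BED6 file (each tag a 1-bp interval at its 5' base).

    Returns tags sorted by (chrom, pos). Lines starting with '#' or
    'track' are skipped. Malformed lines raise :class:`BedFormatError`
    naming the offending line.
    """
    tags: list[Tag] = []
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            strand = fields[5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start < 0:
                raise BedFormatError(f"{path}:{lineno}: negative coordinate {start}")
            if end != start + 1:
                raise BedFormatError(
                    f"{path}:{lineno}: a tag must be a 1-bp interval, "
                    f"got [{start},{end})"
                )
            _check_strand(strand, path, lineno)
            tags.append(Tag(chrom, start, strand))
    tags.sort(key=lambda t: (t.chrom, t.pos, t.strand))
    return tags


def write_tags_bed(tags: Iterable[Tag], path: str | os.PathLike) -> None:
    """Write tags as BED6 (name=".", score=0); one 1-bp interval per tag."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\t.\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read a gene-model TSV: chrom, tss, tes, strand, gene_id.

    Validates strand/TSS/TES consistency: + strand genes must have
    tss < tes, - strand genes tss > tes.
    """
    genes: list[GeneModel] = []
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedFormatError(
                    f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                )
            chrom, tss_s, tes_s, strand, gene_id = fields[:5]
            try:
                tss, tes = int(tss_s), int(tes_s)
            except ValueError:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer TSS/TES"
                ) from None
            if min(tss, tes) < 0:
                raise BedFormatError(f"{path}:{lineno}: negative coordinate")
            _check_strand(strand, path, lineno)
            if strand == "+" and not tss < tes:
                raise BedFormatError(
                    f"{path}:{lineno}: + strand gene requires tss < tes "
                    f"(got {tss} >= {tes})"
                )
            if strand == "-" and not tss > tes:
                raise BedFormatError(
                    f"{path}:{lineno}: - strand gene requires tss > tes "
                    f"(got {tss} <= {tes})"
                )
            genes.append(GeneModel(chrom, tss, tes, strand, gene_id))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tes}\t{g.strand}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# peaks

_PEAK_HEADER = "#chrom\tstart\tend\tname\trank_score\tstrand\ttag_count\tratio\tsummit"


def write_peaks_bed(peaks: Sequence, path: str | os.PathLike) -> None:
    """Write peaks as BED6+ with tag_count, ratio and summit columns.

    Column 5 carries the rank score used for "top N" ordering. Float
    fields use repr so the round-trip is exact.
    """
    with open(path, "w") as fh:
        fh.write(_PEAK_HEADER + "\n")
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.rank_score!r}\t.\t"
                f"{p.tag_count}\t{p.ratio!r}\t{p.summit}\n"
            )


def read_peaks_bed(path: str | os.PathLike):
    """Read a peak BED6+ written by :func:`write_peaks_bed`."""
    from .peakcall import Peak  # local import: avoid cycle

    peaks = []
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise BedFormatError(
                    f"{path}:{lineno}: expected 9 columns, got {len(f)}"
                )
            peaks.append(
                Peak(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    summit=int(f[8]),
                    tag_count=int(f[6]),
                    ratio=float(f[7]),
                    rank_score=float(f[4]),
                    name=f[3],
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(chrom: str, values: np.ndarray, path: str | os.PathLike) -> None:
    """Write a per-base array as bedGraph with fixed-value runs collapsed.

    Zero-valued runs are omitted, as is conventional.
    """
    values = np.asarray(values)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str | os.PathLike, chrom_length: int) -> tuple[str, np.ndarray]:
    """Expand a single-chromosome bedGraph back to a per-base array."""
    values = np.zeros(chrom_length, dtype=np.int64)
    chrom = ""
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")[:4]
            if chrom and c != chrom:
                raise BedFormatError(
                    f"{path}:{lineno}: multiple chromosomes in single-chrom bedGraph"
                )
            chrom = c
            values[int(s):int(e)] = int(v)
    return chrom, values


# ---------------------------------------------------------------------------
# FASTA and count tables


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA into a name -> sequence dict (via pyfaidx)."""
    fa = Fasta(os.fspath(path), rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column = gene_id index)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: dict[str, int] = {}
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise BedFormatError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_counts_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t")
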
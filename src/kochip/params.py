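"""Pipeline-wide parameters.

All coordinates in this package are 0-based, half-open (UCSC BED
convention). Every threshold below is inclusive where the underlying
filter says "at least".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of the occupancy pipeline, with their defaults.

    Attributes
    ----------
    extension:
        Length in bp to which each single-end tag is extended in its
        strand direction before pileup (fragment-size proxy).
    min_tags:
        Minimum number of extended tags overlapping a peak for it to
        survive the knockout filter (inclusive).
    min_ratio:
        Minimum depth-corrected treatment/control tag ratio (inclusive).
    window, step:
        Candidate-caller scan window width and step in bp.
    p_cutoff:
        Poisson upper-tail p-value below which a scan window is
        considered enriched over the control expectation.
    local_half_width:
        Half-width in bp of the local-background window used for the
        control rate (lambda is the max of global and local rates).
    merge_gap:
        Enriched windows closer than this many bp are merged into one
        candidate.
    min_lambda:
        Floor on the control Poisson rate per scan window; guards
        against empty control regions declaring everything enriched.
    pseudo_control_tags:
        Pseudo-count applied to the control tag count in the
        enrichment ratio (knockout controls can have zero local tags).
    summit_flank:
        Half-width in bp of summit-centred rows in signal matrices.
    motif_window:
        Width in bp of summit-centred sequence windows for motif
        scanning.
    gene_upstream:
        Upstream extension in bp (transcription direction) of the
        TSS-to-TES window used for peak-to-gene association.
    top_n_motif, top_n_dependency:
        How many top-ranked peaks feed motif analysis and
        dependency classification respectively.
    expr_fold:
        Fold-change threshold (inclusive, both directions) calling a
        gene differentially expressed.
    dependency_fold:
        WT/ko fold change at or above which binding at a site counts
        as "reduced" in that knockout. The source analysis classifies
        sites by scatter shape without a stated numeric boundary; this
        default mirrors the 3x enrichment convention and is surfaced
        in all outputs.
    truncate_percentile:
        Signal matrices are capped at this per-sample percentile.
    depth_scale:
        Tag counts are normalised to this library size (tags per 10
        million).
    """

    extension: int = 200
    min_tags: int = 30
    min_ratio: float = 3.0
    window: int = 200
    step: int = 50
    p_cutoff: float = 1e-5
    local_half_width: int = 5000
    merge_gap: int = 200
    min_lambda: float = 0.05
    pseudo_control_tags: int = 1
    summit_flank: int = 2000
    motif_window: int = 300
    gene_upstream: int = 2500
    top_n_motif: int = 600
    top_n_dependency: int = 500
    expr_fold: float = 2.0
    dependency_fold: float = 3.0
    truncate_percentile: float = 99.0
    depth_scale: float = 1e7

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"PipelineParams.{f.name} must be positive, got {v}")

    def replace(self, **kwargs) -> "PipelineParams":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
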
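"""Binding-vs-expression integration and small quantifications.

Expression changes are called with a counts-per-million fold-change
threshold (the only criterion the upstream analysis states is >=2-fold
altered expression); the overlap of bound genes with up/down sets and
cumulative growth-curve arithmetic live here too.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def cpm(table: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per library (column)."""
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every library must have positive total counts")
    return table * 1e6 / totals


def expression_fold_changes(
    table: pd.DataFrame,
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    pseudocount: float = 1.0,
    fold: float = 2.0,
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Per-gene knockout/WT fold change on CPM and >=fold-changed sets.

    FC = (mean ko CPM + p) / (mean WT CPM + p). The up-set holds genes
    with FC >= fold, the down-set FC <= 1/fold, both boundaries
    inclusive. Returns ``(per-gene table, up_set, down_set)``.
    """
    missing = [s for s in list(wt_samples) + list(ko_samples) if s not in table.columns]
    if missing:
        raise ValueError(f"samples missing from the count table: {missing}")
    if not wt_samples or not ko_samples:
        raise ValueError("need at least one replicate per condition")
    norm = cpm(table)
    wt_mean = norm[list(wt_samples)].mean(axis=1)
    ko_mean = norm[list(ko_samples)].mean(axis=1)
    fc = (ko_mean + pseudocount) / (wt_mean + pseudocount)
    out = pd.DataFrame(
        {
            "wt_cpm": wt_mean,
            "ko_cpm": ko_mean,
            "fc": fc,
            "log2fc": np.log2(fc),
        }
    )
    up = set(out.index[out["fc"] >= fold])
    down = set(out.index[out["fc"] <= 1.0 / fold])
    return out, up, down


def overlap_with_bound(
    bound_genes: Iterable[str], up_set: Iterable[str], down_set: Iterable[str]
) -> dict:
    """Overlap of factor-bound genes with de-regulated gene sets.

    Percentages are rounded to the nearest integer percent; for an
    empty set the percentage is reported as None. Bound and not-bound
    percentages of each set sum to 100 up to rounding.
    """
    bound = set(bound_genes)

    def summarise(genes: set[str]) -> dict:
        n = len(genes)
        n_bound = len(genes & bound)
        n_not = n - n_bound
        return {
            "n": n,
            "bound": n_bound,
            "not_bound": n_not,
            "pct_bound": round(100 * n_bound / n) if n else None,
            "pct_not_bound": round(100 * n_not / n) if n else None,
        }

    return {"up": summarise(set(up_set)), "down": summarise(set(down_set))}


def cumulative_growth(
    initial_count: float,
    counted: Sequence[float],
    replated: Sequence[float] | None = None,
) -> list[float]:
    """Cumulative cell numbers from serial count-and-replate passages.

    ``counted[i]`` cells are counted at the end of interval ``i``, of
    which ``replated[i]`` are put back for the next interval (defaults
    to replating the initial seeding number each passage). The
    cumulative number multiplies the running total by each interval's
    fold increase ``counted[i] / seeded_i``:

    c_0 = initial; c_i = c_{i-1} * counted[i] / replated[i-1].
    """
    counted = list(counted)
    if replated is None:
        replated = [initial_count] * len(counted)
    replated = list(replated)
    if len(replated) < len(counted):
        raise ValueError("need a replated count for every interval")
    if initial_count <= 0 or any(c <= 0 for c in counted) or any(
        r <= 0 for r in replated
    ):
        raise ValueError("cell counts must be positive")
    cumulative = [float(initial_count)]
    seeded = initial_count
    for i, c in enumerate(counted):
        cumulative.append(cumulative[-1] * c / seeded)
        seeded = replated[i]
    return cumulative
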
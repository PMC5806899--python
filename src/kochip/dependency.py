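"""Per-site knockout dependence of binding.

For each wild-type-defined binding site, the fold change of
depth-normalised ChIP signal between wild type and each knockout
quantifies how much binding that subunit's loss removes; thresholding
the fold changes classifies sites into dependency types
(L3MBTL2-dependent, E2F6-dependent, dependent on both, or independent).
The numeric "reduced" boundary is a package choice (default 3x,
mirroring the enrichment-filter convention) and is carried in the
output so downstream readers see it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

BOTH_DEP = "BOTH_DEP"
L3MBTL2_DEP = "L3MBTL2_DEP"
E2F6_DEP = "E2F6_DEP"
INDEPENDENT = "INDEPENDENT"

DEPENDENCY_CLASSES = (BOTH_DEP, L3MBTL2_DEP, E2F6_DEP, INDEPENDENT)


@dataclass(frozen=True)
class DependencyCall:
    """Fold changes of one site across knockouts and the resulting class."""

    site: str
    fc_l3: float
    fc_e2f6: float
    dep_class: str
    fc_pcgf6: float | None = None


def binding_fold_change(
    wt_counts: np.ndarray, ko_counts: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-site WT/knockout fold change: (wt + p) / (ko + p).

    Counts must come from :func:`~kochip.signal_matrix.peak_region_counts`
    on identical regions; the pseudo-count keeps the ratio finite when a
    knockout removes every tag.
    """
    wt = np.asarray(wt_counts, dtype=float)
    ko = np.asarray(ko_counts, dtype=float)
    if wt.shape != ko.shape:
        raise ValueError(f"length mismatch: {wt.shape} vs {ko.shape}")
    return (wt + pseudocount) / (ko + pseudocount)


def classify_dependency(
    fc_l3: np.ndarray, fc_e2f6: np.ndarray, threshold: float = 3.0
) -> list[str]:
    """Class label per site from its L3MBTL2ko and E2F6ko fold changes.

    Binding counts as reduced in a knockout when fc >= threshold
    (inclusive): reduced in both -> BOTH_DEP, in exactly one ->
    L3MBTL2_DEP / E2F6_DEP, in neither -> INDEPENDENT.
    """
    fc_l3 = np.asarray(fc_l3, dtype=float)
    fc_e2f6 = np.asarray(fc_e2f6, dtype=float)
    if fc_l3.shape != fc_e2f6.shape:
        raise ValueError("fold-change vectors differ in length")
    out = []
    for a, b in zip(fc_l3 >= threshold, fc_e2f6 >= threshold):
        if a and b:
            out.append(BOTH_DEP)
        elif a:
            out.append(L3MBTL2_DEP)
        elif b:
            out.append(E2F6_DEP)
        else:
            out.append(INDEPENDENT)
    return out


def fold_change_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of log2 fold changes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("fold changes must be positive (pseudo-counted)")
    lx, ly = np.log2(x), np.log2(y)
    if np.allclose(lx, lx[0]) or np.allclose(ly, ly[0]):
        raise ValueError("zero variance in log2 fold changes")
    return float(stats.pearsonr(lx, ly)[0])


def dependency_table(
    site_ids: Sequence[str],
    fc_l3: np.ndarray,
    fc_e2f6: np.ndarray,
    threshold: float = 3.0,
    fc_pcgf6: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-form per-site table: fold changes, log2 fold changes, class.

    The classification threshold is stored in ``df.attrs["threshold"]``
    and written into the TSV header by :func:`write_dependency_tsv`.
    """
    classes = classify_dependency(fc_l3, fc_e2f6, threshold)
    df = pd.DataFrame(
        {
            "site": list(site_ids),
            "fc_l3mbtl2ko": np.asarray(fc_l3, dtype=float),
            "fc_e2f6ko": np.asarray(fc_e2f6, dtype=float),
            "log2fc_l3mbtl2ko": np.log2(fc_l3),
            "log2fc_e2f6ko": np.log2(fc_e2f6),
            "dep_class": classes,
        }
    )
    if fc_pcgf6 is not None:
        df["fc_pcgf6ko"] = np.asarray(fc_pcgf6, dtype=float)
    df.attrs["threshold"] = threshold
    return df


def write_dependency_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reduced-binding threshold: fc >= {df.attrs.get('threshold')}\n")
        df.to_csv(fh, sep="\t", index=False)
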
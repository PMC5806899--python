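"""Shared fixtures: a fast toy simulation and the full desk-scale study.

The full-scale fixture (5 x 2 Mb genome, 550 sites, seed 42) is built
once per session and shared by the recovery/classification/motif
checks; the small fixture keeps unit tests fast.
"""

from __future__ import annotations

import dataclasses

import pytest

from kochip.params import PipelineParams
from kochip.peakcall import call_peaks_genome
from kochip.synthetic_data import (
    ALWAYS_MGA,
    ARTIFACT,
    BOTH_DEP,
    E2F6_DEP,
    L3MBTL2_DEP,
    SimConfig,
    generate_truth,
    simulate_sample_tags,
)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    base = dict(
        chrom_lengths={"chrA": 300_000, "chrB": 300_000},
        sites_per_class={
            ALWAYS_MGA: 10,
            L3MBTL2_DEP: 10,
            E2F6_DEP: 10,
            BOTH_DEP: 4,
            ARTIFACT: 4,
        },
        n_background_genes=20,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def small_sim():
    cfg = small_config(seed=7)
    truth, genes = generate_truth(cfg)
    return cfg, truth, genes


@pytest.fixture(scope="session")
def full_study():
    """The desk-scale study conditions: defaults of SimConfig, seed 42."""
    cfg = dataclasses.replace(SimConfig(), seed=42)
    truth, genes = generate_truth(cfg)
    return cfg, truth, genes


@pytest.fixture(scope="session")
def full_wt_peaks(full_study):
    """Filtered MGA peaks, wild type vs MGA-in-MGAko control, seed 42."""
    cfg, truth, genes = full_study
    params = PipelineParams()
    treat = simulate_sample_tags(truth, cfg, "MGA", "WT")
    control = simulate_sample_tags(truth, cfg, "MGA", "MGAko")
    peaks = call_peaks_genome(treat, control, cfg.chrom_lengths, params)
    return peaks, treat, control, params
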
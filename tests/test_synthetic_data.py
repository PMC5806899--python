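"""Ground-truth simulator: determinism, spacing, class structure,
genotype-dependent occupancy, and motif planting."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from conftest import small_config
from kochip.synthetic_data import (
    ALWAYS_MGA,
    ARTIFACT,
    BOTH_DEP,
    E2F6_DEP,
    L3MBTL2_DEP,
    SimConfig,
    emit_region_sequences,
    generate_truth,
    reverse_complement,
    simulate_sample_tags,
    site_multiplier,
)


class TestGenerateTruth:
    def test_same_seed_identical(self):
        cfg = small_config(seed=3)
        assert generate_truth(cfg) == generate_truth(cfg)

    def test_different_seed_differs(self):
        a, _ = generate_truth(small_config(seed=1))
        b, _ = generate_truth(small_config(seed=2))
        assert a != b

    def test_zero_sites_keeps_genes(self):
        cfg = small_config(seed=0, sites_per_class={}, n_background_genes=15)
        truth, genes = generate_truth(cfg)
        assert truth == []
        assert len(genes) == 15

    def test_chromosome_too_short_fails(self):
        cfg = small_config(
            seed=0,
            chrom_lengths={"tiny": 20_000},
            sites_per_class={ALWAYS_MGA: 50},
        )
        with pytest.raises(ValueError, match="too short"):
            generate_truth(cfg)

    def test_minimum_spacing_and_bounds(self):
        cfg = small_config(seed=5)
        truth, _ = generate_truth(cfg)
        by_chrom: dict[str, list[int]] = {}
        for s in truth:
            assert 0 <= s.summit < cfg.chrom_lengths[s.chrom]
            assert s.strength > 0
            by_chrom.setdefault(s.chrom, []).append(s.summit)
        for summits in by_chrom.values():
            summits.sort()
            gaps = np.diff(summits)
            assert gaps.size == 0 or gaps.min() >= cfg.min_spacing

    def test_class_counts_within_binomial_ci_at_n_1000(self):
        """1000 sites at 25/25/25/15/10% land inside exact binomial 99% CIs."""
        cfg = small_config(
            seed=11,
            chrom_lengths={f"c{i}": 2_000_000 for i in range(4)},
            sites_per_class={
                ALWAYS_MGA: 250, L3MBTL2_DEP: 250, E2F6_DEP: 250,
                BOTH_DEP: 150, ARTIFACT: 100,
            },
        )
        truth, _ = generate_truth(cfg)
        assert len(truth) == 1000
        observed = {c: sum(s.dep_class == c for s in truth) for c in cfg.sites_per_class}
        for cls, n_cls in cfg.sites_per_class.items():
            lo = stats.binom.ppf(0.005, 1000, n_cls / 1000)
            hi = stats.binom.ppf(0.995, 1000, n_cls / 1000)
            assert lo <= observed[cls] <= hi

    def test_every_real_site_assigned_to_a_gene(self):
        from kochip.interval_algebra import gene_window

        cfg = small_config(seed=9)
        truth, genes = generate_truth(cfg)
        windows = [gene_window(g) for g in genes]
        for site in truth:
            if site.dep_class == ARTIFACT:
                continue
            assert any(
                c == site.chrom and lo <= site.summit < hi for c, lo, hi in windows
            ), site


class TestSimulateTags:
    def test_unknown_factor_or_genotype_fails(self, small_sim):
        cfg, truth, _ = small_sim
        with pytest.raises(ValueError, match="factor"):
            simulate_sample_tags(truth, cfg, "RING2", "WT")
        with pytest.raises(ValueError, match="genotype"):
            simulate_sample_tags(truth, cfg, "MGA", "WTT")

    def test_determinism(self, small_sim):
        cfg, truth, _ = small_sim
        a = simulate_sample_tags(truth, cfg, "E2F6", "WT")
        b = simulate_sample_tags(truth, cfg, "E2F6", "WT")
        assert a == b

    def test_mgako_leaves_only_artifact_tags(self):
        """ChIP of L3MBTL2 in MGA-depleted cells: background + artifacts only."""
        cfg = small_config(seed=4, lambda_bg=0.0)
        truth, _ = generate_truth(cfg)
        tags = simulate_sample_tags(truth, cfg, "L3MBTL2", "MGAko")
        artifact_summits = [
            (s.chrom, s.summit) for s in truth if s.dep_class == ARTIFACT
        ]
        assert tags  # artifacts do produce tags
        for t in tags:
            assert any(
                t.chrom == c and abs(t.pos - p) < cfg.extension
                for c, p in artifact_summits
            )

    def test_own_knockout_is_a_clean_control(self, small_sim):
        cfg, truth, _ = small_sim
        for site in truth:
            expected = 1.0 if site.dep_class == ARTIFACT else 0.0
            assert site_multiplier(site, "E2F6", "E2F6ko", cfg) == expected

    def test_doubling_depth_doubles_site_tags(self):
        cfg = small_config(seed=6, lambda_bg=0.0)
        truth, _ = generate_truth(cfg)
        n1 = len(simulate_sample_tags(truth, cfg, "MGA", "WT"))
        cfg2 = dataclasses.replace(cfg, depth=2 * cfg.depth)
        n2 = len(simulate_sample_tags(truth, cfg2, "MGA", "WT"))
        assert 1.8 < n2 / n1 < 2.2

    def test_site_tag_count_matches_poisson_over_seeds(self):
        """Strength 100 at depth 10M: tags near the site follow Poisson(100)."""
        totals = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimConfig(
                chrom_lengths={"c": 100_000},
                sites_per_class={ALWAYS_MGA: 1},
                lambda_bg=0.0,
                depth=1e7,
                strength_range=(100.0, 100.0),
                n_background_genes=0,
                seed=seed,
            )
            truth, _ = generate_truth(cfg)
            tags = simulate_sample_tags(truth, cfg, "MGA", "WT")
            summit = truth[0].summit
            totals += sum(1 for t in tags if abs(t.pos - summit) <= 3000)
        lam = 100 * n_seeds
        assert stats.poisson.ppf(0.005, lam) <= totals <= stats.poisson.ppf(0.995, lam)

    def test_tag_counts_conserved_per_chromosome(self, small_sim):
        cfg, truth, _ = small_sim
        tags = simulate_sample_tags(truth, cfg, "PCGF6", "WT")
        per_chrom = {c: 0 for c in cfg.chrom_lengths}
        for t in tags:
            per_chrom[t.chrom] += 1
        assert sum(per_chrom.values()) == len(tags)

    def test_artifact_wt_ko_ratio_near_one(self):
        """Artifact sites produce the same expected tags in WT and knockouts."""
        wt_total = ko_total = 0
        for seed in range(10):
            cfg = small_config(seed=seed, lambda_bg=0.0)
            truth, _ = generate_truth(cfg)
            art = {(s.chrom, s.summit) for s in truth if s.dep_class == ARTIFACT}

            def n_art(tags):
                return sum(
                    1 for t in tags
                    if any(t.chrom == c and abs(t.pos - p) < 300 for c, p in art)
                )

            wt_total += n_art(simulate_sample_tags(truth, cfg, "MGA", "WT"))
            ko_total += n_art(simulate_sample_tags(truth, cfg, "MGA", "MGAko"))
        assert 0.9 < wt_total / ko_total < 1.1


class TestEmitSequences:
    def test_seed_determinism(self, small_sim):
        cfg, truth, _ = small_sim
        assert emit_region_sequences(truth, cfg) == emit_region_sequences(truth, cfg)

    def test_planted_motif_readable_at_offset(self):
        cfg = small_config(seed=8, sigma_motif=1e-9)  # offsets collapse to 0
        truth, _ = generate_truth(cfg)
        genome = emit_region_sequences(truth, cfg)
        for site in truth:
            if site.motif is None:
                continue
            motif_id, offset = site.motif
            assert offset == 0
            word = cfg.motifs[motif_id]
            found = genome[site.chrom][site.summit:site.summit + len(word)]
            assert found in (word, reverse_complement(word))

    def test_motif_longer_than_window_fails(self):
        cfg = small_config(seed=0, motifs={"EBOX": "A" * 400, "E2F6": "GCGGGAA", "NRF1": "GCGCATGC"})
        truth, _ = generate_truth(cfg)
        with pytest.raises(ValueError, match="longer"):
            emit_region_sequences(truth, cfg, window=300)

    def test_background_composition_uniform(self):
        cfg = small_config(seed=2, sites_per_class={}, n_background_genes=0)
        truth, _ = generate_truth(cfg)
        genome = emit_region_sequences(truth, cfg)
        seq = genome["chrA"]
        counts = {b: seq.count(b) for b in "ACGT"}
        assert sum(counts.values()) == len(seq)
        for b in "ACGT":
            assert abs(counts[b] / len(seq) - 0.25) < 0.01
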
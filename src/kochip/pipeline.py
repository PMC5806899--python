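"""End-to-end orchestration: simulate -> call -> filter -> colocalize ->
classify -> motif -> integrate, deterministic under a fixed seed.

Every stage communicates through the plain-text file contracts of
:mod:`kochip.genomic_io`; every output file starts with a provenance
comment recording the seed and the thresholds actually used.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dependency as dep
from . import integration, interval_algebra, motif_centrality, signal_matrix
from . import synthetic_data as sd
from .genomic_io import (
    write_chrom_sizes,
    write_fasta,
    write_gene_models,
    write_peaks_bed,
    write_tags_bed,
)
from .params import PipelineParams
from .peakcall import call_peaks_genome, top_ranked
from .synthetic_data import FACTORS, SimConfig


@dataclass
class RunConfig:
    """One reproducible pipeline run on simulated data.

    ``control_mode`` selects the background library per factor:
    "knockout" pairs each factor with its own-knockout ChIP (the
    default design), "IgG" uses a single mock-IP library for every
    factor.
    """

    outdir: str
    seed: int = 42
    sim: SimConfig | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    factors: tuple[str, ...] = FACTORS
    control_mode: str = "knockout"
    write_tag_beds: bool = True

    def __post_init__(self) -> None:
        if self.control_mode not in ("knockout", "IgG"):
            raise ValueError(f"unknown control_mode {self.control_mode!r}")
        for f in self.factors:
            if f not in FACTORS:
                raise ValueError(f"unknown factor {f!r}")
        if self.sim is None:
            self.sim = dataclasses.replace(SimConfig(), seed=self.seed)


@dataclass
class RunResult:
    truth: list
    genes: list
    peaks_by_factor: dict
    venn_counts: dict
    dependency_table: object
    fc_correlation: float
    motif_results: dict
    integration_summary: dict
    recovery: dict
    outdir: str


def _provenance(config: RunConfig) -> str:
    p = config.params
    return (
        f"# kochip run seed={config.seed} control_mode={config.control_mode} "
        f"min_tags={p.min_tags} min_ratio={p.min_ratio} extension={p.extension} "
        f"dependency_fold={p.dependency_fold}"
    )


def _prepend_provenance(path: Path, header: str) -> None:
    body = path.read_text()
    path.write_text(header + "\n" + body)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage on one simulated experiment; see module docstring.

    Raises with the failing stage's name on any stage error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    params = config.params
    header = _provenance(config)
    log: dict = {"seed": config.seed, "params": params.as_dict(), "stages": []}

    def stage(name):
        log["stages"].append(name)
        return name

    try:
        stage("simulate")
        truth, genes = sd.generate_truth(sim)
        sd.write_truth_bed(truth, out / "truth_sites.bed")
        write_gene_models(genes, out / "genes.tsv")
        write_chrom_sizes(sim.chrom_lengths, out / "chrom.sizes")
        for p in ("truth_sites.bed", "genes.tsv", "chrom.sizes"):
            _prepend_provenance(out / p, header)

        controls: dict[str, list] = {}
        if config.control_mode == "IgG":
            igg = sd.simulate_sample_tags(truth, sim, FACTORS[0], "IgG")
            controls = {f: igg for f in config.factors}
        else:
            for f in config.factors:
                controls[f] = sd.simulate_sample_tags(truth, sim, f, f"{f}ko")
        wt_tags = {
            f: sd.simulate_sample_tags(truth, sim, f, "WT") for f in config.factors
        }
        if config.write_tag_beds:
            for f in config.factors:
                write_tags_bed(wt_tags[f], out / f"tags_{f}_WT.bed")
                write_tags_bed(controls[f], out / f"tags_{f}_control.bed")
                _prepend_provenance(out / f"tags_{f}_WT.bed", header)
                _prepend_provenance(out / f"tags_{f}_control.bed", header)

        stage("call")
        peaks_by_factor = {}
        for f in config.factors:
            peaks = call_peaks_genome(
                wt_tags[f], controls[f], sim.chrom_lengths, params
            )
            peaks_by_factor[f] = peaks
            write_peaks_bed(peaks, out / f"peaks_{f}.bed")
            _prepend_provenance(out / f"peaks_{f}.bed", header)

        stage("venn")
        sets = [
            interval_algebra.RegionSet.from_peaks(f, peaks_by_factor[f])
            for f in config.factors
        ]
        union_regions, memberships, counts = interval_algebra.venn_membership(sets)
        venn_counts = {
            "union_n": len(union_regions),
            "per_set": {f: len(peaks_by_factor[f]) for f in config.factors},
            "categories": {
                "+".join(sorted(k)): v for k, v in sorted(counts.items())
            },
        }
        (out / "venn.json").write_text(
            json.dumps({"provenance": header, **venn_counts}, indent=2)
        )

        stage("metagene")
        anchor = config.factors[0]
        summits = [(p.chrom, p.summit) for p in peaks_by_factor[anchor]]
        profile = interval_algebra.metagene_profile(summits, genes)
        np.savetxt(
            out / "metagene_profile.tsv",
            profile,
            fmt="%.6g",
            header=header.lstrip("# "),
        )

        stage("heatmap")
        top_summits = [
            (p.chrom, p.summit)
            for p in top_ranked(peaks_by_factor[anchor], params.top_n_motif)
        ]
        mats = signal_matrix.summit_signal_matrix(
            top_summits,
            {f: wt_tags[f] for f in config.factors},
            sim.chrom_lengths,
            flank=params.summit_flank,
            params=params,
        )
        for f, mat in mats.items():
            signal_matrix.write_matrix_tsv(mat, out / f"heatmap_{f}_WT.tsv")
            _prepend_provenance(out / f"heatmap_{f}_WT.tsv", header)

        stage("classify")
        top_peaks = top_ranked(peaks_by_factor[anchor], params.top_n_dependency)
        ko_tags = {
            g: sd.simulate_sample_tags(truth, sim, anchor, g)
            for g in ("L3MBTL2ko", "E2F6ko", "PCGF6ko")
        }
        counts_wt = signal_matrix.peak_region_counts(
            top_peaks, wt_tags[anchor], sim.chrom_lengths,
            scale=params.depth_scale, extension=params.extension,
        )
        per_ko = {
            g: signal_matrix.peak_region_counts(
                top_peaks, tags, sim.chrom_lengths,
                scale=params.depth_scale, extension=params.extension,
            )
            for g, tags in ko_tags.items()
        }
        fc_l3 = dep.binding_fold_change(counts_wt, per_ko["L3MBTL2ko"])
        fc_e2f6 = dep.binding_fold_change(counts_wt, per_ko["E2F6ko"])
        fc_pcgf6 = dep.binding_fold_change(counts_wt, per_ko["PCGF6ko"])
        table = dep.dependency_table(
            [p.name for p in top_peaks], fc_l3, fc_e2f6,
            threshold=params.dependency_fold, fc_pcgf6=fc_pcgf6,
        )
        dep.write_dependency_tsv(table, out / "dependency_calls.tsv")
        _prepend_provenance(out / "dependency_calls.tsv", header)

        # co-loss of two factors in a third factor's knockout
        l3_in_e2f6ko = sd.simulate_sample_tags(truth, sim, "L3MBTL2", "E2F6ko")
        counts_l3_wt = signal_matrix.peak_region_counts(
            top_peaks, wt_tags.get("L3MBTL2")
            or sd.simulate_sample_tags(truth, sim, "L3MBTL2", "WT"),
            sim.chrom_lengths, scale=params.depth_scale, extension=params.extension,
        )
        counts_l3_ko = signal_matrix.peak_region_counts(
            top_peaks, l3_in_e2f6ko, sim.chrom_lengths,
            scale=params.depth_scale, extension=params.extension,
        )
        fc_l3_in_e2f6ko = dep.binding_fold_change(counts_l3_wt, counts_l3_ko)
        fc_correlation = dep.fold_change_correlation(fc_e2f6, fc_l3_in_e2f6ko)

        stage("motif")
        genome = sd.emit_region_sequences(truth, sim, window=params.motif_window)
        write_fasta(genome, out / "genome.fa")
        motif_summits = [
            (p.chrom, p.summit)
            for p in top_ranked(peaks_by_factor[anchor], params.top_n_motif)
        ]
        windows = motif_centrality.extract_summit_windows(
            genome, motif_summits, params.motif_window
        )
        motif_results = {}
        for motif_id in ("EBOX", "NRF1"):
            motif = motif_centrality.Motif(motif_id, consensus=sim.motifs[motif_id])
            sites = motif_centrality.scan_best_sites(windows, motif)
            offsets = [s.offset for s in sites if s is not None]
            if offsets:
                res = motif_centrality.central_enrichment_test(
                    offsets, params.motif_window, motif.width
                )
                motif_results[motif_id] = {
                    "n_windows": len(windows),
                    "n_with_site": res.n,
                    "best_width": res.best_width,
                    "k_central": res.k_central,
                    "p_value": res.p_value,
                    "log10_p": res.log10_p,
                }
            else:
                motif_results[motif_id] = {
                    "n_windows": len(windows), "n_with_site": 0, "p_value": None,
                }
        (out / "motif_centrality.json").write_text(
            json.dumps({"provenance": header, **motif_results}, indent=2)
        )

        stage("integrate")
        bound = interval_algebra.bound_gene_ids(
            peaks_by_factor[anchor], genes, params.gene_upstream
        )
        gene_ids = [g.gene_id for g in genes]
        n_planted = min(50, len(gene_ids) // 8, len(bound) or len(gene_ids))
        expr, planted = sd.simulate_expression(
            gene_ids, seed=config.seed, n_up=n_planted, n_down=n_planted,
            up_pool=sorted(bound) or None,
        )
        fc_table, up, down = integration.expression_fold_changes(
            expr, [c for c in expr if c.startswith("WT")],
            [c for c in expr if c.startswith("KO")], fold=params.expr_fold,
        )
        summary = integration.overlap_with_bound(bound, up, down)
        summary["n_bound_genes"] = len(bound)
        summary["planted"] = {
            "up": sum(1 for v in planted.values() if v == "up"),
            "down": sum(1 for v in planted.values() if v == "down"),
        }
        (out / "integration_summary.json").write_text(
            json.dumps({"provenance": header, **summary}, indent=2)
        )

        stage("recover")
        recovery = recovery_report(truth, peaks_by_factor[anchor])
        (out / "recovery.json").write_text(
            json.dumps({"provenance": header, **recovery}, indent=2)
        )

        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        return RunResult(
            truth=truth,
            genes=genes,
            peaks_by_factor=peaks_by_factor,
            venn_counts=venn_counts,
            dependency_table=table,
            fc_correlation=fc_correlation,
            motif_results=motif_results,
            integration_summary=summary,
            recovery=recovery,
            outdir=os.fspath(out),
        )
    except Exception as exc:  # annotate with the failing stage
        current = log["stages"][-1] if log["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc


def recovery_report(
    truth: list, filtered_peaks: list, summit_tol: int = 100
) -> dict:
    """Compare filtered peaks against ground truth.

    A truth site is recovered when some filtered peak's summit lies
    within ``summit_tol`` bp of the true summit; an artifact site
    "passes" when any filtered peak overlaps it.
    """
    non_artifact = [s for s in truth if s.dep_class != sd.ARTIFACT]
    artifacts = [s for s in truth if s.dep_class == sd.ARTIFACT]
    by_chrom: dict[str, list] = {}
    for p in filtered_peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    def near(site, tol):
        return any(
            abs(p.summit - site.summit) <= tol
            for p in by_chrom.get(site.chrom, ())
        )

    def overlapped(site):
        return any(
            p.start <= site.summit < p.end for p in by_chrom.get(site.chrom, ())
        )

    n_rec = sum(near(s, summit_tol) for s in non_artifact)
    n_art = sum(overlapped(s) for s in artifacts)
    return {
        "n_truth": len(non_artifact),
        "n_recovered": n_rec,
        "recovery_rate": n_rec / len(non_artifact) if non_artifact else None,
        "summit_tolerance_bp": summit_tol,
        "n_artifact": len(artifacts),
        "n_artifact_passing": n_art,
        "n_filtered_peaks": len(filtered_peaks),
    }
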
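"""Ground-truth simulator for knockout-controlled ChIP-seq experiments.

Emulates the statistical structure of a multi-subunit complex (PRC1.6:
MGA, L3MBTL2, E2F6, PCGF6) binding a shared set of genomic sites:

* every real site is bound by all four factors in wild-type chromatin;
* knocking out MGA abolishes binding of every factor at every real site
  (MGA is the essential scaffold);
* L3MBTL2ko / E2F6ko abolish binding only at the sites that depend on
  that subunit (dependency classes), PCGF6ko abolishes none;
* ChIP of a factor in its own knockout — the pipeline's control
  library — contains only background and artifact tags;
* artifact sites yield tags identically in every genotype, including
  knockouts and IgG, and are what the knockout filter exists to remove;
* libraries differ in depth; tag positions scatter around the site
  summit with the strand chosen so the 200-bp extension covers it.

All outputs are deterministic functions of the configuration seed.
Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .genomic_io import GeneModel, Tag

ALWAYS_MGA = "ALWAYS_MGA"
L3MBTL2_DEP = "L3MBTL2_DEP"
E2F6_DEP = "E2F6_DEP"
BOTH_DEP = "BOTH_DEP"
ARTIFACT = "ARTIFACT"

DEP_CLASSES = (ALWAYS_MGA, L3MBTL2_DEP, E2F6_DEP, BOTH_DEP, ARTIFACT)
NON_ARTIFACT_CLASSES = (ALWAYS_MGA, L3MBTL2_DEP, E2F6_DEP, BOTH_DEP)

FACTORS = ("MGA", "L3MBTL2", "E2F6", "PCGF6")
GENOTYPES = ("WT", "MGAko", "L3MBTL2ko", "E2F6ko", "PCGF6ko", "IgG")

# E-box bound by MGA/MAX; E2F6/DP1 recognition sequence; an unrelated
# GC-rich control motif used as the non-planted negative.
DEFAULT_MOTIFS = {
    "EBOX": "CACGTG",
    "E2F6": "GCGGGAA",
    "NRF1": "GCGCATGC",
}

DEFAULT_MOTIF_BY_CLASS = {
    ALWAYS_MGA: "EBOX",
    L3MBTL2_DEP: "EBOX",
    E2F6_DEP: "E2F6",
    BOTH_DEP: "EBOX",
    ARTIFACT: None,
}


def default_multipliers() -> dict[str, dict[str, float]]:
    """Occupancy multiplier per (genotype, dependency class).

    ARTIFACT sites are pinned to 1.0 in every genotype by the
    simulator itself and need no entry.
    """
    one = {c: 1.0 for c in NON_ARTIFACT_CLASSES}
    zero = {c: 0.0 for c in NON_ARTIFACT_CLASSES}
    return {
        "WT": dict(one),
        "MGAko": dict(zero),  # scaffold loss: no factor binds anywhere
        "L3MBTL2ko": {ALWAYS_MGA: 1.0, L3MBTL2_DEP: 0.0, E2F6_DEP: 1.0, BOTH_DEP: 0.0},
        "E2F6ko": {ALWAYS_MGA: 1.0, L3MBTL2_DEP: 1.0, E2F6_DEP: 0.0, BOTH_DEP: 0.0},
        "PCGF6ko": dict(one),
        "IgG": dict(zero),  # mock ChIP: background + artifacts only
    }


class TruthSite(NamedTuple):
    """A ground-truth binding site with a known dependency class."""

    site_id: str
    chrom: str
    summit: int
    strength: float  # expected tag count at full occupancy per 10M depth
    dep_class: str
    motif: Optional[tuple[str, int]]  # (motif id, offset from summit) or None


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the package's desk-scale study.

    ``depth`` is the nominal library size that scales per-site expected
    tag counts (``strength * depth / 1e7``); the realised library total
    is the Poisson sum actually drawn. Occupancy ``multipliers`` map
    genotype -> dependency class -> [0, 1].
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 2_000_000 for i in range(1, 6)}
    )
    sites_per_class: dict[str, int] = field(
        default_factory=lambda: {
            ALWAYS_MGA: 150,
            L3MBTL2_DEP: 150,
            E2F6_DEP: 150,
            BOTH_DEP: 50,
            ARTIFACT: 50,
        }
    )
    lambda_bg: float = 0.005  # background tags per bp
    depth: float = 2e6  # nominal per-sample depth
    sigma: float = 60.0  # tag-position dispersion around the summit (bp)
    min_spacing: int = 5000  # no two sites closer than this
    strength_range: tuple[float, float] = (300.0, 1500.0)  # per 10M depth
    extension: int = 200
    multipliers: dict[str, dict[str, float]] = field(default_factory=default_multipliers)
    factor_efficiency: dict[str, float] = field(
        default_factory=lambda: {f: 1.0 for f in FACTORS}
    )
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    motif_by_class: dict[str, Optional[str]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_BY_CLASS)
    )
    sigma_motif: float = 20.0  # motif offset dispersion around the summit (bp)
    n_background_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_bg < 0:
            raise ValueError("lambda_bg must be >= 0")
        if self.depth <= 0 or self.sigma <= 0 or self.min_spacing <= 0:
            raise ValueError("depth, sigma and min_spacing must be positive")
        if not 0 < self.strength_range[0] <= self.strength_range[1]:
            raise ValueError("strength_range must be positive and ordered")
        for geno, per_class in self.multipliers.items():
            if geno not in GENOTYPES:
                raise ValueError(f"unknown genotype in multipliers: {geno}")
            for cls, m in per_class.items():
                if not 0.0 <= m <= 1.0:
                    raise ValueError(f"multiplier {geno}/{cls}={m} outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return sum(self.sites_per_class.values())


# ---------------------------------------------------------------------------
# truth generation


def _place_summits(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Place site summits with guaranteed minimum spacing.

    Each chromosome is tiled into slots of ``min_spacing + jitter`` bp
    (5-kb margins at both ends); sites occupy distinct slots with a
    uniform jitter inside the slot, so consecutive summits are always
    at least ``min_spacing`` apart.
    """
    jitter = 1000
    slot_width = config.min_spacing + jitter
    margin = config.min_spacing
    slots: list[tuple[str, int]] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_slots = (length - 2 * margin) // slot_width
        slots.extend((chrom, margin + i * slot_width) for i in range(max(n_slots, 0)))
    n = config.n_sites
    if n > len(slots):
        raise ValueError(
            f"chromosomes too short: {n} sites requested but only "
            f"{len(slots)} slots of {slot_width} bp available"
        )
    chosen = rng.choice(len(slots), size=n, replace=False)
    offsets = rng.integers(0, jitter, size=n)
    placed = [
        (slots[i][0], int(slots[i][1] + off)) for i, off in zip(chosen, offsets)
    ]
    placed.sort()
    return placed


def generate_truth(config: SimConfig) -> tuple[list[TruthSite], list[GeneModel]]:
    """Generate ground-truth sites and a matching gene annotation.

    Every non-artifact site is assigned a gene whose promoter window
    (2.5 kb upstream of the TSS through the TES) contains the summit;
    unbound background genes are added elsewhere. Deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    positions = _place_summits(config, rng)

    labels: list[str] = []
    for cls in DEP_CLASSES:
        labels.extend([cls] * config.sites_per_class.get(cls, 0))
    labels = [labels[i] for i in rng.permutation(len(labels))]

    lo, hi = config.strength_range
    strengths = rng.uniform(lo, hi, size=len(positions))

    sites: list[TruthSite] = []
    genes: list[GeneModel] = []
    for i, ((chrom, summit), cls, strength) in enumerate(
        zip(positions, labels, strengths)
    ):
        motif_id = config.motif_by_class.get(cls)
        motif = None
        if motif_id is not None:
            offset = int(np.clip(round(rng.normal(0.0, config.sigma_motif)), -100, 100))
            motif = (motif_id, offset)
        sites.append(
            TruthSite(f"site_{i:04d}", chrom, summit, float(strength), cls, motif)
        )
        if cls != ARTIFACT:
            genes.append(_gene_for_site(sites[-1], config, rng))

    chrom_names = sorted(config.chrom_lengths)
    for j in range(config.n_background_genes):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(rng.integers(3000, 20000))
        clen = config.chrom_lengths[chrom]
        start = int(rng.integers(0, max(clen - length - 1, 1)))
        if rng.random() < 0.5:
            genes.append(GeneModel(chrom, start, start + length, "+", f"bg_{j:04d}"))
        else:
            genes.append(GeneModel(chrom, start + length, start, "-", f"bg_{j:04d}"))
    return sites, genes


def _gene_for_site(
    site: TruthSite, config: SimConfig, rng: np.random.Generator
) -> GeneModel:
    # summit sits near the TSS: offset along transcription direction,
    # clipped inside the -2.5 kb .. TES association window
    clen = config.chrom_lengths[site.chrom]
    length = int(rng.integers(3000, 20000))
    o = int(np.clip(round(rng.normal(0.0, 300.0)), -2000, 2000))
    if rng.random() < 0.5:
        tss = site.summit - o
        tes = min(tss + length, clen - 1)
        tss = max(min(tss, tes - 100), 0)
        return GeneModel(site.chrom, tss, tes, "+", f"g_{site.site_id}")
    tss = site.summit + o
    tes = max(tss - length, 0)
    tss = min(max(tss, tes + 100), clen - 1)
    return GeneModel(site.chrom, tss, tes, "-", f"g_{site.site_id}")


# ---------------------------------------------------------------------------
# tag simulation


def site_multiplier(site: TruthSite, factor: str, genotype: str, config: SimConfig) -> float:
    """Occupancy multiplier for one site in one (factor, genotype) library."""
    if site.dep_class == ARTIFACT:
        return 1.0  # artifacts appear identically in every library
    if genotype == f"{factor}ko":
        return 0.0  # ChIP of a factor in its own knockout = control library
    return config.multipliers[genotype][site.dep_class]


def simulate_sample_tags(
    truth: list[TruthSite], config: SimConfig, factor: str, genotype: str
) -> list[Tag]:
    """Draw one (factor x genotype) tag library.

    Background tags are Poisson(``lambda_bg * L``) uniform per
    chromosome; site tags are Poisson with mean
    ``strength * depth/1e7 * multiplier``, positions normal around the
    summit (sd ``sigma``, clipped to +-(extension-1)), strand chosen so
    the extended read always covers the summit.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = np.random.default_rng(
        [config.seed, 2, FACTORS.index(factor), GENOTYPES.index(genotype)]
    )
    ext = config.extension
    tags: list[Tag] = []

    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_bg = rng.poisson(config.lambda_bg * length)
        pos = rng.integers(0, length, size=n_bg)
        strands = rng.random(n_bg) < 0.5
        tags.extend(
            Tag(chrom, int(p), "+" if s else "-") for p, s in zip(pos, strands)
        )

    eff = config.factor_efficiency.get(factor, 1.0)
    for site in truth:
        mult = site_multiplier(site, factor, genotype, config)
        mean = site.strength * (config.depth / 1e7) * mult * eff
        if mean <= 0:
            continue
        n = rng.poisson(mean)
        if n == 0:
            continue
        d = np.clip(
            np.rint(rng.normal(0.0, config.sigma, size=n)), -(ext - 1), ext - 1
        ).astype(np.int64)
        clen = config.chrom_lengths[site.chrom]
        p = np.clip(site.summit + d, 0, clen - 1)
        tags.extend(
            Tag(site.chrom, int(pp), "+" if dd <= 0 else "-")
            for pp, dd in zip(p, d)
        )
    tags.sort(key=lambda t: (t.chrom, t.pos, t.strand))
    return tags


# ---------------------------------------------------------------------------
# genome sequence with planted motifs

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sample_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else _IUPAC[c][int(rng.integers(0, len(_IUPAC[c])))]
        for c in consensus.upper()
    )


def emit_region_sequences(
    truth: list[TruthSite], config: SimConfig, window: int = 300
) -> dict[str, str]:
    """Generate the genome sequence with motifs planted near summits.

    Background bases are i.i.d. uniform ACGT. For each site carrying a
    motif annotation, the consensus (or its reverse complement, on a
    random strand) is written starting at ``summit + offset``.
    Deterministic in ``config.seed``.
    """
    for motif_id in {m for m in config.motif_by_class.values() if m is not None}:
        if len(config.motifs[motif_id]) > window:
            raise ValueError(
                f"motif {motif_id!r} longer than the {window}-bp scan window"
            )
    rng = np.random.default_rng([config.seed, 3])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, np.ndarray] = {}
    for chrom in sorted(config.chrom_lengths):
        idx = rng.integers(0, 4, size=config.chrom_lengths[chrom], dtype=np.uint8)
        genome[chrom] = alphabet[idx].copy()
    for site in truth:
        if site.motif is None:
            continue
        motif_id, offset = site.motif
        word = _sample_iupac(config.motifs[motif_id], rng)
        if rng.random() < 0.5:
            word = reverse_complement(word)
        start = site.summit + offset
        arr = genome[site.chrom]
        if 0 <= start and start + len(word) <= arr.size:
            arr[start:start + len(word)] = np.frombuffer(
                word.encode("ascii"), dtype=np.uint8
            )
    return {c: a.tobytes().decode("ascii") for c, a in genome.items()}


# ---------------------------------------------------------------------------
# expression counts (RNA-seq emulation)


def simulate_expression(
    gene_ids: list[str],
    seed: int,
    n_wt: int = 3,
    n_ko: int = 3,
    n_up: int = 50,
    n_down: int = 50,
    fold: float = 4.0,
    dispersion: float = 0.1,
    up_pool: Optional[list[str]] = None,
):
    """Simulate a WT-vs-knockout expression count table with planted changes.

    Negative-binomial counts (var = mu + dispersion * mu^2) for ``n_wt``
    wild-type and ``n_ko`` knockout replicates; ``n_up`` genes gain and
    ``n_down`` genes lose expression ``fold``-fold in the knockout. If
    ``up_pool`` is given, up-regulated genes are drawn from it
    (modelling de-repression of bound targets). Returns
    ``(DataFrame genes x samples, {gene_id: "up" | "down"})``.

    Import is deferred to keep pandas out of the tag-simulation path.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 4])
    n_genes = len(gene_ids)
    if n_up + n_down > n_genes:
        raise ValueError("more planted changes than genes")
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)

    pool = list(up_pool) if up_pool else list(gene_ids)
    up_ids = [pool[i] for i in rng.choice(len(pool), size=n_up, replace=False)]
    remaining = [g for g in gene_ids if g not in set(up_ids)]
    down_ids = [
        remaining[i] for i in rng.choice(len(remaining), size=n_down, replace=False)
    ]
    planted = {g: "up" for g in up_ids}
    planted.update({g: "down" for g in down_ids})

    ko_mean = base.copy()
    index = {g: i for i, g in enumerate(gene_ids)}
    for g in up_ids:
        ko_mean[index[g]] *= fold
    for g in down_ids:
        ko_mean[index[g]] /= fold

    def draw(mean: np.ndarray) -> np.ndarray:
        r = 1.0 / dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    data = {}
    for i in range(n_wt):
        data[f"WT_{i + 1}"] = draw(base)
    for i in range(n_ko):
        data[f"KO_{i + 1}"] = draw(ko_mean)
    table = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return table, planted


def write_truth_bed(sites: list[TruthSite], path) -> None:
    """Truth sites as BED6+class (1-bp summit intervals, 0-based half-open)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.summit}\t{s.summit + 1}\t{s.site_id}\t"
                f"{s.strength:.3f}\t.\t{s.dep_class}\n"
            )
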
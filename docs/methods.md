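# Methods

This note documents the models, parameters and numerical choices
behind `kochip`, in the spirit of a methods appendix. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis problem

ChIP-seq of a subunit of a multi-protein complex faces two specific
confounders. First, antibody cross-reactivity and open-chromatin bias
produce "peaks" that do not reflect binding of the assayed factor.
Using chromatin from a knockout of that factor as the control library
makes these artifacts appear in both libraries, so a depth-corrected
treatment/control ratio separates them from true binding. Second, when
subunits assemble on a common scaffold, the interesting biology is not
*where* one subunit binds but *how* binding at each site responds to
the loss of other subunits — a per-site differential-occupancy
question. `kochip` implements both analyses plus the colocalization,
motif and expression readouts that surround them.

## Peak calling and the knockout filter

Tags (single-end reads reduced to chromosome, 0-based 5′ position,
strand) are extended to `extension = 200` bp in their strand direction,
a fragment-length proxy. Candidate discovery is a sliding-window
Poisson test: windows of 200 bp every 50 bp; the control rate is
λ = max(global chromosome rate, local rate over ±5 kb) scaled to
treatment depth, floored at `min_lambda = 0.05` per window so an
empty control region cannot declare everything enriched; windows with
Poisson upper-tail p < 10⁻⁵ are kept and merged when closer than
200 bp. This caller is deliberately simple — the scientific content of
the pipeline is in the filter and everything downstream, which are
caller-agnostic; the caller sits behind a small interface
(`call_candidates`) and can be swapped.

The filter itself retains a candidate iff

* tag count (extended tags overlapping the peak) ≥ `min_tags = 30`, and
* ratio = (t/D_t) / (max(c, c₀)/D_c) ≥ `min_ratio = 3`,

both boundaries inclusive ("at least 30" is inclusive by definition;
3× is treated symmetrically). The pseudo-count c₀ = 1 control tag
keeps the ratio finite where a knockout control has no local tags at
all; the cost is that exact ratio invariance under control
up-scaling holds only where the control count is ≥ 1, which in
practice is everywhere the background rate is non-zero. Summits are
the leftmost argmax of the extended pileup inside the peak. Peaks are
ranked for "top N" selections by depth-normalised tag count (tags per
10 million); the ranking statistic is configurable because tag count,
ratio and caller score are all defensible and the choice is not
determined by the analyses this package reproduces. An IgG-control
mode runs identical mathematics with a mock-IP library as the shared
control for every factor.

## Interval algebra

All coordinates are 0-based half-open; overlap means ≥ 1 shared base,
so abutting intervals do not overlap. Venn counting is **region
based**: the counting unit is a maximal merged region of the union of
all input sets, and a set belongs to a region if any of its intervals
overlaps it. This makes "the union comprises n regions" a single
well-defined statistic across 2–4 factors. Peak–gene association uses
the window from 2.5 kb upstream of the TSS (in transcription
direction) through the TES, inclusive of both anchors; a peak can hit
several genes and vice versa. Metagene profiles place each peak
*summit* (not the whole interval, avoiding double counting across
bins) on a composite axis: 2 kb of fixed 50-bp bins upstream, the gene
body rescaled to 100 bins, 2 kb downstream; whole-interval assignment
is not offered because summit assignment is strictly finer.

## Signal matrices

Rows are summit ± 2 kb windows (2 × flank + 1 columns, centre column =
summit), values are per-base extended coverage × 10⁷/depth. Each
sample is truncated at its own 99th percentile computed over **all**
entries of that sample's matrix (not per row), which modifies at most
1% of entries up to ties and is purely a display-contrast device. Rows
are ordered by descending row sum of the first sample, stably (ties
keep input order), and that order is applied to every sample so
samples remain comparable row by row. Windows crossing a chromosome
edge are zero-padded and flagged. The 10⁷ normalisation scale is
cosmetic and configurable.

## Dependency classification

Counts are taken in **fixed wild-type-defined peak regions** across
genotypes, so per-site signals are paired. Fold change per site:
fc = (wt + p)/(ko + p) with pseudo-count p = 1 normalised count.
Binding is "reduced" in a knockout when fc ≥ `dependency_fold = 3`;
the four classes follow from the two indicators (both / only
L3MBTL2ko / only E2F6ko / neither). The underlying wet-lab analysis
distinguishes these classes from the *shape* of scatter plots without
committing to a numeric boundary; 3× is this package's explicit
choice, mirrors the enrichment-filter convention, is configurable, and
is written into every output header. Correlations are Pearson on log₂
fold changes (symmetric in gain/loss); inputs must be positive,
length ≥ 3 and non-degenerate.

## Central motif enrichment

Summit windows are 300 bp (±150). Consensus motifs match by exact
IUPAC comparison on both strands; PWMs score log-odds against a
uniform background with a hit threshold at 80% of the maximum score —
dependency-free and adequate for planted-motif studies. Per window the
best site is the maximal-scoring hit, ties resolved towards the
centre, then leftmost, then + strand; its offset is relative to the
window centre. The test statistic for n best sites is the binomial
tail P(K ≥ k) with success probability m_c/m, where m is the number
of possible site positions and m_c of them fall inside a central
window; widths {10, 20, …, 200} are scanned and the minimum tail is
Bonferroni-multiplied by the number of widths. This is a simplified,
documented analogue of CentriMo-style local enrichment; CentriMo's own
statistic and E-values are intentionally not reproduced. Two numerical
notes: extreme enrichment underflows double precision, so results
carry log₁₀ p computed from the log survival function; and the
multi-width Bonferroni statistic is conservative by construction, so
null-uniformity of p-values holds (and is tested) for the
single-width statistic, not the corrected minimum.

## Expression integration and growth curves

Expression changes use counts-per-million, mean over replicates per
condition, fc = (ko + p)/(wt + p), and inclusive ≥ 2-fold boundaries
for the up/down sets. This transparent threshold rule — not a
model-based test — is used because the analysis being reproduced
states only the 2-fold criterion; replication of real-data
differential gene counts is out of scope, and on real data a
dispersion-aware method (e.g. a negative-binomial GLM) would be
preferable. Overlaps with bound genes report counts and
nearest-integer percentages (an empty set reports its percentage as
undefined). Cumulative growth multiplies the running cell number by
each interval's fold increase counted/seeded, with replating defaults
matching the serial-passage design.

## The synthetic-data generator

The generator emulates the statistical structure of the deposited
experiments it stands in for: a set of shared complex binding sites
with factor tag enrichment; genotype-dependent loss of binding per
dependency class; artifact sites emitting tags identically in every
genotype including knockouts and IgG; library-depth differences; and
sequence motifs planted near summits.

Default study conditions (all configurable in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| genome | 5 × 2 Mb | desk-scale in seconds |
| sites | 150/150/150/50 + 50 | ALWAYS_MGA / L3MBTL2_DEP / E2F6_DEP / BOTH_DEP + ARTIFACT |
| spacing | ≥ 5 kb | candidate peaks never merge across truth sites |
| λ_bg | 0.005 tags/bp | uniform Poisson background per library |
| depth | 2 × 10⁶ nominal | scales site means: strength × depth/10⁷ |
| strength | U(300, 1500) per 10⁷ | 60–300 expected tags per site at default depth |
| σ | 60 bp | tag-position spread around the summit (a free choice; no fragment-size distribution is specified for the emulated libraries) |
| σ_motif | 20 bp | planted-motif offset spread |

Occupancy multipliers per (genotype, class) encode the biology: wild
type 1 everywhere; MGA loss 0 everywhere (scaffold); L3MBTL2ko /
E2F6ko 0 at their dependent classes and at BOTH_DEP; PCGF6ko 1
everywhere; IgG 0 everywhere; artifacts pinned to 1 in every genotype;
and ChIP of a factor in its own knockout is forced to 0 at every real
site — that library *is* the pipeline's control. Tag strand is chosen
so the 200-bp extension always covers the summit, which makes the
summit the pileup maximum in expectation. Site placement uses
slot-tiling with jitter, guaranteeing minimum spacing exactly rather
than by rejection. Each real site is assigned a generated gene whose
association window contains the summit (offset ~ N(0, 300 bp) along
the transcription direction), plus unbound background genes.
Expression counts are negative binomial (var = μ + 0.1 μ²) for 3 + 3
replicates with planted 4-fold changes; at this noise level the 2-fold
threshold recovers ≥ 95% of planted changes while miscalling at most
~5% of null genes (driven by the low-expression tail of the
lognormal(4, 1) mean distribution).

Everything is a deterministic function of the seed (per-sample streams
are derived from (seed, factor, genotype), so adding samples never
perturbs existing ones). What the generator does **not** model —
sequencing errors, duplicates, mappability, GC bias, fragment-length
variation, chromatin-state-dependent background — bounds what the
tests show: they validate the pipeline's logic and statistics under
its stated noise model, not robustness to real-library pathologies.

## Problem sizes and determinism

The default study (550 sites, ~1.4 × 10⁵ tags per library, 10 Mb
genome) runs each stage in seconds and the full pipeline in well under
a minute on one CPU; the test suite uses a 2 × 300 kb toy genome for
unit tests and the full default study for end-to-end checks. Repeated
runs with the same configuration produce byte-identical output files
(floats are serialised with `repr`), which the pipeline test enforces
by file comparison.

## Known limitations

* The candidate caller is not a reimplementation of any published
  caller; absolute peak counts from real data are expected to differ
  and are not an output this package claims.
* The dependency-class boundary (fc ≥ 3) and the "top N" ranking
  statistic are package choices surfaced in outputs; other defensible
  choices shift class counts at the margin.
* The central-enrichment statistic is a simplified binomial analogue
  of CentriMo, suitable for detection, not for comparing E-values
  across studies.
* Expression calls are threshold-based on CPM means; no variance
  shrinkage or multiple-testing control is applied.
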
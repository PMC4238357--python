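# Methods

This note documents the models and procedures implemented in `ncarray`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data does and does not establish.

## Region selection

A candidate locus is a *coverage contig*: an interval with strand, a
transcript-sense sequence, a per-base read-coverage vector and a supporting
read count. Coordinates are 0-based half-open; offsets within a contig are
always transcript-sense (minus-strand inputs are flipped on read, so
`coverage[0]` is the transcript 5′ end).

* **Read-support filter.** Contigs need ≥ `min_reads` (default 5) supporting
  reads; the boundary is inclusive.
* **Short contigs** (< 70 nt) give exactly one signal region: the sliding
  window of length `min(25, contig length)` (necessarily within 18–30 nt)
  with the highest mean coverage, leftmost on ties.
* **Long contigs** are tiled with windows of 30 nt anchored at offset 0
  (the anchor is a convention; any fixed grid would do — the last partial
  window is dropped below 18 nt). A window is *elevated* when its mean
  coverage strictly exceeds the contig-wide mean; all elevated windows are
  selected, or the single best window when coverage is flat. "Elevated
  versus the surroundings" is operationalized as window mean > contig mean
  because it is the simplest monotone criterion consistent with that idea.
* **Control/precursor region.** Among the grid windows, the one with the
  lowest mean qualifies when its mean is strictly below ⅓ of the contig's
  single-base maximum coverage; it is discarded if it overlaps a signal
  region. High coverage flanked by low coverage marks a processing product,
  so the low-coverage window reports on the precursor.
* Degenerate input: all-zero coverage selects the leftmost window (every
  window ties); contigs shorter than 18 nt are rejected.
* An optional pre-filter hook (`filter_candidate_ids`) restricts the contig
  set to an externally supplied candidate list, for selection criteria
  evaluated outside this package (e.g. expression changes across stem-cell
  differentiation stages); no differentiation data is modeled here.

All selection rules are exercised against an independent brute-force
enumerator in the test suite and the acceptance script.

## Probe design

Candidate oligos are all antisense sub-sequences of a region with length
18–30 (preferred 25). Five sub-scores, each in [0, 1] with 1 best:

| score | formula | rationale |
|---|---|---|
| ΔTm | exp(−\|Tm − 60 °C\|/5) | smooth penalty, ~37 % score loss per 5 °C |
| position | 1 − \|center offset\| / (region length/2), clipped | center preference |
| complexity | dinucleotide Shannon entropy / log₂16 | penalize low-complexity |
| folding | 1 − min(1, longest self-complementary stem/10) | hairpin risk |
| cross-hyb | 1 − longest off-target match / oligo length | specificity |

Off-target matches are found with a 12-mer seeded scan against the
background transcript set (by default the other contigs of the design run),
always excluding the probe's own source contig; matches shorter than the
seed count as zero. The sub-score formulas are this package's own
transparent definitions; the weights (24.2 % cross-hybridization, 32.3 %
ΔTm, 6.1 % folding, 11.3 % position, 16.1 % complexity — raw sum 0.900,
renormalized to 1 before combination), the 60 °C target, the 18–30 nt
window with 25 nt preference, and the center preference are the platform's
constraints. The combined score is the renormalized weighted mean, so it is
monotone in every sub-score; ties break toward the preferred length, then
leftmost.

**Melting temperature.** DNA:RNA hybrids melt differently from DNA:DNA
duplexes, so Tm uses the Sugimoto 1995 RNA/DNA nearest-neighbor parameter
set (via Biopython's `Tm_NN`), equal strand concentrations at 250 nM total,
and an entropy salt correction relative to the 1 M Na⁺ reference
(`na_molar` configurable, default 1.0 so the correction vanishes). The
model assumes a fully complementary duplex; it is a design-ranking
criterion, not a hybridization-kinetics prediction.

**MM construction.** The mismatch control substitutes one base at position
13 (1-based from the probe 5′ end — interior for every allowed length).
The substituted base must actually mismatch the opposing RNA base, and must
not be G opposite U nor T opposite G: G·U/T·G wobble juxtapositions retain
duplex stability and would make the MM probe behave like a second PM. The
wobble rule is enforced against the RNA *target* (not probe-vs-probe),
since cross-stability with the target is what the control must avoid.
Among admissible bases the A↔C / G↔T transversion partner of the PM base is
preferred, falling back to alphabetical order — a fixed table so that
regenerated chips are identical.

**Controls.** Eight seeded random 25-mer spike-ins (GC 40–60 %, no
self-complementary stem ≥ 6 nt) and 40 probes tiling U2/U6 snRNAs (20
each, evenly spaced). The bundled U2/U6 sequences are synthetic stand-ins
of realistic length generated from a fixed seed; supply real snRNA
sequences for a production chip. Control probes carry no MM partner.

## Array layout

Requirements: PM immediately left of its MM (same row, adjacent columns);
eight replicates per probe as two quadruplicates in disjoint halves of the
block list; no cell used twice. "Spatial distribution" of replicates is
realized by splitting the blocks into halves and spreading a probe's four
replicates round-robin over the (seed-shuffled) blocks of its half; within
a block, cells are handed out even rows first, then odd rows, so replicates
that land in the same block sit on non-adjacent rows whenever capacity
allows. The layout is deterministic given the seed, and an independent
validator checks every invariant on any layout file.

## Hybridization simulator

Per-spot generative model (log₂ scale unless noted): specific signal
S = 2^(μ_g + x_c β_g + b), with baseline μ_g ~ U(6, 12) (net intensities
~64–4096, a realistic scanner mid-range), condition indicator x_c, effect
β_g, and biological noise b ~ N(0, σ_bio²) drawn per gene × array ×
condition. MM spots see κ·S. Channel foreground is

F = 2^(±(g_b(a) + δ_g)/2) · (S + ν) · e^ε + B,

with per-block quadratic curvature g_b(a) in a centered log-intensity
coordinate (coefficients ~N(0, (0.10, 0.05, 0.02)²)), gene-wise dye bias
δ_g ~ N(0, 0.05²), nonspecific floor ν = 2, multiplicative noise
ε ~ N(0, 0.12²) (≈12 % CV — a well-behaved two-color hybridization), and
background B ~ N(100, 10²) truncated at 0. The sign is + for the Cy5
(635 nm) channel and − for Cy3, so the curvature and dye bias land on the
M scale where print-tip loess and dye-swap averaging must remove them. The
reported background column is the drawn B, so net intensity is exact in
the noise-free limit: the model then collapses to F − B = 2^(μ + xβ) on PM
spots, which the tests assert.

Defaults: 3 dye-swap pairs (each biological replicate hybridized twice
with dyes reversed), 10 % DE at |log₂FC| = 1 with balanced signs, κ = 0.2,
2000 candidates in the simulation study. Biological noise is drawn
independently per hybridization (each array uses its own aliquot and
labeling of the sample), which matches the independence assumption of the
simple dye-swap linear model below; if the two arrays of a swap pair
shared one biological draw, array-level residuals would be pairwise
correlated and the stated residual degrees of freedom would be optimistic
— a limitation of the simple dye-swap design itself, not of this
implementation.

What the simulator does **not** model: scanner saturation, spatial
gradients within blocks, spot-morphology variation, carry-over between
channels, and segmentation error in the background estimate. Passing tests
therefore show the pipeline is correct *for data matching its model
assumptions*; they do not certify performance on arrays whose artifacts
fall outside that class.

## Expression analysis

* **Net intensity** = foreground − local background per channel; values
  ≤ 0 are floored at ε = 0.5 before log₂ (avoids −∞, common practice).
* **PM > MM filter** runs on *raw* net intensities, before normalization:
  the condition-level PM (MM) intensity is the mean net intensity over all
  spots, arrays and channels assigned to that condition, and a candidate
  passes when PM > MM strictly in at least one condition. Raw intensities
  are used because the filter asks a physical question (did the PM spot
  bind more material than its control), which normalization would blur.
  MM-less probes pass automatically and are flagged.
* **M/A values**: M is oriented case-minus-control using the experiment
  sheet (constant sign convention across arrays); A = ½(log₂ net₁ +
  log₂ net₂).
* **Within-array normalization**: per print-tip block, robust lowess of M
  on A (span 0.4, 4 robustness iterations, interpolation grid at 1 % of
  the A-range); M is replaced by its residual, A is untouched. Blocks with
  < 20 spots fall back to one whole-array fit. The local-linear smoother
  reproduces an exactly linear trend, so block-wise linear biases are
  removed identically (asserted in tests).
* **Between-array normalization**: quantile normalization of the A-values
  only, with M preserved — normalizing A aligns the intensity scales
  without touching the within-array contrasts that carry the biology. A
  full-channel quantile variant was considered and rejected as the default
  because it would re-open the M sign conventions; the A-only reading is
  idempotent and keeps the dye-swap algebra exact.
* **Dye-swap linear model**: per candidate, M = β + error across arrays.
  Replicate spots are combined by within-array averaging (default):
  β̂ = mean of per-array values, s²_g their sample variance with
  d_g = n_arrays − 1 (= 5 for three dye-swap pairs). The alternative
  `dup_method="gls"` fits all spot-level values under a chip-wide
  equicorrelation ρ of replicate spots (moment estimate); on balanced
  layouts the point estimate coincides with the average, while the
  residual variance uses all spots (d_g = n_spots − 1). Averaging is the
  default because the array, not the spot, is the unit of independent
  replication.
* **Empirical-Bayes moderation**: the prior (d₀, s₀²) is fitted by moment
  matching on log s²_g — with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the
  mean of e identifies s₀² and the excess of Var(e) over ψ′(d_g/2)
  identifies ψ′(d₀/2), inverted by Newton iteration. Zero excess
  dispersion gives d₀ = ∞: all genes share s₀² and the statistic is
  referred to the normal distribution; otherwise t̃_g = β̂_g/(s̃_g√v_g)
  with d₀ + d_g degrees of freedom. Fewer than 10 usable candidates is an
  error (an exact t-test is the advised fallback); genes with zero
  residual variance are excluded from the prior fit, which is why the
  *exactly* noise-free simulation exercises the fold-change path but not
  the p-value path.
* **Multiple testing**: Benjamini–Hochberg step-up; DE call at adjusted
  p < 0.05. Two-fold-change lines in volcano-style outputs are annotation
  only, never a filter.

## Simulation study and problem sizes

The operating-characteristics study (`ncarray.workbench.simulation_study`,
also run by `scripts/acceptance.py` and the acceptance tests) uses a
16-block chip of 46 × 44 cells holding 2000 candidate probe pairs plus the
48 controls, 3 dye-swap pairs, and 50 replicate seeds, each seed
contributing one experiment with 10 % DE and one fully null experiment.
Reported: pooled empirical FDR at adjusted p < 0.05, mean sensitivity,
mean |β̂ − β| over DE candidates, and the null raw-p rate. These sizes
give ~100 000 null tests per metric, enough that the binomial noise on the
reported rates is below a percentage point.

## Known limitations

* The Tm model ranks candidate oligos; it does not predict on-chip
  hybridization yield.
* The cross-hybridization score sees only contiguous matches ≥ 12 nt;
  gapped or accumulated shorter homologies are invisible to it.
* The GLS replicate option assumes one chip-wide replicate-spot
  correlation; strongly probe-specific correlation structures are averaged
  over.
* The PM>MM filter compares means; a candidate expressed in a small
  minority of spots/arrays can be masked.
* Real-chip counts (how many probes a given RNA-Seq data set produces)
  depend entirely on the input contigs; the package reports both PM-type
  and total spotted species counts for any design it builds but does not
  target any particular historical chip.
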
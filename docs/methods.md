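# Methods

This note documents the models, estimators and numerical choices behind
each pipeline stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the procedure was
genuinely open.

## Reporter-screen triage

Each compound is measured in three channels: a fusion-oncogene-selective
super-enhancer luciferase (ALK), a constitutive CMV-promoter luciferase,
and XTT viability. Signals are normalized per plate and per channel to
the mean of that plate's vehicle-control wells (≥ 2 required, mean > 0):
`pct = 100 · signal / vehicle_mean`. Normalizing per plate rather than
per run is standard high-throughput-screening practice and makes the
statistic invariant to plate-to-plate instrument drift (a property the
tests assert). Compounds missing any of the three channels are excluded
with a warning rather than imputed, because the triage score needs all
three terms.

The triage score is the fixed convex combination
`(4·ALK + 2·CMV + XTT) / 7`, weighting the fusion-selective channel
highest. Being convex, it is bounded by the smallest and largest of its
inputs.

Classification applies, in order: **strong** if both reporters are below
10% of control; else **HDACi-like** if ALK ≤ 50% and CMV ≥ 120%; else
**ALK-selective** if ALK ≤ 50% and CMV within 100 ± 20%; else
unclassified. The 10% strong rule is a fixed convention of the assay;
the 50% / ±20-point thresholds operationalize "decreased", "increased"
and "no significant change", are exposed on `ClassificationRules`, and
their defaults were chosen so the three planted mechanism classes of the
generator are qualitatively separated. Rule order makes the labelling a
total function with strong taking precedence.

Primary hit selection is a weighted-score threshold with optional top-N
truncation, ranked ascending with lexicographic compound-id tie-breaks.
A threshold of 0 is legal and yields an empty list.

## Dose-response

The 4PL model is the dose-ratio ("variable slope") form
`f(d) = bottom + (top − bottom)/(1 + (d/EC50)^h)`, which satisfies
`f(EC50) = (top + bottom)/2` identically and is scale-equivariant in
dose. Fitting is ordinary least squares (Levenberg–Marquardt via
`scipy.optimize.curve_fit`) with the EC50 parameterized internally as
log10(EC50) for conditioning; tight tolerances (1e-14) let noiseless
series converge to machine precision. Initialization is data-driven:
bottom = min, top = max, EC50 = geometric-mean dose, Hill = ±1 by the
dose–response correlation sign. The model is invariant under swapping
(bottom, top) while negating the Hill slope, so fits are canonicalized
to top ≥ bottom. Flat series (range below `degenerate_tol`, default
1e-6) are flagged degenerate with no EC50; optimizer failures return
`converged=False` with the message rather than raising. No outlier
rejection is applied. Confidence intervals are not computed by default
(`ci_ec50` is a placeholder for bootstrap estimates).

The monotone-response QC criterion computes the Spearman rank
correlation between dose and the mean response per distinct dose and
passes when ρ ≤ −0.8 (configurable). This makes "signal falls with
rising dose" explicit and unit-invariant; constant series have undefined
ρ and fail with a reason.

At 2% additive response noise (s.d. 2 on a 0–100 scale) with 5 doses ×
3 replicates, EC50 recovery within 10% relative error is achieved in
roughly nine out of ten series when the true EC50 lies on the tested
dilution grid; this is the sampling variance of the least-squares
estimator at that design, not an optimizer limitation (error
distributions are smooth with no divergent fits).

## Tiled-CRISPR depletion mapping

Counts are normalized by median-ratio size factors (median over
all-nonzero guides of count / geometric-mean-across-samples). When a
reference (plasmid-pool) sample is designated, factors are rescaled so
the reference factor is exactly 1, putting normalized counts on the
reference scale; this also makes a sample that is an exact k-fold copy
of the reference come out with factor k. Reads-per-million is available
as the alternative. Per-guide depletion is
`log2((sample + 0.5)/(reference + 0.5))` on normalized counts — the 0.5
pseudocount is symmetric and keeps the statistic defined at zero counts.

Smoothing is a trailing walking average of w = 4 guides reported over
the half-open interval its guides cover; the >4-fold depleted fraction
uses the strict per-guide rule `lfc < −log2(4)` on unsmoothed values.
Hotspots are maximal runs of ≥ 2 consecutive windows with smoothed LFC
≤ −2, merged into coordinate intervals. Each call gets an empirical p:
the add-one-corrected fraction of null window means (w non-targeting
LFCs resampled 10,000 times with a fixed internal seed, so calls are
deterministic) at or below the observed mean; with fewer than 10
non-targeting guides the p is reported unavailable. Each timepoint of a
time-course is compared independently to the plasmid pool; no
longitudinal model is fitted.

## Spike-in chromatin analysis

Samples carrying a constant exogenous spike-in are scaled by
`1e6 / spike_total` ("spike-in reads per million"), with no library-size
blending: after scaling, every sample's spike signal is exactly 1e6, and
a genome-wide k-fold change in target signal remains k-fold — the
property that motivates spike-ins in the first place, asserted by a
planted-shift simulation.

Differential regions are tested per region with a two-sample t on
`log2(scaled + 0.5)`, BH-adjusted across regions, and called up/down
at padj ≤ 0.05 and |FC| ≥ 1.5. This is a deliberate, self-contained
simplification of shared-dispersion negative-binomial modelling; the
thresholds are kept. The **pooled** (Student) t is the default: in the
balanced three-vs-three designs this module targets, the pooled test is
exact under normality, whereas the Welch–Satterthwaite approximation is
badly conservative at such small df (measured size ≈ 0.035 at α = 0.05
on normal data), which would defeat the calibration the null simulation
checks. Welch remains available (`equal_var=False`) for unbalanced or
heteroscedastic designs. Constant regions get p = 1; swapping condition
labels negates all fold changes and preserves p exactly.

Interval conventions are BED throughout: 0-based, half-open.
Nearest-gene distance is 0 on overlap, else the gap, signed positive
when the gene lies right of the peak; |distance| ties break to the
leftmost gene start with a tie flag, and peaks on chromosomes missing
from the gene set are returned unassigned rather than dropped. Anchored
profiles average length-weighted bedGraph signal in equal bins across
[center − flank, center + flank), treat uncovered positions as 0 with a
per-anchor flag (keeping the matrix rectangular), and reverse bin order
for minus-strand anchors. State aggregation allocates each bin's count
to segmentation states proportionally to overlap, so total signal is
conserved exactly (states + unassigned = grand total); segmentations
must be non-overlapping.

## Preranked enrichment

With genes ranked by score descending, set members increment the
running sum by `|score|^p / Σ_hits |score|^p` (p = 1, the "weighted"
scheme; p = 0 gives the classic KS form) and non-members decrement by
`1/(N − m)`; ES is the signed extremum (first index on ties). If all
member scores are exactly zero the hit weights fall back to 1/m. The
null is gene-set permutation: random same-size member sets from the
ranked universe, vectorized in blocks.

Estimators: NES divides ES by the mean |null ES| of matching sign.
The permutation p is the add-one **magnitude** estimator
`p = (1 + #{|null ES| ≥ |ES|}) / (1 + n_perm)`: under the null it is
exactly uniform by exchangeability, its floor is 1/(1 + n_perm), and it
is never 0. A sign-stratified one-sided estimator was considered and
rejected because with mixed-sign nulls its denominator halves (floor
≈ 2/n_perm) while making it uniform requires the same-sign denominator —
the two properties cannot be had together; the magnitude estimator keeps
both. Results are flagged unstable when fewer than 10 nulls share the
observed ES sign (the NES denominator is then poorly estimated). FDR
across multiple sets is the standard sign-stratified
ratio-of-tail-proportions on pooled null NES vs observed NES, clamped to
[0, 1] — an approximation, documented as such. Duplicate gene ids are an
error, never silently collapsed.

Leading edge: members at or before the running-sum maximum for positive
ES, at or after the minimum for negative ES; ES = 0 yields an empty,
flagged result. UP/DOWN signature construction takes the k largest
strictly positive and k smallest strictly negative statistics (default
k = 50, log2 fold change), breaking boundary ties by lexicographic gene
id and flagging shortfalls instead of padding.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their spec (seed included), emit
ground-truth sidecars, and reproduce planted means exactly at zero
noise. Defaults, with rationale:

* **Screen** (`ScreenSimSpec`): 2,000 compounds on 384-well plates with
  16 vehicle and 8 positive-control wells per plate per channel;
  class mix 5% HDACi-like / 5% ALK-selective / 2% strong / 88% inactive
  (largest-remainder apportionment, so counts are exact); per-class mean
  percents (ALK, CMV, XTT): 30/140/90, 30/100/90, 5/5/40, 100/100/100;
  multiplicative lognormal noise with CV 5% (mean exactly 1) — reporter
  luminescence is positive and right-skewed, so lognormal is the
  natural noise model. Not emulated: plate spatial artifacts (edge
  effects), replicate structure, reader dialects.
* **Dose-response**: five 10-fold dilutions, 20 µM down to 2 nM,
  triplicates, additive Gaussian noise on the response.
* **Tiling** (`TilingSimSpec`): 479 guides evenly spaced over a
  4,790-bp coding span, a planted hotspot at [3000, 3350) (≈ 7% of
  guides, emulating an essential enzymatic domain) with mean LFC −3;
  32 essential-control guides (8 genes × 4) at LFC −3 and 20
  non-targeting at 0; negative-binomial counts (var = m + α·m²) with
  α = 0.01 at ≈ 1,880 expected reads/guide — a well-powered pooled
  screen at high coverage.
* **Regions** (`RegionSimSpec`): 5,000 regions, lognormal baseline
  around mean 100, NB dispersion 0.02 (highly reproducible cell-line
  triplicates), 3 vs 3 replicates, planted fold change 4 in 10% of
  regions, per-sample spike totals (default 1e6 each), and an optional
  uniform `global_shift` multiplying all treated counts — visible only
  through the spike-in.
* **Ranked lists** (`RankSimSpec`): N(0, 1) scores over 1,000 genes
  with an additive shift on one planted set.

Passing tests on these data show the estimators are correct and
calibrated under their stated models; they do not show robustness to
real-data pathologies (batch effects, GC bias, guide-efficiency
heterogeneity, copy-number confounding, correlated genes in enrichment
nulls), which are out of scope.

## Problem sizes

The test suite and the acceptance script run the study-scale designs
directly — 2,000-compound screens, 100 dose-response refits, the
479-guide tiling library, 5,000-region differential matrices, and
1,000-permutation enrichment with a 200-run null calibration — since
all of them complete in seconds at these sizes.
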
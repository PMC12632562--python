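# Methods

This note records the statistical models implemented in `splicepharm`, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Differential exon inclusion

Each alternative-splicing event in a sample is summarized by two junction
read counts: reads supporting inclusion of the cassette exon and reads
supporting its exclusion. The inclusion level Ψ (percent spliced in) is
modeled conjugately: with a Beta(a, b) prior (default a = b = 1, i.e.
uniform), inclusion `i` and exclusion `e` reads give the posterior
Ψ ~ Beta(i + a, e + b). `estimate_psi` reports the posterior mean and the
central 95% posterior interval. This two-proportion model deliberately
ignores isoform lengths: every downstream decision uses only the
inclusion/exclusion evidence, so a read-assignment model over isoform
structures would add parameters without changing any quantity the pipeline
reports. An optional per-event effective-length pair can rescale counts
before the Beta update; it is off by default.

**Bayes factor.** Differential inclusion between conditions is scored with
a Savage–Dickey density ratio. Under H₁ the two Ψ values are independent
Uniform(0, 1); H₀ pins ΔΨ = Ψ_mut − Ψ_wt at 0. Then

BF₁₀ = p(ΔΨ = 0 | prior) / p(ΔΨ = 0 | data).

The prior density of ΔΨ at 0 is exactly 1 (the difference of two
independent uniforms has a triangular density peaking at 1). The posterior
density at 0 is the integral over [0, 1] of the product of the two Beta
posterior densities, evaluated by trapezoidal quadrature on a uniform grid
(default 1001 points). Quadrature rather than sampling makes every BF
value exactly reproducible. The grid value agrees with the closed form
B(a₁+a₂−1, b₁+b₂−1) / (B(a₁,b₁) B(a₂,b₂)) to ~1e−6 relative error for all
count pairs exercised in the tests. The function refuses, with a
diagnostic, when a posterior's 95% interval is narrower than two grid
cells; for junction depths up to ~10⁵ reads the default grid is safe.

A Monte-Carlo cross-check (`bayes_factor_mc`) estimates the same posterior
density by importance sampling from a tempered proposal — a Beta whose
evidence counts are halved, hence wider than the integrand everywhere —
with weights accumulated in log space. Direct draws from the two
posteriors cannot resolve the density at 0 when the posteriors barely
overlap (it can be below 1e−40), which is why the oracle uses importance
sampling; with 10⁶ draws its relative error is below 1% for every pair at
junction depth ≤ 100.

**Calling rule.** An event is called differential when |ΔΨ| ≥ 0.10 *and*
BF ≥ 5. Both comparisons are inclusive (a 1e−12 absolute tolerance absorbs
float representation noise at exact ties). ΔΨ is the difference of
posterior means, mutant minus wild type; `direction` follows its sign.
Replicate libraries within a condition are pooled by summing counts before
testing, and the pooling policy is recorded in output metadata. Class
summaries always report all five event classes (CE, RI, MXE, A5SS, A3SS),
zero-filled, counting significant calls by direction.

## SSNG motif enrichment

The SSNG exonic-splicing-enhancer family is the 16 four-mers with S ∈
{G, C} at positions 1–2, any base at position 3 and G at position 4. The
biologically opposed subfamilies are CCNG (bound more tightly by mutant
SRSF2, promoting inclusion) and GGNG (bound more weakly, promoting
skipping). Counting is a sliding-window scan of the sense-oriented
sequence: overlapping occurrences all count (the simpler convention with
clean conservation invariants; occurrence counts, not coverage, are
reported), and any window containing N never matches.

Per-variant enrichment is (count_inc + pc) / (count_dec + pc) with
pseudocount pc = 1 applied always, to both numerator and denominator, so
the statistic is defined and antisymmetric under set swap even at zero
counts. Totals run over exon intervals only; flanks are excluded. Because
"mean of counts" is ambiguous between raw totals and per-exon means when
set sizes differ, both are emitted (`mean_enrichment` and
`per_exon_enrichment`).

**Metagene.** Two windows are anchored per cassette exon: at the 3′ splice
site (intronic offsets −w_i…−1, exonic 0…w_e−1) and at the 5′ splice site
(exonic −w_e…−1, intronic 0…w_i−1); defaults w_e = w_i = 50 nt, a window
wide enough to cover the footprint over which SR-protein enhancers act
while fitting typical cassette exons. A motif is assigned to the offset of
its start position. The profile is log₂((inc + pc)/(dec + pc)) of
per-position totals; 95% confidence bands come from a percentile bootstrap
(default B = 1000, seeded) resampling exons with replacement within each
set. Percentile rather than BCa: the statistic is a smooth function of
sums, set sizes are in the hundreds to thousands, and percentile intervals
are exactly antisymmetric under set swap. Intervals are widened, when
needed, to bracket the point estimate. Under the null the bands cover zero
at 0.95–0.96 empirically (measured over 2400 position×replicate cells).

## Dose-response scoring

**Normalization.** Viability = raw signal / mean(DMSO wells) within each
(sample, drug) context; values above 1 (growth stimulation) are kept,
negative signals are clipped to 0. Replicates are averaged per
concentration with n recorded, and replicate-level points are retained so
curve fits see the noise structure. Concentrations are converted to molar
on read from the declared unit column.

**DSS.** Inhibition = 100·(1 − viability). The drug sensitivity score is
the normalized thresholded area

DSS = 100 · A / ((100 − t) · (log₁₀C_max − log₁₀C_min)),

where A integrates max(0, inhibition − t) over log₁₀ concentration by
trapezoid, with threshold crossings located exactly on each
piecewise-linear segment; activity threshold t = 10% by default. Forced
values: 0 for inhibition everywhere ≤ t, 100 for complete inhibition, and
exactly 50 for a linear 0→100% ramp at t = 0. Absolute DSS values depend
on the tested concentration window, so only orderings and group contrasts
are comparable across assay designs.

**GR metrics.** GR(c) = 2^(log₂(x(c)/x₀) / log₂(x_ctrl/x₀)) − 1 from
initial count x₀, treated endpoint x(c) and untreated endpoint x_ctrl
(which must exceed x₀). GR = 1 means no effect, 0 cytostasis, negative
cytotoxicity, and GR > −1 always. The GR dose curve
gr_inf + (1 − gr_inf)/(1 + (c/GEC₅₀)^h) is fitted by bounded least squares
from three deterministic starts, and GR₅₀ solves GR = 0.5 analytically
from the fitted parameters (undefined when the curve never reaches 0.5).

**IC₅₀.** Viability curves are fitted with a four-parameter logistic
(bounds: top ∈ [0.5, 1.5], bottom ∈ [0, 1], hill ∈ [0.3, 5], EC₅₀ within
the tested range ± 2 log units; EC₅₀ is parameterized in log₁₀ space),
again from three deterministic starts, on replicate-level points. A fit
that does not beat the flat mean-viability model by AIC is flagged
no-response. The reported IC₅₀ is the absolute 50%-of-control crossing of
the fitted curve (defined only when the crossing lies within the tested
range extended one log unit); the relative EC₅₀ is also emitted. On
noise-free curves the EC₅₀ is recovered to well under 1%; at 2% additive
noise the median error over 100 simulated curves is ~4%.

**Group statistics.** Group DSS contrasts use the two-sided Mann–Whitney U
test: exact enumeration of all C(n_a+n_b, n_a) assignments (midranks for
ties) when the combined n ≤ 12, the normal approximation with tie
correction otherwise. VAF–DSS association is ordinary least squares with a
two-sided t-test on the slope; a perfectly flat response returns r = 0 by
convention. IC₅₀ group comparisons use one-way ANOVA on log₁₀ IC₅₀
(log_transform=True by default) with Tukey HSD adjusted pairwise p-values
from the studentized-range distribution.

## VAF and mutant-allele copies

VAF = alt/(alt+ref), reported to 4 decimals; zero depth is an error. Copy
inference on a locus with `total_copies` alleles rounds the VAF to the
nearest integer percent and assigns copies = ceil(percent/100 ×
total_copies), with 0% mapping to 0 copies. For a triploid locus this is
exactly the 1–33% → 1, 34–66% → 2, 67–100% → 3 rule. Note the geometry
this rule implies: the *expected* VAF of a k-of-3 clone (33.33%, 66.67%)
sits exactly on a bin edge, so a sample whose true VAF is exactly k/3 is
intrinsically ambiguous between k and k+1 under sampling noise; the rule
decides cleanly whenever the true VAF lies interior to a bin. Ploidies
other than 3 use the same equal-range rule and are an extrapolation beyond
the triploid setting the rule was designed for.

## Synthetic data

The generator emulates the study designs the pipeline targets, one RNG
stream per output (derived from the master seed by a stable text label, so
adding an output never perturbs the others; identical configs give
byte-identical files).

- *Junction counts*: per event, inclusion ~ Binomial(depth, Ψ) with depth
  ~ Poisson(200) by default — typical junction evidence for a deeply
  sequenced bulk library — and one library per condition, matching a
  clone-vs-control design. Base Ψ is uniform on (0.3, 0.7); "true" events
  (half by default) get Ψ_mut = clip(Ψ_wt ± 0.3), a shift comfortably
  above the 10% calling threshold.
- *Sequences*: uniform A/C/G/T background over exon (120 nt) plus flanks
  (100 nt). Increased-inclusion exons receive Poisson(3.5) planted CCNG
  motifs, decreased-inclusion exons Poisson(3.5) GGNG, uniformly placed
  inside the exon, never overlapping each other and never straddling the
  exon boundary. 3.5 per 120 nt exon is roughly twice the uniform
  background class rate ((L−3)·4/256 ≈ 1.8), i.e. about a 3× total rate —
  a strong but realistic enhancer-density contrast. Configs whose rate
  could not physically fit (rate > exon_len/4) are rejected; a Poisson
  tail draw exceeding capacity is clamped, and the realized planted counts
  are what the truth table records.
- *Viability plates*: five-point dilution series 0.001–10 µM in equal log
  steps, three replicates, six DMSO wells, signal = 4PL(c) + N(0,
  noise_sd·top) with noise_sd = 0.02 — few-percent noise typical of
  luminescent viability assays. An EC₅₀ outside the tested range is
  flagged in the truth table, not rejected.
- *Amplicon counts*: alt ~ Binomial(depth, VAF) at depth 5000, VAF one of
  {0, 1/3, 2/3, 1} by default, mirroring a triploid clone panel.

Not emulated: read-level artifacts (alignment, duplicates, GC bias),
overdispersion beyond binomial/Poisson, batch and plate-position effects,
allele-specific expression (RNA VAF is simulated at the DNA allele
fraction), and linkage between the splicing and pharmacology arms.
Passing recovery tests therefore demonstrates correctness of the
statistics under their own sampling assumptions, not robustness to real
data pathologies.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 200 events at depth 200 for
differential-calling recovery; 50 random count pairs (depth ≤ 100) with
10⁶-draw MC for the Bayes-factor cross-check; 1000 exons per set with
B = 1000 for planted-direction enrichment and metagene checks; 20
replicate null datasets of 400 exons per set (window 30/30 nt) for
bootstrap calibration; and 100 noisy curves for EC₅₀ recovery. These sizes
put Monte-Carlo error well below the asserted tolerances while keeping the
whole suite under a minute of CPU.

Ties at calling thresholds are significant. Degenerate inputs fail loudly:
zero amplicon depth, missing or non-positive DMSO controls, non-growing GR
controls, hill = 0 curves, windows exceeding flanks, and grids too coarse
for the posterior all raise with messages naming the offending quantity.

## Known limitations

- The Bayes factor tests equality of two binomial proportions; it is not
  MISO's generative isoform model, and BF values are comparable across
  events only under equal priors and pooling policy.
- Intron-retention and alt-splice-site events are carried through the same
  junction-count model as cassette exons; coverage-based RI quantification
  is out of scope.
- DSS is reported on this package's fixed thresholded-AUC definition;
  published DSS values computed with other variants or concentration
  windows are not directly comparable.
- The exact Mann–Whitney path enumerates up to C(12,6) = 924 assignments;
  larger designs switch to the tie-corrected normal approximation.
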
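# Methods

## The model

`sweepmix` models a windowed haplotype-based selection statistic as a
two-component Gaussian mixture whose mixing probability is a logistic
function of genomic covariates (a mixture density regression, MDR; in the
mixture-of-experts literature, a two-expert model with a logistic gate and
constant experts).

For gene window *i* with standardized covariate row *x<sub>i</sub>* and
response *Y<sub>i</sub>* (the z-scored natural log of the window mean
|iHS|):

```
p_i   = sigmoid(a + Σ_j b_j x_ij)
P(Y_i) = p_i N(Y_i | μ1, σ1) + (1 − p_i) N(Y_i | μ0, σ0)
```

The component with the larger mean, `N(μ1, σ1)`, is interpreted as enriched
in recent positive selection (sweeps elongate haplotypes and raise |iHS|);
the other component absorbs drift and demography. A positive slope
*b<sub>j</sub>* means the covariate increases the probability that a window
belongs to the selection-enriched component. The mean of the fitted
*p<sub>i</sub>* over windows (the *component magnitude*) summarizes how much
of the genome the enriched component claims.

Assumptions worth keeping in mind: two components suffice (empirically,
windowed |iHS| is well described by a bimodal mixture); covariates act
linearly on the logit of the mixing probability, not on the component means;
windows are treated as independent, which overlapping gene-centered windows
violate — p-values are therefore anti-conservative on real data and should
be read comparatively.

## Estimation

Parameters `(a, b, μ0, σ0, μ1, σ1)` are estimated by direct maximum
likelihood with L-BFGS-B — no EM. The per-window likelihood is evaluated in
log space (log-sum-exp over the two weighted components) so tail
observations cannot underflow, and the analytic gradient is supplied (the
gradient flows through the gate as `responsibility − p`).

Constraints are handled by an unconstrained reparameterization
`θ = (a, b, μ0, log σ0, δ, log σ1)` with `μ1 = μ0 + exp(δ)`, which enforces
`σ > 0` and `μ1 > μ0` smoothly and resolves label switching
deterministically (component 1 is always the high-mean component). The
log-scale coordinates are additionally box-bounded to ±20 so `exp` cannot
overflow when the optimizer explores a flat ridge.

Initialization: `μ0` at the 40th percentile of Y, `μ1` at the 90th,
`σ0 = σ1 = SD(Y)`, `a = logit(0.25)`, `b = 0` — robust for a right-heavy
response. Multi-start (default 5 restarts) jitters this start with a seeded
RNG; the best log-likelihood wins, ties broken by first occurrence.
Convergence tolerances default to `ftol = 1e-9`, `gtol = 1e-6`, 2,000
iterations (all configurable via `FitConfig`); non-convergence on every
restart is reported with `converged=False` and a warning, never silently.

### Degenerate (collapsed) fits

When the response carries no mixture structure the two components collapse
onto one Gaussian and the gate — intercept and slopes — becomes
unidentifiable. The fit is then flagged `degenerate` rather than reported as
a genuine two-component solution. The detector triggers when any of:
effective separation `(μ1 − μ0) / sqrt((σ0² + σ1²)/2) < 0.5`; mean fitted
`p` outside `[0.01, 0.99]`; log-likelihood gain over the single-Gaussian MLE
below the number of extra parameters (`k + 3`). On pure-noise responses the
flexible mixture typically overfits by a handful of log-likelihood units
(the chi-bar-square scale of its extra parameters), while a genuinely
bimodal response yields gains orders of magnitude larger, so the three
conditions separate the regimes cleanly.

### Likelihood-ratio tests

Each covariate's slope is tested by refitting the nested model without that
column (all remaining parameters free, warm-started from the full solution)
and referring `max(0, 2(ℓ_full − ℓ_null))` to χ²₁. Raw p-values are
reported; a Benjamini–Hochberg q-value column is available behind a flag
(off by default). An optional intercept test refits with `a` fixed at 0.
The mixing-weight *level* is weakly identified when components overlap
(see Limitations), but slope contrasts — what the LRT measures — remain
well calibrated: with a pure-noise covariate appended the test's null
rejection rate at α = 0.05 sits inside [0.03, 0.07] over 1,000 replicates
at n = 2,000 (part of the test suite).

## From raw iHS to the model inputs

1. **MAF filter.** SNPs with minor allele frequency strictly > 0.05 are
   kept (frequencies are derived-allele frequencies, the polarization iHS
   uses).
2. **Frequency-bin standardization.** Raw iHS depends on allele frequency,
   so scores are standardized within 50 genome-wide frequency bins —
   half-open `[k/50, (k+1)/50)`, the top bin closed at 1.0 — as
   `(raw − bin mean) / bin SD`. Bin statistics are computed over the whole
   genome, never per chromosome or window. Bins with fewer than 2 SNPs
   (configurable) or zero SD drop their SNPs with a logged count.
3. **Window summaries.** Windows of a fixed size (50, 100, 200, 500 or
   1,000 kb) are centered at each gene's genomic center
   (`floor((start+end)/2)` of the outermost transcription span). Per window
   the mean of |standardized iHS| and the SNP count are recorded; windows
   with zero SNPs are dropped. Interval membership is half-open
   `[start, end)` throughout, 0-based.
4. **Response and covariates.** `Y` is the z-score of the natural log of
   the window mean |iHS| over the analysis set; covariates are centered and
   scaled the same way. Sample SD (`ddof=1`) is the convention everywhere.
   The log base is immaterial (absorbed by the z-score) but fixed at *e*.

## Genomic covariates

* **Recombination rate** (cM/Mb): genetic distance between the window edges
  over physical distance. An edge's cM comes from the genetic map — exact
  map point, or linear interpolation between the two flanking points when
  both lie within 50 kb of the edge; otherwise the window is discarded for
  recombination and, by complete-case filtering, from the analysis. The
  50 kb cap prevents interpolating across distances larger than the window
  itself. (For SNP positions the analogous search radius is 1,000 kb.)
* **Interval densities** (coding, conserved, DNaseI, ChIP-seq tracks):
  merged-interval bases inside the window, excluding assembly-gap bases
  from numerator and denominator; missing when the window is entirely gap.
  Scored tracks (conserved, regulatory) are first thresholded at the
  smallest score that keeps at most a target genome fraction — 4.17% for
  conserved elements, 10% for regulatory tracks — with score ties kept
  together (all-or-none per score value).
* **GC content**: (G+C)/(A+C+G+T) per window; ambiguous bases are excluded
  from the denominator, all-N windows are missing.
* **Gene-level covariates**: gene length; number of genes intersecting the
  window (≥ 1 bp, self included); `log2(TPM + 1)` expression per tissue set
  (the pseudocount handles silent genes); `log2(PPI + 1)`; distance to the
  nearest virus-interacting-protein (VIP) gene, measured edge-to-edge with
  0 on overlap (center-to-center available behind a flag), missing when the
  chromosome has no VIP.
* **Fine-scale recombination near regulatory elements** (optional): over
  merged element ± 5 kb regions clipped to the window, the rates between
  consecutive map points are averaged weighted by physical span (which
  telescopes to total cM over total bp per region), together with the
  number of map points used.

Rows with any missing covariate are excluded (complete-case), with per-
reason counts logged and returned. An optional greedy left-to-right filter
retains only mutually non-overlapping windows for robustness checks.

## Synthetic data

`simulate_mdr_dataset` samples the model's exact generative process:
standard-normal covariates (optionally correlated through a Gaussian
copula, since real genomic factors such as GC and recombination co-vary),
Bernoulli component labels through the logistic gate, Gaussian response per
label. `study_parameters()` fixes the canonical truth for simulation
studies: baseline probability 0.3, components at μ0 = −0.39 (σ0 = 0.85) and
μ1 = 0.90 (σ1 = 0.95) on the z-scored response scale — the clearly
separated, ~30%-weight regime the method is designed for — and a slope
pattern spanning ±0.4 down to exact zeros.

`simulate_toy_genome` builds a 2 × 5 Mb genome: a piecewise-uniform genetic
map (constant rate per 1 Mb block, map points every 5 kb), 50 genes with
expression/PPI/VIP annotations, scored interval tracks, assembly gaps
mirrored as N-runs in the sequence, and ~12,000 binned SNP scores. Gene
centers sit on the 5 kb map grid so every window edge of the five standard
sizes coincides with a map point. A companion feature table is computed *by
construction* with independent brute-force code (per-base coverage masks,
dictionary cM lookups, exhaustive loops); the pipeline must reproduce it
bit-exactly, which the suite asserts both in memory and through the on-disk
formats (floats are written at full precision and parsed with round-trip
semantics).

What the toy genome does **not** emulate: linkage disequilibrium and
haplotype structure (SNP scores are drawn, not computed from haplotypes),
realistic gene clustering, correlated annotation tracks, and overlapping-
window dependence. Passing tests therefore demonstrate correctness of the
bookkeeping and estimation machinery, not power on real genomes.

## Numerical choices

* Likelihood and responsibilities in log space; mixing probabilities
  clipped to the open unit interval at the nearest representable doubles.
* LR statistics clipped at 0 before the χ² tail (they are nonnegative up to
  optimizer noise).
* Uniform-map interpolation reproduces the constant rate to ~1e−14
  relative (last-ulp decimal-cM effects); the suite asserts 1e−12.
* Score thresholding assumes non-overlapping intervals, as in clustered
  annotation tracks.
* Degenerate inputs raise early with named errors: zero-variance covariates
  and responses, empty datasets, all-degenerate frequency bins, invalid
  maps (non-monotone), frequency outside [0, 1].
* Every stochastic step takes an explicit seed; identical seeds give
  bit-identical datasets and fits.

## Problem sizes used in the checks

Parameter recovery runs 25 replicates at n = 20,000 windows with k = 17
covariates (slope RMSE ≤ 0.1, all |b| ≥ 0.15 signs recovered); LRT
calibration runs 1,000 replicates at n = 2,000. The acceptance script uses
10 and 400 replicates respectively, plus an 8-replicate average for the
component magnitude. These sizes give Monte-Carlo error comfortably below
the asserted bounds while keeping a full run in well under a minute.

## Known limitations

* The mixing-weight *level* (hence the component magnitude of a single
  dataset) is weakly identified when the components overlap; its MLE has a
  spread of ~0.09 under the canonical study conditions at n = 20,000. It is
  unbiased — the suite checks the replicate average — and slope inference
  is unaffected, but single-dataset magnitudes should be compared across
  populations or conditions, not read as precise fractions.
* χ²₁ p-values ignore dependence between overlapping windows.
* The gate is linear on the logit scale; non-monotone covariate effects
  (e.g. coding density helping and hindering selection in different
  recombination regimes) are not captured.
* Two components only; no EM, no penalized or Bayesian variants.
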
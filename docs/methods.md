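# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic benchmarks can show. It is the package's own account of
its science; every number cited here is computed by the test suite or by
`scripts/acceptance.py`, not asserted.

## LFQ reduction chain

The processing order is fixed: **filter → normalize → impute → log2**.

**Detection filter.** A protein is retained iff (i) it is identified by at
least one protein-unique peptide (`min_unique_peptides`, default 1) and
(ii) it is observed — non-missing and strictly positive — in at least 60%
(`min_frac`) of the samples of at least one study group. Coverage in a
single group suffices: a protein absent from one lesion type but
reproducibly present in the other is biologically the most interesting
case and must not be discarded. The filter is idempotent.

**Loading normalization.** Each sample column is scaled so its summed
observed intensity equals the cohort **median** of the per-sample sums.
The median reference is a design choice (any common reference yields the
same inference); it is robust to a single aberrant sample and leaves an
already-balanced matrix untouched. Sums are computed over observed cells
only, *before* imputation, so imputed values can never influence the
loading factors.

Summed-intensity normalization is compositional: if a subset of proteins
genuinely changes in one group, that group's total shifts and every other
protein absorbs a small opposite shift. This matters for exactness claims
(see "Noise-free validation" below) and is inherent to the method, not to
this implementation.

**Imputation.** Missing cells are filled with `factor ×` the minimum
observed intensity *of the same sample* (default factor 1.5), after
normalization, using normalized minima. Note the anomaly: a factor above 1
imputes *above* the observed floor, unlike conventional down-shifted
imputation which places censored values below it. The rule is implemented
exactly as stated with the factor configurable; users who prefer
below-floor imputation can pass `factor < 1` (e.g. 1/1.5 ≈ 0.667).
The imputation mask is carried so downstream consumers can distinguish
measured from filled cells.

**NSAF.** Spectral counts are converted to normalized spectral abundance
factors: NSAFᵢ = (cᵢ/Lᵢ) / Σⱼ(cⱼ/Lⱼ) per sample. Columns sum to one, and
NSAF is invariant to per-sample count depth.

## Differential expression

Per protein, an unpaired two-tailed Student *t*-test with pooled variance
(df = n₁+n₂−2) compares the two groups on the log2 scale; Welch's variant
is available via `equal_var=False`. The log2 fold change is the difference
of group means (mean_b − mean_a), matching the axes of a volcano plot.
Degenerate inputs follow a fixed contract rather than propagating NaN:
zero pooled variance with equal means gives t = 0, p = 1; zero pooled
variance with unequal means gives p = 0 with a degeneracy flag — required
so that exactly-recovered noise-free spike-ins are called significant.

**Two-stage adaptive FDR.** Stage one runs the Benjamini–Hochberg step-up
at q′ = q/(1+q); with r₁ rejections, m̂₀ = m − r₁ estimates the true nulls
(r₁ = 0 → reject nothing; r₁ = m → reject everything). Stage two runs BH
at q′·m/m̂₀. The procedure has no closed-form adjusted p-value, so the
per-hypothesis q-value is defined by **threshold inversion**: the smallest
nominal level at which that hypothesis is rejected. The rejection count is
monotone non-decreasing in the nominal level, so the inversion is found by
bisection (tolerance 1e−6 by default; the sorted q-values are
non-decreasing, which lets each search reuse the previous upper bracket).

A caution on a folklore claim: the two-stage rejection set does **not**
always contain the plain BH set at the same level. Stage two's level
q′·m/m̂₀ exceeds q only when m/m̂₀ ≥ 1+q, i.e. when stage one rejects at
least m·q/(1+q) hypotheses; in sparse-signal regimes the adaptive
procedure can reject slightly fewer than BH. What always holds, and what
the tests assert, is containment of BH at the deflated level q/(1+q), plus
the same-level containment whenever the adaptive boost reaches 1+q. The
implementation agrees exactly with statsmodels' independent `fdr_tsbky`
rejection masks on randomized inputs.

**DEP call.** q < `q_threshold` (default 0.01) and |log2FC| >
`log2fc_threshold` (default 1). The published-figure variant (p < 0.01,
|log2FC| > 2) is reachable purely by configuration. The patient-paired
lesion comparison uses the same unpaired test by design. Ranked lists for
enrichment tools use sign(log2FC)·(−log10 p) with p floored at 1e−300 —
a stated convention, since no canonical formula exists for the "signed"
ranking metric.

## PRM quantitation

**Model.** The response ratio is oriented analyte/internal-standard
(light/heavy, NAT/SIS): with the SIS amount constant, this ratio is linear
in the spiked light amount, which is what a linear calibration model
requires. (The inverse orientation would be hyperbolic in the analyte
amount.) The assay design is 50 fmol SIS spiked into 1 µg digested
protein, so back-calculated fmol divided by the input mass gives fmol/µg.

**Weighted fit.** Per-level mean ratios are regressed on nominal fmol with
weights 1/x², implemented as ordinary least squares on the √w-scaled
design. With proportional (constant-CV) noise the response SD grows
linearly with the level, and 1/x² weighting is the variance-stabilizing
choice; it is algebraically identical to OLS on the transformed model
y/x = b·(1/x) + a, which the tests verify to 1e−8.

**Level acceptance.** Precision = 100·SD/mean of a level's replicate
ratios (sample SD, n−1); accuracy = 100·(mean back-calculated fmol)/nominal,
where back-calculation uses the current fit, x̂ = (y−a)/b. "Average"
criteria are interpreted as means over a level's replicates. Because
accuracy depends on the fit, acceptance iterates: fit on the included
levels, re-evaluate all levels, include exactly those passing, repeat
until stable (cap 10 iterations; levels may re-enter, hence the cap). A
curve is valid only if the final set contains a run of ≥3 consecutive
ladder levels; among multiple qualifying runs the one containing the
highest level is kept, preserving the widest usable dynamic range toward
the top of the ladder. r² is computed on the accepted level means under
the final fit. Acceptance is deterministic and independent of input
ordering.

One behavior worth knowing: with 1/x² weights the lowest level carries by
far the largest weight, so a *mildly* biased bottom level tends to be
interpolated by the free intercept and back-calculates near 100% — it is
excluded only when its bias is large enough to survive that absorption.
This is a property of accuracy-by-back-calculation itself, visible in any
compliant implementation.

**LOD / LOQ.** Each blank replicate ratio is back-calculated through the
fitted curve; LOD = mean + 3.3×SD (sample SD), floored at zero. LOQ is the
lowest accepted calibration level. LOD < LOQ is expected; the converse is
reported, not hidden, via the censoring codes. Concentrations are censored
as not_detected (no ratio), below_LOD, below_LOQ, or quantified; negative
back-calculations report 0 with below_LOD.

**PRM differential profile.** Peptides not detected in more than 60% of
samples are excluded (strictly "more than": exactly 60% is retained).
Below-LOD and not-detected cells are treated as missing and imputed with
the LFQ per-sample-minimum rule; the comparison then runs on log2
fmol/µg through the same t-test/adaptive-FDR machinery.

## Synthetic data: what it emulates, what it does not

The LFQ generator draws latent log2 intensities as
baseline + protein effect + group effect + loading offset + within-group
noise, and observes 2^latent with **logistic intensity-dependent dropout**:
P(missing) = expit(k·(midpoint − latent)). Low-abundance censoring is the
mechanism that motivates minimum-based imputation, and the analysis chain
assumes it; no missingness mechanism is published for these data, so the
logistic MNAR form is a stand-in, as are all distributional defaults
below.

Defaults (chosen once as realistic for FFPE label-free proteomics on an
Orbitrap): baseline 20 log2 units (~10⁶ intensity); between-protein SD 4
log2 (≈5 orders of magnitude dynamic range); within-group SD 0.5 log2;
per-sample loading SD 0.25 log2; dropout midpoint 16, steepness 0.8 —
giving ~15–20% missing cells overall; cohort 29 + 18 samples mirroring the
pure-lesion arms; group effects applied to the second (IDC-like) group,
positive log2FC = higher there. `true_log2fc` accepts a scalar or one
value per spiked protein.

The PRM generator draws a slope per peptide (default U(0.01, 0.04),
bracketing the 1/50-per-fmol expected of equal light/heavy response at
50 fmol SIS), places the true ratio slope·x + intercept on a geometric
seven-point ladder 0.41–250 fmol (the published endpoints; intermediate
levels configurable), and perturbs replicates multiplicatively with
N(0, cv) noise — exactly the heteroscedasticity that justifies the 1/x²
weights. Triplicate levels are the default (the minimum count that yields
a meaningful CV is 2; 3 is routine practice). Blanks are small
concentrations N(0.10, 0.05) fmol mapped through the true curve, placing
the LOD (~0.27 fmol) below the lowest calibrant, as a usable assay
requires.

Not emulated: peptide-to-protein roll-up, shared peptides, FFPE fixation
chemistry, batch effects beyond scalar loading, retention-time or spectral
structure, and interference in transitions. Passing tests therefore
validate the *statistical pipeline* — filtering, normalization,
imputation, testing, calibration, censoring — not upstream identification
or peak integration.

## Validation designs and their rationale

- **Null calibration / spike-in recovery** (2,000 proteins, 15 vs 15,
  within-group SD 0.5, 20 and 10 cohorts): run with dropout disabled and
  zero loading variation, and the differential stage applied to the log2
  matrix directly. These runs calibrate the testing stage; normalizing a
  cohort that has no loading variation only injects factor-estimation
  noise that is shared across proteins (the sums are dominated by the few
  most abundant ones), correlating all p-values and blurring the
  calibration being measured without biasing it. Measured: mean fraction
  of raw p < 0.05 ≈ 0.05, adaptive-FDR rejections at 1% near zero;
  spike-in (100 proteins at |log2FC| = 2) sensitivity ~1.0, FDP ~0.
- **Noise-free end-to-end** runs the *full* chain including normalization.
  Because summed-intensity normalization is compositional, exact recovery
  requires mass-balanced spikes; the design uses one +2 spike per four −2
  spikes (3·k = 0.75·4k), making per-sample totals identical across groups
  so the factors cancel exactly. Under that design every spiked log2FC is
  recovered to floating-point precision and the DEP set equals the spiked
  set exactly.
- **Oracles.** The two-stage FDR is checked against an independently coded
  plain-loop brute-force implementation (q-value agreement to 1e−5) and
  against statsmodels rejection masks; the weighted fit against the
  transformed-model OLS identity; the t-test against scipy.
- **Calibration recovery** at 5% ratio CV, triplicates, 100 peptides:
  median relative slope error ≈ 1%, noiseless ladders recovered to machine
  precision, and the worked blank example (back-calculated blanks 0.9,
  1.0, 1.1 fmol → LOD = 1.0 + 3.3·0.1 = 1.33 fmol) reproduced exactly.

Problem sizes throughout (2,000 proteins, tens of cohorts, 100–1,000
Monte-Carlo replicates) are the package's chosen balance between
statistical resolution and a test suite that runs in seconds.

## Known limitations

- The two comparison-threshold variants in circulation (q < 0.01,
  |log2FC| > 1 vs p < 0.01, |log2FC| > 2) are both expressible; defaults
  follow the former.
- The q-value from threshold inversion is procedure-consistent but, like
  all adaptive-FDR "adjusted p-values", is not a per-hypothesis error
  estimate.
- Imputation above the per-sample floor (factor 1.5) compresses fold
  changes of proteins missing predominantly in one group; sensitivity
  losses concentrate at low abundance (visible in the README example:
  49/60 spiked proteins recovered under ~19% dropout).
- Calibration-level acceptance with a free intercept rarely excludes a
  mildly biased lowest level (see above); fixing the intercept at zero is
  not offered because the blank model requires one.
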
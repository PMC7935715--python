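# Methods

`ffanips` is a desk-scale simulation and analysis toolkit for studying how
**fetal fraction amplification (FFA)** — molecular size selection of cfDNA
sequencing libraries — changes the analytical performance of WGS-based
noninvasive prenatal screening (NIPS). This note records the models, the
defaults and their rationale, the numerical choices, and what the synthetic
data do and do not establish.

## The generative model

### Scaled genome

The simulated genome is GRCh38 scaled down 1/1000 per chromosome and tiled
with 50 bp bins (50 kb-equivalent); trailing partial bins are dropped. All
24 chromosomes are present so the relative chromosome sizes — which set the
per-region count totals and hence the z-score variances — are preserved. At
the default depth of 5×10⁵–10⁷ fragments per sample, per-bin and per-region
counting statistics are comparable to a production assay at this bin
resolution. The region table holds every whole chromosome (chr13/18/21 for
the common trisomies, the other autosomes for rare autosomal aneuploidies,
chrX/chrY for the sex analysis) plus five syndromic microdeletions
(22q11.2, 5p15, 1p36, 4p16.3, 15q11.2) at their approximate true locations,
3–6 Mb-equivalent each. The production bin width and genome build of any
particular assay are not modelled; the scaled genome is a declared stand-in.

### Two-compartment cfDNA

Each pregnancy contributes a maternal compartment (2 autosomal copies, 2
chrX, 0 chrY) and a fetal compartment whose per-bin copy numbers follow the
karyotype (trisomy = 3 on the chromosome, microdeletion = 1 on the region,
MX = X1Y0, TX = X3Y0, XXY = X2Y1, XYY = X1Y2, with XX/XY euploid baselines).
The expected count in bin *i* is

    E[c_i] ∝ width_i · [ FF·c_fetal(i)/2 + (1−FF)·c_maternal(i)/2 ],

so a disomic bin's expected fetal share is exactly the fetal fraction FF.
Counts are Poisson per (bin, compartment) by default; a multinomial mode
(exact depth conservation) and a gamma–Poisson (negative-binomial) mode with
configurable dispersion exist because production data are overdispersed, but
the default is the simplest law consistent with the z-score machinery.

Two small realism terms:

* **chrY background** (`chry_background`, default 0.002): a copy-number-
  equivalent floor on chrY in both compartments, standing in for
  mismapped/homologous reads. It gives female-fetus pregnancies a
  small-positive, noisy FF_chrY — without it the female FF_chrY distribution
  would be degenerate and the sex-call model unfittable.
* **FF-correlated autosomal tilt** (`ff_tilt_amplitude`, default 0.3): bin
  weights are multiplied by `1 + FF·t_i` where `t` is a fixed, zero-mean-
  per-chromosome pattern. This plants the fragment-level positional biases
  that make FF learnable from autosomal depth alone, giving the FF
  regression a signal; the zero-sum constraint leaves every whole-chromosome
  and (to first order) region mean untouched, so z-scores and region FF
  estimates are unaffected. The true autosomal FF signature of real cfDNA
  is unknown at this level; the tilt is an admitted surrogate that enables
  parameter-recovery tests only.

### FF | BMI model and calibration

BMI ~ LogNormal(3.26, 0.23) kg/m² (a first-trimester-like distribution with
~3% class-III obesity), and

    log FF = a − b·BMI + ε,  ε ~ N(0, σ²),  FF clipped to [0.005, 0.5].

Defaults a = −1.676, b = 0.024, σ = 0.48 were fixed once by a grid search so
that the generator reproduces two stated rates of the study population this
emulates — ≈3.7% of samples below the 4% low-FF threshold overall and ≈16%
within the BMI ≥ 40 stratum — while keeping the median FF near 10%. These
are threshold-event rates, not distribution parameters; the lognormal-with-
linear-log-mean family is one of many consistent with them.

### Batch structure

Cohorts are split into batches; each batch carries a no-template control
(NTC; contamination-only counts at `ntc_contamination`×depth, default
1e-3), a pooled XX and a pooled XY control (euploid, aggregate FF =
`pooled_ff`, default 0.10 — pooled-control FF is not publicly stated
anywhere, so this is a convention). Replicate samples across batches are
supported for reproducibility experiments. Multiple gestations, maternal
CNVs, confined placental mosaicism and GC waves are out of scope.

## Size selection (FFA)

Fragment lengths are truncated normals: fetal mean 143 nt (SD 18), maternal
mean 167 nt (SD 20) — literature-typical values giving a pre-selection
library mean near 165 nt at low FF. Selection retains a fragment with
probability `r(l)`: a hard cutoff `1{l ≤ L}` by default (the closed-form
oracle case), or a logistic window (`softness` 4 nt) because gel elution is
not a step function. The cutoff L is solved by bisection (monotonicity of
the retained mean in L is asserted first) so the retained library's mean
length is 140 nt within 0.1 nt — the elution stopping rule of the protocol
this emulates. Per-compartment retention probabilities give the closed-form
law

    ff_post = ff·r_f / (ff·r_f + (1−ff)·r_m),  gain = ff_post / ff,

which tends to r_f/r_m as ff → 0 and decreases strictly in ff: the
lowest-FF samples gain the most. At the defaults the gain is ≈3.0× in the
low-FF limit and ≈2.4× at FF = 10%.

**Two noise regimes.** `apply_size_selection` thins realized counts
binomially and (optionally) re-amplifies to the original depth by
multinomial resampling — the correct model when counts *are* molecules
(it is validated against the closed-form gain law). But a real cfDNA
library holds orders of magnitude more unique molecules than the sequencer
samples, so molecular selection shifts the *composition* without adding
counting noise, and the two protocol arms of a validation are replicate
aliquots sequenced independently. The cohort pipeline therefore generates
the FFA arm as a fresh sequencing draw whose expected composition carries
the solved per-compartment retention (`simulate_bin_counts(retention=...)`).
Using the finite-pool operator there instead would inflate the post-arm
noise ≈2.2× and contradict the validated mechanism (euploid z-scores
unchanged, every positive's z increased). A bioinformatic alternative —
length-weighting fragments downstream of sequencing — is provided
(`bioinformatic_weighting`); an indicator weight reproduces hard molecular
selection without re-amplification.

## Fetal fraction estimation

Depth is normalized per sample: each bin's per-bp rate is divided by the
**median of the 22 autosomal per-chromosome rates**. A per-chromosome
(rather than per-bin) median keeps robustness against a whole-chromosome
aneuploidy in the sample itself while avoiding the discreteness bias of a
median over small integer bin counts (~8 fragments/bin at default depth),
which would offset the denominator by several percent.

* **FF_chrY** = 2 × (chrY mean ratio) − background, where the background is
  the mean uncorrected FF_chrY over known-female euploids. chrY counts are
  aggregated chromosome-wide before forming the ratio (single chrY bins
  hold fractional counts at desk scale). The subtraction removes the
  constant offset the mismapping background adds to every sample; female
  pregnancies read ≈0.
* **FF_positive** = 2 × the directional depth deviation of an aneuploid
  region (gain: 2(ratio−1); loss: 2(1−ratio)). The signed form is used
  rather than an absolute value because |·| is upward-biased when noise is
  comparable to signal (exactly the regime of a 3 Mb microdeletion at low
  FF); a negative value is flagged as a direction mismatch, and the
  reported value is clipped to [0, 1] with the raw value retained.
* **Autosomal regression** (SeqFF-style stand-in): ridge regression of
  FF_chrY labels (male-fetus euploids) on autosomal bin ratios, computed in
  kernel (n×n) form. With far more bins than samples, ridge predictions are
  attenuated toward zero, so the fit is followed by an exact closed-form
  leave-one-out calibration: LOO predictions are regressed on the labels
  and the slope/intercept folded into the coefficients. Two error scales
  are stored — `loo_sd` (honest error on new samples) and `residual_sd`
  (training residuals of the final model, larger, because de-attenuation
  rescales a near-interpolating fit; its training predictions overshoot).
  The penalty defaults to 6× the mean squared row norm (the noise-Gram
  magnitude); `calibrate=False` recovers plain ridge (coefficients → 0 and
  prediction → training mean as λ → ∞). Because male euploids are the
  training set, their own regression predictions are overdispersed;
  pipelines use FF_chrY for male fetuses and the regression for female
  fetuses.

A learnability caveat: the tilt direction must be estimated against a noise
Gram matrix of comparable magnitude, and the spiked-model signal-to-noise
ratio `(A²/3)·Σff²/σ²_bin` is independent of the number of bins. At tilt
0.3 it crosses usefulness around depth ~2×10⁶ with ~100 training samples —
the sizes the regression experiments use. At the generator default depth of
5×10⁵ the regression is honestly uninformative.

## Screening

Per region, `z = (region mean ratio − μ_ref)/σ_ref` with reference moments
estimated over ≥10 euploid samples (degenerate σ_ref raises). Losses are
sign-flipped so more positive = more evidence; a sample calls positive at
`z ≥ threshold` (ties positive), threshold 4.0 for every class by default
(configurable per class: common aneuploidy, RAA, microdeletion). The
reference scope defaults to the whole cohort's euploids; a per-batch option
exists for batch-effect experiments. Euploid z's are standard normal by
construction, which the null-calibration tests verify (KS at n = 1000, and
the false-positive rate at z = 3 against 1−Φ(3)). Note that σ_ref is
estimated: its relative error (≈(2·n_ref)^(−1/2)) propagates directly into
the spread of reported z's, which is why calibration experiments use
reference sets of several hundred samples.

Sex and sex-chromosome-aneuploidy calls use no z-scores: each sample is
placed in the (d_X, f_Y) plane, d_X = 2(1 − chrX mean ratio), f_Y = FF_chrY,
and matched to hypothesis locations in units of its FF (XX at (0,0), XY at
(FF,FF), MX (FF,0), TX (−FF,0), XXY (0,FF), XYY (FF,2FF)); the nearest
hypothesis within tolerance τ = max(0.35·FF, 0.01) wins, none → no-call.
Two guards keep the rule honest: τ is floored at 3× the per-coordinate
measurement noise (estimated from female euploids), and every non-XX
hypothesis requires FF ≥ max(4%, 3×noise) — without the latter, the
implied-FF fallback would self-fit any noisy chrX deviation as a low-FF
monosomy X (or a noisy female as a borderline male). The flip side is
realistic: a genuinely low-FF male falls to the female/no-call side — the
borderline sex-miscall mode that FFA removes.

## Two-phase ROC performance model

Observed positives are few and FF-biased, so performance is estimated by a
train-then-simulate model. **Training:** z-scores of positives follow

    z ~ Normal(β · FF · sqrt(N/N₀), σ_z),

the minimal form consistent with a Poisson z-statistic (signal ∝ FF, noise
∝ 1/√N); priors β ~ HalfNormal(200), σ_z = 1 + HalfNormal(2) (positives
cannot be less noisy than the null). The sampler is a self-contained
adaptive Metropolis–Hastings: 4 lock-stepped chains, Gaussian proposals
with step size adapted during burn-in toward 20–40% acceptance (default
2000 burn-in + 8000 kept), split-chain potential-scale-reduction < 1.05
required (a design with no FF/depth variation is accepted but flagged
weakly identified). **Simulation:** each mock positive draws (β, σ_z) from
the posterior and FF/N from population distributions; mock negatives are
exact standard normal (justified by the null calibration; an empirical
option resamples observed euploid z's). Sweeping thresholds yields the ROC;
uncertainty bands are 2.5/97.5 percentiles over per-draw mock cohorts, and
they are reported as percentile intervals (not ±SD). Draw order is fixed so
equal seeds share (β, σ_z, noise) draws, enabling paired pre/post-FFA
comparisons with common random numbers. Aggregation over a region class
uses equal weights by default, incidence weights optionally. SCAs use
coupled chrX/chrY information and are outside this one-dimensional model;
they get only the standard confusion-matrix metrics (sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP), computed in exact rational
arithmetic, undefined metrics reported as absent).

## Sex-call accuracy model

Over euploid samples only: a plain normal is fit to female FF_chrY (no
truncation — tail mass below 0 is part of the model error) and a beta, by
maximum likelihood with method-of-moments initialization, to male FF_chrY
clipped into (0,1) by machine epsilon. With equal sex priors (0.5/0.5,
overridable) the expected miscall rate at threshold y is

    rate(y) = 0.5·(1 − Φ((y−μ_F)/σ_F)) + 0.5·I_y(a, b),

minimized over y by a 10⁴-point grid scan plus bounded refinement (ties
toward smaller y; verified against a 10⁶-point brute force). Protocols are
compared by the fold reduction of minimized rates, with a parametric
bootstrap CI; a rate underflowing 1e-15 is reported as a bound, not
infinity. The fold reduction is a deep-tail quantity and varies strongly
across simulated cohorts (hundreds to thousands at the defaults); only its
direction and rough magnitude are meaningful.

## Problem sizes and reproducibility

The test suite runs cohorts of 10²–4×10³ samples at depths 10⁵–10⁷ on the
1/1000-scale genome — sizes chosen so each experiment's Monte Carlo error
is several times smaller than the band it must hit. `scripts/acceptance.py`
simulates a 400-sample, 4-batch validation-style cohort (positives
enriched as validation sets are) at 2×10⁶ fragments/sample, runs both
protocol arms end to end, and reports the headline metrics. Every stage is
deterministic given (config, seed): one master seed feeds a single
generator chain per run, and the CLI pipeline re-run with the same config
and seed is bit-identical.

## What passing tests do and do not show

The synthetic cohorts reproduce the *statistical structure* the method
assumes: Poisson-level counting noise, the FF|BMI dependence calibrated to
two stated rates, compartment copy-number signals, and a size-selection
operator with a known gain law. They do not contain GC waves, mapping
artifacts, overdispersion (unless enabled), maternal CNVs, or mosaicism.
Passing tests therefore establish internal correctness — estimators
recover planted truth, the calling machinery is calibrated, the ROC and
sex-call models agree with independent oracles, and FFA's benefit follows
mechanically from differential fragment-length retention — not clinical
performance on real specimens. Cohort-level numbers printed by the
acceptance script (gain folds, sensitivities, miscall reductions) depend on
this package's declared defaults and desk-scale depths.
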
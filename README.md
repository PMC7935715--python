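# ffanips

Simulation and analysis toolkit for **fetal fraction amplification (FFA)**
in WGS-based noninvasive prenatal screening (NIPS).

In cfDNA-based prenatal screening, the fetal fraction (FF) — the share of
plasma cfDNA fragments of placental origin — drives sensitivity for fetal
chromosomal abnormalities, and samples below 4% FF have historically
triggered test failures, disproportionately in patients with high BMI.
Because fetal fragments are shorter than maternal ones (~143 vs ~167 nt),
size-selecting a sequencing library to a shorter mean length preferentially
retains fetal DNA and multiplies FF. This package implements, end to end
and at desk scale, the computational machinery needed to study that
intervention:

* a synthetic cohort generator — two-compartment (maternal/fetal) binned
  fragment counts over a 1/1000-scale genome, FF negatively correlated
  with BMI (calibrated so ~3.7% of samples fall below 4% FF, ~16% in the
  BMI ≥ 40 stratum), karyotypes spanning T13/T18/T21, rare autosomal
  aneuploidies, syndromic microdeletions and sex chromosome aneuploidies,
  with batch structure and NTC/pooled controls;
* an in-silico size-selection model: fragment-length mixtures, a cutoff
  solved so the retained library's mean length is 140 nt, and the closed
  form `ff_post = ff·r_f / (ff·r_f + (1−ff)·r_m)` for the resulting FF gain;
* FF estimators: `FF_chrY = 2 × chrY depth ratio` (background-corrected),
  `FF_positive = 2 × |aneuploid-region depth deviation|` (signed form), and
  a LOO-calibrated ridge regression on autosomal bin depth;
* reference-based screening: `z = (region ratio − μ_ref)/σ_ref` against a
  euploid reference, thresholded per region class, plus a two-dimensional
  chrX/chrY analysis for fetal sex and SCA calls;
* a two-phase ROC performance model: an adaptive Metropolis–Hastings fit of
  `z ~ Normal(β·FF·√(N/N₀), σ_z)` on observed positives, then mock-cohort
  simulation and threshold sweeps yielding sensitivity/specificity with
  posterior uncertainty bands;
* a sex-call accuracy model: normal (female) / beta (male) fits to FF_chrY,
  threshold optimization, and the expected-miscall fold reduction between
  protocols.

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

Simulate a 110-sample cohort, create its size-selected arm, estimate FF and
screen both arms:

```bash
cat > config.yaml <<EOF
genome_scale: 10000
cohort_size: 110
depth: 100000
EOF

ffanips simulate   --config config.yaml --seed 7 --outdir run/standard
ffanips ffa        --config config.yaml --seed 7 --indir run/standard --outdir run/ffa
ffanips estimate-ff --config config.yaml --seed 7 --indir run/standard --out run/standard/ff.csv
ffanips estimate-ff --config config.yaml --seed 7 --indir run/ffa      --out run/ffa/ff.csv
ffanips screen     --config config.yaml --seed 7 --indir run/standard \
                   --out-results run/standard/results.csv --out-sexcalls run/standard/sexcalls.csv
ffanips sexcall    --config config.yaml --seed 7 --ff-standard run/standard/ff.csv \
                   --ff-ffa run/ffa/ff.csv --manifest run/standard/manifest.csv --out run/sexcall.json
```

Each stage logs to stderr, e.g.:

```
[ffanips:simulate] seed=7 samples=113 bins=6164
[ffanips:ffa] seed=7 samples=113
[ffanips:screen] seed=7 results=3024 sexcalls=112
[ffanips:sexcall] seed=7 arms=2
```

`results.csv` holds one row per sample-region
(`sample_id,region,depth_ratio,z_score,ff_positive,call`): a euploid sample
sits near `depth_ratio ≈ 1, z ≈ 0`, while a trisomy-21 pregnancy at FF 0.12
shows `depth_ratio ≈ 1.06` on chr21 and a z-score far above the calling
threshold of 4. `sexcall.json` reports the fitted female normal and male
beta, the optimized calling threshold per protocol arm, and the fold
reduction in expected sex miscalls conferred by size selection.

The library surface mirrors the CLI: `ffanips.cohort` (generation),
`ffanips.sizesel` (selection and gain law), `ffanips.ff` (estimators),
`ffanips.screen` (z-scores, sex/SCA calls), `ffanips.performance` (ROC
model), `ffanips.sexcall` (miscall model).

## File formats

All plain text: sample manifest CSV (header
`sample_id,batch_id,bmi,karyotype,fetal_sex,protocol,true_ff,control_type`);
wide counts TSV (BED3 coordinates, 0-based half-open, one integer column
per sample, with `counts.fetal.tsv`/`counts.maternal.tsv` sidecars carrying
the simulation-internal compartment split); regions BED4; results CSV as
above; YAML config (flat keys, see `ffanips/config.py` for every parameter
and its default).

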
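"""Run configuration: one flat dataclass, loadable from YAML.

Keys are grouped by pipeline stage (genome, cohort generator, size selection,
screening, ROC model, sex-call model).  Every parameter has a documented
default; a YAML config overrides any subset of keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration value violates its documented constraint."""


@dataclass
class RunConfig:
    # --- genome ---
    genome_scale: int = 1000          # divisor on GRCh38 chromosome lengths
    bin_width: int = 50               # scaled bp (= 50 kb-equivalent)

    # --- cohort generator ---
    cohort_size: int = 200            # patient samples per simulated cohort
    n_batches: int = 1
    depth: int = 500_000              # fragments per sample (N)
    bmi_meanlog: float = 3.26         # BMI ~ LogNormal(meanlog, sdlog), kg/m^2
    bmi_sdlog: float = 0.23
    ff_intercept: float = -1.676      # log FF = a - b*BMI + eps
    ff_bmi_slope: float = 0.024       # b >= 0 (FF falls with BMI)
    ff_noise_sd: float = 0.48         # SD of eps
    ff_min: float = 0.005             # clipping bounds for true FF
    ff_max: float = 0.5
    # karyotype frequencies for the non-euploid part of the cohort; the
    # remainder is euploid.  RAA chromosomes and microdeletion regions are
    # drawn uniformly from the eligible sets.
    karyotype_freqs: dict = field(default_factory=lambda: {
        "T21": 0.02, "T18": 0.01, "T13": 0.005,
        "RAA": 0.01, "microdeletion": 0.01,
        "MX": 0.005, "TX": 0.003, "XXY": 0.003, "XYY": 0.003,
    })
    p_male: float = 0.5
    noise_model: str = "poisson"      # poisson | multinomial | negbin
    negbin_dispersion: float = 0.0    # extra-Poisson dispersion (negbin only)
    chry_background: float = 0.002    # chrY mismapping background, copy-number
                                      # equivalent added to both compartments
    ff_tilt_amplitude: float = 0.3    # FF-correlated autosomal depth tilt
    ntc_contamination: float = 0.001  # NTC depth as a fraction of `depth`
    pooled_ff: float = 0.10           # aggregate FF of the pooled XY control

    # --- size selection (FFA) ---
    fetal_length_mean: float = 143.0  # nt
    fetal_length_sd: float = 18.0
    maternal_length_mean: float = 167.0
    maternal_length_sd: float = 20.0
    target_mean_length: float = 140.0  # post-selection mean (nt)
    selection_mode: str = "hard"      # hard | logistic
    selection_softness: float = 4.0   # logistic scale (nt), logistic mode only
    reamplify: bool = True            # re-normalize depth to original N

    # --- fetal fraction ---
    ridge_lambda: float | None = None  # FF-regression ridge penalty; None =
                                       # auto-scale to the training data

    # --- screening ---
    z_threshold_common: float = 4.0
    z_threshold_raa: float = 4.0
    z_threshold_microdeletion: float = 4.0
    sca_tolerance_frac: float = 0.35  # tau = max(frac*FF, floor, 3*noise)
    sca_tolerance_floor: float = 0.01
    sca_min_ff: float = 0.04          # minimum FF for a callable SCA
    min_reference: int = 10

    # --- ROC performance model ---
    mcmc_chains: int = 4
    mcmc_burn: int = 2000
    mcmc_keep: int = 8000
    beta_prior_scale: float = 200.0   # HalfNormal scale on beta
    sigma_prior_scale: float = 2.0    # HalfNormal scale on (sigma_z - 1)
    reference_depth: float = 500_000.0  # N0 in z ~ beta*FF*sqrt(N/N0)
    n_mock_pos: int = 100_000
    n_mock_neg: int = 100_000
    roc_interval_draws: int = 200

    # --- sex-call model ---
    sex_prior_male: float = 0.5

    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ConfigError("seed must be a nonnegative integer")
        if self.ff_bmi_slope < 0:
            raise ConfigError("ff_bmi_slope must be >= 0: FF decreases with BMI")
        for key in ("p_male", "ntc_contamination", "pooled_ff", "ff_min", "ff_max"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}={v} outside [0, 1]")
        total = sum(self.karyotype_freqs.values())
        if any(p < 0 for p in self.karyotype_freqs.values()) or total > 1.0:
            raise ConfigError("karyotype_freqs must be nonnegative and sum to <= 1")
        for key in ("z_threshold_common", "z_threshold_raa", "z_threshold_microdeletion"):
            v = getattr(self, key)
            if not (v == v and abs(v) != float("inf")):
                raise ConfigError(f"{key} must be finite")
        if self.noise_model not in ("poisson", "multinomial", "negbin"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.selection_mode not in ("hard", "logistic"):
            raise ConfigError(f"unknown selection_mode {self.selection_mode!r}")
        if self.ridge_lambda is not None and self.ridge_lambda <= 0:
            raise ConfigError("ridge_lambda must be positive (or null for auto)")
        if self.depth < 10_000:
            raise ConfigError("depth must be >= 1e4 fragments")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected to catch typos."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
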
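"""Synthetic cfDNA cohort generator.

Emulates the statistical structure a WGS-based NIPS validation assumes:

* two-compartment (maternal + fetal) cfDNA, the fetal share being the
  fetal fraction FF;
* FF negatively correlated with BMI: ``log FF = a - b*BMI + eps``, with
  defaults calibrated so ~3.7% of samples fall below the 4% low-FF
  threshold overall and ~16% do within the class-III obesity stratum;
* karyotypes spanning the common trisomies (T13/T18/T21), rare autosomal
  aneuploidies (RAA), syndromic microdeletions, and the sex chromosome
  aneuploidies (MX, TX, XXY, XYY);
* batch structure with no-template controls (NTC) and pooled XX/XY controls.

Counts are drawn per (bin, compartment) from a Poisson law by default
(multinomial and negative-binomial options available); expected counts follow
``w_i ∝ bin_width * [FF*c_fetal/2 + (1-FF)*c_maternal/2]`` so a disomic bin's
expected fetal share is exactly FF.

A small, fixed, FF-proportional "tilt" of autosomal bin weights (zero-mean
within each chromosome) stands in for the fragment-level positional biases
that make FF learnable from autosomal depth alone; it gives the ridge FF
regression a signal to recover without perturbing region-level ratios.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .genome import AUTOSOMES, DEFAULT_MICRODELETIONS, GenomeModel
from .io import MANIFEST_COLUMNS, BinCounts

RAA_ELIGIBLE = tuple(c for c in AUTOSOMES if c not in ("chr13", "chr18", "chr21"))
SIMPLE_KARYOTYPES = {"euploid", "T13", "T18", "T21", "MX", "TX", "XXY", "XYY"}
_PARAM_RE = re.compile(r"^(RAA|microdeletion)\((.+)\)$")

# seed for the shared autosomal tilt pattern; fixed so every sample in every
# cohort sees the same pattern (it is a property of the "genome", not of a draw)
_TILT_SEED = 20201115


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class SampleProfile:
    """Latent truth for one simulated pregnancy (or control)."""

    sample_id: str
    batch_id: str
    bmi: float
    true_ff: float
    karyotype: str          # e.g. "euploid", "T21", "RAA(chr7)", "microdeletion(22q11.2)"
    fetal_sex: str          # "XX" | "XY"
    protocol: str = "standard"
    control_type: str = "none"


@dataclass(frozen=True)
class CopyNumberMap:
    """Per-bin integer copy numbers for the two compartments.

    Maternal copies are fixed (2 autosomal, 2 chrX, 0 chrY); fetal copies
    follow the karyotype.
    """

    fetal: np.ndarray
    maternal: np.ndarray


def parse_karyotype(label: str) -> tuple[str, str | None]:
    """Split ``'RAA(chr7)'`` into ``('RAA', 'chr7')``; plain labels pass through."""
    if label in SIMPLE_KARYOTYPES:
        return label, None
    m = _PARAM_RE.match(label)
    if m:
        return m.group(1), m.group(2)
    raise CohortError(f"unknown karyotype label {label!r}")


def draw_sample_profile(
    params: RunConfig,
    rng: np.random.Generator,
    sample_id: str = "S0",
    batch_id: str = "B0",
    microdeletion_names: tuple[str, ...] | None = None,
) -> SampleProfile:
    """Draw one pregnancy: BMI, FF | BMI, karyotype, fetal sex."""
    if params.ff_bmi_slope < 0:
        raise CohortError("ff_bmi_slope < 0 would make FF rise with BMI")
    bmi = float(rng.lognormal(params.bmi_meanlog, params.bmi_sdlog))
    log_ff = (
        params.ff_intercept
        - params.ff_bmi_slope * bmi
        + params.ff_noise_sd * rng.standard_normal()
    )
    ff = float(np.clip(np.exp(log_ff), params.ff_min, params.ff_max))

    labels = list(params.karyotype_freqs)
    probs = np.array([params.karyotype_freqs[k] for k in labels])
    labels.append("euploid")
    probs = np.append(probs, 1.0 - probs.sum())
    karyotype = str(rng.choice(labels, p=probs))
    if karyotype == "RAA":
        karyotype = f"RAA({rng.choice(RAA_ELIGIBLE)})"
    elif karyotype == "microdeletion":
        names = microdeletion_names or tuple(DEFAULT_MICRODELETIONS)
        karyotype = f"microdeletion({rng.choice(names)})"

    kind, _ = parse_karyotype(karyotype)
    if kind in ("MX", "TX"):
        fetal_sex = "XX"
    elif kind in ("XXY", "XYY"):
        fetal_sex = "XY"
    else:
        fetal_sex = "XY" if rng.random() < params.p_male else "XX"
    return SampleProfile(sample_id, batch_id, bmi, ff, karyotype, fetal_sex)


def karyotype_to_copy_map(profile: SampleProfile, genome: GenomeModel) -> CopyNumberMap:
    """Translate a karyotype label into per-bin fetal/maternal copy numbers."""
    n = genome.n_bins
    maternal = np.full(n, 2, dtype=np.int64)
    maternal[genome.chrom_mask("chrY")] = 0

    fetal = np.full(n, 2, dtype=np.int64)
    x_mask = genome.chrom_mask("chrX")
    y_mask = genome.chrom_mask("chrY")
    if profile.fetal_sex == "XY":
        fetal[x_mask], fetal[y_mask] = 1, 1
    else:
        fetal[x_mask], fetal[y_mask] = 2, 0

    kind, arg = parse_karyotype(profile.karyotype)
    if kind == "euploid":
        pass
    elif kind in ("T13", "T18", "T21"):
        fetal[genome.chrom_mask(f"chr{kind[1:]}")] = 3
    elif kind == "RAA":
        if arg not in genome.chrom_names or arg in ("chr13", "chr18", "chr21", "chrX", "chrY"):
            raise CohortError(f"RAA chromosome {arg!r} not eligible")
        fetal[genome.chrom_mask(arg)] = 3
    elif kind == "microdeletion":
        if arg not in genome.region_bins:
            raise CohortError(f"microdeletion region {arg!r} not in genome")
        fetal[genome.region_bins[arg]] = 1
    elif kind == "MX":
        fetal[x_mask], fetal[y_mask] = 1, 0
    elif kind == "TX":
        fetal[x_mask], fetal[y_mask] = 3, 0
    elif kind == "XXY":
        fetal[x_mask], fetal[y_mask] = 2, 1
    elif kind == "XYY":
        fetal[x_mask], fetal[y_mask] = 1, 2
    return CopyNumberMap(fetal=fetal, maternal=maternal)


def tilt_pattern(genome: GenomeModel, amplitude: float) -> np.ndarray:
    """Fixed autosomal depth-tilt pattern, zero-mean within each chromosome.

    Multiplying bin weights by ``1 + FF * tilt`` plants an FF-proportional
    depth signature while leaving every whole-chromosome mean weight exactly
    unchanged (so z-scores and region FF estimates are untouched).
    """
    t = np.zeros(genome.n_bins)
    if amplitude == 0:
        return t
    rng = np.random.default_rng(_TILT_SEED)
    for name in genome.chrom_names:
        mask = genome.chrom_mask(name)
        draw = rng.uniform(-amplitude, amplitude, mask.sum())
        if name not in ("chrX", "chrY"):
            t[mask] = draw - draw.mean()
    return t


def _expected_weights(
    profile: SampleProfile,
    copy_map: CopyNumberMap,
    genome: GenomeModel,
    config: RunConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized expected weights per (bin, compartment)."""
    ff = profile.true_ff
    width = float(genome.bin_width)
    y_mask = genome.chrom_mask("chrY")
    c_f = copy_map.fetal.astype(float)
    c_m = copy_map.maternal.astype(float)
    # chrY mismapping background: a small copy-number-equivalent floor in both
    # compartments so female-fetus FF_chrY is small-positive, as in real data
    bg = 2.0 * config.chry_background
    c_f = np.where(y_mask, c_f + bg, c_f)
    c_m = np.where(y_mask, c_m + bg, c_m)
    tilt = 1.0 + ff * tilt_pattern(genome, config.ff_tilt_amplitude)
    w_f = width * ff * c_f / 2.0 * tilt
    w_m = width * (1.0 - ff) * c_m / 2.0 * tilt
    return w_f, w_m


def simulate_bin_counts(
    profile: SampleProfile,
    copy_map: CopyNumberMap,
    genome: GenomeModel,
    depth: int,
    rng: np.random.Generator,
    config: RunConfig | None = None,
    retention: tuple[float, float] | None = None,
) -> BinCounts:
    """Draw one sample's compartment-resolved bin counts at total depth ``depth``.

    ``retention`` = (r_f, r_m) applies per-compartment size-selection
    retention to the expected library composition before sequencing — the
    infinite-library limit of molecular size selection, appropriate when the
    cfDNA library holds far more unique molecules than the sequencer reads
    (so selection shifts composition without adding sampling noise).  The
    finite-molecule operator is ``sizesel.apply_size_selection``.
    """
    config = config or RunConfig()
    if depth < 10_000:
        raise CohortError("depth must be >= 1e4 fragments")
    w_f, w_m = _expected_weights(profile, copy_map, genome, config)
    if retention is not None:
        r_f, r_m = retention
        if not (0.0 < r_f <= 1.0 and 0.0 <= r_m <= 1.0):
            raise CohortError(f"invalid retention {retention}")
        w_f = w_f * r_f
        w_m = w_m * r_m
    w_sum = w_f.sum() + w_m.sum()
    if w_sum <= 0:
        raise CohortError("all-zero expected weights: nothing to sequence")
    lam_f = depth * w_f / w_sum
    lam_m = depth * w_m / w_sum

    if config.noise_model == "poisson":
        fetal = rng.poisson(lam_f)
        maternal = rng.poisson(lam_m)
    elif config.noise_model == "multinomial":
        p = np.concatenate([w_f, w_m]) / w_sum
        draw = rng.multinomial(depth, p)
        fetal, maternal = draw[: genome.n_bins], draw[genome.n_bins:]
    elif config.noise_model == "negbin":
        d = config.negbin_dispersion
        if d <= 0:
            fetal, maternal = rng.poisson(lam_f), rng.poisson(lam_m)
        else:
            # gamma-Poisson: Var = lam * (1 + d*lam)
            fetal = rng.poisson(rng.gamma(1.0 / d, d * np.maximum(lam_f, 1e-12)))
            maternal = rng.poisson(rng.gamma(1.0 / d, d * np.maximum(lam_m, 1e-12)))
    else:  # pragma: no cover - validated in RunConfig
        raise CohortError(f"unknown noise model {config.noise_model!r}")

    return BinCounts(
        genome=genome,
        sample_ids=[profile.sample_id],
        total=(fetal + maternal)[:, None],
        fetal=fetal[:, None],
        maternal=maternal[:, None],
    )


def _control_profiles(batch_id: str, config: RunConfig) -> list[SampleProfile]:
    return [
        SampleProfile(f"{batch_id}_NTC", batch_id, np.nan, 0.0, "euploid", "XX",
                      control_type="ntc"),
        SampleProfile(f"{batch_id}_POOLXX", batch_id, np.nan, config.pooled_ff,
                      "euploid", "XX", control_type="pooled_xx"),
        SampleProfile(f"{batch_id}_POOLXY", batch_id, np.nan, config.pooled_ff,
                      "euploid", "XY", control_type="pooled_xy"),
    ]


def _simulate_ntc(genome: GenomeModel, depth: int, eps: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """NTC: contamination only — expected ~eps*depth maternal-like fragments."""
    lam = eps * depth / genome.n_bins
    maternal = rng.poisson(np.full(genome.n_bins, lam))
    maternal[genome.chrom_mask("chrY")] = 0
    return np.zeros(genome.n_bins, dtype=np.int64), maternal


def profiles_from_manifest(manifest: pd.DataFrame) -> list[SampleProfile]:
    """Reconstruct latent profiles from a simulation manifest (which stores
    the latent truth for downstream parameter-recovery experiments)."""
    profiles = []
    for _, row in manifest.iterrows():
        ctl = row["control_type"] if pd.notna(row["control_type"]) else "none"
        karyotype = row["karyotype"] if pd.notna(row["karyotype"]) else "euploid"
        ff = float(row["true_ff"]) if pd.notna(row["true_ff"]) else 0.0
        profiles.append(SampleProfile(
            sample_id=str(row["sample_id"]),
            batch_id=str(row["batch_id"]),
            bmi=float(row["bmi"]) if pd.notna(row["bmi"]) else np.nan,
            true_ff=ff,
            karyotype=karyotype,
            fetal_sex=row["fetal_sex"],
            protocol=row["protocol"],
            control_type=ctl,
        ))
    return profiles


def simulate_from_profiles(
    profiles: list[SampleProfile],
    config: RunConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
    retention_for=None,
) -> BinCounts:
    """Simulate compartment-resolved counts for an explicit profile list.

    ``retention_for`` optionally maps a profile to per-compartment retention
    probabilities (the size-selected protocol arm); None = no selection.
    """
    n = genome.n_bins
    fetal = np.zeros((n, len(profiles)), dtype=np.int64)
    maternal = np.zeros((n, len(profiles)), dtype=np.int64)
    for j, profile in enumerate(profiles):
        if profile.control_type == "ntc":
            fetal[:, j], maternal[:, j] = _simulate_ntc(
                genome, config.depth, config.ntc_contamination, rng)
            continue
        cmap = karyotype_to_copy_map(profile, genome)
        retention = retention_for(profile) if retention_for is not None else None
        counts = simulate_bin_counts(profile, cmap, genome, config.depth, rng,
                                     config, retention=retention)
        fetal[:, j] = counts.fetal[:, 0]
        maternal[:, j] = counts.maternal[:, 0]
    return BinCounts(
        genome=genome,
        sample_ids=[p.sample_id for p in profiles],
        total=fetal + maternal,
        fetal=fetal,
        maternal=maternal,
    )


def profiles_to_manifest(profiles: list[SampleProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "sample_id": p.sample_id,
            "batch_id": p.batch_id,
            "bmi": p.bmi,
            "karyotype": p.karyotype if p.control_type == "none" else None,
            "fetal_sex": p.fetal_sex,
            "protocol": p.protocol,
            "true_ff": p.true_ff if p.control_type != "ntc" else None,
            "control_type": p.control_type,
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def simulate_cohort(
    config: RunConfig,
    rng: np.random.Generator,
    genome: GenomeModel,
    include_controls: bool = True,
    replicate_every: int = 0,
) -> tuple[pd.DataFrame, BinCounts, list[SampleProfile]]:
    """Draw a full cohort: patient profiles + per-batch controls + counts.

    ``replicate_every``: if k > 0, every k-th patient sample is re-sequenced
    in the following batch (same latent profile, new counts, sample_id with a
    ``_rep`` suffix) for reproducibility experiments.
    """
    md_names = tuple(
        name for name in genome.region_bins
        if name not in genome.chrom_names
    )
    batches = [f"B{b:02d}" for b in range(config.n_batches)]
    per_batch = np.full(config.n_batches, config.cohort_size // config.n_batches)
    per_batch[: config.cohort_size % config.n_batches] += 1

    profiles: list[SampleProfile] = []
    idx = 0
    for b, batch_id in enumerate(batches):
        batch_profiles = []
        for _ in range(int(per_batch[b])):
            p = draw_sample_profile(
                config, rng, sample_id=f"S{idx:04d}", batch_id=batch_id,
                microdeletion_names=md_names or None,
            )
            batch_profiles.append(p)
            idx += 1
        if not any(p.karyotype == "euploid" for p in batch_profiles):
            raise CohortError(
                f"batch {batch_id} has no euploid sample: reference statistics "
                "would be impossible"
            )
        profiles.extend(batch_profiles)
        if replicate_every > 0 and b + 1 < len(batches):
            for p in batch_profiles[::replicate_every]:
                profiles.append(replace(
                    p, sample_id=f"{p.sample_id}_rep", batch_id=batches[b + 1]))
        if include_controls:
            profiles.extend(_control_profiles(batch_id, config))

    counts = simulate_from_profiles(profiles, config, genome, rng)
    return profiles_to_manifest(profiles), counts, profiles
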
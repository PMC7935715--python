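"""Cohort-level pipeline steps shared by the CLI and the analysis scripts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .ff import (
    estimate_chry_background,
    estimate_ff_chry,
    normalize_depth,
    predict_ff_regression,
    train_ff_regression,
)
from .genome import GenomeModel
from .io import BinCounts
from .sizesel import (
    FragmentLengthMixture,
    SizeSelectionSpec,
    solve_cutoff_for_target_mean,
)


def solved_selection_specs(config: RunConfig):
    """Per-FF solved size-selection specs, cached on FF rounded to 1e-2
    (retention varies negligibly below that)."""
    cache: dict[float, SizeSelectionSpec] = {}

    def get(ff: float) -> SizeSelectionSpec:
        key = round(max(float(ff), 0.0), 2)
        if key not in cache:
            mixture = FragmentLengthMixture.from_config(config, key)
            cache[key] = solve_cutoff_for_target_mean(
                mixture, config.target_mean_length,
                mode=config.selection_mode, softness=config.selection_softness,
            )
        return cache[key]

    return get


def ffa_cohort(
    manifest: pd.DataFrame,
    config: RunConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> tuple[BinCounts, pd.DataFrame]:
    """Simulate the size-selected (FFA) protocol arm of a cohort.

    The two arms of the validation design are replicate plasma aliquots
    sequenced independently, so the FFA arm is a fresh sequencing draw whose
    expected library composition carries the per-compartment retention of
    the solved size selection (the cutoff is solved per sample — the
    elution stopping rule targets each library's own mean length, which
    depends on its FF).  Selection acts on composition, not on the realized
    reads of the standard arm: the cfDNA library holds far more molecules
    than the sequencer samples, so size selection does not add counting
    noise.  Returns the post-selection counts and a manifest copy with
    ``protocol='ffa'`` and the realized post-selection latent FF.
    """
    from .cohort import profiles_from_manifest, simulate_from_profiles

    profiles = profiles_from_manifest(manifest)
    spec_for = solved_selection_specs(config)

    def retention_for(profile):
        spec = spec_for(profile.true_ff)
        return (spec.r_f, spec.r_m)

    counts = simulate_from_profiles(profiles, config, genome, rng,
                                    retention_for=retention_for)
    totals = counts.depths().astype(float)
    with np.errstate(invalid="ignore"):
        shares = np.divide(counts.fetal.sum(axis=0), totals,
                           out=np.zeros_like(totals), where=totals > 0)
    manifest_ffa = manifest.copy()
    manifest_ffa["protocol"] = "ffa"
    share_by_id = dict(zip(counts.sample_ids, shares))
    manifest_ffa["true_ff"] = [
        share_by_id.get(sid, np.nan) if not pd.isna(tf) else np.nan
        for sid, tf in zip(manifest_ffa["sample_id"], manifest_ffa["true_ff"])
    ]
    return counts, manifest_ffa


def estimate_ff_table(
    counts: BinCounts,
    manifest: pd.DataFrame,
    genome: GenomeModel,
    config: RunConfig,
) -> pd.DataFrame:
    """Per-sample FF estimates: FF_chrY always; the autosomal regression when
    enough (>= 50) male-fetus euploid training samples exist."""
    man = manifest.set_index("sample_id")
    ctl = man["control_type"].fillna("none")
    ratio_cols = {}
    for sid in counts.sample_ids:
        if ctl.get(sid, "none") == "ntc":
            continue
        ratio_cols[sid] = normalize_depth(counts.column(sid), genome)

    xx_eu = [
        sid for sid in counts.sample_ids
        if sid in ratio_cols
        and ctl.get(sid) == "none"
        and man.loc[sid, "karyotype"] == "euploid"
        and man.loc[sid, "fetal_sex"] == "XX"
    ]
    background = estimate_chry_background(
        np.stack([ratio_cols[s] for s in xx_eu], axis=1), genome,
    ) if xx_eu else 0.0

    rows = []
    for sid in counts.sample_ids:
        if sid not in ratio_cols:
            rows.append({"sample_id": sid, "ff_chry": np.nan,
                         "ff_chry_raw": np.nan, "ff_regression": np.nan})
            continue
        est = estimate_ff_chry(ratio_cols[sid], genome, sid, counts.column(sid),
                               background=background)
        rows.append({"sample_id": sid, "ff_chry": est.value,
                     "ff_chry_raw": est.raw + background,  # uncorrected
                     "ff_regression": np.nan})
    df = pd.DataFrame(rows)

    xy_eu = [
        sid for sid in counts.sample_ids
        if sid in ratio_cols
        and ctl.get(sid) == "none"
        and man.loc[sid, "karyotype"] == "euploid"
        and man.loc[sid, "fetal_sex"] == "XY"
    ]
    if len(xy_eu) >= 50:
        labels = df.set_index("sample_id").loc[xy_eu, "ff_chry"].to_numpy()
        model = train_ff_regression(
            np.stack([ratio_cols[s] for s in xy_eu], axis=1), labels, genome,
            ridge_lambda=config.ridge_lambda,
        )
        preds = {
            sid: predict_ff_regression(model, ratios, genome, sid).value
            for sid, ratios in ratio_cols.items()
        }
        df["ff_regression"] = df["sample_id"].map(preds)
    return df
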
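"""Reference-based z-score screening and the 2-D chrX/chrY sex-karyotype call.

A region's screening statistic is

    z = (region mean depth ratio - mu_ref) / sigma_ref,

with (mu_ref, sigma_ref) estimated over euploid reference samples.  For
deletion hypotheses the calling direction is negative, so z is sign-flipped
internally — "more positive = more evidence" uniformly.  A sample screens
positive when its directional z meets the class threshold (ties call
positive).

Sex and sex-chromosome-aneuploidy calls do not use z-scores: they place each
sample in the (chrX deviation, FF_chrY) plane and match it against the
expected location of each karyotype hypothesis at the sample's FF:

    d_X = 2*(1 - mean chrX ratio),  f_Y = FF_chrY
    XX: (0, 0)    XY: (FF, FF)    MX: (FF, 0)
    TX: (-FF, 0)  XXY: (0, FF)    XYY: (FF, 2FF)

with tolerance band tau = max(0.35*FF, 0.01, 3*measurement noise); the
nearest hypothesis within tolerance wins, none -> no-call, and non-XX
hypotheses require a minimally detectable FF (see ``call_sex_sca``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .ff import (
    estimate_chry_background,
    estimate_ff_chry,
    estimate_ff_region,
    normalize_depth,
    region_mean_ratio,
)
from .genome import GenomeModel
from .io import BinCounts


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceStats:
    """Per-region mean/SD of region mean depth ratio over euploid references."""

    mu: dict[str, float]
    sigma: dict[str, float]
    n_ref: int
    scope: str = "cohort"


@dataclass(frozen=True)
class RegionCall:
    sample_id: str
    region: str
    depth_ratio: float
    z_score: float
    ff_positive: float
    call: str                 # "negative" | "positive"
    threshold: float


@dataclass(frozen=True)
class SexKaryotypeCall:
    sample_id: str
    ff_chrx_deviation: float
    ff_chry: float
    call: str                 # XX | XY | MX | TX | XXY | XYY | no-call


def region_class(genome: GenomeModel, region: str) -> str:
    if region in ("chr13", "chr18", "chr21"):
        return "common"
    if region in ("chrX", "chrY"):
        return "sex"
    if region in genome.chrom_names:
        return "raa"
    return "microdeletion"


def region_direction(genome: GenomeModel, region: str) -> str:
    """Calling direction per clinical hypothesis: trisomy/RAA = gain,
    microdeletion = loss."""
    return "loss" if region_class(genome, region) == "microdeletion" else "gain"


def screened_regions(genome: GenomeModel) -> list[str]:
    """Autosomal whole chromosomes plus microdeletion regions (chrX/chrY are
    handled by the 2-D sex-karyotype analysis, not by z-scores)."""
    return [
        r for r in genome.region_bins
        if r not in ("chrX", "chrY")
    ]


def build_reference(
    ratios: np.ndarray,
    genome: GenomeModel,
    regions: list[str] | None = None,
    min_n: int = 10,
    scope: str = "cohort",
) -> ReferenceStats:
    """Per-region reference statistics over euploid samples.

    ``ratios`` is (n_bins, n_ref) of normalized depth ratios from samples
    known (by manifest truth or prior call) to be euploid.
    """
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    n_ref = ratios.shape[1]
    if n_ref < min_n:
        raise ScreenError(f"reference needs >= {min_n} euploid samples, got {n_ref}")
    regions = regions if regions is not None else screened_regions(genome)
    mu, sigma = {}, {}
    for region in regions:
        vals = ratios[genome.region_bins[region]].mean(axis=0)
        s = float(np.std(vals, ddof=1))
        if s <= 0:
            raise ScreenError(f"degenerate reference for region {region!r} (sigma = 0)")
        mu[region] = float(np.mean(vals))
        sigma[region] = s
    return ReferenceStats(mu=mu, sigma=sigma, n_ref=n_ref, scope=scope)


def region_z(
    ratio: float,
    reference: ReferenceStats,
    region: str,
    direction: str = "gain",
) -> float:
    """Directional z: positive = evidence for the clinical hypothesis."""
    if region not in reference.mu:
        raise ScreenError(f"reference does not cover region {region!r}")
    z = (ratio - reference.mu[region]) / reference.sigma[region]
    return float(-z if direction == "loss" else z)


def class_threshold(config: RunConfig, cls: str) -> float:
    key = {
        "common": "z_threshold_common",
        "raa": "z_threshold_raa",
        "microdeletion": "z_threshold_microdeletion",
    }.get(cls)
    if key is None:
        raise ScreenError(f"no z threshold configured for region class {cls!r}")
    return getattr(config, key)


def call_regions(
    z_by_region: dict[str, float],
    genome: GenomeModel,
    config: RunConfig,
    sample_id: str = "",
    ratios: np.ndarray | None = None,
) -> list[RegionCall]:
    """Threshold each region's directional z (z == threshold calls positive)."""
    calls = []
    for region, z in z_by_region.items():
        thr = class_threshold(config, region_class(genome, region))
        if ratios is not None:
            ratio = region_mean_ratio(ratios, genome, region)
            ffp = estimate_ff_region(
                ratios, genome, region, region_direction(genome, region)).raw
        else:
            ratio, ffp = np.nan, np.nan
        calls.append(RegionCall(
            sample_id=sample_id,
            region=region,
            depth_ratio=ratio,
            z_score=z,
            ff_positive=ffp,
            call="positive" if z >= thr else "negative",
            threshold=thr,
        ))
    return calls


# (d_X, f_Y) hypothesis locations in units of the sample's FF
_SCA_HYPOTHESES = {
    "XX": (0.0, 0.0),
    "XY": (1.0, 1.0),
    "MX": (1.0, 0.0),
    "TX": (-1.0, 0.0),
    "XXY": (0.0, 1.0),
    "XYY": (1.0, 2.0),
}


def call_sex_sca(
    ff_chrx_deviation: float,
    ff_chry: float,
    ff_baseline: float | None = None,
    tolerance_frac: float = 0.35,
    tolerance_floor: float = 0.01,
    noise_dx: float = 0.0,
    noise_fy: float = 0.0,
    min_sca_ff: float = 0.04,
    sample_id: str = "",
) -> SexKaryotypeCall:
    """Two-dimensional sex / SCA call.

    ``ff_baseline`` is the sample's FF estimate (regression, or chrY where
    appropriate).  When omitted, each hypothesis's implied FF is inferred
    from the observed coordinates themselves (e.g. f_Y for XXY, d_X for MX),
    making the rule usable without a trained regression.

    Two guards keep the rule honest against measurement noise: the
    tolerance band is never tighter than 3x the coordinate's measurement
    noise (``noise_dx``/``noise_fy``, e.g. the spread of each coordinate
    over known-female euploids), and every non-XX hypothesis requires its
    FF to reach a minimally detectable level (``min_sca_ff``, defaulting to
    the 4% low-FF threshold) — without that, the implied-FF fallback would
    self-fit any noisy coordinate as a low-FF abnormality (or a noisy
    female as a borderline male).  The flip side is realistic too: a
    genuinely low-FF male fetus falls back to the female/no-call side,
    the borderline sex-miscall mode that fetal-fraction amplification
    exists to remove.
    """
    d_x, f_y = float(ff_chrx_deviation), float(ff_chry)
    ff_floor = max(min_sca_ff, 3.0 * noise_dx, 3.0 * noise_fy)
    candidates: list[tuple[float, str]] = []
    for name, (hx, hy) in _SCA_HYPOTHESES.items():
        if ff_baseline is not None:
            ff = ff_baseline
        else:
            # least-squares FF implied by this hypothesis's direction vector
            norm = hx * hx + hy * hy
            ff = (hx * d_x + hy * f_y) / norm if norm > 0 else 0.0
        ff = max(ff, 0.0)
        if name != "XX" and ff < ff_floor:
            continue
        tau_x = max(tolerance_frac * ff, tolerance_floor, 3.0 * noise_dx)
        tau_y = max(tolerance_frac * ff, tolerance_floor, 3.0 * noise_fy)
        ex, ey = hx * ff, hy * ff
        if abs(d_x - ex) <= tau_x and abs(f_y - ey) <= tau_y:
            dist = float(np.hypot(d_x - ex, f_y - ey))
            candidates.append((dist, name))
    if not candidates:
        return SexKaryotypeCall(sample_id, d_x, f_y, "no-call")
    candidates.sort()
    if len(candidates) > 1 and candidates[1][0] - candidates[0][0] < 1e-12:
        return SexKaryotypeCall(sample_id, d_x, f_y, "no-call")
    return SexKaryotypeCall(sample_id, d_x, f_y, candidates[0][1])


def screen_cohort(
    counts: BinCounts,
    manifest: pd.DataFrame,
    genome: GenomeModel,
    config: RunConfig,
    reference: ReferenceStats | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ReferenceStats]:
    """Run the full screen on a cohort.

    Builds the euploid reference from manifest truth (excluding controls),
    z-scores every screened region for every non-NTC sample, and issues 2-D
    sex-karyotype calls (implied-FF mode with noise floors estimated from
    the female euploids).  Returns (region results, sex calls, reference).
    """
    man = manifest.set_index("sample_id")
    ctl = man["control_type"].fillna("none")

    ratio_cols: dict[str, np.ndarray] = {}
    for sid in counts.sample_ids:
        if ctl.get(sid, "none") == "ntc":
            continue
        ratio_cols[sid] = normalize_depth(counts.column(sid), genome)

    eu_ids = [
        sid for sid in counts.sample_ids
        if sid in ratio_cols
        and ctl.get(sid) == "none"
        and man.loc[sid, "karyotype"] == "euploid"
    ]
    xx_eu = [s for s in eu_ids if man.loc[s, "fetal_sex"] == "XX"]
    background = estimate_chry_background(
        np.stack([ratio_cols[s] for s in xx_eu], axis=1), genome,
    ) if xx_eu else 0.0
    if reference is None:
        ref_ratios = np.stack([ratio_cols[s] for s in eu_ids], axis=1) if eu_ids else \
            np.zeros((genome.n_bins, 0))
        reference = build_reference(ref_ratios, genome, min_n=config.min_reference)

    # measurement-noise floors for the 2-D sex call, from female euploids
    if len(xx_eu) >= 3:
        dx_xx = np.array([
            2.0 * (1.0 - region_mean_ratio(ratio_cols[s], genome, "chrX"))
            for s in xx_eu
        ])
        fy_xx = np.array([
            estimate_ff_chry(ratio_cols[s], genome, background=background).raw
            for s in xx_eu
        ])
        noise_dx = float(np.std(dx_xx, ddof=1))
        noise_fy = float(np.std(fy_xx, ddof=1))
    else:
        noise_dx = noise_fy = 0.0

    region_rows, sex_rows = [], []
    regions = screened_regions(genome)
    for sid, ratios in ratio_cols.items():
        z_by_region = {
            r: region_z(region_mean_ratio(ratios, genome, r), reference, r,
                        region_direction(genome, r))
            for r in regions
        }
        for call in call_regions(z_by_region, genome, config, sid, ratios):
            region_rows.append({
                "sample_id": sid, "region": call.region,
                "depth_ratio": call.depth_ratio, "z_score": call.z_score,
                "ff_positive": call.ff_positive, "call": call.call,
            })
        d_x = 2.0 * (1.0 - region_mean_ratio(ratios, genome, "chrX"))
        f_y = estimate_ff_chry(ratios, genome, sid, counts.column(sid),
                               background=background).value
        # implied-FF mode: each hypothesis's FF comes from the sample's own
        # (d_X, f_Y) coordinates, guarded by the noise and min-FF floors
        sc = call_sex_sca(
            d_x, f_y, None,
            tolerance_frac=config.sca_tolerance_frac,
            tolerance_floor=config.sca_tolerance_floor,
            noise_dx=noise_dx,
            noise_fy=noise_fy,
            min_sca_ff=config.sca_min_ff,
            sample_id=sid,
        )
        sex_rows.append({
            "sample_id": sid, "ff_chrx_deviation": sc.ff_chrx_deviation,
            "ff_chry": sc.ff_chry, "call": sc.call,
        })

    return pd.DataFrame(region_rows), pd.DataFrame(sex_rows), reference
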
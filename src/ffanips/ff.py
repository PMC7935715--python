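"""Fetal fraction estimators from binned read depth.

Three estimators, all operating on normalized per-bin depth ratios (a euploid
disomic bin has expected ratio 1):

* ``FF_chrY`` — for male-fetus pregnancies the fetal compartment carries one
  chrY copy against a maternal background of zero, so the chrY depth ratio is
  FF/2; doubling it estimates FF directly.
* ``FF_positive`` — an aneuploid region's depth deviates from 1 by ±FF/2
  (trisomy/deletion), so twice the directional deviation estimates FF from
  the aneuploid region itself.
* regression — a ridge regression of FF on autosomal bin ratios (a
  SeqFF-style stand-in), trained on male-fetus euploid samples with FF_chrY
  as the label; applies to female-fetus samples where chrY is uninformative.

Normalization divides each bin's per-bp rate by the median of the 22
autosomal per-chromosome rates.  A per-chromosome (rather than per-bin)
median keeps the robustness of a median against a whole-chromosome outlier
while avoiding the discreteness bias of a median over integer-valued bin
counts at moderate depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .genome import AUTOSOMES, GenomeModel


class DepthError(ValueError):
    pass


@dataclass(frozen=True)
class FfEstimate:
    sample_id: str
    method: str               # "chrY" | "region" | "regression"
    value: float              # clipped to [0, 1]
    raw: float                # unclipped (diagnostic; may be negative)
    se: float | None = None
    sign_mismatch: bool = False


def _chrom_slices(genome: GenomeModel) -> list[tuple[str, slice]]:
    slices = []
    start = 0
    for name, length in genome.chromosomes:
        n = length // genome.bin_width
        slices.append((name, slice(start, start + n)))
        start += n
    return slices


def normalize_depth(counts: np.ndarray, genome: GenomeModel) -> np.ndarray:
    """Per-bin depth ratios: (count/width) / median autosomal chromosome rate.

    Accepts a (n_bins,) vector or (n_bins, n_samples) matrix.  Raises on a
    zero autosomal median (an NTC-like sample with insufficient depth).
    """
    counts = np.asarray(counts, dtype=float)
    squeeze = counts.ndim == 1
    if squeeze:
        counts = counts[:, None]
    if counts.shape[0] != genome.n_bins:
        raise DepthError(f"{counts.shape[0]} rows vs {genome.n_bins} genome bins")
    rate = counts / genome.bin_width
    chrom_rates = []
    for name, sl in _chrom_slices(genome):
        if name in AUTOSOMES:
            width = (sl.stop - sl.start) * genome.bin_width
            chrom_rates.append(counts[sl].sum(axis=0) / width)
    denom = np.median(np.stack(chrom_rates, axis=0), axis=0)
    if np.any(denom <= 0):
        bad = int(np.flatnonzero(denom <= 0)[0])
        raise DepthError(
            f"insufficient depth: zero autosomal median rate (sample column {bad})"
        )
    ratios = rate / denom
    return ratios[:, 0] if squeeze else ratios


def region_mean_ratio(ratios: np.ndarray, genome: GenomeModel, region: str) -> float:
    if region not in genome.region_bins:
        raise DepthError(f"region {region!r} not in genome")
    return float(np.mean(ratios[genome.region_bins[region]]))


def estimate_ff_chry(
    ratios: np.ndarray,
    genome: GenomeModel,
    sample_id: str = "",
    counts: np.ndarray | None = None,
    background: float = 0.0,
) -> FfEstimate:
    """FF_chrY = 2 * (chrY mean depth ratio) - background, clipped to [0, 1].

    chrY counts are aggregated across the whole chromosome before forming the
    ratio: at desk-scale depth single chrY bins hold fractional counts, so
    only the chromosome total is informative.  ``background`` is the chrY
    mismapping level on the FF scale (the mean uncorrected FF_chrY of
    known-female pregnancies); subtracting it removes the constant offset
    that mismapped maternal reads add to every sample.  The delta-method SE
    uses the Poisson variance of the chrY count total when counts are
    supplied.
    """
    ratio_y = region_mean_ratio(ratios, genome, "chrY")
    raw = 2.0 * ratio_y - background
    se = None
    if counts is not None:
        c_y = float(np.asarray(counts)[genome.chrom_mask("chrY")].sum())
        se = 2.0 * ratio_y / np.sqrt(c_y) if c_y > 0 else None
    return FfEstimate(sample_id, "chrY", float(np.clip(raw, 0.0, 1.0)), raw, se)


def estimate_ff_region(
    ratios: np.ndarray,
    genome: GenomeModel,
    region: str,
    direction: str,
    sample_id: str = "",
    counts: np.ndarray | None = None,
) -> FfEstimate:
    """FF_positive: twice the directional depth deviation of an aneuploid
    region (gain: 2*(ratio-1); loss: 2*(1-ratio)).

    The signed form is unbiased even when noise is comparable to the signal;
    a negative raw value means the observed deviation contradicts the
    declared direction and is flagged (``sign_mismatch``).
    """
    if direction not in ("gain", "loss"):
        raise DepthError(f"direction must be 'gain' or 'loss', got {direction!r}")
    mean_ratio = region_mean_ratio(ratios, genome, region)
    dev = mean_ratio - 1.0
    raw = 2.0 * dev if direction == "gain" else -2.0 * dev
    se = None
    if counts is not None:
        c_r = float(np.asarray(counts)[genome.region_bins[region]].sum())
        if c_r > 0:
            se = 2.0 * mean_ratio / np.sqrt(c_r)
    return FfEstimate(sample_id, "region", float(np.clip(raw, 0.0, 1.0)), raw,
                      se, sign_mismatch=raw < 0)


def estimate_chry_background(ratios: np.ndarray, genome: GenomeModel) -> float:
    """chrY mismapping background on the FF scale: mean uncorrected FF_chrY
    over known-female euploid samples.  ``ratios`` is (n_bins, n_female)."""
    ratios = np.atleast_2d(np.asarray(ratios, dtype=float))
    if ratios.shape[1] == 0:
        return 0.0
    return float(2.0 * ratios[genome.region_bins["chrY"]].mean())


@dataclass(frozen=True)
class FfRegressionModel:
    """Ridge regression of FF on autosomal bin depth ratios."""

    coef: np.ndarray          # one weight per autosomal bin
    intercept: float
    ridge_lambda: float
    n_training: int
    residual_sd: float        # SD of training residuals of the final model
    loo_sd: float = 0.0       # SD of calibrated leave-one-out residuals

    def __post_init__(self) -> None:
        if self.coef.ndim != 1:
            raise DepthError("coefficient vector must be 1-D")


def train_ff_regression(
    ratios: np.ndarray,
    labels: np.ndarray,
    genome: GenomeModel,
    ridge_lambda: float | None = None,
    seed: int = 0,
    calibrate: bool = True,
) -> FfRegressionModel:
    """Fit the autosomal-depth FF regression.

    ``ratios`` is (n_bins, n_samples); ``labels`` are FF_chrY estimates of
    male-fetus euploid training samples.  The fit is deterministic given the
    inputs and penalty (``seed`` is accepted for interface symmetry).

    With far more bins than samples the ridge fit is computed in its kernel
    (n x n) form and its predictions are strongly attenuated — the signal
    direction must be learned against a noise Gram matrix of comparable
    magnitude — so the fit is followed by a leave-one-out calibration:
    exact closed-form LOO predictions are regressed on the labels and the
    resulting slope/intercept folded into the coefficients.  Two error
    scales are stored: ``loo_sd``, the SD of calibrated LOO residuals (an
    honest estimate of error on new samples), and ``residual_sd``, the SD of
    the final model's own training residuals — larger than ``loo_sd``
    because de-attenuation rescales a near-interpolating fit, so its
    training predictions overshoot their labels.  ``ridge_lambda=None``
    scales the penalty to the data (6x the mean squared row norm, the
    noise-Gram magnitude).
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = labels.size
    if n < 50:
        raise DepthError(f"insufficient training samples: {n} < 50")
    if ratios.shape != (genome.n_bins, n):
        raise DepthError("training ratio matrix does not match genome/labels")
    mask = genome.autosomal_mask
    X = ratios[mask].T - 1.0
    if ridge_lambda is None:
        ridge_lambda = 6.0 * float(np.mean(np.sum(X * X, axis=1)))

    x_mean = X.mean(axis=0)
    y_mean = float(labels.mean())
    Xc = X - x_mean
    yc = labels - y_mean
    K = Xc @ Xc.T
    Myc = np.linalg.solve(K + ridge_lambda * np.eye(n), yc)
    coef = Xc.T @ Myc
    fitted = K @ Myc                                   # in-sample, centered
    H_diag = np.einsum("ij,ji->i", K, np.linalg.inv(K + ridge_lambda * np.eye(n)))
    loo = (fitted - H_diag * yc) / np.clip(1.0 - H_diag, 1e-12, None) + y_mean

    intercept = y_mean - float(x_mean @ coef)
    if calibrate and np.std(loo) > 1e-12:
        slope, cal_intercept = np.polyfit(loo, labels, 1)
        if slope > 0:      # only de-attenuate a positively informative fit
            coef *= slope
            intercept = intercept * slope + cal_intercept
            loo = loo * slope + cal_intercept
    loo_sd = float(np.std(labels - loo, ddof=1))
    train_pred = X @ coef + intercept
    resid_sd = float(np.std(labels - train_pred, ddof=1))
    return FfRegressionModel(
        coef=coef,
        intercept=float(intercept),
        ridge_lambda=float(ridge_lambda),
        n_training=n,
        residual_sd=resid_sd,
        loo_sd=loo_sd,
    )


def predict_ff_regression(
    model: FfRegressionModel,
    ratios: np.ndarray,
    genome: GenomeModel,
    sample_id: str = "",
) -> FfEstimate:
    """Apply the regression to one sample's ratios (XX or XY alike)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (genome.n_bins,):
        raise DepthError(
            f"ratio vector length {ratios.shape} does not match genome binning"
        )
    x = ratios[genome.autosomal_mask] - 1.0
    if x.size != model.coef.size:
        raise DepthError("bin count mismatch between model and genome")
    raw = float(x @ model.coef + model.intercept)
    return FfEstimate(sample_id, "regression", float(np.clip(raw, 0.0, 1.0)),
                      raw, model.residual_sd)
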
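"""In-silico fetal fraction amplification: fragment-length mixture,
size-selection operator, and the closed-form FF gain law.

Fetal-derived cfDNA fragments are shorter on average than maternal ones
(defaults: truncated normals with means 143 nt and 167 nt, giving a
pre-selection overall mean near 165 nt at low FF).  Size selection retains a
fragment with probability ``r(l)`` — a hard cutoff ``1{l <= L}`` by default,
or a logistic soft window — and the cutoff is solved so the retained
library's mean length hits a target (140 nt by default, the elution stopping
rule of the wet-lab protocol this emulates).

Because retention acts per compartment, the post-selection fetal fraction is

    ff_post = ff * r_f / (ff * r_f + (1 - ff) * r_m),

so the fold gain ``ff_post / ff`` tends to ``r_f / r_m`` as ff -> 0 and is
strictly decreasing in ff whenever ``r_f > r_m``: the lowest-FF samples gain
the most.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .genome import GenomeModel
from .io import BinCounts


class SizeSelectionError(ValueError):
    pass


def _truncated_normal(mean: float, sd: float):
    """Normal(mean, sd) truncated to positive lengths."""
    return stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)


@dataclass(frozen=True)
class FragmentLengthMixture:
    """Two-compartment fragment-length model; mixture weight = FF."""

    fetal: object            # frozen scipy distribution
    maternal: object
    ff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff <= 1.0:
            raise SizeSelectionError(f"ff={self.ff} outside [0, 1]")
        if self.fetal.mean() >= self.maternal.mean():
            raise SizeSelectionError("fetal mean length must be below maternal")

    @classmethod
    def from_config(cls, config: RunConfig, ff: float) -> "FragmentLengthMixture":
        return cls(
            fetal=_truncated_normal(config.fetal_length_mean, config.fetal_length_sd),
            maternal=_truncated_normal(config.maternal_length_mean, config.maternal_length_sd),
            ff=ff,
        )

    def overall_mean(self) -> float:
        return self.ff * self.fetal.mean() + (1.0 - self.ff) * self.maternal.mean()


@dataclass(frozen=True)
class SizeSelectionSpec:
    """Selection operator: mode, cutoff, and resulting retention probabilities."""

    mode: str                 # "hard" | "logistic"
    cutoff: float             # L (nt); +inf = no selection
    softness: float = 4.0     # logistic scale (nt); unused in hard mode
    target_mean: float | None = None
    r_f: float = 1.0
    r_m: float = 1.0

    def retention(self, lengths: np.ndarray) -> np.ndarray:
        """P(retain | length)."""
        lengths = np.asarray(lengths, dtype=float)
        if self.mode == "hard":
            return (lengths <= self.cutoff).astype(float)
        if self.mode == "logistic":
            if np.isinf(self.cutoff):
                return np.ones_like(lengths)
            arg = np.clip((lengths - self.cutoff) / self.softness, -60.0, 60.0)
            return 1.0 / (1.0 + np.exp(arg))
        raise SizeSelectionError(f"unknown selection mode {self.mode!r}")


def _truncnorm_partial_mean(dist, cutoff: float) -> float:
    """Closed-form E[L ; L <= cutoff] for a truncated normal (unconditional
    on the cutoff, conditional on the truncation interval)."""
    mu, sd = dist.kwds["loc"], dist.kwds["scale"]
    a, b = dist.args
    alpha = np.clip((cutoff - mu) / sd, a, b)
    phi, Phi = stats.norm.pdf, stats.norm.cdf
    z = Phi(b) - Phi(a)
    return (mu * (Phi(alpha) - Phi(a)) - sd * (phi(alpha) - phi(a))) / z


def _retained_mass_and_mean(dist, mode: str, cutoff: float, softness: float
                            ) -> tuple[float, float]:
    """(E[r(L)], E[L r(L)]) for one compartment's length distribution."""
    if np.isinf(cutoff) and cutoff > 0:
        return 1.0, float(dist.mean())
    if mode == "hard":
        mass = float(dist.cdf(cutoff))
        if mass <= 0:
            return 0.0, 0.0
        if getattr(getattr(dist, "dist", None), "name", "") == "truncnorm":
            return mass, _truncnorm_partial_mean(dist, cutoff)
        mean = float(dist.expect(lambda l: l, ub=cutoff))
        return mass, mean
    spec = SizeSelectionSpec(mode=mode, cutoff=cutoff, softness=softness)
    mass = float(dist.expect(lambda l: spec.retention(l)))
    mean = float(dist.expect(lambda l: l * spec.retention(l)))
    return mass, mean


def retention_probabilities(mixture: FragmentLengthMixture,
                            spec: SizeSelectionSpec) -> tuple[float, float]:
    """Per-compartment retention probabilities under the selection operator."""
    r_f, _ = _retained_mass_and_mean(mixture.fetal, spec.mode, spec.cutoff, spec.softness)
    r_m, _ = _retained_mass_and_mean(mixture.maternal, spec.mode, spec.cutoff, spec.softness)
    if r_f < 1e-12 and r_m < 1e-12:
        raise SizeSelectionError("retention is (numerically) zero: empty library")
    return r_f, r_m


def _post_selection_mean(mixture: FragmentLengthMixture, mode: str,
                         cutoff: float, softness: float) -> float:
    mf, sf = _retained_mass_and_mean(mixture.fetal, mode, cutoff, softness)
    mm, sm = _retained_mass_and_mean(mixture.maternal, mode, cutoff, softness)
    mass = mixture.ff * mf + (1.0 - mixture.ff) * mm
    if mass <= 0:
        return np.nan
    return (mixture.ff * sf + (1.0 - mixture.ff) * sm) / mass


def solve_cutoff_for_target_mean(
    mixture: FragmentLengthMixture,
    target_mean: float = 140.0,
    mode: str = "hard",
    softness: float = 4.0,
    tol: float = 0.05,
) -> SizeSelectionSpec:
    """Find the cutoff L whose retained library has the target mean length.

    The retained conditional mean is monotone increasing in L (asserted on a
    grid before solving); bisection then locates L to within ``tol`` nt of
    the target (spec tolerance 0.1 nt).  A target at or above the
    pre-selection mean needs no selection (L = +inf); a target below the
    achievable minimum raises with the achievable range.
    """
    pre_mean = mixture.overall_mean()
    if target_mean >= pre_mean:
        return SizeSelectionSpec(mode=mode, cutoff=np.inf, softness=softness,
                                 target_mean=target_mean, r_f=1.0, r_m=1.0)

    lo = float(max(mixture.fetal.ppf(1e-9), 1.0))
    hi = float(mixture.maternal.ppf(1.0 - 1e-12)) + 20.0 * softness
    grid = np.linspace(lo, hi, 25)
    means = np.array([_post_selection_mean(mixture, mode, L, softness) for L in grid])
    ok = ~np.isnan(means)
    if not np.all(np.diff(means[ok]) > -1e-9):
        raise SizeSelectionError("retained conditional mean is not monotone in L")
    achievable_lo = np.nanmin(means)
    if target_mean < achievable_lo:
        raise SizeSelectionError(
            f"target mean {target_mean} nt unachievable; achievable range is "
            f"[{achievable_lo:.1f}, {pre_mean:.1f}] nt"
        )

    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        m = _post_selection_mean(mixture, mode, mid, softness)
        if np.isnan(m) or m < target_mean:
            a = mid
        else:
            b = mid
        if b - a < 1e-4:
            break
    cutoff = 0.5 * (a + b)
    realized = _post_selection_mean(mixture, mode, cutoff, softness)
    if not abs(realized - target_mean) <= max(tol, 0.1):
        raise SizeSelectionError(
            f"bisection failed: realized mean {realized:.3f} vs target {target_mean}"
        )
    spec = SizeSelectionSpec(mode=mode, cutoff=cutoff, softness=softness,
                             target_mean=target_mean)
    r_f, r_m = retention_probabilities(mixture, spec)
    return replace(spec, r_f=r_f, r_m=r_m)


def expected_ff_gain(ff: float, r_f: float, r_m: float) -> tuple[float, float]:
    """Closed-form post-selection FF and fold gain.

    Handles ff in {0, 1} as limits (gain -> r_f/r_m and 1 respectively).
    """
    if not 0.0 <= ff <= 1.0:
        raise SizeSelectionError(f"ff={ff} outside [0, 1]")
    for name, r in (("r_f", r_f), ("r_m", r_m)):
        if not 0.0 < r <= 1.0:
            raise SizeSelectionError(f"{name}={r} outside (0, 1]")
    if ff == 0.0:
        return 0.0, r_f / r_m
    if ff == 1.0:
        return 1.0, 1.0
    ff_post = ff * r_f / (ff * r_f + (1.0 - ff) * r_m)
    return ff_post, ff_post / ff


def apply_size_selection(
    counts: BinCounts,
    spec: SizeSelectionSpec,
    rng: np.random.Generator,
    reamplify: bool = True,
) -> tuple[BinCounts, np.ndarray]:
    """Thin compartment counts binomially with (r_f, r_m); optionally
    re-amplify (multinomial resample) back to each sample's original depth.

    Returns the post-selection counts and the realized post-selection latent
    FF per sample (fetal share among retained fragments).
    """
    if not counts.has_compartments:
        raise SizeSelectionError(
            "size selection requires compartment-resolved counts "
            "(molecular selection acts on latent fragment origin)"
        )
    fetal = rng.binomial(counts.fetal, spec.r_f)
    maternal = rng.binomial(counts.maternal, spec.r_m)
    retained = fetal + maternal
    totals = retained.sum(axis=0)
    fetal_share = np.divide(
        fetal.sum(axis=0), totals,
        out=np.zeros(len(counts.sample_ids)), where=totals > 0,
    )

    if reamplify:
        orig_depth = counts.depths()
        n_bins = counts.genome.n_bins
        new_f = np.zeros_like(fetal)
        new_m = np.zeros_like(maternal)
        for j in range(len(counts.sample_ids)):
            tot = totals[j]
            if tot == 0:
                continue
            p = np.concatenate([fetal[:, j], maternal[:, j]]) / tot
            draw = rng.multinomial(int(orig_depth[j]), p)
            new_f[:, j] = draw[:n_bins]
            new_m[:, j] = draw[n_bins:]
        fetal, maternal = new_f, new_m

    out = BinCounts(
        genome=counts.genome,
        sample_ids=list(counts.sample_ids),
        total=fetal + maternal,
        fetal=fetal,
        maternal=maternal,
    )
    return out, fetal_share


def simulate_fragment_lengths(
    counts: BinCounts,
    config: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit per-fragment lengths (TSV sidecar layout) for the bioinformatic
    re-weighting path.  Intended for small cohorts: one row per fragment."""
    if not counts.has_compartments:
        raise SizeSelectionError("fragment lengths require compartment-resolved counts")
    fetal_dist = _truncated_normal(config.fetal_length_mean, config.fetal_length_sd)
    maternal_dist = _truncated_normal(config.maternal_length_mean, config.maternal_length_sd)
    frames = []
    g = counts.genome
    for j, sid in enumerate(counts.sample_ids):
        for comp, mat, dist in (("fetal", counts.fetal, fetal_dist),
                                ("maternal", counts.maternal, maternal_dist)):
            col = mat[:, j]
            nz = np.flatnonzero(col)
            n_frag = int(col[nz].sum())
            if n_frag == 0:
                continue
            bin_idx = np.repeat(nz, col[nz])
            lengths = dist.rvs(size=n_frag, random_state=rng)
            frames.append(pd.DataFrame({
                "chrom": g.bin_chrom[bin_idx],
                "start": g.bin_start[bin_idx],
                "end": g.bin_end[bin_idx],
                "sample_id": sid,
                "length": lengths,
                "compartment": comp,
            }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "sample_id",
                                     "length", "compartment"])
    return pd.concat(frames, ignore_index=True)


def bioinformatic_weighting(
    fragments: pd.DataFrame,
    weight_fn,
    genome: GenomeModel,
) -> BinCounts:
    """Length-weighted counts: each bin's value is the sum of per-fragment
    weights.  ``w = 1{length <= L}`` reproduces hard molecular selection
    without re-amplification; any nonnegative weight function is allowed."""
    w = np.asarray(weight_fn(fragments["length"].to_numpy()), dtype=float)
    if np.any(w < 0):
        raise SizeSelectionError("negative fragment weights")
    key = pd.MultiIndex.from_arrays([
        fragments["chrom"], fragments["start"],
    ])
    bin_lookup = {
        (c, s): i
        for i, (c, s) in enumerate(zip(genome.bin_chrom, genome.bin_start))
    }
    bin_idx = np.array([bin_lookup[k] for k in key], dtype=np.int64)
    sample_ids = sorted(fragments["sample_id"].unique())
    col = fragments["sample_id"].map({s: j for j, s in enumerate(sample_ids)}).to_numpy()
    mat = np.zeros((genome.n_bins, len(sample_ids)))
    np.add.at(mat, (bin_idx, col), w)
    return BinCounts(genome=genome, sample_ids=sample_ids, total=mat)
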
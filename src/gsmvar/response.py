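"""Spike-count readout of posterior samples and the simulated experiments.

A single-trial response is a deterministic function of one posterior sample of
the RF feature pair: r = c * sqrt(g1+^2 + g1-^2) (the modulus of the local
oriented energy, scaled into a realistic spike-count range by c). Because the
samples come from the posterior, across-trial response variability is entirely
inherited from posterior uncertainty — no extra spiking noise is assumed.
r is kept continuous by default and treated as a count (the rounding error is
small once c is large enough); strict integer counts are available via
``round_counts``. An alternative rectified expansive readout
r = c * max(g1+, 0)**p is provided because the modulus readout mispredicts the
contrast dependence of variance at fixed stimulus size, while the size-tuning
and surround-tuning predictions are robust to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filterbank import FilterBank, apply_filterbank
from .gsm import GSMParams, Posterior, _PosteriorSolver, posterior_noisy
from .stimuli import make_compound_grating, make_grating, mask_disc

__all__ = [
    "SpikeResponse",
    "spike_transform",
    "response_stats",
    "run_mean_variance_scan",
    "run_size_tuning",
    "run_surround_orientation",
]


@dataclass
class SpikeResponse:
    """Per-stimulus spike-count samples and their summary statistics."""

    r_samples: np.ndarray
    mean: float
    variance: float
    ff: float  # nan when the mean is zero (flagged undefined)
    c: float
    variant: str

    @property
    def ff_defined(self) -> bool:
        return np.isfinite(self.ff)


def spike_transform(
    g1_plus: np.ndarray,
    g1_minus: np.ndarray,
    c: float,
    variant: str = "modulus",
    expansive_exponent: float = 2.0,
    round_counts: bool = False,
) -> np.ndarray:
    """Map samples of the RF feature pair to spike counts."""
    if c <= 0:
        raise ValueError("scaling factor c must be positive")
    g1_plus = np.asarray(g1_plus, dtype=float)
    g1_minus = np.asarray(g1_minus, dtype=float)
    if variant == "modulus":
        r = c * np.hypot(g1_plus, g1_minus)
    elif variant == "expansive":
        r = c * np.maximum(g1_plus, 0.0) ** expansive_exponent
    else:
        raise ValueError(f"unknown readout variant: {variant!r}")
    if round_counts:
        r = np.rint(r)
    return r


def response_stats(
    posterior: Posterior,
    c: float,
    variant: str = "modulus",
    **transform_kwargs,
) -> SpikeResponse:
    """Mean, unbiased variance and Fano factor of the readout over samples."""
    if posterior.samples.shape[0] < 2:
        raise ValueError("need at least 2 posterior samples")
    r = spike_transform(
        posterior.samples[:, 0], posterior.samples[:, 1], c, variant, **transform_kwargs
    )
    mean = float(r.mean())
    var = float(r.var(ddof=1))
    ff = var / mean if mean > 0 else np.nan
    return SpikeResponse(r_samples=r, mean=mean, variance=var, ff=ff, c=c, variant=variant)


def _bootstrap_ci(
    r: np.ndarray, stat: str, n_boot: int, rng: np.random.Generator, level: float = 0.68
) -> tuple[float, float]:
    """Percentile bootstrap CI over response samples for 'mean' or 'ff'."""
    n = r.size
    idx = rng.integers(n, size=(n_boot, n))
    boots = r[idx]
    if stat == "mean":
        vals = boots.mean(axis=1)
    else:
        m = boots.mean(axis=1)
        v = boots.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(m > 0, v / m, np.nan)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return (np.nan, np.nan)
    lo, hi = np.percentile(vals, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


def _condition_row(
    params: GSMParams,
    solver: _PosteriorSolver,
    x: np.ndarray,
    c: float,
    variant: str,
    n_samples: int,
    seed: int,
    n_boot: int,
) -> dict:
    post = posterior_noisy(x, params, n_samples=n_samples, seed=seed, solver=solver)
    resp = response_stats(post, c, variant)
    rng = np.random.default_rng(seed + 1)
    m_lo, m_hi = _bootstrap_ci(resp.r_samples, "mean", n_boot, rng)
    f_lo, f_hi = _bootstrap_ci(resp.r_samples, "ff", n_boot, rng)
    return {
        "mean": resp.mean,
        "variance": resp.variance,
        "ff": resp.ff,
        "mean_lo": m_lo,
        "mean_hi": m_hi,
        "ff_lo": f_lo,
        "ff_hi": f_hi,
        "lam": post.lam,
        "e_nu": post.e_nu,
    }


@dataclass
class ScanResult:
    """Across-image mean/variance/FF table with the mean-FF association."""

    table: pd.DataFrame
    pearson_r: float
    p_value: float
    slope: float  # linear fit of FF against mean
    n_excluded: int


def run_mean_variance_scan(
    params: GSMParams,
    bank: FilterBank,
    images: np.ndarray,
    c: float,
    seed: int = 0,
    variant: str = "modulus",
    n_samples: int = 400,
) -> ScanResult:
    """Posterior-sampled mean, variance and FF for each image in an ensemble,
    plus the across-image Pearson correlation between FF and mean (two-sided
    test against zero correlation) and the linear-fit slope.

    The ensemble should already be restricted to patches with sufficient RF
    signal (see ``load_image_patches`` / ``rf_signal_strength``); images whose
    mean response is zero have no defined FF and are excluded with a count.
    """
    solver = _PosteriorSolver(params)
    xs = apply_filterbank(bank, images)
    n_distinct = np.unique(xs.round(decimals=10), axis=0).shape[0]
    rows = []
    for i, x in enumerate(xs):
        post = posterior_noisy(x, params, n_samples=n_samples, seed=seed + i, solver=solver)
        resp = response_stats(post, c, variant)
        rows.append(
            {"image": i, "mean": resp.mean, "variance": resp.variance, "ff": resp.ff}
        )
    table = pd.DataFrame(rows)
    ok = table[np.isfinite(table["ff"])]
    n_excluded = len(table) - len(ok)
    # a degenerate ensemble (too few distinct stimuli) has no meaningful
    # across-image correlation: flag it as undefined
    if n_distinct < 3 or len(ok) < 3:
        return ScanResult(table, np.nan, np.nan, np.nan, n_excluded)
    r, p = stats.pearsonr(ok["mean"], ok["ff"])
    slope = float(np.polyfit(ok["mean"], ok["ff"], 1)[0])
    return ScanResult(table, float(r), float(p), slope, n_excluded)


def run_size_tuning(
    params: GSMParams,
    bank: FilterBank,
    base_image: np.ndarray,
    diameters_deg: np.ndarray,
    c: float,
    seed: int = 0,
    variant: str = "modulus",
    n_samples: int = 400,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Mean and FF (with 68% bootstrap CIs) versus stimulus size.

    The base image is masked by a hard circular aperture at each diameter. The
    returned table also records lambda and the posterior mixer mean per size:
    stimuli growing beyond the RF keep raising lambda (surround filters join
    in), which is what drives the continued FF decrease after the mean peaks.
    """
    diameters = np.asarray(diameters_deg, dtype=float)
    if diameters.size < 3:
        raise ValueError("need at least 3 diameters")
    if not np.all(np.diff(diameters) > 0):
        raise ValueError("diameters must be strictly increasing")
    solver = _PosteriorSolver(params)
    rows = []
    for i, diam in enumerate(diameters):
        x = apply_filterbank(bank, mask_disc(base_image, bank.spec, diam))
        row = _condition_row(params, solver, x, c, variant, n_samples, seed + i, n_boot)
        row["diameter_deg"] = diam
        rows.append(row)
    cols = ["diameter_deg", "mean", "variance", "ff", "mean_lo", "mean_hi", "ff_lo", "ff_hi", "lam", "e_nu"]
    return pd.DataFrame(rows)[cols]


def run_surround_orientation(
    params: GSMParams,
    bank: FilterBank,
    surround_orientations_deg: np.ndarray,
    c: float,
    center_diameter_deg: float = 1.0,
    surround_inner_deg: float = 1.0,
    surround_outer_deg: float = 3.8,
    center_orientation_deg: float | None = None,
    seed: int = 0,
    variant: str = "modulus",
    n_samples: int = 400,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Mean and FF versus surround orientation, with a center-alone reference.

    First row is the center grating alone (condition 'center_alone'); the rest
    are compound gratings with the annular surround at each orientation.
    A surround matched to the center orientation drives the same-orientation
    surround filters, raises the inferred mixer, and so suppresses both the
    mean and the FF more than an orthogonal surround does.
    """
    solver = _PosteriorSolver(params)
    if center_orientation_deg is None:
        center_orientation_deg = bank.spec.orientation_deg
    rows = []
    center_img = make_grating(bank.spec, center_diameter_deg, orientation_deg=center_orientation_deg)
    x = apply_filterbank(bank, center_img)
    row = _condition_row(params, solver, x, c, variant, n_samples, seed, n_boot)
    row["condition"] = "center_alone"
    row["surround_orientation_deg"] = np.nan
    rows.append(row)
    for i, ori in enumerate(np.asarray(surround_orientations_deg, dtype=float)):
        img = make_compound_grating(
            bank.spec,
            center_diameter_deg,
            surround_inner_deg,
            surround_outer_deg,
            center_orientation_deg=center_orientation_deg,
            surround_orientation_deg=ori,
        )
        x = apply_filterbank(bank, img)
        row = _condition_row(params, solver, x, c, variant, n_samples, seed + 1 + i, n_boot)
        row["condition"] = f"surround_{ori:g}"
        row["surround_orientation_deg"] = ori
        rows.append(row)
    cols = [
        "condition",
        "surround_orientation_deg",
        "mean",
        "variance",
        "ff",
        "mean_lo",
        "mean_hi",
        "ff_lo",
        "ff_hi",
        "lam",
        "e_nu",
    ]
    return pd.DataFrame(rows)[cols]
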
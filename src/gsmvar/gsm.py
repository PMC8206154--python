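"""Gaussian scale mixture (GSM) generative model and posterior inference.

The model explains a vector of oriented-filter activations x as

    x = nu * g + eta,     g ~ N(0, C_g),  nu ~ Rayleigh(mean 1),
                          eta ~ N(0, C_noise),

where g are the local oriented features the model neuron encodes and the
scalar mixer nu is a global modulator (e.g. overall contrast) shared by all
features. Inference marginalizes the mixer: because nu is scalar, the
posterior p(nu | x) is an exactly tractable 1-D integral, and g | nu, x is
Gaussian. The sampler here is therefore Rao-Blackwellized — a dense grid over
nu plus conditional Gaussian draws — with no burn-in or convergence issues,
and is cross-checked in the tests against a brute-force importance sampler
over the (nu, g) prior.

Asymptotics (noiseless model).  Writing s for the Rayleigh scale and
lambda = sqrt(x' C_g^{-1} x), the posterior over the mixer concentrates at
E[nu|x] ~ sqrt(s*lambda), and the RF feature obeys

    E[g1+|x]  ~ x1+ / sqrt(s*lambda),
    FF[g1+|x] ~ x1+ * sqrt(s) / (4 * lambda**1.5),

valid up to relative corrections of order 1/lambda. At s = 1 these reduce to
the familiar x/sqrt(lambda) and x/(4*lambda*sqrt(lambda)) divisive-
normalization forms; the scale factors keep them exact asymptotics under the
mean-1 mixer prior used here (s = sqrt(2/pi)). Both the mean and the Fano
factor of the encoded feature are divided by powers of lambda — the same
normalization signal — which is what ties mean responses and variability
together throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, integrate
from scipy.stats import rayleigh

from .filterbank import FilterBank, apply_filterbank

__all__ = [
    "RAYLEIGH_MEAN1_SCALE",
    "GSMParams",
    "NoiselessSummary",
    "Posterior",
    "train_moment_matching",
    "estimate_noise_cov",
    "lambda_stat",
    "admissible_feature_interval",
    "noiseless_posterior_summary",
    "noiseless_posterior_1d_exact",
    "posterior_noisy",
    "additive_control_posterior_1d",
]

# scale parameter of the mean-1 Rayleigh mixer prior; E[nu] = s*sqrt(pi/2) = 1
RAYLEIGH_MEAN1_SCALE = float(np.sqrt(2.0 / np.pi))

# lambda below which the O(1/lambda) corrections to the asymptotic summaries
# are no longer negligible and a warning is raised
ASYMPTOTIC_LAMBDA_THRESHOLD = 5.0


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(M, M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


@dataclass
class GSMParams:
    """Trained model parameters: feature covariance, noise covariance, mixer prior."""

    C_g: np.ndarray
    C_noise: np.ndarray
    mixer_scale: float = RAYLEIGH_MEAN1_SCALE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.C_g = _check_symmetric(self.C_g, "C_g")
        self.C_noise = _check_symmetric(self.C_noise, "C_noise")
        if self.C_g.shape != self.C_noise.shape:
            raise ValueError("C_g and C_noise must have matching shapes")
        if np.linalg.eigvalsh(self.C_g).min() <= 0:
            raise ValueError("C_g must be positive definite")
        if np.linalg.eigvalsh(self.C_noise).min() < -1e-10:
            raise ValueError("C_noise must be positive semidefinite")
        if self.mixer_scale <= 0:
            raise ValueError("mixer_scale must be positive")

    @property
    def n_dim(self) -> int:
        return self.C_g.shape[0]

    @property
    def mixer_mean(self) -> float:
        return self.mixer_scale * float(np.sqrt(np.pi / 2.0))

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (matrices + prior + provenance)."""
        np.savez(
            path,
            C_g=self.C_g,
            C_noise=self.C_noise,
            mixer_scale=self.mixer_scale,
            meta=json.dumps(self.meta),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GSMParams":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                C_g=z["C_g"],
                C_noise=z["C_noise"],
                mixer_scale=float(z["mixer_scale"]),
                meta=json.loads(str(z["meta"])),
            )


def train_moment_matching(
    filter_outputs: np.ndarray,
    mixer_scale: float = RAYLEIGH_MEAN1_SCALE,
    min_n: int = 1000,
    eig_floor_rel: float = 1e-8,
) -> np.ndarray:
    """Fit C_g by moment matching on an (N, d) matrix of filter outputs.

    Under the generative model (training images treated as noise-free) the
    output covariance is E[nu^2] * C_g with E[nu^2] = 2 * mixer_scale^2
    (= 4/pi for the mean-1 prior), so C_g is the empirical covariance divided
    by that factor. The result is symmetrized and eigenvalue-floored at
    ``eig_floor_rel`` times the leading eigenvalue to guarantee positive
    definiteness on real image ensembles.
    """
    X = np.asarray(filter_outputs, dtype=float)
    if X.ndim != 2:
        raise ValueError("filter_outputs must be an (N, d) matrix")
    if X.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} training vectors, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("filter_outputs contain non-finite entries")
    e_nu2 = 2.0 * mixer_scale**2
    C = np.cov(X, rowvar=False) / e_nu2
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    floor = eig_floor_rel * w.max()
    if w.max() <= 0:
        raise ValueError("training covariance is not positive; check inputs")
    w = np.maximum(w, floor)
    C = (V * w) @ V.T
    return 0.5 * (C + C.T)


def estimate_noise_cov(
    bank: FilterBank,
    n_patches: int = 10000,
    scale: float = 0.1,
    seed: int = 0,
    pixel_sd: float = 0.2,
    chunk: int = 1000,
) -> np.ndarray:
    """Observation-noise covariance: ``scale`` times the empirical covariance
    of the bank's outputs on i.i.d. pixel-noise patches.

    ``pixel_sd`` sets the noise-patch pixel sd; the default matches the
    typical RMS contrast of the training ensembles, so the heuristic
    ``scale`` = 0.1 keeps its meaning of "noise small relative to the trained
    signal covariance" regardless of the luminance units in use.
    """
    if n_patches < 100:
        raise ValueError("n_patches must be at least 100")
    rng = np.random.default_rng(seed)
    h, w = bank.kernels.shape[1:]
    outs = np.empty((n_patches, bank.n_filters))
    for start in range(0, n_patches, chunk):
        stop = min(start + chunk, n_patches)
        noise = pixel_sd * rng.standard_normal((stop - start, h, w))
        outs[start:stop] = apply_filterbank(bank, noise)
    C = scale * np.cov(outs, rowvar=False)
    return 0.5 * (C + C.T)


def lambda_stat(x: np.ndarray, C_g: np.ndarray) -> float:
    """The divisive-normalization signal lambda = sqrt(x' C_g^{-1} x).

    lambda pools the activations of all filters (center and surround) through
    the feature covariance and is, asymptotically, the posterior estimate of
    the mixer (up to the prior-scale factor). Computed via Cholesky for
    stability; raises if C_g is not positive definite.
    """
    x = np.asarray(x, dtype=float).ravel()
    try:
        cho = linalg.cho_factor(C_g, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("C_g is not positive definite") from exc
    z = linalg.solve_triangular(cho[0], x, lower=True)
    return float(np.linalg.norm(z))


def admissible_feature_interval(
    x: float, nu_low: float, nu_high: float
) -> tuple[float, float]:
    """Noiseless 1-D constraint nu = x / g: the feature values compatible with
    input ``x`` when the mixer is confined to [nu_low, nu_high].

    E.g. x = 10 with the mixer between 4 and 5 confines g to [2, 2.5]: a larger
    mixer estimate shrinks both the admissible range and its midpoint, the
    worked intuition behind the mean-variance dependence.
    """
    if nu_low <= 0 or nu_high <= nu_low:
        raise ValueError("need 0 < nu_low < nu_high")
    return (x / nu_high, x / nu_low)


@dataclass
class NoiselessSummary:
    """Asymptotic posterior summaries for the RF odd-phase feature g1+."""

    g1_mean: float
    g1_ff: float
    mixer_estimate: float
    lam: float
    applicable: bool  # False when x1+ <= 0 (asymptotic form assumes x1+ > 0)


def noiseless_posterior_summary(
    x: np.ndarray,
    C_g: np.ndarray,
    mixer_scale: float = RAYLEIGH_MEAN1_SCALE,
    lambda_warn: float = ASYMPTOTIC_LAMBDA_THRESHOLD,
) -> NoiselessSummary:
    """Asymptotic noiseless posterior mean, Fano factor and mixer estimate.

    Valid for large lambda (warns below ``lambda_warn``); exact 1-D posteriors
    for cross-checking are provided by :func:`noiseless_posterior_1d_exact`.
    """
    x = np.asarray(x, dtype=float).ravel()
    lam = lambda_stat(x, C_g)
    s = mixer_scale
    x1 = float(x[0])
    applicable = x1 > 0
    if not applicable:
        warnings.warn("asymptotic summary assumes x1+ > 0; flagged inapplicable")
    if 0 < lam < lambda_warn:
        warnings.warn(
            f"lambda = {lam:.3g} below asymptotic-validity threshold {lambda_warn}; "
            "O(1/lambda) corrections may be large"
        )
    if lam == 0:
        return NoiselessSummary(0.0, np.nan, 0.0, 0.0, applicable)
    return NoiselessSummary(
        g1_mean=x1 / np.sqrt(s * lam),
        g1_ff=x1 * np.sqrt(s) / (4.0 * lam**1.5),
        mixer_estimate=float(np.sqrt(s * lam)),
        lam=lam,
        applicable=applicable,
    )


def noiseless_posterior_1d_exact(
    x: float,
    sigma_g: float = 1.0,
    mixer_scale: float = RAYLEIGH_MEAN1_SCALE,
    n_grid: int = 200001,
) -> dict:
    """Exact noiseless 1-D posterior of g (and nu) by numeric quadrature.

    With no noise the constraint nu = x/g maps the priors onto a 1-D posterior
    density p(g | x) ∝ N(g; 0, sigma_g^2) * p_Rayleigh(x/g) / g on the
    half-line sign(g) = sign(x). Serves as the independent oracle for the
    asymptotic formulas. Returns mean, variance, Fano factor of g and the
    posterior mixer mean.
    """
    if x == 0:
        raise ValueError("x = 0 has a degenerate noiseless posterior")
    ax = abs(x)
    s = mixer_scale
    g = np.linspace(1e-9 * sigma_g, 20.0 * sigma_g, n_grid)
    nu = ax / g
    logw = (
        -(g**2) / (2 * sigma_g**2)
        + np.log(nu)
        - nu**2 / (2 * s**2)
        - np.log(g)
    )
    w = np.exp(logw - logw.max())
    Z = integrate.trapezoid(w, g)
    w /= Z
    mean = integrate.trapezoid(w * g, g)
    m2 = integrate.trapezoid(w * g * g, g)
    var = m2 - mean**2
    e_nu = integrate.trapezoid(w * nu, g)
    sign = 1.0 if x > 0 else -1.0
    return {
        "mean": sign * mean,
        "var": var,
        "ff": var / mean,
        "e_nu": e_nu,
    }


@dataclass
class Posterior:
    """Posterior over (nu, g) for one input x, from exact 1-D marginalization.

    ``nu_grid``/``nu_weights`` tabulate p(nu | x); ``samples`` are joint draws
    (one conditional-Gaussian g draw per sampled nu). ``g_mean``/``g_cov`` are
    the analytic (grid-integrated) posterior moments of g, not sample moments.
    """

    nu_grid: np.ndarray
    nu_weights: np.ndarray
    g_mean: np.ndarray
    g_cov: np.ndarray
    samples: np.ndarray  # (n_samples, d)
    nu_samples: np.ndarray
    e_nu: float
    lam: float
    seed: int


class _PosteriorSolver:
    """Precomputed factorization shared across many inputs x for one model.

    Uses C_noise = L L' and the generalized eigenproblem
    L^{-1} C_g L^{-T} = U diag(d) U', so that for every nu,
    (nu^2 C_g + C_noise)^{-1} factors through diag(nu^2 d + 1): likelihoods,
    conditional means and conditional covariances all become diagonal
    operations, making grid marginalization and sampling cheap.
    """

    def __init__(self, params: GSMParams):
        self.params = params
        w_noise = np.linalg.eigvalsh(params.C_noise)
        if w_noise.min() <= 0:
            raise ValueError(
                "posterior_noisy requires positive-definite C_noise; "
                "use noiseless_posterior_summary for the noise-free model"
            )
        L = np.linalg.cholesky(params.C_noise)
        A = linalg.solve_triangular(L, params.C_g, lower=True)
        A = linalg.solve_triangular(L, A.T, lower=True).T
        d, U = np.linalg.eigh(0.5 * (A + A.T))
        self.d = np.maximum(d, 0.0)
        self.M = L @ U  # maps diagonal coordinates back to g space
        self.L = L
        self.U = U

    def whiten(self, x: np.ndarray) -> np.ndarray:
        y = linalg.solve_triangular(self.L, x, lower=True)
        return self.U.T @ y

    def log_likelihood(self, y: np.ndarray, nu: np.ndarray) -> np.ndarray:
        """log N(x; 0, nu^2 C_g + C_noise) up to an x-independent constant."""
        denom = np.outer(nu**2, self.d) + 1.0  # (n_nu, d)
        return -0.5 * (np.log(denom) + (y**2)[None, :] / denom).sum(axis=1)

    def conditional_coeffs(self, y: np.ndarray, nu: np.ndarray):
        """Mean and sd of g | nu, x in the diagonal coordinates of M."""
        denom = np.outer(nu**2, self.d) + 1.0
        mean_coef = nu[:, None] * self.d[None, :] * y[None, :] / denom
        sd_coef = np.sqrt(self.d[None, :] / denom)
        return mean_coef, sd_coef


def _prior_grid(mixer_scale: float, n_grid: int, lo_q: float, hi_q: float) -> np.ndarray:
    lo = rayleigh.ppf(lo_q, scale=mixer_scale)
    hi = rayleigh.ppf(hi_q, scale=mixer_scale)
    return np.geomspace(lo, hi, n_grid)


def posterior_noisy(
    x: np.ndarray,
    params: GSMParams,
    n_samples: int = 400,
    seed: int = 0,
    n_grid: int = 2000,
    tail_tol: float = 1e-6,
    max_widenings: int = 60,
    solver: _PosteriorSolver | None = None,
) -> Posterior:
    """Posterior over (nu, g) for the full noisy model, by 1-D marginalization.

    p(nu | x) ∝ p_Rayleigh(nu) N(x; 0, nu^2 C_g + C_noise) is evaluated on a
    log-spaced grid covering the prior's [1e-4, 1 - 1e-8] quantiles; the grid
    is widened (upper edge doubled) until the posterior mass at the edges is
    below ``tail_tol``, and an error is raised if that fails. nu draws come
    from the grid weights; each is completed with one conditional Gaussian
    draw of g | nu, x. Same seed gives bit-identical output.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != params.n_dim:
        raise ValueError("x dimension does not match model")
    if solver is None:
        solver = _PosteriorSolver(params)
    s = params.mixer_scale
    y = solver.whiten(x)

    grid = _prior_grid(s, n_grid, 1e-4, 1.0 - 1e-8)
    for _ in range(max_widenings + 1):
        logp = solver.log_likelihood(y, grid) + rayleigh.logpdf(grid, scale=s)
        logp -= logp.max()
        dens = np.exp(logp)
        # trapezoid masses double as categorical sampling weights
        dnu = np.gradient(grid)
        w = dens * dnu
        w /= w.sum()
        if w[0] < tail_tol and w[-1] < tail_tol:
            break
        lo = grid[0] / (2.0 if w[0] >= tail_tol else 1.0)
        hi = grid[-1] * (2.0 if w[-1] >= tail_tol else 1.0)
        grid = np.geomspace(lo, hi, n_grid)
    else:
        raise RuntimeError("posterior grid still truncated after widening limit")

    mean_coef, sd_coef = solver.conditional_coeffs(y, grid)  # (n_grid, d)
    g_mean_coef = w @ mean_coef
    g_mean = solver.M @ g_mean_coef
    # law of total covariance in diagonal coordinates
    second = (w[:, None] * (sd_coef**2 + mean_coef**2)).sum(axis=0)
    cross = np.einsum("k,ki,kj->ij", w, mean_coef, mean_coef)
    cov_coef = cross + np.diag(second - np.diag(cross)) - np.outer(g_mean_coef, g_mean_coef)
    g_cov = solver.M @ cov_coef @ solver.M.T

    rng = np.random.default_rng(seed)
    idx = rng.choice(grid.size, size=n_samples, p=w)
    z = rng.standard_normal((n_samples, params.n_dim))
    draws_coef = mean_coef[idx] + sd_coef[idx] * z
    samples = draws_coef @ solver.M.T

    return Posterior(
        nu_grid=grid,
        nu_weights=w,
        g_mean=g_mean,
        g_cov=0.5 * (g_cov + g_cov.T),
        samples=samples,
        nu_samples=grid[idx],
        e_nu=float(w @ grid),
        lam=lambda_stat(x, params.C_g),
        seed=seed,
    )


def additive_control_posterior_1d(
    x: float, g_sd: float, offset_sd: float, noise_sd: float
) -> tuple[float, float]:
    """Posterior of g in the additive control model x = g + nu + eta.

    All three latent terms Gaussian and zero-mean: the posterior is conjugate,
    its mean linear in x with slope g_sd^2 / (g_sd^2 + offset_sd^2 + noise_sd^2)
    and its variance independent of x. This is the contrast case to the
    multiplicative mixer: an additive modulator shifts the inferred feature but
    cannot modulate its uncertainty, so it predicts no mean-variance coupling.
    """
    if min(g_sd, offset_sd, noise_sd) <= 0:
        raise ValueError("standard deviations must be positive")
    total = g_sd**2 + offset_sd**2 + noise_sd**2
    mean = x * g_sd**2 / total
    var = g_sd**2 * (offset_sd**2 + noise_sd**2) / total
    return mean, var
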
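"""Stimulus ensembles for the simulated experiments.

All generators emit luminance patches in the bank's geometry: zero-mean gray
background (luminance 0), values in contrast units where a 100%-contrast
grating spans [-1, 1]. Apertures are hard binary masks (no taper); the region
outside an aperture is exactly at background level.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .filterbank import FilterBankSpec, rf_signal_strength

__all__ = [
    "make_grating",
    "make_compound_grating",
    "mask_disc",
    "make_texture_ensemble",
    "load_image_patches",
]


def _grating_field(
    spec: FilterBankSpec,
    orientation_deg: float,
    spatial_frequency_cpd: float,
    phase_deg: float,
    contrast: float,
) -> np.ndarray:
    """Full-field sinusoidal grating; phase 0 is sine phase (odd), aligned
    with the center odd filter when orientation and frequency match the bank."""
    X, Y = spec.grid_deg()
    theta = np.deg2rad(orientation_deg)
    u = X * np.cos(theta + np.pi / 2) + Y * np.sin(theta + np.pi / 2)
    return contrast * np.sin(
        2 * np.pi * spatial_frequency_cpd * u + np.deg2rad(phase_deg)
    )


def _radius_map(spec: FilterBankSpec) -> np.ndarray:
    X, Y = spec.grid_deg()
    return np.hypot(X, Y)


def make_grating(
    spec: FilterBankSpec,
    diameter_deg: float,
    orientation_deg: float | None = None,
    spatial_frequency_cpd: float | None = None,
    phase_deg: float = 0.0,
    contrast: float = 1.0,
) -> np.ndarray:
    """Static sinusoidal grating in a hard circular aperture on gray background.

    Orientation and spatial frequency default to the bank spec's values (a
    stimulus matched to the model RF). Raises if the aperture exceeds the patch.
    """
    if diameter_deg <= 0:
        raise ValueError("diameter must be positive")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    if diameter_deg > spec.patch_extent_deg:
        raise ValueError(
            f"aperture {diameter_deg} deg exceeds patch extent "
            f"{spec.patch_extent_deg} deg"
        )
    if orientation_deg is None:
        orientation_deg = spec.orientation_deg
    if spatial_frequency_cpd is None:
        spatial_frequency_cpd = spec.spatial_frequency_cpd
    field = _grating_field(spec, orientation_deg, spatial_frequency_cpd, phase_deg, contrast)
    mask = _radius_map(spec) <= diameter_deg / 2.0
    return np.where(mask, field, 0.0)


def make_compound_grating(
    spec: FilterBankSpec,
    center_diameter_deg: float,
    surround_inner_deg: float,
    surround_outer_deg: float,
    center_orientation_deg: float | None = None,
    surround_orientation_deg: float | None = None,
    spatial_frequency_cpd: float | None = None,
    phase_deg: float = 0.0,
    center_contrast: float = 1.0,
    surround_contrast: float = 1.0,
) -> np.ndarray:
    """Center grating plus an annular surround grating of independent
    orientation; the gap between the center disc and the annulus inner edge is
    gray. Raises if the annulus would overlap the center disc."""
    if surround_inner_deg < center_diameter_deg:
        raise ValueError("surround inner diameter must be >= center diameter")
    if surround_outer_deg <= surround_inner_deg:
        raise ValueError("surround outer diameter must exceed inner diameter")
    if surround_outer_deg > spec.patch_extent_deg:
        raise ValueError("surround annulus exceeds patch extent")
    center = make_grating(
        spec,
        center_diameter_deg,
        orientation_deg=center_orientation_deg,
        spatial_frequency_cpd=spatial_frequency_cpd,
        phase_deg=phase_deg,
        contrast=center_contrast,
    )
    if surround_orientation_deg is None:
        surround_orientation_deg = spec.orientation_deg
    if spatial_frequency_cpd is None:
        spatial_frequency_cpd = spec.spatial_frequency_cpd
    field = _grating_field(
        spec, surround_orientation_deg, spatial_frequency_cpd, phase_deg, surround_contrast
    )
    r = _radius_map(spec)
    annulus = (r >= surround_inner_deg / 2.0) & (r <= surround_outer_deg / 2.0)
    return center + np.where(annulus, field, 0.0)


def mask_disc(image: np.ndarray, spec: FilterBankSpec, diameter_deg: float) -> np.ndarray:
    """Mask any patch-sized image by a hard circular aperture (size-tuning series)."""
    if diameter_deg > spec.patch_extent_deg:
        raise ValueError("aperture exceeds patch extent")
    mask = _radius_map(spec) <= diameter_deg / 2.0
    return np.where(mask, image, 0.0)


def make_texture_ensemble(
    kind: str,
    n: int,
    patch_size_px: int,
    seed: int,
    contrast_log_sd: float | None = None,
    rms_contrast: float | None = None,
) -> np.ndarray:
    """Seeded ensemble of texture patches, shape (n, patch, patch).

    ``white_noise``: i.i.d. standard-normal pixels (unit pixel sd by default).
    ``pink_texture``: random phases under a 1/f amplitude spectrum — a
    stand-in for natural image patches when none are on disk. Oriented
    structure is absent, but two contrast statistics of natural patches are
    emulated: a modest typical RMS contrast (median ``rms_contrast``, default
    0.2 on the [-1, 1] luminance scale, versus 0.71 for a full-contrast
    grating) and heavy-tailed patch-to-patch contrast variation (log-normal
    RMS contrast, default log-sd 0.5). White noise defaults to neither.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "white_noise":
        patches = rng.standard_normal((n, patch_size_px, patch_size_px))
        if contrast_log_sd is None:
            contrast_log_sd = 0.0
        if rms_contrast is None:
            rms_contrast = 1.0
    elif kind == "pink_texture":
        fx = np.fft.fftfreq(patch_size_px)[None, :]
        fy = np.fft.fftfreq(patch_size_px)[:, None]
        f = np.hypot(fx, fy)
        f[0, 0] = np.inf  # kill DC
        amp = 1.0 / f
        spec_c = rng.standard_normal((n, patch_size_px, patch_size_px)) + 1j * rng.standard_normal(
            (n, patch_size_px, patch_size_px)
        )
        patches = np.fft.ifft2(spec_c * amp[None]).real
        patches -= patches.mean(axis=(1, 2), keepdims=True)
        patches /= patches.std(axis=(1, 2), keepdims=True)
        if contrast_log_sd is None:
            contrast_log_sd = 0.5
        if rms_contrast is None:
            rms_contrast = 0.2
    else:
        raise ValueError(f"unknown texture kind: {kind!r}")
    patches = patches * rms_contrast
    if contrast_log_sd > 0:
        gains = np.exp(rng.normal(0.0, contrast_log_sd, size=n))
        patches = patches * gains[:, None, None]
    return patches


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Image file contents -> grayscale luminance in [-1, 1]."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr / 127.5 - 1.0


def load_image_patches(
    path: str | Path,
    n: int,
    patch_size_px: int,
    seed: int,
    selection: str = "random",
    bank=None,
) -> np.ndarray:
    """Sample mean-centered grayscale patches from image files in a directory.

    ``selection='rf_signal_above_median'`` draws 2n candidates, keeps those
    whose RF oriented energy (x1+^2 + x1-^2 under ``bank``) is at or above the
    candidate-ensemble median, and returns the first n of them — the selection
    used for the natural-image mean/variance scan.
    """
    from PIL import Image

    from .filterbank import apply_filterbank

    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    )
    if not files:
        raise FileNotFoundError(f"no readable images under {path}")
    rng = np.random.default_rng(seed)
    n_cand = 2 * n if selection == "rf_signal_above_median" else n
    candidates = np.empty((n_cand, patch_size_px, patch_size_px))
    for i in range(n_cand):
        f = files[rng.integers(len(files))]
        img = _to_gray(np.asarray(Image.open(f)))
        if img.shape[0] < patch_size_px or img.shape[1] < patch_size_px:
            raise ValueError(f"{f} smaller than requested patch size")
        r0 = rng.integers(img.shape[0] - patch_size_px + 1)
        c0 = rng.integers(img.shape[1] - patch_size_px + 1)
        patch = img[r0 : r0 + patch_size_px, c0 : c0 + patch_size_px]
        candidates[i] = patch - patch.mean()
    if selection == "random":
        return candidates
    if selection == "rf_signal_above_median":
        if bank is None:
            raise ValueError("selection by RF signal requires a filter bank")
        strength = rf_signal_strength(apply_filterbank(bank, candidates))
        keep = candidates[strength >= np.median(strength)]
        if keep.shape[0] < n:
            raise ValueError(f"only {keep.shape[0]} patches pass selection, need {n}")
        return keep[:n]
    raise ValueError(f"unknown selection rule: {selection!r}")
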
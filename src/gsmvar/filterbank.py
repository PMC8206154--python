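"""Oriented quadrature filter bank defining the model receptive field and surround.

The model neuron observes an image only through a fixed array of 18 linear,
oriented filters: one quadrature pair (odd and even spatial phase) centered on
the receptive field (RF), plus eight quadrature pairs whose Gaussian envelopes
are uniformly distributed on a ring around the RF, all sharing one orientation.
Applying the bank to an image yields the 18-dimensional observable ``x`` on
which the generative model operates.

Coordinate conventions (fixed for reproducibility): images are row-major 2-D
arrays; the spatial origin is at the patch center; the horizontal axis points
right (increasing column), the vertical axis points up (decreasing row);
angles are measured counterclockwise from the horizontal axis, in degrees.
``orientation_deg`` is the orientation of the preferred grating's bars, so a
vertical-bar filter (orientation 90) modulates along the horizontal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "FilterBankSpec",
    "FilterBank",
    "build_filterbank",
    "apply_filterbank",
    "rf_signal_strength",
]


@dataclass(frozen=True)
class FilterBankSpec:
    """Geometry of the 18-filter bank.

    Defaults give a ~1 deg RF (Gaussian envelope sd 0.3 deg, preferred spatial
    frequency 1 cycle/deg) inside a 4 x 4 deg patch, with the surround ring at
    1.0 deg so the surround envelopes slightly overlap the center envelope and
    the pooled surround covers stimuli out to ~2 deg eccentricity.
    """

    patch_size_px: int = 80
    deg_per_px: float = 0.05
    orientation_deg: float = 90.0
    spatial_frequency_cpd: float = 1.0
    envelope_sd_deg: float = 0.3
    surround_ring_radius_deg: float = 1.0
    n_surround_positions: int = 8

    def __post_init__(self) -> None:
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if self.deg_per_px <= 0 or self.envelope_sd_deg <= 0:
            raise ValueError("deg_per_px and envelope_sd_deg must be positive")
        if self.n_surround_positions < 1:
            raise ValueError("need at least one surround position")

    @property
    def patch_extent_deg(self) -> float:
        """Full width/height of the patch in degrees."""
        return self.patch_size_px * self.deg_per_px

    def grid_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinates in degrees, origin at patch center."""
        n = self.patch_size_px
        c = (n - 1) / 2.0
        cols = (np.arange(n) - c) * self.deg_per_px
        rows = (c - np.arange(n)) * self.deg_per_px  # y increases upward
        X, Y = np.meshgrid(cols, rows)
        return X, Y

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBankSpec":
        return cls(**d)


@dataclass(frozen=True)
class FilterBank:
    """The built bank: 18 DC-free, unit-norm kernels in a fixed order.

    Ordering: index 0 is the center odd-phase kernel (x1+), index 1 the center
    even-phase kernel (x1-), then surround pairs at ring angles 2*pi*k/8 for
    k = 0..7, odd phase before even within each pair.
    """

    kernels: np.ndarray  # (18, H, W)
    spec: FilterBankSpec
    centers_deg: np.ndarray = field(repr=False)  # (9, 2) envelope centers (x, y)

    @property
    def n_filters(self) -> int:
        return self.kernels.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """(n_filters, n_pixels) view used for fast batched application."""
        return self.kernels.reshape(self.n_filters, -1)


def _gabor_pair(spec: FilterBankSpec, cx: float, cy: float) -> tuple[np.ndarray, np.ndarray]:
    """Odd (sine) and even (cosine) Gabor kernels centered at (cx, cy) deg."""
    X, Y = spec.grid_deg()
    theta = np.deg2rad(spec.orientation_deg)
    # modulation axis is perpendicular to the bars
    u = (X - cx) * np.cos(theta + np.pi / 2) + (Y - cy) * np.sin(theta + np.pi / 2)
    env = np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2) / (2 * spec.envelope_sd_deg**2)))
    arg = 2 * np.pi * spec.spatial_frequency_cpd * u
    odd = env * np.sin(arg)
    even = env * np.cos(arg)
    return odd, even


def _finalize(kernel: np.ndarray) -> np.ndarray:
    """Remove DC and normalize to unit L2 norm."""
    k = kernel - kernel.mean()
    nrm = np.linalg.norm(k)
    if nrm == 0:
        raise ValueError("degenerate (all-zero) kernel")
    return k / nrm


def build_filterbank(spec: FilterBankSpec) -> FilterBank:
    """Construct the 18-kernel bank from its geometric spec.

    Deterministic in the spec. Raises a geometry error if the patch cannot
    contain the surround ring plus two envelope standard deviations.
    """
    half = spec.patch_extent_deg / 2.0
    reach = spec.surround_ring_radius_deg + 2.0 * spec.envelope_sd_deg
    if reach > half:
        raise ValueError(
            f"patch half-extent {half:.3f} deg too small for surround ring "
            f"radius {spec.surround_ring_radius_deg} deg + 2 envelope sd "
            f"({reach:.3f} deg needed)"
        )

    centers = [(0.0, 0.0)]
    ring_angles = 2 * np.pi * np.arange(spec.n_surround_positions) / spec.n_surround_positions
    for a in ring_angles:
        centers.append(
            (
                spec.surround_ring_radius_deg * np.cos(a),
                spec.surround_ring_radius_deg * np.sin(a),
            )
        )

    kernels = []
    for cx, cy in centers:
        odd, even = _gabor_pair(spec, cx, cy)
        odd = _finalize(odd)
        even = _finalize(even)
        # patch-edge truncation leaves a small odd/even overlap for surround
        # positions; project it out so every pair is an exact quadrature pair
        even = _finalize(even - float((even * odd).sum()) * odd)
        kernels.append(odd)
        kernels.append(even)
    return FilterBank(
        kernels=np.stack(kernels), spec=spec, centers_deg=np.asarray(centers)
    )


def apply_filterbank(bank: FilterBank, image: np.ndarray) -> np.ndarray:
    """Project an image (or a stack of images) onto the bank.

    Parameters
    ----------
    image : (H, W) or (N, H, W) array
        Luminance patch(es) matching the bank's patch size.

    Returns
    -------
    x : (18,) or (N, 18) array of filter activations. Each entry is the inner
        product of one kernel with the image, so the map is linear in the image.
    """
    image = np.asarray(image, dtype=float)
    hw = bank.kernels.shape[1:]
    if image.shape[-2:] != hw:
        raise ValueError(f"image shape {image.shape[-2:]} does not match bank patch {hw}")
    if image.ndim == 2:
        return bank.matrix @ image.ravel()
    if image.ndim == 3:
        return image.reshape(image.shape[0], -1) @ bank.matrix.T
    raise ValueError("image must be 2-D or a 3-D stack")


def rf_signal_strength(x: np.ndarray) -> np.ndarray:
    """Oriented energy inside the RF: x1+^2 + x1-^2.

    Works on a single response vector or a stack (N, 18); used to select image
    patches with sufficient signal inside the RF (above the ensemble median).
    """
    x = np.asarray(x, dtype=float)
    return x[..., 0] ** 2 + x[..., 1] ** 2
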
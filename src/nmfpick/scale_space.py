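"""Phase I: multi-scale Perona-Malik / difference-of-Gaussians feature stack.

The micrograph is resampled into a family of scales, each scale is
regularized with an increasing number of explicit Perona-Malik diffusion
iterations, a short Gaussian sequence is built per scale, and the
differences of each Gaussian image to the last of its octave are flattened
(after resampling back to the original frame) into one nonnegative feature
matrix, one row per scale-space variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigurationError, InvalidInputError
from .micrograph import MIN_DIM, Micrograph


@dataclass
class ScaleSpaceConfig:
    """Settings for the scale-space stack.

    ``n_scales`` (U) and ``pm_K`` follow the published settings (16 scales,
    diffusion contrast constant 0.05 on [0, 1] intensities); the iteration
    schedule grows linearly with the scale index.
    """

    n_scales: int = 16
    pm_K: float = 0.05
    pm_iters_per_scale: int = 5
    pm_dt: float = 0.2
    sigma_base: float = 1.6
    scales_per_octave: int = 4

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ConfigurationError("n_scales must be >= 2")
        if self.pm_K <= 0:
            raise ConfigurationError("pm_K must be positive")
        if self.pm_iters_per_scale < 1:
            raise ConfigurationError("pm_iters_per_scale must be >= 1")
        if not 0.0 < self.pm_dt <= 0.25:
            raise ConfigurationError("pm_dt must lie in (0, 0.25]")
        if self.sigma_base <= 0:
            raise ConfigurationError("sigma_base must be positive")
        if self.scales_per_octave < 2:
            raise ConfigurationError("scales_per_octave must be >= 2")


@dataclass
class ScaleStack:
    """Ordered family of rescaled, diffusion-regularized images."""

    layers: list[tuple[int, float, np.ndarray]]
    origin_shape: tuple[int, int]


@dataclass
class FeatureMatrix:
    """Flattened nonnegative scale-space stack: one row per DOG variation."""

    values: np.ndarray
    row_meta: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def scale_factor(u: int, n_scales: int) -> float:
    """Resampling factor of scale ``u``: 2**((u+1)/U - 1), increasing to 1."""
    return float(2.0 ** ((u + 1) / n_scales - 1.0))


def pm_diffuse(image: np.ndarray, K: float, n_iter: int, dt: float = 0.2) -> np.ndarray:
    """Explicit 4-neighbor Perona-Malik diffusion with reflecting boundaries.

    Diffusivity g(s) = exp(-(s/K)^2) decreases with the local intensity
    difference s, so smoothing is strong in flat areas and weak across
    edges. The symmetric inter-pixel fluxes conserve total intensity, and
    for dt <= 0.25 each update is a convex combination of neighbors, so the
    intensity range cannot expand.
    """
    if K <= 0:
        raise ConfigurationError("K must be positive")
    if not 0.0 < dt <= 0.25:
        raise ConfigurationError("dt must lie in (0, 0.25] for stability")
    img = np.asarray(image, dtype=np.float64).copy()
    for _ in range(int(n_iter)):
        d_n = np.zeros_like(img)
        d_s = np.zeros_like(img)
        d_w = np.zeros_like(img)
        d_e = np.zeros_like(img)
        d_n[1:, :] = img[:-1, :] - img[1:, :]
        d_s[:-1, :] = img[1:, :] - img[:-1, :]
        d_w[:, 1:] = img[:, :-1] - img[:, 1:]
        d_e[:, :-1] = img[:, 1:] - img[:, :-1]
        flux = sum(np.exp(-((d / K) ** 2)) * d for d in (d_n, d_s, d_w, d_e))
        img += dt * flux
    return img


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian convolution, kernel truncated at 4 sigma, reflecting borders."""
    if sigma < 0:
        raise ConfigurationError("sigma must be nonnegative")
    if sigma == 0:
        return np.asarray(image, dtype=np.float64).copy()
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=np.float64), sigma, mode="reflect", truncate=4.0
    )


def _resample(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    # bilinear, no anti-alias prefilter: deterministic and cheap
    return resize(
        image, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )


def build_scale_family(micrograph: Micrograph, config: ScaleSpaceConfig) -> ScaleStack:
    """Resample the micrograph to U scales and PM-diffuse each one.

    Scale u is resampled by s_u = 2**((u+1)/U - 1) (dimensions rounded to
    the nearest integer; the last layer is full size) and diffused for
    ``pm_iters_per_scale * (u + 1)`` iterations, so coarser regularization
    accompanies each added scale.
    """
    px = micrograph.pixels
    if px.min() < 0 or px.max() > 1:
        raise InvalidInputError("build_scale_family expects a normalized micrograph")
    m, n = px.shape
    layers: list[tuple[int, float, np.ndarray]] = []
    for u in range(config.n_scales):
        s_u = scale_factor(u, config.n_scales)
        shape = (int(round(m * s_u)), int(round(n * s_u)))
        if min(shape) < MIN_DIM:
            raise ConfigurationError(
                f"scale {u} would produce a {shape[0]}x{shape[1]} layer; "
                f"input too small for n_scales={config.n_scales}"
            )
        scaled = np.clip(_resample(px, shape), 0.0, 1.0)
        diffused = pm_diffuse(
            scaled, config.pm_K, config.pm_iters_per_scale * (u + 1), config.pm_dt
        )
        layers.append((u, s_u, diffused))
    return ScaleStack(layers=layers, origin_shape=(m, n))


def dog_to_last(octave_layers: list[np.ndarray]) -> list[np.ndarray]:
    """Difference of each image in an octave to the octave's last image."""
    if len(octave_layers) < 2:
        raise InvalidInputError("an octave needs at least two images")
    last = np.asarray(octave_layers[-1], dtype=np.float64)
    out = []
    for layer in octave_layers[:-1]:
        layer = np.asarray(layer, dtype=np.float64)
        if layer.shape != last.shape:
            raise InvalidInputError("octave images must share one shape")
        out.append(layer - last)
    return out


def assemble_feature_matrix(
    difference_images: list[np.ndarray],
    origin_shape: tuple[int, int],
    row_meta: list[tuple[int, int, float]] | None = None,
) -> FeatureMatrix:
    """Resample difference images to the origin frame and flatten them.

    Rows are row-major flattenings; the global minimum is subtracted so the
    matrix is nonnegative (a shift, not a clip, preserving structure for
    the factorization stage).
    """
    if not difference_images:
        raise InvalidInputError("no difference images to assemble")
    m, n = origin_shape
    rows = np.empty((len(difference_images), m * n), dtype=np.float64)
    for i, img in enumerate(difference_images):
        img = np.asarray(img, dtype=np.float64)
        if img.shape != (m, n):
            img = _resample(img, (m, n))
        rows[i] = img.ravel()
    rows -= rows.min()
    meta = list(row_meta) if row_meta is not None else []
    return FeatureMatrix(values=rows, row_meta=meta)


def build_feature_matrix(
    micrograph: Micrograph, config: ScaleSpaceConfig
) -> FeatureMatrix:
    """Full Phase I: scale family -> per-scale Gaussian octave -> DOG -> matrix.

    Each scale layer forms one octave of ``scales_per_octave`` Gaussian
    images with sigma = sigma_base * 2**(j / scales_per_octave); the
    differences to the last octave image give scales_per_octave - 1 rows
    per scale.
    """
    stack = build_scale_family(micrograph, config)
    diffs: list[np.ndarray] = []
    meta: list[tuple[int, int, float]] = []
    for u, _s_u, layer in stack.layers:
        sigmas = [
            config.sigma_base * 2.0 ** (j / config.scales_per_octave)
            for j in range(config.scales_per_octave)
        ]
        octave = [gaussian_blur(layer, s) for s in sigmas]
        for j, d in enumerate(dog_to_last(octave)):
            diffs.append(d)
            meta.append((u, j, sigmas[j]))
    return assemble_feature_matrix(diffs, stack.origin_shape, meta)
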
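"""Phase II: Otsu segmentation, size-gated candidates, radial border
profiles, and cepstrum-based false-positive filtering.

Candidates are the connected components of the thresholded background
channel (where each region of interest shows a well-delineated centroid);
border evidence is read from the structure channel's binary image along
concentric rays, and a polar-unwrapped intensity patch around each centroid
is screened with a cepstrum / spectral-coherence test that favors closed
borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

_EPS = 1e-8
MAX_RADIUS = 50  # published search-radius bound, in pixels


@dataclass
class PickingConfig:
    area_min: int = 100
    area_max: int = 1500
    radius: int = 50
    n_rays: int = 64
    connectivity: int = 8
    cepstrum_accept_threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.area_min <= 0 or self.area_max <= 0:
            raise ConfigurationError("area bounds must be positive")
        if self.area_min >= self.area_max:
            raise ConfigurationError("area_min must be < area_max")
        if not 0 < self.radius <= MAX_RADIUS:
            raise ConfigurationError(f"radius must lie in (0, {MAX_RADIUS}]")
        if self.n_rays < 4:
            raise ConfigurationError("n_rays must be >= 4")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")


class OtsuResult(NamedTuple):
    threshold: float
    binary: np.ndarray
    degenerate: bool


@dataclass
class BinaryPair:
    """Thresholded structure (B1) and background (B2) channels."""

    B1: np.ndarray
    B2: np.ndarray
    t1: float
    t2: float


@dataclass
class RegionCandidate:
    """A size-gated connected region with its border evidence."""

    label: int
    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray | None = None  # component pixels inside bbox
    profiles: np.ndarray | None = None  # n_rays x r binary ray samples
    border_distances: np.ndarray | None = None  # first-impulse step per ray
    polar_patch: np.ndarray | None = None  # n_rays x r intensities
    cepstrum_score: float = field(default=0.0)
    accepted: bool = field(default=False)


def otsu_threshold(image: np.ndarray) -> OtsuResult:
    """Otsu's threshold over 256 uniform bins on [0, 1].

    Returns the bin edge maximizing the between-class variance and the
    binary image ``image >= threshold``. A constant image yields its own
    value as threshold, an empty foreground, and the degenerate flag.
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise InvalidInputError("otsu_threshold expects intensities in [0, 1]")
    if img.min() == img.max():
        return OtsuResult(float(img.flat[0]), np.zeros(img.shape, dtype=bool), True)
    counts, edges = np.histogram(img, bins=256, range=(0.0, 1.0))
    w = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(w)[:-1]  # class 0 = bins < t, for t = 1..255
    w1 = 1.0 - w0
    cummean = np.cumsum(w * centers)[:-1]
    mu = cummean[-1] + w[-1] * centers[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = np.where(
            (w0 > 0) & (w1 > 0), (mu * w0 - cummean) ** 2 / (w0 * w1), -np.inf
        )
    t_star = int(np.argmax(var_b)) + 1
    threshold = float(edges[t_star])
    return OtsuResult(threshold, img >= threshold, False)


def extract_candidates(
    binary_structure: np.ndarray,
    binary_background: np.ndarray,
    channel_background: np.ndarray,
    config: PickingConfig,
) -> list[RegionCandidate]:
    """Label B2's connected components and keep those inside the area gate.

    The area gate is inclusive at both bounds. Candidates are returned
    sorted by centroid (row, col) so downstream processing is
    deterministic.
    """
    B2 = np.asarray(binary_background, dtype=bool)
    if B2.shape != np.asarray(binary_structure).shape or B2.shape != np.asarray(
        channel_background
    ).shape:
        raise InvalidInputError("picking inputs must share one shape")
    structure = (
        np.ones((3, 3), dtype=int)
        if config.connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n_labels = ndimage.label(B2, structure=structure)
    if n_labels == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(
        (areas >= config.area_min) & (areas <= config.area_max)
    ) + 1
    if keep.size == 0:
        return []
    centroids = ndimage.center_of_mass(B2, labels, keep)
    slices = ndimage.find_objects(labels)
    out = []
    for lab, (cr, cc) in zip(keep, centroids):
        sl = slices[lab - 1]
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        out.append(
            RegionCandidate(
                label=int(lab),
                centroid=(float(cr), float(cc)),
                area=int(areas[lab - 1]),
                bbox=bbox,
                mask=(labels[sl] == lab),
            )
        )
    out.sort(key=lambda c: c.centroid)
    return out


def _ray_samples(
    centroid: tuple[float, float], n_rays: int, radius: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-pixel indices along n_rays rays at steps 1..r; OOB flagged."""
    angles = 2.0 * np.pi * np.arange(n_rays) / n_rays
    steps = np.arange(1, radius + 1)
    rows = np.rint(centroid[0] + np.sin(angles)[:, None] * steps[None, :]).astype(int)
    cols = np.rint(centroid[1] + np.cos(angles)[:, None] * steps[None, :]).astype(int)
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows, cols, inside


def radial_profiles(
    binary: np.ndarray, centroid: tuple[float, float], config: PickingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a binary image along concentric rays and locate the border.

    The border distance of ray i is the step of the first positive impulse
    of the discrete derivative of its profile (the centroid pixel acts as
    step 0); rays without any impulse report 0.
    """
    B = np.asarray(binary, dtype=bool)
    r0, c0 = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= r0 < B.shape[0] and 0 <= c0 < B.shape[1]):
        raise InvalidInputError("centroid lies outside the image")
    rows, cols, inside = _ray_samples(centroid, config.n_rays, config.radius, B.shape)
    profiles = np.zeros((config.n_rays, config.radius), dtype=np.int8)
    profiles[inside] = B[rows[inside], cols[inside]]
    start = np.full((config.n_rays, 1), int(B[r0, c0]), dtype=np.int8)
    deriv = np.diff(np.concatenate([start, profiles], axis=1), axis=1)
    positive = deriv > 0
    d = np.where(positive.any(axis=1), positive.argmax(axis=1) + 1, 0)
    return profiles, d.astype(int)


def polar_unwrap(
    channel: np.ndarray, centroid: tuple[float, float], config: PickingConfig
) -> np.ndarray:
    """Unwrap intensities around a centroid into an n_rays x r polar patch."""
    W = np.asarray(channel, dtype=np.float64)
    r0, c0 = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= r0 < W.shape[0] and 0 <= c0 < W.shape[1]):
        raise InvalidInputError("centroid lies outside the image")
    rows, cols, inside = _ray_samples(centroid, config.n_rays, config.radius, W.shape)
    patch = np.zeros((config.n_rays, config.radius), dtype=np.float64)
    patch[inside] = W[rows[inside], cols[inside]]
    return patch


def cepstrum_accept(
    polar_patch: np.ndarray, config: PickingConfig
) -> tuple[float, bool]:
    """Score the cross-ray coherence of a polar patch and gate it.

    The cepstrum C = log|F(patch)| is formed (magnitude floored) and its
    inverse transform is asserted to be purely real, which holds for any
    real patch. The discriminative score is the fraction of non-DC spectral
    power of the standardized patch carried by the low angular harmonics
    (|k| <= 2): a closed border is a band coherent across all rays and
    concentrates power there, while noise spreads it over all harmonics.
    """
    G = np.asarray(polar_patch, dtype=np.float64)
    if not np.all(np.isfinite(G)):
        raise InvalidInputError("polar patch contains non-finite values")
    sd = G.std()
    if sd < 1e-12:
        return 0.0, False
    G = (G - G.mean()) / sd
    F = np.fft.fft2(G)
    C = np.log(np.maximum(np.abs(F), _EPS))
    inv = np.fft.ifft2(C)
    if np.abs(inv.imag).max() >= 1e-6 * max(np.abs(inv.real).max(), _EPS):
        raise AssertionError("cepstrum realness constraint violated for real patch")
    P = np.abs(F) ** 2
    P[0, 0] = 0.0
    total = P.sum()
    if total <= 0:
        return 0.0, False
    k_ang = np.fft.fftfreq(G.shape[0]) * G.shape[0]
    score = float(P[np.abs(k_ang) <= 2].sum() / total)
    return score, score >= config.cepstrum_accept_threshold


def analyze_candidate(
    candidate: RegionCandidate,
    binary_structure: np.ndarray,
    channel_background: np.ndarray,
    config: PickingConfig,
) -> RegionCandidate:
    """Fill border profiles, polar patch and the cepstrum decision in place."""
    candidate.profiles, candidate.border_distances = radial_profiles(
        binary_structure, candidate.centroid, config
    )
    candidate.polar_patch = polar_unwrap(
        channel_background, candidate.centroid, config
    )
    candidate.cepstrum_score, candidate.accepted = cepstrum_accept(
        candidate.polar_patch, config
    )
    return candidate


def pick_candidates(
    W1: np.ndarray, W2: np.ndarray, config: PickingConfig
) -> tuple[list[RegionCandidate], BinaryPair | None]:
    """Run Phase II on a channel pair: threshold, gate, profile, filter.

    Channels are affinely normalized to [0, 1] before Otsu. A degenerate
    (constant) channel aborts picking with a warning rather than an error.
    """
    chans = []
    for W in (W1, W2):
        W = np.asarray(W, dtype=np.float64)
        lo, hi = W.min(), W.max()
        chans.append(np.zeros_like(W) if hi == lo else (W - lo) / (hi - lo))
    t1, B1, deg1 = otsu_threshold(chans[0])
    t2, B2, deg2 = otsu_threshold(chans[1])
    if deg1 or deg2:
        logger.warning("degenerate Otsu threshold; skipping picking on this image")
        return [], None
    pair = BinaryPair(B1=B1, B2=B2, t1=t1, t2=t2)
    candidates = extract_candidates(B1, B2, chans[1], config)
    for cand in candidates:
        analyze_candidate(cand, B1, chans[1], config)
    n_acc = sum(c.accepted for c in candidates)
    logger.info("picking: %d candidates, %d accepted", len(candidates), n_acc)
    return candidates, pair
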
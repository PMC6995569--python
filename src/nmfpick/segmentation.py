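"""Phase III: border closing by geodesic distance, Fourier boundary
smoothing, direct least-squares ellipse fitting, and view classification.

Each accepted candidate's region is reduced to a border band, the geodesic
distance from the centroid is propagated through the non-border domain
(which closes open borders, since leakage through a gap travels farther
than the direct path), the level set at three times the median border
distance is traced as a closed curve, low-pass filtered at 98% of its
spectral energy, and fitted with an ellipse whose aspect ratio separates
top (round) from side (elongated) views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric
from skimage.measure import EllipseModel, find_contours

from .errors import CandidateRejected, EllipseFitError, InvalidInputError
from .picking import RegionCandidate


@dataclass
class SegmentationConfig:
    energy_fraction: float = 0.98
    view_aspect_threshold: float = 1.5
    critical_distance_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.energy_fraction <= 1:
            raise InvalidInputError("energy_fraction must lie in (0, 1]")
        if self.view_aspect_threshold <= 1:
            raise InvalidInputError("view_aspect_threshold must be > 1")
        if self.critical_distance_multiplier <= 0:
            raise InvalidInputError("critical_distance_multiplier must be positive")


@dataclass
class GeodesicMap:
    distances: np.ndarray  # +inf where unreachable or on the border
    source: tuple[int, int]


@dataclass
class BoundaryCurve:
    points: np.ndarray  # (N, 2) array of (row, col), closed, no repeated endpoint
    is_closed: bool = True

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class EllipseParams:
    """Geometric ellipse parameters; (cx, cy) = (col, row) in pixels."""

    cx: float
    cy: float
    a: float  # semi-major
    b: float  # semi-minor
    theta: float  # radians in [0, pi); 0 by convention for circles

    @property
    def aspect(self) -> float:
        return self.a / self.b


@dataclass
class ParticleRecord:
    candidate: RegionCandidate
    ellipse: EllipseParams
    view: str  # "top" or "side"
    boundary: BoundaryCurve


def erase_interior(mask: np.ndarray, centroid: tuple[float, float] | None = None) -> np.ndarray:
    """Remove pixels whose full 8-neighborhood is foreground.

    Leaves a 1-2 px border band; realized as the complement of the
    morphological erosion interior, which is the parameter-free equivalent
    of superposing an internal polygon on the centroid.
    """
    del centroid  # the erosion interior needs no anchor point
    m = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return m & ~interior


def geodesic_map(border_mask: np.ndarray, source: tuple[float, float]) -> GeodesicMap:
    """8-neighbor chamfer geodesic distance (steps 1 and sqrt(2)).

    The traversable domain is the non-border set; border pixels and any
    region unreachable from the source stay at +inf.
    """
    B = np.asarray(border_mask, dtype=bool)
    r0, c0 = int(round(source[0])), int(round(source[1]))
    if not (0 <= r0 < B.shape[0] and 0 <= c0 < B.shape[1]):
        raise InvalidInputError("source lies outside the grid")
    if B[r0, c0]:
        raise InvalidInputError("source lies on a border pixel")
    costs = np.where(B, np.inf, 1.0)
    mcp = MCP_Geometric(costs, fully_connected=True)
    cum, _ = mcp.find_costs([(r0, c0)])
    cum = np.asarray(cum, dtype=np.float64)
    cum[B] = np.inf
    return GeodesicMap(distances=cum, source=(r0, c0))


def extract_boundary(
    gmap: GeodesicMap,
    candidate: RegionCandidate,
    config: SegmentationConfig | None = None,
) -> BoundaryCurve:
    """Trace the region enclosed by the geodesic level set.

    The critical distance is ``critical_distance_multiplier`` times the
    median of the candidate's positive per-ray border distances; the outer
    contour of ``{g <= D}`` is returned as a closed curve. Candidates with
    no border evidence on any ray are rejected.
    """
    config = config or SegmentationConfig()
    d = candidate.border_distances
    if d is None or not np.any(np.asarray(d) > 0):
        raise CandidateRejected(
            f"candidate {candidate.label}: no border impulse on any ray"
        )
    d = np.asarray(d)
    D = config.critical_distance_multiplier * float(np.median(d[d > 0]))
    region = np.isfinite(gmap.distances) & (gmap.distances <= D)
    if not region.any():
        raise CandidateRejected(f"candidate {candidate.label}: empty level set")
    contours = find_contours(region.astype(np.float64), 0.5)
    closed = [
        c for c in contours if len(c) > 8 and np.allclose(c[0], c[-1])
    ]
    if not closed:
        raise CandidateRejected(
            f"candidate {candidate.label}: no closed level-set contour"
        )
    curve = max(closed, key=len)[:-1]  # drop the repeated endpoint
    return BoundaryCurve(points=np.asarray(curve, dtype=np.float64), is_closed=True)


def fourier_smooth(
    boundary: BoundaryCurve, energy_fraction: float = 0.98
) -> BoundaryCurve:
    """Low-pass a closed boundary, keeping >= the requested energy share.

    The curve is taken as the complex sequence x + iy (centroid removed);
    symmetric harmonic groups (+k, -k) are retained in ascending frequency
    until their cumulative energy reaches the requested fraction of the
    total non-DC energy, the rest are zeroed, and the curve is rebuilt.
    """
    if not boundary.is_closed:
        raise InvalidInputError("fourier_smooth requires a closed boundary")
    pts = np.asarray(boundary.points, dtype=np.float64)
    if len(pts) < 8:
        raise InvalidInputError("boundary must have at least 8 points")
    z = pts[:, 1] + 1j * pts[:, 0]  # x + iy
    center = z.mean()
    Z = np.fft.fft(z - center)
    N = len(Z)
    harmonic = np.abs(np.fft.fftfreq(N) * N)  # 0, 1, ..., N/2, ..., 1
    energy = np.abs(Z) ** 2
    total = energy.sum()
    if total <= 0:
        return BoundaryCurve(points=pts.copy(), is_closed=True)
    keep = np.zeros(N, dtype=bool)
    keep[harmonic == 0] = True  # centroid term (zero after centering)
    acc = 0.0
    for h in np.unique(harmonic[harmonic > 0]):
        sel = harmonic == h
        keep[sel] = True
        acc += energy[sel].sum()
        if acc >= energy_fraction * total:
            break
    z_smooth = np.fft.ifft(np.where(keep, Z, 0.0)) + center
    out = np.column_stack([z_smooth.imag, z_smooth.real])
    return BoundaryCurve(points=out, is_closed=True)


def _conic_residuals(pts_xy: np.ndarray, e: EllipseParams) -> np.ndarray:
    """Normalized algebraic residuals of points against an ellipse's conic."""
    ct, st = np.cos(e.theta), np.sin(e.theta)
    x = pts_xy[:, 0] - e.cx
    y = pts_xy[:, 1] - e.cy
    u = (x * ct + y * st) / e.a
    v = (-x * st + y * ct) / e.b
    return np.abs(u**2 + v**2 - 1.0)


def _direct_fit(pts_xy: np.ndarray) -> EllipseParams:
    model = EllipseModel.from_estimate(pts_xy)
    if not model:
        raise EllipseFitError("degenerate point set: direct ellipse fit failed")
    (cx, cy), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([cx, cy, a, b, theta]).all() and a > 0 and b > 0):
        raise EllipseFitError("fit produced a non-ellipse conic")
    if a < b:
        a, b = b, a
        theta += np.pi / 2
    theta = float(np.mod(theta, np.pi))
    if abs(a - b) <= 1e-9 * a:
        theta = 0.0  # circles carry no orientation
    return EllipseParams(cx=float(cx), cy=float(cy), a=float(a), b=float(b), theta=theta)


def fit_ellipse(points: np.ndarray | BoundaryCurve) -> EllipseParams:
    """Direct least-squares (Fitzgibbon-type) ellipse fit with one
    median-residual outlier-rejection pass.

    ``points`` are (row, col) pairs. After the first fit, points with
    algebraic residual above twice the median absolute residual are
    dropped and the model is refitted, provided at least 5 points remain.
    """
    if isinstance(points, BoundaryCurve):
        points = points.points
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EllipseFitError("ellipse fitting needs at least 5 (row, col) points")
    pts_xy = pts[:, ::-1]  # (x, y) = (col, row)
    first = _direct_fit(pts_xy)
    res = _conic_residuals(pts_xy, first)
    med = float(np.median(res))
    if med > 0:
        inliers = res <= 2.0 * med
        if inliers.sum() >= 5 and inliers.sum() < len(pts_xy):
            return _direct_fit(pts_xy[inliers])
    return first


def classify_view(ellipse: EllipseParams, view_aspect_threshold: float = 1.5) -> str:
    """Round projections (aspect < threshold) are top views, else side."""
    return "top" if ellipse.aspect < view_aspect_threshold else "side"


def segment_candidate(
    candidate: RegionCandidate,
    border_binary: np.ndarray,
    config: SegmentationConfig | None = None,
    window_pad: int = 56,
) -> ParticleRecord:
    """Run Phase III for one accepted candidate.

    Works in a padded window around the centroid: the border band is the
    structure-channel binary restricted to the window, augmented with the
    candidate's own eroded outline, the geodesic level set closes it, and
    the traced, smoothed boundary is fitted with an ellipse.
    """
    config = config or SegmentationConfig()
    B = np.asarray(border_binary, dtype=bool)
    m, n = B.shape
    cr, cc = candidate.centroid
    r0 = max(0, int(round(cr)) - window_pad)
    c0 = max(0, int(round(cc)) - window_pad)
    r1 = min(m, int(round(cr)) + window_pad + 1)
    c1 = min(n, int(round(cc)) + window_pad + 1)
    window = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)  # 1 px guard ring
    window[1:-1, 1:-1] = B[r0:r1, c0:c1]
    window = erase_interior(window)  # filled blobs become border bands
    local = (cr - r0 + 1, cc - c0 + 1)
    li, lj = int(round(local[0])), int(round(local[1]))
    if window[li, lj]:
        window[li, lj] = False  # centroid must be a traversable source
    gmap = geodesic_map(window, local)
    raw = extract_boundary(gmap, candidate, config)
    smooth = fourier_smooth(raw, config.energy_fraction)
    shifted = smooth.points + np.array([r0 - 1, c0 - 1])
    ellipse = fit_ellipse(shifted)
    view = classify_view(ellipse, config.view_aspect_threshold)
    return ParticleRecord(
        candidate=candidate,
        ellipse=ellipse,
        view=view,
        boundary=BoundaryCurve(points=shifted, is_closed=True),
    )
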
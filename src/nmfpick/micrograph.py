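"""In-memory micrograph container and intensity normalization."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

MIN_DIM = 8


@dataclass
class Micrograph:
    """A single 2D micrograph.

    Parameters
    ----------
    pixels:
        Real-valued intensity grid of shape ``(m, n)`` with ``m, n >= 8``.
    pixel_size_angstrom:
        Physical pixel size at the specimen, if known.
    source_path:
        Provenance of the image, if it was read from disk.
    degenerate:
        Set by :func:`normalize` when the input had zero dynamic range.
    """

    pixels: np.ndarray
    pixel_size_angstrom: float | None = None
    source_path: str | None = None
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InvalidInputError(
                f"micrograph must be 2D, got shape {self.pixels.shape}"
            )
        m, n = self.pixels.shape
        if m < MIN_DIM or n < MIN_DIM:
            raise InvalidInputError(
                f"micrograph must be at least {MIN_DIM}x{MIN_DIM}, got {m}x{n}"
            )
        if self.pixel_size_angstrom is not None and self.pixel_size_angstrom <= 0:
            raise InvalidInputError("pixel_size_angstrom must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize(micrograph: Micrograph) -> Micrograph:
    """Affinely rescale intensities to [0, 1] (min -> 0, max -> 1).

    A constant image maps to all zeros and is flagged ``degenerate``.
    NaN or infinite pixels are rejected.
    """
    px = micrograph.pixels
    if not np.all(np.isfinite(px)):
        raise InvalidInputError("micrograph contains NaN or infinite pixels")
    lo = px.min()
    hi = px.max()
    if hi == lo:
        return replace(micrograph, pixels=np.zeros_like(px), degenerate=True)
    return replace(micrograph, pixels=(px - lo) / (hi - lo), degenerate=False)


def invert(micrograph: Micrograph) -> Micrograph:
    """Flip contrast of a normalized micrograph (dark particles -> bright)."""
    px = micrograph.pixels
    if px.min() < 0 or px.max() > 1:
        raise InvalidInputError("invert expects a normalized micrograph in [0, 1]")
    return replace(micrograph, pixels=1.0 - px)
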
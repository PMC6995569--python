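"""File I/O: micrographs (MRC/TIFF/PNG), pick coordinates (.box/.star/.csv)
and ground-truth tables.

Internal coordinates are 0-based (row, col) with a top-left origin;
exported x = col. The EMAN .box writer performs the bottom-left origin
flip that format expects.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .micrograph import Micrograph
from .segmentation import ParticleRecord
from .synthetic import GroundTruthParticle

_MRC_EXT = {".mrc", ".map", ".mrcs"}
_IMG_EXT = {".tif", ".tiff", ".png"}


def read_micrograph(path: str | os.PathLike) -> Micrograph:
    """Read a 2D micrograph from MRC (modes 0/1/2), TIFF or PNG."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    ext = path.suffix.lower()
    if ext in _MRC_EXT:
        try:
            ccp4 = gemmi.read_ccp4_map(str(path))
        except Exception as exc:  # gemmi raises bare RuntimeError
            raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
        arr = np.array(ccp4.grid, copy=True)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise FormatError(
                f"{path}: 3D MRC stacks are not supported; expected a single 2D image"
            )
        cell = ccp4.grid.unit_cell
        nu = ccp4.grid.nu
        pixel_size = None
        if cell.a > 0 and not np.isclose(cell.a, 1.0):
            pixel_size = float(cell.a / nu) if nu else None
        return Micrograph(
            pixels=arr.astype(np.float64),
            pixel_size_angstrom=pixel_size,
            source_path=str(path),
        )
    if ext in _IMG_EXT:
        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:
            raise FormatError(f"cannot read image file {path}: {exc}") from exc
        if arr.ndim == 3 and arr.shape[2] in (3, 4):
            arr = arr[..., :3].mean(axis=2)
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected a single 2D grayscale image")
        return Micrograph(pixels=arr.astype(np.float64), source_path=str(path))
    raise FormatError(f"unsupported micrograph format: {path}")


def write_micrograph(
    micrograph: Micrograph, path: str | os.PathLike, dtype: str = "float32"
) -> None:
    """Write a micrograph as MRC mode 2 (float32) or 16-bit TIFF."""
    path = Path(path)
    ext = path.suffix.lower()
    px = micrograph.pixels
    if ext in _MRC_EXT:
        ccp4 = gemmi.Ccp4Map()
        data = px.astype(np.float32)[None, :, :]  # nz = 1
        ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(data))
        if micrograph.pixel_size_angstrom:
            ps = micrograph.pixel_size_angstrom
            ccp4.grid.unit_cell = gemmi.UnitCell(
                ps * data.shape[0], ps * data.shape[1], ps * data.shape[2], 90, 90, 90
            )
        ccp4.update_ccp4_header()
        ccp4.write_ccp4_map(str(path))
    elif ext in {".tif", ".tiff"}:
        lo, hi = px.min(), px.max()
        scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    else:
        raise ConfigurationError(f"unsupported output format: {path}")


def _box_size(record: ParticleRecord) -> int:
    return 2 * int(np.ceil(record.ellipse.a)) + 4


def write_picks(
    particles: list[ParticleRecord],
    path: str | os.PathLike,
    format: str = "csv",
    image_shape: tuple[int, int] | None = None,
) -> None:
    """Write particle records as EMAN .box, STAR coordinates, or CSV.

    .box uses a bottom-left origin (y flipped over the image height, which
    must be supplied); STAR and CSV use the internal top-left origin with
    x = col.
    """
    path = Path(path)
    if format == "box":
        if image_shape is None:
            raise ConfigurationError(".box output requires image_shape for the y flip")
        m = image_shape[0]
        lines = []
        for p in particles:
            box = _box_size(p)
            cr, cc = p.candidate.centroid
            x = int(round(cc - box / 2))
            y = int(round((m - 1) - cr - box / 2))
            lines.append(f"{x}\t{y}\t{box}\t{box}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "star":
        header = [
            "data_",
            "",
            "loop_",
            "_rlnCoordinateX #1",
            "_rlnCoordinateY #2",
        ]
        rows = [
            f"{p.candidate.centroid[1]:.3f}\t{p.candidate.centroid[0]:.3f}"
            for p in particles
        ]
        path.write_text("\n".join(header + rows) + "\n")
    elif format == "csv":
        df = pd.DataFrame(
            [
                {
                    "row": p.candidate.centroid[0],
                    "col": p.candidate.centroid[1],
                    "semi_major": p.ellipse.a,
                    "semi_minor": p.ellipse.b,
                    "theta_deg": np.degrees(p.ellipse.theta),
                    "view": p.view,
                    "cepstrum_score": p.candidate.cepstrum_score,
                    "area": p.candidate.area,
                }
                for p in particles
            ],
            columns=[
                "row",
                "col",
                "semi_major",
                "semi_minor",
                "theta_deg",
                "view",
                "cepstrum_score",
                "area",
            ],
        )
        df.to_csv(path, index=False, float_format="%.9f")
    else:
        raise ConfigurationError(f"unknown picks format: {format!r}")


def read_picks_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a CSV picks table."""
    return pd.read_csv(path)


def read_coords(
    path: str | os.PathLike, image_shape: tuple[int, int] | None = None
) -> list[tuple[float, float]]:
    """Read (row, col) coordinates from a CSV or EMAN .box file."""
    path = Path(path)
    if path.suffix.lower() == ".box":
        if image_shape is None:
            raise ConfigurationError(".box input requires image_shape for the y flip")
        m = image_shape[0]
        coords = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            x, y, w, h = (float(v) for v in line.split()[:4])
            coords.append(((m - 1) - y - h / 2, x + w / 2))
        return coords
    df = pd.read_csv(path)
    if {"row", "col"} <= set(df.columns):
        return list(zip(df["row"].astype(float), df["col"].astype(float)))
    if {"x", "y"} <= set(df.columns):
        return list(zip(df["y"].astype(float), df["x"].astype(float)))
    raise FormatError(f"{path}: expected columns row/col or x/y")


def write_truth(
    truth: list[GroundTruthParticle], path: str | os.PathLike
) -> None:
    """Write ground-truth particles as CSV (row, col, view, orientation, dims)."""
    df = pd.DataFrame(
        [
            {
                "row": t.center[0],
                "col": t.center[1],
                "view": t.view,
                "orientation": t.orientation,
                "dim1": t.dims[0],
                "dim2": t.dims[1],
            }
            for t in truth
        ],
        columns=["row", "col", "view", "orientation", "dim1", "dim2"],
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_truth(path: str | os.PathLike) -> list[GroundTruthParticle]:
    df = pd.read_csv(path)
    return [
        GroundTruthParticle(
            center=(float(r.row), float(r.col)),
            view=str(r.view),
            orientation=float(r.orientation),
            dims=(float(r.dim1), float(r.dim2)),
        )
        for r in df.itertuples()
    ]
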
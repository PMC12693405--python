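"""Calibrated image and annotation I/O.

Conventions used throughout the package:

* Pixel centers sit at integer coordinates; the origin is the top-left
  pixel center, ``x`` runs rightward (columns), ``y`` downward (rows).
* ImageJ ROI vertices address pixel *corners*; they are shifted by
  (-0.5, -0.5) on read so that an ImageJ rectangle covering pixels
  ``0..9`` maps onto our pixel-center convention.
* Physical calibration is a single isotropic ``scale`` in µm/pixel,
  always supplied by the caller (SEM vendors rarely embed it portably).
"""

from __future__ import annotations

import struct
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibratedImage",
    "PolygonRoi",
    "Polyline",
    "StudyRecord",
    "load_image",
    "save_image",
    "read_rois",
    "write_imagej_roi",
    "write_imagej_roi_zip",
    "rasterize_roi",
    "polygon_area",
    "write_measurements",
    "read_measurements",
]


@dataclass
class CalibratedImage:
    """A 2D grayscale image with a physical pixel-size calibration.

    Parameters
    ----------
    pixels
        2D array of intensities (any real dtype; kept as loaded).
    scale
        Pixel size in µm/pixel. Must be positive.
    bit_depth
        Bit depth of the source data (8 or 16 for integer TIFFs; 0 for
        synthetic float images).
    source_id
        Identifier for provenance (file stem or simulator tag).
    """

    pixels: np.ndarray
    scale: float
    bit_depth: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be a positive µm/pixel value, got {self.scale}")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("image intensities must be finite")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_float(self) -> np.ndarray:
        """Intensities as float64, normalized to [0, 1] by bit depth when known."""
        data = np.asarray(self.pixels, dtype=np.float64)
        if self.bit_depth in (8, 16):
            return data / float(2**self.bit_depth - 1)
        lo, hi = float(data.min()), float(data.max())
        if hi > lo:
            return (data - lo) / (hi - lo)
        return np.zeros_like(data)

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        return CalibratedImage(pixels=pixels, scale=self.scale,
                               bit_depth=self.bit_depth, source_id=self.source_id)


@dataclass
class PolygonRoi:
    """A closed polygon region of interest, vertices in pixel coordinates."""

    vertices: np.ndarray  # (n, 2) float array of (x, y)
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("polygon vertices must be finite")


@dataclass
class Polyline:
    """An open polyline (profile path), vertices in pixel coordinates."""

    vertices: np.ndarray  # (n, 2) float array of (x, y)
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        if self.length_px <= 0:
            raise ValueError("polyline must have positive length")

    @property
    def length_px(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class StudyRecord:
    """Maps one micrograph to its glomerulus, mouse and experimental group."""

    image_id: str
    glomerulus_id: str
    mouse_id: str
    group: str
    covariates: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# images


def load_image(path: str | Path, scale: float) -> CalibratedImage:
    """Read a single-channel TIFF (8- or 16-bit) as a :class:`CalibratedImage`.

    Multi-channel inputs are collapsed to luminance with a warning.
    """
    path = Path(path)
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel image collapsed to luminance")
        data = data.mean(axis=-1 if data.shape[-1] in (3, 4) else 0)
    if data.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {data.ndim}")
    if data.dtype == np.uint8:
        depth = 8
    elif data.dtype == np.uint16:
        depth = 16
    else:
        depth = 0
    return CalibratedImage(pixels=data, scale=scale, bit_depth=depth,
                           source_id=path.stem)


def save_image(image: CalibratedImage, path: str | Path) -> None:
    """Write the raw pixel grid to TIFF (dtype preserved)."""
    tifffile.imwrite(str(path), np.asarray(image.pixels))


# ---------------------------------------------------------------------------
# ImageJ .roi codec
#
# Binary layout follows the public ImageJ RoiDecoder format: a 64-byte
# big-endian header ("Iout", version, type, bounding box, vertex count)
# followed by int16 x- then y-offsets relative to the bounding box.

_IJ_MAGIC = b"Iout"
_IJ_POLYGON = 0
_IJ_POLYLINE = 5
_IJ_VERSION = 227
_IJ_OPTIONS_OFFSET = 50
_IJ_SUB_PIXEL = 128


def _decode_imagej_roi(buf: bytes, label: str) -> PolygonRoi | Polyline:
    if buf[:4] != _IJ_MAGIC:
        raise ValueError(f"{label}: not an ImageJ ROI (bad magic)")
    roi_type = buf[6]
    top, left, bottom, right = struct.unpack(">4h", buf[8:16])
    n = struct.unpack(">H", buf[16:18])[0]
    if roi_type not in (_IJ_POLYGON, _IJ_POLYLINE):
        raise ValueError(f"{label}: unsupported ImageJ ROI type {roi_type} "
                         "(only polygon and polyline are handled)")
    if n < 2:
        raise ValueError(f"{label}: corrupt ROI record (n={n})")
    off = 64
    options = struct.unpack(">H", buf[_IJ_OPTIONS_OFFSET:_IJ_OPTIONS_OFFSET + 2])[0]
    if options & _IJ_SUB_PIXEL and len(buf) >= off + 4 * n + 8 * n:
        foff = off + 4 * n
        xs = np.frombuffer(buf, dtype=">f4", count=n, offset=foff).astype(float)
        ys = np.frombuffer(buf, dtype=">f4", count=n, offset=foff + 4 * n).astype(float)
    else:
        xs = np.frombuffer(buf, dtype=">i2", count=n, offset=off).astype(float) + left
        ys = np.frombuffer(buf, dtype=">i2", count=n, offset=off + 2 * n).astype(float) + top
    # corner -> pixel-center convention
    verts = np.column_stack([xs - 0.5, ys - 0.5])
    if roi_type == _IJ_POLYGON:
        return PolygonRoi(vertices=verts, label=label)
    return Polyline(vertices=verts, label=label)


def _encode_imagej_roi(roi: PolygonRoi | Polyline) -> bytes:
    """Encode with sub-pixel (float) coordinates so arbitrary vertices
    round-trip exactly; integer coordinates are kept for plain readers."""
    verts = np.asarray(roi.vertices, dtype=float) + 0.5  # center -> corner
    xs = np.floor(verts[:, 0]).astype(int)
    ys = np.floor(verts[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    roi_type = _IJ_POLYGON if isinstance(roi, PolygonRoi) else _IJ_POLYLINE
    header = bytearray(64)
    header[:4] = _IJ_MAGIC
    struct.pack_into(">h", header, 4, _IJ_VERSION)
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    struct.pack_into(">H", header, _IJ_OPTIONS_OFFSET, _IJ_SUB_PIXEL)
    body = b"".join([
        np.asarray(xs - left, dtype=">i2").tobytes(),
        np.asarray(ys - top, dtype=">i2").tobytes(),
        np.asarray(verts[:, 0], dtype=">f4").tobytes(),
        np.asarray(verts[:, 1], dtype=">f4").tobytes(),
    ])
    return bytes(header) + body


def write_imagej_roi(roi: PolygonRoi | Polyline, path: str | Path) -> None:
    Path(path).write_bytes(_encode_imagej_roi(roi))


def write_imagej_roi_zip(rois: Sequence[PolygonRoi | Polyline], path: str | Path) -> None:
    """Write a RoiSet.zip-style archive; entries named from each ROI label."""
    with zipfile.ZipFile(str(path), "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois):
            name = roi.label or f"roi_{i:03d}"
            zf.writestr(f"{name}.roi", _encode_imagej_roi(roi))


def _parse_text_polygon(text: str, label: str, closed: bool) -> PolygonRoi | Polyline:
    pairs = [p for p in text.replace("\n", " ").split() if p.strip()]
    verts = np.array([[float(v) for v in p.split(",")] for p in pairs])
    if closed:
        return PolygonRoi(vertices=verts, label=label)
    return Polyline(vertices=verts, label=label)


def read_rois(path: str | Path, dialect: str | None = None,
              ) -> list[PolygonRoi | Polyline]:
    """Read ROIs from an ImageJ ``.roi`` file, a RoiSet ``.zip``, or a plain
    text polygon file (``x,y x,y ...``, one ROI per line; prefix a line with
    ``line:`` for an open polyline).

    ``dialect`` is one of ``imagej-roi``, ``imagej-zip``, ``text-polygon`` or
    ``None`` to infer from the file suffix.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".roi": "imagej-roi", ".zip": "imagej-zip"}.get(suffix, "text-polygon")
    if dialect == "imagej-roi":
        return [_decode_imagej_roi(path.read_bytes(), path.stem)]
    if dialect == "imagej-zip":
        out: list[PolygonRoi | Polyline] = []
        with zipfile.ZipFile(str(path)) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    out.append(_decode_imagej_roi(zf.read(name), Path(name).stem))
        if not out:
            raise ValueError(f"{path}: zip archive contains no .roi entries")
        return out
    if dialect == "text-polygon":
        out = []
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            closed = True
            if line.startswith("line:"):
                closed = False
                line = line[len("line:"):]
            out.append(_parse_text_polygon(line, f"{path.stem}_{i}", closed))
        if not out:
            raise ValueError(f"{path}: no ROI records found")
        return out
    raise ValueError(f"unsupported ROI dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# rasterization


def polygon_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (absolute value, px²)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def points_in_polygon(points_x: np.ndarray, points_y: np.ndarray,
                      vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points.

    A point on a horizontal edge or exactly at a vertex follows the standard
    half-open ray-crossing rule, which assigns every boundary point to
    exactly one side deterministically.
    """
    x = np.asarray(points_x, dtype=float)
    y = np.asarray(points_y, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (x < np.where(cond, xint, np.inf))
    return inside


def rasterize_roi(roi: PolygonRoi, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centers lie inside the polygon (even-odd)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # restrict to the bounding box for speed
    v = roi.vertices
    x0 = max(0, int(np.floor(v[:, 0].min())))
    x1 = min(w - 1, int(np.ceil(v[:, 0].max())))
    y0 = max(0, int(np.floor(v[:, 1].min())))
    y1 = min(h - 1, int(np.ceil(v[:, 1].max())))
    if x1 < x0 or y1 < y0:
        raise ValueError(f"ROI {roi.label!r} lies entirely outside the image")
    mask = np.zeros((h, w), dtype=bool)
    sub = points_in_polygon(xx[y0:y1 + 1, x0:x1 + 1], yy[y0:y1 + 1, x0:x1 + 1], v)
    mask[y0:y1 + 1, x0:x1 + 1] = sub
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} covers no pixel centers")
    return mask


# ---------------------------------------------------------------------------
# tabular output


def write_measurements(rows: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write measurement records as CSV with full float precision.

    An empty row list still produces a header-only file when a schema can be
    inferred (DataFrame input); a bare empty list writes an empty file with
    the standard measurement header.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=["mouse_id", "glomerulus_id", "image_id",
                                       "roi_label", "method", "value", "units",
                                       "parameters_hash"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
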
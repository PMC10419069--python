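"""Brightfield ingestion: RGB→optical density, colour deconvolution, ROIs, metadata.

Everything downstream quantifies the DAB (diaminobenzidine) optical-density
channel.  A brightfield pixel with transmitted intensity I and white reference
I0 has, per channel,

    OD = -log10((I + 1) / (I0 + 1)),  clipped at 0,

(the +1 guards saturated black pixels).  Stain separation follows
Ruifrok–Johnston colour deconvolution: the 3-vector of per-channel ODs is a
non-negative combination of unit stain vectors, so stain amounts are obtained
by inverting the 3×3 stain matrix and clipping negative projections.

Coordinate convention, fixed project-wide: 0-based pixel indices, x right,
y down; pixel (row i, col j) covers the unit square [j, j+1) × [i, i+1) and
has its center at (j + 0.5, i + 0.5); polygon containment is decided by the
pixel center (even-odd rule).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "REGIONS",
    "HEMISPHERES",
    "DEFAULT_WHITE",
    "StainVectors",
    "BrightfieldImage",
    "ODChannel",
    "RegionOutline",
    "MouseRecord",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "deconvolve_dab",
    "rasterize_polygon",
    "rasterize_roi",
    "read_image",
    "write_image",
    "read_rois",
    "write_rois",
    "read_metadata",
    "write_metadata",
]

REGIONS = ("hippocampus", "amygdala", "piriform_cortex", "somatosensory_cortex")
HEMISPHERES = ("left", "right")
GENOTYPES = ("P301S", "WT")
GROUPS = ("sonicated", "non_sonicated")

DEFAULT_WHITE = (255.0, 255.0, 255.0)

# Classic H-DAB absorbance directions (hematoxylin, DAB).
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.269, 0.568, 0.778)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


def _complete_residual(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Third stain direction orthogonal-ish complement with non-negative entries.

    Per channel c the residual is sqrt(max(0, 1 - a_c^2 - b_c^2)), then
    normalised — the rule used by the classic colour-deconvolution plugin,
    which keeps the vector physically meaningful (non-negative absorbance).
    """
    r = np.sqrt(np.clip(1.0 - a**2 - b**2, 0.0, None))
    return _unit(r)


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density directions for hematoxylin, DAB and residual."""

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]
    residual: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        h = _unit(np.asarray(self.hematoxylin, dtype=float))
        d = _unit(np.asarray(self.dab, dtype=float))
        if self.residual is None:
            r = _complete_residual(h, d)
        else:
            r = _unit(np.asarray(self.residual, dtype=float))
        for name, v in (("hematoxylin", h), ("dab", d), ("residual", r)):
            if np.any(v < 0):
                raise ValueError(f"{name} stain vector has negative components")
        object.__setattr__(self, "hematoxylin", tuple(h))
        object.__setattr__(self, "dab", tuple(d))
        object.__setattr__(self, "residual", tuple(r))
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix with one unit stain vector per row (H, DAB, residual)."""
        return np.array([self.hematoxylin, self.dab, self.residual], dtype=float)

    @classmethod
    def hdab(cls) -> "StainVectors":
        """Standard hematoxylin–DAB vectors with completed residual."""
        return cls(_HEMATOXYLIN, _DAB)


@dataclass
class BrightfieldImage:
    """H×W×3 brightfield pixels with a physical pixel size in µm/pixel.

    ``pixels`` may be uint8 or float in [0, 255]; float images preserve the
    sub-quantization precision of the synthetic renderer.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("brightfield image must be H×W×3")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ODChannel:
    """Per-pixel optical density of one stain (here: DAB), with pixel size."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ODChannel values must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.values < 0):
            raise ValueError("optical densities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rgb_to_od(
    image: BrightfieldImage | np.ndarray,
    white: Sequence[float] = DEFAULT_WHITE,
) -> np.ndarray:
    """Convert RGB intensities to per-channel optical densities.

    OD = -log10((I + 1) / (I0 + 1)) per channel, clipped at 0, so a pixel at
    the white reference has OD 0 and OD is monotone decreasing in intensity.
    """
    pixels = image.pixels if isinstance(image, BrightfieldImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an H×W×3 image")
    white = np.asarray(white, dtype=float)
    if white.shape != (3,) or np.any(white <= 0):
        raise ValueError("white reference must be 3 positive intensities")
    od = -np.log10((pixels.astype(float) + 1.0) / (white + 1.0))
    return np.clip(od, 0.0, None)


def od_to_rgb(
    od: np.ndarray, white: Sequence[float] = DEFAULT_WHITE
) -> np.ndarray:
    """Beer–Lambert inverse of :func:`rgb_to_od` (float output, no rounding)."""
    white = np.asarray(white, dtype=float)
    rgb = (white + 1.0) * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(rgb, 0.0, 255.0)


def deconvolve(od: np.ndarray, vectors: StainVectors) -> np.ndarray:
    """Project per-pixel OD vectors onto stain coordinates.

    Returns an H×W×3 array of stain amounts (H, DAB, residual), negative
    projections clipped to 0.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("expected an H×W×3 OD field")
    m = vectors.matrix
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("stain matrix is singular")
    conc = od @ np.linalg.inv(m)
    return np.clip(conc, 0.0, None)


def deconvolve_dab(
    od: np.ndarray, vectors: StainVectors, pixel_size: float = 1.0
) -> ODChannel:
    """DAB stain channel from a per-channel OD field."""
    return ODChannel(deconvolve(od, vectors)[..., 1], pixel_size)


@dataclass
class RegionOutline:
    """A named ROI polygon (vertices in pixel coordinates, x right, y down)."""

    region: str
    hemisphere: str
    polygon: np.ndarray  # (N, 2) array of (x, y)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon needs at least 3 (x, y) vertices")
        shp = _ShapelyPolygon(poly)
        if not shp.is_simple:
            raise ValueError("polygon is self-intersecting")
        if shp.area <= 0:
            raise ValueError("polygon has zero area")
        self.polygon = poly

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.polygon)


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers (x+0.5, y+0.5) lie in the polygon."""
    poly = _ShapelyPolygon(np.asarray(polygon, dtype=float))
    if poly.area <= 0:
        raise ValueError("degenerate polygon (zero area)")
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    j0 = max(int(np.floor(minx - 0.5)), 0)
    j1 = min(int(np.ceil(maxx + 0.5)), w)
    i0 = max(int(np.floor(miny - 0.5)), 0)
    i1 = min(int(np.ceil(maxy + 0.5)), h)
    if j0 >= j1 or i0 >= i1:
        warnings.warn("polygon lies entirely outside the image; empty mask")
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    inside = shapely.contains_xy(poly, jj.ravel() + 0.5, ii.ravel() + 0.5)
    mask[i0:i1, j0:j1] = inside.reshape(i1 - i0, j1 - j0)
    if not mask.any():
        warnings.warn("polygon contains no pixel centers; empty mask")
    return mask


def rasterize_roi(outline: RegionOutline, shape: tuple[int, int]) -> np.ndarray:
    return rasterize_polygon(outline.polygon, shape)


@dataclass(frozen=True)
class MouseRecord:
    """Study metadata for one animal."""

    id: str
    genotype: str
    sex: str
    group: str
    delay_days: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.delay_days not in (1, 7):
            raise ValueError("delay_days must be 1 or 7")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_size: float) -> BrightfieldImage:
    """Read an 8-bit RGB TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("RGB"))
    return BrightfieldImage(pixels, pixel_size)


def write_image(path: str | Path, image: BrightfieldImage) -> None:
    """Write an image as 8-bit RGB TIFF (float pixels are rounded)."""
    pixels = np.clip(np.rint(np.asarray(image.pixels, dtype=float)), 0, 255)
    tifffile.imwrite(Path(path), pixels.astype(np.uint8), photometric="rgb")


def read_rois(path: str | Path) -> list[RegionOutline]:
    """Read ROIs from a GeoJSON FeatureCollection.

    Each Feature must be a Polygon with properties ``region`` and
    ``hemisphere``; only the exterior ring is used.
    """
    with open(path) as fh:
        doc = json.load(fh)
    outlines = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.get('type')!r}")
        props = feat.get("properties", {})
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        # GeoJSON rings repeat the first vertex; drop the closing copy.
        if ring.shape[0] > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        outlines.append(RegionOutline(props["region"], props["hemisphere"], ring))
    return outlines


def write_rois(path: str | Path, outlines: Iterable[RegionOutline]) -> None:
    features = []
    for o in outlines:
        ring = [[float(x), float(y)] for x, y in o.polygon]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"region": o.region, "hemisphere": o.hemisphere},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_metadata(path: str | Path) -> list[MouseRecord]:
    """Read the per-mouse metadata CSV (id,genotype,sex,group,delay_days)."""
    records = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = MouseRecord(
                id=row["id"],
                genotype=row["genotype"],
                sex=row["sex"],
                group=row["group"],
                delay_days=int(row["delay_days"]),
            )
            if rec.id in seen:
                raise ValueError(f"duplicate mouse id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
    return records


def write_metadata(path: str | Path, records: Iterable[MouseRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "genotype", "sex", "group", "delay_days"])
        for r in records:
            writer.writerow([r.id, r.genotype, r.sex, r.group, r.delay_days])
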
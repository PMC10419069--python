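"""Morphological counting of Iba1-positive cell somata.

The seven-step macro, re-specified as explicit image operators applied in a
pinned order to the DAB OD channel of an ROI:

1. eight-bit conversion (linear min-max rescale over the ROI);
2. local contrast normalization (contrast-limited adaptive histogram
   equalization, CLAHE);
3. auto-thresholding (IsoData by default, Otsu available; stain = bright =
   foreground);
4. binary closing (square structuring element);
5. binary erosion (square structuring element) — this is the step that
   strips the thin ramified processes so only compact somata remain;
6. despeckle (3×3 median filter — the literal definition of the command in
   the originating tool);
7. 8-connected particle counting with an inclusive area cut-off
   (default 8 µm²–infinity).

Counts are normalized by ROI area (mm²) to give soma densities.  Every
intermediate image is retained on the result for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .stain import ODChannel

__all__ = [
    "MorphParams",
    "Particle",
    "ParticleSet",
    "DensityResult",
    "run_soma_pipeline",
    "particle_density",
]


@dataclass(frozen=True)
class MorphParams:
    """Parameters of the soma-counting chain.

    clahe_clip follows the convention of the originating tool (multiple of
    the uniform histogram height, default 2.0) and is mapped internally to
    skimage's [0, 1] clip fraction as clip/100; clahe_clip = 0 disables the
    contrast step.  closing_se / erosion_se are structuring-element radii in
    pixels (0 = skip); median_size is the despeckle window (1 = skip);
    min_area is the inclusive particle cut-off in µm².
    """

    clahe_tile: int = 64
    clahe_clip: float = 2.0
    threshold_method: str = "isodata"
    closing_se: int = 1
    erosion_se: int = 1
    median_size: int = 3
    min_area: float = 8.0

    def __post_init__(self) -> None:
        if not self.min_area > 0:
            raise ValueError("min_area must be > 0")
        if self.clahe_tile < 1 or self.median_size < 1:
            raise ValueError("window sizes must be >= 1")
        if self.closing_se < 0 or self.erosion_se < 0:
            raise ValueError("structuring-element radii must be >= 0")
        if self.threshold_method not in ("isodata", "otsu"):
            raise ValueError("threshold_method must be 'isodata' or 'otsu'")


@dataclass(frozen=True)
class Particle:
    label: int
    area_um2: float
    centroid: tuple[float, float]  # (y, x) pixel coordinates


@dataclass
class ParticleSet:
    """Connected components surviving the area filter, plus audit intermediates."""

    particles: list[Particle]
    pixel_size: float
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.particles)

    def dump_intermediates(self, directory) -> None:
        """Write every audit intermediate as a TIFF, one per pipeline step."""
        import tifffile
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, (name, img) in enumerate(self.intermediates.items()):
            out = img if img.dtype == np.uint8 else img.astype(np.uint16)
            tifffile.imwrite(directory / f"{i}_{name}.tif", out)


@dataclass(frozen=True)
class DensityResult:
    count: int
    roi_area_mm2: float
    density_per_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.roi_area_mm2 > 0:
            raise ValueError("ROI area must be > 0")
        object.__setattr__(self, "density_per_mm2", self.count / self.roi_area_mm2)


def _square(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def run_soma_pipeline(
    channel: ODChannel,
    roi_mask: np.ndarray,
    params: MorphParams = MorphParams(),
) -> ParticleSet:
    """Run the seven-step chain on one ROI and return surviving particles.

    An all-background result after thresholding is a valid empty
    ParticleSet, not an error.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    od = channel.values
    if roi.shape != od.shape:
        raise ValueError("roi_mask shape must match the OD channel")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    ps = channel.pixel_size
    inter: dict[str, np.ndarray] = {}

    # (1) 8-bit conversion: linear min-max over ROI pixels
    lo, hi = float(od[roi].min()), float(od[roi].max())
    if hi == lo:
        img8 = np.zeros_like(od, dtype=np.uint8)
    else:
        img8 = np.clip(np.rint((od - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)
    inter["8bit"] = img8

    # (2) local contrast normalization (CLAHE)
    if params.clahe_clip > 0 and hi != lo:
        tile = min(params.clahe_tile, min(od.shape))
        eq = exposure.equalize_adapthist(
            img8, kernel_size=tile, clip_limit=params.clahe_clip / 100.0
        )
        img8 = np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    inter["contrast"] = img8

    # (3) auto-threshold; stain (high OD) is foreground
    vals = img8[roi]
    if vals.min() == vals.max():
        inter["binary"] = np.zeros_like(roi)
        return ParticleSet([], ps, inter)
    thr = threshold_isodata(vals) if params.threshold_method == "isodata" else threshold_otsu(vals)
    binary = (img8 > thr) & roi
    inter["binary"] = binary

    # (4) closing
    if params.closing_se >= 1:
        binary = ndimage.binary_closing(binary, structure=_square(params.closing_se))
        binary &= roi
    inter["closed"] = binary

    # (5) erosion
    if params.erosion_se >= 1:
        binary = ndimage.binary_erosion(binary, structure=_square(params.erosion_se))
    inter["eroded"] = binary

    # (6) despeckle (median)
    if params.median_size > 1:
        binary = ndimage.median_filter(
            binary.astype(np.uint8), size=params.median_size, mode="reflect"
        ).astype(bool)
        binary &= roi
    inter["despeckled"] = binary

    # (7) 8-connected labeling with inclusive area filter
    labels = cc_label(binary, connectivity=2)
    particles = []
    for rp in regionprops(labels):
        area_um2 = rp.area * ps * ps
        if area_um2 >= params.min_area:
            particles.append(Particle(rp.label, float(area_um2), tuple(rp.centroid)))
    inter["labels"] = labels
    return ParticleSet(particles, ps, inter)


def particle_density(
    particles: ParticleSet, roi_mask: np.ndarray, pixel_size: float | None = None
) -> DensityResult:
    """Particle count normalized by ROI area in mm²."""
    roi = np.asarray(roi_mask, dtype=bool)
    n_px = int(roi.sum())
    if n_px == 0:
        raise ValueError("ROI mask is empty; density undefined")
    ps = particles.pixel_size if pixel_size is None else pixel_size
    area_mm2 = n_px * ps * ps / 1e6
    return DensityResult(particles.count, area_mm2)
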
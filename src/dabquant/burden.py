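"""Stained-area ("load") quantification for glial markers.

Two routes reduce a DAB OD channel to a percent-stained-area per ROI:

* a trainable pixel classifier (used for Iba1, microglia): a small random
  forest over a per-pixel feature stack (raw OD, Gaussian-smoothed OD and
  local standard deviation at configurable physical radii), trained from
  positive/negative polygon annotations;
* Phansalkar local thresholding (used for GFAP, astrocytes): a local
  adaptive threshold suited to faint, finely branched objects,

        t = μ · (1 + p·e^(−q·μ) + k·(σ/r − 1)),

  with μ, σ the mean and standard deviation of the normalized stain
  intensity inside a disk window; a pixel is foreground iff its value > t.
  The formula assumes bright objects, so the OD channel is min-max
  normalized (stain-positive = high), never inverted.

All windowed operations use symmetric (edge-mirrored) padding at image
borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .stain import ODChannel, rasterize_polygon

__all__ = [
    "PixelFeatureSpec",
    "AnnotationSet",
    "TrainedClassifier",
    "PhansalkarParams",
    "LoadResult",
    "extract_features",
    "train_classifier",
    "predict_mask",
    "phansalkar_mask",
    "normalize_stain",
    "load_fraction",
]


@dataclass(frozen=True)
class PixelFeatureSpec:
    """Per-pixel feature stack: raw OD, Gaussian blurs and local stds (radii in µm)."""

    gaussian_radii_um: tuple[float, ...] = (0.5, 1.0)
    std_radii_um: tuple[float, ...] = (1.0,)
    include_raw: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.gaussian_radii_um + self.std_radii_um):
            raise ValueError("feature radii must be > 0")
        if not self.include_raw and not (self.gaussian_radii_um or self.std_radii_um):
            raise ValueError("at least one feature required")

    @property
    def names(self) -> tuple[str, ...]:
        names = ["od"] if self.include_raw else []
        names += [f"gauss_{r}um" for r in self.gaussian_radii_um]
        names += [f"std_{r}um" for r in self.std_radii_um]
        return tuple(names)


@dataclass
class AnnotationSet:
    """Training polygons: list of (polygon (N,2) xy, label 'positive'|'negative')."""

    annotations: list[tuple[np.ndarray, str]]

    def __post_init__(self) -> None:
        labels = {lab for _, lab in self.annotations}
        for lab in labels:
            if lab not in ("positive", "negative"):
                raise ValueError(f"annotation label must be positive/negative, got {lab!r}")
        for lab in ("positive", "negative"):
            if lab not in labels:
                raise ValueError(f"missing {lab!r} annotations; both labels are required")


def extract_features(
    channel: ODChannel, spec: PixelFeatureSpec = PixelFeatureSpec()
) -> np.ndarray:
    """H×W×F feature stack; radii converted from µm through the pixel size."""
    od = channel.values
    planes = []
    if spec.include_raw:
        planes.append(od)
    for r_um in spec.gaussian_radii_um:
        sigma = r_um / channel.pixel_size
        if sigma < 1:
            raise ValueError(
                f"gaussian radius {r_um} µm is below one pixel at {channel.pixel_size} µm/px"
            )
        planes.append(ndimage.gaussian_filter(od, sigma, mode="reflect"))
    for r_um in spec.std_radii_um:
        r_px = int(round(r_um / channel.pixel_size))
        if r_px < 1:
            raise ValueError(
                f"std radius {r_um} µm is below one pixel at {channel.pixel_size} µm/px"
            )
        size = 2 * r_px + 1
        mean = ndimage.uniform_filter(od, size, mode="reflect")
        meansq = ndimage.uniform_filter(od * od, size, mode="reflect")
        planes.append(np.sqrt(np.clip(meansq - mean * mean, 0.0, None)))
    return np.stack(planes, axis=-1)


@dataclass
class TrainedClassifier:
    """A fitted pixel classifier with its feature spec and training metadata."""

    model: RandomForestClassifier
    feature_spec: PixelFeatureSpec
    n_positive: int
    n_negative: int
    seed: int
    version: str = "1"

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        import joblib

        obj = joblib.load(Path(path))
        if not isinstance(obj, TrainedClassifier):
            raise ValueError("file does not contain a TrainedClassifier")
        return obj


def train_classifier(
    features: np.ndarray,
    annotations: AnnotationSet,
    seed: int = 0,
    feature_spec: PixelFeatureSpec = PixelFeatureSpec(),
    max_pixels_per_class: int = 5000,
    n_estimators: int = 50,
) -> TrainedClassifier:
    """Fit a random forest on pixels sampled from the annotation polygons.

    Training is seed-deterministic: both the per-class pixel subsample and
    the forest use ``seed``.
    """
    h, w, _ = features.shape
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for polygon, label in annotations.annotations:
        mask = rasterize_polygon(np.asarray(polygon), (h, w))
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            continue
        xs.append(features.reshape(-1, features.shape[-1])[idx])
        ys.append(np.full(idx.size, 1 if label == "positive" else 0))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    for cls, name in ((1, "positive"), (0, "negative")):
        if not (y == cls).any():
            raise ValueError(f"no usable pixels for the {name!r} label")
    # balanced subsample, deterministic
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, max_pixels_per_class, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(x[keep], y[keep])
    return TrainedClassifier(
        model,
        feature_spec,
        n_positive=int((y[keep] == 1).sum()),
        n_negative=int((y[keep] == 0).sum()),
        seed=seed,
    )


def predict_mask(classifier: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Per-pixel stained/background prediction as a boolean H×W mask."""
    expected = len(classifier.feature_spec.names)
    if features.ndim != 3 or features.shape[-1] != expected:
        raise ValueError(
            f"feature stack mismatch: expected {expected} planes "
            f"({classifier.feature_spec.names}), got shape {features.shape}"
        )
    h, w, f = features.shape
    pred = classifier.model.predict(features.reshape(-1, f))
    return pred.reshape(h, w).astype(bool)


@dataclass(frozen=True)
class PhansalkarParams:
    """Phansalkar threshold constants (common published defaults) and disk radius."""

    radius: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be > 0")


def _disk_kernel(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx <= radius * radius).astype(float)


def normalize_stain(channel: ODChannel) -> np.ndarray:
    """Min-max normalize an OD channel to [0, 1] (stain-positive = high)."""
    od = channel.values
    lo, hi = float(od.min()), float(od.max())
    if hi == lo:
        return np.zeros_like(od)
    return (od - lo) / (hi - lo)


def phansalkar_mask(
    stain_image: np.ndarray, params: PhansalkarParams = PhansalkarParams()
) -> np.ndarray:
    """Local Phansalkar binarization of a normalized stain-intensity field.

    Per pixel, with μ and σ the mean and standard deviation over the disk
    window of the given radius (symmetric padding at edges):

        t = μ·(1 + p·e^(−q·μ) + k·(σ/r − 1));  foreground iff value > t.
    """
    img = np.asarray(stain_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("stain image must be 2-D")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("stain image must be normalized to [0, 1]")
    if 2 * params.radius + 1 > min(img.shape):
        raise ValueError("window radius larger than the image")
    kernel = _disk_kernel(params.radius)
    kernel /= kernel.sum()
    mu = ndimage.correlate(img, kernel, mode="reflect")
    musq = ndimage.correlate(img * img, kernel, mode="reflect")
    sigma = np.sqrt(np.clip(musq - mu * mu, 0.0, None))
    t = mu * (1.0 + params.p * np.exp(-params.q * mu) + params.k * (sigma / params.r - 1.0))
    return img > t


@dataclass(frozen=True)
class LoadResult:
    """Stained-area readout: load = 100 · stained / roi percent."""

    stained_pixels: int
    roi_pixels: int
    load: float = field(init=False)

    def __post_init__(self) -> None:
        if self.roi_pixels <= 0:
            raise ValueError("empty ROI: load undefined")
        if self.stained_pixels > self.roi_pixels:
            raise ValueError("stained pixel count exceeds ROI")
        object.__setattr__(self, "load", 100.0 * self.stained_pixels / self.roi_pixels)


def load_fraction(mask: np.ndarray, roi_mask: np.ndarray) -> LoadResult:
    """Percent of ROI area covered by the stain mask (content outside ROI ignored)."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi_mask, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError("mask and ROI shapes differ")
    return LoadResult(int((mask & roi).sum()), int(roi.sum()))
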
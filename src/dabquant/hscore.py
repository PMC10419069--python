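"""Superpixel H-scoring of phospho-tau (AT8) DAB staining.

The quantification proceeds in three steps on each ROI:

1. the ROI is partitioned into ~10 µm SLIC superpixels — grid-seeded
   iterative clustering in joint (space, optical density), so superpixels
   adapt their shape to local staining contrasts rather than imposing a
   rigid grid;
2. each superpixel's mean DAB OD is classified against three thresholds,
   constant across all images of one experiment, into negative / weak /
   moderate / strong;
3. the H-score is computed as

       H = (SP_W·100 + SP_M·200 + SP_H·300) / SP_T ∈ [0, 300],

   where SP_W, SP_M, SP_H count weak/moderate/strong superpixels and SP_T is
   the total.  The score combines stained surface area and staining
   intensity in a single dynamic-range readout.

Bins are lower-inclusive: mean OD m is negative if m < t_weak, weak if
t_weak ≤ m < t_moderate, moderate if t_moderate ≤ m < t_strong, strong if
m ≥ t_strong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label

from .stain import ODChannel

__all__ = [
    "SlicParams",
    "IntensityThresholds",
    "SuperpixelMap",
    "ClassCounts",
    "HScoreResult",
    "CLASS_NAMES",
    "slic_segment",
    "classify_superpixels",
    "hscore",
    "hscore_roi",
    "intensity_distribution",
    "thresholds_from_quantiles",
]

CLASS_NAMES = ("negative", "weak", "moderate", "strong")


@dataclass(frozen=True)
class SlicParams:
    """SLIC parameters.

    target_diameter: nominal superpixel diameter in µm (seed spacing).
    compactness: spatial-vs-intensity weight, in OD units; higher values give
        squarer superpixels, lower values let them hug intensity boundaries.
    """

    target_diameter: float = 10.0
    compactness: float = 0.25
    max_iterations: int = 10
    enforce_connectivity: bool = True

    def __post_init__(self) -> None:
        if not self.target_diameter > 0:
            raise ValueError("target_diameter must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.compactness < 0:
            raise ValueError("compactness must be >= 0")


@dataclass(frozen=True)
class IntensityThresholds:
    """OD cut points separating negative/weak/moderate/strong superpixels.

    Held constant across every image of one experiment (both cohorts).
    """

    t_weak: float
    t_moderate: float
    t_strong: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_weak < self.t_moderate < self.t_strong):
            raise ValueError("thresholds must satisfy 0 <= t_weak < t_moderate < t_strong")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.t_weak, self.t_moderate, self.t_strong])


@dataclass
class SuperpixelMap:
    """Label partition of an ROI with per-label statistics.

    labels: H×W int array, 0 outside the ROI, 1..n inside.
    mean_od[k-1], area_px[k-1]: mean OD and pixel count of label k.
    """

    labels: np.ndarray
    n_superpixels: int
    mean_od: np.ndarray
    area_px: np.ndarray

    def __post_init__(self) -> None:
        if self.n_superpixels != len(self.mean_od) or self.n_superpixels != len(self.area_px):
            raise ValueError("per-label arrays must have n_superpixels entries")

    def save_labels(self, path) -> None:
        """Export the label image as 16-bit TIFF."""
        import tifffile

        if self.labels.max() > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for 16-bit export")
        tifffile.imwrite(path, self.labels.astype(np.uint16))


@dataclass(frozen=True)
class ClassCounts:
    """Superpixel tallies: weak, moderate, strong ("high") and total."""

    SP_W: int
    SP_M: int
    SP_H: int
    SP_T: int

    def __post_init__(self) -> None:
        if min(self.SP_W, self.SP_M, self.SP_H, self.SP_T) < 0:
            raise ValueError("counts must be non-negative")
        if self.SP_W + self.SP_M + self.SP_H > self.SP_T:
            raise ValueError("class counts exceed total")

    @property
    def SP_N(self) -> int:
        """Negative (no-signal) superpixels."""
        return self.SP_T - self.SP_W - self.SP_M - self.SP_H

    def fractions(self) -> dict[str, float]:
        if self.SP_T == 0:
            raise ValueError("no superpixels; fractions undefined")
        t = self.SP_T
        return {
            "negative": self.SP_N / t,
            "weak": self.SP_W / t,
            "moderate": self.SP_M / t,
            "strong": self.SP_H / t,
        }


@dataclass(frozen=True)
class HScoreResult:
    hscore: float
    fractions: dict[str, float]


# ---------------------------------------------------------------------------
# SLIC
# ---------------------------------------------------------------------------

def _seed_grid(roi: np.ndarray, s: float) -> np.ndarray:
    """Grid seed coordinates (y, x) with spacing s, kept inside the ROI."""
    h, w = roi.shape
    ys = np.arange(s / 2.0, h, s)
    xs = np.arange(s / 2.0, w, s)
    seeds = []
    for y in ys:
        for x in xs:
            iy, ix = int(y), int(x)
            if roi[iy, ix]:
                seeds.append((y, x))
    return np.array(seeds, dtype=float).reshape(-1, 2)


def _enforce_connectivity(labels: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Merge disconnected fragments of each label into adjacent labels.

    For every label, the largest connected component keeps the label; every
    orphan fragment is merged into the adjacent label sharing the longest
    border.  Fragments with no labelled neighbour (isolated ROI islands)
    keep their label.
    """
    out = labels.copy()
    for _ in range(10):
        comp = _cc_label(out, connectivity=1, background=0)
        changed = False
        n_comp = comp.max()
        if n_comp == 0:
            break
        comp_sizes = np.bincount(comp.ravel())[1:]
        # main component of each label = its largest fragment
        main: dict[int, int] = {}
        for c in range(1, n_comp + 1):
            idx = np.argwhere(comp == c)
            lab = out[idx[0][0], idx[0][1]]
            if lab not in main or comp_sizes[c - 1] > comp_sizes[main[lab] - 1]:
                main[lab] = c
        for c in range(1, n_comp + 1):
            mask = comp == c
            lab = out[mask][0]
            if main[lab] == c:
                continue
            ring = ndimage.binary_dilation(mask) & ~mask & (out > 0)
            neighbours = out[ring]
            neighbours = neighbours[neighbours != lab]
            if neighbours.size == 0:
                continue
            vals, counts = np.unique(neighbours, return_counts=True)
            out[mask] = vals[np.argmax(counts)]
            changed = True
        if not changed:
            break
    return out


def slic_segment(
    channel: ODChannel,
    roi_mask: np.ndarray,
    params: SlicParams = SlicParams(),
) -> SuperpixelMap:
    """Partition an ROI into SLIC superpixels of the OD channel.

    Grid-seeded k-means-style clustering in joint (space, intensity) with
    seed spacing s = target_diameter / pixel_size; each center's search
    window is 2s×2s and the distance is

        D = sqrt(d_int² + compactness² · (d_spatial / s)²).

    The returned labels partition the ROI exactly: every ROI pixel carries
    exactly one label ≥ 1 and no label leaks outside the ROI.
    """
    values = channel.values
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != values.shape:
        raise ValueError("roi_mask shape must match the OD channel")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI mask is empty")
    s = params.target_diameter / channel.pixel_size
    if s < 2:
        raise ValueError("target_diameter must be at least 2 pixels at this pixel size")

    h, w = values.shape
    seeds = _seed_grid(roi, s)
    if len(seeds) <= 1:
        warnings.warn("ROI smaller than one superpixel; returning a single label")
        labels = np.where(roi, 1, 0).astype(np.int32)
        return SuperpixelMap(
            labels,
            1,
            np.array([float(values[roi].mean())]),
            np.array([n_roi]),
        )

    cy = seeds[:, 0].copy()
    cx = seeds[:, 1].copy()
    cv = values[cy.astype(int), cx.astype(int)].astype(float)
    comp2 = params.compactness**2
    s2 = s * s

    yy_full, xx_full = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)

    for _ in range(params.max_iterations):
        best = np.full((h, w), np.inf)
        labels.fill(0)
        for k in range(len(cy)):
            y0 = max(int(cy[k] - s), 0)
            y1 = min(int(cy[k] + s) + 1, h)
            x0 = max(int(cx[k] - s), 0)
            x1 = min(int(cx[k] + s) + 1, w)
            if y0 >= y1 or x0 >= x1:
                continue
            win_v = values[y0:y1, x0:x1]
            dy = yy_full[y0:y1, x0:x1] - cy[k]
            dx = xx_full[y0:y1, x0:x1] - cx[k]
            d2 = (win_v - cv[k]) ** 2 + comp2 * (dy * dy + dx * dx) / s2
            upd = roi[y0:y1, x0:x1] & (d2 < best[y0:y1, x0:x1])
            best[y0:y1, x0:x1][upd] = d2[upd]
            labels[y0:y1, x0:x1][upd] = k + 1
        # ROI pixels outside every search window: assign to overall-nearest center
        orphan = roi & (labels == 0)
        if orphan.any():
            oy, ox = np.nonzero(orphan)
            ov = values[oy, ox]
            d2 = (ov[:, None] - cv[None, :]) ** 2 + comp2 * (
                (oy[:, None] - cy[None, :]) ** 2 + (ox[:, None] - cx[None, :]) ** 2
            ) / s2
            labels[oy, ox] = np.argmin(d2, axis=1) + 1
        # update centers
        flat = labels[roi]
        idx = labels
        sums_y = ndimage.sum_labels(yy_full, idx, index=np.arange(1, len(cy) + 1))
        sums_x = ndimage.sum_labels(xx_full, idx, index=np.arange(1, len(cy) + 1))
        sums_v = ndimage.sum_labels(values, idx, index=np.arange(1, len(cy) + 1))
        counts = np.bincount(flat, minlength=len(cy) + 1)[1:].astype(float)
        keep = counts > 0
        if not keep.all():
            # drop empty clusters and relabel
            remap = np.zeros(len(cy) + 1, dtype=np.int32)
            remap[1:][keep] = np.arange(1, int(keep.sum()) + 1)
            labels = remap[labels]
            cy, cx, cv = cy[keep], cx[keep], cv[keep]
            sums_y, sums_x, sums_v, counts = (
                sums_y[keep],
                sums_x[keep],
                sums_v[keep],
                counts[keep],
            )
        cy = sums_y / counts
        cx = sums_x / counts
        cv = sums_v / counts

    if params.enforce_connectivity:
        labels = _enforce_connectivity(labels, roi)

    # relabel consecutively
    present = np.unique(labels[roi])
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    labels = remap[labels]
    n = len(present)
    index = np.arange(1, n + 1)
    mean_od = ndimage.mean(values, labels, index=index)
    area = np.bincount(labels[roi], minlength=n + 1)[1:]
    return SuperpixelMap(labels, n, np.asarray(mean_od, dtype=float), area)


# ---------------------------------------------------------------------------
# Classification and scoring
# ---------------------------------------------------------------------------

def classify_superpixels(
    spmap: SuperpixelMap, thresholds: IntensityThresholds
) -> ClassCounts:
    """Tally superpixels into the four intensity classes (lower-inclusive bins)."""
    if spmap.n_superpixels == 0:
        warnings.warn("empty superpixel map; all counts zero")
        return ClassCounts(0, 0, 0, 0)
    bins = np.digitize(spmap.mean_od, thresholds.edges)  # 0=neg,1=weak,2=mod,3=strong
    counts = np.bincount(bins, minlength=4)
    return ClassCounts(int(counts[1]), int(counts[2]), int(counts[3]), int(spmap.n_superpixels))


def hscore(counts: ClassCounts) -> HScoreResult:
    """H-score = (SP_W·100 + SP_M·200 + SP_H·300) / SP_T, in [0, 300]."""
    if counts.SP_T == 0:
        raise ValueError("SP_T = 0: H-score undefined (distinct from score 0)")
    score = (counts.SP_W * 100 + counts.SP_M * 200 + counts.SP_H * 300) / counts.SP_T
    return HScoreResult(score, counts.fractions())


def hscore_roi(
    channel: ODChannel,
    roi_mask: np.ndarray,
    thresholds: IntensityThresholds,
    params: SlicParams = SlicParams(),
) -> tuple[HScoreResult, ClassCounts, SuperpixelMap]:
    """Full per-ROI H-score: segment, classify, score."""
    spmap = slic_segment(channel, roi_mask, params)
    counts = classify_superpixels(spmap, thresholds)
    return hscore(counts), counts, spmap


def thresholds_from_quantiles(
    od_values: np.ndarray, quantiles: tuple[float, float, float] = (0.90, 0.97, 0.995)
) -> IntensityThresholds:
    """Set experiment-wide thresholds from quantiles of control-image OD.

    The method constrains thresholds only to be constant within an
    experiment; this helper derives them once from pooled control pixels so
    both cohorts are scored on the same scale.
    """
    q = np.quantile(np.asarray(od_values, dtype=float).ravel(), quantiles)
    return IntensityThresholds(float(q[0]), float(q[1]), float(q[2]))


def intensity_distribution(
    counts_by_group: dict[str, list[ClassCounts]],
) -> "pd.DataFrame":
    """Per-class fraction comparison between two groups (signal-intensity distributions).

    For each intensity class, reports the mean per-mouse fraction in each
    group and a two-sided Mann–Whitney test between groups (the same test
    used for all cohort comparisons).  Returns a tidy DataFrame with one row
    per class.
    """
    import pandas as pd

    from .stats import group_compare

    if len(counts_by_group) != 2:
        raise ValueError("exactly two groups required")
    (g1, counts1), (g2, counts2) = counts_by_group.items()
    if min(len(counts1), len(counts2)) < 1:
        raise ValueError("each group needs at least one mouse")
    fracs = {
        g: np.array([[c.fractions()[cls] for cls in CLASS_NAMES] for c in cs])
        for g, cs in ((g1, counts1), (g2, counts2))
    }
    rows = []
    for j, cls in enumerate(CLASS_NAMES):
        a, b = fracs[g1][:, j], fracs[g2][:, j]
        if len(a) > 1 or len(b) > 1:
            cmp = group_compare(a, b)
            u, p, star = cmp.U, cmp.p, cmp.stars
        else:
            u, p, star = np.nan, 1.0, "ns"  # n too small for any inference
        rows.append(
            {
                "class": cls,
                f"mean_fraction_{g1}": float(a.mean()),
                f"mean_fraction_{g2}": float(b.mean()),
                "difference": float(a.mean() - b.mean()),
                "U": u,
                "p": p,
                "stars": star,
            }
        )
    return pd.DataFrame(rows)
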
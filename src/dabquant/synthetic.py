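"""Synthetic DAB-like brightfield scenes and cohorts with exact ground truth.

The generator emulates the staining phenotypes the pipeline quantifies on
coronal brain sections:

* ``diffuse_patch`` — flat disks of DAB OD in one of the four intensity
  strata (negative / weak / moderate / strong), emulating diffuse
  phospho-tau immunoreactivity;
* ``tangle_blob`` — small compact high-OD deposits (tangle-like);
* ``ramified_cell`` — a compact soma disk plus 3–6 thin random-walk
  processes, emulating Iba1-positive microglia; the soma area is the
  ground-truth "particle" area and the thin processes are what the erosion
  step of the soma pipeline must remove;
* ``star_cell`` — a small soma with fine radiating branches, emulating
  GFAP-positive astrocytes.

Scenes are synthesized in OD space along a fixed DAB stain vector and
converted to RGB through the Beer–Lambert inverse, which makes the
round-trip through colour deconvolution exact by construction.  RGB images
are kept as floats; 8-bit quantization happens only on TIFF export.

The cohort generator reproduces a two-group design (e.g. sonicated n=10 vs
non-sonicated n=6, delays 1 or 7 days) with a programmed per-region effect
multiplier on one target metric and log-normal between-mouse variability
(strictly positive, CV-parameterized).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hscore import IntensityThresholds
from .stain import (
    REGIONS,
    BrightfieldImage,
    MouseRecord,
    RegionOutline,
    StainVectors,
    od_to_rgb,
    write_image,
    write_rois,
)

__all__ = [
    "GENERATION_THRESHOLDS",
    "CLASS_OD",
    "StainElement",
    "SceneSpec",
    "SceneGroundTruth",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "render_scene",
    "generate_cohort",
    "scene_for_metric",
]

#: Default OD thresholds the scenes are generated against (weak/moderate/strong).
GENERATION_THRESHOLDS = IntensityThresholds(0.15, 0.35, 0.65)

#: Representative OD painted for each intended intensity class (bin interiors).
CLASS_OD = {"negative": 0.04, "weak": 0.25, "moderate": 0.50, "strong": 0.90}

ELEMENT_KINDS = ("diffuse_patch", "tangle_blob", "ramified_cell", "star_cell")

METRICS = ("AT8_hscore", "Iba1_load", "Iba1_density", "GFAP_load")

#: Baseline metric values for cohort generation (H-score units, %, per mm², %).
DEFAULT_BASELINES = {
    "AT8_hscore": 60.0,
    "Iba1_load": 16.0,
    "Iba1_density": 150.0,
    "GFAP_load": 12.0,
}


@dataclass(frozen=True)
class StainElement:
    """One painted object in a scene.

    center is (x, y) in pixel coordinates; area is the object (soma, for
    cell kinds) area in µm²; peak_od overrides the class-default OD.
    """

    kind: str
    center: tuple[float, float]
    area: float
    peak_od: float | None = None
    intended_class: str = "moderate"

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not self.area > 0:
            raise ValueError("element area must be > 0")
        if self.peak_od is not None and self.peak_od < 0:
            raise ValueError("peak_od must be >= 0")
        if self.intended_class not in CLASS_OD:
            raise ValueError(f"unknown intensity class {self.intended_class!r}")

    def od(self) -> float:
        if self.peak_od is not None:
            return self.peak_od
        if self.kind == "diffuse_patch":
            return CLASS_OD[self.intended_class]
        if self.kind == "tangle_blob":
            return CLASS_OD["strong"]
        if self.kind == "ramified_cell":
            return 0.75
        return 0.60  # star_cell

    def radius_px(self, pixel_size: float) -> float:
        return float(np.sqrt(self.area / np.pi) / pixel_size)


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic tile; identical (spec, seed) → identical scene."""

    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 0.25
    background_od: tuple[float, float] = (0.02, 0.005)  # mean, spread
    elements: tuple[StainElement, ...] = ()
    seed: int = 0
    thresholds: IntensityThresholds = GENERATION_THRESHOLDS

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "elements", tuple(self.elements))


@dataclass
class SceneGroundTruth:
    """Exact per-scene truth, the twin of every downstream readout.

    class_area_fractions are per-pixel area fractions of the four intensity
    classes under the generation thresholds (sum to 1); true_hscore is
    computed from them; true_stained_fraction is the fraction of pixels at
    or above the weak threshold; soma_count/soma_areas track ramified cells.
    """

    class_area_fractions: dict[str, float]
    true_stained_fraction: float
    soma_count: int
    soma_areas: list[float]
    true_hscore: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.class_area_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class area fractions must sum to 1")
        if not 0 <= self.true_stained_fraction <= 1:
            raise ValueError("true_stained_fraction must lie in [0, 1]")
        if self.soma_count != len(self.soma_areas):
            raise ValueError("soma_count must equal len(soma_areas)")
        f = self.class_area_fractions
        self.true_hscore = (
            f.get("weak", 0.0) * 100 + f.get("moderate", 0.0) * 200 + f.get("strong", 0.0) * 300
        )
        if not 0 <= self.true_hscore <= 300 + 1e-9:
            raise ValueError("true_hscore out of [0, 300]")


def _disk(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    h, w = shape
    y0 = max(int(np.floor(cy - radius)) - 1, 0)
    y1 = min(int(np.ceil(cy + radius)) + 2, h)
    x0 = max(int(np.floor(cx - radius)) - 1, 0)
    x1 = min(int(np.ceil(cx + radius)) + 2, w)
    mask = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= radius**2
    return mask


def _paint_walk(
    od: np.ndarray,
    start: tuple[float, float],
    direction: float,
    length: int,
    value: float,
    rng: np.random.Generator,
    wobble: float = 0.5,
) -> None:
    """Paint a 1-px-wide random-walk process, clipped to the image."""
    h, w = od.shape
    x, y = start
    theta = direction
    for _ in range(length):
        theta += rng.normal(0.0, wobble)
        x += np.cos(theta)
        y += np.sin(theta)
        ix, iy = int(round(x)), int(round(y))
        if 0 <= iy < h and 0 <= ix < w:
            od[iy, ix] = max(od[iy, ix], value)


def render_scene(spec: SceneSpec) -> tuple[BrightfieldImage, SceneGroundTruth]:
    """Render a scene to a float RGB brightfield image with exact ground truth.

    Raises ValueError naming the offending element if an element (center ±
    object radius) does not fit inside the image bounds.  Re-quantifying the
    returned image through OD conversion and deconvolution recovers the
    generated DAB OD field exactly (floats) or to ~2e-3 after 8-bit export.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    mean_bg, spread_bg = spec.background_od
    od = np.clip(rng.normal(mean_bg, spread_bg, size=(h, w)), 0.0, None) if spread_bg > 0 else np.full((h, w), float(mean_bg))

    soma_areas: list[float] = []
    for i, el in enumerate(spec.elements):
        r = el.radius_px(spec.pixel_size)
        cx, cy = el.center
        if not (r <= cx <= w - r and r <= cy <= h - r):
            raise ValueError(
                f"element {i} ({el.kind}) at center {el.center} with radius "
                f"{r:.1f}px does not fit inside the {h}x{w} image"
            )
        value = el.od()
        if el.kind in ("diffuse_patch", "tangle_blob"):
            mask = _disk((h, w), cx, cy, r)
            od[mask] = np.maximum(od[mask], value)
        elif el.kind == "ramified_cell":
            mask = _disk((h, w), cx, cy, r)
            od[mask] = np.maximum(od[mask], value)
            n_proc = int(rng.integers(3, 7))
            length = max(int(10.0 / spec.pixel_size), 4)
            for k in range(n_proc):
                theta = 2 * np.pi * k / n_proc + rng.uniform(-0.3, 0.3)
                start = (cx + (r + 0.5) * np.cos(theta), cy + (r + 0.5) * np.sin(theta))
                _paint_walk(od, start, theta, length, 0.45, rng)
            soma_areas.append(el.area)
        else:  # star_cell
            mask = _disk((h, w), cx, cy, r)
            od[mask] = np.maximum(od[mask], value)
            n_branch = int(rng.integers(6, 11))
            length = max(int(12.0 / spec.pixel_size), 4)
            for k in range(n_branch):
                theta = 2 * np.pi * k / n_branch + rng.uniform(-0.2, 0.2)
                start = (cx + r * np.cos(theta), cy + r * np.sin(theta))
                _paint_walk(od, start, theta, length, value * 0.8, rng, wobble=0.2)

    edges = spec.thresholds.edges
    bins = np.digitize(od, edges)
    n_px = od.size
    fracs = {
        name: float((bins == j).sum()) / n_px
        for j, name in enumerate(("negative", "weak", "moderate", "strong"))
    }
    truth = SceneGroundTruth(
        class_area_fractions=fracs,
        true_stained_fraction=float((od >= edges[0]).sum()) / n_px,
        soma_count=len(soma_areas),
        soma_areas=soma_areas,
    )
    dab = np.asarray(StainVectors.hdab().dab)
    rgb = od_to_rgb(od[:, :, None] * dab[None, None, :])
    return BrightfieldImage(rgb, spec.pixel_size), truth


# ---------------------------------------------------------------------------
# Metric-targeted scene construction
# ---------------------------------------------------------------------------

def _placed_disks(
    spec_size: tuple[int, int],
    pixel_size: float,
    coverage: float,
    patch_area_um2: float,
    rng: np.random.Generator,
    kind: str = "diffuse_patch",
    intended_class: str = "moderate",
    peak_od: float | None = None,
) -> list[StainElement]:
    """Non-overlapping jittered-grid disks covering ≈``coverage`` of the tile."""
    h, w = spec_size
    tile_um2 = h * w * pixel_size**2
    total_um2 = coverage * tile_um2
    if total_um2 <= 0:
        return []
    # n full patches plus one remainder disk so the programmed coverage is
    # met to well under one patch of quantization error
    n_full = int(total_um2 // patch_area_um2)
    rem = total_um2 - n_full * patch_area_um2
    areas = [patch_area_um2] * n_full
    if rem > 0.02 * patch_area_um2:
        areas.append(rem)
    if not areas:
        return []
    grid = int(np.ceil(np.sqrt(len(areas))))
    cell_h, cell_w = h / grid, w / grid
    cells = [(i, j) for i in range(grid) for j in range(grid)]
    order = rng.permutation(len(cells))[: len(areas)]
    elements = []
    for area, idx in zip(areas, order):
        i, j = cells[idx]
        r_px = np.sqrt(area / np.pi) / pixel_size
        jit_y = max((cell_h - 2 * r_px) / 2 - 1, 0.0)
        jit_x = max((cell_w - 2 * r_px) / 2 - 1, 0.0)
        cy = (i + 0.5) * cell_h + rng.uniform(-jit_y, jit_y)
        cx = (j + 0.5) * cell_w + rng.uniform(-jit_x, jit_x)
        cy = float(np.clip(cy, r_px + 1, h - r_px - 1))
        cx = float(np.clip(cx, r_px + 1, w - r_px - 1))
        elements.append(StainElement(kind, (cx, cy), area, peak_od, intended_class))
    return elements


def scene_for_metric(
    metric: str,
    target_value: float,
    *,
    image_size: tuple[int, int] = (256, 256),
    pixel_size: float = 0.25,
    seed: int = 0,
    thresholds: IntensityThresholds = GENERATION_THRESHOLDS,
) -> SceneSpec:
    """Build a SceneSpec whose ground truth realizes ``target_value`` for ``metric``.

    AT8_hscore h is realized as moderate-class coverage h/200; the load
    metrics as stain coverage value/100; Iba1_density as a matching count of
    ramified cells.  Coverage realization is approximate at the single-scene
    level (disk packing); the returned scene's own ground truth is exact.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    rng = np.random.default_rng(seed)
    h, w = image_size
    if metric == "AT8_hscore":
        coverage = min(target_value / 200.0, 0.5)
        # diffuse patches several superpixel-diameters across, so that
        # superpixel counting can resolve them; capped by the tile size
        tile_um2 = h * w * pixel_size**2
        patch_area = min(6000.0, tile_um2 / 6.0)
        elements = _placed_disks(
            image_size, pixel_size, coverage, patch_area, rng, intended_class="moderate"
        )
    elif metric in ("Iba1_load", "GFAP_load"):
        coverage = min(target_value / 100.0, 0.5)
        kind = "diffuse_patch"
        elements = _placed_disks(
            image_size, pixel_size, coverage, 120.0, rng, kind=kind,
            intended_class="strong", peak_od=0.6,
        )
    else:  # Iba1_density, per mm²
        tile_mm2 = h * w * pixel_size**2 / 1e6
        n_cells = max(int(round(target_value * tile_mm2)), 0)
        soma_area = 20.0
        r_px = np.sqrt(soma_area / np.pi) / pixel_size
        elements = []
        grid = max(int(np.ceil(np.sqrt(max(n_cells, 1)))), 1)
        cell_h, cell_w = h / grid, w / grid
        cells = [(i, j) for i in range(grid) for j in range(grid)]
        order = rng.permutation(len(cells))[:n_cells]
        for idx in order:
            i, j = cells[idx]
            cy = float(np.clip((i + 0.5) * cell_h, r_px + 1, h - r_px - 1))
            cx = float(np.clip((j + 0.5) * cell_w, r_px + 1, w - r_px - 1))
            elements.append(StainElement("ramified_cell", (cx, cy), soma_area))
    return SceneSpec(
        image_size=image_size,
        pixel_size=pixel_size,
        elements=tuple(elements),
        seed=seed,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: label, size and per-region effect multiplier.

    multiplier may be a scalar (applied in every region) or a mapping
    region → multiplier (unlisted regions default to 1.0).
    """

    label: str
    n: int
    multiplier: float | Mapping[str, float] = 1.0
    genotype: str = "P301S"
    delay_days: int = 7
    arm: str = "sonicated"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        if self.arm not in ("sonicated", "non_sonicated"):
            raise ValueError("arm must be 'sonicated' or 'non_sonicated'")
        mults = (
            [self.multiplier]
            if np.isscalar(self.multiplier)
            else list(self.multiplier.values())
        )
        if any(m <= 0 for m in mults):
            raise ValueError("effect multipliers must be > 0")

    def region_multiplier(self, region: str) -> float:
        if np.isscalar(self.multiplier):
            return float(self.multiplier)
        return float(self.multiplier.get(region, 1.0))


@dataclass(frozen=True)
class CohortSpec:
    """Study-design recipe: groups, variability, regions, target metric, seed."""

    groups: tuple[GroupSpec, ...]
    between_mouse_cv: float = 0.25
    within_mouse_cv: float = 0.0
    regions: tuple[str, ...] = REGIONS
    metric: str = "AT8_hscore"
    seed: int = 0
    baseline: float | None = None
    slices_per_mouse: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        for r in self.regions:
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}; expected one of {REGIONS}")
        if self.between_mouse_cv < 0 or self.within_mouse_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.slices_per_mouse < 1:
            raise ValueError("slices_per_mouse must be >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal draw with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))


@dataclass
class Cohort:
    """A generated cohort: metadata, per-scene truths, and scene recipes."""

    spec: CohortSpec
    metadata: list[MouseRecord]
    measures: pd.DataFrame  # mouse_id, group, region, hemisphere, metric, true_value, scene_seed

    def scene_spec(
        self,
        mouse_id: str,
        region: str,
        hemisphere: str = "left",
        image_size: tuple[int, int] = (256, 256),
        pixel_size: float = 0.25,
    ) -> SceneSpec:
        row = self.measures[
            (self.measures.mouse_id == mouse_id)
            & (self.measures.region == region)
            & (self.measures.hemisphere == hemisphere)
        ]
        if row.empty:
            raise KeyError(f"no scene for ({mouse_id}, {region}, {hemisphere})")
        r = row.iloc[0]
        return scene_for_metric(
            self.spec.metric,
            float(r.true_value),
            image_size=image_size,
            pixel_size=pixel_size,
            seed=int(r.scene_seed),
        )

    def write(self, directory: str | Path, render: bool = False) -> Path:
        """Write metadata, the measure manifest, and (optionally) scene TIFFs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from .stain import write_metadata

        write_metadata(directory / "metadata.csv", self.metadata)
        manifest = self.measures.copy()
        if render:
            paths = []
            for _, r in manifest.iterrows():
                spec = self.scene_spec(r.mouse_id, r.region, r.hemisphere)
                image, truth = render_scene(spec)
                stem = f"{r.mouse_id}_{r.region}_{r.hemisphere}"
                write_image(directory / f"{stem}.tif", image)
                h, w = spec.image_size
                write_rois(
                    directory / f"{stem}.geojson",
                    [RegionOutline(r.region, r.hemisphere, np.array([[0, 0], [w, 0], [w, h], [0, h]]))],
                )
                paths.append(f"{stem}.tif")
            manifest["image_path"] = paths
        manifest.to_csv(directory / "manifest.csv", index=False)
        return directory


def _scene_seed(base_seed: int, *parts: str) -> int:
    """Stable per-scene seed below 2**31 derived from the cohort seed."""
    key = "|".join(parts).encode()
    return (base_seed * 2654435761 + zlib.crc32(key)) % (2**31)


def generate_cohort(cohort: CohortSpec) -> Cohort:
    """Generate per-mouse metadata and per-(mouse, region, hemisphere) truths.

    Group sizes are honored exactly; the per-mouse metric value is
    baseline × group multiplier(region) × L_mouse × L_hemisphere with
    unit-mean log-normal factors at the configured CVs, so across many mice
    the ratio of group means converges to the programmed multiplier.
    """
    rng = np.random.default_rng(cohort.seed)
    baseline = (
        cohort.baseline
        if cohort.baseline is not None
        else DEFAULT_BASELINES[cohort.metric]
    )
    records: list[MouseRecord] = []
    rows = []
    for g in cohort.groups:
        for m in range(g.n):
            mouse_id = f"{g.label}_{m + 1:02d}"
            records.append(
                MouseRecord(mouse_id, g.genotype, "M", g.arm, g.delay_days)
            )
            l_mouse = _lognormal_factor(rng, cohort.between_mouse_cv)
            for region in cohort.regions:
                mult = g.region_multiplier(region)
                for hemisphere in ("left", "right"):
                    l_hemi = _lognormal_factor(rng, cohort.within_mouse_cv)
                    value = baseline * mult * l_mouse * l_hemi
                    rows.append(
                        {
                            "mouse_id": mouse_id,
                            "group": g.label,
                            "region": region,
                            "hemisphere": hemisphere,
                            "metric": cohort.metric,
                            "true_value": value,
                            "scene_seed": _scene_seed(
                                cohort.seed, mouse_id, region, hemisphere
                            ),
                        }
                    )
    return Cohort(cohort, records, pd.DataFrame(rows))
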
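"""End-to-end study orchestration.

Ingests a cohort (synthetic or from files), runs the quantification arms
blind to group membership, assembles the measure table, and runs the
statistics.  Blinding is structural: the quantification stage
(:func:`quantify_scene`) receives only pixels and an ROI mask — it has no
access to group labels, which are joined onto the table only at the
statistics stage.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .burden import (
    AnnotationSet,
    TrainedClassifier,
    extract_features,
    load_fraction,
    normalize_stain,
    phansalkar_mask,
    predict_mask,
    train_classifier,
)
from .config import StudyConfig, config_fingerprint, validate_config
from .hscore import hscore_roi
from .soma import particle_density, run_soma_pipeline
from .stain import (
    BrightfieldImage,
    ODChannel,
    StainVectors,
    deconvolve_dab,
    rasterize_roi,
    read_image,
    read_metadata,
    read_rois,
    rgb_to_od,
)
from .stats import (
    bilateral_average,
    detect_outlier,
    group_compare,
    hemisphere_test,
    validate_measure_table,
)
from .synthetic import SceneSpec, StainElement, generate_cohort, render_scene

__all__ = ["StudyReport", "run_study", "quantify_scene", "train_study_classifier"]


@dataclass
class StudyReport:
    """Everything a run produces, traceable back to the measure table."""

    fingerprint: str
    software: str
    seed: int
    measure_table: pd.DataFrame
    comparisons: list[dict[str, Any]]
    hemisphere_tests: list[dict[str, Any]]
    exclusions: list[dict[str, Any]]

    def to_dict(self) -> dict[str, Any]:
        return {
            "fingerprint": self.fingerprint,
            "software": self.software,
            "seed": self.seed,
            "measure_table": self.measure_table.to_dict(orient="records"),
            "comparisons": self.comparisons,
            "hemisphere_tests": self.hemisphere_tests,
            "exclusions": self.exclusions,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1, default=_json_default)

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.measure_table.to_csv(directory / "measures.csv", index=False)
        pd.DataFrame(self.comparisons).to_csv(directory / "comparisons.csv", index=False)
        (directory / "report.json").write_text(self.to_json())
        return directory


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Blind quantification stage (no group labels in scope)
# ---------------------------------------------------------------------------

def quantify_scene(
    image: BrightfieldImage,
    roi_mask: np.ndarray,
    metric: str,
    config: StudyConfig,
    classifier: TrainedClassifier | None = None,
) -> float:
    """Quantify one metric on one image+ROI. Never sees group membership."""
    od = rgb_to_od(image)
    dab = deconvolve_dab(od, StainVectors.hdab(), image.pixel_size)
    if metric == "AT8_hscore":
        result, _, _ = hscore_roi(dab, roi_mask, config.thresholds, config.slic)
        return result.hscore
    if metric == "Iba1_load":
        if classifier is None:
            raise ValueError("Iba1_load requires a trained pixel classifier")
        features = extract_features(dab, classifier.feature_spec)
        mask = predict_mask(classifier, features)
        return load_fraction(mask, roi_mask).load
    if metric == "GFAP_load":
        mask = phansalkar_mask(normalize_stain(dab), config.phansalkar)
        return load_fraction(mask, roi_mask).load
    if metric == "Iba1_density":
        particles = run_soma_pipeline(dab, roi_mask, config.morph)
        return particle_density(particles, roi_mask).density_per_mm2
    raise ValueError(f"unknown metric {metric!r}")


def train_study_classifier(config: StudyConfig) -> TrainedClassifier:
    """Train the study's pixel classifier on a dedicated annotated training scene.

    The training tile contains one large strong-DAB patch on clean
    background; positive and negative annotation rectangles are drawn well
    inside / outside the patch.
    """
    h, w = config.image_size
    ps = config.pixel_size
    patch_r_um = min(h, w) * ps / 4
    spec = SceneSpec(
        image_size=(h, w),
        pixel_size=ps,
        elements=(
            StainElement(
                "diffuse_patch",
                (w / 2, h / 2),
                np.pi * patch_r_um**2,
                peak_od=0.6,
                intended_class="strong",
            ),
        ),
        seed=config.seed + 101,
    )
    image, _ = render_scene(spec)
    od = rgb_to_od(image)
    dab = deconvolve_dab(od, StainVectors.hdab(), ps)
    features = extract_features(dab, config.features)
    r_px = patch_r_um / ps
    cx, cy = w / 2, h / 2
    # positive: polygon tracing the patch up to 1 px inside its boundary, so
    # edge-adjacent pixels (partially smoothed features) are in training
    theta = np.linspace(0, 2 * np.pi, 33)[:-1]
    positive = np.column_stack(
        [cx + (r_px - 1) * np.cos(theta), cy + (r_px - 1) * np.sin(theta)]
    )
    # negatives: four border bands stopping 2 px outside the patch
    gap = r_px + 2
    negatives = [
        np.array([[0, 0], [w, 0], [w, cy - gap], [0, cy - gap]], float),
        np.array([[0, cy + gap], [w, cy + gap], [w, h], [0, h]], float),
        np.array([[0, cy - gap], [cx - gap, cy - gap], [cx - gap, cy + gap], [0, cy + gap]], float),
        np.array([[cx + gap, cy - gap], [w, cy - gap], [w, cy + gap], [cx + gap, cy + gap]], float),
    ]
    annotations = AnnotationSet(
        [(positive, "positive")] + [(neg, "negative") for neg in negatives]
    )
    return train_classifier(
        features, annotations, seed=config.seed, feature_spec=config.features
    )


# ---------------------------------------------------------------------------
# Study runner
# ---------------------------------------------------------------------------

def _blind_measures_synthetic(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (blind frame without group labels, metadata join table)."""
    cohort = generate_cohort(config.cohort)
    meta = pd.DataFrame(
        {
            "mouse_id": [r.id for r in cohort.metadata],
            "genotype": [r.genotype for r in cohort.metadata],
            "delay_days": [r.delay_days for r in cohort.metadata],
        }
    )
    groups = cohort.measures[["mouse_id", "group"]].drop_duplicates()
    meta = meta.merge(groups, on="mouse_id")
    blind = cohort.measures[["mouse_id", "region", "hemisphere", "metric", "true_value"]].copy()
    if not config.render:
        blind = blind.rename(columns={"true_value": "value"})
        return blind, meta
    classifier = (
        train_study_classifier(config) if config.cohort.metric == "Iba1_load" else None
    )
    values = []
    for _, row in cohort.measures.iterrows():
        spec = cohort.scene_spec(
            row.mouse_id,
            row.region,
            row.hemisphere,
            image_size=config.image_size,
            pixel_size=config.pixel_size,
        )
        image, _ = render_scene(spec)
        roi = np.ones(config.image_size, dtype=bool)
        values.append(quantify_scene(image, roi, row.metric, config, classifier))
    blind = blind.drop(columns=["true_value"])
    blind["value"] = values
    return blind, meta


def _blind_measures_files(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    records = read_metadata(config.metadata_csv)
    meta = pd.DataFrame(
        {
            "mouse_id": [r.id for r in records],
            "genotype": [r.genotype for r in records],
            "delay_days": [r.delay_days for r in records],
            "group": [r.group for r in records],
        }
    )
    manifest = pd.read_csv(config.manifest_csv)
    classifier = None
    rows = []
    base = Path(config.manifest_csv).parent
    for _, row in manifest.iterrows():
        image = read_image(base / row.image_path, config.pixel_size)
        if "roi_path" in manifest.columns and isinstance(row.get("roi_path"), str):
            outlines = read_rois(base / row.roi_path)
            match = [
                o
                for o in outlines
                if o.region == row.region and o.hemisphere == row.hemisphere
            ]
            if not match:
                warnings.warn(
                    f"no ROI for {row.mouse_id}/{row.region}/{row.hemisphere}; skipped"
                )
                continue
            roi = rasterize_roi(match[0], image.shape)
        else:
            roi = np.ones(image.shape, dtype=bool)
        metric = row.metric
        if metric == "Iba1_load" and classifier is None:
            classifier = train_study_classifier(config)
        rows.append(
            {
                "mouse_id": row.mouse_id,
                "region": row.region,
                "hemisphere": row.hemisphere,
                "metric": metric,
                "value": quantify_scene(image, roi, metric, config, classifier),
            }
        )
    return pd.DataFrame(rows), meta


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full study described by ``config`` and return its report."""
    findings = validate_config(config)
    if findings:
        raise ValueError(f"invalid configuration: {findings}")
    if config.mode == "synthetic":
        blind, meta = _blind_measures_synthetic(config)
    else:
        blind, meta = _blind_measures_files(config)

    # statistics stage: group labels join here, and only here
    table = blind.merge(meta, on="mouse_id")
    table = table[
        ["mouse_id", "genotype", "group", "delay_days", "region", "hemisphere", "metric", "value"]
    ]
    validate_measure_table(table)

    exclusions: list[dict[str, Any]] = []
    hemi_results: list[dict[str, Any]] = []
    comparisons: list[dict[str, Any]] = []

    control_label = config.stats.control_group
    treated_labels = [g for g in table.group.unique() if g != control_label]

    for (metric, region), sub in table.groupby(["metric", "region"], sort=True):
        if config.stats.hemisphere_tests:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ht = hemisphere_test(sub, metric, region)
                hemi_results.append(
                    {
                        "metric": metric,
                        "region": region,
                        "W": ht.statistic,
                        "p": ht.p,
                        "n_pairs": ht.n_pairs,
                        "underpowered": ht.underpowered,
                        "dropped_mice": list(ht.dropped_mice),
                    }
                )
                for m in ht.dropped_mice:
                    exclusions.append(
                        {"mouse_id": m, "metric": metric, "region": region,
                         "reason": "missing hemisphere in paired test"}
                    )
            except ValueError:
                pass
        avg = bilateral_average(sub)
        control_vals = avg[avg.group == control_label]
        if config.stats.outlier_screen and len(control_vals) >= 3:
            rep = detect_outlier(
                control_vals.value.to_numpy(),
                alpha=config.stats.outlier_alpha,
                ids=control_vals.mouse_id.tolist(),
                group=control_label,
            )
            for m in rep.flagged:
                exclusions.append(
                    {"mouse_id": m, "metric": metric, "region": region,
                     "reason": f"Grubbs outlier (G={rep.statistic:.3f} > {rep.critical:.3f})"}
                )
                avg = avg[avg.mouse_id != m]
                control_vals = avg[avg.group == control_label]
        for treated_label in treated_labels:
            treated_vals = avg[avg.group == treated_label]
            if treated_vals.empty or control_vals.empty:
                continue
            cmp = group_compare(
                treated_vals.value.to_numpy(),
                control_vals.value.to_numpy(),
                group_labels=(treated_label, control_label),
                exact_max_n=config.stats.exact_max_n,
            )
            comparisons.append(
                {
                    "metric": metric,
                    "region": region,
                    "treated_group": treated_label,
                    "control_group": control_label,
                    "n_treated": cmp.n_treated,
                    "n_control": cmp.n_control,
                    "U": cmp.U,
                    "p": cmp.p,
                    "method": cmp.method,
                    "control_mean": cmp.control_mean,
                    "normalized_mean_treated": cmp.normalized_means[treated_label],
                    "normalized_mean_control": cmp.normalized_means[control_label],
                    "percent_change": cmp.percent_change,
                    "stars": cmp.stars,
                }
            )

    return StudyReport(
        fingerprint=config_fingerprint(config),
        software=f"dabquant {__version__}",
        seed=config.seed,
        measure_table=table,
        comparisons=comparisons,
        hemisphere_tests=hemi_results,
        exclusions=exclusions,
    )
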
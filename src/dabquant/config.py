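"""Study configuration: one serializable object drives an entire run.

Per-experiment constants (notably the intensity thresholds, which must stay
constant across every image of one experiment) live here rather than
per-image, so a run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .burden import PhansalkarParams, PixelFeatureSpec
from .hscore import IntensityThresholds, SlicParams
from .soma import MorphParams
from .stain import REGIONS
from .synthetic import METRICS, CohortSpec, GroupSpec

__all__ = ["StudyConfig", "StatsOptions", "validate_config", "config_fingerprint"]


@dataclass(frozen=True)
class StatsOptions:
    control_group: str = "control"
    exact_max_n: int = 16
    outlier_screen: bool = False
    outlier_alpha: float = 0.05
    hemisphere_tests: bool = True
    normalize: bool = True


@dataclass
class StudyConfig:
    """Everything needed to run a study.

    mode 'synthetic' generates a cohort from ``cohort``; mode 'files' reads
    ``metadata_csv`` and ``manifest_csv`` (mouse_id, region, hemisphere,
    image_path, roi_path columns).  ``render`` controls whether synthetic
    scenes are rendered and re-quantified through the imaging arms, or the
    generator's ground-truth metric values feed the statistics directly.
    """

    seed: int = 0
    mode: str = "synthetic"
    cohort: CohortSpec | None = None
    render: bool = True
    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 0.25
    metadata_csv: str | None = None
    manifest_csv: str | None = None
    thresholds: IntensityThresholds = field(
        default_factory=lambda: IntensityThresholds(0.15, 0.35, 0.65)
    )
    slic: SlicParams = field(default_factory=SlicParams)
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    morph: MorphParams = field(default_factory=MorphParams)
    features: PixelFeatureSpec = field(default_factory=PixelFeatureSpec)
    stats: StatsOptions = field(default_factory=StatsOptions)

    def __post_init__(self) -> None:
        if self.mode == "synthetic" and self.cohort is None:
            self.cohort = CohortSpec(
                groups=(
                    GroupSpec("sonicated", 10, 1.48, arm="sonicated"),
                    GroupSpec("control", 6, 1.0, arm="non_sonicated"),
                ),
                seed=self.seed,
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        return enc(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        if d.get("cohort"):
            c = dict(d["cohort"])
            c["groups"] = tuple(
                GroupSpec(**{**g, "multiplier": _as_multiplier(g.get("multiplier", 1.0))})
                for g in c.get("groups", [])
            )
            c["regions"] = tuple(c.get("regions", REGIONS))
            d["cohort"] = CohortSpec(**c)
        for key, klass in (
            ("thresholds", IntensityThresholds),
            ("slic", SlicParams),
            ("phansalkar", PhansalkarParams),
            ("morph", MorphParams),
            ("stats", StatsOptions),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**d[key])
        if "features" in d and isinstance(d["features"], dict):
            f = d["features"]
            d["features"] = PixelFeatureSpec(
                gaussian_radii_um=tuple(f.get("gaussian_radii_um", (0.5, 1.0, 2.0))),
                std_radii_um=tuple(f.get("std_radii_um", (1.0, 2.0))),
                include_raw=f.get("include_raw", True),
            )
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _as_multiplier(m: Any) -> Any:
    return {str(k): float(v) for k, v in m.items()} if isinstance(m, dict) else float(m)


def config_fingerprint(config: StudyConfig) -> str:
    """Stable digest; changes iff the configuration changes."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: StudyConfig | dict) -> list[dict[str, str]]:
    """Schema/range check; returns findings (empty = valid), never mutates.

    Accepts a StudyConfig or a raw mapping; construction errors (e.g. a
    threshold-ordering violation) are reported as findings, not raised.
    """
    findings: list[dict[str, str]] = []

    def add(fld: str, msg: str) -> None:
        findings.append({"field": fld, "message": msg})

    if isinstance(config, dict):
        try:
            config = StudyConfig.from_dict(config)
        except (ValueError, TypeError) as exc:
            add("config", str(exc))
            return findings

    if config.mode not in ("synthetic", "files"):
        add("mode", f"unknown mode {config.mode!r}")
    if config.mode == "files":
        for name in ("metadata_csv", "manifest_csv"):
            p = getattr(config, name)
            if p is None:
                add(name, "required in files mode")
            elif not Path(p).exists():
                add(name, f"path does not exist: {p}")
    if config.mode == "synthetic" and config.cohort is not None:
        try:
            groups = config.cohort.groups
            if len(groups) < 2:
                add("cohort.groups", "at least two groups required for comparison")
            labels = [g.label for g in groups]
            if config.stats.control_group not in labels:
                add(
                    "stats.control_group",
                    f"{config.stats.control_group!r} not among group labels {labels}",
                )
        except Exception as exc:  # defensive: report, never raise
            add("cohort", str(exc))
    t = config.thresholds
    if not (0 <= t.t_weak < t.t_moderate < t.t_strong):
        add("thresholds", "require 0 <= t_weak < t_moderate < t_strong")
    if not config.pixel_size > 0:
        add("pixel_size", "must be > 0")
    if config.slic.target_diameter / config.pixel_size < 2:
        add("slic.target_diameter", "below 2 pixels at this pixel size")
    if not config.morph.min_area > 0:
        add("morph.min_area", "must be > 0")
    if config.phansalkar.radius < 1:
        add("phansalkar.radius", "must be >= 1")
    if not (0 < config.stats.outlier_alpha < 1):
        add("stats.outlier_alpha", "must lie in (0, 1)")
    return findings
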
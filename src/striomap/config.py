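"""Run configuration: every stage threshold as a first-class, auditable parameter.

A :class:`RunConfig` is a single JSON-serializable object whose defaults
are the analysis constants used throughout the pipeline (density tier
thresholds 0.2 / 0.05 / 0.005, 100 um injection-core erosion, 150 um
clustering voxel, network cutoffs 0.15 / 0.2 / 0.5, and the graded /
binary confidence-criteria sets).  Serializing the config reproduces a
run bit-identically for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

from .alignment import SectionTransform
from .synthetic_data import SceneConfig


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    scene: SceneConfig = None  # type: ignore[assignment]
    density_thresholds: tuple[float, float, float] = (0.2, 0.05, 0.005)
    core_erosion_um: float = 100.0
    cluster_voxel_um: float = 150.0
    cluster_metric: str = "spearman"
    n_clusters: int | None = None  # default: the scene's planted count
    corticocortical_cutoff: float = 0.15
    thalamic_cutoff: float = 0.20
    convergent_cutoff: float = 0.50
    primary_occupancy_cutoff: float = 0.20
    primary_within_cutoff: float = 0.50
    alignment_rounds: int = 2
    confidence_level_mode: str = "ge"

    def __post_init__(self):
        if self.scene is None:
            self.scene = SceneConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        mis = d["scene"].get("misalignment")
        if mis is not None and mis.get("per_section_shifts") is not None:
            import numpy as np

            mis["per_section_shifts"] = np.asarray(mis["per_section_shifts"]).tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = d.get("scene")
        if isinstance(scene, dict):
            scene = dict(scene)
            mis = scene.get("misalignment")
            if isinstance(mis, dict):
                scene["misalignment"] = SectionTransform(**mis)
            if isinstance(scene.get("grid_shape"), list):
                scene["grid_shape"] = tuple(scene["grid_shape"])
            d["scene"] = SceneConfig(**scene)
        if isinstance(d.get("density_thresholds"), list):
            d["density_thresholds"] = tuple(d["density_thresholds"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def setup_logging(level: str = "INFO", log_file=None) -> None:
    """Log to stderr and, when given, to a run-directory file."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(str(log_file)))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
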
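"""Access to the shipped configuration and reference-data files.

The package ships plain-text ``.cfg`` files (YAML syntax) for the material
libraries, pendulum modalities, loading grid, boot layer curves and risk
curves, plus small CSV transcriptions of published result tables used as
inputs by the assessment machinery.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .limb_model import BootModel
from .loading import LoadingGrid, PendulumSpec, load_grid, \
    load_pendulum_modalities
from .materials import MaterialLibrary, SpringCurve, load_library

__all__ = [
    "data_path",
    "reference_materials",
    "calibrated_materials",
    "pendulum_modalities",
    "ubb_grid",
    "load_boot",
    "default_boot_config",
    "published_force_differences",
    "published_risk_reductions",
    "published_rating_metrics",
]


def data_path(name: str) -> Path:
    """Path to a shipped data file."""
    return Path(str(resources.files("ubblimb") / "data" / name))


def reference_materials() -> MaterialLibrary:
    """Pre-calibration material library (literature parameter set)."""
    return load_library(data_path("table1.cfg"))


def calibrated_materials() -> MaterialLibrary:
    """Calibrated plantar tissue and plantar fascia parameters."""
    return load_library(data_path("table3.cfg"))


def pendulum_modalities() -> list[PendulumSpec]:
    """The ten pendulum validation test modalities."""
    return load_pendulum_modalities(data_path("table2.cfg"))


def ubb_grid() -> LoadingGrid:
    """The canonical 25-point loading sweep."""
    return load_grid(data_path("ubb_grid.cfg"))


def load_boot(path: str | Path) -> BootModel:
    """Read a boot layer stack from a ``.cfg`` file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    layers = []
    for name, entry in raw["layers"].items():
        pts = tuple(tuple(p) for p in entry["points"])
        layers.append((name, SpringCurve(pts, tension_only=False)))
    return BootModel(layers=layers,
                     junction_mass=raw.get("junction_mass", 0.02))


def default_boot_config() -> BootModel:
    return load_boot(data_path("boot.cfg"))


def published_force_differences() -> pd.DataFrame:
    """Published percent force differences over the 25-point sweep."""
    return pd.read_csv(data_path("table5.csv"))


def published_risk_reductions() -> pd.DataFrame:
    """Published injury-probability changes for the first 15 combinations."""
    return pd.read_csv(data_path("table6.csv"))


def published_rating_metrics() -> pd.DataFrame:
    """Published objective-rating sub-scores and grades per model version."""
    return pd.read_csv(data_path("cora_reference.csv"))
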
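"""Shared YAML configuration for the command-line pipeline.

One file with sections mirroring the library modules; unknown keys are
rejected and omitted keys fall back to the defaults below, which are the
full-scale study values (disk radius 8, learning rate 0.1, Nesterov
momentum 0.8, batch 5, peak threshold 0.2, peak min distance 5, pseudo
radius 6, matching distance 20, KDE sigma 50 with 5 bins, 6 adaptation
cycles).
"""

from __future__ import annotations

import copy
import json
import platform
import sys
from pathlib import Path

import numpy as np
import yaml

__all__ = ["default_config", "load_config", "write_manifest", "stage_seed"]

_DEFAULTS: dict = {
    "model": {"depth": 3, "base_filters": 16, "in_channels": 3},
    "schedule": {
        "total_epochs": 60,
        "cycle_length": 10,
        "lr0": 0.1,
        "lr_decay": 0.5,
        "momentum": 0.8,
        "batch_size": 5,
        "val_fraction": 0.25,
        "patch_sizes": [256, 384, 192, 320, 256, 384],
    },
    "targets": {"max_radius": 8},
    "adapt": {
        "n_cycles": 6,
        "epochs_per_cycle": 10,
        "peak_threshold": 0.2,
        "peak_min_distance": 5,
        "pseudo_radius": 6,
        "n_target_images_per_cycle": 4,
        "source_fraction": 0.5,
    },
    "detect": {"triplet_start": 13, "peak_threshold": 0.2, "peak_min_distance": 5},
    "evaluate": {"max_dist": 20.0, "sigma": 50.0, "n_bins": 5},
    "simulate": {"image_shape": [128, 128], "n_planes": 5},
    "stack": {"plane_spacing_um": 10.0, "in_focus_index": 13},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def load_config(path: str | Path | None) -> dict:
    """Defaults overlaid with a YAML file (section-wise)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in cfg[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            cfg[section][key] = value
    return cfg


def stage_seed(global_seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from the global seed and the stage name.

    The derivation (SeedSequence over the seed plus the stage name's
    bytes) makes every stage independently reproducible from the single
    run seed.
    """
    tokens = [int(global_seed)] + list(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(tokens))


def write_manifest(out_dir: str | Path, command: str, seed: int | None,
                   config: dict, extra: dict | None = None) -> Path:
    """Echo everything needed to reproduce a run into ``run_manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import stackdetect

    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "versions": {
            "stackdetect": stackdetect.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
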
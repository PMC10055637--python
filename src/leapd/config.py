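"""One structured YAML config file for the command-line interface.

Top-level keys mirror the pipeline stages: ``simulate``, ``preprocess``,
``lpc``, ``subspace``, ``train``, ``evaluate``.  Anything omitted falls
back to the package defaults; unknown keys are rejected so typos fail
loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .preprocess import Band
from .synthetic import SyntheticSpec
from .training import TrainingSettings, default_grid, reduced_grid

KNOWN_KEYS = {"simulate", "preprocess", "lpc", "subspace", "train", "evaluate"}


def load_config(path=None) -> dict:
    if path is None:
        return {}
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config sections {sorted(unknown)}; "
            f"expected a subset of {sorted(KNOWN_KEYS)}"
        )
    return cfg


def synthetic_spec_from_config(cfg: dict, **overrides) -> SyntheticSpec:
    block = dict(cfg.get("simulate", {}))
    block.update({k: v for k, v in overrides.items() if v is not None})
    if "informative_channels" in block:
        block["informative_channels"] = frozenset(block["informative_channels"])
    if "channel_labels" in block:
        block["channel_labels"] = tuple(block["channel_labels"])
    return SyntheticSpec(**block)


def training_settings_from_config(cfg: dict, **overrides) -> TrainingSettings:
    """Build settings from the ``train``/``lpc``/``subspace`` sections.

    The grid can be given as ``train.grid: full|reduced`` or spelled out
    as a list of ``[f_lo, f_hi, order, k_normal, k_impaired]`` rows.
    """
    block = dict(cfg.get("train", {}))
    block.update({k: v for k, v in overrides.items() if v is not None})
    grid = block.pop("grid", "reduced")
    if grid == "full":
        grid = default_grid()
    elif grid == "reduced":
        grid = reduced_grid()
    else:
        grid = [
            (Band(row[0], row[1]), int(row[2]), int(row[3]), int(row[4]))
            for row in grid
        ]
    line_freq = cfg.get("preprocess", {}).get("line_freq", 60.0)
    return TrainingSettings(grid=grid, line_freq=line_freq, **block)
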
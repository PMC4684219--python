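"""Run configuration: every tunable of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

__all__ = ["RunConfig", "load_config", "parse_sides"]


@dataclass
class RunConfig:
    """Pipeline parameters with their conventional defaults.

    Distances in Angstrom, energies in kcal/mol. ``td_factor`` scales the
    sum of van der Waals radii into the contact distance threshold;
    ``beta_angle_deg`` is the interruption angle of the beta-contact test.
    """

    td_factor: float = 1.25
    beta_angle_deg: float = 85.0
    trim_low_frac: float = 0.01
    trim_high_frac: float = 0.09
    probe_radius: float = 1.4
    asa_n_points: int = 960
    water_asa_max: float = 1.0  # A^2, burial threshold of the water rule
    water_min_contacts: int = 3
    label_threshold: float = 2.0  # kcal/mol, observed hot-spot definition
    prediction_threshold: float = 1.5  # kcal/mol, predicted hot-spot call
    n_trees: int = 500
    min_node_size: int = 3
    max_features_frac: float = 1.0 / 3.0  # regression convention
    min_nonzero: int = 3  # keep features with MORE than this many non-zeros
    seed: int = 1

    def __post_init__(self) -> None:
        if not (1.0 <= self.td_factor <= 2.0):
            raise ValueError("td_factor must lie in [1.0, 2.0]")
        if not (0.0 < self.beta_angle_deg < 180.0):
            raise ValueError("beta_angle_deg must lie in (0, 180)")
        if self.label_threshold <= 0 or self.prediction_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def parse_sides(spec: str) -> tuple[set, set]:
    """Parse a chain-side spec like ``"A:B"`` or ``"AB:CD"``."""
    parts = spec.split(":")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValueError(f"side spec {spec!r} must look like 'A:B' or 'AB:CD'")
    side_a, side_b = set(parts[0]), set(parts[1])
    if side_a & side_b:
        raise ValueError(f"side spec {spec!r} assigns a chain to both sides")
    return side_a, side_b
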
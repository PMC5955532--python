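"""Flat key = value configuration files and run manifests.

The configuration grammar is deliberately minimal: one ``key = value``
assignment per line, ``#`` comments, blank lines ignored.  Keys mirror
:class:`~pyrolith.simulate.SimulationConfig` fields; the grid comes from
``area_file`` (a path) or ``grid`` (``LAYER1``, ``LAYER2`` or ``RxC``
for an all-interior rectangle).  Unknown keys are rejected outright so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .grid import CaveLayer, make_case_study_cave, make_rectangle, parse_area_file
from .simulate import (
    FirePlacement,
    LithicPlacement,
    ScatterKernel,
    SimulationConfig,
)


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration files."""


_INT_KEYS = {
    "n_occupations",
    "fires_per_occupation",
    "scatters_per_occupation",
    "lithics_per_scatter",
    "skip",
    "seed",
    "n_experiments",
}
_FLOAT_KEYS = {"tb_pct", "introduced_pct"}
_KNOWN_KEYS = _INT_KEYS | _FLOAT_KEYS | {
    "grid",
    "area_file",
    "fire_size",
    "fire_placement",
    "lithic_placement",
    "scatter_kernel",
}


def _parse_lines(text: str) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        if key in values:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        values[key] = value
    return values


def _resolve_grid(values: dict[str, str], base_dir: Path | None):
    if "area_file" in values and "grid" in values:
        raise ConfigError("give either 'grid' or 'area_file', not both")
    if "area_file" in values:
        path = Path(values["area_file"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ConfigError(f"area file not found: {path}")
        return parse_area_file(path.read_text())
    if "grid" not in values:
        raise ConfigError("missing grid: set 'grid' or 'area_file'")
    spec = values["grid"].upper()
    if spec in (layer.value for layer in CaveLayer):
        return make_case_study_cave(spec)
    if "X" in spec:
        try:
            rows, cols = (int(p) for p in spec.split("X"))
            return make_rectangle(rows, cols)
        except ValueError:
            pass
    raise ConfigError(
        f"invalid grid {values['grid']!r}: use LAYER1, LAYER2 or RxC"
    )


def parse_config(
    source: str | Path, base_dir: Path | None = None
) -> tuple[SimulationConfig, int]:
    """Parse a config file (path or text) into a config and replicate count.

    Returns ``(SimulationConfig, n_experiments)`` with defaults applied
    (100 lithics per scatter, 1 % introduced, skip 0, 30 experiments).
    """
    if isinstance(source, Path):
        base_dir = base_dir or source.parent
        text = source.read_text()
    else:
        text = source
    values = _parse_lines(text)
    grid = _resolve_grid(values, base_dir)
    kwargs: dict = {"grid": grid}
    n_experiments = 30

    for key in _INT_KEYS & values.keys():
        try:
            parsed = int(values[key])
        except ValueError:
            raise ConfigError(f"{key}: expected an integer, got {values[key]!r}")
        if key == "n_experiments":
            n_experiments = parsed
        else:
            kwargs[key] = parsed
    for key in _FLOAT_KEYS & values.keys():
        try:
            kwargs[key] = float(values[key])
        except ValueError:
            raise ConfigError(f"{key}: expected a number, got {values[key]!r}")
    if "fire_size" in values:
        try:
            size = int(values["fire_size"])
        except ValueError:
            size = -1
        if size not in (1, 4):
            raise ConfigError(
                f"fire_size: invalid value {values['fire_size']!r}; choices: 1, 4"
            )
        kwargs["fire_size"] = size
    if "fire_placement" in values:
        try:
            kwargs["fire_placement"] = FirePlacement(values["fire_placement"].upper())
        except ValueError:
            choices = ", ".join(m.value for m in FirePlacement)
            raise ConfigError(
                f"fire_placement: invalid value {values['fire_placement']!r}; "
                f"choices: {choices}"
            )
    if "lithic_placement" in values:
        try:
            kwargs["lithic_placement"] = LithicPlacement(
                values["lithic_placement"].upper()
            )
        except ValueError:
            choices = ", ".join(m.value for m in LithicPlacement)
            raise ConfigError(
                f"lithic_placement: invalid value {values['lithic_placement']!r}; "
                f"choices: {choices}"
            )
    if "scatter_kernel" in values:
        parts = values["scatter_kernel"].split(",")
        if len(parts) != 3:
            raise ConfigError(
                "scatter_kernel: expected 'center,orthogonal,diagonal' weights"
            )
        try:
            kwargs["kernel"] = ScatterKernel(*(float(p) for p in parts))
        except ValueError as exc:
            raise ConfigError(f"scatter_kernel: {exc}")
    if "n_occupations" not in kwargs:
        raise ConfigError("missing required key 'n_occupations'")
    try:
        config = SimulationConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc))
    if n_experiments < 1:
        raise ConfigError("n_experiments must be >= 1")
    return config, n_experiments


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a logged run exactly."""

    config_text: str
    resolved: dict
    seed: int
    version: str
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool": "pyrolith",
                "version": self.version,
                "seed": self.seed,
                "config_text": self.config_text,
                "resolved": self.resolved,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def make_manifest(
    config_text: str, config: SimulationConfig, n_experiments: int, outputs: list[str]
) -> RunManifest:
    resolved = {
        "grid_name": config.grid.name or f"{config.grid.n_rows}x{config.grid.n_cols}",
        "grid_area_file_sha": None,
        "n_interior": config.grid.n_interior,
        "n_occupations": config.n_occupations,
        "fires_per_occupation": config.fires_per_occupation,
        "fire_size": config.fire_size,
        "fire_placement": config.fire_placement.value,
        "scatters_per_occupation": config.scatters_per_occupation,
        "lithics_per_scatter": config.lithics_per_scatter,
        "lithic_placement": config.lithic_placement.value,
        "kernel": [config.kernel.center, config.kernel.orthogonal, config.kernel.diagonal],
        "tb_pct": config.tb_pct,
        "introduced_pct": config.introduced_pct,
        "skip": config.skip,
        "seed": config.seed,
        "n_experiments": n_experiments,
    }
    return RunManifest(
        config_text=config_text,
        resolved=resolved,
        seed=config.seed,
        version=__version__,
        outputs=outputs,
    )
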
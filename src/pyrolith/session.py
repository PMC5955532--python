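"""Replicate sessions, parameter sweeps and CSV simulation logs.

A *session* repeats one parameter configuration over independent
experiments (30 by default) and reports the heated-lithic percentage as
mean and sample standard deviation.  Random substreams are derived from
the master seed by a fixed counter scheme — seed sequence entropy
``(seed, session_index, experiment_index)`` — so experiments are
order-independent and any logged run is exactly reproducible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .simulate import (
    LayerState,
    SimulationConfig,
    heated_percentage,
    run_experiment,
)


def experiment_rng(
    seed: int, experiment_index: int, session_index: int = 0
) -> np.random.Generator:
    """Independent random stream for one experiment of one session."""
    ss = np.random.SeedSequence([seed, session_index, experiment_index])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SessionResult:
    """Aggregate of one session's replicate experiments."""

    config: SimulationConfig
    n_experiments: int
    heated_percentages: tuple[float, ...]
    mean_pct: float
    sd_pct: float  #: sample SD (n-1 denominator); 0 when undefined
    sd_defined: bool  #: False for single-experiment sessions
    session_index: int = 0

    @property
    def se_pct(self) -> float:
        """Standard error of the session mean."""
        return self.sd_pct / math.sqrt(self.n_experiments)


def run_session(
    config: SimulationConfig,
    n_experiments: int = 30,
    session_index: int = 0,
    keep_states: bool = False,
) -> SessionResult | tuple[SessionResult, list[LayerState]]:
    """Run ``n_experiments`` independent experiments and aggregate them."""
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    pcts = []
    states = []
    for i in range(n_experiments):
        rng = experiment_rng(config.seed, i, session_index)
        state = run_experiment(config, rng)
        pcts.append(heated_percentage(state))
        if keep_states:
            states.append(state)
    arr = np.asarray(pcts)
    sd_defined = n_experiments > 1
    result = SessionResult(
        config=config,
        n_experiments=n_experiments,
        heated_percentages=tuple(pcts),
        mean_pct=float(arr.mean()),
        sd_pct=float(arr.std(ddof=1)) if sd_defined else 0.0,
        sd_defined=sd_defined,
        session_index=session_index,
    )
    return (result, states) if keep_states else result


def sweep(
    base_config: SimulationConfig,
    parameter: str,
    values: list,
    n_experiments: int = 30,
) -> list[SessionResult]:
    """One session per parameter value, all other parameters held fixed.

    Sessions are indexed by their position in ``values``, so the whole
    sweep is deterministic under a fixed master seed.
    """
    names = {f.name for f in dc_fields(SimulationConfig)}
    if parameter not in names:
        raise ValueError(
            f"unknown parameter {parameter!r}; choose one of {sorted(names)}"
        )
    results = []
    for i, value in enumerate(values):
        cfg = base_config.with_(**{parameter: value})
        results.append(run_session(cfg, n_experiments, session_index=i))
    return results


_CONFIG_COLUMNS = [
    "grid_name",
    "grid_rows",
    "grid_cols",
    "n_interior",
    "n_occupations",
    "fires_per_occupation",
    "fire_size",
    "fire_placement",
    "scatters_per_occupation",
    "lithics_per_scatter",
    "lithic_placement",
    "kernel",
    "tb_pct",
    "introduced_pct",
    "skip",
    "seed",
]


def _config_values(config: SimulationConfig) -> list:
    k = config.kernel
    return [
        config.grid.name or f"{config.grid.n_rows}x{config.grid.n_cols}",
        config.grid.n_rows,
        config.grid.n_cols,
        config.grid.n_interior,
        config.n_occupations,
        config.fires_per_occupation,
        config.fire_size,
        config.fire_placement.value,
        config.scatters_per_occupation,
        config.lithics_per_scatter,
        config.lithic_placement.value,
        f"{k.center:g}/{k.orthogonal:g}/{k.diagonal:g}",
        config.tb_pct,
        config.introduced_pct,
        config.skip,
        config.seed,
    ]


def write_session_log(results: SessionResult | list[SessionResult], path) -> None:
    """Write a CSV simulation log: one row per experiment plus a summary row.

    Floats are written with ``repr`` precision so the per-experiment
    percentages round-trip exactly and re-runs with the same seed
    produce byte-identical files.
    """
    if isinstance(results, SessionResult):
        results = [results]
    if not results:
        raise ValueError("no session results to log")
    header = ["row_type", "session", "experiment", *_CONFIG_COLUMNS,
              "total_lithics", "heated_lithics", "heated_pct"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for res in results:
            cfg_vals = _config_values(res.config)
            total = (
                res.config.n_occupations
                * res.config.scatters_per_occupation
                * res.config.lithics_per_scatter
            )
            for i, pct in enumerate(res.heated_percentages):
                heated = round(pct / 100.0 * total)
                writer.writerow(
                    ["experiment", res.session_index, i, *cfg_vals,
                     total, heated, repr(pct)]
                )
            writer.writerow(
                ["session_summary", res.session_index, "", *cfg_vals,
                 total, "", repr(res.mean_pct)]
            )
            writer.writerow(
                ["session_sd", res.session_index, "", *cfg_vals,
                 total, "", repr(res.sd_pct)]
            )


def read_session_log(path) -> dict[int, list[float]]:
    """Recover per-experiment heated percentages from a session log."""
    out: dict[int, list[float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["row_type"] == "experiment":
                out.setdefault(int(row["session"]), []).append(
                    float(row["heated_pct"])
                )
    return out
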
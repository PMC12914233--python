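"""One-way sensitivity sweeps over the simulation's intervention knobs.

Each sweep varies a single parameter over a value list while holding
everything else (including the per-trial seeds) fixed, so runs differ only
through the swept parameter. Supported parameters: ``initial_trust_mean``
(location-shift of the agents' initial trust distribution, clamped to
[1, 5]), ``broadcast_penalty``, ``reward_magnitude``,
``rewire_interval_days``. Sweeping an intervention parameter implies
running that intervention's strategy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .abm import ABMConfig, TrajectorySummary, run_experiment
from .regression import LogisticFit

__all__ = ["SweepSpec", "sweep", "SWEEP_PARAMETERS", "DEFAULT_SWEEP_VALUES"]

#: parameter -> strategy it exercises
SWEEP_PARAMETERS = {
    "initial_trust_mean": "baseline",
    "broadcast_penalty": "broadcast",
    "reward_magnitude": "reward",
    "rewire_interval_days": "rewire",
}

#: default value grids (the anchor values of each published range)
DEFAULT_SWEEP_VALUES = {
    "initial_trust_mean": (2.5, 3.0, 3.5),
    "broadcast_penalty": (0.05, 0.10, 0.20),
    "reward_magnitude": (0.03, 0.05, 0.10),
    "rewire_interval_days": (2, 5, 10),
}


@dataclass
class SweepSpec:
    """A one-way sweep: parameter name, value list, base configuration."""

    parameter: str
    values: Sequence[float]
    base_config: ABMConfig

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; expected one "
                f"of {sorted(SWEEP_PARAMETERS)}")
        if len(self.values) == 0:
            raise ValueError("value list must be nonempty")


def sweep(spec: SweepSpec, records: pd.DataFrame, fit: LogisticFit
          ) -> tuple[dict[float, TrajectorySummary], pd.DataFrame]:
    """Run one experiment per swept value.

    Returns the per-value trajectory summaries and a comparison table of
    the day-1/7/14 (or last-day) delay rates. The base seed is shared
    across values, so trajectories differ only through the parameter.
    """
    strategy = SWEEP_PARAMETERS[spec.parameter]
    cast = int if spec.parameter == "rewire_interval_days" else float
    summaries: dict[float, TrajectorySummary] = {}
    rows = []
    for value in spec.values:
        cfg = dataclasses.replace(spec.base_config, strategy=strategy,
                                  **{spec.parameter: cast(value)})
        summary = run_experiment(records, fit, cfg)
        summaries[value] = summary
        marks = sorted({1, min(7, cfg.days), cfg.days})
        row = {"parameter": spec.parameter, "value": value}
        for d in marks:
            row[f"delay_rate_day{d}"] = float(summary.delay_rate[d - 1])
            row[f"mean_trust_day{d}"] = float(summary.mean_trust[d - 1])
        rows.append(row)
    return summaries, pd.DataFrame(rows)
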
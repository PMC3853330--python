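"""Run configuration: model parameters plus experiment settings in one file.

The config file is a flat YAML mapping.  Keys that name a model parameter
go to :class:`~msabm.params.Params`; the remaining recognized keys control
the experiment (scenario, seed, steps, output).  Unknown keys are an
error; missing keys take documented defaults and are logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .cohort import SCENARIOS
from .params import Params

logger = logging.getLogger(__name__)

#: 5 simulated years at the default step of 2.4 hours
DEFAULT_STEPS = 18250

RUN_KEYS = {
    "scenario": "healthy",
    "seed": 0,
    "steps": DEFAULT_STEPS,
    "out_dir": "msabm-out",
    "write_timeseries": True,
    "write_snapshot": True,
    "write_cohort_csv": True,
}


@dataclass(frozen=True)
class RunConfig:
    """A complete, validated experiment description."""

    params: Params
    scenario: str = "healthy"
    seed: int = 0
    steps: int = DEFAULT_STEPS
    out_dir: str = "msabm-out"
    write_timeseries: bool = True
    write_snapshot: bool = True
    write_cohort_csv: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"scenario must be one of {sorted(SCENARIOS)}, got {self.scenario!r}"
            )
        if self.steps < 0:
            raise ValueError("steps must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d.update(d.pop("params"))
        return d


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> RunConfig:
    """Load and validate a RunConfig from a flat YAML file.

    An absent path yields the all-defaults configuration (published
    parameter table, healthy scenario, 5-year horizon).  Keyword overrides
    are applied after the file and obey the same validation.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a flat key/value mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    param_names = set(Params.field_names())
    unknown = set(raw) - param_names - set(RUN_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    param_kwargs = {k: v for k, v in raw.items() if k in param_names}
    run_kwargs = {k: raw.get(k, default) for k, default in RUN_KEYS.items()}
    defaulted = sorted((param_names | set(RUN_KEYS)) - set(raw))
    if defaulted:
        logger.info("config keys left at defaults: %s", ", ".join(defaulted))

    # Scenario and duplication rates are kept consistent: a named scenario
    # fills eff_dup/p_t unless those were given explicitly, and an explicit
    # hill-valued p_t selects the hill scenario label when none was named.
    if "scenario" in raw and run_kwargs["scenario"] in SCENARIOS:
        scen = SCENARIOS[run_kwargs["scenario"]]
        param_kwargs.setdefault("eff_dup", scen.eff_dup)
        param_kwargs.setdefault("p_t", scen.p_t)
    elif param_kwargs.get("p_t") == SCENARIOS["hill"].p_t:
        run_kwargs["scenario"] = "hill"

    return RunConfig(params=Params.from_dict(param_kwargs), **run_kwargs)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
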
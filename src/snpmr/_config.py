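"""Configuration-file loading for the command-line interface.

One file, TOML (preferred) or YAML, with up to four sections:

``[io]``         column-dialect mapping (file column -> canonical field)
``[instrument]`` variant_id, effect_allele, other_allele, beta_exposure,
                 se_exposure, units, optional r2 / n_exposure / eaf
``[meta]``       disease label -> list of member study labels
``[scenario]``   SimScenario fields for `simulate` / `recover`
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any

from .mr_core import InstrumentRecord
from .simulate import SimScenario

__all__ = ["load_config", "instrument_from_config", "scenario_from_config"]


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration root must be a mapping")
    return data


def instrument_from_config(config: dict[str, Any]) -> InstrumentRecord:
    try:
        section = config["instrument"]
    except KeyError:
        raise ValueError("configuration lacks an [instrument] section") from None
    known = {"variant_id", "effect_allele", "other_allele", "beta_exposure", "se_exposure", "units", "r2", "n_exposure"}
    return InstrumentRecord(**{k: v for k, v in section.items() if k in known})


def scenario_from_config(config: dict[str, Any], seed: int | None = None) -> SimScenario:
    section = dict(config.get("scenario", {}))
    if seed is not None:
        section["seed"] = seed
    return SimScenario(**section)
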
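"""CSV readers/writers, run configuration and logging helpers.

Interchange formats are plain comma-separated text with a header row:

- survival datasets: ``time,event[,cause],group[,age,sex]``
- life tables: ``age,sex,qx``
- cause fractions: ``age_start,age_end,sex,fraction``

Run configuration is YAML; each CLI run writes a plain-text log echoing
the configuration, the seed, package versions and a configuration hash,
so outputs are traceable and byte-identical under identical configs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .data import SurvivalData
from .population import CauseFractionTable, LifeTable

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_life_table",
    "read_cause_fractions",
    "RunConfig",
    "config_hash",
    "write_run_log",
]


def read_dataset(path, cause_labelled: Optional[bool] = None) -> SurvivalData:
    """Read a survival dataset from CSV, validating row by row.

    Validation failures (nonpositive times, events outside {0,1}, cause
    labels on censored rows) raise with the offending row numbers.  If
    ``cause_labelled`` is True, every event must carry a cause.
    """
    frame = pd.read_csv(path)
    ds = SurvivalData(frame)
    if cause_labelled and not ds.cause_labelled:
        raise ValueError(f"{path}: dataset is not fully cause-labelled")
    return ds


def write_dataset(ds: SurvivalData, path) -> None:
    ds.frame.to_csv(path, index=False)


def read_life_table(path, max_age: Optional[int] = None) -> LifeTable:
    return LifeTable.from_frame(pd.read_csv(path), max_age=max_age)


def read_cause_fractions(path) -> CauseFractionTable:
    return CauseFractionTable(pd.read_csv(path))


@dataclass
class RunConfig:
    """Settings for one model-fitting run."""

    model_variant: str = "poly-weibull"
    seed: int = 0
    mcmc: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)  # overrides, e.g. treatment HR
    population_path: Optional[str] = None
    study_path: Optional[str] = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        for p in (cfg.population_path, cfg.study_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(out_dir, config: dict) -> Path:
    """Write a plain-text run log (config echo, seed, versions, hash)."""
    import arviz
    import emcee
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [
        f"polyhazard {__version__}",
        f"numpy {numpy.__version__} scipy {scipy.__version__} "
        f"emcee {emcee.__version__} arviz {arviz.__version__}",
        f"config_hash {config_hash(config)}",
        "config:",
    ]
    lines += [f"  {k}: {config[k]}" for k in sorted(config)]
    path = out_dir / "run_log.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
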
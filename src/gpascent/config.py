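"""Run configuration, hierarchical seeding, logging and table writers.

A :class:`RunConfig` collects everything a run needs: the factor
operability regions, the genome layout, replication counts, predictor
settings and response-surface-method settings, plus the master seed and
output directory.  Configurations round-trip losslessly through YAML or
JSON, and unknown keys are rejected with field paths.

Randomness is hierarchical: every stream is derived from
(master seed, purpose label, replicate index) through
:func:`numpy.random.SeedSequence` spawn keys, so changing e.g. the SVR
settings never perturbs the genotype simulation streams.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .doe import Factor
from .errors import ConfigurationError, ConstraintViolation

__all__ = [
    "RunConfig",
    "FactorConfig",
    "GenomeConfig",
    "ReplicationConfig",
    "PredictorConfig",
    "RSMConfig",
    "DesignPointConfig",
    "load_config",
    "save_config",
    "write_table",
    "child_seed",
    "rng_for",
    "setup_logging",
]

logger = logging.getLogger("gpascent")


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FactorConfig(_Model):
    name: str
    low: float
    high: float
    integer_valued: bool = False
    operability_min: float = float("-inf")
    operability_max: float = float("inf")

    def to_factor(self) -> Factor:
        return Factor(
            self.name, self.low, self.high, self.integer_valued,
            self.operability_min, self.operability_max,
        )


def default_factors() -> list[FactorConfig]:
    """The initial two-level region of the study (natural units)."""
    return [
        FactorConfig(name="ind", low=200, high=1000, integer_valued=True, operability_min=5),
        FactorConfig(name="m", low=100, high=400, integer_valued=True, operability_min=2),
        FactorConfig(name="qtl", low=10, high=100, integer_valued=True, operability_min=1),
        FactorConfig(name="epi", low=0.2, high=0.5, operability_min=0.0, operability_max=1.0),
        FactorConfig(name="h", low=0.2, high=0.5, operability_min=0.01, operability_max=1.0),
    ]


class GenomeConfig(_Model):
    n_chromosomes: int = Field(10, ge=1)
    map_length_per_chromosome: float = Field(1.0, gt=0)
    remainder_policy: Literal["strict", "spread"] = "spread"


class ReplicationConfig(_Model):
    n_datasets: int = Field(20, ge=1)
    n_splits: int = Field(25, ge=1)
    test_fraction: float = Field(0.2, gt=0, lt=1)

    @property
    def total(self) -> int:
        return self.n_datasets * self.n_splits


class PredictorConfig(_Model):
    svr_kernel: str = "rbf"
    svr_cost: float = Field(1.0, gt=0)
    svr_gamma: Optional[float] = None  # None -> 1/m
    svr_epsilon: float = Field(0.1, ge=0)
    blup_lambda: Optional[float] = None  # None -> REML
    pairing: Literal["disjoint", "chain"] = "disjoint"
    qtl_rule: Literal["evenly_spaced", "random"] = "evenly_spaced"


class RSMConfig(_Model):
    basis_step: float = 0.25
    max_iterations: int = Field(5, ge=1)
    k_max: int = Field(9, ge=1)
    margin: float = 0.0
    compat_rounding: bool = False
    coded_step_decimals: Optional[int] = None
    fraction_sign: Literal[-1, 1] = -1


class DesignPointConfig(_Model):
    ind: int = Field(ge=5)
    m: int = Field(ge=1)
    qtl: int = Field(ge=1)
    epi: float = Field(ge=0.0, le=1.0)
    h: float = Field(gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _qtl_within_markers(self):
        if self.qtl > self.m:
            raise ValueError("qtl must not exceed the number of markers (qtl <= m)")
        return self


class RunConfig(_Model):
    seed: int = 0
    output_dir: str = "."
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    replication: ReplicationConfig = Field(default_factory=ReplicationConfig)
    predictor: PredictorConfig = Field(default_factory=PredictorConfig)
    rsm: RSMConfig = Field(default_factory=RSMConfig)
    factors: list[FactorConfig] = Field(default_factory=default_factors)
    design_point: Optional[DesignPointConfig] = None

    def factor_map(self) -> dict[str, Factor]:
        return {f.name: f.to_factor() for f in self.factors}


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(map(str, e["loc"])) + ": " + e["msg"] for e in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration ({path}): {locs}") from exc


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def write_table(records, path, format: str = "csv", round_decimals: int | None = None) -> None:
    """Write homogeneous records as CSV or JSON with deterministic columns.

    ``round_decimals`` produces a presentation view (e.g. 2 decimals for
    accuracies); by default full precision is preserved.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if round_decimals is not None:
        df = df.round(round_decimals)
    path = Path(path)
    try:
        if format == "csv":
            df.to_csv(path, index=False)
        elif format == "json":
            df.to_json(path, orient="records", indent=2)
        else:
            raise ConfigurationError(f"unknown table format {format!r}")
    except OSError as exc:
        raise ConfigurationError(f"cannot write table to {path}: {exc}") from exc


def _label_key(label) -> int:
    if isinstance(label, str):
        return zlib.crc32(label.encode())
    return int(label)


def child_seed(master: int, *path) -> np.random.SeedSequence:
    """Deterministic sub-stream seed for (master, purpose..., index...)."""
    return np.random.SeedSequence(entropy=master, spawn_key=tuple(_label_key(p) for p in path))


def rng_for(master: int, *path) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *path))
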
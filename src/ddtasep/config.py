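"""Run configuration: YAML schema, validation, and output writing.

The schema is strict — unknown keys are a hard error so a typo cannot
silently fall back to a default — and every run requires an explicit
seed.  All outputs are plain tab-separated text with a ``#``-prefixed
header carrying the package version, the full parameter echo and the
seed, and numbers are written at full precision so tables round-trip
losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import ddtasep

__all__ = ["ModelBlock", "RunBlock", "OutputBlock", "RunConfig", "load_config", "write_table", "read_table"]


@dataclass
class ModelBlock:
    length_bp: int = 20_000
    k_L: int = 1
    k_N: int = 3
    alpha: float = 0.05
    beta: float = 1.0
    q: float = 1.0
    h_c: float = 0.01
    h_o: float = 0.01
    gamma_target: float | None = None  # overrides h_o when given
    heterogeneity: str = "none"  # none | static | dynamic
    gc_seed: int | None = None  # required for heterogeneous genes


@dataclass
class RunBlock:
    steps: int = 200_000
    replicates: int = 1
    seed: int | None = None


@dataclass
class OutputBlock:
    record_events: bool = False
    sample_every: int = 0
    formats: tuple[str, ...] = ("tsv",)


@dataclass
class RunConfig:
    model: ModelBlock = field(default_factory=ModelBlock)
    run: RunBlock = field(default_factory=RunBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    def validate(self) -> "RunConfig":
        if self.run.seed is None:
            raise ValueError("run.seed is mandatory (reproducibility contract)")
        if self.model.heterogeneity not in ("none", "static", "dynamic"):
            raise ValueError(f"unknown heterogeneity mode {self.model.heterogeneity!r}")
        if self.model.heterogeneity != "none" and self.model.gc_seed is None:
            raise ValueError("model.gc_seed is required for heterogeneous genes")
        return self

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _from_mapping(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path} block")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Parse and schema-validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"model", "run", "output"}
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    cfg = RunConfig(
        model=_from_mapping(ModelBlock, raw.get("model") or {}, "model"),
        run=_from_mapping(RunBlock, raw.get("run") or {}, "run"),
        output=_from_mapping(OutputBlock, raw.get("output") or {}, "output"),
    )
    return cfg.validate()


def _header_lines(meta: dict) -> list[str]:
    lines = [f"# ddtasep {ddtasep.__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k} = {v!r}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a TSV with a commented header (version, parameter echo, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(meta or {}):
            fh.write(line + "\n")
        # pandas' default float repr is shortest-round-trip exact
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (header comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
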
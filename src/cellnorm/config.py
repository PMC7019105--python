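"""Run configuration, validation and seeded reproducibility helpers."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .data import DataError

__all__ = ["RunConfig", "load_config", "derive_seed"]


def derive_seed(seed: int, stage: str | int) -> int:
    """Derive a per-stage child seed from one global seed.

    Counter-based: the (seed, stage) pair feeds a SeedSequence, so every
    stage gets an independent stream and can be rerun in isolation.  The
    result is kept below 2**31.
    """
    if isinstance(stage, str):
        stage_key = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
    else:
        stage_key = int(stage)
    ss = np.random.SeedSequence([int(seed), stage_key])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Validated parameters for the simulate/normalize/evaluate pipeline."""

    # simulation
    n_genes: int = 10000
    n_cells_per_group: int = 24
    fold_change: float = 2.0
    n_de: int = 1000
    theta: float = 0.3
    n_spikeins: int = 8
    # cleaning
    min_gene_total: int = 10
    min_cell_total: int = 10000
    # evaluation
    methods: list[str] = field(default_factory=lambda: [
        "simple", "samstrt", "basics", "grm", "scran", "scnorm", "linnorm"
    ])
    knn_k: int = 5
    train_fraction: float = 0.7
    n_repeats: int = 100
    n_components: int = 50
    compute_de: bool = True
    de_alpha: float = 0.05
    # method knobs used by the benchmark
    basics_n_iter: int = 4000
    basics_burn_in: int = 2000
    basics_thin: int = 4
    basics_max_genes: int = 1000
    scnorm_min_nonzero: int = 10
    linnorm_c: float = 0.5
    # bookkeeping
    seed: int = 1
    log_level: str = "INFO"
    output_prefix: str = "cellnorm_run"
    template: str | None = None   # optional template counts TSV for simulation

    def __post_init__(self) -> None:
        _require(isinstance(self.seed, int) and not isinstance(self.seed, bool), "seed", "an integer")
        for name in ("n_genes", "n_cells_per_group", "n_de", "n_spikeins",
                     "knn_k", "n_repeats", "n_components",
                     "basics_n_iter", "basics_burn_in", "basics_thin",
                     "basics_max_genes", "scnorm_min_nonzero",
                     "min_gene_total", "min_cell_total"):
            v = getattr(self, name)
            _require(isinstance(v, int) and not isinstance(v, bool), name, "an integer")
        _require(self.knn_k >= 1, "knn_k", ">= 1")
        _require(self.n_repeats >= 1, "n_repeats", ">= 1")
        _require(isinstance(self.fold_change, (int, float)) and not isinstance(self.fold_change, bool),
                 "fold_change", "a number")
        _require(self.fold_change >= 1, "fold_change", ">= 1")
        _require(0.0 < self.train_fraction < 1.0, "train_fraction", "in (0, 1)")
        _require(0.0 < self.de_alpha < 1.0, "de_alpha", "in (0, 1)")
        _require(0.0 <= self.linnorm_c <= 1.0, "linnorm_c", "in [0, 1]")
        _require(self.theta >= 0, "theta", ">= 0")
        from .normalize import METHODS
        for m in self.methods:
            _require(m in METHODS, "methods", f"a subset of {METHODS} (got {m!r})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _require(ok: bool, name: str, what: str) -> None:
    if not ok:
        raise DataError(f"config field {name!r} must be {what}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file; unknown keys are rejected by name.

    An absent or empty file yields all defaults.  ``overrides`` (e.g. CLI
    flags) are applied on top.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise DataError(f"{path}: config must be a mapping")
        raw = loaded
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"unknown config key(s): {sorted(unknown)}")
    for f in fields(RunConfig):
        if f.name in raw and raw[f.name] is not None:
            v = raw[f.name]
            if f.type in ("int",) and isinstance(v, float) and v.is_integer():
                raw[f.name] = int(v)
    return RunConfig(**raw)
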
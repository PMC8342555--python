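"""Flat key-value run configuration with seed control.

The config file is newline-delimited ``key = value`` pairs; ``#``
starts a comment. Values are parsed as int, then float, then left as
strings. Every stochastic operation takes its replicate counts from the
config so a run is fully reproducible from (config, inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

_DEFAULTS: dict = {
    "seed": 1,
    "hwe_batches": 1000,
    "hwe_iters_per_batch": 10000,
    "hwe_burn_in": 10000,
    "fst_permutations": 10000,
    "ibd_permutations": 9999,
    "bottleneck_sims_per_locus": 1000,
    "phi_st_permutations": 1000,
    "dnds_bootstrap": 2000,
    "structure_burnin": 100000,
    "structure_generations": 400000,
    "structure_runs": 10,
    "quality_mode": "mean",
    "min_reads": 1000,
    "min_freq": 0.1,
    "validation_rule": "or",
    "single_allele": "homozygote",
    "hwe_alpha": 0.05,
}


@dataclass
class RunConfig:
    """Flat configuration mapping with typed access and defaults."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged
        if int(self.values["seed"]) < 0:
            raise ValueError("seed must be non-negative")
        for key, v in self.values.items():
            if (key.endswith(("_permutations", "_batches", "_bootstrap", "_runs"))
                    or "iters" in key or "sims" in key) and int(v) < 1:
                raise ValueError(f"{key} must be >= 1, got {v}")

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    def get_int(self, key: str) -> int:
        return int(self.values[key])

    def get_float(self, key: str) -> float:
        return float(self.values[key])


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def read_config(path: str | Path) -> RunConfig:
    values = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {line_no}: expected 'key = value'")
        key, _, raw = line.partition("=")
        values[key.strip()] = _coerce(raw.strip())
    return RunConfig(values)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{k} = {v}" for k, v in sorted(config.values.items())) + "\n"
    )
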
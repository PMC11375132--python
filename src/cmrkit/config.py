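"""Run configuration and logging setup shared by the CLI and pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All thresholds and knobs of a conditional-MR run.

    Defaults follow standard practice for GWAS instrument selection
    (genome-wide significance, stringent clumping) and the stage-1
    joint-significance threshold of 5e-6.
    """

    clump_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    p_cojo: float = 5e-6
    collinearity_r: float = 0.9
    alpha: float = 0.05
    methods: list[str] = field(default_factory=lambda: [
        "ivw", "raps", "weighted_median", "weighted_mode", "cml"])
    seed: int = 1
    n_boot: int = 1000
    steiger: bool = False
    palindrome_policy: str = "drop_ambiguous"
    min_ivs: int = 3
    default_n_exposure: float | None = None
    default_n_outcome: float | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML (TOML also accepted by suffix)."""
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib
            data = tomllib.loads(path.read_text())
        else:
            data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot(self, out_dir: str | Path) -> Path:
        """Write the resolved config next to a run's outputs."""
        out = Path(out_dir) / "config_snapshot.json"
        out.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return out


def setup_logging(level: int = logging.INFO, log_file: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers, force=True)
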
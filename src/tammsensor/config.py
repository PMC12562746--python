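"""Run configuration: validated, serializable simulation requests.

A :class:`RunConfig` fully determines a run (stack source, wavelength grid,
angles, polarization, analyte indices, output directory), so a persisted
config alone reproduces it.  The physics is deterministic; the seed only
feeds stochastic test utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Schema violation in a run configuration; names the offending field."""


@dataclass
class RunConfig:
    structure: str = "baseline"              # builder name, or "file"
    stack_file: str | None = None            # explicit layer list (when structure == "file")
    metal: str = "Ag"
    n_a: list[float] = field(default_factory=lambda: [1.335])
    lam_start_nm: float = 750.0
    lam_stop_nm: float = 1100.0
    lam_step_nm: float = 0.1
    refine_tol_nm: float = 1e-3
    theta_deg: list[float] = field(default_factory=lambda: [0.0])
    polarization: str = "TE"
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> "RunConfig":
        def bad(name, expected):
            raise ConfigError(f"config field '{name}': expected {expected}, "
                              f"got {getattr(self, name)!r}")
        if self.structure not in ("baseline", "enhanced", "file"):
            bad("structure", "'baseline', 'enhanced' or 'file'")
        if self.structure == "file" and not self.stack_file:
            bad("stack_file", "a path when structure == 'file'")
        if self.metal not in ("Ag", "Au", "Cu"):
            bad("metal", "one of Ag, Au, Cu")
        if not self.n_a or any(v < 1.0 for v in self.n_a):
            bad("n_a", "a non-empty list of indices >= 1.0")
        if not (0 < self.lam_start_nm < self.lam_stop_nm):
            bad("lam_start_nm", "0 < start < stop")
        if self.lam_step_nm <= 0:
            bad("lam_step_nm", "a positive step")
        if any(not (0 <= t < 90) for t in self.theta_deg):
            bad("theta_deg", "angles in [0, 90)")
        if self.polarization not in ("TE", "TM"):
            bad("polarization", "'TE' or 'TM'")
        if int(self.seed) != self.seed:
            bad("seed", "an integer")
        return self


_FIELDS = set(RunConfig.__dataclass_fields__)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    try:
        cfg = RunConfig(**raw)
    except TypeError as err:
        raise ConfigError(str(err)) from None
    return cfg.validate()


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
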
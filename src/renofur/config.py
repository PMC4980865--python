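"""Validated run configuration (pydantic models; unknown keys rejected)."""

from __future__ import annotations

from typing import Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError


class AnalysisConfig(BaseModel):
    """Analysis options for the per-mouse FUR pipeline.

    blood_window_min:
        Fit window (min) for the mono-exponential blood-pool fit; starts
        after bolus mixing.
    lu_segment:
        Patlak linear-uptake segment in minutes, or ``"auto"`` to search
        for the longest admissible pre-peak window.
    lu_r2_min:
        Minimum segment R^2 before a QC flag (and the bar for the auto
        search).
    id_window_s:
        Early whole-body window (s) for the injected-dose count rate.
    id_mode:
        ``"wb"`` uses the whole-body ROI as the dose denominator;
        ``"wb_minus_injection"`` subtracts the injection-site TAC.
    """

    model_config = ConfigDict(extra="forbid")

    blood_window_min: Tuple[float, float] = (1.0, 12.0)
    lu_segment: Union[Tuple[float, float], Literal["auto"]] = (0.5, 2.5)
    lu_r2_min: float = 0.98
    id_window_s: Tuple[float, float] = (10.0, 60.0)
    id_mode: Literal["wb", "wb_minus_injection"] = "wb"

    @field_validator("blood_window_min", "id_window_s")
    @classmethod
    def _ordered(cls, v):
        if v[0] >= v[1]:
            raise ValueError("window bounds must be increasing")
        return v


class RunConfig(BaseModel):
    """End-to-end run options: scenario, simulation and analysis settings."""

    model_config = ConfigDict(extra="forbid")

    scenario: Optional[str] = None
    design_file: Optional[str] = None
    seed: int = 0
    noise: Literal["poisson", "none"] = "poisson"
    grid_size: int = 128
    analysis: AnalysisConfig = AnalysisConfig()


def load_config(path: str, model=RunConfig):
    """Load and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: BaseModel, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
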
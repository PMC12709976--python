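"""Run configuration: documented defaults, YAML round-trip."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from .classify import DEFAULT_BANDS, FlowBand
from .errors import ContractError
from .metrics import DEFAULT_BIMODALITY_CUT, DEFAULT_MIN_COMPONENT_PX

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Analysis parameters with defaults matching the package's documented choices.

    polarity: "auto" detects backlight vs frontlight from the ROI border band.
    roi: None (full frame) or a rectangle [x0, y0, w, h].
    bands: flow classification bands (label, lo, hi), a partition of [0, 100].
    bimodality_cut: Ashman's D above which the powder histogram counts as bimodal.
    min_component_px: connected powder components below this size are dropped.
    psd_interpolation: percentile interpolation, "log" (default) or "linear".
    """

    polarity: str = "auto"
    roi: list[int] | None = None
    bands: list[list] = field(
        default_factory=lambda: [[b.label, b.lo, b.hi] for b in DEFAULT_BANDS]
    )
    bimodality_cut: float = DEFAULT_BIMODALITY_CUT
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX
    psd_interpolation: str = "log"

    def flow_bands(self) -> tuple[FlowBand, ...]:
        return tuple(FlowBand(label, float(lo), float(hi)) for label, lo, hi in self.bands)

    def roi_tuple(self) -> tuple[int, int, int, int] | None:
        return tuple(int(v) for v in self.roi) if self.roi is not None else None


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ContractError(f"{os.fspath(path)!r}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ContractError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
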
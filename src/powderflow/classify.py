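"""Four-band flow classification and replicate aggregation.

The Flow Index maps onto four flow classes whose boundaries are anchored by
microcrystalline cellulose (MCC) reference grades spanning the flow spectrum
encountered in die filling: PH-200 (best), PH-102 (acceptable/poor boundary
for high-speed machinery) and PH-101 (poorest). The default bands partition
[0, 100] with left-closed, half-open intervals so each boundary value belongs
to the better class:

=============  ===========  ==================================
FI band (%)    Class        Boundary material
=============  ===========  ==================================
[50, 100]      Excellent    well above MCC PH-200
[30, 50)       Good         MCC PH-200 .. MCC PH-102
[10, 30)       Acceptable   MCC PH-102 .. MCC PH-101
[0, 10)        Poor         well below MCC PH-101
=============  ===========  ==================================

Classification holds for a fixed applied flow rate; the bands are
configuration, not measurements, and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "FlowBand",
    "ReplicateStats",
    "DEFAULT_BANDS",
    "CLASS_ORDER",
    "classify_flow",
    "summarize_replicates",
    "rank_report",
]


@dataclass(frozen=True)
class FlowBand:
    """One flow class: a half-open FI interval ``[lo, hi)`` (the top band is closed)."""

    label: str
    lo: float
    hi: float
    boundary_material: str = ""


DEFAULT_BANDS: tuple[FlowBand, ...] = (
    FlowBand("Poor", 0.0, 10.0, "well below MCC PH-101"),
    FlowBand("Acceptable", 10.0, 30.0, "MCC PH-102 .. MCC PH-101"),
    FlowBand("Good", 30.0, 50.0, "MCC PH-200 .. MCC PH-102"),
    FlowBand("Excellent", 50.0, 100.0, "well above MCC PH-200"),
)

#: Rank order of the classes, worst to best.
CLASS_ORDER: dict[str, int] = {"Poor": 0, "Acceptable": 1, "Good": 2, "Excellent": 3}


def _validate_bands(bands: Sequence[FlowBand]) -> None:
    if not bands:
        raise ContractError("at least one band required")
    ordered = sorted(bands, key=lambda b: b.lo)
    if ordered[0].lo != 0.0 or ordered[-1].hi != 100.0:
        raise ContractError("bands must span [0, 100]")
    for a, b in zip(ordered, ordered[1:]):
        if a.hi != b.lo:
            raise ContractError(f"bands must partition [0, 100]: gap/overlap at {a.hi}/{b.lo}")


def classify_flow(fi: float, bands: Sequence[FlowBand] = DEFAULT_BANDS) -> FlowBand:
    """Map an FI percentage onto its flow class.

    Intervals are left-closed half-open; the top band includes 100.
    """
    if not 0.0 <= fi <= 100.0:
        raise ContractError(f"FI must lie in [0, 100], got {fi}")
    _validate_bands(bands)
    ordered = sorted(bands, key=lambda b: b.lo)
    for band in ordered[:-1]:
        if band.lo <= fi < band.hi:
            return band
    return ordered[-1]


@dataclass(frozen=True)
class ReplicateStats:
    """Mean, sample standard deviation (n-1 denominator) and count.

    ``sd`` is ``None`` for a single replicate, mirroring the mean +/- sd
    (n = 3) presentation of replicated measurements.
    """

    mean: float
    sd: float | None
    n: int


def summarize_replicates(values: Iterable[float]) -> ReplicateStats:
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ContractError("at least one replicate required")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return ReplicateStats(mean, sd, int(arr.size))


def rank_report(
    samples: Mapping[str, Mapping[str, Sequence[float]]],
    bands: Sequence[FlowBand] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-sample FI/AG replicate statistics, classified and ranked.

    ``samples`` maps a sample label to ``{"fi": [...], "ag": [...]}`` replicate
    values. The class is assigned to the *mean* FI (one class per material),
    and rows are sorted by mean FI descending; ties keep insertion order.
    """
    rows = []
    for name, reps in samples.items():
        fi = summarize_replicates(reps["fi"])
        ag = summarize_replicates(reps.get("ag", [])) if len(reps.get("ag", [])) else None
        rows.append(
            {
                "sample": name,
                "n": fi.n,
                "fi_mean": fi.mean,
                "fi_sd": fi.sd,
                "ag_mean": ag.mean if ag else None,
                "ag_sd": ag.sd if ag else None,
                "flow_class": classify_flow(fi.mean, bands).label,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("fi_mean", ascending=False, kind="stable", ignore_index=True)
    return df
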
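"""Volume-weighted particle size percentiles (Dv10/Dv50/Dv90) and span.

Laser-diffraction instruments export a volume-weighted size distribution: a
set of size classes (μm) with the volume fraction in each. The standard
summary is the triple Dv10/Dv50/Dv90 — the sizes below which 10/50/90 % of
the particle volume lies — and the dimensionless width

    span = (Dv90 - Dv10) / Dv50.

Percentile extraction treats the class sizes as the upper edges of a
cumulative curve starting at 0 and inverts it with interpolation linear in
log(size) (Mastersizer-style classes are log-spaced); linear-in-size
interpolation is available as an option. The lower edge of the first class is
extrapolated at the geometric spacing of the first two classes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ReplicateStats, summarize_replicates
from .errors import ContractError

__all__ = [
    "SizeDistribution",
    "PsdSummary",
    "PsdReport",
    "dv_percentile",
    "span",
    "summarize_distribution",
    "summarize_psd",
    "read_distribution_csv",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Volume-weighted PSD: strictly increasing sizes (μm) with nonnegative weights."""

    sizes_um: np.ndarray
    volume_fractions: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes_um, dtype=np.float64)
        v = np.asarray(self.volume_fractions, dtype=np.float64)
        if s.ndim != 1 or s.size == 0 or s.shape != v.shape:
            raise ContractError("sizes and fractions must be matching non-empty 1-D arrays")
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ContractError("sizes must be positive and strictly increasing")
        if np.any(v < 0) or v.sum() <= 0:
            raise ContractError("volume fractions must be nonnegative with positive total")
        object.__setattr__(self, "sizes_um", s)
        object.__setattr__(self, "volume_fractions", v / v.sum())


def dv_percentile(dist: SizeDistribution, p: float, interpolation: str = "log") -> float:
    """Size at which the cumulative normalized volume first reaches ``p``.

    ``p`` is a fraction in (0, 1): Dv50 is ``dv_percentile(dist, 0.5)``.
    """
    if not 0.0 < p < 1.0:
        raise ContractError(f"percentile fraction must lie in (0, 1), got {p}")
    if interpolation not in ("log", "linear"):
        raise ContractError(f"interpolation must be 'log' or 'linear', got {interpolation!r}")
    s = dist.sizes_um
    if s.size == 1:
        return float(s[0])
    # Lower edge of the first class, extrapolated at the first class spacing.
    lo_edge = s[0] ** 2 / s[1] if interpolation == "log" else max(2 * s[0] - s[1], 0.0)
    edges = np.concatenate([[lo_edge], s])
    cum = np.concatenate([[0.0], np.cumsum(dist.volume_fractions)])
    cum[-1] = 1.0  # guard rounding
    k = int(np.searchsorted(cum, p, side="left"))  # first edge with cum >= p
    if cum[k] == p or cum[k] == cum[k - 1]:
        return float(edges[k])
    frac = (p - cum[k - 1]) / (cum[k] - cum[k - 1])
    if interpolation == "log":
        return float(math.exp(math.log(edges[k - 1]) + frac * (math.log(edges[k]) - math.log(edges[k - 1]))))
    return float(edges[k - 1] + frac * (edges[k] - edges[k - 1]))


def span(dv10: float, dv50: float, dv90: float) -> float:
    """Distribution width: (Dv90 - Dv10) / Dv50."""
    if dv50 <= 0:
        raise ContractError(f"Dv50 must be positive, got {dv50}")
    if dv10 > dv90:
        raise ContractError("Dv10 must not exceed Dv90")
    return (dv90 - dv10) / dv50


@dataclass(frozen=True)
class PsdSummary:
    """Dv10/Dv50/Dv90 (μm) and span for one measured distribution."""

    dv10: float
    dv50: float
    dv90: float
    span: float


def summarize_distribution(dist: SizeDistribution, interpolation: str = "log") -> PsdSummary:
    d10 = dv_percentile(dist, 0.10, interpolation)
    d50 = dv_percentile(dist, 0.50, interpolation)
    d90 = dv_percentile(dist, 0.90, interpolation)
    return PsdSummary(d10, d50, d90, span(d10, d50, d90))


@dataclass(frozen=True)
class PsdReport:
    """Replicate statistics (mean +/- sample sd) per PSD summary field."""

    dv10: ReplicateStats
    dv50: ReplicateStats
    dv90: ReplicateStats
    span: ReplicateStats
    replicates: tuple[PsdSummary, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for field in ("dv10", "dv50", "dv90", "span"):
            st: ReplicateStats = getattr(self, field)
            rows.append({"quantity": field, "mean": st.mean, "sd": st.sd, "n": st.n})
        return pd.DataFrame(rows)


def summarize_psd(
    replicates: Iterable[SizeDistribution], interpolation: str = "log"
) -> PsdReport:
    """Summarise replicate distributions: span is computed per replicate, then averaged."""
    summaries = tuple(summarize_distribution(d, interpolation) for d in replicates)
    if not summaries:
        raise ContractError("at least one replicate distribution required")
    return PsdReport(
        dv10=summarize_replicates(s.dv10 for s in summaries),
        dv50=summarize_replicates(s.dv50 for s in summaries),
        dv90=summarize_replicates(s.dv90 for s in summaries),
        span=summarize_replicates(s.span for s in summaries),
        replicates=summaries,
    )


def read_distribution_csv(path: str | os.PathLike) -> SizeDistribution:
    """Read a two-column CSV (``size_um``, ``volume_fraction``) into a distribution."""
    df = pd.read_csv(path)
    for col in ("size_um", "volume_fraction"):
        if col not in df.columns:
            raise ContractError(f"{os.fspath(path)!r}: missing required column {col!r}")
    s = df["size_um"].to_numpy(dtype=np.float64)
    bad = np.nonzero(np.diff(s) <= 0)[0]
    if bad.size:
        # +2 header line, +1 one-based: first offending data row in file coordinates
        raise ContractError(
            f"{os.fspath(path)!r}: sizes not strictly increasing at line {int(bad[0]) + 3}"
        )
    return SizeDistribution(s, df["volume_fraction"].to_numpy(dtype=np.float64))
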
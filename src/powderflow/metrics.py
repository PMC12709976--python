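"""Flow Index and Agglomeration Ratio from flow-pattern images.

The two metrics quantify microdynamic powder flowability from a single
grayscale image of the pattern a powder leaves after flowing through an
orifice:

* **Flow Index (FI, %)** — the area fraction of the illuminated background
  (the ROI) occupied by powder. Higher FI means better flow: a free-flowing
  powder disperses widely, a cohesive one stays lumped.
* **Agglomeration Ratio (AG, 0–1)** — the fraction of *darker* pixels within
  the powder pattern itself. Cohesive agglomerates are optically thicker than
  a monolayer of dispersed particles, so under backlight they show up as
  distinctly darker regions; AG measures their share of the pattern area.

Both rely on Otsu's histogram threshold: once over the ROI to separate powder
from background (polarity-aware: dark powder on a bright backlit field, or
the inverse for frontlight), and once within the powder pattern to separate
agglomerates from dispersed particles. Otsu assumes a reasonably bimodal
histogram, so the AG step is gated by an Ashman's-D separability check; a
pattern whose internal histogram is judged unimodal reports AG = 0 with
``bimodality_flag = False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import ContractError, DegenerateHistogramError
from .image import GrayImage, Histogram, RegionMask, histogram, resolve_roi

__all__ = [
    "FlowMeasurement",
    "PowderSegmentation",
    "AgResult",
    "otsu_threshold",
    "segment_powder",
    "flow_index",
    "agglomeration_ratio",
    "analyze_image",
    "DEFAULT_MIN_COMPONENT_PX",
    "DEFAULT_BIMODALITY_CUT",
]

#: Connected powder components smaller than this are treated as sensor noise.
DEFAULT_MIN_COMPONENT_PX = 4

#: Ashman's D above this value declares the within-pattern histogram bimodal.
DEFAULT_BIMODALITY_CUT = 2.0


def otsu_threshold(hist: Histogram) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the cut level ``t`` maximizing the between-class variance of the
    classes ``{<= t}`` and ``{> t}``; ties are broken by the lowest such ``t``
    so the result is deterministic.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (or fewer than two pixels): no
        two-class split exists and the caller decides the fallback.
    """
    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    if total < 2 or hist.n_occupied < 2:
        raise DegenerateHistogramError(
            "histogram mass concentrated in a single bin; no threshold exists"
        )
    bins = np.arange(counts.size, dtype=np.float64)
    w1 = np.cumsum(counts)  # mass of class {<= t}
    m1 = np.cumsum(counts * bins)  # first moment of class {<= t}
    w2 = total - w1
    mu_total = m1[-1]
    # between-class variance sigma_b^2(t) = w1*w2*(mu1 - mu2)^2 / total^2;
    # the constant total^2 does not affect the argmax.
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = m1 / w1
        mu2 = (mu_total - m1) / w2
        var_b = w1 * w2 * (mu1 - mu2) ** 2
    var_b = np.where((w1 > 0) & (w2 > 0), var_b, -np.inf)
    # t = 255 has an empty upper class; argmax over valid cuts, lowest wins.
    return int(np.argmax(var_b[:-1]))


@dataclass(frozen=True)
class PowderSegmentation:
    """Result of separating the powder pattern from the illuminated background."""

    mask: RegionMask
    threshold: int | None
    polarity: str  # resolved to "backlight" or "frontlight"
    degenerate: bool  # ROI histogram had a single occupied bin (no powder found)


#: Minimum border-vs-interior mean difference (gray bins) for a confident call.
_POLARITY_MARGIN = 5.0


def _resolve_polarity(image: GrayImage, roi: RegionMask, polarity: str) -> str:
    """Auto-detect lighting polarity.

    Primary cue: the ROI border band (outer shell, ~5% of the shorter frame
    side) versus the interior — a flow pattern lands centrally, so a clearly
    brighter border means empty backlit background (backlight) and a clearly
    darker border means frontlight. When the contrast is below a small margin
    (the pattern reaches the border, as in spatially uniform scenes), fall
    back on the Otsu majority class: powder is the minority phase, so a
    brighter majority class implies backlight.
    """
    if polarity in ("backlight", "frontlight"):
        return polarity
    if polarity != "auto":
        raise ContractError(f"polarity must be backlight/frontlight/auto, got {polarity!r}")
    h, w = image.pixels.shape
    band = max(1, min(h, w) // 20)
    interior = ndimage.binary_erosion(roi.members, iterations=band)
    border = roi.members & ~interior
    vals = image.bin_indices().astype(np.float64)
    if border.any() and interior.any():
        diff = vals[border].mean() - vals[interior].mean()
        if abs(diff) >= _POLARITY_MARGIN:
            return "backlight" if diff > 0 else "frontlight"
    hist = histogram(image, roi)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return "backlight"
    dark = int(hist.counts[: t + 1].sum())
    return "backlight" if hist.total - dark >= dark else "frontlight"


def segment_powder(
    image: GrayImage,
    roi: RegionMask,
    polarity: str = "auto",
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> PowderSegmentation:
    """Segment the powder flow pattern inside the ROI via Otsu thresholding.

    Backlight: powder is the dark class (``<= t``); frontlight: the bright
    class (``> t``). A degenerate ROI histogram (uniform field, i.e. no
    powder) yields an empty mask with ``degenerate=True`` rather than an
    exception. Connected components smaller than ``min_component_px`` pixels
    are removed as sensor noise before any area is counted.
    """
    if roi.count == 0:
        raise ContractError("ROI is empty")
    resolved = _resolve_polarity(image, roi, polarity)
    hist = histogram(image, roi)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return PowderSegmentation(
            RegionMask.empty(*image.pixels.shape), None, resolved, degenerate=True
        )
    bins = image.bin_indices()
    if resolved == "backlight":
        powder = roi.members & (bins <= t)
    else:
        powder = roi.members & (bins > t)
    if min_component_px > 1:
        # drop components of size < min_component_px (max_size is inclusive)
        powder = morphology.remove_small_objects(powder, max_size=min_component_px - 1)
    return PowderSegmentation(RegionMask(powder), t, resolved, degenerate=False)


def flow_index(powder: RegionMask, roi: RegionMask) -> float:
    """FI = 100 x |powder| / |ROI|, the percentage of the ROI covered by powder."""
    if roi.count == 0:
        raise ContractError("ROI is empty; FI undefined")
    if not powder.is_subset_of(roi):
        raise ContractError("powder mask is not a subset of the ROI")
    return 100.0 * powder.count / roi.count


def _class_moments(counts: np.ndarray) -> tuple[float, float]:
    """Mean and standard deviation of a histogram segment (bin-index units)."""
    n = counts.sum()
    bins = np.arange(counts.size, dtype=np.float64)
    mu = float((counts * bins).sum() / n)
    var = float((counts * (bins - mu) ** 2).sum() / n)
    return mu, math.sqrt(var)


def ashman_d(hist: Histogram, t: int) -> float:
    """Ashman's D separability of the two Otsu classes split at ``t``.

    D = |mu1 - mu2| / sqrt((s1^2 + s2^2) / 2). Two zero-width spikes give
    infinite D (perfect separation).
    """
    lo, hi = hist.counts[: t + 1], hist.counts[t + 1 :]
    if lo.sum() == 0 or hi.sum() == 0:
        return 0.0
    mu1, s1 = _class_moments(lo)
    mu2, s2 = _class_moments(np.concatenate([np.zeros(t + 1, dtype=np.int64), hi]))
    pooled = math.sqrt((s1**2 + s2**2) / 2.0)
    if pooled == 0.0:
        return math.inf
    return abs(mu1 - mu2) / pooled


@dataclass(frozen=True)
class AgResult:
    """Agglomeration Ratio with its thresholding diagnostics."""

    ag: float
    threshold: int | None
    bimodal: bool
    ashman_d: float
    dense_count: int  # pixels in the dense (agglomerate) class
    powder_count: int


def agglomeration_ratio(
    image: GrayImage,
    powder: RegionMask,
    bimodality_cut: float = DEFAULT_BIMODALITY_CUT,
    dense_is_dark: bool = True,
) -> AgResult:
    """AG = fraction of darker pixels within the powder flow pattern.

    A second Otsu threshold is taken on the histogram restricted to the
    powder mask; AG is the dark-class share (cohesive lumps are optically
    thicker, hence darker, under transmitted backlight). Under frontlight
    the contrast ordering of the pattern is inverted and the dense phase is
    the bright class; pass ``dense_is_dark=False`` for that case.

    Because Otsu is only meaningful on a reasonably bimodal histogram, the
    split is accepted only when Ashman's D between the two classes exceeds
    ``bimodality_cut``; otherwise the pattern is judged unimodal (no distinct
    agglomerates) and AG = 0 with ``bimodal=False``.
    """
    n = powder.count
    if n == 0:
        raise ContractError("powder mask is empty; AG undefined")
    hist = histogram(image, powder)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return AgResult(0.0, None, False, 0.0, 0, n)
    d = ashman_d(hist, t)
    if not d > bimodality_cut:
        return AgResult(0.0, t, False, d, 0, n)
    dark = int(hist.counts[: t + 1].sum())
    dense = dark if dense_is_dark else n - dark
    return AgResult(dense / n, t, True, d, dense, n)


@dataclass(frozen=True)
class FlowMeasurement:
    """Full flowability readout for one image."""

    fi_percent: float
    ag_ratio: float
    powder_threshold: int | None
    agglomerate_threshold: int | None
    polarity: str
    bimodality_flag: bool
    powder_pixel_count: int
    roi_pixel_count: int
    degenerate_roi: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_image(
    image: GrayImage,
    roi_spec: RegionMask | tuple[int, int, int, int] | None = None,
    polarity: str = "auto",
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
    bimodality_cut: float = DEFAULT_BIMODALITY_CUT,
) -> FlowMeasurement:
    """Run the full FI/AG pipeline on one image.

    Deterministic for fixed inputs and parameters. An image with no
    detectable powder (uniform ROI, or nothing surviving the component
    filter) reports FI = 0 and AG = 0 with ``bimodality_flag = False``.
    """
    roi = resolve_roi(image, roi_spec)
    seg = segment_powder(image, roi, polarity, min_component_px)
    fi = flow_index(seg.mask, roi)
    if seg.mask.count == 0:
        ag = AgResult(0.0, None, False, 0.0, 0, 0)
    else:
        ag = agglomeration_ratio(
            image, seg.mask, bimodality_cut, dense_is_dark=(seg.polarity == "backlight")
        )
    return FlowMeasurement(
        fi_percent=fi,
        ag_ratio=ag.ag,
        powder_threshold=seg.threshold,
        agglomerate_threshold=ag.threshold,
        polarity=seg.polarity,
        bimodality_flag=ag.bimodal,
        powder_pixel_count=seg.mask.count,
        roi_pixel_count=roi.count,
        degenerate_roi=seg.degenerate,
    )
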
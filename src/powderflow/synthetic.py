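"""Seeded synthetic flow-pattern scenes with known ground-truth FI and AG.

No raw flow-pattern images from the measuring rig are publicly deposited, so
validation of the image metrics relies on a generator that emulates the two
phenomenologies seen in practice:

* **dispersed particles** — a homogeneous Boolean model: disk centres from a
  uniform point process, radii lognormal;
* **cohesive agglomerates** — Thomas-type parent–offspring clusters: parent
  centres uniform, member disks displaced by an isotropic Gaussian of the
  cluster radius, so members overlap heavily and form compact lumps.

Rendering uses a transmitted-light (backlight) optical-thickness model:
``I(x) = background * exp(-kappa * T(x))`` plus Gaussian noise, clipped to the
8-bit range. Dispersed particles settle as a monolayer against the cuvette
wall (``T = 1``); agglomerates are three-dimensional lumps several particles
deep (``T = agglomerate_layers``, default 3), which reproduces the distinctly
darker appearance of cohesive lumps. Frontlight inverts the rendered
intensities (``255 - I``), so the contrast ordering flips exactly: powder
bright on a dark field, with the dense lumps as the brightest phase.

Ground truth comes from the *geometry*, never from the rendering: a pixel is
labelled "agglomerate" when any cluster-member disk covers it, "dispersed"
when only free disks cover it, else "background". ``truth_fi`` and
``truth_ag`` are exact pixel counts over the label map, so the analysis
pipeline can be scored against labels that are independent of the intensity
model it thresholds.

Identical :class:`SceneParams` (including the seed) produce byte-identical
images: each scene uses one ``numpy.random.default_rng(seed)`` and no global
state.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, asdict, replace

import numpy as np

from .errors import ContractError, GenerationError
from .image import GrayImage, save_image

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "make_fixture_suite"]

_BG = 0  # label codes
_DISPERSED = 1
_AGGLOMERATE = 2


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and noise of one synthetic flow-pattern scene.

    Defaults give a 512x512 backlit frame with background 230, dispersed
    monolayer at ~160 and agglomerate lumps at ~77 gray levels (mode
    separation >= 60, comfortably inside the bimodality regime the Otsu-based
    metrics assume), with mild sensor noise (sd 5).
    """

    width: int = 512
    height: int = 512
    target_coverage: float = 0.30  # fraction of the frame the powder should cover
    agglomerate_fraction: float = 0.0  # share of covered area belonging to lumps
    particle_radius_median: float = 4.0  # px, lognormal median
    particle_radius_sigma: float = 0.35  # lognormal shape
    cluster_mean_particles: float = 12.0  # Poisson mean members per cluster (min 2)
    cluster_radius: float = 6.0  # px, sd of member displacement around the parent
    lighting: str = "backlight"  # or "frontlight"
    background_level: int = 230  # gray level of the empty illuminated field
    attenuation: float = math.log(230.0 / 160.0)  # kappa per optical layer
    agglomerate_layers: int = 3  # optical thickness of a lump, in particle layers
    noise_sd: float = 5.0  # gray levels
    seed: int = 0
    coverage_tolerance: float = 0.01  # accepted overshoot, fraction of frame
    max_attempts: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 < self.target_coverage < 1.0:
            raise ContractError("target_coverage must lie in (0, 1)")
        if not 0.0 <= self.agglomerate_fraction <= 1.0:
            raise ContractError("agglomerate_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be nonnegative")
        if self.lighting not in ("backlight", "frontlight"):
            raise ContractError(f"lighting must be backlight/frontlight, got {self.lighting!r}")
        if not 0 < self.background_level <= 255:
            raise ContractError("background_level must lie in (0, 255]")
        if self.width < 1 or self.height < 1:
            raise ContractError("frame must be at least 1x1")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene with its per-pixel labels and exact truth values."""

    image: GrayImage
    label_map: np.ndarray  # uint8: 0 background, 1 dispersed, 2 agglomerate
    truth_fi: float  # percent of frame covered by powder
    truth_ag: float  # agglomerate share of covered pixels
    params: SceneParams


def _disk_patch(
    cy: float, cx: float, r: float, height: int, width: int
) -> tuple[slice, slice, np.ndarray] | None:
    """Boolean patch of the disk clipped to the frame; None if fully outside."""
    y0 = max(int(math.floor(cy - r)), 0)
    y1 = min(int(math.ceil(cy + r)) + 1, height)
    x0 = max(int(math.floor(cx - r)), 0)
    x1 = min(int(math.ceil(cx + r)) + 1, width)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.ogrid[y0:y1, x0:x1]
    patch = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    if not patch.any():
        return None
    return slice(y0, y1), slice(x0, x1), patch


def _fill_phase(
    label: np.ndarray,
    code: int,
    target_px: int,
    tol_px: int,
    params: SceneParams,
    rng: np.random.Generator,
    clustered: bool,
) -> None:
    """Place disks (free or clustered) until ``code``-labelled area reaches target.

    A placement that would overshoot ``target_px + tol_px`` is rejected and
    re-drawn; a bounded number of consecutive rejections raises
    :class:`GenerationError` (radii too large for the requested coverage).
    """
    h, w = label.shape
    mu_r = math.log(params.particle_radius_median)
    count = int((label == code).sum()) if code == _AGGLOMERATE else 0
    # dispersed phase tracks total covered area instead (union with lumps)
    if code == _DISPERSED:
        count = int((label != _BG).sum())
    attempts = 0
    while count < target_px:
        attempts += 1
        if attempts > params.max_attempts:
            raise GenerationError(
                f"could not reach target coverage after {params.max_attempts} attempts; "
                "particle/cluster size too large for the frame"
            )
        if clustered:
            py, px = rng.uniform(0, h), rng.uniform(0, w)
            n_members = max(2, int(rng.poisson(params.cluster_mean_particles)))
            offsets = rng.normal(0.0, params.cluster_radius, size=(n_members, 2))
            centers = offsets + [py, px]
            radii = rng.lognormal(mu_r, params.particle_radius_sigma, size=n_members)
        else:
            centers = np.array([[rng.uniform(0, h), rng.uniform(0, w)]])
            radii = rng.lognormal(mu_r, params.particle_radius_sigma, size=1)
        if clustered:
            placement = np.zeros((h, w), dtype=bool)
            for (cy, cx), r in zip(centers, radii):
                p = _disk_patch(cy, cx, r, h, w)
                if p is None:
                    continue
                ys, xs, patch = p
                placement[ys, xs] |= patch
            fresh = placement & (label != code)
            new_px = int(fresh.sum())
            if new_px == 0 or count + new_px > target_px + tol_px:
                continue  # reject: nothing placed inside the frame, or overshoot
            label[placement] = code
        else:
            p = _disk_patch(centers[0, 0], centers[0, 1], radii[0], h, w)
            if p is None:
                continue
            ys, xs, patch = p
            fresh = patch & (label[ys, xs] == _BG)
            new_px = int(fresh.sum())
            if new_px == 0 or count + new_px > target_px + tol_px:
                continue
            # free disks never overwrite agglomerate ground truth
            label[ys, xs][fresh] = code
        count += new_px
        attempts = 0


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate one seeded scene with exact ground-truth FI and AG.

    Agglomerate clusters are placed first (until their pixel budget
    ``coverage * agglomerate_fraction`` is met), then free dispersed disks
    until the total covered area reaches ``target_coverage``; each phase
    rejects placements that would overshoot its budget beyond the tolerance,
    so the realized coverage sits within ``coverage_tolerance`` of the target.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    n = h * w
    label = np.zeros((h, w), dtype=np.uint8)
    tol_px = max(1, int(round(params.coverage_tolerance * n)))
    target_total = int(round(params.target_coverage * n))
    target_agg = int(round(target_total * params.agglomerate_fraction))
    if target_agg > 0:
        _fill_phase(label, _AGGLOMERATE, target_agg, tol_px, params, rng, clustered=True)
    if target_total > int((label != _BG).sum()):
        _fill_phase(label, _DISPERSED, target_total, tol_px, params, rng, clustered=False)

    covered = int((label != _BG).sum())
    agg = int((label == _AGGLOMERATE).sum())
    truth_fi = 100.0 * covered / n
    truth_ag = agg / covered if covered else 0.0

    thickness = np.zeros((h, w), dtype=np.float64)
    thickness[label == _DISPERSED] = 1.0
    thickness[label == _AGGLOMERATE] = float(params.agglomerate_layers)
    bg = float(params.background_level)
    intensity = bg * np.exp(-params.attenuation * thickness)
    if params.lighting == "frontlight":
        intensity = 255.0 - intensity
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return SyntheticScene(GrayImage(pixels), label, truth_fi, truth_ag, params)


def make_fixture_suite(
    out_dir: str | os.PathLike,
    coverages: list[float],
    agglomerate_fractions: list[float],
    noise_sds: list[float],
    seeds: list[int],
    base_params: SceneParams | None = None,
) -> str:
    """Write a grid of scenes as 8-bit TIFFs with JSON ground-truth sidecars.

    One fixture per (coverage, agglomerate_fraction, noise, seed) cell. A
    ``manifest.csv`` lists every fixture with its parameters and seed;
    regenerating from the manifest's seeds reproduces identical files.
    Returns the manifest path.
    """
    if not (coverages and agglomerate_fractions and noise_sds and seeds):
        raise ContractError("fixture grid must be non-empty in every dimension")
    base = base_params or SceneParams()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    rows = []
    for cov in coverages:
        for ag in agglomerate_fractions:
            for noise in noise_sds:
                for seed in seeds:
                    params = replace(
                        base,
                        target_coverage=cov,
                        agglomerate_fraction=ag,
                        noise_sd=noise,
                        seed=seed,
                    )
                    scene = generate_scene(params)
                    stem = f"scene_cov{cov:g}_ag{ag:g}_noise{noise:g}_seed{seed}"
                    img_path = os.path.join(out_dir, stem + ".tiff")
                    save_image(scene.image, img_path)
                    sidecar = {
                        "truth_fi": scene.truth_fi,
                        "truth_ag": scene.truth_ag,
                        "params": asdict(params),
                        "seed": seed,
                    }
                    with open(os.path.join(out_dir, stem + ".json"), "w") as fh:
                        json.dump(sidecar, fh, indent=2, sort_keys=True)
                    rows.append(
                        {
                            "image": stem + ".tiff",
                            "sidecar": stem + ".json",
                            "target_coverage": cov,
                            "agglomerate_fraction": ag,
                            "noise_sd": noise,
                            "seed": seed,
                            "truth_fi": f"{scene.truth_fi:.6f}",
                            "truth_ag": f"{scene.truth_ag:.6f}",
                        }
                    )
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
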
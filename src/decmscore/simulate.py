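"""Synthetic stained-slide simulator with exact ground truth.

Renders seeded synthetic section images that emulate the qualitative
phenomenology of the four stains used for decellularized-matrix QC:

* nuclei (two reference fibroblast-like types) are elongated — strip-like,
  spindle-shaped or curved — with caliper aspect ratio well above 2 under the
  brightfield stains, and rounder under DAPI;
* dust particles are near-round, darker than nuclei, with a larger size
  variance, and are sometimes suspended above the focal plane (emulated as a
  Gaussian-blurred sprite);
* DAPI fields show bright nuclei on a dim background, and dust is rendered at
  background intensity — present in the ground truth but invisible, so a
  detector should find none of it.

All geometry works in pixel units.  Every random draw flows from the scene
seed, so a (config, seed) pair renders bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .stains import STAIN_PALETTES, StainMethod

OBJECT_CLASSES = ("nucleus_1", "nucleus_2", "dust")
NUCLEUS_CLASSES = ("nucleus_1", "nucleus_2")

_GEOMETRY_RETRIES = 20


class PlacementError(RuntimeError):
    """Raised when an object class cannot be placed within the overlap budget."""


@dataclass(frozen=True)
class ObjectClassParams:
    """Generative distributions for one object class.

    Distributions are (mean, SD) pairs: ``area_dist`` in px^2,
    ``feret_ratio_dist`` dimensionless (>= 1), ``gray_dist`` on the 0-255
    analysis-channel scale.  ``curvature`` is the probability that a nucleus
    is bent along a circular arc (banana shape); ``blur_sigma_dist`` emulates
    out-of-focus dust suspended above the section plane.
    """

    class_label: str
    area_dist: tuple[float, float]
    feret_ratio_dist: tuple[float, float]
    gray_dist: tuple[float, float]
    curvature: float = 0.0
    blur_sigma_dist: tuple[float, float] = (0.0, 0.0)
    blur_prob: float = 0.0             # fraction suspended above the focal plane

    def __post_init__(self):
        if self.class_label not in OBJECT_CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        for name in ("area_dist", "feret_ratio_dist", "gray_dist", "blur_sigma_dist"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if not (0.0 <= self.gray_dist[0] <= 255.0):
            raise ValueError("gray mean must lie in [0, 255]")
        if self.feret_ratio_dist[0] < 1.0:
            raise ValueError("feret ratio mean must be >= 1")
        if not (0.0 <= self.curvature <= 1.0):
            raise ValueError("curvature is a probability")
        if not (0.0 <= self.blur_prob <= 1.0):
            raise ValueError("blur_prob is a probability")


def default_class_params(stain: StainMethod | str) -> dict[str, ObjectClassParams]:
    """Per-stain generative defaults.

    Brightfield nuclei are elongated (ratio mean 3.0 / 2.5) and mid-gray;
    dust is near-round (ratio mean 1.05), darker, with about twice the
    relative size spread.  DAPI nuclei are rounder, larger and bright; DAPI
    dust carries the same geometry but is invisible by construction.
    """
    stain = StainMethod.parse(stain)
    if stain.is_fluorescent:
        return {
            "nucleus_1": ObjectClassParams("nucleus_1", (620.0, 90.0), (1.60, 0.15),
                                           (200.0, 12.0), curvature=0.10),
            "nucleus_2": ObjectClassParams("nucleus_2", (520.0, 80.0), (1.45, 0.12),
                                           (185.0, 12.0), curvature=0.10),
            "dust": ObjectClassParams("dust", (260.0, 120.0), (1.05, 0.04),
                                      (22.0, 2.0)),
        }
    nucleus_gray = {
        StainMethod.HE: (110.0, 125.0),
        StainMethod.FEULGEN: (100.0, 115.0),
        StainMethod.ACETOCARMINE: (105.0, 120.0),
    }[stain]
    return {
        "nucleus_1": ObjectClassParams("nucleus_1", (420.0, 60.0), (3.00, 0.30),
                                       (nucleus_gray[0], 9.0), curvature=0.35),
        "nucleus_2": ObjectClassParams("nucleus_2", (330.0, 50.0), (2.50, 0.25),
                                       (nucleus_gray[1], 9.0), curvature=0.25),
        "dust": ObjectClassParams("dust", (260.0, 120.0), (1.05, 0.04),
                                  (55.0, 12.0), blur_sigma_dist=(1.0, 0.3),
                                  blur_prob=0.25),
    }


@dataclass
class SceneConfig:
    """One synthetic section: stain, canvas, per-class counts and colors."""

    stain: StainMethod = StainMethod.HE
    image_size: tuple[int, int] = (384, 384)
    counts: dict[str, int] = field(default_factory=lambda: {"nucleus_1": 8, "dust": 8})
    ecm_coverage_fraction: float = 0.55
    class_params: dict[str, ObjectClassParams] | None = None
    noise_sigma: float = 0.04          # multiplicative shading noise
    placement_retries: int = 50
    rng_seed: int = 0

    def __post_init__(self):
        self.stain = StainMethod.parse(self.stain)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("object counts must be >= 0")
        if not (0.0 <= self.ecm_coverage_fraction <= 1.0):
            raise ValueError("ecm_coverage_fraction must lie in [0, 1]")
        if self.class_params is None:
            self.class_params = default_class_params(self.stain)

    @property
    def total_objects(self) -> int:
        return sum(self.counts.values())


@dataclass
class GroundTruthObject:
    """One simulated object with its true generative parameters."""

    class_label: str
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray                 # local boolean mask within bbox
    centroid: tuple[float, float]
    params: dict[str, float]         # sampled area / feret_ratio / gray / blur_sigma
    in_ecm: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.nonzero(self.mask)
        return rr + self.bbox[0], cc + self.bbox[1]


@dataclass
class SyntheticSlide:
    """Rendered image plus complete ground truth."""

    image: np.ndarray                # uint8, (H, W, 3) or (H, W) for DAPI
    objects: list[GroundTruthObject]
    ecm_mask: np.ndarray
    config: SceneConfig

    def objects_of(self, *labels: str) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.class_label in labels]


# ---------------------------------------------------------------------------
# geometry sampling


def _sample_truncated(rng, mean, sd, low, retries=_GEOMETRY_RETRIES):
    for _ in range(retries):
        value = rng.normal(mean, sd)
        if value >= low:
            return value
    raise ValueError(f"could not sample a value >= {low} from N({mean}, {sd}^2) "
                     f"in {retries} attempts")


def _rasterize_polygon(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    rows = y - y.min() + 1.0
    cols = x - x.min() + 1.0
    shape = (int(np.ceil(rows.max())) + 2, int(np.ceil(cols.max())) + 2)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


def _nucleus_mask(area: float, ratio: float, bent: bool, theta: float) -> np.ndarray:
    # ellipse with pi*a*b = area and a/b = ratio, optionally bent along an arc
    b = np.sqrt(area / (np.pi * ratio))
    a = ratio * b
    t = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    if bent:
        rho = 2.0 * a  # mild banana: endpoints subtend ~1 rad
        phi = x / rho
        x, y = (rho + y) * np.sin(phi), (rho + y) * np.cos(phi) - rho
    ct, st = np.cos(theta), np.sin(theta)
    return _rasterize_polygon(ct * x - st * y, st * x + ct * y)


def _dust_mask(area: float, ratio: float, theta: float, rng) -> np.ndarray:
    # irregular near-round blob: top-`area` pixels of a noisy anisotropic
    # radial field, largest connected component, holes filled
    b = np.sqrt(area / (np.pi * ratio))
    a = ratio * b
    half = int(np.ceil(2.0 * a)) + 3
    grid = np.arange(-half, half + 1, dtype=float)
    yy, xx = np.meshgrid(grid, grid, indexing="ij")
    ct, st = np.cos(theta), np.sin(theta)
    u, v = ct * xx + st * yy, -st * xx + ct * yy
    r2 = (u / a) ** 2 + (v / b) ** 2
    noise = ndimage.gaussian_filter(rng.standard_normal(r2.shape), sigma=max(1.0, a / 3.0))
    noise_sd = noise.std()
    field = -r2 + 0.25 * (noise / noise_sd if noise_sd > 0 else noise)
    n_pix = max(1, int(round(area)))
    cutoff = np.partition(field.ravel(), -n_pix)[-n_pix]
    mask = field >= cutoff
    labels, n = ndimage.label(mask)
    if n > 1:
        mask = labels == (np.bincount(labels.ravel())[1:].argmax() + 1)
    return ndimage.binary_fill_holes(mask)


def _sample_geometry(params: ObjectClassParams, rng) -> tuple[np.ndarray, float, float]:
    area = _sample_truncated(rng, *params.area_dist, low=1.0)
    ratio = max(1.0, rng.normal(*params.feret_ratio_dist))
    theta = rng.uniform(0.0, np.pi)
    if params.class_label == "dust":
        mask = _dust_mask(area, ratio, theta, rng)
    else:
        bent = rng.random() < params.curvature
        mask = _nucleus_mask(area, ratio, bent, theta)
    if not mask.any():
        raise ValueError("sampled geometry rasterized to an empty mask")
    rr, cc = np.nonzero(mask)
    return mask[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1], area, ratio


def sample_object_geometry(params: ObjectClassParams, rng) -> np.ndarray:
    """Sample one connected binary mask from the class' shape distributions.

    Nuclei are rasterized ellipses (aspect ratio = sampled Feret ratio),
    optionally bent with probability ``curvature``; dust is a thresholded
    noisy blob.  Returns a tight local mask; raises ``ValueError`` if the
    sampled area stays below 1 px after a bounded number of retries.
    """
    return _sample_geometry(params, rng)[0]


# ---------------------------------------------------------------------------
# rendering


def _paint(image, rr, cc, color, rng, noise_sigma):
    gain = rng.normal(1.0, noise_sigma, size=rr.shape)
    if image.ndim == 3:
        image[rr, cc, :] = np.asarray(color)[None, :] * gain[:, None]
    else:
        image[rr, cc] = color * gain


def _paint_blurred(image, bbox, local_mask, color, sigma, rng, noise_sigma):
    r0, c0, r1, c1 = bbox
    margin = int(np.ceil(3.0 * sigma))
    h, w = image.shape[:2]
    R0, C0 = max(0, r0 - margin), max(0, c0 - margin)
    R1, C1 = min(h, r1 + margin), min(w, c1 + margin)
    alpha = np.zeros((R1 - R0, C1 - C0))
    alpha[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = local_mask
    alpha = ndimage.gaussian_filter(alpha, sigma=sigma)
    gain = rng.normal(1.0, noise_sigma, size=alpha.shape)
    region = image[R0:R1, C0:C1]
    if image.ndim == 3:
        sprite = np.asarray(color)[None, None, :] * gain[..., None]
        region[:] = region * (1.0 - alpha[..., None]) + sprite * alpha[..., None]
    else:
        region[:] = region * (1.0 - alpha) + color * gain * alpha


def render_slide(config: SceneConfig, rng=None) -> SyntheticSlide:
    """Render one synthetic section.

    Deterministic given (config, ``config.rng_seed``).  Objects never overlap
    each other (rejection sampling with a bounded retry budget); nuclei are
    preferentially embedded in the ECM while dust lands anywhere, mirroring
    how real contamination distributes.  Raises :class:`PlacementError` naming
    the class if placement fails.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    h, w = config.image_size
    palette = STAIN_PALETTES[config.stain]
    fluorescent = config.stain.is_fluorescent

    # ECM region: thresholded smooth noise at the requested coverage
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8.0)
    if config.ecm_coverage_fraction >= 1.0:
        ecm_mask = np.ones((h, w), dtype=bool)
    elif config.ecm_coverage_fraction <= 0.0:
        ecm_mask = np.zeros((h, w), dtype=bool)
    else:
        ecm_mask = field > np.quantile(field, 1.0 - config.ecm_coverage_fraction)

    shade = np.clip(rng.normal(1.0, config.noise_sigma, size=(h, w)), 0.5, 1.5)
    if fluorescent:
        image = np.full((h, w), palette["background_luminance"], dtype=float)
        image[ecm_mask] = palette["ecm_luminance"]
        image *= shade
    else:
        bg = palette["background_luminance"]
        image = np.full((h, w, 3), bg, dtype=float)
        image[ecm_mask] = np.asarray(palette["ecm_hue"]) * palette["ecm_luminance"]
        image *= shade[..., None]

    occupancy = np.zeros((h, w), dtype=bool)
    objects: list[GroundTruthObject] = []

    for label in OBJECT_CLASSES:
        count = config.counts.get(label, 0)
        params = config.class_params[label]
        is_nucleus = label in NUCLEUS_CLASSES
        for _ in range(count):
            placed = False
            for _ in range(config.placement_retries):
                local, true_area, true_ratio = _sample_geometry(params, rng)
                lh, lw = local.shape
                if lh + 2 >= h or lw + 2 >= w:
                    continue
                r0 = int(rng.integers(1, h - lh - 1))
                c0 = int(rng.integers(1, w - lw - 1))
                # occupancy holds 2 px-dilated footprints, so raw overlap here
                # already enforces a moat between components
                if occupancy[r0 : r0 + lh, c0 : c0 + lw][local].any():
                    continue
                rr, cc = np.nonzero(local)
                cr, cjc = float(rr.mean()) + r0, float(cc.mean()) + c0
                # nuclei sit in the matrix; dust is indifferent to it
                if is_nucleus and not ecm_mask[int(cr), int(cjc)] and rng.random() > 0.15:
                    continue
                gray = float(np.clip(rng.normal(*params.gray_dist), 2.0, 253.0))
                blur = 0.0
                if label == "dust" and rng.random() < params.blur_prob:
                    blur = max(0.0, rng.normal(*params.blur_sigma_dist))
                bbox = (r0, c0, r0 + lh, c0 + lw)

                visible = not (fluorescent and label == "dust")
                if visible:
                    hue = palette["nucleus_hue"] if is_nucleus else palette["dust_hue"]
                    color = gray if fluorescent else np.asarray(hue) * gray
                    if blur > 0.3:
                        _paint_blurred(image, bbox, local.astype(float), color,
                                       blur, rng, config.noise_sigma)
                    else:
                        _paint(image, rr + r0, cc + c0, color, rng, config.noise_sigma)

                # keep a 2 px moat so neighboring components never merge
                halo_r0, halo_c0 = max(0, r0 - 2), max(0, c0 - 2)
                pad = np.zeros((min(h, r0 + lh + 2) - halo_r0,
                                min(w, c0 + lw + 2) - halo_c0), dtype=bool)
                pad[r0 - halo_r0 : r0 - halo_r0 + lh, c0 - halo_c0 : c0 - halo_c0 + lw] = local
                occupancy[halo_r0 : halo_r0 + pad.shape[0],
                          halo_c0 : halo_c0 + pad.shape[1]] |= ndimage.binary_dilation(
                    pad, iterations=2)

                ecm_overlap = int(ecm_mask[rr + r0, cc + c0].sum())
                objects.append(GroundTruthObject(
                    class_label=label,
                    bbox=bbox,
                    mask=local,
                    centroid=(cr, cjc),
                    params={"area": true_area, "feret_ratio": true_ratio,
                            "gray": gray, "blur_sigma": blur,
                            "raster_area": float(local.sum())},
                    in_ecm=ecm_overlap >= 0.5 * local.sum(),
                ))
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {label!r} object within "
                    f"{config.placement_retries} retries")

    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SyntheticSlide(image=image, objects=objects, ecm_mask=ecm_mask, config=config)


# ---------------------------------------------------------------------------
# study grid: groups x stains x sections


@dataclass(frozen=True)
class StudyGroup:
    """One experimental group with per-class section count ranges (inclusive).

    Positive-control groups contain nuclei; decellularized samples and the
    negative control contain dust only.
    """

    name: str
    count_ranges: dict[str, tuple[int, int]]
    is_positive: bool = False

    def nucleus_class(self) -> str | None:
        for label in NUCLEUS_CLASSES:
            if label in self.count_ranges:
                return label
        return None


@dataclass
class StudyConfig:
    """The full synthetic study grid (groups x stains x sections)."""

    groups: tuple[StudyGroup, ...]
    stains: tuple[StainMethod, ...] = tuple(StainMethod)
    n_sections: int = 15
    image_size: tuple[int, int] = (384, 384)
    master_seed: int = 0

    def __post_init__(self):
        self.stains = tuple(StainMethod.parse(s) for s in self.stains)
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")


def default_study_config(master_seed: int = 0, n_sections: int = 15,
                         image_size: tuple[int, int] = (384, 384)) -> StudyConfig:
    """Five groups mirroring the dECM QC design: two decellularized samples,
    two cellular positive controls (one per reference nucleus type) and one
    acellular negative control, each stained four ways."""
    groups = (
        StudyGroup("sample_1", {"dust": (4, 9)}),
        StudyGroup("sample_2", {"dust": (4, 9)}),
        StudyGroup("positive_1", {"nucleus_1": (12, 18), "dust": (5, 10)}, is_positive=True),
        StudyGroup("positive_2", {"nucleus_2": (12, 18), "dust": (5, 10)}, is_positive=True),
        StudyGroup("negative", {"dust": (4, 9)}),
    )
    return StudyConfig(groups=groups, n_sections=n_sections,
                       image_size=image_size, master_seed=master_seed)


@dataclass(frozen=True)
class SlideSpec:
    """Address of one slide in the study grid plus its fully resolved scene."""

    group: str
    stain: StainMethod
    section: int
    scene: SceneConfig
    is_positive: bool


class StudySet:
    """Lazy collection of the study's slides; rendering is deterministic
    per-slide (seeds derived from the master seed and the grid address)."""

    def __init__(self, config: StudyConfig, specs: list[SlideSpec]):
        self.config = config
        self.specs = specs

    def __len__(self) -> int:
        return len(self.specs)

    @staticmethod
    def render(spec: SlideSpec) -> SyntheticSlide:
        return render_slide(spec.scene)

    def slides(self):
        for spec in self.specs:
            yield spec, render_slide(spec.scene)


def _derived_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_study(config: StudyConfig) -> StudySet:
    """Lay out the full grid of slides with reproducible per-slide seeds.

    Per-section object counts are drawn uniformly from each group's count
    ranges using a seed derived from (master seed, group, stain, section), so
    the whole grid is a pure function of the study config.
    """
    specs: list[SlideSpec] = []
    for gi, group in enumerate(config.groups):
        for si, stain in enumerate(config.stains):
            for sec in range(config.n_sections):
                count_rng = np.random.default_rng(
                    _derived_seed(config.master_seed, 1, gi, si, sec))
                counts = {label: int(count_rng.integers(lo, hi + 1))
                          for label, (lo, hi) in group.count_ranges.items()}
                scene = SceneConfig(
                    stain=stain,
                    image_size=config.image_size,
                    counts=counts,
                    rng_seed=_derived_seed(config.master_seed, 2, gi, si, sec),
                )
                specs.append(SlideSpec(group=group.name, stain=stain, section=sec,
                                       scene=scene, is_positive=group.is_positive))
    return StudySet(config, specs)
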
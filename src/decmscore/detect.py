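"""Channel conversion, tiling, dataset splitting and suspicious-point detection.

A "suspicious point" is any stained object on a section that could be either a
residual nucleus or an impurity particle.  Detection is plain thresholding plus
connected components with a size filter that mirrors the practice of excluding
particles that are too large or too small to be credible nuclei.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .stains import LUMA_WEIGHTS, StainMethod, luminance

logger = logging.getLogger(__name__)

#: Reference nucleus colors used by the "stain_distance" channel mode (RGB).
_STAIN_REFERENCE_NUCLEUS_RGB = {
    StainMethod.HE: (110.0, 88.0, 198.0),
    StainMethod.FEULGEN: (168.0, 65.0, 102.0),
    StainMethod.ACETOCARMINE: (175.0, 74.0, 83.0),
    StainMethod.DAPI: (60.0, 80.0, 255.0),
}


@dataclass
class DetectConfig:
    """Configuration of suspicious-point detection for one stain.

    ``channel_mode`` is "luminance", "stain_distance" or "auto" (luminance for
    brightfield stains, raw channel for DAPI).  ``threshold`` is "multiotsu"
    (three-class Otsu: background / tissue / objects, using the threshold on
    the object side of the polarity — robust when objects are sparse),
    "otsu" (plain two-class Otsu) or a fixed level in [0, 255].  ``polarity``
    is "dark" (objects darker than background: HE / Feulgen / acetocarmine),
    "bright" (DAPI) or "auto".  ``max_area`` of None means 1% of the image
    area.
    """

    stain: StainMethod = StainMethod.HE
    channel_mode: str = "auto"
    threshold: float | str = "multiotsu"
    min_area: int = 10
    max_area: int | None = None
    polarity: str = "auto"
    #: with automatic thresholds, the mean foreground-background contrast
    #: must reach this many gray levels, else the image is called empty —
    #: guards against thresholding pure background noise on blank slides
    min_contrast: float = 25.0

    def __post_init__(self):
        self.stain = StainMethod.parse(self.stain)
        if self.channel_mode not in ("auto", "luminance", "stain_distance", "raw"):
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")
        if self.polarity not in ("auto", "dark", "bright"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not (isinstance(self.threshold, str)
                and self.threshold in ("otsu", "multiotsu")):
            t = float(self.threshold)
            if not (0.0 <= t <= 255.0):
                raise ValueError("fixed threshold must lie in [0, 255]")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area is not None and self.max_area <= self.min_area:
            raise ValueError("require min_area < max_area")

    def resolved_polarity(self) -> str:
        if self.polarity != "auto":
            return self.polarity
        return "bright" if self.stain.is_fluorescent else "dark"

    def resolved_max_area(self, image_shape) -> int:
        if self.max_area is not None:
            return self.max_area
        return max(self.min_area + 1, int(0.01 * image_shape[0] * image_shape[1]))


@dataclass
class SuspiciousPoint:
    """One detected candidate object (nucleus or impurity)."""

    id: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray                 # local boolean mask within bbox
    stain: StainMethod
    centroid: tuple[float, float] = (0.0, 0.0)
    in_ecm: bool | None = None

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


def to_analysis_channel(image: np.ndarray, stain: StainMethod | str,
                        channel_mode: str = "auto") -> np.ndarray:
    """Collapse an image to the single grayscale analysis channel in [0, 255].

    Single-channel inputs pass through unchanged.  RGB inputs are converted by
    fixed-weight luminance (0.299/0.587/0.114) or, in "stain_distance" mode, by
    the Euclidean RGB distance to the stain's reference nucleus color rescaled
    to [0, 255] (0 = at the reference color).
    """
    stain = StainMethod.parse(stain)
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim == 3 and image.shape[2] == 3:
        if channel_mode == "auto":
            channel_mode = "luminance"
        if channel_mode in ("luminance", "raw"):
            return luminance(image.astype(float))
        if channel_mode == "stain_distance":
            ref = np.array(_STAIN_REFERENCE_NUCLEUS_RGB[stain])
            dist = np.sqrt(((image.astype(float) - ref) ** 2).sum(axis=2))
            max_dist = np.sqrt(3.0) * 255.0
            return 255.0 * dist / max_dist
        raise ValueError(f"unknown channel_mode {channel_mode!r}")
    raise ValueError(f"unsupported channel count for shape {image.shape}")


@dataclass(frozen=True)
class Tile:
    """One tile cut from a larger image (padded to full tile size at edges)."""

    image: np.ndarray
    offset: tuple[int, int]          # (row, col) of the tile origin
    pad: tuple[int, int]             # rows/cols of zero padding on bottom/right

    @property
    def valid_shape(self) -> tuple[int, int]:
        return (self.image.shape[0] - self.pad[0], self.image.shape[1] - self.pad[1])


def _tile_starts(extent: int, tile_size: int, stride: int) -> list[int]:
    if extent <= tile_size:
        return [0]
    n = int(np.ceil((extent - tile_size) / stride)) + 1
    return [i * stride for i in range(n)]


def tile_image(image: np.ndarray, tile_size: int, stride: int | None = None) -> list[Tile]:
    """Cut an image into ``tile_size`` x ``tile_size`` tiles covering every pixel.

    Edge tiles are zero-padded to full size with the padding amount recorded,
    so stitching the unpadded regions reproduces the original exactly.
    """
    if tile_size < 1 or (stride is not None and stride < 1):
        raise ValueError("tile_size and stride must be >= 1")
    stride = tile_size if stride is None else stride
    image = np.asarray(image)
    h, w = image.shape[:2]
    tiles = []
    for r0 in _tile_starts(h, tile_size, stride):
        for c0 in _tile_starts(w, tile_size, stride):
            block = image[r0 : r0 + tile_size, c0 : c0 + tile_size]
            pad_r = tile_size - block.shape[0]
            pad_c = tile_size - block.shape[1]
            if pad_r or pad_c:
                pad_spec = [(0, pad_r), (0, pad_c)] + [(0, 0)] * (image.ndim - 2)
                block = np.pad(block, pad_spec)
            tiles.append(Tile(image=block, offset=(r0, c0), pad=(pad_r, pad_c)))
    return tiles


def stitch_tiles(tiles: list[Tile], shape) -> np.ndarray:
    """Reassemble the original image from tiles (inverse of :func:`tile_image`)."""
    out = np.zeros(shape, dtype=tiles[0].image.dtype)
    for t in tiles:
        vr, vc = t.valid_shape
        r0, c0 = t.offset
        out[r0 : r0 + vr, c0 : c0 + vc] = t.image[:vr, :vc]
    return out


def split_dataset(items, ratios=(0.6, 0.2, 0.2), rng=None):
    """Split items into disjoint subsets whose sizes match ``ratios``.

    Uniform random assignment without overlap; subset sizes follow the
    largest-remainder rule so they are exact up to rounding.  Returns a tuple
    of lists, one per ratio.
    """
    rng = np.random.default_rng(rng)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0) or ratios.sum() <= 0:
        raise ValueError("ratios must be nonnegative with a positive sum")
    ratios = ratios / ratios.sum()
    items = list(items)
    n = len(items)
    if n < int(np.count_nonzero(ratios)):
        raise ValueError("fewer items than nonzero ratio parts")

    exact = ratios * n
    sizes = np.floor(exact).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(exact - sizes), kind="stable")
    for k in order[:remainder]:
        sizes[k] += 1

    perm = rng.permutation(n)
    subsets, start = [], 0
    for size in sizes:
        subsets.append([items[i] for i in perm[start : start + size]])
        start += size
    return tuple(subsets)


def detect_suspicious_points(channel: np.ndarray, config: DetectConfig) -> list[SuspiciousPoint]:
    """Detect candidate objects on a single-channel image.

    Threshold (Otsu or fixed), binarize with the stain's polarity, take
    8-connected components and keep those within [min_area, max_area].  Ids
    follow raster order of the component centroids.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("detection expects a single-channel image")

    polarity = config.resolved_polarity()
    if isinstance(config.threshold, str):
        if channel.max() == channel.min():
            logger.warning("constant image: no threshold separates foreground")
            return []
        if config.threshold == "multiotsu":
            try:
                lo, hi = threshold_multiotsu(channel, classes=3)
            except ValueError:
                # fewer than three intensity populations: fall back to Otsu
                lo = hi = threshold_otsu(channel)
            thresh = float(lo if polarity == "dark" else hi)
        else:
            thresh = float(threshold_otsu(channel))
    else:
        thresh = float(config.threshold)
    fg = channel < thresh if polarity == "dark" else channel > thresh
    if not fg.any():
        logger.warning("threshold %.1f excludes all pixels (polarity=%s)", thresh, polarity)
        return []
    if isinstance(config.threshold, str) and fg.any() and not fg.all():
        contrast = abs(float(channel[fg].mean()) - float(channel[~fg].mean()))
        if contrast < config.min_contrast:
            logger.warning("foreground-background contrast %.1f below %.1f: "
                           "treating the image as object-free", contrast,
                           config.min_contrast)
            return []

    labels, n_labels = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return []
    max_area = config.resolved_max_area(channel.shape)
    objects = ndimage.find_objects(labels)

    candidates = []
    for lab, slc in enumerate(objects, start=1):
        local = labels[slc] == lab
        area = int(local.sum())
        if not (config.min_area <= area <= max_area):
            continue
        rr, cc = np.nonzero(local)
        centroid = (float(rr.mean()) + slc[0].start, float(cc.mean()) + slc[1].start)
        bbox = (slc[0].start, slc[1].start, slc[0].stop, slc[1].stop)
        candidates.append((centroid, bbox, local))

    candidates.sort(key=lambda c: (c[0][0], c[0][1]))
    return [
        SuspiciousPoint(id=i, bbox=bbox, mask=local, stain=config.stain, centroid=centroid)
        for i, (centroid, bbox, local) in enumerate(candidates)
    ]


def flag_ecm_location(points: list[SuspiciousPoint], ecm_mask: np.ndarray,
                      min_overlap: float = 0.5) -> list[SuspiciousPoint]:
    """Set ``in_ecm`` on each point: True iff >= ``min_overlap`` of its pixels
    lie inside the extracellular-matrix mask.  Mutates and returns the list."""
    ecm_mask = np.asarray(ecm_mask, dtype=bool)
    for p in points:
        r0, c0, r1, c1 = p.bbox
        if r1 > ecm_mask.shape[0] or c1 > ecm_mask.shape[1]:
            raise ValueError("ecm_mask shape does not cover the point's bounding box")
        overlap = int((p.mask & ecm_mask[r0:r1, c0:c1]).sum())
        p.in_ecm = overlap >= min_overlap * p.area
    return points


def match_to_ground_truth(points: list[SuspiciousPoint], truth_masks, shape,
                          min_iou: float = 0.5) -> dict[int, int]:
    """Greedy IoU matching of detections to ground-truth masks.

    ``truth_masks`` is a sequence of full-frame boolean masks or of objects
    with a ``pixel_coords()`` method.  Ground-truth objects must be pairwise
    disjoint (the simulator guarantees this).  Returns {point id -> truth
    index} for pairs with IoU >= ``min_iou``; each truth object is matched at
    most once, best IoU first.
    """
    label_img = np.zeros(shape, dtype=np.int32)
    truth_area = []
    for j, t in enumerate(truth_masks):
        rr, cc = np.nonzero(t) if isinstance(t, np.ndarray) else t.pixel_coords()
        label_img[rr, cc] = j + 1
        truth_area.append(len(rr))

    pairs = []
    for p in points:
        rr, cc = p.pixel_coords()
        hits = np.bincount(label_img[rr, cc], minlength=len(truth_area) + 1)
        for j in np.nonzero(hits[1:])[0]:
            inter = int(hits[j + 1])
            union = len(rr) + truth_area[j] - inter
            iou = inter / union
            if iou >= min_iou:
                pairs.append((iou, p.id, int(j)))
    pairs.sort(reverse=True)
    matched, used_p, used_t = {}, set(), set()
    for iou, pid, j in pairs:
        if pid in used_p or j in used_t:
            continue
        matched[pid] = j
        used_p.add(pid)
        used_t.add(j)
    return matched
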
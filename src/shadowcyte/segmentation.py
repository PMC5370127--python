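"""Locate and crop white-blood-cell shadows in a smear image.

Stained leukocytes transmit far less light than the bright field around
them, so on an 8-bit shadow image their pixels fall below a fixed
intensity cutoff (default 95) while the background and the much fainter
red cells stay above it. Segmentation is therefore a global threshold,
marker-controlled watershed splitting of touching shadows, an area
filter, and a bilinear resize of each cell's bounding box to the 64×64
patch the feature extractor expects. Each cell also gets an
equivalent-circular diameter in µm, measured on the raw (pre-resize)
mask, which later feeds the size prior of the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed
from skimage.transform import resize

from .image_io import DEFAULT_PIXEL_PITCH_UM, GrayImage

PATCH_SIZE = 64

#: Upper bound of the size-prior bins, in µm; anything wider than this is
#: not a single leukocyte.
MAX_WBC_DIAMETER_UM = 25.0


def measure_diameter(mask_area_px: int, pixel_pitch: float) -> float:
    """Equivalent circular diameter, in µm, of a mask of the given area.

    ``2 * sqrt(area / pi) * pixel_pitch`` — the diameter of the circle
    with the same pixel area as the cell mask.
    """
    if mask_area_px <= 0:
        raise ValueError(f"mask area must be positive, got {mask_area_px}")
    return 2.0 * math.sqrt(mask_area_px / math.pi) * pixel_pitch


def _area_of_diameter_um(diameter_um: float, pixel_pitch: float) -> float:
    r_px = diameter_um / (2.0 * pixel_pitch)
    return math.pi * r_px * r_px


@dataclass
class SegmentationParams:
    """Tunables of the shadow segmenter.

    ``wbc_threshold`` is the strict upper intensity bound of leukocyte
    shadows; ``max_area_px`` defaults (when None) to the pixel area of a
    25 µm disk at the given pitch.
    """

    wbc_threshold: int = 95
    min_area_px: int = 9
    max_area_px: int | None = None
    crop_margin_px: int = 2
    drop_border: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.wbc_threshold < 255:
            raise ValueError(f"wbc_threshold must be in (0, 255), got {self.wbc_threshold}")
        if self.min_area_px <= 0:
            raise ValueError("min_area_px must be positive")
        if self.max_area_px is not None and self.max_area_px <= self.min_area_px:
            raise ValueError("max_area_px must exceed min_area_px")

    def resolved_max_area(self, pixel_pitch: float) -> int:
        if self.max_area_px is not None:
            return self.max_area_px
        return int(math.ceil(_area_of_diameter_um(MAX_WBC_DIAMETER_UM, pixel_pitch)))


@dataclass
class CellCrop:
    """One segmented cell: 64×64 patch plus raw-mask geometry.

    ``bbox`` is (row_min, col_min, row_max, col_max), 0-based half-open,
    on the source image. ``diameter_um`` is measured on the raw mask
    before the resize, so it stays in physical units.
    """

    patch: GrayImage
    bbox: tuple[int, int, int, int]
    mask_area_px: int
    diameter_um: float

    def __post_init__(self) -> None:
        if self.patch.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {self.patch.shape}")
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")


def threshold_foreground(img: GrayImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Boolean mask of pixels strictly below the WBC intensity cutoff."""
    params = params or SegmentationParams()
    return img.pixels < params.wbc_threshold


def split_touching(mask: np.ndarray, params: SegmentationParams | None = None,
                   marker_smooth_sigma: float = 1.0) -> np.ndarray:
    """Split touching shadows with a marker-controlled watershed.

    Markers are local maxima of the (lightly smoothed) Euclidean
    distance transform, with a minimum separation equal to the radius
    implied by ``min_area_px``; flooding the negated distance map from
    those markers separates blobs joined by a neck. The smoothing
    (default sigma 1 px) suppresses the spurious secondary maxima that
    a noise-roughened mask boundary creates, which would otherwise
    over-split single cells. Components that contribute a single marker
    come back unchanged, so on a mask with no touching cells the result
    equals plain connected-component labeling.
    """
    params = params or SegmentationParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)

    components = cc_label(mask, connectivity=2)
    distance = ndimage.distance_transform_edt(mask)
    smoothed = ndimage.gaussian_filter(distance, marker_smooth_sigma)
    min_sep = max(2, int(round(math.sqrt(params.min_area_px / math.pi))))
    peaks = peak_local_max(
        smoothed, min_distance=min_sep, labels=components, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k

    # A flat or tiny component can yield no peak; seed it at its own
    # distance maximum so no foreground is lost.
    seeded = set(np.unique(components[markers > 0]))
    next_id = len(peaks) + 1
    for comp in np.unique(components):
        if comp == 0 or comp in seeded:
            continue
        rr, cc = np.nonzero(components == comp)
        best = np.argmax(distance[rr, cc])
        markers[rr[best], cc[best]] = next_id
        next_id += 1

    return watershed(-distance, markers, mask=mask).astype(np.int32)


def extract_crops(img: GrayImage, labels: np.ndarray,
                  params: SegmentationParams | None = None) -> list[CellCrop]:
    """Cut one 64×64 crop per acceptably sized labeled region.

    The region's bounding box is padded by ``crop_margin_px``, clipped to
    the image, and resampled bilinearly to 64×64. Crops come back in scan
    order (row_min, then col_min).
    """
    params = params or SegmentationParams()
    max_area = params.resolved_max_area(img.pixel_pitch)
    nrows, ncols = img.shape
    crops: list[CellCrop] = []
    for region in regionprops(np.asarray(labels)):
        if not params.min_area_px <= region.area <= max_area:
            continue
        r0, c0, r1, c1 = region.bbox
        if params.drop_border and (r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols):
            continue
        m = params.crop_margin_px
        r0, c0 = max(0, r0 - m), max(0, c0 - m)
        r1, c1 = min(nrows, r1 + m), min(ncols, c1 + m)
        window = img.pixels[r0:r1, c0:c1].astype(np.float64)
        patch = resize(window, (PATCH_SIZE, PATCH_SIZE), order=1,
                       preserve_range=True, anti_aliasing=False)
        patch = np.clip(np.rint(patch), 0, 255).astype(np.uint8)
        crops.append(CellCrop(
            patch=GrayImage(patch, img.pixel_pitch),
            bbox=(r0, c0, r1, c1),
            mask_area_px=int(region.area),
            diameter_um=measure_diameter(int(region.area), img.pixel_pitch),
        ))
    crops.sort(key=lambda c: (c.bbox[0], c.bbox[1]))
    return crops


def segment(img: GrayImage, params: SegmentationParams | None = None) -> list[CellCrop]:
    """Full segmentation chain: threshold → watershed split → crops."""
    params = params or SegmentationParams()
    mask = threshold_foreground(img, params)
    labels = split_touching(mask, params)
    return extract_crops(img, labels, params)
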
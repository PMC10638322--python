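"""Object-Location-Map extraction from saliency maps.

The normalization stage strips continuous visual attributes (size, shape,
intensity) from a scene before numerosity is extracted.  Given a grayscale
saliency map in which objects appear as bright, spatially separated
patches, the pipeline is:

1. rescale intensities to the nominal 0-255 range,
2. threshold (default 30) to a binary foreground map,
3. label connected foreground patches,
4. project each patch to the single cell of an 8x8 grid containing its
   centroid — the Object Location Map (OLM), a binary occupancy grid in
   which every object occupies exactly one cell regardless of its size or
   shape,
5. turn the OLM into a network stimulus: active cells (row-major) are the
   driven units, so set size equals the number of detected objects.

Saliency computation itself is out of scope; the module consumes
precomputed maps (PNG/PGM/TIFF) or the synthetic blob images produced by
:func:`synth_blob_image`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from skimage import measure

from .dynamics import StimulusSpec

__all__ = [
    "SaliencyMap",
    "OLMGrid",
    "load_saliency_map",
    "threshold_map",
    "count_patches",
    "to_olm_grid",
    "olm_to_stimulus",
    "synth_blob_image",
]

logger = logging.getLogger(__name__)

GRID_SIZE = 8
DEFAULT_THRESHOLD = 30.0


@dataclass
class SaliencyMap:
    """A grayscale intensity map of candidate object locations."""

    pixels: np.ndarray
    intensity_scale: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("saliency map must be 2-D")
        h, w = self.pixels.shape
        if h < GRID_SIZE or w < GRID_SIZE:
            raise ValueError(
                f"saliency map must be at least {GRID_SIZE}x{GRID_SIZE}, got {h}x{w}"
            )
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def rescaled(self) -> np.ndarray:
        """Intensities mapped onto 0..255 (max-normalised)."""
        peak = self.pixels.max()
        if peak == 0:
            return np.zeros_like(self.pixels)
        return self.pixels * (255.0 / peak)


def load_saliency_map(path) -> SaliencyMap:
    """Read a grayscale image (PNG/PGM/TIFF/...) as a saliency map."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return SaliencyMap(pixels=arr)


def threshold_map(sal: SaliencyMap, thresh: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary foreground map: rescaled intensity >= thresh (0-255 scale)."""
    if not 0 <= thresh <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {thresh}")
    return (sal.rescaled() >= thresh).astype(np.uint8)


def count_patches(
    binary: np.ndarray, connectivity: int = 8, min_area: int = 1
) -> Tuple[int, np.ndarray]:
    """Connected-component labelling of the foreground.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default).  Components smaller than ``min_area`` pixels are
    dropped (speckle suppression on real saliency maps).  Returns the
    patch count and the labelled image (0 = background).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("count_patches expects a binary map")
    labeled = measure.label(binary, connectivity=1 if connectivity == 4 else 2)
    if min_area > 1:
        keep = np.zeros_like(labeled)
        next_id = 1
        for region in measure.regionprops(labeled):
            if region.area >= min_area:
                keep[labeled == region.label] = next_id
                next_id += 1
        labeled = keep
    return int(labeled.max()), labeled


@dataclass
class OLMGrid:
    """8x8 binary occupancy map; one active cell per detected object."""

    grid: np.ndarray
    patch_count: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"OLM grid must be {GRID_SIZE}x{GRID_SIZE}")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("OLM grid entries must be 0/1")
        if self.patch_count < 0:
            raise ValueError("patch_count must be >= 0")

    @property
    def n_active(self) -> int:
        return int(self.grid.sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.grid, fmt="%d", delimiter=",")


def to_olm_grid(labeled: np.ndarray) -> OLMGrid:
    """Project labelled patches onto the 8x8 grid by centroid.

    Each patch activates exactly the grid cell containing its centroid,
    discarding patch size and shape.  Distinct patches whose centroids
    fall in the same cell merge into one active cell (logged).
    """
    labeled = np.asarray(labeled)
    h, w = labeled.shape
    grid = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.uint8)
    regions = measure.regionprops(labeled)
    merged = 0
    for region in regions:
        r, c = region.centroid
        gr = min(int(r * GRID_SIZE / h), GRID_SIZE - 1)
        gc = min(int(c * GRID_SIZE / w), GRID_SIZE - 1)
        if grid[gr, gc]:
            merged += 1
        grid[gr, gc] = 1
    if merged:
        logger.warning(
            "to_olm_grid: %d patch(es) merged into occupied cells", merged
        )
    return OLMGrid(grid=grid, patch_count=len(regions))


def olm_to_stimulus(
    olm: OLMGrid, presentation_steps: int = 100, input_current: float = 1.0
) -> StimulusSpec:
    """Network stimulus driving one unit per active OLM cell (row-major)."""
    idx = tuple(int(i) for i in np.flatnonzero(olm.grid.ravel(order="C")))
    return StimulusSpec(
        set_size=len(idx),
        input_current=input_current,
        presentation_steps=presentation_steps,
        node_indices=idx if idx else None,
    )


def synth_blob_image(
    k: int,
    size: Tuple[int, int] = (128, 128),
    seed: int = 0,
    radius: int = 6,
    peak: float = 230.0,
    background_sd: float = 2.0,
    shape: str = "disk",
) -> SaliencyMap:
    """Synthetic saliency-map stand-in: k bright, well-separated blobs.

    Blob centres are placed by seeded rejection sampling with pairwise
    separation of at least ``2 * radius + 2`` pixels (patches stay
    disjoint after thresholding) and at most one centre per cell of the
    8x8 projection grid (objects closer than one grid cell are
    unresolvable by the normalization by construction).  ``shape`` is ``"disk"``
    (uniform intensity ``peak``) or ``"gaussian"`` (peak ``peak``, sigma
    ``radius / 2``).  The background is low-level noise (clipped at
    ``10``), far below the default threshold.
    """
    h, w = int(size[0]), int(size[1])
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), k, h, w)))
    img = np.clip(np.abs(rng.normal(0.0, background_sd, size=(h, w))), 0, 10.0)

    margin = radius + 1
    if k > 0 and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise ValueError("image too small for the requested blob radius")
    centers: list[Tuple[int, int]] = []
    min_sep = 2 * radius + 2
    attempts = 0
    max_attempts = 2000 * max(k, 1)
    while len(centers) < k:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {k} blobs of radius {radius} on a {h}x{w} "
                f"canvas with separation {min_sep}"
            )
        attempts += 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        cell = (r * GRID_SIZE // h, c * GRID_SIZE // w)
        cells = {(r0 * GRID_SIZE // h, c0 * GRID_SIZE // w) for r0, c0 in centers}
        if cell not in cells and all(
            (r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers
        ):
            centers.append((r, c))

    yy, xx = np.mgrid[0:h, 0:w]
    for r0, c0 in centers:
        d2 = (yy - r0) ** 2 + (xx - c0) ** 2
        if shape == "gaussian":
            sigma = radius / 2.0
            blob = peak * np.exp(-d2 / (2 * sigma**2))
            img = np.maximum(img, np.where(d2 <= (2 * radius) ** 2, blob, 0.0))
        elif shape == "disk":
            img = np.maximum(img, np.where(d2 <= radius**2, peak, 0.0))
        else:
            raise ValueError(f"unknown blob shape {shape!r}")
    return SaliencyMap(pixels=img)


def extract_olm(
    sal: SaliencyMap,
    thresh: float = DEFAULT_THRESHOLD,
    connectivity: int = 8,
    min_area: int = 1,
) -> OLMGrid:
    """Convenience pipeline: threshold, label, project to the 8x8 grid."""
    binary = threshold_map(sal, thresh)
    _, labeled = count_patches(binary, connectivity=connectivity, min_area=min_area)
    return to_olm_grid(labeled)
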
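"""Marker-controlled watershed: probability map -> instance label map.

The pre-segmenter emits a probabilistic grayscale map in which touching or
overlapping white cells merge into single blobs.  This stage separates them:
Sobel gradient of the map, morphological smoothing by opening/closing by
reconstruction (disc radius 3), foreground markers from regional maxima,
background markers from the watershed ridge of the distance transform,
minima imposition so the gradient's only regional minima are the markers,
and a final marker-seeded watershed flood.  Seeding one marker per cell
gives a one-to-one marker/instance relationship, which is what suppresses
the over-segmentation of the plain watershed transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation

__all__ = [
    "WatershedParams", "MarkerSet", "DegenerateInputError",
    "sobel_gradient", "reconstruct_open_close", "foreground_markers",
    "background_markers", "impose_minima", "watershed_segment",
    "separate_cells", "label_overlay",
]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful marker construction."""


@dataclass(frozen=True)
class WatershedParams:
    """Tunables of the separation stage.

    ``radius``: disc radius of the structuring element for the
    reconstruction-based smoothing (px).  ``binarize_threshold``: cell/
    background cut as a fraction of the field's intensity range.
    ``min_marker_area``: smallest foreground marker kept, in px at 256x256
    (rescaled by (H/256)^2 for other sizes).  ``marker_sigma``: Gaussian
    smoothing of the distance transform before maxima extraction.
    ``marker_merge``: two distance-transform maxima closer than this
    fraction of the smaller one's inscribed radius are treated as splinters
    of one cell and merged.  ``saturation_fraction``: if more than this
    fraction of pixels sit at the map's maximum, markers come from the
    distance transform of the binarized map instead of intensity maxima (a
    near-binary map is flat inside cells, so intensity maxima would merge
    touching cells).
    """

    radius: int = 3
    binarize_threshold: float = 0.5
    min_marker_area: int = 20
    marker_sigma: float = 1.5
    marker_merge: float = 0.7
    saturation_fraction: float = 0.01

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("structuring element radius must be >= 1")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")


@dataclass
class MarkerSet:
    """Foreground marker components (one per putative cell) + background."""

    foreground: np.ndarray  # HxW int labels, 0 = none
    background: np.ndarray  # HxW bool ridge pixels

    def __post_init__(self):
        if np.any((self.foreground > 0) & self.background):
            raise ValueError("foreground and background markers overlap")

    @property
    def n_markers(self) -> int:
        return int(self.foreground.max(initial=0))


def _require_single_channel(field) -> np.ndarray:
    arr = np.asarray(field, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel field, got shape {arr.shape}")
    return arr


def sobel_gradient(gray) -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) of the two 3x3 Sobel kernels.

    Borders are handled by reflection; the output is zero on constant
    regions and non-negative everywhere.
    """
    arr = _require_single_channel(gray)
    gx = ndi.convolve(arr, _SOBEL_X, mode="reflect")
    gy = ndi.convolve(arr, _SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy)


def reconstruct_open_close(gray, radius: int = 3) -> np.ndarray:
    """Opening- then closing-by-reconstruction with a disc element.

    Removes bright peaks and dark valleys smaller than the disc while
    preserving the edges of larger structures (unlike a plain open/close,
    which rounds them off).
    """
    arr = _require_single_channel(gray)
    if radius < 1:
        raise ValueError("structuring element radius must be >= 1")
    selem = morphology.disk(radius)
    eroded = morphology.erosion(arr, selem)
    opened = morphology.reconstruction(eroded, arr, method="dilation")
    dilated = morphology.dilation(opened, selem)
    closed = morphology.reconstruction(dilated, opened, method="erosion")
    return closed


def foreground_markers(smoothed, min_marker_area: int = 20,
                       connectivity: int = 2) -> np.ndarray:
    """Label the regional maxima of a smoothed field as marker components.

    A regional maximum is a connected plateau strictly brighter than all
    its neighbors (8-connected by default).  Components smaller than
    ``min_marker_area`` are discarded and the rest relabeled 1..K.
    """
    arr = _require_single_channel(smoothed)
    maxima = morphology.local_maxima(arr, connectivity=connectivity)
    labels, _ = ndi.label(maxima, structure=np.ones((3, 3)) if connectivity == 2
                          else None)
    if min_marker_area > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_marker_area)
        labels[np.isin(labels, small[small > 0])] = 0
    return _relabel_consecutive(labels)


def background_markers(smoothed, threshold: float = 0.5) -> np.ndarray:
    """Background ridge mask from the distance-transform watershed.

    Binarize the field at ``threshold`` of its range, take the Euclidean
    distance of every background pixel to the nearest cell, and flood it:
    the watershed ridge runs midway between cells and marks background
    confidently far from every cell.  If there is a single basin (no ridge),
    the background pixels farthest from any cell are used instead.
    """
    arr = _require_single_channel(smoothed)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    lo, hi = float(arr.min()), float(arr.max())
    binary = arr > lo + threshold * (hi - lo)
    if binary.all():
        raise DegenerateInputError("binarization yields no background")
    if not binary.any():
        return np.zeros(arr.shape, dtype=bool)
    dist = ndi.distance_transform_edt(~binary)
    flooded = segmentation.watershed(dist, connectivity=1, watershed_line=True)
    ridge = (flooded == 0) & ~binary
    if not ridge.any():
        # single basin: mark the locally deepest background instead
        ridge = morphology.local_maxima(dist, connectivity=2) & ~binary
    return ridge


def impose_minima(gradient, marker_set: MarkerSet) -> np.ndarray:
    """Force the field's regional minima to be exactly the marker pixels.

    Grayscale reconstruction by erosion of a two-level marker field over
    ``min(gradient + h, marker field)``: marker pixels are pulled to the
    global floor and every other basin is filled just enough that no
    spurious minimum survives.
    """
    arr = _require_single_channel(gradient)
    markers = (marker_set.foreground > 0) | marker_set.background
    if markers.shape != arr.shape:
        raise ValueError("gradient and marker shapes differ")
    if not markers.any():
        raise DegenerateInputError("cannot impose minima on an empty marker set")
    rng_span = float(arr.max() - arr.min())
    h = rng_span / 1000.0 if rng_span > 0 else 1e-3
    lo = float(arr.min()) - 1.0
    hi = float(arr.max()) + h + 1.0
    seed = np.where(markers, lo, hi)
    mask = np.minimum(arr + h, seed)
    return morphology.reconstruction(seed, mask, method="erosion")


def watershed_segment(corrected, marker_set: MarkerSet) -> np.ndarray:
    """Marker-seeded watershed flood of the corrected gradient.

    Pixels flooded from a foreground marker take its id; pixels flooded
    from the background ridge take 0.  Flooding is 4-connected with
    deterministic (row-major) tie-breaking, so the result is reproducible.
    """
    arr = _require_single_channel(corrected)
    k = marker_set.n_markers
    if k == 0:
        raise DegenerateInputError("no foreground markers to flood from")
    seeds = marker_set.foreground.astype(np.int32).copy()
    bg_id = k + 1
    seeds[marker_set.background] = bg_id
    flooded = segmentation.watershed(arr, markers=seeds, connectivity=1)
    flooded[flooded == bg_id] = 0
    return _relabel_consecutive(flooded)


def separate_cells(prob_map, params: WatershedParams | None = None) -> np.ndarray:
    """Full separation stage: probability map in, instance label map out.

    Composition: smoothing by reconstruction -> foreground/background
    markers -> Sobel gradient -> minima imposition -> seeded watershed,
    with the result restricted to the binarized cell region.  An
    all-background map yields an empty label map (0 instances).
    """
    params = params or WatershedParams()
    arr = _require_single_channel(prob_map)
    lo, hi = float(arr.min()), float(arr.max())
    # the binarized silhouette is taken from the raw map: the reconstruction
    # smoothing fills the concave notches where cells meet, which widens
    # necks and can swallow the distance-transform maximum of a small cell
    binary = arr > lo + params.binarize_threshold * (hi - lo)
    if not binary.any() or hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    smoothed = reconstruct_open_close(arr, params.radius)

    scale = (arr.shape[0] / 256.0) ** 2
    min_area = max(1, int(round(params.min_marker_area * scale)))

    saturated = arr >= hi - 1e-9
    if saturated[binary].mean() > params.saturation_fraction:
        # near-binary map: interiors are flat at the maximum, so intensity
        # maxima cannot separate touching cells — use the distance
        # transform of the binarized silhouette instead
        fg = _distance_markers(binary, min_area, params.marker_sigma,
                               params.marker_merge)
    else:
        fg = foreground_markers(smoothed, min_marker_area=min_area)
        fg[~binary] = 0
        fg = _relabel_consecutive(fg)
    if fg.max(initial=0) == 0:
        return np.zeros(arr.shape, dtype=np.int64)

    bg = background_markers(arr, params.binarize_threshold)
    bg &= fg == 0
    markers = MarkerSet(foreground=fg, background=bg)

    gradient = sobel_gradient(smoothed)
    corrected = impose_minima(gradient, markers)
    labels = watershed_segment(corrected, markers)

    labels[~binary] = 0
    labels = _keep_marker_components(labels, fg)
    return _relabel_consecutive(labels)


def _distance_markers(binary: np.ndarray, min_area: int, sigma: float,
                      merge: float) -> np.ndarray:
    """One marker per cell from the silhouette's distance transform.

    Regional maxima of the lightly smoothed Euclidean distance transform,
    with two cleanups: maxima shallower than the radius of the smallest
    admissible cell are noise and dropped, and maxima closer together than
    ``merge`` times the smaller inscribed radius are splinters of a single
    (elongated) cell and are given one id.
    """
    dist = ndi.distance_transform_edt(binary)
    relief = ndi.gaussian_filter(dist, sigma=sigma) if sigma > 0 else dist
    maxima = morphology.local_maxima(relief, connectivity=2) & binary
    lab, n = ndi.label(maxima, structure=np.ones((3, 3)))
    if n == 0:
        return lab
    min_radius = np.sqrt(min_area / np.pi)
    peaks = np.atleast_1d(ndi.maximum(dist, labels=lab,
                                      index=np.arange(1, n + 1)))
    ids = [i for i in range(1, n + 1) if peaks[i - 1] >= min_radius]
    if not ids:
        return np.zeros_like(lab)
    cents = np.atleast_2d(ndi.center_of_mass(maxima, lab, ids))
    pks = peaks[np.asarray(ids) - 1]

    m = len(ids)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(m):
        for j in range(i + 1, m):
            sep = float(np.hypot(*(cents[i] - cents[j])))
            if sep < max(3.0, merge * min(pks[i], pks[j])):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    group = {}
    out = np.zeros_like(lab)
    for k, comp_id in enumerate(ids):
        root = find(k)
        group.setdefault(root, len(group) + 1)
        out[lab == comp_id] = group[root]
    return out


def label_overlay(image_pixels: np.ndarray, labels: np.ndarray,
                  seed: int = 0, alpha: float = 0.5) -> np.ndarray:
    """RGB overlay with one fixed random color per instance id."""
    rng = np.random.default_rng(seed)
    out = np.asarray(image_pixels, dtype=np.float64).copy()
    if out.ndim == 2:
        out = np.repeat(out[..., None], 3, axis=2)
    for lab in range(1, int(labels.max(initial=0)) + 1):
        color = rng.uniform(60, 255, size=3)
        sel = labels == lab
        out[sel] = (1 - alpha) * out[sel] + alpha * color
    return np.clip(out, 0, 255).astype(np.uint8)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int64)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def _keep_marker_components(labels: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """Keep, per id, only the connected component containing its marker.

    Restricting the flood to the binarized region can strand small
    fragments of an instance; each instance must stay connected, so the
    fragments are dropped to background.
    """
    out = labels.copy()
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        comp, n = ndi.label(labels == lab, structure=np.ones((3, 3)))
        if n <= 1:
            continue
        marker_comp = np.unique(comp[(fg == lab) & (comp > 0)])
        keep = int(marker_comp[0]) if len(marker_comp) else int(
            np.argmax(np.bincount(comp[comp > 0])) )
        out[(comp > 0) & (comp != keep)] = 0
    return out
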
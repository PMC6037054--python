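"""Recursive multilevel-threshold detection of lipid droplets in z-stacks.

Each focal plane is quantized into ``n_levels`` intensity classes; the top
class is the detection layer. Connected components of that layer that are
small and compact are accepted as droplets; over-large or non-circular
components are re-thresholded at a higher level (multilevel quantization of
the intensities *inside* the offending component), recursively, until they
split into acceptable dots or cannot be shrunk further. Per-plane dot masks
are merged across the stack by pixelwise OR, objects overlapping a manual
exclusion mask or smaller than a minimum area are removed, and intensity /
shape features are extracted for every object against the maximum-intensity
projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter_crofton, regionprops

from .image_io import ExclusionMask, ZStack, DROPLET_TABLE_COLUMNS

__all__ = [
    "SegmentationParams",
    "PlaneSegmentation",
    "SegmentationResult",
    "DegeneratePlaneWarning",
    "multiotsu_thresholds",
    "quantize",
    "top_level_mask",
    "circularity",
    "segment_plane",
    "merge_slices",
    "apply_filters",
    "max_projection",
    "segment_stack",
]


class DegeneratePlaneWarning(UserWarning):
    """A plane carries no usable intensity structure (constant, or noise only)."""


@dataclass
class SegmentationParams:
    """Tunables of the recursive thresholding procedure.

    Attributes
    ----------
    n_levels : int
        Number of quantization classes per thresholding step (default 5);
        the top class is the detection layer.
    max_area : int
        Components larger than this (pixels) are re-thresholded (default 800).
    min_area : int
        Objects strictly smaller than this after the z-merge are removed
        (default 4). Areas of exactly ``min_area`` survive and areas of
        exactly ``max_area`` do not recurse (strict-inequality readings).
    circularity_min : float
        Compactness cutoff 4*pi*area/perimeter^2 below which a component is
        re-thresholded (default 0.6).
    max_depth : int
        Recursion cap; at this depth a still-violating component is accepted
        as-is and flagged ``forced`` (default 10).
    connectivity : int
        4 or 8; pixel connectivity for component labeling (default 8).
    quantizer : str
        ``"otsu"`` for multilevel Otsu (minimize within-class intensity
        variance) or ``"equal-width"`` for uniform binning of the range.
    noise_margin : float
        Structure guard: a plane is treated as degenerate (no detection
        layer) when its top threshold lies within ``noise_margin`` robust
        standard deviations (1.4826*MAD) of the plane median. Separates
        planes with genuine bright structure (margins of order 100) from
        pure detector noise (margins of order 1); see the methods note.
    """

    n_levels: int = 5
    max_area: int = 800
    min_area: int = 4
    circularity_min: float = 0.6
    max_depth: int = 10
    connectivity: int = 8
    quantizer: str = "otsu"
    noise_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if not 0 < self.circularity_min <= 1:
            raise ValueError("circularity_min must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.quantizer not in ("otsu", "equal-width"):
            raise ValueError("quantizer must be 'otsu' or 'equal-width'")

    @property
    def _ndi_structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


def multiotsu_thresholds(values: np.ndarray, classes: int, nbins: int = 256) -> np.ndarray:
    """Globally optimal multilevel Otsu thresholds.

    Histograms the intensities into ``nbins`` bins and finds the partition
    into ``classes`` contiguous bin runs minimizing the total within-class
    (count-weighted) intensity variance, by dynamic programming over
    segment boundaries — O(classes * nbins^2), exact. Returns the
    ``classes - 1`` threshold values (bin edges); a pixel's class is the
    number of thresholds at or below it.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cs = np.concatenate([[0.0], np.cumsum(w * centers)])
    css = np.concatenate([[0.0], np.cumsum(w * (centers ** 2))])

    idx = np.arange(nbins + 1)
    # cost[i, j] = weighted SSE of bins i..j-1 around their mean
    W = cw[None, :] - cw[:, None]
    S = cs[None, :] - cs[:, None]
    SS = css[None, :] - css[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = SS - np.where(W > 0, S * S / np.where(W > 0, W, 1.0), 0.0)
    cost[W <= 0] = 0.0
    cost = np.where(idx[:, None] > idx[None, :], np.inf, cost)  # only i <= j

    # D[j] = min cost of covering bins 0..j-1 with the classes so far
    D = cost[0, :].copy()
    splits = np.zeros((classes, nbins + 1), dtype=int)
    for c in range(1, classes):
        total = D[:, None] + cost  # total[i, j]: last class = bins i..j-1
        arg = np.argmin(total, axis=0)
        D = total[arg, idx]
        splits[c] = arg
    # backtrack boundaries of the optimal partition of all nbins bins
    bounds = []
    j = nbins
    for c in range(classes - 1, 0, -1):
        j = int(splits[c][j])
        bounds.append(j)
    bounds.reverse()
    return edges[np.asarray(bounds, dtype=int)]


def quantize(plane: np.ndarray, n_levels: int = 5, quantizer: str = "otsu") -> np.ndarray:
    """Quantize intensities into ``n_levels`` ordered classes 0..n_levels-1.

    The mapping is monotone in intensity. With at least ``n_levels`` distinct
    intensities the classes span the full 0..n_levels-1 range; with fewer,
    the distinct values are spread monotonically over the range so the
    brightest pixels always occupy the top class. A constant input yields
    all-zero levels and a :class:`DegeneratePlaneWarning` (not an exception).

    Works on 2D planes and on 1D intensity vectors (used by the recursion to
    re-threshold inside a single component).
    """
    plane = np.asarray(plane)
    if plane.size == 0:
        raise ValueError("empty plane")
    values = np.unique(plane)
    if values.size == 1:
        warnings.warn("degenerate plane: constant intensity", DegeneratePlaneWarning,
                      stacklevel=2)
        return np.zeros(plane.shape, dtype=np.int8)
    if quantizer == "equal-width":
        lo, hi = float(values[0]), float(values[-1])
        levels = np.floor((plane - lo) * n_levels / (hi - lo + 1)).astype(np.int8)
        return np.clip(levels, 0, n_levels - 1)
    if quantizer != "otsu":
        raise ValueError(f"unknown quantizer {quantizer!r}")
    if values.size <= n_levels:
        # Too few distinct intensities for n_levels-class Otsu: rank-spread
        # the distinct values over 0..n_levels-1 (monotone; max -> top class).
        ranks = np.searchsorted(values, plane)
        levels = np.round(ranks * (n_levels - 1) / (values.size - 1)).astype(np.int8)
        return levels
    # Thresholds are applied back to the original intensities, so the level
    # mapping is exactly monotone regardless of histogram binning.
    thresholds = multiotsu_thresholds(plane, classes=n_levels, nbins=256)
    # searchsorted instead of digitize: tolerant of coincident thresholds
    return np.searchsorted(thresholds, plane, side="right").astype(np.int8)


def top_level_mask(plane: np.ndarray, levels: np.ndarray, n_levels: int = 5) -> np.ndarray:
    """Mask of pixels in the highest quantization class (the detection layer)."""
    del plane  # retained in the signature for symmetry with quantize
    return np.asarray(levels) == n_levels - 1


def _perimeter(mask: np.ndarray) -> float:
    return float(perimeter_crofton(np.pad(mask, 1), directions=4))


def _components(mask: np.ndarray, structure: np.ndarray):
    """Yield (bounding-box slices, cropped component mask) per component."""
    labeled, n = ndimage.label(mask, structure=structure)
    for k, sl in enumerate(ndimage.find_objects(labeled, max_label=n), start=1):
        if sl is not None:
            yield sl, labeled[sl] == k


def circularity(mask: np.ndarray) -> float:
    """Compactness 4*pi*area/perimeter^2 of a single connected component.

    Perimeter is the 4-direction Crofton estimator. Discretization can push
    the ratio slightly above 1 for compact rasters; values are clipped to 1.
    A single pixel returns 1 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty pixel set")
    if area == 1:
        return 1.0
    perim = _perimeter(mask)
    if perim == 0:
        return 1.0
    return float(min(1.0, 4 * np.pi * area / perim**2))


@dataclass
class PlaneSegmentation:
    """Per-plane output of :func:`segment_plane`.

    ``mask`` is the union of accepted dots; ``forced_mask`` marks the subset
    belonging to components accepted only because they could not be split
    further (recursion cap or uniform intensity); ``depth_map`` records, per
    accepted pixel, the recursion depth at which its component was accepted.
    """

    mask: np.ndarray
    forced_mask: np.ndarray
    depth_map: np.ndarray
    degenerate: bool = False


def _plane_is_degenerate(plane: np.ndarray, top_threshold: float, margin: float) -> bool:
    med = float(np.median(plane))
    mad = float(np.median(np.abs(plane - med)))
    robust_sigma = 1.4826 * mad
    if robust_sigma == 0:
        return top_threshold <= med
    return (top_threshold - med) < margin * robust_sigma


def segment_plane(plane: np.ndarray,
                  params: SegmentationParams | None = None) -> PlaneSegmentation:
    """Detect droplet dots on one focal plane by recursive re-thresholding.

    The plane is quantized and the top class labeled into components. Each
    component with ``area <= max_area`` and ``circularity >= circularity_min``
    is accepted. Each violating component is re-quantized (its own pixel
    intensities, ``n_levels`` classes); the new top class, a strict subset of
    the component, is relabeled and processed one recursion level deeper. A
    component that cannot shrink (uniform intensity) or that is still
    violating at ``max_depth`` is accepted as-is with the forced flag.
    """
    if params is None:
        params = SegmentationParams()
    plane = np.asarray(plane)
    shape = plane.shape
    out = PlaneSegmentation(
        mask=np.zeros(shape, dtype=bool),
        forced_mask=np.zeros(shape, dtype=bool),
        depth_map=np.full(shape, -1, dtype=np.int16),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneratePlaneWarning)
        levels = quantize(plane, params.n_levels, params.quantizer)
    top = top_level_mask(plane, levels, params.n_levels)
    if not top.any():
        out.degenerate = True
        return out
    # Structure guard: on a noise-only plane the top class is just the upper
    # tail of the noise distribution; treat such planes as degenerate.
    top_threshold = float(plane[top].min())
    if _plane_is_degenerate(plane, top_threshold, params.noise_margin):
        out.degenerate = True
        return out

    structure = params._ndi_structure

    def accept(sl, comp: np.ndarray, depth: int, forced: bool) -> None:
        out.mask[sl] |= comp
        out.depth_map[sl][comp] = depth
        if forced:
            out.forced_mask[sl] |= comp

    def process(sl, comp: np.ndarray, depth: int) -> None:
        # sl: bounding-box slices into the plane; comp: cropped component mask
        area = int(comp.sum())
        if area <= params.max_area and circularity(comp) >= params.circularity_min:
            accept(sl, comp, depth, forced=False)
            return
        if depth >= params.max_depth:
            accept(sl, comp, depth, forced=True)
            return
        vals = plane[sl][comp]
        if np.unique(vals).size == 1:
            accept(sl, comp, depth + 1, forced=True)
            return
        sub_levels = quantize(vals, params.n_levels, params.quantizer)
        candidate = np.zeros(comp.shape, dtype=bool)
        candidate[comp] = sub_levels == params.n_levels - 1
        n_cand = int(candidate.sum())
        if n_cand in (0, area):  # cannot shrink
            accept(sl, comp, depth + 1, forced=True)
            return
        r_off, c_off = sl[0].start, sl[1].start
        for sub_sl, sub_comp in _components(candidate, structure):
            abs_sl = (slice(r_off + sub_sl[0].start, r_off + sub_sl[0].stop),
                      slice(c_off + sub_sl[1].start, c_off + sub_sl[1].stop))
            process(abs_sl, sub_comp, depth + 1)

    for sl, comp in _components(top, structure):
        process(sl, comp, depth=0)
    return out


def merge_slices(masks: list[np.ndarray]) -> np.ndarray:
    """Pixelwise OR of per-plane dot masks."""
    if len(masks) == 0:
        raise ValueError("no masks to merge")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    merged = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        merged |= np.asarray(m, dtype=bool)
    return merged


@dataclass
class SegmentationResult:
    """Labeled droplets plus everything removed by the post-merge filters.

    ``droplets`` and ``removed`` partition the set of merged-mask objects;
    ``label_image`` labels the accepted droplets 1..K. Both tables carry the
    fixed on-disk columns plus in-memory extras (``depth_found``, ``forced``).
    """

    label_image: np.ndarray
    droplets: pd.DataFrame
    removed: pd.DataFrame
    params: SegmentationParams
    provenance: dict = field(default_factory=dict)

    @property
    def n_droplets(self) -> int:
        return len(self.droplets)


def _empty_table() -> pd.DataFrame:
    cols = DROPLET_TABLE_COLUMNS + ["depth_found", "forced"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def max_projection(stack: ZStack) -> np.ndarray:
    """Maximum-intensity projection: per-pixel max across all planes."""
    return np.max(np.asarray(stack.planes), axis=0)


def apply_filters(merged_mask: np.ndarray,
                  exclusion: ExclusionMask | None,
                  reference: np.ndarray,
                  params: SegmentationParams | None = None,
                  *,
                  slice_masks: list[np.ndarray] | None = None,
                  forced_mask: np.ndarray | None = None,
                  depth_map: np.ndarray | None = None,
                  source_image: str = "") -> SegmentationResult:
    """Label the merged mask, drop masked / too-small objects, extract features.

    An object is removed if it has at least one pixel on the exclusion mask
    (reason ``mask_overlap``) or area strictly below ``min_area`` (reason
    ``below_min_area``); survivors are relabeled 1..K. Features (area,
    centroid, Crofton perimeter, circularity, integrated and max intensity
    over the ``reference`` image) are extracted for accepted and removed
    objects alike.
    """
    if params is None:
        params = SegmentationParams()
    merged_mask = np.asarray(merged_mask, dtype=bool)
    reference = np.asarray(reference)
    if merged_mask.shape != reference.shape:
        raise ValueError("merged mask and reference image shapes differ")
    excl = (np.zeros(merged_mask.shape, dtype=bool) if exclusion is None
            else np.asarray(exclusion.grid, dtype=bool))
    if excl.shape != merged_mask.shape:
        raise ValueError("exclusion mask shape does not match image")

    labeled, n = ndimage.label(merged_mask, structure=params._ndi_structure)
    accepted_rows: list[dict] = []
    removed_rows: list[dict] = []
    label_image = np.zeros(merged_mask.shape, dtype=np.int32)

    for region in regionprops(labeled):
        sl, comp = region.slice, region.image  # bounding box + cropped mask
        area = int(region.area)
        if excl[sl][comp].any():
            reason = "mask_overlap"
        elif area < params.min_area:
            reason = "below_min_area"
        else:
            reason = ""
        row = {
            "source_image": source_image,
            "slice_first_seen": _first_slice(sl, comp, slice_masks),
            "area_px": area,
            "centroid_row": float(region.centroid[0]),
            "centroid_col": float(region.centroid[1]),
            "perimeter_px": _perimeter(comp),
            "circularity": circularity(comp),
            "integrated_intensity": float(reference[sl][comp].sum()),
            "max_intensity": float(reference[sl][comp].max()),
            "excluded_reason": reason,
            "depth_found": int(depth_map[sl][comp].max()) if depth_map is not None else 0,
            "forced": bool(forced_mask[sl][comp].any()) if forced_mask is not None else False,
        }
        if reason:
            removed_rows.append(row)
        else:
            accepted_rows.append((row, sl, comp))

    droplet_rows = []
    for new_id, (row, sl, comp) in enumerate(accepted_rows, start=1):
        label_image[sl][comp] = new_id
        droplet_rows.append({"droplet_id": new_id, **row})
    removed_tbl = [{"droplet_id": i, **row} for i, row in enumerate(removed_rows, start=1)]

    droplets = pd.DataFrame(droplet_rows) if droplet_rows else _empty_table()
    removed = pd.DataFrame(removed_tbl) if removed_tbl else _empty_table()
    provenance = {"source_image": source_image, "n_objects_prefilter": int(n)}
    return SegmentationResult(label_image=label_image, droplets=droplets,
                              removed=removed, params=params, provenance=provenance)


def _first_slice(sl, comp: np.ndarray, slice_masks: list[np.ndarray] | None) -> int:
    if not slice_masks:
        return 0
    for z, m in enumerate(slice_masks):
        if (np.asarray(m, dtype=bool)[sl] & comp).any():
            return z
    return 0


def segment_stack(stack: ZStack,
                  exclusion: ExclusionMask | None = None,
                  params: SegmentationParams | None = None,
                  *,
                  source_image: str = "") -> SegmentationResult:
    """End-to-end droplet detection on a z-stack.

    Runs :func:`segment_plane` on every plane independently, merges the
    per-plane dot masks by pixelwise OR, and applies the exclusion / minimum
    area filters with features extracted against the maximum-intensity
    projection of the stack.
    """
    if params is None:
        params = SegmentationParams()
    planes = np.asarray(stack.planes)
    per_plane = [segment_plane(p, params) for p in planes]
    masks = [ps.mask for ps in per_plane]
    merged = merge_slices(masks)
    forced = merge_slices([ps.forced_mask for ps in per_plane])
    depth_map = np.max(np.stack([ps.depth_map for ps in per_plane]), axis=0)
    reference = max_projection(stack)
    result = apply_filters(merged, exclusion, reference, params,
                           slice_masks=masks, forced_mask=forced,
                           depth_map=depth_map, source_image=source_image)
    result.provenance.update({
        "n_slices": stack.n_slices,
        "degenerate_planes": [z for z, ps in enumerate(per_plane) if ps.degenerate],
        "params": asdict(params),
    })
    return result
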
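"""Cell and nuclear mask extraction from per-cell image tiles.

Cells are segmented from the bright-field proxy (dark interior on a bright
background) with a grayscale Otsu threshold; nuclei from the marker channel
with an in-cell Otsu threshold plus a minimum-area filter. Masks can be
eroded with a disk element before intensity measurement, and septated cells
are split into two masks at the detected septum plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from functools import lru_cache

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk

disk = lru_cache(maxsize=None)(lambda radius: _disk(radius))

from .errors import SegmentationError, ValidationError


def _otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold maximising between-class variance (histogram-based)."""
    v = values.ravel()
    vmin, vmax = float(v.min()), float(v.max())
    scale = (nbins - 1) / (vmax - vmin)
    hist = np.bincount(((v - vmin) * scale).astype(np.intp), minlength=nbins)
    centers = vmin + (np.arange(nbins) + 0.5) / scale
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m = np.cumsum(hist * centers)
    mu0 = m / np.where(w0 == 0, 1, w0)
    mu1 = (m[-1] - m) / np.where(w1 == 0, 1, w1)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    return float(centers[np.argmax(var_between)])

__all__ = [
    "CellMask",
    "NuclearMask",
    "segment_cell",
    "erode_mask",
    "segment_nuclei",
    "split_septated",
    "MIN_NUCLEAR_RADIUS_UM",
]

# Nuclear components smaller than a 0.5 um-radius disk are noise specks.
MIN_NUCLEAR_RADIUS_UM = 0.5


@dataclass
class CellMask:
    """A single-cell binary mask with physical pixel size."""

    mask: np.ndarray
    pixel_size: float
    provenance: str = "BF_OTSU"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise SegmentationError("cell mask is empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size ** 2


@dataclass
class NuclearMask:
    """Labelled nuclear components inside a cell mask."""

    mask: np.ndarray
    component_count: int
    labels: np.ndarray = field(repr=False, default=None)


def segment_cell(bf: np.ndarray, pixel_size: float) -> CellMask:
    """Segment the cell from a bright-field image by Otsu thresholding.

    The foreground is the darker Otsu class (cell interiors are dark in
    bright field); the largest connected component is kept and holes are
    filled.  Raises :class:`SegmentationError` when no foreground exists
    (e.g. a blank image).
    """
    bf = np.asarray(bf, dtype=float)
    if bf.max() - bf.min() <= 1e-12:
        raise SegmentationError("blank bright-field image: no foreground")
    t = _otsu(bf)
    fg = bf < t
    if not fg.any():
        raise SegmentationError("empty foreground after Otsu threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == sizes.argmax()
    fg = ndimage.binary_fill_holes(fg)
    return CellMask(mask=fg, pixel_size=pixel_size, provenance="BF_OTSU")


def erode_mask(mask: CellMask, radius: int = 3) -> CellMask:
    """Morphologically erode a cell mask with a disk structuring element."""
    if radius < 0:
        raise ValidationError("erosion radius must be >= 0")
    if radius == 0:
        return replace(mask, mask=mask.mask.copy())
    eroded = ndimage.binary_erosion(mask.mask, structure=disk(radius))
    if not eroded.any():
        raise SegmentationError(f"erosion with radius {radius} emptied the mask")
    return replace(mask, mask=eroded)


def segment_nuclei(marker: np.ndarray, cell_mask: CellMask,
                   min_radius_um: float = MIN_NUCLEAR_RADIUS_UM) -> NuclearMask:
    """Threshold the nuclear-marker channel inside the cell mask.

    Otsu is computed over in-cell pixels only; connected components smaller
    than a ``min_radius_um`` disk are discarded. Zero components is a valid
    outcome (e.g. an unlabelled marker channel), not an error.
    """
    marker = np.asarray(marker, dtype=float)
    inside = marker[cell_mask.mask]
    empty = NuclearMask(mask=np.zeros_like(cell_mask.mask), component_count=0,
                        labels=np.zeros(cell_mask.mask.shape, dtype=int))
    if inside.max() - inside.min() <= 1e-12:
        return empty
    t = _otsu(inside)
    # Guard against thresholding pure noise: require real contrast between
    # the two Otsu classes relative to the in-cell spread.
    lo, hi = inside[inside <= t], inside[inside > t]
    if hi.size == 0 or hi.mean() - lo.mean() < 4.0 * max(lo.std(), 1e-12):
        return empty
    nuc = (marker > t) & cell_mask.mask
    labels, n = ndimage.label(nuc)
    if n == 0:
        return empty
    min_area_px = np.pi * (min_radius_um / cell_mask.pixel_size) ** 2
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_area_px)
    keep = keep[keep != 0]
    out = np.isin(labels, keep)
    relabeled, count = ndimage.label(out)
    return NuclearMask(mask=out, component_count=int(count), labels=relabeled)


def _axis_bf_profile(mask: np.ndarray, bf: np.ndarray):
    """Mean bright-field value per occupied column along the long axis."""
    counts = mask.sum(axis=0)
    cols = np.flatnonzero(counts)
    sums = np.where(mask, bf, 0.0).sum(axis=0)
    prof = sums[cols] / counts[cols]
    return cols, prof


def split_septated(cell_mask: CellMask, bf: np.ndarray | None = None,
                   septum_halfwidth_px: int = 1, k_mad: float = 3.0,
                   min_lift: float = 5.0,
                   min_child_area_px: int = 200) -> list[CellMask]:
    """Split a cell mask in two at a detected division septum.

    The septum appears as a bright transverse band in the bright-field
    proxy. Detection: the per-column mean bright-field profile inside the
    mask, restricted to the central 50% of the cell, must exceed
    ``median + max(k_mad * MAD, min_lift)``; the qualifying column nearest
    mid-length is the cut plane. If no septum is detected, or a cut would
    produce a component smaller than ``min_child_area_px``, the input mask
    is returned unchanged (as a one-element list).
    """
    if bf is None:
        return [cell_mask]
    cols, prof = _axis_bf_profile(cell_mask.mask, np.asarray(bf, dtype=float))
    if cols.size < 8:
        return [cell_mask]
    med = np.median(prof)
    mad = np.median(np.abs(prof - med))
    thr = med + max(k_mad * 1.4826 * mad, min_lift)
    q1, q3 = cols.size // 4, (3 * cols.size) // 4
    central = np.arange(q1, q3)
    cand = central[prof[central] > thr]
    if cand.size == 0:
        return [cell_mask]
    mid = (cols.size - 1) / 2.0
    cut = cols[cand[np.argmin(np.abs(cand - mid))]]

    cut_mask = cell_mask.mask.copy()
    lo = max(0, cut - septum_halfwidth_px)
    hi = min(cut_mask.shape[1], cut + septum_halfwidth_px + 1)
    cut_mask[:, lo:hi] = False
    labels, n = ndimage.label(cut_mask)
    if n < 2:
        return [cell_mask]
    sizes = np.bincount(labels.ravel())
    order = np.argsort(sizes[1:])[::-1] + 1
    a, b = order[:2]
    if sizes[a] < min_child_area_px or sizes[b] < min_child_area_px:
        return [cell_mask]  # splitting suppressed: child too small
    children = []
    for lab in sorted((a, b), key=lambda l: np.flatnonzero((labels == l).any(axis=0))[0]):
        children.append(replace(cell_mask, mask=labels == lab))
    return children
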
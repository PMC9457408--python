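"""Per-cell fluorescence measurements.

Implements the imaging-flow-cytometry-style measurement path: whole-cell
total/mean/max intensity and top-percentile pixel mean over an eroded cell
mask, medial-line nucleus counting with per-nucleus intensities,
dual-channel nuclear means, background (autofluorescence) correction from
an untagged control, and sequential shape/focus/intensity gating.

Collections of cells are handled as pandas DataFrames (one row per
measured cell, columns as in :data:`RECORD_COLUMNS`); :class:`CellRecord`
is the single-cell view of a row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import skeletonize

from .errors import (DegenerateShapeError, FitError, SegmentationError,
                     ValidationError)
from .segmentation import (CellMask, NuclearMask, erode_mask, segment_cell,
                           segment_nuclei, split_septated)
from .synthetic import (CellSpec, ImageTile, NoiseParams, PopulationParams,
                        simulate_tiles)

__all__ = [
    "CellRecord",
    "BackgroundModel",
    "GateSet",
    "RECORD_COLUMNS",
    "medial_line",
    "marker_profile",
    "count_nuclei_medial",
    "top_percent_mean",
    "nuclear_mean",
    "shape_features",
    "measure_tile",
    "measure_population",
    "fit_background",
    "subtract_background",
    "apply_gates",
]

RECORD_COLUMNS = [
    "cell_id", "parent_id", "length_um", "area_px",
    "total_intensity", "mean_intensity", "max_pixel", "top_p_mean",
    "n_nuclei", "nuclear_mean_1", "nuclear_mean_2",
    "septated", "from_split", "parent_length_um",
    "width_um", "thickness_max_um", "thickness_min_um", "gradient_rms",
    "background_corrected",
]

TRUTH_COLUMNS = [
    "stage", "cycle_position", "true_wholecell_conc", "true_nuclear_conc",
    "true_length_um",
]


@dataclass
class CellRecord:
    """Measurements for one cell (one row of a record table)."""

    length_um: float
    total_intensity: float
    mean_intensity: float
    max_pixel: float
    top_p_mean: float
    n_nuclei: int
    nuclear_mean_mono: float | None = None
    nuclear_means_bi: tuple[float, float] | None = None
    septated: bool = False
    gates_passed: bool | None = None
    background_corrected: bool = False


@dataclass(frozen=True)
class BackgroundModel:
    """Linear-in-length background for one intensity feature."""

    slope: float
    intercept: float
    feature: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise FitError("background model coefficients must be finite")

    def predict(self, length_um):
        return self.intercept + self.slope * np.asarray(length_um, dtype=float)


@dataclass(frozen=True)
class GateSet:
    """Sequential gates R1-R5 on shape, focus and intensity features.

    Intervals are closed; defaults are the imaging-flow gate coordinates
    used for wild-type fission yeast (widths/thicknesses in um, focus
    score on the instrument scale). R5 removes per-strain intensity extremes outside the configured
    quantile pair.
    """

    width_range: tuple[float, float] = (3.75, 6.75)
    thickness_max_range: tuple[float, float] = (3.75, 6.75)
    thickness_min_range: tuple[float, float] = (3.1, 5.5)
    gradient_rms_range: tuple[float, float] = (65.0, 78.0)
    intensity_extreme_policy: tuple[float, float] = (0.001, 0.999)

    def __post_init__(self) -> None:
        for name in ("width_range", "thickness_max_range", "thickness_min_range",
                     "gradient_rms_range", "intensity_extreme_policy"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: lower bound exceeds upper bound")


# ---------------------------------------------------------------------------
# Medial line


def _skeleton_graph(skel: np.ndarray):
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    nbrs: list[list[int]] = [[] for _ in coords]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(map(tuple, coords)):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                nbrs[i].append(j)
    return coords, nbrs


def _prune_skeleton(skel: np.ndarray, max_iter: int = 20) -> np.ndarray:
    """Iteratively remove the shortest side branch until two endpoints remain."""
    skel = skel.copy()
    for _ in range(max_iter):
        coords, nbrs = _skeleton_graph(skel)
        deg = np.array([len(n) for n in nbrs])
        endpoints = np.flatnonzero(deg == 1)
        if endpoints.size <= 2:
            return skel
        # walk from each endpoint to the first junction; drop shortest branch
        branches = []
        for e in endpoints:
            path = [e]
            seen = {e}
            cur = e
            for _ in range(len(coords)):
                nxt = [j for j in nbrs[cur] if j not in seen]
                if len(nxt) != 1:
                    break
                cur = nxt[0]
                seen.add(cur)
                if deg[cur] >= 3:
                    break
                path.append(cur)
            branches.append(path)
        shortest = min(branches, key=len)
        for i in shortest:
            skel[tuple(coords[i])] = False
    return skel


def _order_path(skel: np.ndarray) -> np.ndarray:
    coords, nbrs = _skeleton_graph(skel)
    deg = np.array([len(n) for n in nbrs])
    endpoints = np.flatnonzero(deg == 1)
    if endpoints.size != 2:
        raise DegenerateShapeError(
            f"skeleton has {endpoints.size} endpoints after pruning; "
            "mask is not rod-shaped"
        )
    order = [int(endpoints[0])]
    seen = {order[0]}
    for _ in range(len(coords)):
        cur = order[-1]
        nxt = [j for j in nbrs[cur] if j not in seen]
        if not nxt:
            break
        # prefer a degree-2 continuation over cutting a corner diagonally
        cur = min(nxt, key=lambda j: len(nbrs[j]))
        order.append(cur)
        seen.add(cur)
        if cur == endpoints[1]:
            break
    if order[-1] != endpoints[1]:
        raise DegenerateShapeError("could not trace a tip-to-tip medial path")
    return coords[order]


def _end_tangent(path: np.ndarray, endidx: int, sign: int, k: int = 15) -> np.ndarray:
    """Robust outward tangent at a path end: principal direction of the last
    ``k`` points (the raw skeleton jitters between adjacent rows)."""
    if sign > 0:
        seg = path[max(0, len(path) - k):].astype(float)
    else:
        seg = path[: min(k, len(path))].astype(float)
    seg = seg - seg.mean(axis=0)
    _, _, vt = np.linalg.svd(seg, full_matrices=False)
    d = vt[0]
    along = seg @ d
    # orient outward: endpoint should have the extreme projection
    end_proj = along[-1] if sign > 0 else along[0]
    if end_proj < 0:
        d = -d
    return d


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Prolong the medial path along its end tangents until it leaves the mask."""
    out = [path.astype(float)]
    for endidx, sign in ((0, -1), (len(path) - 1, 1)):
        d = _end_tangent(path, endidx, sign)
        pts = []
        p = path[endidx].astype(float)
        while True:
            p = p + 0.5 * d
            r, c = int(round(p[0])), int(round(p[1]))
            if r < 0 or c < 0 or r >= mask.shape[0] or c >= mask.shape[1] or not mask[r, c]:
                break
            pts.append(p.copy())
        if pts:
            seg = np.array(pts)
            out = [seg[::-1]] + out if sign == -1 else out + [seg]
    return np.vstack(out)


def _polyline_length(path: np.ndarray, step: int = 5) -> float:
    """Arc length of a sub-sampled polyline through the path (pixels).

    Sub-sampling suppresses the staircase overestimate of 8-connected
    chains for rotated rods.
    """
    idx = np.arange(0, len(path), step)
    if idx[-1] != len(path) - 1:
        idx = np.append(idx, len(path) - 1)
    pts = path[idx].astype(float)
    return float(np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1)).sum())


def medial_line(mask: CellMask):
    """Single-pixel medial path from tip to tip, and its length in um.

    The skeleton of the mask is pruned of side branches, ordered by a
    geodesic walk between its two endpoints and extended along the end
    tangents to the mask boundary. Raises :class:`DegenerateShapeError`
    for non-rod shapes (e.g. a circle, whose skeleton has no two-endpoint
    path).
    """
    skel = skeletonize(mask.mask)
    if skel.sum() < 3:
        raise DegenerateShapeError("skeleton too small for a medial line")
    skel = _prune_skeleton(skel)
    path = _order_path(skel)
    path = _extend_to_boundary(path, mask.mask)
    length = _polyline_length(path) * mask.pixel_size
    return path, length


def marker_profile(marker: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Sample an intensity channel at each (sub-pixel) medial-line point."""
    r = np.clip(np.round(path[:, 0]).astype(int), 0, marker.shape[0] - 1)
    c = np.clip(np.round(path[:, 1]).astype(int), 0, marker.shape[1] - 1)
    return np.asarray(marker, dtype=float)[r, c]


def count_nuclei_medial(profile: np.ndarray, spacing_um: float,
                        k_mad: float = 3.0, min_separation_um: float = 1.5,
                        prominence_frac: float = 0.3,
                        smooth_px: int = 5):
    """Count nuclei from the marker intensity profile along the medial line.

    Peaks are local maxima above ``median + k_mad * MAD`` separated by at
    least ``min_separation_um``; because a nucleus spans many profile
    samples, peaks must additionally rise by ``prominence_frac`` of the
    profile dynamic range so that noise on a nuclear plateau is not counted
    twice.  Returns ``(n_nuclei, peak_positions_um, peak_values, ambiguous)``
    with at most the two highest peaks reported; ``ambiguous`` flags >2
    qualifying peaks (such records are excluded downstream).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 5:
        raise ValidationError("profile must have at least 5 samples")
    if smooth_px > 1:
        kernel = np.ones(smooth_px) / smooth_px
        smoothed = np.convolve(profile, kernel, mode="same")
    else:
        smoothed = profile
    med = np.median(smoothed)
    mad = np.median(np.abs(smoothed - med)) * 1.4826
    height = med + k_mad * max(mad, 1e-12)
    dyn = smoothed.max() - med
    distance = max(1, int(round(min_separation_um / spacing_um)))
    peaks, props = find_peaks(smoothed, height=height, distance=distance,
                              prominence=prominence_frac * max(dyn, 1e-12))
    ambiguous = peaks.size > 2
    if peaks.size > 2:
        top = np.argsort(props["peak_heights"])[::-1][:2]
        peaks = np.sort(peaks[top])
    values = profile[peaks]
    positions = peaks * spacing_um
    return int(peaks.size), positions, values, ambiguous


# ---------------------------------------------------------------------------
# Intensity statistics


def top_percent_mean(pixels: np.ndarray, p: float = 15.0) -> float:
    """Mean of the brightest ``p`` percent of pixel values.

    Uses the ceil(p/100 * N) largest values; with ``p`` matched to the
    projected nuclear area fraction this proxies nuclear concentration from
    a single channel.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size == 0:
        raise ValidationError("empty pixel set")
    if not 0 < p <= 100:
        raise ValidationError("p must lie in (0, 100]")
    k = math.ceil(p / 100.0 * pixels.size)
    return float(np.partition(pixels, pixels.size - k)[pixels.size - k:].mean())


def nuclear_mean(protein: np.ndarray, nuclear_mask: NuclearMask,
                 cell_mask: CellMask) -> list[float]:
    """Mean protein intensity per nuclear component, ordered along the cell
    axis (left tip to right tip). Empty list when there are no components."""
    if nuclear_mask.component_count == 0:
        return []
    protein = np.asarray(protein, dtype=float)
    labels = nuclear_mask.labels
    flat = labels.ravel()
    n_lab = int(labels.max())
    counts = np.bincount(flat, minlength=n_lab + 1)[1:]
    sums = np.bincount(flat, weights=protein.ravel(), minlength=n_lab + 1)[1:]
    cols = np.broadcast_to(np.arange(labels.shape[1]), labels.shape).ravel()
    col_sums = np.bincount(flat, weights=cols, minlength=n_lab + 1)[1:]
    valid = counts > 0
    means = sums[valid] / counts[valid]
    axis_pos = col_sums[valid] / counts[valid]
    return [float(m) for m in means[np.argsort(axis_pos)]]


# ---------------------------------------------------------------------------
# Shape / focus features (instrument-feature emulations)

# Frozen calibration constant mapping the synthetic edge-sharpness statistic
# onto the focus-score scale on which the in-focus gate is 65-78 (set so a
# noise-free default-geometry tile scores ~=70).
GRADIENT_RMS_SCALE = 70.0 / 15.45


def _chords(mask: np.ndarray) -> np.ndarray:
    counts = mask.sum(axis=0)
    return counts[counts > 0]


def gradient_rms(bf: np.ndarray, mask: np.ndarray) -> float:
    """RMS bright-field gradient magnitude in a band around the cell
    boundary, scaled to the instrument's focus-score units."""
    from .segmentation import disk

    band = ndimage.binary_dilation(mask, structure=disk(2)) ^ ndimage.binary_erosion(
        mask, structure=disk(2))
    gy, gx = np.gradient(np.asarray(bf, dtype=float))
    g2 = gx ** 2 + gy ** 2
    return float(np.sqrt(g2[band].mean()) * GRADIENT_RMS_SCALE)


def shape_features(mask: CellMask, bf: np.ndarray | None = None,
                   central_frac: float = 0.6) -> dict[str, float]:
    """Width, thickness and focus features of a (near-axis-aligned) rod mask.

    width = median transverse chord; thickness_max = largest chord;
    thickness_min = smallest chord over the central ``central_frac`` of the
    axis (the raw minimum is a single pixel at the cap tips). These emulate
    the instrument's shape features on the synthetic geometry.
    """
    chords = _chords(mask.mask)
    n = chords.size
    lo = int(n * (1 - central_frac) / 2)
    hi = max(lo + 1, n - lo)
    central = chords[lo:hi]
    px = mask.pixel_size
    feats = {
        "width_um": float(np.median(chords) * px),
        "thickness_max_um": float(chords.max() * px),
        "thickness_min_um": float(central.min() * px),
    }
    if bf is not None:
        feats["gradient_rms"] = gradient_rms(bf, mask.mask)
    return feats


def mask_length_um(mask: CellMask) -> float:
    """Cell length as the extent of the mask along its principal axis."""
    rr, cc = np.nonzero(mask.mask)
    pts = np.stack([rr, cc]).astype(float)
    pts -= pts.mean(axis=1, keepdims=True)
    cov = pts @ pts.T / pts.shape[1]
    w, v = np.linalg.eigh(cov)
    proj = v[:, -1] @ pts
    return float((proj.max() - proj.min() + 1.0) * mask.pixel_size)


# ---------------------------------------------------------------------------
# Tile measurement


def measure_tile(tile: ImageTile, spec: CellSpec | None = None,
                 top_p: float = 15.0, erosion_radius: int = 3,
                 split: bool = True, cell_id: int = 0) -> list[dict]:
    """Measure one tile into one or two record dicts (two if a septated
    cell was split; each half is then an individual mononucleate)."""
    cm = segment_cell(tile.bf, tile.pixel_size)
    grms = gradient_rms(tile.bf, cm.mask)  # per-object focus score, inherited by halves
    parent_length = mask_length_um(cm)
    children = split_septated(cm, tile.bf) if split else [cm]
    was_split = len(children) == 2

    records = []
    for child in children:
        try:
            inner = erode_mask(child, erosion_radius)
        except SegmentationError:
            continue
        pix = tile.protein[inner.mask]
        nm = segment_nuclei(tile.marker, child)
        nmeans = nuclear_mean(tile.protein, nm, child)
        feats = shape_features(child)
        rec = {
            "cell_id": cell_id,
            "parent_id": cell_id,
            "length_um": parent_length if child is cm else mask_length_um(child),
            "area_px": inner.area_px,
            "total_intensity": float(pix.sum()),
            "mean_intensity": float(pix.mean()),
            "max_pixel": float(pix.max()),
            "top_p_mean": top_percent_mean(pix, top_p),
            "n_nuclei": nm.component_count,
            "nuclear_mean_1": nmeans[0] if len(nmeans) >= 1 else np.nan,
            "nuclear_mean_2": nmeans[1] if len(nmeans) >= 2 else np.nan,
            "septated": was_split,
            "from_split": was_split,
            "parent_length_um": parent_length,
            "gradient_rms": grms,
            "background_corrected": False,
        }
        rec.update({k: feats[k] for k in
                    ("width_um", "thickness_max_um", "thickness_min_um")})
        if spec is not None:
            rec.update({
                "stage": spec.stage.value,
                "cycle_position": spec.cycle_position,
                "true_wholecell_conc": spec.true_wholecell_conc,
                "true_nuclear_conc": spec.true_nuclear_conc,
                "true_length_um": spec.length,
            })
        records.append(rec)
    return records


def measure_population(specs: Sequence[CellSpec], params: PopulationParams,
                       noise: NoiseParams | None = None, top_p: float = 15.0,
                       erosion_radius: int = 3, split: bool = True,
                       keep_truth: bool = True) -> pd.DataFrame:
    """Render, degrade and measure a population of cells into a record table.

    One row per measured cell (septated cells contribute two rows). Ground
    truth columns (stage, true concentrations) are carried alongside the
    measurements when ``keep_truth``; they exist only for synthetic data.
    """
    rows: list[dict] = []
    for i, (spec, tile) in enumerate(simulate_tiles(specs, params, noise)):
        try:
            recs = measure_tile(tile, spec if keep_truth else None, top_p=top_p,
                                erosion_radius=erosion_radius, split=split,
                                cell_id=i)
        except (SegmentationError, DegenerateShapeError):
            continue
        rows.extend(recs)
    if not rows:
        raise SegmentationError("no cell could be measured")
    df = pd.DataFrame(rows)
    cols = [c for c in RECORD_COLUMNS + TRUTH_COLUMNS if c in df.columns]
    return df[cols]


# ---------------------------------------------------------------------------
# Background correction

BACKGROUND_FEATURES = ("total_intensity", "mean_intensity", "max_pixel")
# Features corrected with the per-pixel (mean) background model: uniform
# autofluorescence shifts every pixel equally, hence also these statistics.
MEAN_LIKE_FEATURES = ("top_p_mean", "nuclear_mean_1", "nuclear_mean_2")


def fit_background(control: pd.DataFrame,
                   features: Sequence[str] = BACKGROUND_FEATURES,
                   bin_width: float = 0.33,
                   min_count: int = 50) -> dict[str, BackgroundModel]:
    """Fit a linear-in-length background per feature from an untagged
    control: bin control records by length, then ordinary least squares of
    bin mean against bin centre."""
    from .profiles import bin_by_length  # local import; profiles also uses us

    models = {}
    for feat in features:
        prof = bin_by_length(control, value_col=feat, bin_width=bin_width,
                             min_count=min_count)
        if np.unique(prof.bin_centers).size < 2:
            raise FitError("need at least 2 distinct length bins to fit background")
        slope, intercept = np.polyfit(prof.bin_centers, prof.bin_means, 1)
        models[feat] = BackgroundModel(slope=float(slope),
                                       intercept=float(intercept), feature=feat)
    return models


def subtract_background(records: pd.DataFrame,
                        models: Mapping[str, BackgroundModel],
                        floor: bool = True) -> pd.DataFrame:
    """Subtract each feature's predicted background at the record's length.

    Negative corrected values are floored at zero and flagged in
    ``bg_floored`` (pass ``floor=False`` to keep signed residuals, e.g.
    when validating a correction against an untagged control). Correcting
    twice is an error.
    """
    if "background_corrected" in records and records["background_corrected"].any():
        raise ValidationError("records are already background-corrected")
    out = records.copy()
    floored = np.zeros(len(out), dtype=bool)
    mean_model = models.get("mean_intensity")
    for feat, model in models.items():
        if feat not in out.columns:
            continue
        corrected = out[feat] - model.predict(out["length_um"])
        floored |= (corrected < 0).to_numpy()
        out[feat] = corrected.clip(lower=0.0) if floor else corrected
    if mean_model is not None:
        for feat in MEAN_LIKE_FEATURES:
            if feat in out.columns:
                corrected = out[feat] - mean_model.predict(out["length_um"])
                out[feat] = corrected.clip(lower=0.0) if floor else corrected
    out["background_corrected"] = True
    out["bg_floored"] = floored
    return out


# ---------------------------------------------------------------------------
# Gating


GATE_FEATURES = {
    "R1": ("width_um", "width_range"),
    "R2": ("thickness_max_um", "thickness_max_range"),
    "R3": ("thickness_min_um", "thickness_min_range"),
    "R4": ("gradient_rms", "gradient_rms_range"),
}


def apply_gates(records: pd.DataFrame, gates: GateSet,
                intensity_col: str = "mean_intensity"):
    """Apply the sequential gates R1-R5 to a record table.

    R1-R4 are closed-interval filters on shape and focus features; R5
    removes per-strain intensity extremes outside the configured quantile
    pair, computed among records that survive R1-R4.  Returns
    ``(passed, counts)``: a boolean Series and the (monotone non-increasing)
    count of records surviving each gate in sequence.
    """
    for gate, (col, _) in GATE_FEATURES.items():
        if col not in records.columns:
            raise ValidationError(f"missing feature column {col!r} for gate {gate}")
    passed = pd.Series(True, index=records.index)
    counts = {"input": int(len(records))}
    for gate, (col, rng_name) in GATE_FEATURES.items():
        lo, hi = getattr(gates, rng_name)
        passed &= records[col].between(lo, hi)
        counts[gate] = int(passed.sum())
    qlo, qhi = gates.intensity_extreme_policy
    if passed.any() and (qlo > 0 or qhi < 1):
        vals = records.loc[passed, intensity_col]
        lo_v, hi_v = vals.quantile(qlo), vals.quantile(qhi)
        passed &= records[intensity_col].between(lo_v, hi_v)
    counts["R5"] = int(passed.sum())
    return passed, counts
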
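"""Synthetic populations and image tiles of rod-shaped, fission-yeast-like cells.

The generator produces two linked artefacts:

* ground-truth populations (lists of :class:`CellSpec`) drawn from the
  stationary age structure of an exponentially growing culture, with cell
  length tied to cell-cycle position by tip growth, and
* per-cell two-channel image tiles (:class:`ImageTile`) rendered from each
  spec -- a protein channel, a nuclear-marker channel and a bright-field
  proxy -- with an optional noise model (length-dependent autofluorescence,
  Poisson shot noise, additive Gaussian read noise).

Concentration ground truth comes from :class:`StrainProfileModel`, which
encodes the canonical cell-cycle expression patterns seen for CDK
regulators: constant, linear accumulator (mitotic-cyclin-like), mid-cycle
oscillator (activating-phosphatase-like), G1/S pulse (replication-licensing
-like), and constant whole-cell level with a rising nuclear ramp (CDK-like).

Every routine is deterministic for a fixed seed; all lengths are in
micrometres and intensities in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError

__all__ = [
    "Stage",
    "ProfileKind",
    "PopulationParams",
    "StrainProfileModel",
    "NoiseParams",
    "CellSpec",
    "ImageTile",
    "preset",
    "PRESET_NAMES",
    "concentration_at",
    "length_at",
    "length_cdf",
    "stage_at",
    "cell_area_um2",
    "sample_population",
    "render_tile",
    "apply_noise",
    "simulate_tiles",
]

# Bright-field proxy levels (arbitrary camera units).  Background is bright,
# the cell interior dark, and the division septum a dimmer-than-background
# transverse band that stays inside the Otsu foreground but is detectable as
# a local maximum along the cell axis.
BF_BACKGROUND = 100.0
BF_CELL_DEPTH = 60.0  # interior level = BF_BACKGROUND - BF_CELL_DEPTH
BF_SEPTUM_LIFT = 20.0
BF_EDGE_SIGMA_PX = 1.0  # fixed optical softening of the bright-field edge
MARKER_AMPLITUDE = 120.0  # nuclear-marker signal inside nuclei
TILE_MARGIN_PX = 6


class Stage(str, Enum):
    """Cell-cycle stage of a rod cell, assigned from cycle position."""

    G2_MONO = "G2_MONO"
    MITOTIC_MONO = "MITOTIC_MONO"
    BINUCLEATE = "BINUCLEATE"
    SEPTATED = "SEPTATED"


class ProfileKind(str, Enum):
    CONSTANT = "CONSTANT"
    LINEAR_ACCUMULATOR = "LINEAR_ACCUMULATOR"
    OSCILLATOR = "OSCILLATOR"
    G1S_PULSE = "G1S_PULSE"
    NUCLEAR_RAMP = "NUCLEAR_RAMP"


@dataclass(frozen=True)
class PopulationParams:
    """Geometry and staging of the simulated steady-state population.

    Lengths in micrometres. Defaults follow the classic wild-type anchors:
    cells are born at ~7 um, enter mitosis above ~12 um and divide at ~14 um
    (twice the birth length), with a projected nuclear area of ~15% of the
    cell area.  The stage windows (``mitosis_start`` etc.) are fractions of
    the cycle; the binucleate window implied by the defaults puts ~5% of an
    asynchronous population in the binucleate, pre-septation state
    (``binucleate_fraction_target`` records that target; it is descriptive,
    not enforced).
    """

    birth_length: float = 7.0
    division_length: float = 14.0
    mitotic_entry_length: float = 12.0
    cell_width: float = 4.0
    septum_width: float = 0.3
    nuclear_area_fraction: float = 0.15
    binucleate_fraction_target: float = 0.05
    pixel_size: float = 0.1
    mitosis_start: float = 0.75
    binucleate_start: float = 0.85
    septation_start: float = 0.92

    def __post_init__(self) -> None:
        if not (0 < self.birth_length < self.mitotic_entry_length < self.division_length):
            raise ValidationError(
                "require 0 < birth_length < mitotic_entry_length < division_length, "
                f"got {self.birth_length}, {self.mitotic_entry_length}, {self.division_length}"
            )
        if not 0 < self.nuclear_area_fraction < 1:
            raise ValidationError("nuclear_area_fraction must lie in (0, 1)")
        if abs(self.division_length / (2.0 * self.birth_length) - 1.0) > 0.05:
            raise ValidationError(
                "division_length must be 2 x birth_length within 5% "
                "(fission-yeast cells halve at septation)"
            )
        if not (0 < self.mitosis_start < self.binucleate_start < self.septation_start < 1):
            raise ValidationError("stage breakpoints must be ordered within (0, 1)")
        if self.cell_width <= 0 or self.pixel_size <= 0 or self.septum_width <= 0:
            raise ValidationError("cell_width, septum_width and pixel_size must be positive")


@dataclass(frozen=True)
class StrainProfileModel:
    """Ground-truth concentration profile of one tagged strain.

    ``wholecell_fold`` is the peak/minimum ratio of whole-cell concentration
    across the cycle.  ``nuclear_enrichment`` maps cycle position in [0, 1]
    to the nuclear:whole-cell concentration ratio (a scalar is treated as a
    constant function).  ``division_reset`` decays the whole-cell
    concentration back to baseline across the binucleate window (mitotic
    proteolysis), keeping concentration continuous across division for
    accumulator-type profiles.
    """

    kind: ProfileKind
    baseline_conc: float = 100.0
    wholecell_fold: float = 1.0
    trough_position: float = 1.0 / 3.0
    nuclear_enrichment: float | Callable[[float], float] = 1.0
    division_reset: bool = False
    g1s_decay_end: float = 0.5
    expression_cv: float = 0.15
    name: str = ""

    def __post_init__(self) -> None:
        if self.wholecell_fold < 1.0:
            raise ValidationError("wholecell_fold must be >= 1")
        if self.kind in (ProfileKind.CONSTANT, ProfileKind.NUCLEAR_RAMP) and self.wholecell_fold != 1.0:
            raise ValidationError(f"{self.kind.value} requires wholecell_fold == 1")
        if not 0 < self.trough_position < 1:
            raise ValidationError("trough_position must lie in (0, 1)")
        if self.baseline_conc < 0:
            raise ValidationError("baseline_conc must be >= 0")
        if self.expression_cv < 0:
            raise ValidationError("expression_cv must be >= 0")

    def enrichment_at(self, p):
        """Nuclear:whole-cell ratio at cycle position ``p`` (scalar or array)."""
        if callable(self.nuclear_enrichment):
            fn = np.vectorize(self.nuclear_enrichment, otypes=[float])
            e = fn(np.asarray(p, dtype=float))
        else:
            e = np.full_like(np.asarray(p, dtype=float), float(self.nuclear_enrichment))
        if np.any(e < 0):
            raise ValidationError("nuclear enrichment must be >= 0 everywhere")
        return e if np.ndim(p) else float(e)


@dataclass(frozen=True)
class NoiseParams:
    """Camera/optics noise model.

    Autofluorescence is added uniformly inside the cell at
    ``autofluor_intercept + autofluor_slope * length`` intensity units per
    pixel, matching the linear-in-length mean background that untagged
    control strains exhibit; ``autofluor_cv`` scatters that level from
    cell to cell (unit-mean lognormal), as real control distributions do.
    Shot noise resamples each fluorescence pixel from a Poisson law; read
    noise is additive Gaussian, clipped at zero.
    ``psf_sigma`` (um) optionally blurs the fluorescence channels at render
    time.
    """

    autofluor_intercept: float = 2.0
    autofluor_slope: float = 0.5
    autofluor_cv: float = 0.1
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    psf_sigma: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be >= 0")
        if self.psf_sigma < 0:
            raise ValidationError("psf_sigma must be >= 0")
        if self.autofluor_cv < 0:
            raise ValidationError("autofluor_cv must be >= 0")


@dataclass(frozen=True)
class CellSpec:
    """Ground truth for one synthetic cell."""

    length: float
    stage: Stage
    cycle_position: float
    nucleus_centers: tuple[float, ...]  # positions along the long axis, um from the left tip
    nucleus_radius: float
    true_wholecell_conc: float
    true_nuclear_conc: float
    septum_position: float | None = None

    def __post_init__(self) -> None:
        n_expected = 2 if self.stage in (Stage.BINUCLEATE, Stage.SEPTATED) else 1
        if len(self.nucleus_centers) != n_expected:
            raise ValidationError(
                f"{self.stage.value} cells must have {n_expected} nucleus centers"
            )
        if self.stage is Stage.SEPTATED:
            if self.septum_position is None:
                raise ValidationError("SEPTATED cells require a septum_position")
            lo, hi = sorted(self.nucleus_centers)
            if not lo < self.septum_position < hi:
                raise ValidationError("septum must lie between the two nuclei")


@dataclass
class ImageTile:
    """One rendered cell: protein, nuclear-marker and bright-field channels.

    ``cell_mask``/``nuclear_mask`` carry the rasterised ground truth used by
    the renderer; they are annotations for validation, not measurements.
    """

    protein: np.ndarray
    marker: np.ndarray
    bf: np.ndarray
    pixel_size: float
    cell_mask: np.ndarray | None = None
    nuclear_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.protein.shape == self.marker.shape == self.bf.shape):
            raise ValidationError("all channels must share dimensions")


# ---------------------------------------------------------------------------
# Concentration profiles


def wholecell_concentration(model: StrainProfileModel, p):
    """Whole-cell concentration at cycle position ``p`` (scalar or array)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValidationError("cycle_position must lie in [0, 1]")
    b, f = model.baseline_conc, model.wholecell_fold
    k = model.kind
    if k in (ProfileKind.CONSTANT, ProfileKind.NUCLEAR_RAMP):
        c = np.full_like(p_arr, b)
    elif k is ProfileKind.LINEAR_ACCUMULATOR:
        c = b * (1.0 + (f - 1.0) * p_arr)
    elif k is ProfileKind.OSCILLATOR:
        # Continuous across division: newborns inherit the mitotic peak,
        # fall to the trough, then re-accumulate to the peak at mitosis.
        c = np.interp(p_arr, [0.0, model.trough_position, 1.0], [b * f, b, b * f])
    elif k is ProfileKind.G1S_PULSE:
        # Peak in the shortest (just-divided) cells, decaying to baseline by
        # g1s_decay_end; re-induced during the septated window so that
        # concentration is continuous across division.
        decay = np.clip(1.0 - p_arr / model.g1s_decay_end, 0.0, None)
        c = b * (1.0 + (f - 1.0) * decay)
        rise_start = 0.92
        rise = np.clip((p_arr - rise_start) / (1.0 - rise_start), 0.0, 1.0)
        c = np.maximum(c, b * (1.0 + (f - 1.0) * rise))
    else:  # pragma: no cover
        raise ValidationError(f"unknown profile kind {k}")
    return c if np.ndim(p) else float(c)


def concentration_at(model: StrainProfileModel, cycle_position):
    """Return ``(wholecell_conc, nuclear_conc)`` at a cycle position.

    Nuclear concentration is the whole-cell value times the model's nuclear
    enrichment at that position.
    """
    c = wholecell_concentration(model, cycle_position)
    e = model.enrichment_at(cycle_position)
    return c, c * e


# ---------------------------------------------------------------------------
# Steady-state population sampling


def length_at(p, params: PopulationParams):
    """Map cycle position to cell length by piecewise-linear tip growth."""
    p_arr = np.asarray(p, dtype=float)
    ms = params.mitosis_start
    lb, lm, ld = params.birth_length, params.mitotic_entry_length, params.division_length
    first = lb + (lm - lb) * (p_arr / ms)
    second = lm + (ld - lm) * ((p_arr - ms) / (1.0 - ms))
    out = np.where(p_arr <= ms, first, second)
    return out if np.ndim(p) else float(out)


def _position_at_length(length, params: PopulationParams):
    """Inverse of :func:`length_at` (lengths within [birth, division])."""
    l_arr = np.asarray(length, dtype=float)
    ms = params.mitosis_start
    lb, lm, ld = params.birth_length, params.mitotic_entry_length, params.division_length
    first = ms * (l_arr - lb) / (lm - lb)
    second = ms + (1.0 - ms) * (l_arr - lm) / (ld - lm)
    out = np.where(l_arr <= lm, first, second)
    return np.clip(out, 0.0, 1.0)


def age_cdf(a):
    """CDF of extant-cell age in a steady exponential culture.

    The age density is phi(a) = 2 ln2 * 2^(-a) on [0, 1] doubling times:
    twice as many newborn as about-to-divide cells.
    """
    a_arr = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    out = 2.0 * (1.0 - np.power(2.0, -a_arr))
    return out if np.ndim(a) else float(out)


def length_cdf(length, params: PopulationParams):
    """Closed-form CDF of extant-cell length, pushing the age density
    through the growth map."""
    return age_cdf(_position_at_length(length, params))


def stage_at(p, params: PopulationParams) -> Stage:
    if p < params.mitosis_start:
        return Stage.G2_MONO
    if p < params.binucleate_start:
        return Stage.MITOTIC_MONO
    if p < params.septation_start:
        return Stage.BINUCLEATE
    return Stage.SEPTATED


def cell_area_um2(length: float, width: float) -> float:
    """Projected area of a rod (rectangle body + semicircular caps)."""
    return (length - width) * width + math.pi * (width / 2.0) ** 2


def _nucleus_layout(length: float, stage: Stage, params: PopulationParams):
    area = cell_area_um2(length, params.cell_width)
    frac = params.nuclear_area_fraction
    if stage in (Stage.G2_MONO, Stage.MITOTIC_MONO):
        centers = (length / 2.0,)
        radius = math.sqrt(frac * area / math.pi)
    else:
        centers = (length / 4.0, 3.0 * length / 4.0)
        radius = math.sqrt(frac * area / (2.0 * math.pi))
    return centers, radius


def _effective_concs(model: StrainProfileModel, p: float, stage: Stage,
                     params: PopulationParams) -> tuple[float, float]:
    c = wholecell_concentration(model, p)
    e = model.enrichment_at(p)
    if model.division_reset and stage in (Stage.BINUCLEATE, Stage.SEPTATED):
        # Mitotic proteolysis: rapid relative to the binucleate window --
        # the peak level holds through its first half, then decays to
        # baseline by septation; degraded protein is no longer
        # nuclear-enriched.
        mid = 0.5 * (params.binucleate_start + params.septation_start)
        span = params.septation_start - mid
        w = min(1.0, max(0.0, (p - mid) / span))
        c = c * (1.0 - w) + model.baseline_conc * w
        e = 1.0
    if stage is Stage.MITOTIC_MONO:
        # Nuclear-envelope remodelling at mitosis: enrichment collapses to 1.
        e = 1.0
    return float(c), float(c * e)


def sample_population(params: PopulationParams, model: StrainProfileModel,
                      n: int, seed: int) -> list[CellSpec]:
    """Draw ``n`` cells from the asynchronous steady-state population.

    Ages follow the extant-cell density of an exponential culture; cycle
    position equals age in doubling times; length follows the tip-growth
    map; stages follow the configured cycle windows. Reproducible for a
    fixed seed.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    positions = -np.log2(1.0 - u / 2.0)  # inverse CDF of phi(a)
    lengths = length_at(positions, params)
    # cell-to-cell expression variability: lognormal factor with unit mean
    if model.expression_cv > 0:
        s_ln = math.sqrt(math.log(1.0 + model.expression_cv ** 2))
        scatter = rng.lognormal(-0.5 * s_ln ** 2, s_ln, size=int(n))
    else:
        scatter = np.ones(int(n))
    specs: list[CellSpec] = []
    for p, length, sc in zip(positions.tolist(), lengths.tolist(),
                             scatter.tolist()):
        stage = stage_at(p, params)
        centers, radius = _nucleus_layout(length, stage, params)
        c, nconc = _effective_concs(model, p, stage, params)
        c, nconc = c * sc, nconc * sc
        septum = length / 2.0 if stage is Stage.SEPTATED else None
        specs.append(CellSpec(
            length=length, stage=stage, cycle_position=p,
            nucleus_centers=centers, nucleus_radius=radius,
            true_wholecell_conc=c, true_nuclear_conc=nconc,
            septum_position=septum,
        ))
    return specs


# ---------------------------------------------------------------------------
# Rendering


def _tile_grids(spec: CellSpec, params: PopulationParams, margin_px: int):
    px = params.pixel_size
    w_px = int(round(spec.length / px)) + 2 * margin_px
    h_px = int(round(params.cell_width / px)) + 2 * margin_px
    x = (np.arange(w_px) + 0.5) * px  # um, along the long axis
    y = (np.arange(h_px) + 0.5) * px - h_px * px / 2.0  # um, centred
    return x, y


def render_tile(spec: CellSpec, params: PopulationParams,
                psf_sigma: float = 0.0, margin_px: int = TILE_MARGIN_PX) -> ImageTile:
    """Render a noise-free tile: rod-shaped cell with nuclear disk(s).

    The protein channel is ``true_wholecell_conc`` inside the rod with the
    nuclear disk(s) overwritten at ``true_nuclear_conc``; the marker channel
    is nonzero only inside nuclei; the bright-field proxy encodes the cell
    boundary (dark interior on a bright background) and, for septated cells,
    a transverse septum band.  ``psf_sigma`` > 0 applies a Gaussian blur (um)
    to the fluorescence channels.
    """
    if spec.length < 0.9 * params.birth_length:
        raise ValidationError("spec length inconsistent with population params")
    px = params.pixel_size
    r = params.cell_width / 2.0
    x, y = _tile_grids(spec, params, margin_px)
    x0 = margin_px * px  # left tip of the cell

    ax_lo, ax_hi = x0 + r, x0 + spec.length - r
    dx = x - np.clip(x, ax_lo, ax_hi)
    rod = (dx ** 2)[None, :] + (y ** 2)[:, None] <= r ** 2

    if spec.nucleus_radius > r - px:
        raise ValidationError("nucleus would extend outside the rod")
    nuclei = np.zeros_like(rod)
    rn2 = spec.nucleus_radius ** 2
    for c in spec.nucleus_centers:
        disk = ((x - (x0 + c)) ** 2)[None, :] + (y ** 2)[:, None] <= rn2
        if np.any(disk & ~rod):
            raise ValidationError("nucleus would extend outside the rod")
        nuclei |= disk

    # Conserve total protein: the whole-cell concentration is the cell
    # average, so nuclear enrichment depletes the cytoplasm accordingly
    # (sum of the noise-free protein channel = conc x cell area exactly).
    cell_px = int(rod.sum())
    nuc_px = int(nuclei.sum())
    if nuc_px and nuc_px < cell_px:
        cyto = (spec.true_wholecell_conc * cell_px
                - spec.true_nuclear_conc * nuc_px) / (cell_px - nuc_px)
        if cyto < 0:
            raise ValidationError(
                "nuclear enrichment x nuclear area fraction exceeds 1: "
                "more protein in the nucleus than the cell contains")
    else:
        cyto = spec.true_wholecell_conc
    protein = np.where(rod, cyto, 0.0)
    protein[nuclei] = spec.true_nuclear_conc
    marker = np.where(nuclei, MARKER_AMPLITUDE, 0.0)

    bf = np.full(rod.shape, BF_BACKGROUND)
    bf[rod] -= BF_CELL_DEPTH
    if spec.septum_position is not None:
        band = rod & (np.abs(x - (x0 + spec.septum_position)) <= params.septum_width / 2.0)[None, :]
        bf[band] += BF_SEPTUM_LIFT
    bf = gaussian_filter(bf, BF_EDGE_SIGMA_PX)

    if psf_sigma > 0:
        sig = psf_sigma / px
        protein = gaussian_filter(protein, sig)
        marker = gaussian_filter(marker, sig)

    return ImageTile(protein=protein, marker=marker, bf=bf, pixel_size=px,
                     cell_mask=rod, nuclear_mask=nuclei)


def apply_noise(tile: ImageTile, spec: CellSpec, noise: NoiseParams,
                rng: np.random.Generator | None = None) -> ImageTile:
    """Add autofluorescence, shot noise and read noise to a tile.

    Autofluorescence (``b0 + b1 * length`` per pixel) is added inside the
    cell to the protein channel; shot noise resamples the fluorescence
    channels pixel-wise from a Poisson law; Gaussian read noise is added to
    every channel and the result clipped at zero.  Deterministic for a fixed
    ``noise.seed`` (or an explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if tile.cell_mask is not None:
        inside = tile.cell_mask
    else:
        inside = tile.bf < BF_BACKGROUND - BF_CELL_DEPTH / 2.0

    level = noise.autofluor_intercept + noise.autofluor_slope * spec.length
    if noise.autofluor_cv > 0:
        # cell-to-cell autofluorescence variability (unit-mean lognormal)
        s_ln = math.sqrt(math.log(1.0 + noise.autofluor_cv ** 2))
        level *= rng.lognormal(-0.5 * s_ln ** 2, s_ln)
    protein = tile.protein + level * inside
    marker = tile.marker.copy()
    if noise.shot_noise:
        # Poisson resampling only where the rate is positive (elsewhere the
        # draw is identically zero).
        pos = protein > 0
        protein[pos] = rng.poisson(protein[pos])
        pos = marker > 0
        marker[pos] = rng.poisson(marker[pos])
    bf = tile.bf.copy()
    if noise.read_noise_sd > 0:
        read = rng.normal(0.0, noise.read_noise_sd, (3,) + protein.shape)
        protein = protein + read[0]
        marker = marker + read[1]
        bf = bf + read[2]
    return ImageTile(protein=np.clip(protein, 0.0, None),
                     marker=np.clip(marker, 0.0, None),
                     bf=np.clip(bf, 0.0, None),
                     pixel_size=tile.pixel_size,
                     cell_mask=tile.cell_mask, nuclear_mask=tile.nuclear_mask)


def simulate_tiles(specs: Sequence[CellSpec], params: PopulationParams,
                   noise: NoiseParams | None = None):
    """Yield ``(spec, tile)`` pairs, rendering and (optionally) degrading
    each cell with a single generator seeded from ``noise.seed``."""
    rng = np.random.default_rng(noise.seed) if noise is not None else None
    for spec in specs:
        tile = render_tile(spec, params,
                           psf_sigma=noise.psf_sigma if noise is not None else 0.0)
        if noise is not None:
            tile = apply_noise(tile, spec, noise, rng=rng)
        yield spec, tile


# ---------------------------------------------------------------------------
# Presets

def _cdc2_enrichment(p: float) -> float:
    return 1.3 + 0.9 * p


def _cdc13_enrichment(p: float) -> float:
    return 1.0 + 1.0 * p


def _make_presets() -> dict[str, StrainProfileModel]:
    return {
        # Constant whole-cell concentration, no nuclear enrichment: the
        # null strain used for measurement-artifact bounds.
        "constant": StrainProfileModel(ProfileKind.CONSTANT, name="constant"),
        # Untagged autofluorescence control.
        "untagged": StrainProfileModel(ProfileKind.CONSTANT, baseline_conc=0.0,
                                       name="untagged"),
        # CDK-like: constant whole-cell, nuclear enrichment ramping ~1.3->2.2.
        "cdc2": StrainProfileModel(ProfileKind.NUCLEAR_RAMP,
                                   nuclear_enrichment=_cdc2_enrichment,
                                   name="cdc2"),
        # Mitotic-cyclin-like: whole-cell 4.5x linear accumulation, nuclear
        # amplification to ~9x, degraded at division.
        "cdc13": StrainProfileModel(ProfileKind.LINEAR_ACCUMULATOR,
                                    wholecell_fold=4.5,
                                    nuclear_enrichment=_cdc13_enrichment,
                                    division_reset=True, name="cdc13"),
        # Activating-phosphatase-like: dips to a trough a third of the way
        # through the cycle, peaks at mitosis, nuclear-enriched throughout.
        "cdc25": StrainProfileModel(ProfileKind.OSCILLATOR, wholecell_fold=2.0,
                                    trough_position=1.0 / 3.0,
                                    nuclear_enrichment=1.5, name="cdc25"),
        # Licensing-factor-like G1/S pulse, up to sixfold.
        "cdc18": StrainProfileModel(ProfileKind.G1S_PULSE, wholecell_fold=6.0,
                                    nuclear_enrichment=2.0, name="cdc18"),
    }


_PRESETS = _make_presets()
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> StrainProfileModel:
    """Return a named strain profile preset, optionally overriding fields."""
    try:
        model = _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; known: {PRESET_NAMES}") from None
    return replace(model, **overrides) if overrides else model
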
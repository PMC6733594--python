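"""PHRESH quantification: normalisation, profiles, classification, maps.

The measurement chain mirrors the manual Fiji workflow used on real
photoconverted Kaede embryos:

1. a per-stack reference intensity — the maximum (or a robust percentile) of
   the green channel in the *unconverted* AP region, background-subtracted —
   controls for transgene expression variability between embryos;
2. DV profiles: three vertical lines through / flanking the spinal canal,
   averaged, normalised to the reference and expressed in %;
3. ML profiles: a single horizontal line directly dorsal to the canal;
4. one section per somite over five neighbouring somites, averaged;
5. per-voxel or per-cell response-history classification: green-only = new
   response after t₀, red-only = past response, both = continued, neither =
   none;
6. repeating over a grid of conversion times t₀ assembles the
   spatiotemporal signalling map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, NoReferenceError
from .image_synthesis import ImageStack, reslice_transverse
from .synthetic_embryo import SpinalCordGeometry

__all__ = [
    "IntensityProfile",
    "RESPONSE_CLASSES",
    "SpatiotemporalMap",
    "estimate_background",
    "unconverted_reference",
    "dv_profile",
    "ml_profile",
    "average_over_somites",
    "classify_response",
    "classify_map",
    "class_composition",
    "above_half_max_extent",
    "build_map",
    "profiles_to_frame",
]

#: Common fractional-axis grid so embryos with different pixel sizes average.
PROFILE_GRID = np.linspace(0.0, 1.0, 101)

#: Classification threshold, % of the unconverted-region green reference.
DEFAULT_CLASS_THRESHOLD = 10.0

RESPONSE_CLASSES = ("new", "continued", "past", "none")


@dataclass
class IntensityProfile:
    """Intensity along one anatomical axis, as % of the unconverted-region
    green maximum, on the common 101-point fractional grid."""

    axis: str  # 'DV' or 'ML'
    positions: np.ndarray
    values: np.ndarray
    canal_frac: float
    n_lines_averaged: int = 1
    n_somites_averaged: int = 1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.axis not in ("DV", "ML"):
            raise InvalidParameterError("axis must be 'DV' or 'ML'")
        if self.positions.shape != self.values.shape:
            raise InvalidParameterError("positions/values length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise InvalidParameterError("positions must strictly increase")
        if np.any(self.values < 0):
            raise InvalidParameterError("profile values must be >= 0")


def estimate_background(values: np.ndarray) -> float:
    """Modal intensity of a voxel array, used as the background estimate.

    Computed as the most populated bin of an integer-resolution histogram —
    robust because background voxels dominate any sparse fluorescent scene.
    """
    v = np.asarray(values).ravel()
    lo, hi = np.floor(v.min()), np.ceil(v.max())
    if hi <= lo:
        return float(lo)
    edges = np.arange(lo, hi + 1.0)
    hist, _ = np.histogram(v, bins=edges)
    return float(edges[np.argmax(hist)] + 0.5)


def unconverted_reference(stack: ImageStack,
                          mode: str = "percentile",
                          percentile: float = 99.9,
                          background: float | None = None) -> float:
    """Reference green intensity from the unconverted AP region.

    ``mode='max'`` reproduces the strict protocol (maximum green intensity
    outside the converted window); the default 99.9th-percentile mode is
    robust to isolated hot pixels.  Background (modal intensity unless
    given) is subtracted first.
    """
    if stack.converted_ap_window is None:
        raise NoReferenceError("stack has no converted window annotation")
    if mode not in ("max", "percentile"):
        raise InvalidParameterError(f"unknown reference mode {mode!r}")
    green = stack.channel("green")
    ap = stack.ap_coords()
    lo, hi = stack.converted_ap_window
    outside = (ap < lo) | (ap > hi)
    if not outside.any():
        raise NoReferenceError(
            "converted window covers the full AP extent; no reference region")
    region = green[:, :, outside]
    bg = estimate_background(green) if background is None else background
    vals = np.clip(region - bg, 0.0, None)
    ref = float(vals.max()) if mode == "max" else \
        float(np.percentile(vals, percentile))
    if ref <= 0:
        raise NoReferenceError("unconverted region carries no signal")
    return ref


def _trace_profile(values: np.ndarray, axis_name: str, canal_frac: float,
                   reference: float, background: float,
                   n_lines: int) -> IntensityProfile:
    pct = 100.0 * np.clip(values - background, 0.0, None) / reference
    n = len(pct)
    positions = (np.arange(n) + 0.5) / n
    resampled = np.interp(PROFILE_GRID, positions, pct)
    return IntensityProfile(axis=axis_name, positions=PROFILE_GRID.copy(),
                            values=resampled, canal_frac=canal_frac,
                            n_lines_averaged=n_lines)


def dv_profile(section: np.ndarray,
               canal_px: tuple[int, int],
               reference: float,
               n_lines: int = 3,
               line_spacing: int = 5,
               background: float = 0.0) -> IntensityProfile:
    """Dorsoventral profile: mean of ``n_lines`` vertical traces through and
    flanking the spinal canal, normalised to the reference × 100.

    ``section`` is a 2D transverse view (rows = DV, ventral at row 0;
    columns = ML); ``canal_px`` is the canal (row, col).
    """
    section = np.asarray(section, float)
    if reference <= 0:
        raise InvalidParameterError("reference must be > 0")
    row, col = canal_px
    ny, nx = section.shape
    if not (0 <= row < ny and 0 <= col < nx):
        raise InvalidParameterError("canal position lies outside the section")
    offsets = (np.arange(n_lines) - (n_lines - 1) / 2) * line_spacing
    cols = np.clip(np.round(col + offsets).astype(int), 0, nx - 1)
    trace = section[:, cols].mean(axis=1)
    prof = _trace_profile(trace, "DV", row / ny, reference, background,
                          n_lines)
    return prof


def ml_profile(section: np.ndarray,
               canal_px: tuple[int, int],
               reference: float,
               dorsal_offset: int = 5,
               background: float = 0.0) -> IntensityProfile:
    """Mediolateral profile from one horizontal trace ``dorsal_offset``
    pixels dorsal to the spinal canal."""
    section = np.asarray(section, float)
    if reference <= 0:
        raise InvalidParameterError("reference must be > 0")
    row, col = canal_px
    ny, nx = section.shape
    if not (0 <= row < ny and 0 <= col < nx):
        raise InvalidParameterError("canal position lies outside the section")
    r = row + dorsal_offset
    if not 0 <= r < ny:
        raise InvalidParameterError(
            "dorsal offset places the trace outside the section")
    trace = section[r, :]
    return _trace_profile(trace, "ML", col / nx, reference, background, 1)


def average_over_somites(profiles: list[IntensityProfile],
                         expected_n: int = 5) -> IntensityProfile:
    """Pointwise mean of per-somite profiles sharing one position grid."""
    if not profiles:
        raise InvalidParameterError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.axis != first.axis:
            raise InvalidParameterError("profiles mix DV and ML axes")
        if p.positions.shape != first.positions.shape or \
                not np.allclose(p.positions, first.positions):
            raise InvalidParameterError("profiles use mismatched grids")
    if len(profiles) != expected_n:
        warnings.warn(
            f"averaging {len(profiles)} sections (expected {expected_n})",
            stacklevel=2)
    values = np.mean([p.values for p in profiles], axis=0)
    return IntensityProfile(axis=first.axis, positions=first.positions.copy(),
                            values=values, canal_frac=first.canal_frac,
                            n_lines_averaged=first.n_lines_averaged,
                            n_somites_averaged=len(profiles))


def classify_response(green_norm: float, red_norm: float,
                      threshold: float = DEFAULT_CLASS_THRESHOLD) -> str:
    """Response-history class from normalised green/red intensities (%).

    green only above threshold → 'new' (response begun after t₀);
    red only → 'past' (ended before t₀); both → 'continued'; neither →
    'none'.  The four classes are exhaustive and mutually exclusive.
    """
    if green_norm < 0 or red_norm < 0:
        raise InvalidParameterError("normalised intensities must be >= 0")
    g, r = green_norm > threshold, red_norm > threshold
    if g and r:
        return "continued"
    if g:
        return "new"
    if r:
        return "past"
    return "none"


def classify_map(green_norm: np.ndarray, red_norm: np.ndarray,
                 threshold: float = DEFAULT_CLASS_THRESHOLD) -> np.ndarray:
    """Vectorised :func:`classify_response`; returns an array of class
    labels with the same shape as the inputs."""
    green_norm = np.asarray(green_norm, float)
    red_norm = np.asarray(red_norm, float)
    if np.any(green_norm < 0) or np.any(red_norm < 0):
        raise InvalidParameterError("normalised intensities must be >= 0")
    g, r = green_norm > threshold, red_norm > threshold
    out = np.full(green_norm.shape, "none", dtype=object)
    out[g & ~r] = "new"
    out[~g & r] = "past"
    out[g & r] = "continued"
    return out


def class_composition(labels: np.ndarray) -> dict[str, float]:
    """Fraction of each response class among the given labels."""
    labels = np.asarray(labels).ravel()
    n = len(labels)
    return {c: float(np.mean(labels == c)) if n else 0.0
            for c in RESPONSE_CLASSES}


def above_half_max_extent(profile: IntensityProfile) -> float:
    """Fraction of the axis whose value exceeds half the profile maximum."""
    half = profile.values.max() / 2.0
    return float(np.mean(profile.values > half))


@dataclass
class MapEntry:
    dv: IntensityProfile
    ml: IntensityProfile
    composition: dict[str, float]
    n_stacks: int


@dataclass
class SpatiotemporalMap:
    """Per-t₀ averaged DV/ML profiles and response-class composition."""

    entries: dict[float, MapEntry] = field(default_factory=dict)

    @property
    def t0_grid(self) -> list[float]:
        return sorted(self.entries)

    def __getitem__(self, t0: float) -> MapEntry:
        return self.entries[t0]


def _somite_section_indices(stack: ImageStack,
                            geometry: SpinalCordGeometry,
                            n_somites: int = 5) -> np.ndarray:
    """X indices of one section per somite, centred in the converted window
    (falling back to the full AP extent for unconverted stacks)."""
    ap = stack.ap_coords()
    lo, hi = stack.converted_ap_window or (ap.min(), ap.max())
    s = geometry.somite_length
    first = int(np.ceil(lo / s - 0.5))
    centers = (np.arange(first, first + 64) + 0.5) * s
    centers = centers[(centers >= lo) & (centers <= hi)][:n_somites]
    return np.array([int(np.argmin(np.abs(ap - c))) for c in centers])


def stack_profiles(stack: ImageStack,
                   geometry: SpinalCordGeometry | None = None,
                   reference_mode: str = "percentile",
                   n_lines: int = 3,
                   threshold: float = DEFAULT_CLASS_THRESHOLD,
                   n_somites: int = 5):
    """Full per-stack measurement: averaged DV and ML profiles over one
    section per somite, plus the voxel response-class composition within
    the cord region of the analysed sections."""
    if geometry is None:
        gdict = stack.meta.get("geometry")
        geometry = SpinalCordGeometry(**gdict) if gdict \
            else SpinalCordGeometry()
    bg = estimate_background(stack.channel("green"))
    ref = unconverted_reference(stack, mode=reference_mode, background=bg)
    sections = reslice_transverse(stack)  # (X, C, Y, Z)
    g_idx = stack.channels.index("green")
    canal_row = int(round((geometry.canal_dv_frac * geometry.dv_height
                           - stack.origin[1]) / stack.voxel_size[1]))
    canal_col = int(round((geometry.canal_ml_frac * geometry.ml_width
                           - stack.origin[0]) / stack.voxel_size[0]))
    spacing_px = max(1, int(round(geometry.cell_diameter
                                  / stack.voxel_size[0])))
    idx = _somite_section_indices(stack, geometry, n_somites)
    dv_list, ml_list = [], []
    for i in idx:
        sec = sections[i, g_idx]
        dv_list.append(dv_profile(sec, (canal_row, canal_col), ref,
                                  n_lines=n_lines, line_spacing=spacing_px,
                                  background=bg))
        ml_list.append(ml_profile(sec, (canal_row, canal_col), ref,
                                  dorsal_offset=spacing_px, background=bg))
    dv = average_over_somites(dv_list, expected_n=len(dv_list))
    ml = average_over_somites(ml_list, expected_n=len(ml_list))

    comp = {c: 0.0 for c in RESPONSE_CLASSES}
    if "red" in stack.channels:
        r_idx = stack.channels.index("red")
        bg_r = estimate_background(stack.channel("red"))
        mask = stack.cord_section_mask(geometry)
        labels = []
        for i in idx:
            gn = 100.0 * np.clip(sections[i, g_idx] - bg, 0, None) / ref
            rn = 100.0 * np.clip(sections[i, r_idx] - bg_r, 0, None) / ref
            labels.append(classify_map(gn[mask], rn[mask], threshold))
        comp = class_composition(np.concatenate(labels))
    return dv, ml, comp


def build_map(cohort: dict[float, list[ImageStack]],
              geometry: SpinalCordGeometry | None = None,
              **kwargs) -> SpatiotemporalMap:
    """Assemble a spatiotemporal signalling map from stacks photoconverted
    on a grid of t₀ values (≥ 1 stack per t₀)."""
    if not cohort:
        raise InvalidParameterError("empty cohort")
    out = SpatiotemporalMap()
    for t0, stacks in cohort.items():
        if not stacks:
            raise InvalidParameterError(f"no stacks for t0={t0}")
        dvs, mls, comps = [], [], []
        for st in stacks:
            dv, ml, comp = stack_profiles(st, geometry, **kwargs)
            dvs.append(dv)
            mls.append(ml)
            comps.append(comp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dv = average_over_somites(dvs, expected_n=len(dvs))
            ml = average_over_somites(mls, expected_n=len(mls))
        comp = {c: float(np.mean([x[c] for x in comps]))
                for c in RESPONSE_CLASSES}
        out.entries[float(t0)] = MapEntry(dv=dv, ml=ml, composition=comp,
                                          n_stacks=len(stacks))
    return out


def profiles_to_frame(profiles: dict[str, IntensityProfile],
                      t0_hpf: float | None = None,
                      t_image_hpf: float | None = None):
    """Tidy DataFrame (axis, position_frac, value_pct, n_lines, n_somites,
    t0_hpf, t_image_hpf) for CSV export."""
    import pandas as pd

    rows = []
    for _, p in profiles.items():
        for pos, val in zip(p.positions, p.values):
            rows.append({"axis": p.axis, "position_frac": pos,
                         "value_pct": val, "n_lines": p.n_lines_averaged,
                         "n_somites": p.n_somites_averaged,
                         "t0_hpf": t0_hpf, "t_image_hpf": t_image_hpf})
    return pd.DataFrame(rows)
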
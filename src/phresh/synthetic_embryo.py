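"""Ground-truth synthetic zebrafish embryo.

This module plants the "truth" that the downstream measurement chain is asked
to recover: a spinal-cord coordinate frame, a cell population tiling the cord
and its flanking tissues, per-pathway (Notch, Hedgehog) signalling activity as
a function of position, developmental time and experimental condition, and
the condition-dependent marker-domain trajectories (*ptc2*, *sox2*, *olig2*)
used to paint expression domains onto transverse sections.

The activity model encodes three phases of spinal-cord signalling:

* **activation** (24–42 hpf): Notch response is uniform along the
  dorsoventral (DV) axis of the cord; Hedgehog (Hh) response is graded and
  restricted to the ventral ~75% of the cord.
* **consolidation** (42–66 hpf): both active domains shrink toward a medial
  band 1–2 cell tiers directly dorsal to the spinal canal.
* **termination** (66–78 hpf): both responses relax to a basal level.

Perturbations mirror the classic experiments: the γ-secretase inhibitor
LY-411575 (Notch off), the Smo antagonist cyclopamine (Hh off), heat-shock
driven NICD / rSmoM2 / EGFP-Gli1 transgenes, and the *iguana* (cilia-less)
and *mindbomb* (Notch-dead) genotypes.  The one non-trivial coupling is the
tissue-specific Notch→Hh gate: in the spinal cord Hh response requires Notch
activity, whereas in somites and vasculature it does not.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError

__all__ = [
    "SpinalCordGeometry",
    "PhaseSchedule",
    "PerturbationSpec",
    "Cell",
    "ActivityField",
    "MarkerDomainModel",
    "DRUGS",
    "TRANSGENES",
    "GENOTYPES",
    "MARKERS",
    "build_embryo",
    "notch_activity",
    "hh_activity",
    "marker_domain_truth",
    "population_to_csv",
    "geometry_from_yaml",
]

DRUGS = ("none", "cyclopamine", "LY411575")
TRANSGENES = ("none", "NICD", "rSmoM2", "EGFP_Gli1")
GENOTYPES = ("wildtype", "iguana", "mindbomb")
MARKERS = ("ptc2", "sox2", "olig2")

#: Hh response occupies the ventral 75% of the cord during activation.
VENTRAL_EXTENT = 0.75

#: Hours over which LY-411575 ramps Notch response to zero.
LY_RAMP_HOURS = 4.0

#: Hours over which cyclopamine ramps cord Hh response to its residual floor.
CYC_RAMP_HOURS = 4.0

#: Residual cord Hh level under cyclopamine (Smo-independent Gli1 activity).
CYC_RESIDUAL = 0.1

#: Half-time (h) of cord Hh decay once Notch response is lost.
NOTCH_OFF_HALFTIME = 0.8

#: Uniform Smo-independent cord Hh level in cilia-less iguana mutants.
IGUANA_LEVEL = 0.3

#: Notch-independent cord Hh drive supplied by ectopic EGFP-Gli1.
GLI1_DRIVE = 0.63

_SOMITE_HH = 0.7
_VASC_HH = 0.5
_LATERAL_DROP = 0.3  # cord response is weakest at the lateral (ML) edges
_FINAL_ML_HALFWIDTH = 0.3  # consolidated medial band, fraction of ML width


@dataclass(frozen=True)
class SpinalCordGeometry:
    """Spinal-cord coordinate frame (lengths in µm, landmarks as fractions).

    ``dv_frac`` runs 0 (ventral edge) → 1 (dorsal edge); ``ml_frac`` runs
    0 → 1 across the mediolateral width; ``ap_um`` is absolute position along
    the anterior-posterior axis.
    """

    dv_height: float = 50.0
    ml_width: float = 20.0
    ap_length: float = 200.0
    canal_dv_frac: float = 0.3
    canal_ml_frac: float = 0.5
    somite_length: float = 25.0
    cell_diameter: float = 5.0

    def __post_init__(self):
        for name in ("dv_height", "ml_width", "ap_length", "somite_length",
                     "cell_diameter"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0 < self.canal_dv_frac < 1:
            raise InvalidParameterError("canal_dv_frac must be in (0, 1)")
        if not 0 < self.canal_ml_frac < 1:
            raise InvalidParameterError("canal_ml_frac must be in (0, 1)")
        if self.ap_length < 5 * self.somite_length:
            raise InvalidParameterError(
                "ap_length must cover at least five somites")
        if self.cell_diameter >= min(self.dv_height, self.ml_width):
            raise InvalidParameterError(
                "cell_diameter must be smaller than the cord cross-section")

    @property
    def consolidation_band_frac(self) -> float:
        """DV height of the consolidated medial band (1–2 cell tiers
        directly dorsal to the spinal canal) as a fraction of cord height."""
        return 1.5 * self.cell_diameter / self.dv_height


class _Window(NamedTuple):
    start: float
    end: float


@dataclass(frozen=True)
class PhaseSchedule:
    """The three signalling phases, as half-open [start, end) hpf windows."""

    activation: tuple[float, float] = (24.0, 42.0)
    consolidation: tuple[float, float] = (42.0, 66.0)
    termination: tuple[float, float] = (66.0, 78.0)

    def __post_init__(self):
        a, c, t = self.activation, self.consolidation, self.termination
        for w in (a, c, t):
            if not w[0] < w[1]:
                raise InvalidParameterError("phase windows must have start < end")
        if a[1] != c[0] or c[1] != t[0]:
            raise InvalidParameterError(
                "phase windows must be contiguous and ordered")

    @property
    def start(self) -> float:
        return self.activation[0]

    @property
    def end(self) -> float:
        return self.termination[1]


@dataclass(frozen=True)
class PerturbationSpec:
    """One experimental condition: drug, transgene (with heat shock), genotype."""

    drug: str = "none"
    drug_start: float = 20.0
    transgene: str = "none"
    heatshock_time: float | None = None
    genotype: str = "wildtype"

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise InvalidParameterError(f"unknown drug {self.drug!r}")
        if self.transgene not in TRANSGENES:
            raise InvalidParameterError(f"unknown transgene {self.transgene!r}")
        if self.genotype not in GENOTYPES:
            raise InvalidParameterError(f"unknown genotype {self.genotype!r}")
        if self.drug_start < 0:
            raise InvalidParameterError("drug_start must be >= 0")
        if (self.transgene != "none") != (self.heatshock_time is not None):
            raise InvalidParameterError(
                "heatshock_time must be given iff a transgene is present")

    @property
    def notch_off(self) -> bool:
        """Conditions that abolish Notch response in the spinal cord."""
        return self.drug == "LY411575" or self.genotype == "mindbomb"

    @property
    def notch_off_start(self) -> float:
        """Hpf at which Notch inhibition begins (0 for mindbomb mutants)."""
        if self.genotype == "mindbomb":
            return 0.0
        return self.drug_start

    def transgene_active(self, t: float) -> bool:
        return self.transgene != "none" and t >= self.heatshock_time


class Cell(NamedTuple):
    """A single cell; carrier of position for activity-field evaluation."""

    id: int
    tissue: str
    dv_frac: float
    ml_frac: float
    ap_um: float


# ---------------------------------------------------------------------------
# cell population
# ---------------------------------------------------------------------------

def build_embryo(geometry: SpinalCordGeometry | None = None,
                 cell_spacing: float = 2.5,
                 seed: int = 0) -> pd.DataFrame:
    """Tile the cord, flanking somites and a ventral vasculature strip with
    cells on a jittered grid.

    Returns a DataFrame with columns ``id, tissue, dv_frac, ml_frac, ap_um``
    plus absolute rendering coordinates ``x_um`` (AP), ``y_um`` (DV, 0 at the
    ventral cord edge) and ``z_um`` (ML, 0 at one lateral cord edge).
    Deterministic for a given seed.
    """
    geometry = geometry or SpinalCordGeometry()
    if cell_spacing <= 0:
        raise InvalidParameterError("cell_spacing must be > 0")
    if cell_spacing > 2 * geometry.cell_diameter:
        raise InvalidParameterError(
            "cell_spacing must not exceed twice the cell diameter")
    rng = np.random.default_rng(seed)

    def block(x0, x1, y0, y1, z0, z1, spacing, tissue):
        def centers(lo, hi):
            n = max(1, int(round((hi - lo) / spacing)))
            return lo + (np.arange(n) + 0.5) * (hi - lo) / n

        xs, ys, zs = centers(x0, x1), centers(y0, y1), centers(z0, z1)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        # full-cell stratified jitter: positions are marginally uniform in
        # space, so planted domain boundaries are not quantised to the grid
        pos += rng.uniform(-0.5, 0.5, size=pos.shape) * spacing
        return pd.DataFrame({
            "tissue": tissue,
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "_y0": y0, "_y1": y1, "_z0": z0, "_z1": z1,
        })

    g = geometry
    parts = [
        block(0, g.ap_length, 0, g.dv_height, 0, g.ml_width,
              cell_spacing, "spinal_cord"),
        # somites flank the cord laterally, separated by a small gap
        block(0, g.ap_length, 0, g.dv_height, -13.0, -3.0,
              cell_spacing * 2, "somite"),
        block(0, g.ap_length, 0, g.dv_height, g.ml_width + 3.0,
              g.ml_width + 13.0, cell_spacing * 2, "somite"),
        # ventral vasculature strip (dorsal aorta territory)
        block(0, g.ap_length, -8.0, -3.0, 0.25 * g.ml_width,
              0.75 * g.ml_width, cell_spacing * 1.5, "vasculature"),
    ]
    pop = pd.concat(parts, ignore_index=True)
    pop["dv_frac"] = np.clip((pop["y_um"] - pop["_y0"])
                             / (pop["_y1"] - pop["_y0"]), 0.0, 1.0)
    pop["ml_frac"] = np.clip((pop["z_um"] - pop["_z0"])
                             / (pop["_z1"] - pop["_z0"]), 0.0, 1.0)
    pop = pop.drop(columns=["_y0", "_y1", "_z0", "_z1"])
    pop.insert(0, "id", np.arange(len(pop)))
    pop["ap_um"] = pop["x_um"]
    pop = pop[["id", "tissue", "dv_frac", "ml_frac", "ap_um",
               "x_um", "y_um", "z_um"]]
    pop.attrs["geometry"] = g
    return pop


def population_to_csv(population: pd.DataFrame, path_or_buf) -> None:
    """Export a cell population as CSV (id, tissue, dv_frac, ml_frac, ap_um)."""
    population[["id", "tissue", "dv_frac", "ml_frac", "ap_um"]].to_csv(
        path_or_buf, index=False)


# ---------------------------------------------------------------------------
# activity fields
# ---------------------------------------------------------------------------

def _lateral_factor(ml):
    """Mild mediolateral attenuation: response is weakest at the lateral
    edges of the cord, producing the wide central ML peak."""
    return 1.0 - _LATERAL_DROP * (2.0 * np.abs(ml - 0.5)) ** 4


def _active_region(dv, ml, t, schedule, geometry, dv_hi_start):
    """Boolean mask of the shrinking active domain in the cord.

    During activation the domain spans dv in [0, dv_hi_start) at full ML
    width; over the consolidation window it contracts linearly onto the
    medial band directly dorsal to the spinal canal.
    """
    c0, c1 = schedule.consolidation
    s = np.clip((t - c0) / (c1 - c0), 0.0, 1.0)
    canal = geometry.canal_dv_frac
    band_hi = canal + geometry.consolidation_band_frac
    dv_lo = s * canal
    dv_hi = dv_hi_start - s * (dv_hi_start - band_hi)
    ml_hw = 0.5 - s * (0.5 - _FINAL_ML_HALFWIDTH)
    return (dv >= dv_lo) & (dv < dv_hi) & (np.abs(ml - 0.5) <= ml_hw)


def _ramp_down(t, start, hours):
    """Linear 1 → 0 ramp beginning at `start`, completing after `hours`."""
    return float(np.clip(1.0 - (t - start) / hours, 0.0, 1.0))


def notch_activity(cell, t: float,
                   perturbation: PerturbationSpec | None = None,
                   schedule: PhaseSchedule | None = None,
                   geometry: SpinalCordGeometry | None = None,
                   basal_level: float = 0.02) -> float:
    """Notch response level in [0, 1] for one cell at time ``t`` (hpf)."""
    return float(notch_activity_vec(
        np.asarray([cell.dv_frac]), np.asarray([cell.ml_frac]),
        np.asarray([cell.tissue]), t, perturbation or PerturbationSpec(),
        schedule or PhaseSchedule(), geometry or SpinalCordGeometry(),
        basal_level)[0])


def notch_activity_vec(dv, ml, tissue, t, perturbation, schedule, geometry,
                       basal_level=0.02) -> np.ndarray:
    """Vectorised Notch activity over arrays of cell coordinates."""
    if not schedule.start - 24.0 <= t <= schedule.end + 24.0:
        raise InvalidParameterError(
            f"t={t} is outside the simulated window around the schedule")
    dv = np.asarray(dv, float)
    ml = np.asarray(ml, float)
    tissue = np.asarray(tissue)
    out = np.full(dv.shape, basal_level)

    cord = tissue == "spinal_cord"
    if cord.any():
        level = np.full(dv.shape, basal_level)
        if t >= schedule.start:
            inside = _active_region(dv, ml, t, schedule, geometry,
                                    dv_hi_start=1.0)
            peak = _lateral_factor(ml)
            # Notch returns to basal over the first half of termination
            # (weaker by 66 hpf, basal by 72 hpf).
            t0, t1 = schedule.termination
            fade = float(np.clip(1.0 - (t - t0) / ((t1 - t0) / 2), 0.0, 1.0))
            level = np.where(inside,
                             basal_level + (peak - basal_level) * fade,
                             basal_level)
        out[cord] = level[cord]

    vasc = tissue == "vasculature"
    if vasc.any():
        lvl = basal_level
        # Hh is upstream of Notch response in the vasculature: ectopic Smo
        # activation expands her12 expression around the dorsal aorta.
        if perturbation.transgene == "rSmoM2" and perturbation.transgene_active(t):
            lvl = 0.6
        out[vasc] = lvl

    # drug / genotype / transgene modifiers act on the cord
    if perturbation.notch_off:
        ramp = _ramp_down(t, perturbation.notch_off_start, LY_RAMP_HOURS)
        out[cord] = out[cord] * ramp
    if perturbation.transgene == "NICD" and perturbation.transgene_active(t):
        out[cord] = 1.0
    return np.clip(out, 0.0, 1.0)


def _hh_cord_base(dv, ml, t, schedule, geometry, basal_level):
    """Unperturbed cord Hh envelope: ventrally graded, consolidating, then
    terminating.

    During activation the profile ramps from 1.0 at the ventral edge to 0.5
    at ``dv = VENTRAL_EXTENT`` and is basal above it, so the above-half-max
    region spans the ventral 75% of the cord.
    """
    grad = 1.0 - 0.5 * np.clip(dv, 0.0, 1.0) / VENTRAL_EXTENT
    level = np.full(dv.shape, basal_level)
    if t >= schedule.start:
        inside = _active_region(dv, ml, t, schedule, geometry,
                                dv_hi_start=VENTRAL_EXTENT)
        peak = grad * _lateral_factor(ml)
        # Hh lags Notch slightly: still active at 72 hpf, basal by 78 hpf.
        t0, t1 = schedule.termination
        mid = (t0 + t1) / 2
        fade = float(np.clip(1.0 - (t - mid) / (t1 - mid), 0.0, 1.0)) \
            if t >= mid else 1.0
        level = np.where(inside,
                         basal_level + (peak - basal_level) * fade,
                         basal_level)
    return level


def hh_activity(cell, t: float,
                perturbation: PerturbationSpec | None = None,
                notch_level: float = 1.0,
                schedule: PhaseSchedule | None = None,
                geometry: SpinalCordGeometry | None = None,
                basal_level: float = 0.02) -> float:
    """Hedgehog response level in [0, 1] for one cell at time ``t`` (hpf).

    ``notch_level`` gates the cord response (the tissue-specific Notch→Hh
    coupling); somites and vasculature ignore it.
    """
    return float(hh_activity_vec(
        np.asarray([cell.dv_frac]), np.asarray([cell.ml_frac]),
        np.asarray([cell.tissue]), t, perturbation or PerturbationSpec(),
        np.asarray([notch_level], float), schedule or PhaseSchedule(),
        geometry or SpinalCordGeometry(), basal_level)[0])


def hh_activity_vec(dv, ml, tissue, t, perturbation, notch_level, schedule,
                    geometry, basal_level=0.02) -> np.ndarray:
    """Vectorised Hh activity over arrays of cell coordinates."""
    dv = np.asarray(dv, float)
    ml = np.asarray(ml, float)
    tissue = np.asarray(tissue)
    notch_level = np.broadcast_to(np.asarray(notch_level, float), dv.shape)
    if np.any((notch_level < 0) | (notch_level > 1)):
        raise InvalidParameterError("notch_level must lie in [0, 1]")
    if not schedule.start - 24.0 <= t <= schedule.end + 24.0:
        raise InvalidParameterError(
            f"t={t} is outside the simulated window around the schedule")
    p = perturbation
    out = np.full(dv.shape, basal_level)

    smo_on = p.transgene == "rSmoM2" and p.transgene_active(t)
    cyc_ramp = _ramp_down(t, p.drug_start, CYC_RAMP_HOURS) \
        if p.drug == "cyclopamine" else 1.0

    # --- somites: Hh response is Notch-independent ---
    som = tissue == "somite"
    if som.any():
        lvl = 1.0 if smo_on else _SOMITE_HH * (cyc_ramp if not smo_on else 1.0)
        # cyclopamine drives somite response to zero (no Smo-independent floor)
        out[som] = lvl

    vasc = tissue == "vasculature"
    if vasc.any():
        out[vasc] = 1.0 if smo_on else _VASC_HH * cyc_ramp

    # --- spinal cord: gated by Notch ---
    cord = tissue == "spinal_cord"
    if cord.any():
        if p.genotype == "iguana":
            # cilia-less mutants: uniform low-level, Smo-independent response
            base = np.full(dv.shape, IGUANA_LEVEL if t >= schedule.start
                           else basal_level)
        else:
            base = _hh_cord_base(dv, ml, t, schedule, geometry, basal_level)
            if p.drug == "cyclopamine":
                floor = np.minimum(base, CYC_RESIDUAL)
                base = floor + (base - floor) * cyc_ramp
            if smo_on:
                base = np.full(dv.shape, 1.0)

        gate = notch_level.copy()
        if p.notch_off:
            # exponential loss of Hh competence once Notch response is gone
            dt_off = max(0.0, t - p.notch_off_start)
            gate = np.minimum(gate, 2.0 ** (-dt_off / NOTCH_OFF_HALFTIME))
        # basal transcription also requires (basal) Notch activity, so the
        # gate maps notch_level=0 to exactly 0 while leaving the unperturbed
        # basal state untouched.
        level = (basal_level * np.clip(gate / basal_level, 0.0, 1.0)
                 + np.clip(base - basal_level, 0.0, None) * gate)
        if p.transgene == "EGFP_Gli1" and p.transgene_active(t):
            # ectopic Gli1 supplies a Notch-independent drive, capped below
            # the unperturbed ventral maximum
            level = np.maximum(level, GLI1_DRIVE)
        out[cord] = level[cord]
    return np.clip(out, 0.0, 1.0)


@dataclass
class ActivityField:
    """Callable ground-truth activity field: ``field(cell, t, pathway)``.

    ``heterogeneity_sigma`` > 0 multiplies each cell's activity by a fixed,
    seeded lognormal factor (clipped back into [0, 1]), reproducing the
    salt-and-pepper cell-to-cell variability of real reporter embryos while
    keeping the field deterministic given (cell, t, pathway, perturbation).
    """

    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    geometry: SpinalCordGeometry = field(default_factory=SpinalCordGeometry)
    basal_level: float = 0.02
    heterogeneity_sigma: float = 0.0
    seed: int = 0

    _PATHWAYS = ("notch", "hh")

    def _noise(self, ids: np.ndarray, pathway: str) -> np.ndarray:
        if self.heterogeneity_sigma <= 0:
            return np.ones(len(ids))
        idx = self._PATHWAYS.index(pathway)
        rng = np.random.default_rng([self.seed, idx])
        table = rng.lognormal(0.0, self.heterogeneity_sigma,
                              size=int(np.max(ids)) + 1)
        return table[np.asarray(ids, int)]

    def evaluate(self, population: pd.DataFrame, t: float,
                 pathway: str) -> np.ndarray:
        """Activity for every cell of a population at time ``t``."""
        if pathway not in self._PATHWAYS:
            raise InvalidParameterError(f"unknown pathway {pathway!r}")
        dv = population["dv_frac"].to_numpy()
        ml = population["ml_frac"].to_numpy()
        tis = population["tissue"].to_numpy()
        notch = notch_activity_vec(dv, ml, tis, t, self.perturbation,
                                   self.schedule, self.geometry,
                                   self.basal_level)
        if pathway == "notch":
            lvl = notch
        else:
            lvl = hh_activity_vec(dv, ml, tis, t, self.perturbation, notch,
                                  self.schedule, self.geometry,
                                  self.basal_level)
        lvl = lvl * self._noise(population["id"].to_numpy(), pathway)
        return np.clip(lvl, 0.0, 1.0)

    def __call__(self, cell, t: float, pathway: str) -> float:
        pop = pd.DataFrame({"id": [cell.id], "tissue": [cell.tissue],
                            "dv_frac": [cell.dv_frac],
                            "ml_frac": [cell.ml_frac]})
        return float(self.evaluate(pop, t, pathway)[0])


# ---------------------------------------------------------------------------
# marker-domain ground truth
# ---------------------------------------------------------------------------

#: Control expression-domain fractions of spinal-cord cross-section area.
CONTROL_FRACTIONS = {"ptc2": VENTRAL_EXTENT, "sox2": 0.80, "olig2": 0.10}

#: LY-411575 timecourse knots: hours of treatment -> fractional reduction.
#: ptc2 collapses fast (44% at 1 h), sox2 lags (10% at 1 h); both ~50% at
#: 2 h and 61-70% (midpoint 0.65) by 3 h; full loss by 10 h of treatment.
LY_REDUCTION_KNOTS = {
    "ptc2": ((0.0, 1.0, 2.0, 3.0, 10.0), (0.0, 0.44, 0.50, 0.65, 1.0)),
    "sox2": ((0.0, 1.0, 2.0, 3.0, 10.0), (0.0, 0.10, 0.50, 0.65, 1.0)),
    "olig2": ((0.0, 3.0, 10.0), (0.0, 0.50, 1.0)),
}

#: Domain enlargement under ectopic pathway activation (DMSO background).
ECTOPIC_ENLARGEMENT = 1.25

#: olig2 rescue level (fraction of wild type) for EGFP-Gli1 + LY-411575.
GLI1_RESCUE_FACTOR = 0.63

#: Cyclopamine endpoint reduction of the cord ptc2 domain (reduced but not
#: abolished, residual Smo-independent transcription).
CYC_PTC2_REDUCTION = 0.7


def _ly_reduction(marker: str, hours: float) -> float:
    knots_t, knots_r = LY_REDUCTION_KNOTS[marker]
    return float(np.interp(hours, knots_t, knots_r))


def marker_domain_truth(marker: str,
                        perturbation: PerturbationSpec | None = None,
                        hours_since: float = 0.0) -> float:
    """Planted ground-truth expression-domain fraction of cord area.

    ``hours_since`` counts from drug addition (or heat shock for pure
    transgene conditions). The control trajectory is constant.
    """
    if marker not in MARKERS:
        raise InvalidParameterError(f"unknown marker {marker!r}")
    if hours_since < 0:
        raise InvalidParameterError("hours_since must be >= 0")
    p = perturbation or PerturbationSpec()
    control = CONTROL_FRACTIONS[marker]
    ectopic = p.transgene in ("rSmoM2", "EGFP_Gli1") or p.genotype == "iguana"

    if p.notch_off:
        if marker == "olig2" and p.transgene == "EGFP_Gli1":
            # ectopic Gli1 partially restores the motor-neuron precursor
            # domain in Notch-off cords
            return GLI1_RESCUE_FACTOR * control
        if marker == "ptc2" and p.transgene == "EGFP_Gli1":
            # significant ptc2 rescue, slightly below the DMSO Gli1 level
            return control
        # rSmoM2 and iguana cannot bypass the Notch requirement in the cord
        return control * (1.0 - _ly_reduction(marker, hours_since))

    if p.drug == "cyclopamine" and marker == "ptc2" and p.genotype != "iguana":
        red = CYC_PTC2_REDUCTION * float(np.clip(
            hours_since / CYC_RAMP_HOURS, 0.0, 1.0))
        return control * (1.0 - red)

    if ectopic and marker in ("ptc2", "olig2"):
        return min(1.0, control * ECTOPIC_ENLARGEMENT)
    if p.transgene == "NICD" and marker == "ptc2":
        return min(1.0, control * ECTOPIC_ENLARGEMENT)
    return control


@dataclass(frozen=True)
class MarkerDomainModel:
    """Trajectory wrapper for one marker: condition × time → domain fraction."""

    marker: str

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise InvalidParameterError(f"unknown marker {self.marker!r}")

    def fraction(self, perturbation: PerturbationSpec,
                 hours_since: float) -> float:
        return marker_domain_truth(self.marker, perturbation, hours_since)

    @property
    def control_fraction(self) -> float:
        return CONTROL_FRACTIONS[self.marker]


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def geometry_from_yaml(source) -> SpinalCordGeometry:
    """Load a SpinalCordGeometry from a YAML file path, mapping, or open
    file object (the ``geometry:`` section of ``embryo.yaml``)."""
    if isinstance(source, dict):
        data = source
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    return SpinalCordGeometry(**(data.get("geometry", data)))
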
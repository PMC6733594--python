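"""Expression-domain morphometry on transverse sections.

Quantifies an in-situ-style marker stain (*ptc2*, *sox2*, *olig2*) on
transverse spinal-cord sections: segment the expression domain inside the
cord mask, express its area as a percentage of the cord cross-section,
average 6–10 sections per embryo, normalise per-embryo means to the DMSO
group mean (the "control maximum"), and summarise drug timecourses as
percent reductions versus control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import ContractViolationError, InvalidParameterError

__all__ = [
    "DomainMeasurement",
    "NormalizedMeasurement",
    "EmbryoSummary",
    "segment_expression",
    "domain_percentage",
    "summarize_embryo",
    "normalize_to_control_max",
    "timecourse_reduction",
]

#: The protocol images 6-10 cryosections per embryo.
SECTION_RANGE = (6, 10)


@dataclass(frozen=True)
class DomainMeasurement:
    """Expression-domain area as a percentage of cord cross-section area."""

    area_domain: int
    area_cord: int

    def __post_init__(self):
        if self.area_cord <= 0:
            raise InvalidParameterError("area_cord must be > 0")
        if not 0 <= self.area_domain <= self.area_cord:
            raise InvalidParameterError(
                "area_domain must lie within [0, area_cord]")

    @property
    def pct(self) -> float:
        return 100.0 * self.area_domain / self.area_cord


@dataclass(frozen=True)
class NormalizedMeasurement:
    """A raw domain percentage re-expressed as % of the control maximum."""

    pct_raw: float
    control_max: float

    @property
    def pct_normalized(self) -> float:
        return 100.0 * self.pct_raw / self.control_max


@dataclass(frozen=True)
class EmbryoSummary:
    embryo_id: str
    n_sections: int
    mean_pct: float


def segment_expression(section: np.ndarray,
                       cord_mask: np.ndarray,
                       method: str = "otsu",
                       threshold: float | None = None) -> np.ndarray:
    """Segment the expression domain within the cord mask.

    ``fixed``: pixels >= ``threshold``. ``otsu``: threshold computed from
    the intensity histogram restricted to the cord mask. The returned mask
    is always a subset of ``cord_mask``.
    """
    section = np.asarray(section, float)
    cord_mask = np.asarray(cord_mask, bool)
    if section.shape != cord_mask.shape:
        raise InvalidParameterError("section/cord_mask shape mismatch")
    if not cord_mask.any():
        raise InvalidParameterError("cord_mask is empty")
    if method == "fixed":
        if threshold is None:
            raise InvalidParameterError("fixed method requires a threshold")
        thr = threshold
    elif method == "otsu":
        vals = section[cord_mask]
        if np.ptp(vals) == 0:
            return np.zeros_like(cord_mask)
        thr = threshold_otsu(vals)
    else:
        raise InvalidParameterError(f"unknown segmentation method {method!r}")
    return (section >= thr) & cord_mask


def domain_percentage(domain_mask: np.ndarray,
                      cord_mask: np.ndarray) -> DomainMeasurement:
    """Area of the expression domain over the area of the entire cord."""
    domain_mask = np.asarray(domain_mask, bool)
    cord_mask = np.asarray(cord_mask, bool)
    if not cord_mask.any():
        raise InvalidParameterError("cord_mask is empty")
    if np.any(domain_mask & ~cord_mask):
        raise ContractViolationError("domain pixels fall outside the cord")
    return DomainMeasurement(area_domain=int(domain_mask.sum()),
                             area_cord=int(cord_mask.sum()))


def summarize_embryo(measurements: list[DomainMeasurement],
                     embryo_id: str = "embryo") -> EmbryoSummary:
    """Arithmetic mean of section percentages; one data point per embryo."""
    if not measurements:
        raise InvalidParameterError("no section measurements")
    n = len(measurements)
    if not SECTION_RANGE[0] <= n <= SECTION_RANGE[1]:
        warnings.warn(
            f"{n} sections for {embryo_id}; protocol images "
            f"{SECTION_RANGE[0]}-{SECTION_RANGE[1]}", stacklevel=2)
    return EmbryoSummary(embryo_id=embryo_id, n_sections=n,
                         mean_pct=float(np.mean([m.pct
                                                 for m in measurements])))


def normalize_to_control_max(values,
                             control_values) -> list[NormalizedMeasurement]:
    """Normalise per-embryo percentages to the control-group mean.

    The control maximum is the mean of the DMSO group, so the normalised
    control group itself averages exactly 100%.
    """
    control_values = np.asarray(list(control_values), float)
    if control_values.size == 0:
        raise InvalidParameterError("control group is empty")
    control_max = float(control_values.mean())
    if control_max <= 0:
        raise InvalidParameterError("control group carries no signal")
    return [NormalizedMeasurement(pct_raw=float(v), control_max=control_max)
            for v in values]


def timecourse_reduction(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint percent reduction of treated groups versus control.

    ``measurements`` is tidy with columns ``marker``, ``timepoint_h``,
    ``group`` ('control' or 'treated') and ``mean_pct`` (one row per
    embryo). Each (marker, timepoint) must carry both groups. Returns a
    frame with columns marker, timepoint_h, control_max, normalized_mean,
    reduction_pct where reduction = 100 − mean(normalised treated).
    """
    required = {"marker", "timepoint_h", "group", "mean_pct"}
    if not required <= set(measurements.columns):
        raise InvalidParameterError(
            f"measurements must carry columns {sorted(required)}")
    rows = []
    for (marker, tp), sub in measurements.groupby(["marker", "timepoint_h"]):
        ctl = sub.loc[sub["group"] == "control", "mean_pct"]
        trt = sub.loc[sub["group"] == "treated", "mean_pct"]
        if ctl.empty or trt.empty:
            raise InvalidParameterError(
                f"missing control or treated group for {marker} at {tp} h")
        norm = normalize_to_control_max(trt, ctl)
        norm_mean = float(np.mean([m.pct_normalized for m in norm]))
        rows.append({"marker": marker, "timepoint_h": tp,
                     "control_max": float(ctl.mean()),
                     "normalized_mean": norm_mean,
                     "reduction_pct": 100.0 - norm_mean})
    return pd.DataFrame(rows).sort_values(
        ["marker", "timepoint_h"]).reset_index(drop=True)
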
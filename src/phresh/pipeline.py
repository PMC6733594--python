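"""End-to-end recipes: simulate → render → quantify → compare.

Three standard experiments are wired here:

* :func:`simulate_phresh_stack` / :func:`phresh_map` — Kaede
  photoconversion embryos imaged 6 h post-conversion across a grid of t₀
  values, quantified into the spatiotemporal signalling map;
* :func:`notch_inhibition_timecourse` — the LY-411575 timecourse: ptc2 and
  sox2 expression domains measured after 1–3 h of Notch inhibition and
  normalised to the DMSO control maximum;
* :func:`gli1_rescue_experiment` — heat-shock EGFP-Gli1 embryos with and
  without Notch inhibition, olig2 domain morphometry.

:func:`run_pipeline` executes the configured stages and writes tidy CSVs
plus a machine-readable results JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import domain_morphometry as dm
from . import phresh_quant as pq
from .config import RunConfig, default_config
from .errors import InvalidParameterError, StageError
from .image_synthesis import (ImageStack, NoiseModel, OpticsModel,
                              render_stack, reslice_transverse)
from .reporter_kinetics import (ConversionEvent, ReporterParams,
                                simulate_reporter)
from .stats_report import mann_whitney_u, summarize_groups
from .synthetic_embryo import (ActivityField, PerturbationSpec,
                               PhaseSchedule, SpinalCordGeometry,
                               build_embryo, marker_domain_truth)

logger = logging.getLogger("phresh")

__all__ = [
    "simulate_phresh_stack",
    "phresh_map",
    "simulate_marker_stack",
    "measure_marker_stack",
    "simulate_marker_cohort",
    "notch_inhibition_timecourse",
    "gli1_rescue_experiment",
    "run_pipeline",
]

#: Imaging interval after photoconversion (hours).
POST_CONVERSION_HOURS = 6.0

#: Cell-to-cell reporter heterogeneity (lognormal σ) used by simulations.
HETEROGENEITY_SIGMA = 0.1

#: Marker-stain amplitude (a.u. per cell) and off-domain baseline fraction.
MARKER_AMP = 50.0
MARKER_BASELINE = 0.02

#: Edge-parallel axis of each marker's anatomical band: ptc2 and olig2
#: boundaries run across the DV axis, the sox2 progenitor band across ML.
MARKER_BAND_AXIS = {"ptc2": "dv", "sox2": "ml", "olig2": "dv"}

#: Morphometry sections are imaged at high NA and Nyquist-ish sampling
#: (0.5 µm in-plane, 0.5 µm PSF sigma) so that single-cell-tier domains
#: such as the olig2 band are resolved without edge-blur bias.
MORPHOMETRY_OPTICS = OpticsModel(voxel_size=(0.5, 0.5, 1.0),
                                 psf_sigma=(0.5, 0.5, 0.5))


def _sub_seed(seed: int, *parts) -> list[int]:
    return [int(seed) & 0x7FFFFFFF, *[int(p) & 0x7FFFFFFF for p in parts]]


# ---------------------------------------------------------------------------
# PHRESH (photoconversion) arm
# ---------------------------------------------------------------------------

def default_converted_window(geometry: SpinalCordGeometry) -> tuple[float, float]:
    """Converted AP span: five-plus somites above the yolk extension,
    leaving an anterior unconverted region as the normalisation reference."""
    return (0.2 * geometry.ap_length, 0.825 * geometry.ap_length)


def simulate_phresh_stack(pathway: str,
                          t0: float,
                          perturbation: PerturbationSpec | None = None,
                          seed: int = 0,
                          geometry: SpinalCordGeometry | None = None,
                          schedule: PhaseSchedule | None = None,
                          params: ReporterParams | None = None,
                          optics: OpticsModel | None = None,
                          noise: NoiseModel | None = None,
                          cell_spacing: float = 2.5,
                          dt: float = 0.1,
                          noise_template: NoiseModel | None = None) -> ImageStack:
    """One synthetic photoconverted embryo: convert at ``t0``, image 6 h
    later, render the green/red Kaede channels into a lateral stack."""
    geometry = geometry or SpinalCordGeometry()
    schedule = schedule or PhaseSchedule()
    perturbation = perturbation or PerturbationSpec()
    params = params or ReporterParams()
    optics = optics or OpticsModel()
    if noise is None:
        noise = dataclasses.replace(
            noise_template or NoiseModel(),
            seed=int(np.random.default_rng(_sub_seed(seed, 1))
                     .integers(2**31)))
    pop = build_embryo(geometry, cell_spacing, seed=seed)
    field = ActivityField(perturbation=perturbation, schedule=schedule,
                          geometry=geometry,
                          heterogeneity_sigma=HETEROGENEITY_SIGMA, seed=seed)
    window = default_converted_window(geometry)
    event = ConversionEvent(t0=t0, ap_window=window)
    states = simulate_reporter(pop, field, event,
                               t_image=t0 + POST_CONVERSION_HOURS,
                               params=params, pathway=pathway, dt=dt)
    return render_stack(states, pop, geometry, optics=optics, noise=noise,
                        converted_ap_window=window,
                        meta={"pathway": pathway, "t0_hpf": t0,
                              "t_image_hpf": t0 + POST_CONVERSION_HOURS,
                              "seed": seed})


def phresh_map(pathway: str = "hh",
               t0_grid=(24.0, 30.0, 36.0, 42.0, 48.0, 54.0, 60.0, 66.0, 72.0),
               n_embryos: int = 1,
               seed: int = 0,
               **kwargs) -> pq.SpatiotemporalMap:
    """Spatiotemporal signalling map from embryos photoconverted on a t₀
    grid (6 h intervals by default, as in the live-imaging protocol)."""
    cohort = {}
    for i, t0 in enumerate(t0_grid):
        cohort[float(t0)] = [
            simulate_phresh_stack(pathway, t0,
                                  seed=int(np.random.default_rng(
                                      _sub_seed(seed, i, e)).integers(2**31)),
                                  **kwargs)
            for e in range(n_embryos)]
    return pq.build_map(cohort)


# ---------------------------------------------------------------------------
# marker morphometry arm
# ---------------------------------------------------------------------------

def _marker_domain_mask(marker: str, fraction: float, dv: np.ndarray,
                        ml: np.ndarray) -> np.ndarray:
    """Cells inside the planted expression domain of the given fractional
    area.  ptc2 occupies a ventral band, sox2 the medial progenitor zone,
    olig2 a narrow motor-neuron precursor band above the floor plate."""
    fraction = float(np.clip(fraction, 0.0, 1.0))
    if marker == "ptc2":
        return dv < fraction
    if marker == "sox2":
        return np.abs(ml - 0.5) < fraction / 2.0
    if marker == "olig2":
        centre = 0.2
        lo = max(0.0, centre - fraction / 2.0)
        return (dv >= lo) & (dv < lo + fraction)
    raise InvalidParameterError(f"unknown marker {marker!r}")


def simulate_marker_stack(marker: str,
                          perturbation: PerturbationSpec | None = None,
                          hours_since: float = 0.0,
                          seed: int = 0,
                          geometry: SpinalCordGeometry | None = None,
                          optics: OpticsModel | None = None,
                          noise: NoiseModel | None = None,
                          cell_spacing: float = 2.5,
                          embryo_jitter_sigma: float = 0.03,
                          cell_noise_sigma: float = 0.1,
                          sample_noise: bool = True,
                          noise_template: NoiseModel | None = None) -> ImageStack:
    """Render one embryo's marker stain as a single-channel stack.

    The planted domain fraction comes from the condition's ground-truth
    trajectory, perturbed by a per-embryo lognormal factor (biological
    variability) and painted onto cord cells with per-cell expression noise.
    """
    geometry = geometry or SpinalCordGeometry()
    optics = optics or MORPHOMETRY_OPTICS
    perturbation = perturbation or PerturbationSpec()
    rng = np.random.default_rng(_sub_seed(seed, 7))
    if noise is None:
        noise = dataclasses.replace(noise_template or NoiseModel(),
                                    seed=int(rng.integers(2**31)))
    truth = marker_domain_truth(marker, perturbation, hours_since)
    fraction = float(np.clip(
        truth * rng.lognormal(0.0, embryo_jitter_sigma), 0.0, 1.0)) \
        if embryo_jitter_sigma > 0 else truth
    pop = build_embryo(geometry, cell_spacing, seed=seed)
    cord = (pop["tissue"] == "spinal_cord").to_numpy()
    inside = _marker_domain_mask(marker, fraction,
                                 pop["dv_frac"].to_numpy(),
                                 pop["ml_frac"].to_numpy()) & cord
    amounts = np.where(inside, MARKER_AMP, MARKER_AMP * MARKER_BASELINE)
    amounts = np.where(cord, amounts, 0.0)
    if cell_noise_sigma > 0:
        amounts = amounts * rng.lognormal(0.0, cell_noise_sigma,
                                          size=len(amounts))
    states = pd.DataFrame({"marker": amounts})
    offset = tuple(rng.uniform(0.0, v) for v in optics.voxel_size)
    return render_stack(states, pop, geometry, optics=optics, noise=noise,
                        channels=("marker",), sample_noise=sample_noise,
                        grid_offset_um=offset,
                        meta={"marker": marker, "truth_fraction": truth,
                              "planted_fraction": fraction, "seed": seed,
                              "hours_since": hours_since,
                              "band_axis": MARKER_BAND_AXIS[marker]})


def _stain_split(values: np.ndarray) -> float | None:
    """Log-intensity Otsu split between the off (baseline) and on (stained)
    pixel populations, or None when only one population is present.

    The split is made on log-intensities, where the two modes of a
    high-contrast stain are symmetric and well separated even when one
    class dominates the histogram (an Otsu split on raw intensities breaks
    down there).
    """
    from skimage.filters import threshold_otsu

    v = np.asarray(values, float)
    v = v[v > 0]
    if v.size < 16 or np.ptp(v) == 0:
        return None
    logs = np.log(v)
    split = threshold_otsu(logs)
    on = logs[logs >= split]
    off = logs[logs < split]
    if on.size == 0 or off.size == 0:
        return None
    if np.median(on) - np.median(off) < 1.0:
        return None  # single population: no expressing domain
    return float(np.exp(split))


def _stain_plateau(sections: list[np.ndarray], mask: np.ndarray,
                   split: float, erode_px: int) -> float:
    """Interior stain level: median intensity over the stained mask eroded
    away from its edges, so PSF-attenuated boundary pixels do not drag the
    plateau estimate down (they dominate the stained class for domains only
    a cell tier wide)."""
    from scipy.ndimage import binary_erosion

    interior_vals = []
    for sec in sections:
        on = (sec >= split) & mask
        interior = binary_erosion(on, iterations=erode_px) if erode_px \
            else on
        interior_vals.append(sec[interior if interior.any() else on])
    return float(np.median(np.concatenate(interior_vals)))


def measure_marker_stack(stack: ImageStack,
                         geometry: SpinalCordGeometry | None = None,
                         n_sections: int = 8,
                         method: str = "halfmax",
                         band_axis: str | None = None,
                         smoothing_um: float = 2.0,
                         ap_smoothing_um: float = 4.0) -> list[dm.DomainMeasurement]:
    """Reslice a marker stack and measure the domain percentage on
    ``n_sections`` transverse sections from the central trunk region.

    At cell-scale sampling a single PSF volume holds roughly one cell, so
    raw voxel intensities are too grainy to threshold.  The stack is
    therefore pre-smoothed *along the band direction only* — along AP and
    along the known edge-parallel axis of the marker's anatomy
    (``band_axis`` 'dv' for dorsoventrally stacked domains such as the
    ventral ptc2 gradient readout or the olig2 tier, 'ml' for the medial
    sox2 band) — which averages out cell graininess without blurring the
    domain boundaries being measured.

    The default ``halfmax`` method derives one stain threshold per stack:
    half the interior stain level (see :func:`_stain_plateau`).  For a
    symmetrically blurred stain profile this recovers each boundary where
    the edge crosses half its local plateau, i.e. at the true domain
    boundary.  ``otsu`` and ``fixed:<value>`` instead threshold each
    section independently via :func:`phresh.domain_morphometry.segment_expression`.
    """
    from scipy.ndimage import gaussian_filter

    if geometry is None:
        gdict = stack.meta.get("geometry")
        geometry = SpinalCordGeometry(**gdict) if gdict \
            else SpinalCordGeometry()
    if band_axis is None:
        band_axis = stack.meta.get("band_axis", "dv")
    if band_axis not in ("dv", "ml"):
        raise InvalidParameterError("band_axis must be 'dv' or 'ml'")
    vz, vy, vx = stack.voxel_size
    data = stack.data
    if method == "halfmax" and (smoothing_um > 0 or ap_smoothing_um > 0):
        # (z, y, x) smoothing; the axis normal to the band edges stays sharp
        sigma = ((0.0, smoothing_um / vy, ap_smoothing_um / vx)
                 if band_axis == "ml"
                 else (smoothing_um / vz, 0.0, ap_smoothing_um / vx))
        data = np.stack([gaussian_filter(c, sigma) for c in data])
    sections = reslice_transverse(data)  # (X, C, Y, Z)
    ch = stack.channels.index("marker") if "marker" in stack.channels else 0
    nx = sections.shape[0]
    lo, hi = int(0.25 * nx), int(0.80 * nx)
    idx = np.linspace(lo, hi, n_sections).round().astype(int)
    mask = stack.cord_section_mask(geometry)
    if method == "halfmax":
        # exclude a PSF-blurred margin along the band-parallel axis (the
        # domain spans the cord fully there, so the area fraction within
        # the trimmed mask is unchanged while boundary-mixing pixels drop
        # out of both numerator and denominator)
        margin = 2.0  # µm, ~2.5 PSF sigmas
        dv = stack.dv_coords()
        ml = stack.ml_coords()
        if band_axis == "dv":
            keep = ((ml >= margin) & (ml <= geometry.ml_width - margin))
            mask = mask & keep[None, :]
        else:
            keep = ((dv >= margin) & (dv <= geometry.dv_height - margin))
            mask = mask & keep[:, None]
    secs = [sections[i, ch] for i in idx]
    out = []
    if method == "halfmax":
        split = _stain_split(np.concatenate([s[mask] for s in secs]))
        if split is None:
            thr = None
        else:
            erode_px = max(1, int(round(1.0 / min(vz, vy))))
            plateau = _stain_plateau(secs, mask, split, erode_px)
            thr = 0.5 * plateau
        for sec in secs:
            domain = np.zeros_like(mask) if thr is None else \
                dm.segment_expression(sec, mask, method="fixed",
                                      threshold=thr)
            out.append(dm.domain_percentage(domain, mask))
        return out
    for sec in secs:
        if method.startswith("fixed:"):
            domain = dm.segment_expression(
                sec, mask, method="fixed", threshold=float(method[6:]))
        else:
            domain = dm.segment_expression(sec, mask, method=method)
        out.append(dm.domain_percentage(domain, mask))
    return out


def simulate_marker_cohort(marker: str,
                           perturbation: PerturbationSpec | None = None,
                           hours_since: float = 0.0,
                           n_embryos: int = 8,
                           n_sections: int = 8,
                           seed: int = 0,
                           condition: str = "condition",
                           **stack_kwargs) -> pd.DataFrame:
    """Simulate and measure a cohort; one row of per-embryo mean domain
    percentage per embryo."""
    rows = []
    for e in range(n_embryos):
        embryo_seed = int(np.random.default_rng(
            _sub_seed(seed, zlib.crc32(condition.encode()), e))
            .integers(2**31))
        stack = simulate_marker_stack(marker, perturbation, hours_since,
                                      seed=embryo_seed, **stack_kwargs)
        measurements = measure_marker_stack(stack, n_sections=n_sections)
        summary = dm.summarize_embryo(measurements,
                                      embryo_id=f"{condition}-{e}")
        rows.append({"condition": condition, "marker": marker,
                     "embryo_id": summary.embryo_id,
                     "n_sections": summary.n_sections,
                     "mean_pct": summary.mean_pct,
                     "truth_fraction": stack.meta["truth_fraction"]})
    return pd.DataFrame(rows)


def notch_inhibition_timecourse(seed: int = 0,
                                hours=(1.0, 2.0, 3.0),
                                markers=("ptc2", "sox2"),
                                n_embryos: int = 8,
                                n_sections: int = 8,
                                **stack_kwargs) -> dict:
    """The LY-411575 timecourse: domain morphometry of ptc2/sox2 after each
    treatment duration, normalised to the DMSO control maximum.

    Returns {'measurements': tidy per-embryo frame,
             'reductions': per-(marker, timepoint) reduction frame,
             'comparisons': Mann-Whitney results per endpoint}.
    """
    dmso = PerturbationSpec()
    ly = PerturbationSpec(drug="LY411575", drug_start=20.0)
    frames = []
    for mi, marker in enumerate(markers):
        ctl = simulate_marker_cohort(
            marker, dmso, hours_since=max(hours), n_embryos=n_embryos,
            n_sections=n_sections, seed=seed + 1000 * mi,
            condition=f"DMSO-{marker}", **stack_kwargs)
        for h in hours:
            trt = simulate_marker_cohort(
                marker, ly, hours_since=h, n_embryos=n_embryos,
                n_sections=n_sections, seed=seed + 1000 * mi + int(10 * h),
                condition=f"LY-{h}h-{marker}", **stack_kwargs)
            c = ctl.assign(group="control", timepoint_h=h)
            t = trt.assign(group="treated", timepoint_h=h)
            frames.append(pd.concat([c, t], ignore_index=True))
    measurements = pd.concat(frames, ignore_index=True)
    reductions = dm.timecourse_reduction(measurements)
    comparisons = {}
    for (marker, h), sub in measurements.groupby(["marker", "timepoint_h"]):
        a = sub.loc[sub.group == "control", "mean_pct"]
        b = sub.loc[sub.group == "treated", "mean_pct"]
        comparisons[f"{marker}@{h}h"] = mann_whitney_u(a, b)
    return {"measurements": measurements, "reductions": reductions,
            "comparisons": comparisons}


def gli1_rescue_experiment(seed: int = 0,
                           n_embryos: int = 8,
                           n_sections: int = 8,
                           hours_since: float = 10.0,
                           **stack_kwargs) -> dict:
    """Ectopic EGFP-Gli1 experiment on the olig2 domain.

    Conditions: wild-type DMSO control; heat-shock EGFP-Gli1 (DMSO);
    heat-shock EGFP-Gli1 + LY-411575.  Returns per-embryo measurements,
    the enlargement of the Gli1 domain over control (%), the rescue group's
    normalised mean (% of wild-type control maximum), and Mann-Whitney
    comparisons.
    """
    wt = PerturbationSpec()
    gli1 = PerturbationSpec(transgene="EGFP_Gli1", heatshock_time=20.0)
    gli1_ly = PerturbationSpec(transgene="EGFP_Gli1", heatshock_time=20.0,
                               drug="LY411575", drug_start=20.0)
    cohorts = {
        "control": simulate_marker_cohort(
            "olig2", wt, hours_since, n_embryos, n_sections,
            seed=seed + 5000, condition="control", **stack_kwargs),
        "gli1_dmso": simulate_marker_cohort(
            "olig2", gli1, hours_since, n_embryos, n_sections,
            seed=seed + 6000, condition="gli1_dmso", **stack_kwargs),
        "gli1_ly": simulate_marker_cohort(
            "olig2", gli1_ly, hours_since, n_embryos, n_sections,
            seed=seed + 7000, condition="gli1_ly", **stack_kwargs),
    }
    means = {k: float(v["mean_pct"].mean()) for k, v in cohorts.items()}
    norm = dm.normalize_to_control_max(cohorts["gli1_ly"]["mean_pct"],
                                       cohorts["control"]["mean_pct"])
    rescue_norm = float(np.mean([m.pct_normalized for m in norm]))
    enlargement = 100.0 * (means["gli1_dmso"] / means["control"] - 1.0)
    comparisons = {
        "gli1_dmso_vs_control": mann_whitney_u(
            cohorts["gli1_dmso"]["mean_pct"], cohorts["control"]["mean_pct"]),
        "gli1_ly_vs_control": mann_whitney_u(
            cohorts["gli1_ly"]["mean_pct"], cohorts["control"]["mean_pct"]),
    }
    measurements = pd.concat(cohorts.values(), ignore_index=True)
    return {"measurements": measurements, "group_means": means,
            "enlargement_pct": enlargement,
            "rescue_normalized_mean": rescue_norm,
            "comparisons": comparisons}


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig | None = None, outdir=None) -> dict:
    """Execute the configured stages and (optionally) write a report bundle.

    Writes ``results.json``, ``fig_timecourse.csv`` and ``fig_rescue.csv``
    under ``outdir`` when given.  Deterministic: identical configs produce
    identical results.
    """
    config = config or default_config()
    config.validate()
    logger.info("run_pipeline config_hash=%s seed=%d",
                config.config_hash(), config.seed)
    # config.optics drives the lateral-view PHRESH stacks; the morphometry
    # arm images transverse sections at its own Nyquist-sampled defaults
    stack_kwargs = dict(
        geometry=config.geometry,
        noise_template=config.noise,
        cell_spacing=config.cohort.cell_spacing_um,
        embryo_jitter_sigma=config.cohort.embryo_jitter_sigma,
        cell_noise_sigma=config.cohort.cell_noise_sigma)
    results: dict = {"config_hash": config.config_hash(),
                     "seed": config.seed}

    try:
        tc = notch_inhibition_timecourse(
            seed=config.seed, hours=config.timecourse_hours,
            markers=config.timecourse_markers,
            n_embryos=config.cohort.n_embryos,
            n_sections=config.cohort.n_sections, **stack_kwargs)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("timecourse", str(exc)) from exc
    results["timecourse"] = {
        "reductions": tc["reductions"].to_dict(orient="records"),
        "comparisons": {k: vars(v) for k, v in tc["comparisons"].items()},
    }

    if config.include_gli1_rescue:
        try:
            rescue = gli1_rescue_experiment(
                seed=config.seed, n_embryos=config.cohort.n_embryos,
                n_sections=config.cohort.n_sections, **stack_kwargs)
        except Exception as exc:  # noqa: BLE001
            raise StageError("gli1_rescue", str(exc)) from exc
        results["gli1_rescue"] = {
            "group_means": rescue["group_means"],
            "enlargement_pct": rescue["enlargement_pct"],
            "rescue_normalized_mean": rescue["rescue_normalized_mean"],
            "comparisons": {k: vars(v)
                            for k, v in rescue["comparisons"].items()},
        }

    if config.map_t0_grid:
        try:
            smap = phresh_map(pathway=config.map_pathway,
                              t0_grid=config.map_t0_grid, seed=config.seed,
                              geometry=config.geometry,
                              schedule=config.schedule,
                              params=config.reporter, optics=config.optics,
                              cell_spacing=config.cohort.cell_spacing_um)
        except Exception as exc:  # noqa: BLE001
            raise StageError("map", str(exc)) from exc
        results["map"] = {
            str(t0): {
                "dv_above_half_max": pq.above_half_max_extent(e.dv),
                "composition": e.composition,
            } for t0, e in smap.entries.items()}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "results.json").write_text(
            json.dumps(results, indent=2, default=float))
        tc["measurements"].to_csv(outdir / "fig_timecourse.csv", index=False)
        if config.include_gli1_rescue:
            rescue["measurements"].to_csv(outdir / "fig_rescue.csv",
                                          index=False)
        config.to_yaml(outdir / "config.yaml")
    return results
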
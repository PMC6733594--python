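# Methods

This note documents the models behind `phresh`: what the synthetic embryo
simulates, what the measurement chain assumes, which parameters matter,
and where the design was genuinely open.

## Ground-truth activity model

Each cell carries a position (`dv_frac` ∈ [0,1] ventral→dorsal,
`ml_frac` ∈ [0,1] across the mediolateral width, `ap_um` along the body
axis) and a tissue label (`spinal_cord`, `somite`, `vasculature`).
Pathway activity is a deterministic function
`a(cell, t, condition) ∈ [0, 1]` built from three phases
(activation 24–42 hpf, consolidation 42–66 hpf, termination 66–78 hpf;
configurable via `PhaseSchedule`).

**Notch (her12 readout).** Uniform along DV within the cord during
activation, modulated only by a mild lateral fall-off
`1 − 0.3·(2|ml−0.5|)⁴` so the ML profile peaks medially. During
consolidation the active region contracts linearly onto the medial band
1.5 cell diameters tall directly dorsal to the canal (canal at
`canal_dv_frac = 0.3`, a free choice — the canal sits ventral of centre);
during termination the level relaxes linearly to the basal level by 72
hpf. Outside the cord Notch response is basal, except that constitutive
Smo activation (rSmoM2) raises it in the vasculature, where the pathway
hierarchy is inverted.

**Hedgehog (ptc2 readout).** During activation the cord response is
graded: a ramp from 1.0 at the ventral edge to 0.5 at
`dv_frac = 0.75`, and basal above. This particular shape was an open
choice — the observational anchor is "graded, active over the ventral
~75%"; the ramp-to-half form is the simplest monotone gradient whose
above-half-maximum extent equals the active extent, so the profile
measurement reads back exactly the domain that was planted. A linear
ramp to zero would instead put the half-max point at 37.5% of the axis
and make "active extent" and "above-half-max extent" two different
quantities. Consolidation and termination mirror Notch with a slight
delay (medial domain persists to 72 hpf, basal by 78 hpf). Somites
(level 0.7) and vasculature (0.5) respond independently of the cord.

**The Notch→Hh gate.** In the cord, Hh activity is multiplied by a gate
`g = min(notch_level, 2^(−Δt_off/0.8 h))`, where Δt_off counts hours
since Notch inhibition began; the exponential term gives the fast
cell-autonomous loss of Hh competence (half-time 0.8 h, chosen so the
1 h domain endpoint matches the planted trajectory), while the explicit
`notch_level` argument lets callers probe the gate directly. The full
form is

    level = basal·min(1, g/basal) + (base − basal)·g

so `notch_level = 0` forces exactly zero (as after γ-secretase
inhibition, mindbomb mutation, or rbpja/b knockdown), while the
unperturbed termination state settles at `basal` rather than `basal²`.
Somite and vasculature responses ignore the gate — the coupling is
tissue-specific.

**Perturbations.** LY-411575 ramps cord Notch response to 0 linearly
over 4 h from drug addition; mindbomb is equivalent to LY from t = 0.
Cyclopamine ramps cord Hh down to a residual floor of 0.1 over 4 h
(Smo-independent Gli1 transcription persists) and abolishes the somite
response. NICD raises cord Notch to maximum after heat shock. rSmoM2
raises Hh response to maximum everywhere — except in Notch-off cord
cells, where it is fully blocked. EGFP-Gli1 adds a Notch-independent
cord drive of 0.63, capped below the unperturbed maximum. The iguana
(cilia-less) genotype replaces the cord gradient with a uniform
Smo-independent level of 0.3, still subject to the Notch gate.

**Heterogeneity.** The pure field functions are deterministic; the
`ActivityField` wrapper multiplies each cell by a fixed, seeded
lognormal factor (σ = 0.1, clipped into [0,1]) to reproduce the
salt-and-pepper variability of real reporter embryos. The default
wrapper is noise-free so that field-level evaluations are exact.

## Marker-domain trajectories

Domain fractions of the cord cross-section, used to paint stains:

- control fractions: ptc2 0.75 (the ventral response domain), sox2 0.80
  (medial progenitor band — the control extent is not observed directly,
  only its relative reductions, so 0.80 is a fixed choice), olig2 0.10
  (a single motor-neuron-precursor tier centred at dv_frac 0.2).
- Notch-inhibition reductions, linearly interpolated between knots:
  ptc2 {1 h: 44%, 2 h: 50%, 3 h: 65%, 10 h: 100%}; sox2 {1 h: 10%,
  2 h: 50%, 3 h: 65%, 10 h: 100%}; olig2 {3 h: 50%, 10 h: 100%}
  (long-time knots fixed by the complete loss seen after 10 h).
- ectopic activation (rSmoM2, EGFP-Gli1, iguana; DMSO background):
  ptc2/olig2 × 1.25, capped at 1.0.
- EGFP-Gli1 + Notch inhibition: olig2 at 63% of wild type (constant —
  only the 10 h endpoint is constrained); ptc2 restored to the control
  level; rSmoM2 and iguana cannot bypass the block.
- cyclopamine: ptc2 reduced 70% by 4 h, not abolished.

Whether the Notch-off decay is truly cell-autonomous and exponential is
not knowable from domain-level endpoints; the model commits to the
simplest interpolation consistent with them.

## Reporter kinetics

`dG/dt = α·a(t−lag) − δ·G`, `dR/dt = −δ·R`, integrated with the exact
exponential update for piecewise-constant activity (default dt 0.05 h;
0.1 h for map-scale simulations). Defaults: α = 10 a.u./h per unit
activity (scale-free — all readouts are normalised), δ = ln2/24 h⁻¹
(Kaede is long-lived; a 24 h half-life lets converted red perdure across
the 6 h imaging window), maturation lag 0 h, conversion efficiency
η = 1.0 (the two-pass UV protocol is designed for complete conversion;
lower η is exposed for sensitivity tests), detection floor 1 a.u.
None of the kinetic rates are measured quantities; they are placeholders
with the right orders of magnitude, and the history-classification
logic is insensitive to them by construction (red after t₀ descends
only from pre-t₀ synthesis when η = 1).

## Image synthesis

Cells deposit their channel amounts at the nearest voxel of a
lateral-view grid (axes Z=ML, Y=DV with ventral at 0, X=AP; ventral/ML
padding 2 µm); the deposit volume is blurred with a Gaussian PSF
(sum-preserving), scaled by the photon gain (50 counts/a.u.), Poisson
shot noise and Gaussian read noise (σ = 2 counts) applied, then the
background offset added. With noise off the renderer is linear.
Each embryo's grid is offset by a uniform sub-voxel amount — a mounted
embryo is never aligned with the voxel raster — which also dithers
edge-pixel rounding so planted domain boundaries are recovered without
grid-phase bias. Reslicing to transverse sections is a pure axis
permutation, as with the Fiji reslice operation.

Default optics are 1 µm isotropic voxels with a 1 µm PSF sigma for
lateral PHRESH stacks. The morphometry arm images its transverse
sections at 0.5 µm in-plane sampling with a 0.5 µm PSF
(`MORPHOMETRY_OPTICS`) — high-NA confocal of cryosections — because the
olig2 band is only one cell tier (3–6 µm) tall and a broader PSF
attenuates and widens it enough to bias domain ratios.

## PHRESH quantification

Per stack: background = modal intensity (integer-resolution histogram
mode); reference = 99.9th percentile (robust stand-in for the maximum;
`mode="max"` available) of background-subtracted green in the
unconverted AP region. DV profiles average three vertical lines through
and flanking the canal (spacing one cell diameter — the protocol does
not state a spacing); the ML profile is one line a cell diameter dorsal
to the canal; one section per somite over five somites is averaged.
Because all lines share the per-stack reference, averaging before or
after normalisation is equivalent; profiles are resampled to a common
101-point fractional grid so embryos of different pixel sizes can be
combined. Classification threshold: 10% of the reference (the original
readout is visual presence/absence; 10% sits well above noise and well
below active-domain levels). Plots render intensity axes 0–50% by
convention.

## Domain morphometry

`segment_expression` offers fixed and Otsu thresholding per the module
contract. The pipeline's cohort measurement uses a per-stack variant
tuned for high-contrast stains on grainy cell-scale images
(`measure_marker_stack`):

1. smooth only along directions parallel to the marker's anatomical
   band (ML+AP for the DV-banded ptc2/olig2, DV+AP for the ML-banded
   sox2; 2 µm in-plane, 4 µm along AP) — at cell-scale sampling a PSF
   volume holds roughly one cell, and edge-normal smoothing would widen
   single-tier domains;
2. split stained from unstained pixels by Otsu on log-intensities
   (robust even when one class dominates the histogram); declare "no
   domain" if the two modes are closer than a factor e;
3. estimate the interior stain level as the median over the stained
   mask eroded by ~1 µm, so PSF-attenuated boundary pixels do not drag
   it down;
4. threshold the sections at half that level — a symmetric blurred edge
   crosses half its local plateau exactly at the true boundary;
5. exclude a 2 µm margin along the band-parallel cord boundary from
   numerator and denominator (domains span the cord fully there, so
   the fraction is unchanged while boundary-mixing pixels drop out).

On noiseless renders this recovers planted fractions within ~1
percentage point across the 6–80% range, and its residual gain factor
is width-independent, so control-normalised ratios are unbiased.
Cohort defaults are 8 embryos × 8 sections per condition (midpoints of
the 6–10 sections / 7–8 embryos protocol), sections drawn from the
central five-somite trunk window, per-embryo domain-fraction
variability lognormal σ = 0.03 (enough scatter for meaningful group
statistics while group means of 8 resolve 5-point differences).

## Statistics

Mann-Whitney U via `scipy.stats.mannwhitneyu`: exact when the pooled
sample is ≤ 16 and tie-free, otherwise the normal approximation with
continuity and mid-rank tie correction; two-sided p doubles the smaller
tail, capped at 1. The test suite checks the exact path against a full
enumeration of rank arrangements. Stars follow the printed convention
(*** iff p < 0.001, ** iff 0.001 ≤ p < 0.01, half-open exactly); an
optional `*` band for 0.01 ≤ p < 0.05 exists behind
`include_single_star` but is off by default, because the default
annotation contract fixes p = 0.01 → "ns". No multiple-testing
correction is applied (per-comparison stars); group tables report
mean ± sample SD (n−1), SD absent for singleton groups.

## What the generator does and does not emulate

Simulated: the three-phase spatiotemporal dynamics of both pathways,
their tissue-specific coupling, reporter protein kinetics around a
photoconversion event, confocal blur and photon noise, cell-to-cell
expression variability, inter-embryo variability, and all perturbation
endpoints listed above. Not simulated: cell movement, division and
lineage (populations are static), lateral-inhibition Delta-Notch
dynamics, a mechanistic Gli transcription model, chromogenic in-situ
colorimetry (marker stains are rendered with the same fluorescence
optics as the reporter), depth-dependent attenuation, bleed-through
(available as an optional robustness knob only conceptually — kinetics
carry no spectral mixing), and manual domain outlining (thresholding
stands in for the operator; the paper's boundaries were drawn by hand).
Passing tests therefore demonstrate that the measurement chain recovers
planted truth under realistic imaging statistics — not that it would be
robust to morphogenesis, registration error, or stain chemistry, which
real data add on top.

## Numerical choices and degenerate inputs

Exponential-integrator reporter steps are exact for piecewise-constant
activity; activity is sampled at step starts. Photoconversion conserves
green+red to machine precision. Renders clip negative read-noise
excursions at zero. Profile resampling is linear interpolation onto the
common grid. Empty reference regions, fully-converted stacks, empty
cord masks, domain pixels outside the cord, empty control groups and
mismatched profile grids raise typed errors (`InvalidParameterError`,
`NoReferenceError`, `ContractViolationError`); section counts outside
6–10 warn but proceed. All randomness descends from explicit seeds;
identical configs produce identical results.
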
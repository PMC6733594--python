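# phresh

Simulation and quantification of **PHRESH** (PHotoconvertible REporter of
Signalling History) experiments in the developing zebrafish spinal cord.

## The problem

During spinal cord patterning, Notch signalling maintains neural
progenitors while a ventral Hedgehog (Hh) gradient assigns ventral fates.
Both responses are dynamic: a *signalling activation* phase (24–42 hpf,
Notch response uniform along the dorsoventral axis, Hh response graded over
the ventral ~75% of the cord), a *consolidation* phase (42–66 hpf, both
domains shrink onto a medial band 1–2 cell tiers dorsal to the spinal
canal), and a *termination* phase (66–78 hpf, return to basal levels).
Crucially, the two pathways are coupled: in the spinal cord — but not in
somites or vasculature — Notch activity is required for cells to respond to
Hh at all, acting at the level of the Gli transcription factors.

The PHRESH readout makes these dynamics visible in vivo: a transcriptional
reporter drives the green-to-red photoconvertible protein Kaede
(*ptc2:Kaede* reads Hh response, *her12:Kaede* reads Notch response).
Photoconverting at a chosen time t₀ and imaging 6 h later separates
signalling history per cell:

| channels at t₀ + 6 h | history |
|---|---|
| green only | **new** response, begun after t₀ |
| red only | **past** response, ended before t₀ |
| green + red | **continued** response through t₀ |
| neither | no response |

This package implements the complete measurement chain as tested,
reusable code — and, because the underlying micrographs are not available
as raw data, a synthetic-embryo generator that plants known ground truth
so that every stage of the chain is verifiable end to end:

- `phresh.synthetic_embryo` — cord geometry, cell populations, per-pathway
  activity fields `a(cell, t, condition) ∈ [0, 1]` for the three phases,
  the Notch→Hh gate, drug/transgene/genotype perturbations, and planted
  marker-domain trajectories (*ptc2*, *sox2*, *olig2*).
- `phresh.reporter_kinetics` — Kaede kinetics
  `dG/dt = α·a(t) − δ·G`, `dR/dt = −δ·R`, with instantaneous conversion
  `G → (1−η)G, R → R + ηG` at t₀ (exact exponential-integrator steps).
- `phresh.image_synthesis` — Gaussian-blob rendering into two-channel 3D
  lateral stacks (Z=ML, Y=DV, X=AP) with Poisson + read noise; lossless
  transverse reslicing; TIFF + JSON-sidecar I/O.
- `phresh.phresh_quant` — normalisation to the unconverted-region green
  maximum, three-line DV profiles through the canal, the ML profile dorsal
  to the canal, five-somite averaging, response-history classification,
  and the spatiotemporal map over a grid of t₀ values.
- `phresh.domain_morphometry` — expression-domain segmentation, domain
  area as % of the cord cross-section, per-embryo means over 6–10
  sections, normalisation to the DMSO "control maximum", timecourse
  reductions.
- `phresh.stats_report` — Mann-Whitney U (exact for small tie-free
  samples), ** / *** star annotation, mean ± SD group tables.
- `phresh.pipeline` / `phresh.cli` — end-to-end recipes and the `phresh`
  command-line tool (`simulate | profiles | domains | compare | run`).

## Worked example

The Notch-inhibition timecourse: simulate 8 embryos per condition (DMSO
control; the γ-secretase inhibitor LY-411575 for 1 h or 2 h), render 8
transverse sections each, segment the *ptc2* and *sox2* domains, average
per embryo, and normalise to the DMSO group mean:

```python
from phresh.pipeline import notch_inhibition_timecourse

out = notch_inhibition_timecourse(seed=1, hours=(1.0, 2.0))
print(out["reductions"].to_string(index=False))
```

prints

```
marker  timepoint_h  control_max  normalized_mean  reduction_pct
  ptc2          1.0    73.703613        56.661035      43.338965
  ptc2          2.0    73.703613        49.860545      50.139455
  sox2          1.0    79.498556        90.677491       9.322509
  sox2          2.0    79.498556        49.677678      50.322322
```

Reading the table: the DMSO *ptc2* domain covers ~74% of the cord
cross-section; after 1 h of Notch inhibition the treated group retains
only 56.7% of the control maximum — a 43.3% reduction — while *sox2* has
barely moved (9.3%). By 2 h both domains are down ~50%. The Hh response
collapses *before* the neural progenitor state is lost, the signature of
Notch acting upstream of Hh response rather than through differentiation.
Each comparison carries a Mann-Whitney U test
(`out["comparisons"]["ptc2@1.0h"]` → U=64, p=1.6e-4, \*\*\*).

The same cohorts are available from the shell:

```bash
phresh run --seed 1 --out results/      # timecourse + Gli1 rescue bundle
phresh simulate --mode phresh --t0 30 --out stack.tif
phresh profiles --stack stack.tif --out profiles.csv
```

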
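# Methods

## The measurement problem

In the Rd1 mouse, rod death is followed by a slow secondary loss of
cones. Wholemount immunofluorescence against the two cone opsins
(S-opsin imaged in the red channel, M/L-opsin in green) shows three cone
classes in the merged image — genuine S (red), genuine M/L (green) and
dual cones expressing both opsins (yellow) — and the classic readout is
thresholded pixel *area* per class, not cell counts. This package
implements that analysis chain as code, and pairs it with a synthetic
scene generator whose presets carry the published composition, survival,
microglia and expression values as ground truth. Validation is by
parameter recovery: the pipeline run end-to-end on synthetic scenes must
return the encoded values within tolerance.

## Synthetic retina generator

**Cone mosaic.** Cone centres follow a hardcore point process (random
sequential adsorption, minimum centre-to-centre spacing 8 µm), matching
the exclusion zone of cone somata. The expected count is
`cone_density × soma_survival × field area`, realized as a Poisson draw
truncated at the RSA packing ceiling (≈ 0.52 coverage); analyses that
compare *mean* areas can pin counts at their expectation with stochastic
rounding. Wild-type-equivalent density defaults to 10,000 cones/mm²
(the order of magnitude of published mouse cone densities; only
fractions and ratios are validated quantities, not absolute counts).
Type labels are i.i.d. multinomial in the preset composition;
outer-segment presence is Bernoulli in `segment_survival`.

**Rendering.** Somata are ovoid Gaussian blobs (axes ≈ 8 × 6 µm, peak
≈ 90 on the 8-bit scale over a background of 10); surviving outer
segments are narrow blobs (5 × 2 µm) at 2.5× the soma amplitude,
centred on their own soma (en-face projection) with 1 µm jitter —
keeping them inside the cone's exclusion zone so neighbouring cones of
different types do not blend into false "dual" pixels. A dual cone
shares one overall brightness jitter (0.85–1.15) between its channels
and only the secondary channel is attenuated (0.80–1.0): this bounds the
pixel hue inside the yellow window *and* makes the brightness profile
max(S, M/L) identically distributed across cone types, so thresholded
area per cone carries no class bias (independent per-channel jitter
would make dual cones statistically brighter and inflate their area
share by several points). Each channel is multiplied by its own smooth
illumination field — a random quadratic surface with ±25% amplitude by
default (the two channels are separate exposures) — and Gaussian noise
(sd 4) is added.

**Compositions.** Printed triples that do not sum to 100% (P14 superior
94.1%, P60 nasal 88.1%, P60 temporal 112%) are renormalized to a proper
distribution; the raw triple is retained in `composition_raw` and the
P14-superior recovery check is read on the raw scale with an extra point
of tolerance. The P60 quadrant presets encode the published total-area
ratios (inferior ≈ 3× the other quadrants) as relative `soma_survival`
scalers anchored at 0.10 for the inferior quadrant — deliberately sparse,
because the pixel-area readout is only proportional to cell number when
blob footprints rarely interact, and the ratio (3.05 encoded) leaves
little margin for density-dependent bias.

**Microglia scenes.** Wholemount scenes draw a Poisson number of Iba1+
cells (default 150/mm² at P21, scaled by the published 67% and 33.9%
remaining at P60/P300 — the absolute wholemount density is not a
published quantity). An *activated* cell is a compact amoeboid blob
co-labeled in the CD68 channel; a quiescent cell is a dimmer soma with
3–6 thin radial processes and no CD68. Transverse strips are 2 mm long
with cells placed in a 100 µm ONL band at the preset linear density,
plus ~20% quiescent cells below the band that a correct band restriction
must exclude.

**Ct tables.** Under exponential amplification with per-cycle efficiency
E, a transcript at relative level L crosses threshold
`log_E(L)` cycles early: `Ct = baseline(gene) − ln(L)/ln(E) + N(0, sd)`.
Reference genes sit at level 1 in every group. Expression presets anchor
both opsins at 16% of the wild-type level at P90; intermediate
timepoints are a roughly linear decline chosen once for illustration
(only the P90 value is validated).

## Quantification chain

**Flat-fielding.** Retrospective correction divides by a degree-2
polynomial surface fitted to the background with iterative sigma
clipping (bright labeled pixels are excluded from the fit), then
rescales to the input mean. The polynomial model is exact for the
linear/quadratic gradients of slide illumination and has none of the
edge bias of windowed low-pass filters; a heavy Gaussian low-pass
(kernel 25% of the image diagonal) remains available via
`flatten_method="gaussian"`. Flattening is idempotent to < 1% RMS.

**Channel matching.** The two opsin channels are brought to
"approximately the same labeling intensity" by equalizing the *median
per-cell peak* brightness, not a global percentile: a global percentile
confounds per-cell brightness with label abundance and would, e.g.,
amplify the almost-empty M/L channel of the P60 inferior quadrant into
its noise floor. A channel without credible signal (upper tail
indistinguishable from median + 6 MAD-sigma) is left untouched and
flagged.

**Quantization for hue work.** Both channels are median-filtered
(radius 1) and linearly stretched to 8 bits using a *shared* white point
(pooled upper percentile) and a black point at the pooled histogram
mode, i.e. the background level. The shared scale is what preserves the
red/green balance — per-channel stretches would recolor dual cones —
and anchoring black at background maps unlabeled pixels to ~0 so
pure-colour pixels keep extreme hues.

**All-cone mask and compartments.** Within-field classification uses
Otsu brightness thresholding on the per-pixel channel maximum (a fixed
threshold can be configured; the chosen cut is recorded in result
metadata). The outer-segment/soma split is a 3-class Otsu in the *log*
intensity domain restricted to the mask (fluorescence tiers are roughly
log-normal; linear-domain Otsu parks the cut far above the valley), and
the top class is accepted as segments only when its median exceeds 1.6×
the median of the class below — otherwise the field has no segment tier
(all segments degenerated) and every cone pixel is a soma pixel. The
split runs on an unfiltered copy of the raster because a median filter
erases the 1–2 px segment ridges it is meant to isolate.

**Hue classification.** Merged RGB is R = S-channel, G = M/L-channel,
B = 0, so hue lives on the 0–85 arc of the 0–255 wheel. Hue windows
default to red [0, 21] ∪ [234, 255], yellow [22, 63], green [64, 160]
(pure red 0, balanced yellow 42, pure green 85 all mid-window); windows
are validated as pairwise disjoint and fully configurable, since the
original operator-chosen windows are unrecoverable. Saturation and
brightness stay at full range — brightness selection already happened in
the mask. Classification is pixel-wise; fractions are computed over the
classified area with the unclassified remainder reported. Class areas
plus unclassified equal the mask area exactly, and swapping the two
channels of a noise-free field maps p_S ↔ p_ML exactly (hue mirror about
42.5).

**Cross-field area comparisons.** Survival series and quadrant ratios
compare areas *between* fields, where adaptive per-field thresholds
would compress genuine density differences. These analyses therefore
flatten each channel, denoise with a small Gaussian (σ 0.8 px), combine
by per-pixel maximum and apply one fixed brightness cut (40) to every
field, with a fixed segment cut (140) on the unsmoothed scale. The
per-channel denoise before the maximum matters: max of two *noisy*
channels is upward-biased exactly where both carry label (dual cones),
which would inflate dual-rich quadrants. Soma survival is read from the
somata compartment — segments inflate early-timepoint whole-cone areas,
the same reason cell bodies are only measured from P21, while segments
are referenced to P14.

**Microglia counting.** Iba1 cells are particles (8-connected, 20–5000
px²) above a robust threshold (Otsu floored at median + 6 MAD-sigma; a
blank channel yields zero detections rather than an Otsu cut through
noise). A cell is CD68+ when ≥ 30% of its pixels exceed the CD68
threshold — the published analysis counts double-labeled cells without
stating a rule, so the fraction is configurable. The optional morphology
index (4π·area/perimeter², amoeboid when ≥ 0.6) never gates counting.

**Relative expression.** Pfaffl-style per-gene efficiency correction
with the calibrator-group mean Ct as anchor; the two reference genes are
pooled as a geometric mean of their per-gene factors (the pooling rule
is our construction). Group RQ is the arithmetic mean of per-sample RQ,
renormalized so the calibrator group is exactly 1 (matching mean ± SEM
bar-graph conventions). RQs are invariant to any global Ct shift and to
reference-gene shifts common to all samples; with zero Ct noise the
simulate→quantify round trip reproduces preset levels to machine
precision. Unmeasured efficiencies default to 2.

## Problem sizes and tolerances

Composition recovery runs 5 fields of 526.5 × 422.5 µm at 1 µm/px per
preset and recovers every catalogued composition within ±5 points
(seed-averaged; ±6 on the un-renormalized P14-superior scale). The
quadrant ratio uses 8 expectation-pinned fields per quadrant
(measured 3.05 ± 0.01 encoded vs the ≥ 3 criterion). Survival-curve
recovery uses reduced 360 × 270 µm fields at 20% density (±0.07
absolute). Microglia recovery uses 5 scenes per condition (±5 points on
activated fractions, ±10% on linear density); qPCR uses n = 6 per group,
E = 1.95, Ct sd 0.15 (recovers 0.16 ± 0.02).

## What the generator does and does not emulate

It reproduces the features the quantification chain is sensitive to:
two intensity tiers (segment vs soma), bounded dual-cone hue, smooth
multiplicative illumination, additive noise, hardcore mosaic geometry,
amoeboid-vs-ramified microglia morphology and exponential qPCR noise.
It does not model optics (PSF, defocus), photobleaching, RPE debris and
dissection artefacts, rods, retinal curvature or relaxation cuts,
antibody penetration gradients, or spatially continuous dorsoventral
opsin gradients within a field (the gradient is encoded at quadrant
resolution, since quantification fields are small relative to it).
Passing recovery tests therefore demonstrates the correctness and
internal consistency of the measurement chain, not robustness to every
artefact of real wholemounts.

## Known limitations

- Area-based composition is blind to per-cell opsin stoichiometry; a
  dual cone with a 4:1 opsin ratio would fall outside the yellow window
  by design (window edges are at amplitude ratio ≈ 0.52).
- Touching cells are not declumped; counts (microglia) rely on the
  hardcore spacing of the generator and a size filter rather than
  watershed splitting.
- The fixed cross-field cuts (40/140) are calibrated to the generator's
  8-bit-scale amplitude model; real data need the cuts chosen once per
  staining batch.
- Survival SEM treats seeded fields as independent replicates
  (generator seeds stand in for animals); there is no animal-level
  random effect.
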
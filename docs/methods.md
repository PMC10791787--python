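# Methods

This note documents the models, parameters and numerical choices behind
`microcal`, and what the synthetic benchmarks do and do not establish about
performance on real imaging data.

## Spontaneous transient detection

### Signal model

A recording is a raw fluorescence trace per ROI (soma or single process) at
a fixed frame rate — 1 Hz for GECI (GCaMP-class) imaging, 0.2 Hz for
dye-filled (Fluo-4-class) recordings — typically 5 min long. The trace is
modelled as

    F(t) = F0(t) · (1 + s(t)) + ε(t)

where F0(t) is a slowly varying baseline (specimen drift, slow volume
changes), s(t) is the Ca²⁺ signal in ΔF/F units and ε is frame noise.

### Baseline estimation

The baseline is a PCHIP (piecewise cubic Hermite interpolating polynomial)
through robust local summaries of non-event frames:

1. **Initialisation** — grayscale opening (running minimum then maximum,
   mirror boundaries) of the raw trace with a window of `smooth_frames/3`.
   An opening cannot be dragged upward by piled-up transient tails (a
   running median can, once tails fill more than half a window) and is
   slope-neutral on smooth drift (a bare running minimum is not).
2. **Knot fit** — knots every `smooth_frames/4` frames; each knot is the
   median of the non-excluded frames within a centred window of half-width
   `smooth_frames/4`, anchored at the **median included frame index** (if
   an excluded event empties one side of the window, the summary describes
   the other side and is anchored there). The total temporal support per
   baseline point is therefore on the order of the nominal 100-frame
   smoothing time. Beyond the outermost usable knots the baseline is
   extended linearly with the interpolant's endpoint slope — cubic
   extrapolation can overshoot across a dropped edge window, while a
   constant hold loses genuine drift at the recording boundary.
3. **Iteration** — frames with ΔF/F ≥ 0.10 against the current baseline are
   excluded and the fit repeated until the exclusion set is stable (at most
   `max_baseline_iterations`, default 10). The 0.10 cutoff keeps transient
   contributions out of the baseline and out of its SD.
4. **Residual re-baselining** — one final pass fits the same windowed-median
   PCHIP to the quiescent ΔF/F itself and folds it into the baseline,
   cancelling to second order whatever smooth structure the knot fit missed
   (for example curvature bridged across an event gap). On a flat,
   well-fitted trace the correction is identically zero.

If the exclusion rule rejects every frame, the baseline falls back to the
global median and the result is flagged (`used_fallback`).

Accuracy at the defaults: a noiseless 10 % sinusoidal drift with a 300 s
period on a 5-min, 1 Hz trace is tracked to < 0.2 % relative error; the
tests assert < 1 %.

### Event criteria

Candidate events are maximal runs of frames with
ΔF/F > `sd_multiplier` × `baseline_sd`, where `baseline_sd` is the SD of
ΔF/F over the quiescent frames (those with ΔF/F < 0.10) and
`sd_multiplier` = 2.25. Each event must pass the area criterion
∫ΔF/F dt > 0.15 (ΔF/F·seconds, so the rule behaves consistently at 1 Hz and
0.2 Hz), integrated over the run itself. Events whose peak frame appears in
the ROI's veto list are dropped — the veto list is the auditable stand-in
for the study workflow's manual false-positive rejection, keeping the
automated path fully deterministic.

Two refinements group noisy runs into events:

- **Hysteresis** — a run ends only once ΔF/F falls below
  `release_fraction` (0.5) × threshold. Without it, an event's own decaying
  tail re-crosses the threshold on noise and spawns spurious "events"; at
  the benchmark noise level this was the dominant false-positive source.
  Hysteresis is active only when `baseline_sd` > 0 (on noiseless traces the
  threshold is already at the noise floor).
- **Valley splitting** — within a run, two local maxima are distinct events
  when the valley between them drops below `split_valley_fraction` (0.5) ×
  the smaller peak, both peaks rise at least `split_min_rise_sd` (4) ×
  the frame-to-frame noise scale above the valley, and the later peak is
  itself event-sized (at or above the detection threshold). The decision is
  made on chord-corrected excess fluorescence ΔF = F − F0: ΔF/F shapes are
  tilted by a factor 1/(1+drift) under additive drift, whereas ΔF is
  drift-invariant, and subtracting the chord through the run's boundary
  values also cancels residual baseline error across the event. Ratios of
  ΔF are scale-free, so detection remains invariant to rescaling the raw
  fluorescence. The noise scale used by the rise gate is estimated from
  successive differences of quiescent ΔF/F (divided by √2), which cancels
  the smooth event tails that inflate the plain quiescent SD.

A consequence of the event criteria being threshold rules on continuous
data: two transients closer together than roughly the indicator decay time
produce a single suprathreshold footprint and are reported as one event.
The recovery benchmarks therefore distinguish *matched* events (onset
paired one-to-one within ±2 frames) from *covered* events (onset inside a
detected event's footprint); sensitivity counts both, false positives count
detections that are neither paired with nor contain any injected event.
Event-rate estimates from detection consequently undercount slightly at
higher rates (overlapping events merge); the cohort benchmarks show the
effect (for instance ~0.37 recovered at a true 0.44 events/min).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `smooth_frames` | 100 | frames | baseline smoothing time |
| `sd_multiplier` | 2.25 | — | detection threshold in quiescent SDs |
| `baseline_dff_cutoff` | 0.10 | ΔF/F | quiescence / exclusion cutoff |
| `min_area` | 0.15 | ΔF/F·s | minimal event integral |
| `max_baseline_iterations` | 10 | — | exclusion refits |
| `release_fraction` | 0.5 | — | hysteresis release (× threshold) |
| `split_valley_fraction` | 0.5 | — | valley depth for event splitting |
| `split_min_rise_sd` | 4.0 | noise SDs | significance gate for splitting |

The first five express the published detection recipe; the last three are
robustness mechanisms of this implementation, validated on the synthetic
benchmarks below.

## Evoked responses

ΔF/F = (Fₜ − F₀)/F₀ with F₀ the mean of the pre-lesion baseline (20 s at
1 Hz by default); the peak is the raw maximum over all post-lesion frames
(no smoothing, no search window — reported latencies are ~1 s, so a window
is unnecessary) and no drift correction is applied to these short
recordings. Cells closer than 30 µm to the lesion are rejected as directly
damaged. Group summaries report mean ± SEM of peak ΔF/F and
percent reduction = 100 × (1 − mean_group/mean_reference); a zero reference
mean flags the reduction as undefined rather than raising.

## Sholl morphometry

Edges of the SWC reconstruction (child node of type process) are clipped
against spheres of radius `soma_radius + k·step` (defaults 5 µm + k·5 µm)
centred on the analyst-established cell centre. Crossing parameters come
from the segment–sphere quadratic; each sub-segment's arc length is binned
by its midpoint distance. Shells are half-open [r, r+step) — boundary
points belong to the outer shell — and everything inside the soma radius is
discarded (the soma is assumed to occupy 5 µm so Iba1 signal variation
within it is not mistaken for processes). Dense sampling of each edge at
0.01 µm is retained as a test oracle only; the analytic path agrees with it
to < 0.1 % of total length and conserves total length exactly under shell
refinement.

Ramification is reported as bifurcation nodes per shell (a node with c ≥ 2
children counts c − 1, the root is excluded); classic Sholl intersection
counts per sphere are also computed (`intersections_per_shell`) since the
literature uses both conventions, but branch points are the default.

Surface-area normalisation uses the idealised compartment geometry: sphere
4πr² = 707 µm² for the soma (r = 7.5 µm), lateral cylinder 2πrl = 71 µm²
for a process ROI segment (r = 0.75 µm, l = 15 µm) — a ~10-fold area ratio,
which cannot explain a higher per-process event rate.

## Lysosomal burden

The rolling-ball background is implemented as grayscale opening with a flat
disk footprint (radius 10 px for Iba1 and CD68, 80 px for the coarser Aβ
channel); the result is image − background clipped at zero, idempotent on
flat-background inputs. Thresholding is Otsu's method by default with a
fixed-intensity override, both recorded in the run metadata; a
single-intensity image yields an empty, flagged mask. Coverage is
100 × |Iba1 ∧ CD68| / |Iba1|, undefined (flagged) on an empty Iba1 mask.
Plaque proximity compares the Euclidean distance from the ROI centroid to
the nearest plaque-mask pixel against a 50 µm cutoff; the centroid is used
rather than the nearest cell pixel for determinism, and plaque regions are
an input mask (identifying them — e.g. from microglial clustering — is
upstream of this package). Areas are computed per field; a label mask can
restrict them per cell.

## Rank-based tests

`rank_sum_test` enumerates the full null distribution of the rank sum over
all C(n_a+n_b, n_a) label assignments when n_a+n_b ≤ 12 (midranks for
ties); the two-sided p doubles the smaller tail probability, capped at 1.
`paired_signed_rank_test` drops zero differences (recorded), then
enumerates all 2ⁿ sign assignments for n ≤ 15. Larger samples use normal
approximations with tie-corrected variance and 0.5 continuity correction.
Both exact branches are verified in the tests against independent
enumeration oracles and scipy; simulated type-I error at α = 0.05 sits in
[0.03, 0.07] at the benchmark sizes. ANOVA-family omnibus comparisons are
delegated to scipy behind `omnibus_test`; post-hoc families are left to
dedicated statistical packages.

Paired per-cell comparisons average a cell's process rates into one value;
cells with zero somatic rate carry an undefined ratio but remain usable by
the difference-based paired test. Fold changes are reported from group
means (a per-cell median ratio is also available), since the two differ
when somatic rates are near zero.

## Synthetic data: what it emulates, and what it does not

`generate_trace` produces F0·(1 + drift + Σ amp·kernel) + noise with a
difference-of-exponentials kernel normalised so the injected amplitude is
the peak ΔF/F, homogeneous-Poisson event times, a single low-frequency
sinusoidal drift (plus optional linear term), and white Gaussian noise.
Defaults: 5 min at 1 Hz, τ_rise = 2 s, τ_decay = 8 s, amplitude
0.5 ± 0.1 ΔF/F, noise SD 0.02, drift 5 % of F0 with a 300 s period —
realistic for somatic GECI recordings of microglia, with event rates set
per benchmark inside the observed 0.04–0.6 events/min range. An optional
indicator-saturation map (Hill binding with K_d 0.46 µM, ~30-fold dynamic
range) is off by default; ground truth is always stated in linear ΔF/F.

Not emulated: pixel-level movies (ROIs are simulated directly, so motion
artefacts, neuropil contamination and ROI-drawing variability are outside
the benchmarks), photobleaching, non-Gaussian shot noise, bursty or
refractory event statistics, and amplitude/kinetics heterogeneity between
compartments. Passing benchmarks therefore demonstrate correctness of the
algorithms under the stated signal model, not performance bounds on any
particular microscope's data.

`generate_tree` grows each primary process outward in exponential-length
segments with angular jitter and a mild radial bias (microglial processes
grow roughly centrifugally; the bias also bounds the random walk), with a
per-µm branching probability and a hard extent limit. The
`deramification` factor then prunes non-primary subtrees with probability
0.7·d and shrinks coordinates radially by (1 − 0.5·d), so total process
length decreases strictly and monotonically with d for a fixed seed —
emulating the amoeboid transformation near plaques without claiming
biophysical realism of the branching statistics.

`generate_mask_pair` renders an Iba1 mask as a union of random disks and
takes the CD68∩Iba1 set as exactly the requested fraction of Iba1 pixels
(spatially contiguous around a random focus) plus a disjoint CD68-only
blob, so the recorded true coverage is an exact pixel count and the full
rolling-ball + Otsu pipeline can be checked against it to rasterisation
accuracy.

## Benchmark design notes

- Detection recovery (200 traces, rates 0.1–0.6/min, amplitude 10× noise
  SD): sensitivity (matched + covered, as defined above) is 0.97–0.99 and
  the strict false-positive rate 0.006–0.012 events/min across seed blocks.
- Drift immunity (20 % of F0, 300 s period, added to noiseless
  event-bearing traces): detected counts are unchanged on the overwhelming
  majority of traces; across 1500 simulated pairs, 3 showed a count change
  of one event. All three were doublets 10–14 s apart whose valley-depth
  split decision sat within ~1 % of its threshold, flipped by residual
  baseline interpolation error across the event gap — an inherent
  knife-edge of any threshold rule on continuous data, not a failure of
  drift absorption for isolated events.
- The end-to-end cohorts (somatic rates 0.09/0.25/0.44 per min for the
  wild-type, plaque-distant and plaque-associated conditions; process rates
  fixed at 0.55) reproduce the qualitative pattern — somatic ordering,
  process invariance, process:soma fold collapsing toward 1 at plaques —
  with group means recovered up to the merging undercount described above.
- Evoked-reduction demonstrations set group mean amplitudes to the reported
  remaining fractions (68.8 %, 22.1 %, 22.6 % of reference) with 10 %
  between-cell SD and verify the pipeline recovers reductions near 31.2 %,
  77.9 % and 77.4 %; these are demonstrations of the summary machinery on
  synthetic cohorts, not re-derivations of the biological effect sizes.

## Known limitations

- Event counting merges transients closer than the indicator decay time;
  rate estimates are biased low at the upper end of the observed range.
- `baseline_sd` includes sub-cutoff event tails by definition, so the
  detection threshold rises on very active traces; onsets are then flagged
  a frame or two later.
- The SWC reader accepts any non-soma type code as "process"; multi-node
  somata are treated as a single root plus process children.
- Exact-test enumeration is O(C(n, n_a)) / O(2ⁿ); the exact/approximate
  switch points (12 pooled, 15 pairs) keep worst cases below a millisecond
  but the approximation near the switch is the usual normal-tail
  compromise.
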
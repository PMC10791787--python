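# microcal

Analysis toolkit for microglial Ca²⁺ activity and morphology in brain-slice
imaging experiments: spontaneous Ca²⁺ transient detection on ROI
fluorescence traces, laser-lesion evoked response quantification, 3D Sholl
morphometry of reconstructed cells, and Iba1/CD68 lysosomal-burden scoring —
together with seeded synthetic-data generators that provide ground truth for
every stage.

It is aimed at labs quantifying how microglial Ca²⁺ signalling and
ramification change with amyloid pathology, plaque proximity, or ageing,
where somata and single processes are imaged as separate ROIs at ~1 frame/s
and effects are expressed as per-compartment event rates, evoked ΔF/F peaks,
shell-resolved process length, and mask-coverage percentages.

## Methods at a glance

**Transient detection.** For each ROI the raw trace F(t) is converted to
ΔF/F = (F − F₀(t))/F₀(t) against a locally smoothed baseline F₀(t): a
piecewise cubic Hermite interpolating polynomial (PCHIP) through windowed
medians of non-event frames (100-frame smoothing time), refit iteratively
after excluding frames with ΔF/F ≥ 0.10. Transients are suprathreshold
excursions with ΔF/F > 2.25 × SD of the quiescent baseline points, confirmed
by an area criterion ∫ΔF/F dt > 0.15, and reported as events/min. Only
process ROIs ≥ 1 µm in diameter are analysed (thinner structures are
filopodia).

**Evoked responses.** After a focal laser lesion, somatic ΔF/F is computed
as (Fₜ − F₀)/F₀ with F₀ the mean of the 20 s pre-lesion baseline; the
response is the post-lesion peak ΔF/F and its latency, summarised per group
as mean ± SEM with percent reduction against a reference group.

**Sholl morphometry.** Concentric spheres at 5 µm intervals are drawn
around the cell centre (the innermost 5 µm is soma and excluded); each SWC
reconstruction edge is clipped analytically against the sphere boundaries,
accumulating process length per shell, and ramification is counted as
bifurcation nodes per shell. The soma ROI is modelled as a sphere
(4πr² = 707 µm² at r = 7.5 µm) and a process segment as a cylinder
(2πrl = 71 µm² at r = 0.75 µm, l = 15 µm) for surface-area normalisation.

**Lysosomal burden.** Each channel is background-subtracted with a
rolling-ball estimate (grayscale opening; 10 px for Iba1/CD68, 80 px for
Aβ), thresholded (Otsu by default), and scored as the percentage of Iba1⁺
area that is CD68⁺; cells are classed at/away from plaques by a 50 µm
distance to the nearest Aβ-mask pixel.

**Statistics.** Mann–Whitney rank-sum and Wilcoxon matched-pairs
signed-rank tests are implemented with exact small-sample enumeration
(n ≤ 12 pooled / n ≤ 15 pairs) and tie-corrected normal approximations;
paired per-cell process:soma rate ratios and group summaries
(mean ± SEM, fold change) round out the comparisons in the study design.

See `docs/methods.md` for the full model description, parameter tables and
numerical choices.

## Worked example

```python
from microcal import TraceSimParams, generate_trace, detect_transients

params = TraceSimParams(duration_s=300, rate_hz=1.0, event_rate_per_min=0.4,
                        amp_mean=0.5, noise_sd=0.02, seed=7)
trace, truth = generate_trace(params)
activity = detect_transients(trace)
print(f"injected events : {len(truth.event_times_s)}")
print(f"detected events : {len(activity.events)}")
for ev in activity.events:
    print(f"  onset {ev.onset_frame:>3d} s  peak dF/F {ev.peak_dff:.2f}"
          f"  area {ev.area:.2f} dF/F*s")
print(f"rate            : {activity.rate_per_min:.2f} events/min")
```

prints

```
injected events : 3
detected events : 3
  onset   2 s  peak dF/F 0.61  area 6.25 dF/F*s
  onset  91 s  peak dF/F 0.45  area 4.39 dF/F*s
  onset 263 s  peak dF/F 0.42  area 4.08 dF/F*s
rate            : 0.60 events/min
```

Three transients of ~0.5 ΔF/F were injected into a 5-min, 1 Hz recording on
a slowly drifting baseline; the detector recovers all three (onsets within
one frame of the injected times — threshold crossing lags the true onset by
the indicator rise time), each confirmed by the area criterion, giving the
expected spontaneous rate of 0.6 events/min.

The same stages are available from the shell:

```bash
microcal simulate trace --seed 7 --n-rois 4 --out sim/
microcal detect --traces sim/traces.csv --out detected/
microcal sholl --manifest cells.csv --step 5 --soma-radius 5 --out sholl/
microcal coverage --iba1 iba1.tif --cd68 cd68.tif --out burden/
microcal stats --summary detected/summary.csv --out report/
```

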
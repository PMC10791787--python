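"""Spontaneous Ca2+ transient detection on ROI fluorescence traces.

The detection scheme follows the standard two-photon Ca2+ imaging recipe for
microglia: a locally smoothed baseline is fitted through non-event frames
with a piecewise cubic Hermite interpolating polynomial (PCHIP), ΔF/F is
computed against it, and transients are maximal suprathreshold runs of
ΔF/F > k × SD of quiescent baseline points, confirmed by a minimal
time-integral criterion. Defaults: k = 2.25, quiescence cutoff ΔF/F < 0.10,
∫ΔF/F dt > 0.15 ΔF/F·s, 100-frame smoothing time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import grey_opening

__all__ = [
    "FluorescenceTrace",
    "DetectionParams",
    "BaselineModel",
    "TransientEvent",
    "RoiActivity",
    "fit_baseline",
    "detect_transients",
    "compute_rate",
    "read_traces_csv",
    "extract_traces_from_stack",
]

MIN_PROCESS_DIAMETER_UM = 1.0  # thinner structures are filopodia, excluded


@dataclass
class FluorescenceTrace:
    """One ROI's raw fluorescence time series.

    ``compartment`` is "soma" or "process"; process ROIs must carry a
    diameter so the ≥ 1 µm eligibility rule (excluding filopodia) can be
    applied. ``veto_frames`` lists peak frames of analyst-rejected events.
    """

    roi_id: str
    compartment: str
    values: np.ndarray
    rate_hz: float
    process_diameter_um: float | None = None
    veto_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if self.compartment not in ("soma", "process"):
            raise ValueError("compartment must be 'soma' or 'process'")
        if self.compartment == "process" and self.process_diameter_um is None:
            raise ValueError("process ROIs require process_diameter_um")

    @property
    def duration_min(self) -> float:
        return self.values.size / self.rate_hz / 60.0

    @property
    def eligible(self) -> bool:
        """Analysable ROI: somata always; processes only if ≥ 1 µm diameter."""
        if self.compartment == "soma":
            return True
        return self.process_diameter_um >= MIN_PROCESS_DIAMETER_UM


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds.

    ``release_fraction`` and ``split_valley_fraction`` control how
    suprathreshold runs are grouped into events: a run only ends once ΔF/F
    falls below ``release_fraction`` × threshold (hysteresis, so an event's
    own decaying tail cannot re-trigger on noise; active only when the
    baseline SD is positive), and a run containing several peaks is split
    wherever the valley between two peaks drops below
    ``split_valley_fraction`` × the smaller peak, provided both peaks rise
    at least ``split_min_rise_sd`` noise SDs above the valley and the later
    peak is event-sized. Split decisions are made on chord-corrected excess
    fluorescence, so they are scale-free and insensitive to baseline drift.
    """

    smooth_frames: int = 100
    sd_multiplier: float = 2.25
    baseline_dff_cutoff: float = 0.10
    min_area: float = 0.15          # ΔF/F · s
    max_baseline_iterations: int = 10
    release_fraction: float = 0.5
    split_valley_fraction: float = 0.5
    split_min_rise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.smooth_frames < 2:
            raise ValueError("smooth_frames must be >= 2")
        for name in ("sd_multiplier", "baseline_dff_cutoff", "min_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.release_fraction < 1.0):
            raise ValueError("release_fraction must be in [0, 1)")


@dataclass
class BaselineModel:
    baseline_values: np.ndarray   # fitted baseline fluorescence per frame
    dff: np.ndarray               # (F - baseline) / baseline
    baseline_sd: float            # SD of ΔF/F over quiescent frames
    noise_sd: float               # frame-to-frame noise scale of ΔF/F
    quiescent: np.ndarray         # bool mask of frames with ΔF/F < cutoff
    used_fallback: bool = False   # all frames excluded -> global median
    n_iterations: int = 0


@dataclass(frozen=True)
class TransientEvent:
    onset_frame: int
    peak_frame: int
    offset_frame: int
    peak_dff: float
    area: float                   # ΔF/F · s over the suprathreshold run

    def __post_init__(self) -> None:
        if not (self.onset_frame <= self.peak_frame <= self.offset_frame):
            raise ValueError("need onset <= peak <= offset")


@dataclass
class RoiActivity:
    roi_id: str
    compartment: str
    events: list[TransientEvent]
    duration_min: float
    rate_per_min: float
    baseline: BaselineModel | None = None


def _knot_layout(n: int, smooth_frames: int) -> np.ndarray:
    """Symmetric knot centres spaced ~smooth_frames/4 apart across [0, n-1].

    A symmetric linspace layout keeps detection identical on time-reversed
    traces.
    """
    spacing = max(2, smooth_frames // 4)
    n_knots = max(2, int(np.ceil((n - 1) / spacing)) + 1)
    return np.linspace(0, n - 1, n_knots)


def _fit_pchip_through(values: np.ndarray, include: np.ndarray,
                       smooth_frames: int) -> np.ndarray:
    """PCHIP through windowed medians of included frames.

    Each knot summarises the included frames within a centred window of
    half-width smooth_frames/4; the full smoothing time per baseline point is
    therefore ~smooth_frames, split between the window and the knot spacing.
    Knots whose window holds no included frame are dropped (the interpolant
    bridges the gap).
    """
    n = values.size
    centers = _knot_layout(n, smooth_frames)
    halfwidth = max(1, smooth_frames // 4)
    xs, ys = [], []
    for c in centers:
        # clip the window symmetrically at the ends so edge knots stay
        # centred on their frame (an asymmetric window would bias them)
        hw = min(halfwidth, c, (n - 1) - c)
        lo = max(0, int(np.floor(c - hw)))
        hi = min(n, int(np.ceil(c + hw)) + 1)
        sel = include[lo:hi]
        if not sel.any():
            continue
        # place the knot at the median included index, not the window
        # centre: when an excluded event empties one side of the window the
        # summary describes the other side, and anchoring it at the centre
        # would bend the baseline there
        idx = np.flatnonzero(sel) + lo
        xs.append(float(np.median(idx)))
        ys.append(np.median(values[lo:hi][sel]))
    if xs:
        order = np.argsort(xs)
        merged_x: list[float] = []
        merged_y: list[float] = []
        for i in order:
            if merged_x and abs(xs[i] - merged_x[-1]) < 1e-9:
                merged_y[-1] = 0.5 * (merged_y[-1] + ys[i])
            else:
                merged_x.append(xs[i])
                merged_y.append(ys[i])
        xs, ys = merged_x, merged_y
    if len(xs) < 2:
        # too few usable knots for an interpolant: flat baseline
        level = np.median(values[include]) if include.any() else np.median(values)
        return np.full(n, level)
    # beyond the outermost knots (their windows lost every frame to the
    # event exclusion) extend linearly with the interpolant's endpoint
    # slope: cubic extrapolation can overshoot badly over a dropped edge
    # window, while a constant hold loses genuine baseline drift at the
    # recording boundary
    interp = PchipInterpolator(np.asarray(xs), np.asarray(ys))
    frames = np.arange(n, dtype=float)
    inner = np.clip(frames, xs[0], xs[-1])
    out = interp(inner)
    slope = interp.derivative()
    left = frames < xs[0]
    right = frames > xs[-1]
    if left.any():
        out[left] += float(slope(xs[0])) * (frames[left] - xs[0])
    if right.any():
        out[right] += float(slope(xs[-1])) * (frames[right] - xs[-1])
    return out


def fit_baseline(trace: FluorescenceTrace, params: DetectionParams | None = None
                 ) -> BaselineModel:
    """Iteratively fit a drift-tracking baseline through non-event frames.

    Starts from a running median of the raw trace, computes ΔF/F, excludes
    frames with ΔF/F ≥ ``baseline_dff_cutoff`` and refits the PCHIP through
    windowed medians of the remaining frames, until the exclusion set is
    stable or ``max_baseline_iterations`` is reached. ``baseline_sd`` is the
    SD of ΔF/F over the quiescent (non-excluded) frames. If every frame is
    excluded the baseline falls back to the global median and is flagged.
    """
    params = params or DetectionParams()
    values = trace.values
    n = values.size

    # initial guess: grayscale opening (running min then max). Unlike a
    # running median it cannot be dragged up by piled-up transient tails
    # (positive excursions narrower than the window are removed entirely),
    # and unlike a bare running minimum it is slope-neutral on smooth
    # drift; its residual downward bias only makes the first exclusion
    # pass conservative, and the median-knot iterations remove it
    w = min(n, max(3, params.smooth_frames // 3) | 1)
    baseline = grey_opening(values, size=w, mode="mirror")
    baseline = np.where(baseline > 0, baseline, np.finfo(float).tiny)
    include = ((values - baseline) / baseline) < params.baseline_dff_cutoff

    n_iter = 0
    used_fallback = False
    for n_iter in range(1, params.max_baseline_iterations + 1):
        if not include.any():
            baseline = np.full(n, np.median(values))
            used_fallback = True
            break
        baseline = _fit_pchip_through(values, include, params.smooth_frames)
        baseline = np.where(baseline > 0, baseline, np.finfo(float).tiny)
        new_include = ((values - baseline) / baseline) < params.baseline_dff_cutoff
        if np.array_equal(new_include, include):
            include = new_include
            break
        include = new_include

    # residual re-baselining: whatever smooth structure is left in the
    # quiescent ΔF/F is baseline the knot fit missed (e.g. curvature it
    # bridged across an event gap); folding its windowed-median PCHIP back
    # into the baseline cancels it to second order. On a well fitted flat
    # trace the quiescent residual is ~0 and this is a no-op.
    if not used_fallback and include.any():
        dff0 = (values - baseline) / baseline
        corr = _fit_pchip_through(dff0, include, params.smooth_frames)
        baseline = baseline * (1.0 + corr)
        baseline = np.where(baseline > 0, baseline, np.finfo(float).tiny)
        include = ((values - baseline) / baseline) < params.baseline_dff_cutoff

    dff = (values - baseline) / baseline
    quiescent = dff < params.baseline_dff_cutoff
    baseline_sd = float(np.std(dff[quiescent])) if quiescent.any() else 0.0
    # high-frequency noise scale: successive differences between quiescent
    # neighbours cancel the smooth event tails that inflate baseline_sd
    adj = quiescent[:-1] & quiescent[1:]
    diffs = np.diff(dff)[adj]
    noise_sd = float(np.std(diffs) / np.sqrt(2.0)) if diffs.size else 0.0
    return BaselineModel(
        baseline_values=baseline,
        dff=dff,
        baseline_sd=baseline_sd,
        noise_sd=noise_sd,
        quiescent=quiescent,
        used_fallback=used_fallback,
        n_iterations=n_iter,
    )


def _split_run(delta_f: np.ndarray, start: int, stop: int,
               valley_fraction: float, min_rise: float = 0.0,
               min_peak: float = 0.0) -> list[tuple[int, int]]:
    """Split one suprathreshold run into per-event segments.

    Local maxima are found within the run; two adjacent peaks belong to
    distinct events when (a) the valley between them falls below
    ``valley_fraction`` × the smaller of the two peaks, (b) both peaks
    rise above the valley by at least ``min_rise`` (ΔF units) and (c) the
    later peak is itself event-sized (at least ``min_peak``, the detection
    threshold expressed in ΔF units) — (b) and (c) keep noise wiggles on a
    decaying tail from spawning spurious events. The cut is placed at the
    valley.

    The decision is made on the excess fluorescence ΔF = F − baseline
    (not ΔF/F): an additive baseline drift rescales ΔF/F event shapes by
    1/(1+drift) and would tilt the rise fractions, while ΔF is invariant
    once the baseline is absorbed. The line through ΔF just outside the
    run's boundaries (the chord) is subtracted first, so residual baseline
    error across the event gap — which shifts the run and its chord
    together — cancels as well. Ratios of ΔF are scale-free, so the rule
    behaves identically under fluorescence rescaling.
    """
    if stop - start < 3 or valley_fraction <= 0:
        return [(start, stop)]
    from scipy.signal import find_peaks

    n = delta_f.size
    left = delta_f[start - 1] if start > 0 else 0.0
    right = delta_f[stop] if stop < n else 0.0
    chord = np.linspace(left, right, stop - start + 2)[1:-1]
    seg = delta_f[start:stop] - chord
    peaks, _ = find_peaks(seg)
    if seg[0] > seg[min(1, seg.size - 1)]:
        peaks = np.concatenate(([0], peaks))
    if seg[-1] > seg[-2]:
        peaks = np.concatenate((peaks, [seg.size - 1]))
    if peaks.size < 2:
        return [(start, stop)]

    cuts: list[int] = []
    anchor = peaks[0]          # highest peak of the current event group
    for p in peaks[1:]:
        valley_idx = anchor + int(np.argmin(seg[anchor:p + 1]))
        valley = seg[valley_idx]
        if (valley < valley_fraction * min(seg[anchor], seg[p])
                and min(seg[anchor], seg[p]) - valley >= min_rise
                and seg[p] >= min_peak):
            cuts.append(start + valley_idx)
            anchor = p
        elif seg[p] > seg[anchor]:
            anchor = p
    if not cuts:
        return [(start, stop)]
    bounds = [start] + [c + 1 for c in cuts] + [stop]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def detect_transients(trace: FluorescenceTrace,
                      params: DetectionParams | None = None) -> RoiActivity:
    """Detect spontaneous Ca2+ transients in one ROI trace.

    Candidate events are maximal runs of consecutive frames with
    ΔF/F > sd_multiplier × baseline_sd; each run is kept if its area
    Σ ΔF/F · Δt exceeds ``min_area`` (ΔF/F·s) and its peak frame is not
    vetoed. With baseline_sd = 0 (noiseless quiescence) every positive
    excursion is a candidate and the area criterion does the filtering.
    """
    params = params or DetectionParams()
    model = fit_baseline(trace, params)
    dff = model.dff
    thr = params.sd_multiplier * model.baseline_sd
    above = dff > thr

    dt = 1.0 / trace.rate_hz
    events: list[TransientEvent] = []
    veto = set(trace.veto_frames)
    # maximal runs of suprathreshold frames as [start, stop) pairs
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(idx[::2], idx[1::2]))

    if model.baseline_sd > 0 and runs:
        # hysteresis: a run only releases once dff drops below
        # release_fraction x threshold, so decaying tails do not re-trigger
        release = params.release_fraction * thr
        merged = [list(runs[0])]
        for start, stop in runs[1:]:
            if np.all(dff[merged[-1][1]:start] > release):
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        runs = [(a, b) for a, b in merged]

    for start, stop in runs:
        delta_f = trace.values - model.baseline_values
        scale = float(np.median(model.baseline_values))
        segments = _split_run(delta_f, int(start), int(stop),
                              params.split_valley_fraction,
                              params.split_min_rise_sd * model.noise_sd * scale,
                              thr * scale)
        for s0, s1 in segments:
            run = slice(s0, s1)
            area = float(dff[run].sum() * dt)
            if area <= params.min_area:
                continue
            peak = int(s0 + np.argmax(dff[run]))
            if peak in veto:
                continue
            events.append(TransientEvent(
                onset_frame=int(s0),
                peak_frame=peak,
                offset_frame=int(s1 - 1),
                peak_dff=float(dff[peak]),
                area=area,
            ))

    duration_min = trace.duration_min
    return RoiActivity(
        roi_id=trace.roi_id,
        compartment=trace.compartment,
        events=events,
        duration_min=duration_min,
        rate_per_min=len(events) / duration_min,
        baseline=model,
    )


def compute_rate(activity: RoiActivity) -> float:
    """Events per minute over the full recording duration."""
    if activity.duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    return len(activity.events) / activity.duration_min


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_traces_csv(traces_path: str | Path,
                    rois_path: str | Path | None = None,
                    rate_hz: float | None = None) -> list[FluorescenceTrace]:
    """Load traces from a CSV with a time_s column plus one column per ROI.

    ROI metadata (roi_id, compartment, diameter_um) comes from ``rois_path``;
    without it every column is treated as a somatic ROI. The sampling rate is
    inferred from the time_s column unless given.
    """
    import pandas as pd

    df = pd.read_csv(traces_path)
    if "time_s" not in df.columns:
        raise ValueError("trace CSV must contain a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if rate_hz is None:
        steps = np.diff(t)
        if steps.size == 0 or not np.allclose(steps, steps[0]):
            raise ValueError("cannot infer rate: time_s not uniformly sampled")
        rate_hz = 1.0 / steps[0]

    meta: dict[str, dict] = {}
    if rois_path is not None:
        rdf = pd.read_csv(rois_path)
        for _, row in rdf.iterrows():
            meta[str(row["roi_id"])] = {
                "compartment": str(row["compartment"]),
                "diameter_um": float(row["diameter_um"])
                if "diameter_um" in rdf.columns and not pd.isna(row.get("diameter_um"))
                else None,
            }

    traces = []
    for col in df.columns:
        if col == "time_s":
            continue
        m = meta.get(str(col), {"compartment": "soma", "diameter_um": None})
        traces.append(FluorescenceTrace(
            roi_id=str(col),
            compartment=m["compartment"],
            values=df[col].to_numpy(dtype=float),
            rate_hz=float(rate_hz),
            process_diameter_um=m["diameter_um"],
        ))
    return traces


def extract_traces_from_stack(stack: np.ndarray, labels: np.ndarray,
                              rate_hz: float) -> dict[int, np.ndarray]:
    """Mean intensity per labelled ROI per frame from a registered T×H×W stack."""
    if stack.ndim != 3:
        raise ValueError("stack must be T x H x W")
    if labels.shape != stack.shape[1:]:
        raise ValueError("label image must match stack frame shape")
    out: dict[int, np.ndarray] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        out[int(lab)] = stack[:, mask].mean(axis=1)
    return out
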
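"""Synthetic fluorescence traces, microglial trees and immunofluorescence masks.

Every generator is seeded and returns its ground truth alongside the data, so
the downstream detection, morphometry and coverage stages can be validated
against known answers without access to raw imaging data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .detection import FluorescenceTrace
from .morphology import MorphTree, SwcNode

__all__ = [
    "TraceSimParams",
    "GroundTruth",
    "TreeSimParams",
    "MaskSimParams",
    "generate_trace",
    "generate_tree",
    "generate_mask_pair",
    "match_events",
    "write_trace_csv",
    "write_ground_truth_json",
]


@dataclass(frozen=True)
class TraceSimParams:
    """Parameters of a single simulated ROI fluorescence recording.

    Defaults emulate a 5-min, 1 frame/s GCaMP recording of a spontaneously
    active microglial compartment: sparse transients (a fraction of an event
    per minute), ~0.5 ΔF/F amplitudes with seconds-scale rise and decay, a
    slow drift of a few percent of F0 and low additive shot-like noise.
    """

    duration_s: float = 300.0
    rate_hz: float = 1.0           # 1 Hz GCaMP5g; 0.2 Hz for Fluo-4
    event_rate_per_min: float = 0.3
    amp_mean: float = 0.5          # ΔF/F at transient peak
    amp_sd: float = 0.1
    tau_rise_s: float = 2.0
    tau_decay_s: float = 8.0
    noise_sd: float = 0.02         # ΔF/F units
    drift_amplitude: float = 0.05  # fraction of f0
    drift_period_s: float = 300.0
    drift_linear_per_s: float = 0.0  # optional linear drift, fraction of f0 per s
    f0: float = 100.0
    saturation: bool = False       # apply indicator (Hill) saturation transform
    kd_um: float = 0.46            # GCaMP5g affinity, µM
    dynamic_range: float = 30.0
    rest_ca_um: float = 0.05       # resting [Ca2+]i used by the saturation map
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.tau_decay_s > self.tau_rise_s > 0):
            raise ValueError("need tau_decay_s > tau_rise_s > 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Injected events of one simulated trace."""

    event_times_s: tuple[float, ...]
    event_amps: tuple[float, ...]
    true_rate_per_min: float

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")


def _event_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, normalised to unit peak."""
    k = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    # analytic peak time of the difference of exponentials
    t_pk = (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_pk / tau_decay) - np.exp(-t_pk / tau_rise)
    return k / peak


def generate_trace(params: TraceSimParams) -> tuple[FluorescenceTrace, GroundTruth]:
    """Simulate one ROI's raw fluorescence trace with known transient times.

    The raw trace is ``f0 * (1 + drift(t) + signal(t)) + noise`` where
    ``signal`` is the sum of difference-of-exponential kernels scaled so the
    injected amplitude equals the peak ΔF/F of each event, and ``drift`` is a
    low-frequency sinusoid (plus optional linear term). Event times follow a
    homogeneous Poisson process at ``event_rate_per_min``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    if n < 2:
        raise ValueError("trace must span at least 2 frames")
    t = np.arange(n) / params.rate_hz

    n_events = rng.poisson(params.event_rate_per_min * params.duration_s / 60.0)
    times = np.sort(rng.uniform(0.0, params.duration_s, size=n_events))
    # strictly increasing ground truth (ties have measure zero, but be safe)
    times = np.unique(times)
    amps = np.maximum(rng.normal(params.amp_mean, params.amp_sd, size=times.size), 1e-3)

    signal = np.zeros(n)
    for t0, a in zip(times, amps):
        signal += a * _event_kernel(t - t0, params.tau_rise_s, params.tau_decay_s)

    if params.saturation:
        signal = _saturate(signal, params)

    drift = params.drift_amplitude * np.sin(2 * np.pi * t / params.drift_period_s)
    drift = drift + params.drift_linear_per_s * t
    raw = params.f0 * (1.0 + drift + signal)
    if params.noise_sd > 0:
        raw = raw + rng.normal(0.0, params.noise_sd * params.f0, size=n)

    trace = FluorescenceTrace(
        roi_id="sim", compartment="soma", values=raw, rate_hz=params.rate_hz
    )
    truth = GroundTruth(
        event_times_s=tuple(float(x) for x in times),
        event_amps=tuple(float(a) for a in amps),
        true_rate_per_min=params.event_rate_per_min,
    )
    return trace, truth


def _saturate(signal: np.ndarray, p: TraceSimParams) -> np.ndarray:
    """Optional indicator-saturation map (Hill, n=1) applied to the ΔF/F signal.

    The linear ΔF/F signal is interpreted as a Ca2+ excursion above
    ``rest_ca_um`` and pushed through F ∝ (1 + (R-1)·ca/(ca+kd)) with dynamic
    range R, then re-expressed as ΔF/F about the resting point. Off by
    default; ground truth always refers to the pre-saturation ΔF/F.
    """
    r = p.dynamic_range
    f_of = lambda ca: 1.0 + (r - 1.0) * ca / (ca + p.kd_um)
    f_rest = f_of(p.rest_ca_um)
    # linear scale: one ΔF/F unit ~ one kd of Ca2+ excursion (arbitrary choice)
    ca = p.rest_ca_um + signal * p.kd_um
    return (f_of(ca) - f_rest) / f_rest


def match_events(
    true_times_s: np.ndarray,
    detected_times_s: np.ndarray,
    rate_hz: float,
    tol_frames: int = 2,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-onset matching of detected events to ground truth.

    Each detected event is paired to the closest unmatched true event within
    ``tol_frames`` frames. Onsets are compared on the frame grid: a true
    event at time t first contributes signal to frame ceil(t × rate), which
    is the earliest frame a detector could flag. Returns
    (pairs, unmatched_true, unmatched_detected) as index lists.
    """
    true_times_s = np.ceil(np.asarray(true_times_s, dtype=float) * rate_hz
                           - 1e-9) / rate_hz
    detected_times_s = np.asarray(detected_times_s, dtype=float)
    tol_s = (tol_frames + 1e-9) / rate_hz
    pairs: list[tuple[int, int]] = []
    used_true: set[int] = set()
    order = np.argsort(detected_times_s)
    for j in order:
        if true_times_s.size == 0:
            break
        d = np.abs(true_times_s - detected_times_s[j])
        d[list(used_true)] = np.inf if used_true else d[list(used_true)]
        i = int(np.argmin(d))
        if d[i] <= tol_s:
            pairs.append((i, int(j)))
            used_true.add(i)
    unmatched_true = [i for i in range(true_times_s.size) if i not in used_true]
    matched_det = {j for _, j in pairs}
    unmatched_det = [j for j in range(detected_times_s.size) if j not in matched_det]
    return pairs, unmatched_true, unmatched_det


def recovery_metrics(truth: GroundTruth, activity, rate_hz: float,
                     tol_frames: int = 2) -> dict:
    """Detection-recovery metrics of one trace against its ground truth.

    Injected events are first paired to detected events by nearest onset
    within ``tol_frames``. A true event left unpaired but whose onset falls
    inside a detected event's [onset, offset] footprint is *covered*: its
    signal was detected but not resolved as a separate transient (this is
    how overlapping events within the indicator decay time appear — they
    form a single fluorescence transient). Sensitivity counts matched plus
    covered events; a false positive is a detection that neither pairs with
    nor contains any injected event.
    """
    true_times = np.asarray(truth.event_times_s, dtype=float)
    det_onsets = np.array([e.onset_frame / rate_hz for e in activity.events])
    pairs, unmatched_true, unmatched_det = match_events(
        true_times, det_onsets, rate_hz, tol_frames)
    covered = 0
    covering_dets: set[int] = set()
    for i in unmatched_true:
        t = true_times[i]
        for j, e in enumerate(activity.events):
            if e.onset_frame / rate_hz <= t <= e.offset_frame / rate_hz:
                covered += 1
                covering_dets.add(j)
                break
    false_pos = [j for j in unmatched_det if j not in covering_dets]
    n_true = true_times.size
    return {
        "n_true": int(n_true),
        "n_detected": len(activity.events),
        "matched": len(pairs),
        "covered": covered,
        "missed": int(n_true - len(pairs) - covered),
        "false_positives": len(false_pos),
        "sensitivity": (len(pairs) + covered) / n_true if n_true else float("nan"),
    }


# ---------------------------------------------------------------------------
# Morphology trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSimParams:
    """Random branching-tree parameters for one simulated microglial cell.

    ``deramification`` in [0, 1] shrinks process length and prunes branches,
    emulating the amoeboid transformation of plaque-associated microglia;
    0 is a fully ramified surveillant cell.
    """

    n_primary: int = 5
    branch_prob_per_um: float = 0.05
    mean_segment_um: float = 8.0
    max_extent_um: float = 40.0
    deramification: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 0:
            raise ValueError("n_primary must be >= 0")
        if not (0.0 <= self.deramification <= 1.0):
            raise ValueError("deramification must be in [0, 1]")
        if self.max_extent_um <= 5.0:
            raise ValueError("max_extent_um must exceed the 5 µm soma radius")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_tree(params: TreeSimParams) -> MorphTree:
    """Grow a random 3D microglial tree rooted on a soma node at the origin.

    Growth: ``n_primary`` processes start on the 5 µm soma sphere and extend
    in exponential-length segments with small angular jitter; each segment may
    spawn a side branch with probability ``branch_prob_per_um`` per µm, and
    growth stops at ``max_extent_um`` from the centre. Deramification then
    prunes non-primary subtrees with probability ``0.7·deramification`` and
    radially shrinks all process coordinates by ``1 − 0.5·deramification``,
    so a higher factor strictly reduces total process length for the same
    seed.
    """
    rng = np.random.default_rng(params.seed)
    soma_r = 5.0
    nodes: list[SwcNode] = [SwcNode(1, "soma", 0.0, 0.0, 0.0, soma_r, -1)]
    # first_segment ids of each primary process (never pruned)
    primary_ids: set[int] = set()

    # stack of (parent_node_id, position, direction, primary_start, depth)
    stack: list[tuple[int, np.ndarray, np.ndarray, bool, int]] = []
    for _ in range(params.n_primary):
        d = _random_unit(rng)
        stack.append((1, d * soma_r, d, True, 0))

    next_id = 2
    max_nodes = 5000
    max_segments_per_path = 64
    while stack:
        parent_id, pos, direction, is_primary_start, depth = stack.pop()
        if len(nodes) >= max_nodes or depth >= max_segments_per_path:
            continue
        seg = rng.exponential(params.mean_segment_um)
        seg = float(np.clip(seg, 1.0, 3.0 * params.mean_segment_um))
        new_pos = pos + direction * seg
        if np.linalg.norm(new_pos) > params.max_extent_um:
            continue
        node = SwcNode(next_id, "process",
                       float(new_pos[0]), float(new_pos[1]), float(new_pos[2]),
                       0.5, parent_id)
        nodes.append(node)
        if is_primary_start:
            primary_ids.add(next_id)
        # continue outward with angular jitter; the radial bias mimics the
        # centrifugal growth of microglial processes and bounds the walk
        radial = new_pos / np.linalg.norm(new_pos)
        jitter = direction + 0.4 * rng.normal(size=3) + 0.3 * radial
        jitter /= np.linalg.norm(jitter)
        stack.append((next_id, new_pos, jitter, False, depth + 1))
        # side branch?
        if rng.uniform() < params.branch_prob_per_um * seg:
            bdir = direction + 1.0 * rng.normal(size=3) + 0.3 * radial
            bdir /= np.linalg.norm(bdir)
            stack.append((next_id, new_pos, bdir, False, depth + 1))
        next_id += 1

    # --- deramification: seeded pruning then radial shrinkage ---------------
    d = params.deramification
    if d > 0 and len(nodes) > 1:
        prune_rng = np.random.default_rng((params.seed + 1) & 0x7FFFFFFF)
        by_id = {n.id: n for n in nodes}
        kids: dict[int, list[int]] = {}
        for n in nodes[1:]:
            kids.setdefault(n.parent_id, []).append(n.id)
        doomed: set[int] = set()
        # candidate subtree roots: branch-side children (non-primary starts)
        for n in nodes[1:]:
            if n.id in primary_ids or n.id in doomed:
                continue
            if prune_rng.uniform() < 0.7 * d:
                queue = [n.id]
                while queue:
                    q = queue.pop()
                    doomed.add(q)
                    queue.extend(kids.get(q, []))
        kept = [n for n in nodes if n.id not in doomed]
        shrink = 1.0 - 0.5 * d
        nodes = [
            n if n.type == "soma" else
            SwcNode(n.id, n.type, n.x * shrink, n.y * shrink, n.z * shrink,
                    n.radius, n.parent_id)
            for n in kept
        ]
        # reindex so ids are contiguous (SWC convention)
        remap = {n.id: i + 1 for i, n in enumerate(nodes)}
        nodes = [
            SwcNode(remap[n.id], n.type, n.x, n.y, n.z, n.radius,
                    -1 if n.parent_id == -1 else remap[n.parent_id])
            for n in nodes
        ]

    return MorphTree(nodes=nodes, center=(0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# Immunofluorescence mask pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSimParams:
    """Synthetic Iba1/CD68 channel pair with a known overlap fraction."""

    shape_px: tuple[int, int] = (128, 128)
    iba1_fraction: float = 0.2
    overlap_fraction: float = 0.25   # of Iba1 area that is also CD68+
    blob_radius_px: int = 6
    background_level: float = 10.0
    foreground_level: float = 200.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.iba1_fraction <= 1.0):
            raise ValueError("iba1_fraction must be in [0, 1]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")


def _blob_mask(shape: tuple[int, int], target_fraction: float,
               radius: int, rng: np.random.Generator) -> np.ndarray:
    """Union of random disks until the target area fraction is reached."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    target = target_fraction * h * w
    yy, xx = np.mgrid[0:h, 0:w]
    guard = 0
    while mask.sum() < target and guard < 10_000:
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        guard += 1
    return mask


def generate_mask_pair(
    params: MaskSimParams,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Generate (iba1_image, cd68_image, true_coverage_pct).

    The Iba1 mask is a union of random disks with area fraction close to
    ``iba1_fraction``. The CD68 mask takes exactly the requested fraction of
    Iba1 pixels (the spatially contiguous set nearest a random focus, so the
    overlap looks blob-like) plus a disjoint CD68-only blob. Images are the
    masks rendered at ``foreground_level`` over ``background_level`` with
    additive Gaussian noise. ``true_coverage_pct`` is the exact pixel-count
    percentage of Iba1 area that is CD68 positive.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape_px
    iba1 = _blob_mask(params.shape_px, params.iba1_fraction, params.blob_radius_px, rng)

    cd68 = np.zeros_like(iba1)
    n_iba1 = int(iba1.sum())
    n_overlap = int(round(params.overlap_fraction * n_iba1))
    if n_overlap > 0 and n_iba1 > 0:
        ys, xs = np.nonzero(iba1)
        focus = rng.integers(0, n_iba1)
        d2 = (ys - ys[focus]) ** 2 + (xs - xs[focus]) ** 2
        take = np.argsort(d2, kind="stable")[:n_overlap]
        cd68[ys[take], xs[take]] = True
    if params.overlap_fraction < 1.0:
        # a CD68-only blob outside Iba1 (lysosomal signal in unmasked tissue)
        extra = _blob_mask(params.shape_px, 0.05, params.blob_radius_px, rng)
        cd68 |= extra & ~iba1

    true_coverage_pct = 100.0 * (cd68 & iba1).sum() / n_iba1 if n_iba1 else 0.0

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.full((h, w), params.background_level, dtype=float)
        img[mask] = params.foreground_level
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=(h, w))
        return np.clip(img, 0.0, None)

    return render(iba1), render(cd68), float(true_coverage_pct)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_trace_csv(path: str | Path, traces: list[FluorescenceTrace]) -> None:
    """Write traces as CSV: time_s plus one column per ROI."""
    import pandas as pd

    if not traces:
        raise ValueError("no traces to write")
    n = len(traces[0].values)
    rate = traces[0].rate_hz
    cols = {"time_s": np.arange(n) / rate}
    for tr in traces:
        if len(tr.values) != n or tr.rate_hz != rate:
            raise ValueError("all traces must share length and rate")
        cols[str(tr.roi_id)] = np.asarray(tr.values)
    pd.DataFrame(cols).to_csv(path, index=False)


def write_ground_truth_json(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2))


def write_mask_tiffs(out_dir: str | Path, iba1: np.ndarray, cd68: np.ndarray) -> None:
    out = Path(out_dir)
    tifffile.imwrite(out / "iba1.tif", iba1.astype(np.float32))
    tifffile.imwrite(out / "cd68.tif", cd68.astype(np.float32))
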
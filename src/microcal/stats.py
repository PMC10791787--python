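"""Compartment-level statistics: geometry normalisation, paired soma/process
rates, and rank-based tests.

The two pairwise tests that carry the headline comparisons — the
Mann–Whitney rank-sum test and the Wilcoxon matched-pairs signed-rank test —
are implemented from first principles with exact small-sample enumeration
(rank-sum: all C(n+m, n) label assignments when n+m ≤ 12; signed-rank: all
2^n sign patterns when n ≤ 15) and tie-corrected, continuity-corrected
normal approximations otherwise. Omnibus ANOVA/Kruskal comparisons are
delegated to scipy behind a thin wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "CompartmentGeometry",
    "PairedCellRates",
    "GroupSummary",
    "surface_area",
    "paired_ratios",
    "rank_sum_test",
    "paired_signed_rank_test",
    "summarize_group",
    "omnibus_test",
]


@dataclass(frozen=True)
class CompartmentGeometry:
    """Idealised ROI geometry: spherical soma, cylindrical process segment."""

    soma_radius_um: float = 7.5
    process_radius_um: float = 0.75
    process_length_um: float = 15.0

    def __post_init__(self) -> None:
        for f in ("soma_radius_um", "process_radius_um", "process_length_um"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def surface_area(geom: CompartmentGeometry, compartment: str) -> tuple[float, int]:
    """Membrane surface area (µm²) sampled by a soma or process ROI.

    Soma: sphere, 4πr² (707 µm² at r = 7.5). Process segment: lateral
    cylinder area 2πrl (71 µm² at r = 0.75, l = 15). Returns (exact, rounded).
    """
    if compartment == "soma":
        a = 4.0 * math.pi * geom.soma_radius_um**2
    elif compartment == "process":
        a = 2.0 * math.pi * geom.process_radius_um * geom.process_length_um
    else:
        raise ValueError("compartment must be 'soma' or 'process'")
    return a, round(a)


@dataclass
class PairedCellRates:
    cell_id: str
    soma_rate: float                 # events/min
    mean_process_rate: float         # mean over the cell's processes
    ratio: float                     # process/soma; NaN when soma_rate == 0


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    fold_vs_reference: float | None = None


def paired_ratios(cell_rates: dict[str, dict[str, list[float]]]
                  ) -> tuple[list[PairedCellRates], float]:
    """Per-cell paired soma vs process rates.

    ``cell_rates`` maps cell_id -> {"soma": [rates], "process": [rates]}.
    Process rates are averaged to one value per cell before pairing. Cells
    lacking either compartment are skipped with a warning; cells with zero
    somatic rate carry an undefined (NaN) ratio but remain available for
    difference-based paired tests. Returns the per-cell records and the
    median of the defined ratios.
    """
    import warnings

    out: list[PairedCellRates] = []
    for cell_id, comps in cell_rates.items():
        soma = comps.get("soma") or []
        proc = comps.get("process") or []
        if not soma or not proc:
            warnings.warn(f"cell {cell_id!r} lacks a compartment; excluded",
                          stacklevel=2)
            continue
        s = float(np.mean(soma))
        p = float(np.mean(proc))
        ratio = p / s if s > 0 else float("nan")
        out.append(PairedCellRates(cell_id, s, p, ratio))
    ratios = np.array([r.ratio for r in out if np.isfinite(r.ratio)])
    median_ratio = float(np.median(ratios)) if ratios.size else float("nan")
    return out, median_ratio


# ---------------------------------------------------------------------------
# Rank-based tests
# ---------------------------------------------------------------------------

EXACT_RANKSUM_MAX_N = 12       # n_a + n_b at or below -> full enumeration
EXACT_SIGNRANK_MAX_N = 15


def rank_sum_test(sample_a, sample_b) -> tuple[float, str]:
    """Two-sided Mann–Whitney rank-sum test.

    Exact branch (n_a + n_b ≤ 12): the null distribution of sample A's
    rank sum is built by enumerating every C(n_a+n_b, n_a) assignment of the
    pooled observations (midranks handle ties), and the two-sided p doubles
    the smaller tail (capped at 1). Larger samples use the normal
    approximation with tie-corrected variance and 0.5 continuity correction.
    Returns (p, method).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na, nb = a.size, b.size
    w_obs = ranks[:na].sum()

    if na + nb <= EXACT_RANKSUM_MAX_N:
        sums = np.array([ranks[list(idx)].sum()
                         for idx in combinations(range(na + nb), na)])
        lo = np.mean(sums <= w_obs + 1e-9)
        hi = np.mean(sums >= w_obs - 1e-9)
        return min(1.0, 2.0 * min(lo, hi)), "exact"

    n = na + nb
    mean_w = na * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n) * (n - 1))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_w == 0:
        return 1.0, "normal"
    z = (w_obs - mean_w - math.copysign(0.5, w_obs - mean_w)) / math.sqrt(var_w)
    if w_obs == mean_w:
        z = 0.0
    return min(1.0, 2.0 * norm.sf(abs(z))), "normal"


def paired_signed_rank_test(sample_x, sample_y) -> tuple[float, str]:
    """Two-tailed Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (recorded in the method string). Exact
    branch (≤ 15 informative pairs): the null distribution of the
    positive-rank sum enumerates all 2^n sign assignments; the two-sided p
    doubles the smaller tail. Larger n uses the tie-corrected normal
    approximation with continuity correction. Returns (p, method).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("samples must be equal-length, n >= 2")
    d = x - y
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, "all-zero-differences"
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    suffix = f",dropped_zeros={n_zero}" if n_zero else ""

    if n <= EXACT_SIGNRANK_MAX_N:
        # all 2^n sign patterns; vectorised via bit matrix
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
        sums = signs @ ranks
        lo = np.mean(sums <= w_pos + 1e-9)
        hi = np.mean(sums >= w_pos - 1e-9)
        return min(1.0, 2.0 * min(lo, hi)), "exact" + suffix

    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    if var_w == 0:
        return 1.0, "normal" + suffix
    z = (w_pos - mean_w - math.copysign(0.5, w_pos - mean_w)) / math.sqrt(var_w)
    if w_pos == mean_w:
        z = 0.0
    return min(1.0, 2.0 * norm.sf(abs(z))), "normal" + suffix


# ---------------------------------------------------------------------------
# Group summaries and delegated omnibus tests
# ---------------------------------------------------------------------------

def summarize_group(values, group: str, reference_mean: float | None = None
                    ) -> GroupSummary:
    """Mean ± SEM summary of one group, with fold change vs a reference mean."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    fold = (float(v.mean()) / reference_mean
            if reference_mean not in (None, 0) else None)
    return GroupSummary(group=group, n=int(v.size), mean=float(v.mean()),
                        sem=sem, fold_vs_reference=fold)


def omnibus_test(groups: dict[str, list[float]], parametric: bool = False
                 ) -> tuple[float, str]:
    """Delegated multi-group omnibus comparison (Kruskal–Wallis by default,
    one-way ANOVA if parametric); post-hoc families are left to standard
    statistical packages."""
    from scipy import stats as sps

    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    if parametric:
        res = sps.f_oneway(*samples)
        return float(res.pvalue), "one-way ANOVA (scipy)"
    res = sps.kruskal(*samples)
    return float(res.pvalue), "Kruskal-Wallis (scipy)"
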
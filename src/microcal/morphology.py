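"""3D Sholl morphometry of reconstructed microglia.

Concentric spheres are drawn at fixed (default 5 µm) intervals around an
analyst-established cell centre; the soma is assumed to occupy the innermost
5 µm. Process length is accumulated per shell by clipping each reconstruction
edge analytically against the sphere boundaries, and ramification is
profiled as bifurcation-node counts per shell (Sholl intersection counts are
also available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SwcNode",
    "MorphTree",
    "ShollParams",
    "ShollProfile",
    "read_swc",
    "write_swc",
    "sholl_profile",
    "compare_groups",
]

_SWC_TYPE_TO_NAME = {1: "soma"}          # every non-soma SWC type is a process


@dataclass(frozen=True)
class SwcNode:
    id: int
    type: str                  # "soma" | "process"
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


class SwcFormatError(ValueError):
    pass


@dataclass
class MorphTree:
    """Validated SWC-style reconstruction of one cell.

    Exactly one root (parent −1), connected and acyclic; ``center`` is the
    analyst-established cell centre used as the Sholl origin.
    """

    nodes: list[SwcNode]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise SwcFormatError("duplicate node ids")
        by_id = {n.id: n for n in self.nodes}
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SwcFormatError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in by_id:
                raise SwcFormatError(f"node {n.id} references missing parent "
                                     f"{n.parent_id}")
            if not all(math.isfinite(v) for v in (n.x, n.y, n.z)):
                raise SwcFormatError(f"node {n.id} has non-finite coordinates")
        # connectivity + acyclicity: every node must reach the root
        root_id = roots[0].id
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.id != root_id:
                if cur.id in seen:
                    raise SwcFormatError(f"cycle detected at node {cur.id}")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    @property
    def root(self) -> SwcNode:
        return next(n for n in self.nodes if n.parent_id == -1)

    def children_map(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {}
        for n in self.nodes:
            if n.parent_id != -1:
                kids.setdefault(n.parent_id, []).append(n.id)
        return kids

    def process_edges(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parent_xyz, child_xyz) for every edge ending in a process node."""
        by_id = {n.id: n for n in self.nodes}
        out = []
        for n in self.nodes:
            if n.parent_id == -1 or n.type != "process":
                continue
            p = by_id[n.parent_id]
            out.append((np.array([p.x, p.y, p.z]), np.array([n.x, n.y, n.z])))
        return out

    def total_process_length(self) -> float:
        return float(sum(np.linalg.norm(b - a) for a, b in self.process_edges()))


def read_swc(path: str | Path, center: tuple[float, float, float] | None = None
             ) -> MorphTree:
    """Parse an SWC file (7 whitespace-separated columns, ``#`` comments).

    The cell centre defaults to the root node position. Malformed rows,
    missing parents, multiple roots and cycles raise :class:`SwcFormatError`
    with the offending line number where applicable.
    """
    nodes: list[SwcNode] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcFormatError(f"line {lineno}: expected 7 columns, got "
                                 f"{len(parts)}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SwcFormatError(f"line {lineno}: non-numeric field ({exc})")
        nodes.append(SwcNode(nid, _SWC_TYPE_TO_NAME.get(ntype, "process"),
                             x, y, z, r, parent))
    if not nodes:
        raise SwcFormatError("empty SWC file")
    tree = MorphTree(nodes=nodes, center=center or (0.0, 0.0, 0.0))
    if center is None:
        root = tree.root
        tree.center = (root.x, root.y, root.z)
    return tree


def write_swc(path: str | Path, tree: MorphTree) -> None:
    name_to_type = {"soma": 1, "process": 3}
    lines = ["# id type x y z radius parent"]
    for n in sorted(tree.nodes, key=lambda n: n.id):
        lines.append(f"{n.id} {name_to_type[n.type]} {n.x:.4f} {n.y:.4f} "
                     f"{n.z:.4f} {n.radius:.3f} {n.parent_id}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ShollParams:
    shell_step_um: float = 5.0
    soma_radius_um: float = 5.0

    def __post_init__(self) -> None:
        if self.shell_step_um <= 0 or self.soma_radius_um <= 0:
            raise ValueError("shell_step_um and soma_radius_um must be > 0")


@dataclass
class ShollProfile:
    shell_lower_um: np.ndarray       # inner radius of each shell
    length_um_per_shell: np.ndarray
    branches_per_shell: np.ndarray   # bifurcation nodes per shell
    intersections_per_shell: np.ndarray  # classic Sholl crossings per sphere
    total_length_um: float
    total_branches: int


def _segment_sphere_crossings(a: np.ndarray, b: np.ndarray, r: float
                              ) -> list[float]:
    """Parameters t in (0,1) where |a + t(b-a)| = r."""
    d = b - a
    A = float(d @ d)
    if A == 0.0:
        return []
    B = 2.0 * float(a @ d)
    C = float(a @ a) - r * r
    disc = B * B - 4 * A * C
    if disc <= 0:
        return []
    s = math.sqrt(disc)
    return [t for t in ((-B - s) / (2 * A), (-B + s) / (2 * A)) if 0.0 < t < 1.0]


def sholl_profile(tree: MorphTree, params: ShollParams | None = None
                  ) -> ShollProfile:
    """Shell-resolved process length and branching of one reconstruction.

    Each process edge is clipped analytically against the sphere boundaries
    soma_radius + k·step centred on ``tree.center``: crossing parameters come
    from the segment-sphere quadratic, and each sub-segment's arc length is
    assigned to the shell containing its midpoint. Length inside the soma
    sphere is discarded. Shells are half-open [r, r+step). A bifurcation is
    counted in the shell containing the branching node; nodes with c > 2
    children count as c − 1 bifurcations, and the root is excluded.
    """
    params = params or ShollParams()
    c = np.asarray(tree.center, dtype=float)
    r0, step = params.soma_radius_um, params.shell_step_um

    edges = [(a - c, b - c) for a, b in tree.process_edges()]
    max_r = r0
    for a, b in edges:
        max_r = max(max_r, float(np.linalg.norm(a)), float(np.linalg.norm(b)))
    for n in tree.nodes:
        max_r = max(max_r, float(np.linalg.norm(
            np.array([n.x, n.y, n.z]) - c)))
    if max_r > 0 and not edges:
        pass
    n_shells = max(0, int(math.ceil((max_r - r0) / step)))
    if n_shells == 0 and edges:
        n_shells = 1
    lengths = np.zeros(n_shells)
    boundaries = [r0 + k * step for k in range(n_shells + 1)]

    bbox_lo = np.min([[n.x, n.y, n.z] for n in tree.nodes], axis=0)
    bbox_hi = np.max([[n.x, n.y, n.z] for n in tree.nodes], axis=0)
    if np.any(c < bbox_lo) or np.any(c > bbox_hi):
        warnings.warn("cell centre lies outside the node bounding box",
                      stacklevel=2)

    for a, b in edges:
        seg_len = float(np.linalg.norm(b - a))
        if seg_len == 0.0:
            continue
        ts = {0.0, 1.0}
        for r in boundaries:
            ts.update(_segment_sphere_crossings(a, b, r))
        ts = sorted(ts)
        for t0, t1 in zip(ts[:-1], ts[1:]):
            mid = a + 0.5 * (t0 + t1) * (b - a)
            d = float(np.linalg.norm(mid))
            if d < r0:
                continue                      # inside the soma sphere
            k = int((d - r0) // step)
            if 0 <= k < n_shells:
                lengths[k] += seg_len * (t1 - t0)

    # bifurcation counts per shell
    branches = np.zeros(n_shells, dtype=int)
    kids = tree.children_map()
    by_id = {n.id: n for n in tree.nodes}
    root_id = tree.root.id
    for nid, ch in kids.items():
        if nid == root_id or len(ch) < 2:
            continue
        n = by_id[nid]
        d = float(np.linalg.norm(np.array([n.x, n.y, n.z]) - c))
        if d < r0:
            continue
        k = int((d - r0) // step)
        if 0 <= k < n_shells:
            branches[k] += len(ch) - 1

    # classic Sholl intersections: crossings of each sphere boundary r0+k·step
    intersections = np.zeros(n_shells, dtype=int)
    for a, b in edges:
        for k in range(n_shells):
            r = boundaries[k]
            da, db = float(np.linalg.norm(a)), float(np.linalg.norm(b))
            if (da - r) * (db - r) < 0:
                intersections[k] += 1

    return ShollProfile(
        shell_lower_um=np.array(boundaries[:-1]),
        length_um_per_shell=lengths,
        branches_per_shell=branches,
        intersections_per_shell=intersections,
        total_length_um=float(lengths.sum()),
        total_branches=int(branches.sum()),
    )


def compare_groups(profiles: list[ShollProfile], labels: list[str],
                   reference: str) -> dict:
    """Per-group mean ± SEM of total process length, per-shell mean curves,
    and percent reduction of total length vs the reference group."""
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must align")
    groups = sorted(set(labels), key=labels.index)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    out: dict = {"reference": reference, "groups": {}}
    ref_mean = None
    for g in groups:
        totals = np.array([p.total_length_um
                           for p, l in zip(profiles, labels) if l == g])
        if totals.size == 0:
            raise ValueError(f"group {g!r} is empty")
        max_shells = max(p.length_um_per_shell.size
                         for p, l in zip(profiles, labels) if l == g)
        curves = np.zeros((totals.size, max_shells))
        for i, (p, l) in enumerate(
                (p, l) for p, l in zip(profiles, labels) if l == g):
            curves[i, :p.length_um_per_shell.size] = p.length_um_per_shell
        entry = {
            "n": int(totals.size),
            "mean_total_length_um": float(totals.mean()),
            "sem_total_length_um": float(totals.std(ddof=1) / np.sqrt(totals.size))
            if totals.size > 1 else 0.0,
            "mean_length_per_shell_um": curves.mean(axis=0),
        }
        out["groups"][g] = entry
        if g == reference:
            ref_mean = entry["mean_total_length_um"]
    for g, entry in out["groups"].items():
        entry["pct_reduction_vs_reference"] = (
            100.0 * (1.0 - entry["mean_total_length_um"] / ref_mean)
            if ref_mean else float("nan")
        )
    return out
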
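"""SWC-based arbor morphometry: Sholl profiles and tree-length metrics.

Works on standard 7-column SWC tracings (node id, structure type, x, y,
z in µm, radius, parent id; parent -1 marks the root/soma).  The Sholl
profile counts intersection points of the arbor with concentric spheres
(or circles, in 2D mode) centred on the root at radii k·shell_step.  For
a straight segment the count against one sphere is exact:

* 1 if the endpoints straddle the sphere,
* 2 if both endpoints lie outside but the segment's closest approach to
  the centre dips inside (a chord),
* 0 otherwise.

A crossing that falls exactly on a node is counted by neither adjacent
segment (strict inequalities); such configurations have measure zero for
traced data.

Scalar metrics follow common tracing-software conventions: one "tree"
per primary branch (root child), tree length = summed Euclidean segment
lengths of that subtree including the root-to-child segment, total
length = sum over all segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SWCNode",
    "NeuronTrace",
    "ShollProfile",
    "TreeGenParams",
    "SWCError",
    "read_swc",
    "write_swc",
    "sholl_intersections",
    "primary_branch_count",
    "tree_lengths",
    "generate_tree",
]


class SWCError(ValueError):
    """Raised for structurally invalid SWC data."""


@dataclass(frozen=True)
class SWCNode:
    node_id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root


@dataclass
class NeuronTrace:
    """A validated SWC node tree: exactly one root, acyclic, connected."""

    nodes: list[SWCNode]
    _by_id: dict[int, SWCNode] = field(init=False, repr=False)
    root: SWCNode = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise SWCError("empty trace")
        by_id: dict[int, SWCNode] = {}
        for n in self.nodes:
            if n.node_id in by_id:
                raise SWCError(f"duplicate node id {n.node_id}")
            by_id[n.node_id] = n
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in by_id:
                raise SWCError(
                    f"node {n.node_id} references missing parent {n.parent_id}"
                )
        # cycle / connectivity check by walking to the root from each node
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent_id != -1:
                if cur.node_id in seen:
                    raise SWCError(f"cycle detected at node {cur.node_id}")
                seen.add(cur.node_id)
                cur = by_id[cur.parent_id]
        self._by_id = by_id
        self.root = roots[0]

    def node(self, node_id: int) -> SWCNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[SWCNode]:
        return [n for n in self.nodes if n.parent_id == node_id]

    def segments(self) -> np.ndarray:
        """(n_segments, 2, 3) array of parent->child coordinates (µm)."""
        segs = [
            [
                (self._by_id[n.parent_id].x, self._by_id[n.parent_id].y, self._by_id[n.parent_id].z),
                (n.x, n.y, n.z),
            ]
            for n in self.nodes
            if n.parent_id != -1
        ]
        return np.asarray(segs, dtype=float).reshape(-1, 2, 3)


@dataclass(frozen=True)
class ShollProfile:
    """Intersections per concentric-shell radius."""

    radii: tuple[float, ...]
    intersections: tuple[int, ...]
    shell_step: float

    @property
    def area_under_curve(self) -> float:
        """Sum of intersections × shell_step, a scalar complexity index."""
        return float(sum(self.intersections) * self.shell_step)


def read_swc(path) -> NeuronTrace:
    """Parse a standard SWC file ('#' comments and blank lines allowed)."""
    nodes: list[SWCNode] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 fields, got {len(parts)}")
            try:
                nodes.append(
                    SWCNode(
                        node_id=int(parts[0]),
                        structure=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent_id=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
    return NeuronTrace(nodes)


def write_swc(trace: NeuronTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in trace.nodes:
            fh.write(
                f"{n.node_id} {n.structure} {n.x!r} {n.y!r} {n.z!r} "
                f"{n.radius!r} {n.parent_id}\n"
            )


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------


def _segment_crossings(d0: np.ndarray, d1: np.ndarray, dmin: np.ndarray, r: float) -> int:
    """Crossing count of straight segments with the sphere of radius r.

    ``d0``/``d1`` are endpoint distances to the centre, ``dmin`` the
    closest approach of each segment.  Distance along a straight segment
    from a fixed point is convex, so counts of 0/1/2 are exact.
    """
    straddle = (np.minimum(d0, d1) < r) & (np.maximum(d0, d1) > r)
    chord = (d0 > r) & (d1 > r) & (dmin < r)
    return int(straddle.sum() + 2 * chord.sum())


def _distances(trace: NeuronTrace, mode: str):
    segs = trace.segments()
    center = np.array([trace.root.x, trace.root.y, trace.root.z], dtype=float)
    if mode == "2d":
        segs = segs[:, :, :2]
        center = center[:2]
    a, b = segs[:, 0, :], segs[:, 1, :]
    d0 = np.linalg.norm(a - center, axis=1)
    d1 = np.linalg.norm(b - center, axis=1)
    # closest approach of each segment to the centre
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tproj = np.clip(
            np.where(denom > 0, ((center - a) * ab).sum(axis=1) / denom, 0.0), 0.0, 1.0
        )
    closest = a + tproj[:, None] * ab
    dmin = np.linalg.norm(closest - center, axis=1)
    return d0, d1, dmin


def sholl_intersections(
    trace: NeuronTrace, shell_step: float = 10.0, mode: str = "3d"
) -> ShollProfile:
    """Sholl profile: intersections with shells at radii k·shell_step.

    ``mode='3d'`` (default) uses spheres on the full coordinates;
    ``mode='2d'`` uses circles on the XY projection (appropriate for
    effectively planar brightfield tracings).  The profile runs from
    ``shell_step`` to the first radius beyond the arbor's maximal
    extent (where the count is necessarily 0).
    """
    if not shell_step > 0:
        raise ValueError("shell_step must be > 0")
    if mode not in ("3d", "2d"):
        raise ValueError("mode must be '3d' or '2d'")
    segs = trace.segments()
    if segs.shape[0] == 0:
        raise ValueError("trace has no segments")
    d0, d1, dmin = _distances(trace, mode)
    max_extent = float(np.maximum(d0, d1).max())
    n_shells = int(math.floor(max_extent / shell_step)) + 1
    radii = [shell_step * k for k in range(1, n_shells + 1)]
    counts = [_segment_crossings(d0, d1, dmin, r) for r in radii]
    return ShollProfile(
        radii=tuple(radii), intersections=tuple(counts), shell_step=float(shell_step)
    )


# ---------------------------------------------------------------------------
# Scalar morphometrics
# ---------------------------------------------------------------------------


def primary_branch_count(trace: NeuronTrace) -> int:
    """Number of primary branches = children of the root/soma node."""
    return len(trace.children(trace.root.node_id))


def _segment_length(a: SWCNode, b: SWCNode) -> float:
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


def tree_lengths(
    trace: NeuronTrace, longest_as_path: bool = False
) -> tuple[float, float, dict[int, float]]:
    """Total process length, longest-tree length, and per-tree lengths (µm).

    One tree per primary branch: the subtree rooted at each root child,
    including the root-to-child segment.  ``longest_tree`` is the maximal
    per-tree summed length; with ``longest_as_path`` it is instead the
    longest root-to-tip path distance.  Returns
    ``(total_length, longest_tree_length, {root_child_id: length})``.
    """
    children: dict[int, list[SWCNode]] = {}
    for n in trace.nodes:
        if n.parent_id != -1:
            children.setdefault(n.parent_id, []).append(n)

    per_tree: dict[int, float] = {}
    path_by_tree: dict[int, float] = {}
    for child in children.get(trace.root.node_id, []):
        total = 0.0
        longest_path = 0.0
        stack = [(child, _segment_length(trace.root, child))]
        total += stack[0][1]
        while stack:
            node, dist = stack.pop()
            kids = children.get(node.node_id, [])
            if not kids:
                longest_path = max(longest_path, dist)
            for k in kids:
                step = _segment_length(node, k)
                total += step
                stack.append((k, dist + step))
        per_tree[child.node_id] = total
        path_by_tree[child.node_id] = longest_path
    total_length = float(sum(per_tree.values()))
    if not per_tree:
        return 0.0, 0.0, {}
    if longest_as_path:
        longest = max(path_by_tree.values())
    else:
        longest = max(per_tree.values())
    return total_length, float(longest), per_tree


# ---------------------------------------------------------------------------
# Synthetic tree generator (ground-truth fixture source)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeGenParams:
    """Branching-process parameters for synthetic test arbors.

    Each primary branch grows outward in segments whose lengths are
    uniform in ``segment_length_range``; after each segment the tip
    bifurcates with probability ``branch_prob`` up to ``max_order``
    branch orders, with ``n_segments`` segments per unbranched run.
    """

    n_primaries: int = 6
    branch_prob: float = 0.3
    n_segments: int = 4
    segment_length_range: tuple[float, float] = (5.0, 15.0)
    max_order: int = 4

    def __post_init__(self) -> None:
        if self.n_primaries < 1 or self.n_segments < 1 or self.max_order < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        lo, hi = self.segment_length_range
        if not (0 < lo <= hi):
            raise ValueError("segment_length_range must be 0 < lo <= hi")


def generate_tree(params: TreeGenParams, seed: int) -> tuple[NeuronTrace, float]:
    """Generate a reproducible random arbor and its ground-truth total length.

    With ``branch_prob = 0`` the result is ``n_primaries`` straight
    radial runs.  Returns ``(trace, total_length)`` where the length is
    accumulated independently during construction (bookkeeping oracle
    for :func:`tree_lengths`).
    """
    rng = np.random.default_rng(seed)
    nodes = [SWCNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
    next_id = 2
    total_length = 0.0

    def grow(parent_id: int, pos: np.ndarray, direction: np.ndarray, order: int):
        nonlocal next_id, total_length
        pid, p = parent_id, pos
        for _ in range(params.n_segments):
            step = rng.uniform(*params.segment_length_range)
            jitter = rng.normal(0.0, 0.25, size=3)
            d = direction + jitter
            d = d / np.linalg.norm(d)
            p = p + step * d
            node = SWCNode(next_id, 3, float(p[0]), float(p[1]), float(p[2]), 0.5, pid)
            nodes.append(node)
            total_length += float(np.linalg.norm(step * d))
            pid = next_id
            next_id += 1
        if order < params.max_order and rng.random() < params.branch_prob:
            for _ in range(2):
                grow(pid, p.copy(), _random_direction(rng, direction), order + 1)

    for _ in range(params.n_primaries):
        direction = _random_direction(rng)
        grow(1, np.zeros(3), direction, 1)
    return NeuronTrace(nodes), total_length


def _random_direction(rng: np.random.Generator, around: np.ndarray | None = None):
    v = rng.normal(size=3)
    if around is not None:
        v = around + 0.8 * v
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([1.0, 0.0, 0.0])
    return v / n
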
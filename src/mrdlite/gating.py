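"""Gating chain: debris exclusion, pseudo-Ficoll gate, marker positivity,
and blast-cluster detection with the minimum-cluster-size rule and
back-gating.

Conventions. Rectangle/polygon gates are *closed*: a point on the boundary
is inside. Marker positivity is a *strict* inequality on the log10 scale:
an event exactly at the threshold is negative. A blast "cluster" is a
fixed-radius connected component (default radius 0.15 log10 units) in the
two-marker space (CD19, CD10) or (CD19, CD34): two candidate events are
linked when their Euclidean distance is <= radius, and components are the
transitive closure of that relation — the simplest reproducible
formalization of a visually contiguous population. A component is called
only if it holds at least ``min_cluster`` events (the 10-event limit of
detection) and back-gates cleanly: at least ``backgate_min_fraction`` of
its events fall outside the FSC/SSC debris field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import load_gate_config
from .fcs_io import Sample

__all__ = [
    "Gate",
    "GateResult",
    "BlastCall",
    "GateError",
    "ClusterConfigError",
    "exclude_debris",
    "pseudo_ficoll_gate",
    "marker_positive",
    "find_blast_clusters",
    "blast_event_indices",
    "fixed_radius_components",
    "gate_from_config",
    "default_gates",
]


class GateError(ValueError):
    """Invalid gate definition or gate/sample mismatch."""


class ClusterConfigError(ValueError):
    """Invalid clustering configuration (e.g. min_cluster < 1)."""


@dataclass(frozen=True)
class Gate:
    """A 2-D rectangle or convex polygon gate in (possibly log) coordinates."""

    name: str
    channel_x: str
    channel_y: str
    transform: tuple[str, str] = ("linear", "linear")
    rect: tuple[float, float, float, float] | None = None  # xmin, xmax, ymin, ymax
    vertices: tuple[tuple[float, float], ...] | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.vertices is None):
            raise GateError(f"gate {self.name!r} must define exactly one of rect/vertices")
        for t in self.transform:
            if t not in ("linear", "log10"):
                raise GateError(f"unknown axis transform {t!r} in gate {self.name!r}")
        if self.vertices is not None:
            v = np.asarray(self.vertices, dtype=float)
            if len(v) < 3:
                raise GateError(f"polygon gate {self.name!r} needs >= 3 vertices")
            # non-collinearity: some triple spans nonzero area
            area = 0.0
            for i in range(len(v)):
                x1, y1 = v[i]
                x2, y2 = v[(i + 1) % len(v)]
                area += x1 * y2 - x2 * y1
            if abs(area) < 1e-12:
                raise GateError(f"polygon gate {self.name!r} vertices are collinear")

    def _axis(self, sample: Sample, channel: str, transform: str) -> np.ndarray:
        vals = sample.channel(channel)  # KeyError -> absent channel
        if transform == "log10":
            return np.log10(np.clip(vals, 1e-12, None))
        return vals

    def contains(self, sample: Sample) -> np.ndarray:
        """Boolean membership of every event (closed boundaries)."""
        try:
            x = self._axis(sample, self.channel_x, self.transform[0])
            y = self._axis(sample, self.channel_y, self.transform[1])
        except KeyError as exc:
            raise GateError(f"gate {self.name!r} references absent channel: {exc}") from None
        if self.rect is not None:
            xmin, xmax, ymin, ymax = self.rect
            return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        from matplotlib.path import Path as MplPath

        v = np.asarray(self.vertices, dtype=float)
        poly = MplPath(np.vstack([v, v[:1]]), closed=True)
        # small positive radius makes boundary points count as inside
        return poly.contains_points(np.column_stack([x, y]), radius=1e-9)


@dataclass(frozen=True)
class GateResult:
    """Boolean membership of events in a named gate, with parent lineage."""

    gate_name: str
    membership: np.ndarray
    parent: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "membership", np.asarray(self.membership, dtype=bool))

    @property
    def n_in(self) -> int:
        return int(self.membership.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.membership)


@dataclass(frozen=True)
class BlastCall:
    """One qualifying blast cluster."""

    phenotype: str  # "CD19_CD10" or "CD19_CD34"
    cluster_event_indices: tuple[int, ...]
    passed_backgate: bool

    @property
    def n_cluster(self) -> int:
        return len(self.cluster_event_indices)


def gate_from_config(entry: dict[str, Any]) -> Gate:
    return Gate(
        name=entry["name"],
        channel_x=entry["channel_x"],
        channel_y=entry["channel_y"],
        transform=tuple(entry.get("transform", ["linear", "linear"])),
        rect=tuple(entry["rect"]) if "rect" in entry else None,
        vertices=tuple(map(tuple, entry["vertices"])) if "vertices" in entry else None,
        parent=entry.get("parent"),
    )


def default_gates(config: dict[str, Any] | None = None) -> dict[str, Gate]:
    cfg = config if config is not None else load_gate_config()
    gates = {g["name"]: gate_from_config(g) for g in cfg["gates"]}
    gates["debris_region"] = gate_from_config({"name": "debris_region", **cfg["debris_region"]})
    return gates


# --------------------------------------------------------------------------
# scatter gates

def exclude_debris(sample: Sample, gate: Gate | None = None,
                   config: dict[str, Any] | None = None) -> GateResult:
    """Debris exclusion on the FSC vs SSC plot: retain events inside the
    non-debris gate (default: everything at or above the FSC boundary)."""
    if gate is None:
        gate = default_gates(config)["nondebris"]
    return GateResult(gate.name, gate.contains(sample), parent=None)


def pseudo_ficoll_gate(sample: Sample, parent: GateResult,
                       gate: Gate | None = None,
                       config: dict[str, Any] | None = None) -> GateResult:
    """Limited scatter gate retaining mononuclear-scatter events (below the
    SSC neutrophil boundary, within the lymph/mono FSC range); a strict
    subset of the debris-exclusion parent."""
    if gate is None:
        gate = default_gates(config)["pseudo_ficoll"]
    member = gate.contains(sample) & parent.membership
    return GateResult(gate.name, member, parent=parent.gate_name)


# --------------------------------------------------------------------------
# marker positivity

def marker_positive(sample: Sample, channel: str,
                    threshold_cfg: float | dict[str, Any],
                    parent: GateResult | None = None) -> np.ndarray:
    """Per-event positivity for one marker.

    ``threshold_cfg`` is either a fixed log10 threshold or
    ``{"mode": "quantile", "q": 0.995, "reference": bool-mask}`` deriving
    the threshold as the q-quantile of a designated negative reference
    population in the same sample. Positivity is strict: log10(x) > t.
    Events outside ``parent`` are reported negative.
    """
    vals = np.log10(np.clip(sample.channel(channel), 1e-12, None))
    if isinstance(threshold_cfg, dict):
        if threshold_cfg.get("mode") != "quantile":
            raise ClusterConfigError(f"unknown threshold mode {threshold_cfg.get('mode')!r}")
        ref = threshold_cfg.get("reference")
        if ref is None:
            raise ClusterConfigError(
                "quantile threshold mode requires a 'reference' negative-population mask"
            )
        ref = np.asarray(ref, dtype=bool)
        if not ref.any():
            raise ClusterConfigError("quantile reference population is empty")
        thr = float(np.quantile(vals[ref], float(threshold_cfg.get("q", 0.995))))
    else:
        thr = float(threshold_cfg)
    pos = vals > thr
    if parent is not None:
        pos &= parent.membership
    return pos


# --------------------------------------------------------------------------
# fixed-radius connected components

def fixed_radius_components(points: np.ndarray, radius: float) -> np.ndarray:
    """Connected components of the <=radius proximity graph in 2-D.

    Exact, permutation-invariant, and fast for the dense blobs cytometry
    produces: points are binned into a grid of cell size radius/sqrt(2)
    (so all same-cell points are automatically linked), then neighboring
    cells are linked when any cross-cell pair is within the radius,
    checked with a cheap subset screen before a full KD-tree query.
    Returns an integer component label per point (labels are arbitrary
    but stable for fixed input order after canonicalization).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if not np.isfinite(radius) or radius <= 0:
        if radius <= 0:
            raise ClusterConfigError(f"cluster radius must be positive, got {radius}")
        return np.zeros(n, dtype=np.int64)  # infinite radius: one component

    cell = radius / np.sqrt(2.0)
    ij = np.floor(pts / cell).astype(np.int64)
    # map cells to contiguous ids
    order = np.lexsort((ij[:, 1], ij[:, 0]))
    ij_sorted = ij[order]
    uniq, inverse_sorted, counts = np.unique(ij_sorted, axis=0, return_inverse=True,
                                             return_counts=True)
    cell_of_point = np.empty(n, dtype=np.int64)
    cell_of_point[order] = inverse_sorted
    n_cells = len(uniq)

    # union-find over cells
    parent = np.arange(n_cells, dtype=np.int64)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    cell_index = {(int(i), int(j)): k for k, (i, j) in enumerate(uniq)}
    starts = np.concatenate([[0], np.cumsum(counts)])
    members = [order[starts[k]:starts[k + 1]] for k in range(n_cells)]

    trees: dict[int, cKDTree] = {}

    def tree_of(k: int) -> cKDTree:
        if k not in trees:
            trees[k] = cKDTree(pts[members[k]])
        return trees[k]

    # offsets with minimal inter-cell distance <= radius (cell = r/sqrt(2));
    # restricted to a half-plane so each pair is examined once
    offsets = [(di, dj) for di in range(0, 3) for dj in range(-2, 3)
               if (di, dj) > (0, 0)]
    r2 = radius * radius
    for k, (ci, cj) in enumerate(uniq):
        a_pts = pts[members[k]]
        for di, dj in offsets:
            kb = cell_index.get((int(ci) + di, int(cj) + dj))
            if kb is None or find(k) == find(kb):
                continue
            b_pts = pts[members[kb]]
            # subset screen: any hit proves connectivity
            sa, sb = a_pts[:64], b_pts[:64]
            d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1)
            if (d2 <= r2).any():
                union(k, kb)
                continue
            if len(a_pts) <= 64 and len(b_pts) <= 64:
                continue  # screen was exhaustive
            dmin, _ = tree_of(kb).query(a_pts, k=1, distance_upper_bound=radius * (1 + 1e-12))
            if np.any(np.isfinite(dmin) & (dmin <= radius)):
                union(k, kb)

    roots = np.array([find(k) for k in range(n_cells)])
    _, comp_of_cell = np.unique(roots, return_inverse=True)
    return comp_of_cell[cell_of_point]


def brute_force_components(points: np.ndarray, radius: float) -> np.ndarray:
    """O(n^2) all-pairs reference implementation (for small inputs/tests)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = -np.ones(n, dtype=np.int64)
    if np.isfinite(radius):
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        adj = d2 <= radius * radius
    else:
        adj = np.ones((n, n), dtype=bool)
    comp = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = comp
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(adj[j]):
                if labels[k] < 0:
                    labels[k] = comp
                    stack.append(int(k))
        comp += 1
    return labels


# --------------------------------------------------------------------------
# blast-cluster detection

def find_blast_clusters(sample: Sample, parent: GateResult,
                        min_cluster: int | None = None,
                        debris_gate: Gate | None = None,
                        config: dict[str, Any] | None = None) -> list[BlastCall]:
    """Detect candidate leukemic clusters and apply the LOD and back-gating
    rules.

    Candidates are events inside ``parent`` that are (CD19+ and CD10+) or
    (CD19+ and CD34+) under the configured thresholds. Each phenotype's
    candidates are clustered by fixed-radius connectivity in the log10
    two-marker plane. A component is returned only if it holds at least
    ``min_cluster`` events (default 10, the limit of detection) and at
    least the configured fraction of its events back-gate outside the
    FSC/SSC debris field.
    """
    cfg = config if config is not None else load_gate_config()
    ccfg = cfg["cluster"]
    if min_cluster is None:
        min_cluster = int(ccfg["min_cluster"])
    if min_cluster < 1:
        raise ClusterConfigError(f"min_cluster must be >= 1, got {min_cluster}")
    radius = float(ccfg["radius"])
    backgate_min = float(ccfg["backgate_min_fraction"])
    thresholds = cfg["thresholds"]
    if debris_gate is None:
        debris_gate = default_gates(cfg)["debris_region"]
    in_debris = debris_gate.contains(sample)

    cd19 = marker_positive(sample, "CD19", thresholds["CD19"], parent)
    calls: list[BlastCall] = []
    for second in ("CD10", "CD34"):
        pos2 = marker_positive(sample, second, thresholds[second], parent)
        cand = np.flatnonzero(cd19 & pos2)
        if len(cand) == 0:
            continue
        pts = np.column_stack([
            np.log10(np.clip(sample.channel("CD19")[cand], 1e-12, None)),
            np.log10(np.clip(sample.channel(second)[cand], 1e-12, None)),
        ])
        labels = fixed_radius_components(pts, radius)
        for comp in np.unique(labels):
            idx = cand[labels == comp]
            if len(idx) < min_cluster:
                continue
            frac_outside = 1.0 - float(in_debris[idx].mean())
            if frac_outside < backgate_min:
                continue
            calls.append(BlastCall(
                phenotype=f"CD19_{second}",
                cluster_event_indices=tuple(int(i) for i in np.sort(idx)),
                passed_backgate=True,
            ))
    return calls


def blast_event_indices(calls: Sequence[BlastCall]) -> np.ndarray:
    """Union of event indices across qualifying blast calls."""
    if not calls:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate([np.asarray(c.cluster_event_indices) for c in calls]))
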
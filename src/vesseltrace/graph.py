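"""Centerline graphs of vascular networks.

A :class:`CenterlineGraph` is the common currency between the phantom
generator (which knows the true geometry) and the tracer (which recovers it
from a binary mask): nodes are vessel endpoints and branchpoints with
physical positions, edges carry the full centerline polyline in micrometres
plus optional per-point radii.  Graphs round-trip losslessly through a
JSON-structured text format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Node", "Edge", "CenterlineGraph"]


@dataclass(eq=False)
class Node:
    id: int
    position_um: np.ndarray  # (z, y, x) micrometres
    kind: str = "endpoint"  # endpoint | branchpoint | loop

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)


@dataclass(eq=False)
class Edge:
    u: int
    v: int
    polyline_um: np.ndarray  # (n, 3) ordered (z, y, x) points, micrometres
    radii_um: np.ndarray | None = None  # per-point radius, micrometres
    mean_diameter_um: float | None = None

    def __post_init__(self) -> None:
        self.polyline_um = np.asarray(self.polyline_um, dtype=float)
        if self.polyline_um.ndim != 2 or self.polyline_um.shape[1] != 3:
            raise ValueError("edge polyline must be an (n, 3) array")
        if self.polyline_um.shape[0] < 2:
            raise ValueError("edge polyline needs at least 2 points")
        if self.radii_um is not None:
            self.radii_um = np.asarray(self.radii_um, dtype=float)
            if self.radii_um.shape[0] != self.polyline_um.shape[0]:
                raise ValueError("radii and polyline lengths differ")

    @property
    def length_um(self) -> float:
        """Arc length: sum of consecutive Euclidean distances."""
        return float(np.linalg.norm(np.diff(self.polyline_um, axis=0), axis=1).sum())


@dataclass
class CenterlineGraph:
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    def node_by_id(self, node_id: int) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def degrees(self) -> dict[int, int]:
        deg = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    @property
    def total_length_um(self) -> float:
        return float(sum(e.length_um for e in self.edges))

    def refresh_kinds(self) -> None:
        """Set node kinds from current degrees (1 → endpoint, else branchpoint).

        Nodes tagged ``loop`` (artificial nodes breaking isolated cycles)
        keep their tag.
        """
        deg = self.degrees()
        for n in self.nodes:
            if n.kind == "loop":
                continue
            n.kind = "endpoint" if deg[n.id] == 1 else "branchpoint"

    def simplify(self) -> None:
        """Splice out degree-2 nodes, concatenating their two edges.

        Keeps total length exactly (shared point counted once) and removes
        isolated nodes.  Self-loops and ``loop`` nodes are left alone.
        """
        changed = True
        while changed:
            changed = False
            deg = self.degrees()
            for n in list(self.nodes):
                if n.kind == "loop" or deg.get(n.id, 0) != 2:
                    continue
                incident = [e for e in self.edges if n.id in (e.u, e.v)]
                if len(incident) != 2 or any(e.u == e.v for e in incident):
                    continue
                a, b = incident
                pa = a.polyline_um if a.v == n.id else a.polyline_um[::-1]
                pb = b.polyline_um if b.u == n.id else b.polyline_um[::-1]
                ra = a.radii_um if a.radii_um is not None else None
                rb = b.radii_um if b.radii_um is not None else None
                if ra is not None and a.v != n.id:
                    ra = ra[::-1]
                if rb is not None and b.u != n.id:
                    rb = rb[::-1]
                u = a.u if a.v == n.id else a.v
                v = b.v if b.u == n.id else b.u
                poly = np.vstack([pa, pb[1:]])
                radii = None
                if ra is not None and rb is not None:
                    radii = np.concatenate([ra, rb[1:]])
                self.edges.remove(a)
                self.edges.remove(b)
                self.edges.append(Edge(u, v, poly, radii))
                changed = True
            # drop isolated nodes
            deg = self.degrees()
            for n in list(self.nodes):
                if deg.get(n.id, 0) == 0:
                    self.nodes.remove(n)
        self.refresh_kinds()

    # ---- JSON round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "position_um": list(map(float, n.position_um)), "kind": n.kind}
                for n in self.nodes
            ],
            "edges": [
                {
                    "u": e.u,
                    "v": e.v,
                    "polyline_um": e.polyline_um.tolist(),
                    "radii_um": None if e.radii_um is None else e.radii_um.tolist(),
                    "mean_diameter_um": e.mean_diameter_um,
                    "length_um": e.length_um,
                }
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlineGraph":
        nodes = [Node(n["id"], np.asarray(n["position_um"]), n["kind"]) for n in d["nodes"]]
        edges = [
            Edge(
                e["u"],
                e["v"],
                np.asarray(e["polyline_um"]),
                None if e.get("radii_um") is None else np.asarray(e["radii_um"]),
                e.get("mean_diameter_um"),
            )
            for e in d["edges"]
        ]
        return cls(nodes, edges)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CenterlineGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))
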
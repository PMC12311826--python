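"""ZIP-code-level graph construction.

Three connectivity mechanisms are supported, mirroring the usual choices in
spatial epidemiology:

* an **aggregated contact graph** summing activity-weighted person-level
  contacts between residents of two ZIP codes,
* a **geographic adjacency graph** (unit weight for boundary-sharing pairs),
* a **distance graph** (fully connected, inverse centroid distance).

All builders return symmetric, hollow (zero-diagonal) weight matrices over
one shared ZIP ordering, and `minmax_normalize_weights` rescales realized
edge weights into [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactEdge",
    "ZipGeometry",
    "ZipGraph",
    "build_aggregated_contact_graph",
    "build_adjacency_graph",
    "build_distance_graph",
    "minmax_normalize_weights",
]


@dataclass(frozen=True)
class ContactEdge:
    """One person-to-person contact with its home-ZIP endpoints."""

    person_u: str
    person_v: str
    zip_u: str
    zip_v: str
    weight: float

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError(f"negative contact weight {self.weight}")


@dataclass
class ZipGeometry:
    """Polygon adjacency pairs and planar centroids for a set of ZIPs."""

    adjacency_pairs: set[frozenset]
    centroids: dict[str, tuple[float, float]]

    def neighbors(self, zip_id: str) -> set[str]:
        out = set()
        for pair in self.adjacency_pairs:
            if zip_id in pair:
                out |= set(pair) - {zip_id}
        return out


@dataclass
class ZipGraph:
    """Weighted undirected graph over an ordered list of ZIP codes.

    Invariants: W is symmetric and hollow (no self-loops), entries are
    nonnegative, and after min-max normalization they lie in [0, 1].
    """

    zips: list[str]
    W: np.ndarray
    kind: str = "aggregated_contact"
    normalized: bool = False
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        n = len(self.zips)
        if len(set(self.zips)) != n:
            raise ValueError("duplicate ZIPs in graph")
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} != ({n}, {n})")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal (no self-loops)")
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative")
        self.index = {z: i for i, z in enumerate(self.zips)}

    @property
    def n_nodes(self) -> int:
        return len(self.zips)

    def subset(self, keep_zips: Sequence[str]) -> "ZipGraph":
        """Restrict to `keep_zips`, preserving their given order."""
        idx = [self.index[z] for z in keep_zips]
        return ZipGraph(list(keep_zips), self.W[np.ix_(idx, idx)],
                        kind=self.kind, normalized=self.normalized)

    # ---- serialization (edge-list CSV + JSON header) -------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        ii, jj = np.nonzero(np.triu(self.W))
        pd.DataFrame({
            "zip_i": [self.zips[i] for i in ii],
            "zip_j": [self.zips[j] for j in jj],
            "w": self.W[ii, jj],
        }).to_csv(path, index=False)
        header = {"kind": self.kind, "zips": self.zips,
                  "normalized": self.normalized}
        path.with_suffix(".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, path: str | Path) -> "ZipGraph":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        zips = [str(z) for z in header["zips"]]
        index = {z: i for i, z in enumerate(zips)}
        W = np.zeros((len(zips), len(zips)))
        edges = pd.read_csv(path, dtype={"zip_i": str, "zip_j": str})
        for zi, zj, w in edges.itertuples(index=False):
            W[index[zi], index[zj]] = W[index[zj], index[zi]] = w
        return cls(zips, W, kind=header["kind"], normalized=header["normalized"])


def build_aggregated_contact_graph(edges: Iterable[ContactEdge],
                                   zips: Sequence[str]) -> ZipGraph:
    """Sum person-level contact weights into a ZIP x ZIP matrix.

    Intra-ZIP contacts are discarded (the graph is hollow); edges touching
    unknown ZIPs are dropped with a warning.
    """
    zips = list(zips)
    index = {z: i for i, z in enumerate(zips)}
    W = np.zeros((len(zips), len(zips)))
    n_dropped = 0
    for e in edges:
        if e.zip_u not in index or e.zip_v not in index:
            n_dropped += 1
            continue
        i, j = index[e.zip_u], index[e.zip_v]
        if i == j:
            continue
        W[i, j] += e.weight
        W[j, i] += e.weight
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} contact edges with unknown ZIPs")
    if not W.any():
        raise ValueError("no cross-ZIP contacts: aggregated graph is empty")
    return ZipGraph(zips, W, kind="aggregated_contact")


def build_adjacency_graph(geom: ZipGeometry, zips: Sequence[str]) -> ZipGraph:
    """Unit-weight edge for every boundary-sharing ZIP pair."""
    zips = list(zips)
    index = {z: i for i, z in enumerate(zips)}
    W = np.zeros((len(zips), len(zips)))
    for pair in geom.adjacency_pairs:
        a, b = tuple(pair)
        if a in index and b in index and a != b:
            W[index[a], index[b]] = W[index[b], index[a]] = 1.0
    return ZipGraph(zips, W, kind="adjacency")


def build_distance_graph(geom: ZipGeometry, zips: Sequence[str]) -> ZipGraph:
    """Fully connected graph weighted by inverse centroid distance."""
    zips = list(zips)
    pts = np.array([geom.centroids[z] for z in zips], dtype=np.float64)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(len(zips), dtype=bool)
    if np.any(dist[off] == 0):
        raise ValueError("coincident centroids give an infinite edge weight")
    W = np.zeros_like(dist)
    W[off] = 1.0 / dist[off]
    return ZipGraph(zips, W, kind="distance")


def minmax_normalize_weights(g: ZipGraph) -> ZipGraph:
    """Min-max rescale realized edge weights to [0, 1].

    Structural zeros (absent edges) are excluded from the min/max and stay
    zero; a graph whose realized weights are all equal (e.g. adjacency)
    maps them to 1 to preserve connectivity.
    """
    if g.normalized:
        return ZipGraph(list(g.zips), g.W.copy(), kind=g.kind,
                        normalized=True)
    mask = g.W > 0
    if not mask.any():
        raise ValueError("cannot normalize a graph with no edges")
    w = g.W[mask]
    lo, hi = w.min(), w.max()
    W = np.zeros_like(g.W)
    if hi == lo:
        W[mask] = 1.0
    else:
        W[mask] = (g.W[mask] - lo) / (hi - lo)
    return ZipGraph(list(g.zips), W, kind=g.kind, normalized=True)
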
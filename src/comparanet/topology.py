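"""Centrality and clustering metrics, cross-network rank correlation, and
mean+std hub flagging.

Weighted betweenness uses edge lengths 1/weight; weighted clustering uses the
Onnela cube-root form (weights scaled by the network maximum); eigenvector
centrality is the nonnegative principal eigenvector of the (weighted)
adjacency matrix with unit Euclidean norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import linalg, stats

from .core import Connectome

__all__ = [
    "MetricVector",
    "betweenness",
    "eigenvector_centrality",
    "clustering",
    "cross_species_correlation",
    "hub_flags",
]

METRIC_NAMES = ("degree", "strength", "BC", "EC", "C")


@dataclass(frozen=True)
class MetricVector:
    """A named per-region metric aligned with a label sequence."""

    metric_name: str
    labels: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"metric_name must be one of {METRIC_NAMES}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels),):
            raise ValueError("values length must match labels")
        v.setflags(write=False)

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.labels, self.values)}


def _to_graph(c: Connectome) -> nx.Graph:
    if c.directed:
        raise ValueError("topology metrics require undirected connectomes")
    g = nx.Graph()
    g.add_nodes_from(c.labels)
    i, j = np.nonzero(np.triu(c.weights, k=1))
    for a, b in zip(i, j):
        w = float(c.weights[a, b])
        g.add_edge(c.labels[a], c.labels[b], weight=w, length=1.0 / w)
    return g


def betweenness(c: Connectome, normalized: bool = False) -> MetricVector:
    """Shortest-path betweenness; weighted graphs use lengths 1/weight."""
    g = _to_graph(c)
    if c.n_regions < 3:
        vals = np.zeros(c.n_regions)
    else:
        bc = nx.betweenness_centrality(
            g, normalized=normalized,
            weight="length" if c.weighted else None,
        )
        vals = np.array([bc[lab] for lab in c.labels], dtype=float)
    return MetricVector("BC", c.labels, vals, normalized=normalized)


def eigenvector_centrality(c: Connectome) -> MetricVector:
    """Nonnegative unit-norm principal eigenvector of the adjacency matrix.

    On disconnected graphs the dominant component carries the mass; a warning
    lists the components.
    """
    if c.directed:
        raise ValueError("eigenvector centrality requires undirected input")
    n = c.n_regions
    if n == 0 or c.n_edges == 0:
        raise ValueError("eigenvector centrality undefined on an empty graph")
    g = _to_graph(c)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        warnings.warn(
            f"graph has {len(comps)} connected components; eigenvector "
            f"centrality mass concentrates on the dominant one: "
            f"{[sorted(s) for s in comps]}"
        )
    evals, evecs = linalg.eigh(c.weights)
    v = evecs[:, np.argmax(evals)]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # Perron vector is nonnegative up to sign/rounding
    v = v / np.linalg.norm(v)
    return MetricVector("EC", c.labels, v, normalized=True)


def clustering(c: Connectome, normalized: bool = False) -> MetricVector:
    """Per-region triangle density; Onnela form on weighted graphs.

    Regions of degree < 2 get value 0 by convention.  ``normalized`` is
    recorded on the result but binary/Onnela values are already in [0, 1].
    """
    g = _to_graph(c)
    cc = nx.clustering(g, weight="weight" if c.weighted else None)
    vals = np.array([cc[lab] for lab in c.labels], dtype=float)
    return MetricVector("C", c.labels, vals, normalized=normalized)


def cross_species_correlation(
    m1: MetricVector, m2: MetricVector
) -> tuple[float, float]:
    """Spearman rank correlation between two same-labeled metric vectors.

    Uses tie-corrected ranks with a two-sided t-approximation p-value.
    Constant vectors yield (nan, nan).
    """
    if m1.labels != m2.labels:
        raise ValueError("metric vectors must share the same label order")
    if np.all(m1.values == m1.values[0]) or np.all(m2.values == m2.values[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(m1.values, m2.values)
    return float(rho), float(p)


def hub_flags(m: MetricVector, direction: str = "above") -> dict[str, bool]:
    """Flag regions beyond one standard deviation of the metric's mean."""
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    mean = float(np.mean(m.values))
    std = float(np.std(m.values, ddof=1)) if len(m.values) > 1 else 0.0
    if direction == "above":
        flags = m.values > mean + std
    else:
        flags = m.values < mean - std
    return {lab: bool(f) for lab, f in zip(m.labels, flags)}
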
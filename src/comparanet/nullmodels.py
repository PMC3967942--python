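"""Null-network generation, robustness perturbations, and empirical
statistics shared by all analyses.

Degree-preserving randomization uses attempted double-edge swaps
((a,b),(c,d) -> (a,d),(c,b)) rejecting self-loops and multi-edges; the
weighted null rewires the topology the same way and then permutes the edge
weight multiset over the new edges.  Everything is reproducible from a
single integer seed.

Empirical p-values follow the (1 + count) / (1 + n) convention, so the
minimum attainable p at n = 10000 nulls is about 1e-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .core import Connectome, density

__all__ = [
    "NullEnsemble",
    "PerturbationSpec",
    "degree_preserving_rewire",
    "link_weight_reshuffle",
    "perturb",
    "build_ensemble",
    "build_pair_ensemble",
    "empirical_stats",
    "correct_pvalues",
    "STATISTICS",
]

NULL_MODELS = ("degree_preserving", "link_weight_reshuffle", "region_draw")

#: default attempted swaps per edge for the rewiring chain
DEFAULT_SWAPS_PER_EDGE = 10.0


@dataclass
class NullEnsemble:
    """A sequence of null statistic outcomes with its generator descriptor."""

    model_name: str
    size: int
    seed: int
    values: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model_name not in NULL_MODELS:
            raise ValueError(f"model_name must be one of {NULL_MODELS}")
        if self.size != len(self.values):
            raise ValueError("size must equal the number of stored values")
        if self.size < 1:
            raise ValueError("ensemble must contain at least one draw")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class PerturbationSpec:
    """Robustness perturbation: probabilistic rewiring or edge insertion."""

    kind: str
    parameter: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rewire_prob", "insert_fraction"):
            raise ValueError("kind must be 'rewire_prob' or 'insert_fraction'")
        if self.kind == "rewire_prob" and not 0.0 <= self.parameter <= 1.0:
            raise ValueError("rewire_prob must lie in [0, 1]")
        if self.kind == "insert_fraction" and self.parameter < 0:
            raise ValueError("insert_fraction must be nonnegative")


@njit(cache=True)
def _swap_kernel(adj, edges, pick_a, pick_b, flips):  # pragma: no cover
    for t in range(pick_a.shape[0]):
        ia = pick_a[t]
        ib = pick_b[t]
        if ia == ib:
            continue
        a = edges[ia, 0]
        b = edges[ia, 1]
        c = edges[ib, 0]
        d = edges[ib, 1]
        if flips[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[ia, 0] = a
        edges[ia, 1] = d
        edges[ib, 0] = c
        edges[ib, 1] = b


def _edge_array(c: Connectome) -> np.ndarray:
    i, j = np.nonzero(np.triu(c.weights, k=1))
    return np.column_stack([i, j]).astype(np.int64)


def _rewire_support(
    adj: np.ndarray, edges: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> None:
    """In-place attempted double-edge swaps on a boolean adjacency matrix."""
    if n_attempts <= 0 or len(edges) < 2:
        return
    pick_a = rng.integers(0, len(edges), size=n_attempts)
    pick_b = rng.integers(0, len(edges), size=n_attempts)
    flips = rng.integers(0, 2, size=n_attempts).astype(np.bool_)
    _swap_kernel(adj, edges, pick_a, pick_b, flips)


def degree_preserving_rewire(
    c: Connectome,
    n_swap_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
) -> Connectome:
    """Randomize a binary connectome while conserving every region's degree.

    Performs ``round(n_swap_per_edge * L)`` attempted double-edge swaps.
    Complete and (near-)empty graphs are returned unchanged with a warning.
    """
    if c.directed or c.weighted:
        raise ValueError("degree-preserving rewiring requires binary undirected input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = c.n_regions
    L = c.n_edges
    if L < 2 or L == n * (n - 1) // 2:
        warnings.warn("graph too constrained to swap; returning a copy")
        return Connectome(c.labels, c.weights.copy(), False, False, c.species_tag)
    adj = c.adjacency_bool().copy()
    edges = _edge_array(c)
    _rewire_support(adj, edges, round(n_swap_per_edge * L), rng)
    return Connectome(c.labels, adj.astype(float), False, False, c.species_tag)


def link_weight_reshuffle(
    c: Connectome,
    seed: int | np.random.Generator = 0,
    n_swap_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
) -> Connectome:
    """Weighted null: degree-preserving topology rewire, then permute the
    edge-weight multiset over the new edges.  The weight multiset is
    conserved exactly; strength sequences generally are not."""
    if c.directed:
        raise ValueError("link_weight_reshuffle requires undirected input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = c.n_regions
    L = c.n_edges
    iu = np.triu_indices(n, k=1)
    weights_pool = c.weights[iu]
    weights_pool = weights_pool[weights_pool != 0]
    adj = c.adjacency_bool().copy()
    if L >= 2 and L < n * (n - 1) // 2:
        edges = _edge_array(c)
        _rewire_support(adj, edges, round(n_swap_per_edge * L), rng)
    else:
        warnings.warn("graph too constrained to swap; reshuffling weights only")
    new_w = np.zeros((n, n))
    i, j = np.nonzero(np.triu(adj, k=1))
    perm = rng.permutation(len(weights_pool))
    new_w[i, j] = weights_pool[perm]
    new_w = new_w + new_w.T
    return Connectome(c.labels, new_w, directed=False, weighted=True,
                      species_tag=c.species_tag)


def perturb(c: Connectome, spec: PerturbationSpec) -> Connectome:
    """Apply a robustness perturbation.

    ``rewire_prob``: every edge is considered once in random order and with
    probability p enters a swap pool; pooled edges are paired up and swapped
    where feasible, conserving the degree sequence and edge count.

    ``insert_fraction``: exactly ``round(fraction * L)`` edges are added
    uniformly at random into empty unordered pairs; degrees are NOT
    conserved and the edge count grows accordingly.
    """
    if c.directed or c.weighted:
        raise ValueError("perturbations operate on binary undirected connectomes")
    rng = np.random.default_rng(spec.seed)
    n = c.n_regions
    L = c.n_edges
    if spec.kind == "rewire_prob":
        p = spec.parameter
        if p == 0 or L < 2:
            return Connectome(c.labels, c.weights.copy(), False, False, c.species_tag)
        edges = _edge_array(c)
        marked = np.nonzero(rng.random(L) < p)[0]
        adj = c.adjacency_bool().copy()
        # pair marked edges and swap each at most once, retrying infeasible
        # pairings so the rewired fraction tracks p
        unswapped = list(marked)
        budget = 50 * max(len(marked), 1)
        while len(unswapped) >= 2 and budget > 0:
            budget -= 1
            ia, ib = rng.choice(len(unswapped), size=2, replace=False)
            a, b = edges[unswapped[ia]]
            c_, d = edges[unswapped[ib]]
            if rng.integers(0, 2):
                c_, d = d, c_
            for _ in range(2):
                if not (a == c_ or a == d or b == c_ or b == d
                        or adj[a, d] or adj[c_, b]):
                    adj[a, b] = adj[b, a] = False
                    adj[c_, d] = adj[d, c_] = False
                    adj[a, d] = adj[d, a] = True
                    adj[c_, b] = adj[b, c_] = True
                    edges[unswapped[ia]] = (a, d)
                    edges[unswapped[ib]] = (c_, b)
                    for k in sorted((ia, ib), reverse=True):
                        unswapped.pop(k)
                    break
                c_, d = d, c_
        return Connectome(c.labels, adj.astype(float), False, False, c.species_tag)
    # insert_fraction
    k = round(spec.parameter * L)
    empty = np.argwhere(np.triu(c.weights == 0, k=1))
    if k > len(empty):
        raise ValueError(
            f"cannot insert {k} edges: only {len(empty)} empty pairs available"
        )
    out = c.weights.copy()
    if k > 0:
        pick = rng.choice(len(empty), size=k, replace=False)
        for i, j in empty[pick]:
            out[i, j] = out[j, i] = 1.0
    return Connectome(c.labels, out, False, False, c.species_tag)


# ---------------------------------------------------------------------------
# Ensembles and empirical statistics
# ---------------------------------------------------------------------------

STATISTICS: dict[str, Callable[[Connectome], object]] = {
    "density": density,
    "edge_count": lambda c: c.n_edges,
}


def _resolve_statistic(statistic) -> Callable:
    if callable(statistic):
        return statistic
    try:
        return STATISTICS[statistic]
    except KeyError:
        raise ValueError(
            f"unknown statistic {statistic!r}; known: {sorted(STATISTICS)}"
        ) from None


def _null_draw(c: Connectome, model_name: str, rng: np.random.Generator) -> Connectome:
    if model_name == "degree_preserving":
        return degree_preserving_rewire(c, seed=rng)
    if model_name == "link_weight_reshuffle":
        return link_weight_reshuffle(c, seed=rng)
    raise ValueError(f"unsupported null model {model_name!r}")


def _check_model(c: Connectome, model_name: str) -> None:
    if model_name == "degree_preserving" and c.weighted:
        raise ValueError("degree_preserving nulls apply to binary connectomes")
    if model_name == "link_weight_reshuffle" and not c.weighted:
        raise ValueError("link_weight_reshuffle nulls apply to weighted connectomes")


def build_ensemble(
    c: Connectome, model_name: str, n: int, seed: int, statistic
) -> NullEnsemble:
    """Evaluate ``statistic`` on ``n`` independent null draws of ``c``."""
    if n < 1:
        raise ValueError("ensemble size must be at least 1")
    _check_model(c, model_name)
    stat = _resolve_statistic(statistic)
    rng = np.random.default_rng(seed)
    values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n):
            values.append(stat(_null_draw(c, model_name, rng)))
    return NullEnsemble(model_name=model_name, size=n, seed=seed, values=values)


def build_pair_ensemble(
    a: Connectome, b: Connectome, model_name: str, n: int, seed: int, statistic
) -> NullEnsemble:
    """Two-network statistic under independent nulls of BOTH networks.

    Used for cross-network statistics (intersection ratio, neighborhood
    similarities): each draw independently randomizes both inputs and
    evaluates ``statistic(null_a, null_b)``.
    """
    if n < 1:
        raise ValueError("ensemble size must be at least 1")
    _check_model(a, model_name)
    _check_model(b, model_name)
    stat = statistic if callable(statistic) else _resolve_statistic(statistic)
    rng = np.random.default_rng(seed)
    values = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n):
            na = _null_draw(a, model_name, rng)
            nb = _null_draw(b, model_name, rng)
            values.append(stat(na, nb))
    return NullEnsemble(model_name=model_name, size=n, seed=seed, values=values)


def empirical_stats(
    observed: float, ensemble: NullEnsemble | Sequence[float], side: str = "greater"
) -> tuple[float, float]:
    """z-score and empirical one-sided p against a null ensemble.

    p = (1 + #{null at least as extreme}) / (1 + n); z is NaN when the null
    standard deviation vanishes.
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    values = ensemble.as_array() if isinstance(ensemble, NullEnsemble) else np.asarray(
        ensemble, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("empty null ensemble")
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    z = (observed - mean) / std if std > 0 else float("nan")
    if side == "greater":
        count = int(np.sum(values >= observed))
    else:
        count = int(np.sum(values <= observed))
    p = (1 + count) / (1 + len(values))
    return z, p


def correct_pvalues(
    ps: dict[str, float], method: str = "bonferroni", alpha: float = 0.05
) -> dict[str, bool]:
    """Multiple-testing correction over region-wise p-values.

    NaN p-values (undefined-marked regions) are excluded from the test count
    and flagged False.  ``bonferroni`` declares significance at p < alpha/m;
    ``fdr_bh`` applies the Benjamini-Hochberg step-up at level alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    defined = {k: v for k, v in ps.items() if not np.isnan(v)}
    for k, v in defined.items():
        if not 0 < v <= 1:
            raise ValueError(f"p-value for {k!r} outside (0, 1]: {v}")
    out = {k: False for k in ps}
    m = len(defined)
    if m == 0:
        return out
    if method == "bonferroni":
        for k, v in defined.items():
            out[k] = v < alpha / m
    elif method == "fdr_bh":
        items = sorted(defined.items(), key=lambda kv: kv[1])
        cutoff = 0
        for rank, (_, v) in enumerate(items, start=1):
            if v <= alpha * rank / m:
                cutoff = rank
        for rank, (k, _) in enumerate(items, start=1):
            out[k] = rank <= cutoff
    else:
        raise ValueError("method must be 'bonferroni' or 'fdr_bh'")
    return out
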
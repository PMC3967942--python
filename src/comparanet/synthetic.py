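"""Synthetic inputs: the four-node toy pair, planted-overlap connectome pairs,
and multi-subject weighted matrices.

All generators are deterministic given their seed, so test fixtures and
acceptance runs can be regenerated from scratch with no data downloads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import Connectome, RegionTable, HEMISPHERES, LOBE_CLASSES

__all__ = [
    "PlantedPairSpec",
    "fig1d_toy",
    "generate_planted_pair",
    "generate_subjects",
    "random_connectome",
    "random_weighted_connectome",
    "default_labels",
    "default_region_table",
]


def default_labels(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n)))
    return tuple(f"R{i:0{width}d}" for i in range(1, n + 1))


def default_region_table(n: int) -> RegionTable:
    """Region table with the first half L, second half R, lobes cycling."""
    labels = default_labels(n)
    half = n // 2
    hemis = tuple("L" if i < half else "R" for i in range(n))
    cyc = ("frontal", "temporal", "parietal", "occipital", "limbic",
           "insular", "subcortical")
    lobes = tuple(cyc[i % len(cyc)] for i in range(n))
    return RegionTable(labels, hemis, lobes)


def fig1d_toy() -> tuple[Connectome, Connectome]:
    """Two 4-node, 4-edge toy networks differing by one rewired connection.

    Network 1 edges: A-B, A-C, A-D, B-C.  Network 2 edges: A-B, A-C, A-D, C-D.
    Region A keeps its neighbor set across the pair while its neighborhood
    similarity profile diverges.
    """
    labels = ("A", "B", "C", "D")

    def build(edges):
        w = np.zeros((4, 4))
        pos = {lab: i for i, lab in enumerate(labels)}
        for u, v in edges:
            w[pos[u], pos[v]] = w[pos[v], pos[u]] = 1.0
        return Connectome(labels, w, directed=False, weighted=False)

    net1 = build([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")])
    net2 = build([("A", "B"), ("A", "C"), ("A", "D"), ("C", "D")])
    return net1, net2


@dataclass(frozen=True)
class PlantedPairSpec:
    """Recipe for a pair of binary connectomes with planted structure.

    ``edge_overlap`` is the planted fraction of shared edges.  Regions in
    ``preserved_regions`` get identical neighborhoods across the pair;
    regions in ``rewired_regions`` get (as far as the preserved constraint
    allows) disjoint neighborhoods.
    """

    n_regions: int
    n_edges: int
    edge_overlap: float
    preserved_regions: frozenset[str] = field(default_factory=frozenset)
    rewired_regions: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "preserved_regions",
                           frozenset(self.preserved_regions))
        object.__setattr__(self, "rewired_regions",
                           frozenset(self.rewired_regions))
        if not 0.0 <= self.edge_overlap <= 1.0:
            raise ValueError("edge_overlap must lie in [0, 1]")
        max_edges = self.n_regions * (self.n_regions - 1) // 2
        if not 0 < self.n_edges <= max_edges:
            raise ValueError("n_edges must be positive and fit the node count")
        if self.preserved_regions & self.rewired_regions:
            raise ValueError("preserved and rewired region sets must be disjoint")


def generate_planted_pair(
    spec: PlantedPairSpec, labels: tuple[str, ...] | None = None
) -> tuple[Connectome, Connectome]:
    """Generate two binary undirected connectomes with planted edge overlap.

    Construction: the shared edge set (size round(overlap*L)) is sampled from
    pairs not incident to any rewired region; pairs incident to a preserved
    region may only be shared or absent, so preserved neighborhoods are
    identical by construction; the two species-specific remainders are drawn
    from disjoint candidate pairs, so the realized overlap equals the planted
    count exactly and rewired regions share no incident edges.
    """
    n, L = spec.n_regions, spec.n_edges
    if labels is None:
        labels = default_labels(n)
    if len(labels) != n:
        raise ValueError("label count must equal n_regions")
    label_set = set(labels)
    for r in spec.preserved_regions | spec.rewired_regions:
        if r not in label_set:
            raise ValueError(f"planted region {r!r} not among labels")
    pos = {lab: i for i, lab in enumerate(labels)}
    preserved = {pos[r] for r in spec.preserved_regions}
    rewired = {pos[r] for r in spec.rewired_regions}

    shared_target = round(spec.edge_overlap * L)
    pairs = list(itertools.combinations(range(n), 2))
    p_pres = [p for p in pairs if (p[0] in preserved or p[1] in preserved)]
    p_rew = [p for p in pairs
             if (p[0] in rewired or p[1] in rewired)
             and not (p[0] in preserved or p[1] in preserved)]
    planted = preserved | rewired
    p_rest = [p for p in pairs if p[0] not in planted and p[1] not in planted]

    shared_candidates = p_pres + p_rest
    if shared_target > len(shared_candidates):
        raise ValueError(
            "infeasible spec: not enough pairs outside the rewired regions "
            "for the planted shared edges"
        )
    rng = np.random.default_rng(spec.seed)
    shared_idx = rng.choice(len(shared_candidates), size=shared_target,
                            replace=False)
    shared = {shared_candidates[i] for i in shared_idx}

    # species-specific edges: disjoint draws from pairs that are neither
    # shared nor incident to a preserved region
    specific_pool = [p for p in p_rest + p_rew if p not in shared]
    need = 2 * (L - shared_target)
    if need > len(specific_pool):
        raise ValueError(
            "infeasible spec: overlap and planted-region constraints leave "
            "too few candidate pairs for the species-specific edges"
        )
    pick = rng.choice(len(specific_pool), size=need, replace=False)
    a_only = {specific_pool[i] for i in pick[: L - shared_target]}
    b_only = {specific_pool[i] for i in pick[L - shared_target:]}

    def build(extra):
        w = np.zeros((n, n))
        for i, j in shared | extra:
            w[i, j] = w[j, i] = 1.0
        return Connectome(tuple(labels), w, directed=False, weighted=False)

    a = build(a_only)
    b = build(b_only)
    assert a.n_edges == b.n_edges == L
    return a, b


def generate_subjects(
    base: Connectome, n_subjects: int, noise_sd: float, seed: int
) -> list[Connectome]:
    """Per-subject weighted matrices: base plus clipped symmetric noise."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if base.directed:
        raise ValueError("base connectome must be undirected")
    rng = np.random.default_rng(seed)
    n = base.n_regions
    subjects = []
    for _ in range(n_subjects):
        noise = rng.normal(0.0, noise_sd, size=(n, n)) if noise_sd > 0 else np.zeros((n, n))
        noise = np.triu(noise, k=1)
        noise = noise + noise.T
        w = np.clip(base.weights + noise, 0.0, None)
        np.fill_diagonal(w, 0.0)
        subjects.append(
            Connectome(base.labels, w, directed=False, weighted=True,
                       species_tag=base.species_tag)
        )
    return subjects


def random_connectome(
    n_regions: int, n_edges: int, seed: int,
    labels: tuple[str, ...] | None = None, species_tag: str = ""
) -> Connectome:
    """Uniform binary undirected connectome with exactly ``n_edges`` edges."""
    max_edges = n_regions * (n_regions - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError("n_edges out of range for n_regions")
    if labels is None:
        labels = default_labels(n_regions)
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n_regions), 2))
    pick = rng.choice(len(pairs), size=n_edges, replace=False)
    w = np.zeros((n_regions, n_regions))
    for k in pick:
        i, j = pairs[k]
        w[i, j] = w[j, i] = 1.0
    return Connectome(tuple(labels), w, directed=False, weighted=False,
                      species_tag=species_tag)


def random_weighted_connectome(
    n_regions: int, n_edges: int, seed: int,
    labels: tuple[str, ...] | None = None, species_tag: str = ""
) -> Connectome:
    """Random topology with i.i.d. uniform(0.1, 1) edge weights."""
    binary = random_connectome(n_regions, n_edges, seed, labels, species_tag)
    rng = np.random.default_rng(seed + 1)
    w = binary.weights.copy()
    iu = np.triu_indices(n_regions, k=1)
    vals = rng.uniform(0.1, 1.0, size=len(iu[0]))
    upper = w[iu] * vals
    w = np.zeros_like(w)
    w[iu] = upper
    w = w + w.T
    return Connectome(binary.labels, w, directed=False, weighted=True,
                      species_tag=species_tag)
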
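"""Cross-network similarity statistics for same-parcellation connectomes.

Four region-wise statistics compare two labeled networks sharing a label
sequence:

* :func:`intersection_ratio` — shared edge count over the (common) edge count.
* :func:`hcs` — per-region Jaccard similarity of neighbor sets across the
  two networks ("first-order" connectivity preservation).
* :func:`hmis` — per-region Pearson correlation of matching-index rows
  across the two networks ("second-order" preservation of the connectivity
  similarity profile).
* Weighted variants replacing the set arithmetic with cosine similarity of
  weight rows.

The matching index between regions i and j excludes BOTH endpoint regions
from the neighbor sets before intersecting; the weighted cosine variant
mirrors this by zeroing positions i and j in both rows.  Undefined values
(empty unions, zero rows, zero variance) are marked NaN and propagated —
never silently replaced by 0.  Pearson correlations require at least
``MIN_PAIRED`` valid paired entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Connectome, _require_same_labels

__all__ = [
    "MatchingIndexMatrix",
    "intersection_ratio",
    "hcs",
    "hcs_vector",
    "matching_index",
    "hmis",
    "hmis_vector",
    "weighted_matching_index",
    "weighted_hmis",
    "weighted_hmis_vector",
]

#: minimum number of valid paired entries for a row correlation
MIN_PAIRED = 3


@dataclass(frozen=True)
class MatchingIndexMatrix:
    """Symmetric region-by-region neighborhood-similarity matrix.

    Off-diagonal entries lie in [0, 1]; the diagonal and any entry whose
    denominator vanishes are NaN.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matching-index matrix must match label count")
        v.setflags(write=False)

    def row(self, i: int) -> np.ndarray:
        """Row ``i`` with the diagonal entry removed."""
        return np.delete(self.values[i], i)


def intersection_ratio(
    a: Connectome, b: Connectome, allow_unequal: bool = False
) -> float:
    """Shared unordered edges divided by the common edge count L."""
    _require_same_labels(a, b)
    for c in (a, b):
        if c.directed or c.weighted:
            raise ValueError("intersection_ratio requires binary undirected input")
    la, lb = a.n_edges, b.n_edges
    if la != lb:
        if not allow_unequal:
            raise ValueError(
                f"edge counts differ ({la} vs {lb}); pass allow_unequal=True "
                "to divide by the first network's count"
            )
        warnings.warn("edge counts differ; dividing by the first network's L")
    if la == 0:
        raise ValueError("first network has no edges")
    shared = int(np.count_nonzero(
        np.triu(a.adjacency_bool() & b.adjacency_bool(), k=1)))
    return shared / la


def hcs_vector(a: Connectome, b: Connectome) -> np.ndarray:
    """Per-region Jaccard of neighbor sets, NaN where the union is empty."""
    _require_same_labels(a, b)
    aa, ab = a.adjacency_bool(), b.adjacency_bool()
    inter = (aa & ab).sum(axis=1).astype(float)
    union = (aa | ab).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, np.nan)
    return out


def hcs(a: Connectome, b: Connectome) -> dict[str, float]:
    """Homologue connectivity similarity: label -> Jaccard in [0, 1]."""
    vec = hcs_vector(a, b)
    return {lab: float(v) for lab, v in zip(a.labels, vec)}


def matching_index(a: Connectome) -> MatchingIndexMatrix:
    """Neighborhood-overlap similarity between every region pair.

    MI(i, j) = |(G(i) n G(j)) \\ {i,j}| / |(G(i) u G(j)) \\ {i,j}| on the
    binary support.  Since the graph has no self-loops the intersection never
    contains i or j; the union loses one element per endpoint exactly when
    the pair is itself connected.
    """
    if a.directed:
        raise ValueError("matching_index requires an undirected connectome")
    adj = a.adjacency_bool()
    deg = adj.sum(axis=1).astype(float)
    common = (adj.astype(float) @ adj.astype(float))
    union = deg[:, None] + deg[None, :] - common - 2.0 * adj
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = np.where(union > 0, common / union, np.nan)
    np.fill_diagonal(mi, np.nan)
    return MatchingIndexMatrix(a.labels, mi)


def _row_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with pairwise NaN removal; NaN on short or constant input."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < MIN_PAIRED:
        return float("nan")
    xv, yv = x[mask], y[mask]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(xv, yv)[0, 1])


def _rowwise_correlation(
    ma: MatchingIndexMatrix, mb: MatchingIndexMatrix
) -> np.ndarray:
    n = len(ma.labels)
    out = np.empty(n)
    for i in range(n):
        out[i] = _row_pearson(ma.row(i), mb.row(i))
    return out


def hmis_vector(a: Connectome, b: Connectome) -> np.ndarray:
    _require_same_labels(a, b)
    return _rowwise_correlation(matching_index(a), matching_index(b))


def hmis(a: Connectome, b: Connectome) -> dict[str, float]:
    """Homologue matching-index similarity: label -> Pearson r in [-1, 1].

    Correlates region i's matching-index row between the two networks, with
    the diagonal (self-similarity) entry excluded and undefined entries
    dropped pairwise.
    """
    vec = hmis_vector(a, b)
    return {lab: float(v) for lab, v in zip(a.labels, vec)}


def weighted_matching_index(a: Connectome) -> MatchingIndexMatrix:
    """Cosine similarity of weight rows with positions i and j zeroed.

    The endpoint exclusion mirrors the binary matching index, as does the
    undefined convention: an entry is NaN only when both excluded rows are
    zero (both neighborhoods empty); a single empty row gives similarity 0.
    The diagonal is NaN.
    """
    if a.directed:
        raise ValueError("weighted_matching_index requires undirected input")
    w = a.weights
    n = a.n_regions
    # row i with positions i and j zeroed: w[i] has w[i,i]=0 already, so
    # only position j must be dropped (and symmetrically i from row j).
    norms_sq = (w ** 2).sum(axis=1)
    out = np.full((n, n), np.nan)
    dots = w @ w.T
    for i in range(n):
        for j in range(i + 1, n):
            # dot of excluded rows: positions i and j contribute
            # w[i,j]*w[j,j] + w[i,i]*w[j,i] = 0, so the dot is unchanged
            dot = dots[i, j]
            ni = norms_sq[i] - w[i, j] ** 2
            nj = norms_sq[j] - w[j, i] ** 2
            if ni <= 0 and nj <= 0:
                continue  # both rows empty after exclusion: undefined
            if ni <= 0 or nj <= 0:
                out[i, j] = out[j, i] = 0.0  # one empty row: zero similarity
            else:
                out[i, j] = out[j, i] = dot / np.sqrt(ni * nj)
    return MatchingIndexMatrix(a.labels, out)


def weighted_hmis_vector(a: Connectome, b: Connectome) -> np.ndarray:
    _require_same_labels(a, b)
    return _rowwise_correlation(weighted_matching_index(a),
                                weighted_matching_index(b))


def weighted_hmis(a: Connectome, b: Connectome) -> dict[str, float]:
    """Weighted homologue matching-index similarity per region."""
    vec = weighted_hmis_vector(a, b)
    return {lab: float(v) for lab, v in zip(a.labels, vec)}
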
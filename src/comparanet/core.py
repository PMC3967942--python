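"""Domain types, labeled-matrix I/O, and connectome-construction transforms.

A :class:`Connectome` is a labeled square adjacency matrix together with
``directed``/``weighted`` flags.  A :class:`RegionTable` carries the region
labels, their hemisphere assignment and a coarse lobe classification; its
record order defines the canonical matrix index order.

Two plain-text dialects are supported: a dense delimited matrix with a header
row and a leading label column, and a three-column edge list
``label_i <TAB> label_j <TAB> weight``.  Edge lists describe undirected
connectomes only; directed matrices must use the dense dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "Connectome",
    "RegionMetricResult",
    "read_region_table",
    "read_connectome",
    "write_connectome",
    "symmetrize_binarize",
    "average_subjects",
    "threshold_to_edge_count",
    "density",
    "split_hemispheres",
    "subject_consistency",
    "merge_regions",
]

HEMISPHERES = ("L", "R")
LOBE_CLASSES = (
    "frontal",
    "temporal",
    "parietal",
    "occipital",
    "limbic",
    "insular",
    "subcortical",
    "allocortical",
    "isocortical",
    "unknown",
)


@dataclass(frozen=True)
class RegionTable:
    """Per-region label, hemisphere and lobe class; order is canonical."""

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    lobe_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if not (len(self.labels) == len(self.hemispheres) == len(self.lobe_classes)):
            raise ValueError("labels, hemispheres and lobe_classes must align")
        bad_h = set(self.hemispheres) - set(HEMISPHERES)
        if bad_h:
            raise ValueError(f"unknown hemisphere codes: {sorted(bad_h)}")
        bad_l = set(self.lobe_classes) - set(LOBE_CLASSES)
        if bad_l:
            raise ValueError(f"unknown lobe classes: {sorted(bad_l)}")

    def __len__(self) -> int:
        return len(self.labels)

    def hemisphere_labels(self, hemisphere: str) -> tuple[str, ...]:
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        return tuple(
            lab for lab, h in zip(self.labels, self.hemispheres) if h == hemisphere
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "lobe_class": self.lobe_classes,
            }
        )
        df.to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> RegionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"label", "hemisphere", "lobe_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    return RegionTable(
        labels=tuple(df["label"]),
        hemispheres=tuple(df["hemisphere"]),
        lobe_classes=tuple(df["lobe_class"]),
    )


@dataclass(frozen=True)
class Connectome:
    """Labeled square matrix of nonnegative connection values."""

    labels: tuple[str, ...]
    weights: np.ndarray
    directed: bool = False
    weighted: bool = False
    species_tag: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate region labels")
        if w.ndim != 2 or w.shape != (n, n):
            raise ValueError(
                f"weights must be a {n}x{n} matrix matching the label count"
            )
        if np.any(w < 0):
            raise ValueError("negative connection weights are not allowed")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal entries (self-connections) must be zero")
        if not self.directed and not np.array_equal(w, w.T):
            raise ValueError("undirected connectome requires a symmetric matrix")
        if not self.weighted and not np.all(np.isin(w, (0.0, 1.0))):
            raise ValueError("binary connectome entries must be 0 or 1")
        w.setflags(write=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        """Number of unordered nonzero pairs (undirected edge count L)."""
        if self.directed:
            raise ValueError("edge count over unordered pairs requires undirected")
        iu = np.triu_indices(self.n_regions, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def adjacency_bool(self) -> np.ndarray:
        return self.weights != 0

    def degrees(self) -> np.ndarray:
        """Binary-support degree per region (undirected)."""
        if self.directed:
            raise ValueError("degrees defined for undirected connectomes")
        return (self.weights != 0).sum(axis=1)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in connectome") from None

    def edge_set(self) -> frozenset[tuple[str, str]]:
        """Unordered label pairs with nonzero weight (undirected only)."""
        if self.directed:
            raise ValueError("edge_set defined for undirected connectomes")
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return frozenset(
            tuple(sorted((self.labels[a], self.labels[b])))
            for a, b in zip(i, j)
        )

    def same_labels_as(self, other: "Connectome") -> bool:
        return self.labels == other.labels


@dataclass(frozen=True)
class RegionMetricResult:
    """Per-region observed value with its null calibration.

    ``z`` is NaN when the null standard deviation vanishes or the observed
    value is undefined; ``p`` uses the one-sided empirical convention.
    """

    label: str
    observed: float
    null_mean: float
    null_std: float
    z: float
    p: float
    significant: bool = False


def _require_same_labels(a: Connectome, b: Connectome) -> None:
    if a.labels != b.labels:
        raise ValueError(
            "connectomes have mismatching label sequences; "
            "canonicalize both against the same RegionTable first"
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _reorder(labels: list[str], weights: np.ndarray, region_table: RegionTable):
    missing = set(labels) - set(region_table.labels)
    if missing:
        raise ValueError(f"labels absent from region table: {sorted(missing)}")
    target = [lab for lab in region_table.labels if lab in set(labels)]
    idx = [labels.index(lab) for lab in target]
    return target, weights[np.ix_(idx, idx)]


def read_connectome(
    path: str | Path,
    fmt: str = "dense",
    region_table: RegionTable | None = None,
    species_tag: str = "",
) -> Connectome:
    """Read a labeled connectome from a dense matrix or a 3-column edge list.

    Dense files must have identical row/column label headers.  Edge lists are
    interpreted as undirected: ``(A, B, w)`` and ``(B, A, w)`` denote the same
    edge and must agree in weight when both appear.  Labels are put in
    ``region_table`` order when a table is given, else first-appearance order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        row_labels = [str(x) for x in df.index]
        col_labels = [str(x) for x in df.columns]
        if len(row_labels) != len(col_labels):
            raise ValueError("dense connectome file is not square")
        if row_labels != col_labels:
            raise ValueError("dense file row and column labels differ")
        if len(set(row_labels)) != len(row_labels):
            raise ValueError("duplicate labels in dense file")
        weights = df.to_numpy(dtype=float)
        if np.any(np.diag(weights) != 0):
            warnings.warn("nonzero diagonal entries forced to zero on ingest")
            weights = weights.copy()
            np.fill_diagonal(weights, 0.0)
        labels = row_labels
        if region_table is not None:
            labels, weights = _reorder(labels, weights, region_table)
        directed = not np.array_equal(weights, weights.T)
        weighted = not np.all(np.isin(weights, (0.0, 1.0)))
        return Connectome(tuple(labels), weights, directed, weighted, species_tag)
    elif fmt == "edgelist":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["label_i", "label_j", "weight"],
            dtype={"label_i": str, "label_j": str},
            comment="#",
        )
        # tolerate an optional header row
        if len(df) and str(df.iloc[0]["weight"]).lower() in {"weight", "w"}:
            df = df.iloc[1:]
        seen: dict[tuple[str, str], float] = {}
        order: list[str] = []
        for li, lj, w in df.itertuples(index=False):
            w = float(w)
            if li == lj:
                raise ValueError(f"self-pair ({li},{lj}) not allowed")
            if w < 0:
                raise ValueError(f"negative weight on edge ({li},{lj})")
            key = (li, lj) if li <= lj else (lj, li)
            if key in seen:
                if seen[key] != w:
                    raise ValueError(
                        f"conflicting weights for undirected pair {key}"
                    )
            else:
                seen[key] = w
            for lab in (li, lj):
                if lab not in order:
                    order.append(lab)
        labels = order
        if region_table is not None:
            missing = set(labels) - set(region_table.labels)
            if missing:
                raise ValueError(
                    f"labels absent from region table: {sorted(missing)}"
                )
            labels = list(region_table.labels)
        n = len(labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        weights = np.zeros((n, n))
        for (li, lj), w in seen.items():
            weights[pos[li], pos[lj]] = w
            weights[pos[lj], pos[li]] = w
        weighted = not np.all(np.isin(weights, (0.0, 1.0)))
        return Connectome(tuple(labels), weights, False, weighted, species_tag)
    raise ValueError(f"unknown format {fmt!r}; expected 'dense' or 'edgelist'")


def write_connectome(c: Connectome, path: str | Path, fmt: str = "dense") -> None:
    """Write ``c`` so that :func:`read_connectome` reproduces it exactly."""
    path = Path(path)
    if fmt == "dense":
        df = pd.DataFrame(c.weights, index=list(c.labels), columns=list(c.labels))
        df.to_csv(path, sep="\t", float_format="%.17g")  # bit-exact round trip
    elif fmt == "edgelist":
        if c.directed:
            raise ValueError("edge-list format is undirected-only; use dense")
        i, j = np.nonzero(np.triu(c.weights, k=1))
        with open(path, "w") as fh:
            for a, b in zip(i, j):
                fh.write(f"{c.labels[a]}\t{c.labels[b]}\t{c.weights[a, b]:.17g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Construction transforms
# ---------------------------------------------------------------------------


def symmetrize_binarize(c: Connectome) -> Connectome:
    """Undirected binary connectome: edge iff any nonzero entry either way."""
    adj = ((c.weights != 0) | (c.weights.T != 0)).astype(float)
    np.fill_diagonal(adj, 0.0)
    return Connectome(c.labels, adj, directed=False, weighted=False,
                      species_tag=c.species_tag)


def average_subjects(cs: Sequence[Connectome]) -> Connectome:
    """Entry-wise arithmetic mean of same-labeled weighted connectomes."""
    if len(cs) == 0:
        raise ValueError("cannot average an empty sequence of connectomes")
    first = cs[0]
    for c in cs[1:]:
        _require_same_labels(first, c)
    for c in cs:
        if c.directed:
            raise ValueError("average_subjects requires undirected connectomes")
    mean = np.mean([c.weights for c in cs], axis=0)
    return Connectome(first.labels, mean, directed=False, weighted=True,
                      species_tag=first.species_tag)


def _ranked_pairs(c: Connectome) -> list[tuple[int, int]]:
    """Nonzero unordered pairs sorted by (weight desc, labels lex asc)."""
    i, j = np.nonzero(np.triu(c.weights, k=1))
    pairs = list(zip(i.tolist(), j.tolist()))
    return sorted(
        pairs,
        key=lambda p: (-c.weights[p[0], p[1]],
                       min(c.labels[p[0]], c.labels[p[1]]),
                       max(c.labels[p[0]], c.labels[p[1]])),
    )


def threshold_to_edge_count(
    c: Connectome, target_L: int, keep_weights: bool = False
) -> Connectome:
    """Keep exactly ``target_L`` strongest edges.

    Ties at the cut are broken deterministically: weight descending, then
    lexicographic (label_i, label_j) ascending.  The result is binary unless
    ``keep_weights`` is set, in which case surviving edges retain their
    weights (used by the weighted hemisphere-wise arm).
    """
    if c.directed:
        raise ValueError("thresholding requires an undirected connectome")
    if target_L < 0:
        raise ValueError("target_L must be nonnegative")
    ranked = _ranked_pairs(c)
    if target_L > len(ranked):
        raise ValueError(
            f"target_L={target_L} exceeds available nonzero pairs ({len(ranked)})"
        )
    n = c.n_regions
    out = np.zeros((n, n))
    for a, b in ranked[:target_L]:
        v = c.weights[a, b] if keep_weights else 1.0
        out[a, b] = out[b, a] = v
    return Connectome(c.labels, out, directed=False, weighted=keep_weights,
                      species_tag=c.species_tag)


def density(c: Connectome) -> float:
    """Fraction of unordered pairs connected: L / (N(N-1)/2)."""
    if c.directed:
        raise ValueError("density defined for undirected connectomes")
    n = c.n_regions
    if n < 2:
        raise ValueError("density requires at least 2 regions")
    return c.n_edges / (n * (n - 1) / 2)


def split_hemispheres(c: Connectome, rt: RegionTable) -> tuple[Connectome, Connectome]:
    """Induced subnetworks on L- and R-labeled regions (cross edges dropped)."""
    missing = set(c.labels) - set(rt.labels)
    if missing:
        raise ValueError(f"labels missing from region table: {sorted(missing)}")
    hemi_of = dict(zip(rt.labels, rt.hemispheres))
    out = []
    for h in HEMISPHERES:
        idx = [i for i, lab in enumerate(c.labels) if hemi_of[lab] == h]
        sub = c.weights[np.ix_(idx, idx)]
        out.append(
            Connectome(tuple(c.labels[i] for i in idx), sub,
                       directed=c.directed, weighted=c.weighted,
                       species_tag=c.species_tag)
        )
    return out[0], out[1]


def subject_consistency(
    cs: Sequence[Connectome], target_L: int, m: int
) -> tuple[float, list[float]]:
    """Edge reproducibility of the thresholded average across subjects.

    Returns the fraction of edges of the thresholded average matrix present
    in at least ``m`` individually thresholded subject matrices, plus the
    Pearson correlations of upper-triangle weight vectors for every unordered
    subject pair (unthresholded).
    """
    if len(cs) < 2:
        raise ValueError("need at least two subjects")
    if m > len(cs):
        raise ValueError("m cannot exceed the number of subjects")
    avg_thr = threshold_to_edge_count(average_subjects(cs), target_L)
    subj_sets = [threshold_to_edge_count(c, target_L).edge_set() for c in cs]
    hits = 0
    avg_edges = avg_thr.edge_set()
    for e in avg_edges:
        if sum(e in s for s in subj_sets) >= m:
            hits += 1
    fraction = hits / len(avg_edges) if avg_edges else float("nan")
    iu = np.triu_indices(cs[0].n_regions, k=1)
    correlations = []
    for a in range(len(cs)):
        for b in range(a + 1, len(cs)):
            va, vb = cs[a].weights[iu], cs[b].weights[iu]
            correlations.append(float(np.corrcoef(va, vb)[0, 1]))
    return fraction, correlations


def merge_regions(c: Connectome, mapping: dict[str, str]) -> Connectome:
    """Coarsen a binary connectome by merging regions under ``mapping``.

    A merged pair is connected iff any constituent cross-pair was connected.
    Used by the parcellation-robustness harness.
    """
    if c.weighted or c.directed:
        raise ValueError("merge_regions supports binary undirected input")
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for i, lab in enumerate(c.labels):
        g = mapping.get(lab, lab)
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    n = len(order)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            block = c.weights[np.ix_(groups[order[a]], groups[order[b]])]
            if np.any(block != 0):
                out[a, b] = out[b, a] = 1.0
    return Connectome(tuple(order), out, directed=False, weighted=False,
                      species_tag=c.species_tag)
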
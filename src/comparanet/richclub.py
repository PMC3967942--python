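"""Rich-club analysis: binary/weighted coefficients, null normalization,
member extraction, cross-network overlap permutation test, and rich versus
non-rich metric contrasts.

"Degree higher than k" is strict (>).  The binary coefficient at level k is
phi(k) = 2 E_>k / (N_>k (N_>k - 1)); the weighted form divides the weight sum
among the high-degree set by the sum of the E_>k largest edge weights in the
whole network (degrees always taken on the binary support).  Levels with
fewer than two qualifying regions are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Connectome
from .nullmodels import NullEnsemble, empirical_stats
from .topology import MetricVector

__all__ = [
    "RichClubCurve",
    "rcc",
    "weighted_rcc",
    "normalized_rcc",
    "rich_members",
    "overlap_test",
    "rich_vs_nonrich_test",
]


@dataclass(frozen=True)
class RichClubCurve:
    """Per-level rich-club coefficients with optional null calibration.

    ``ks`` runs from 0 to max degree - 1.  ``phi`` is NaN where fewer than
    two regions exceed the level.  ``null_mean``/``null_std``/``phi_norm``/
    ``p`` are NaN until :func:`normalized_rcc` fills them in.  ``members``
    holds, per level, the tuple of labels with degree > k.
    """

    labels: tuple[str, ...]
    ks: np.ndarray
    phi: np.ndarray
    n_gt_k: np.ndarray
    e_or_w_gt_k: np.ndarray
    members: tuple[tuple[str, ...], ...]
    weighted: bool = False
    null_mean: np.ndarray | None = None
    null_std: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        nk = len(self.ks)
        for name in ("phi", "n_gt_k", "e_or_w_gt_k"):
            if len(getattr(self, name)) != nk:
                raise ValueError(f"{name} must align with ks")
        if len(self.members) != nk:
            raise ValueError("members must align with ks")
        sizes = [len(m) for m in self.members]
        if any(sizes[i] < sizes[i + 1] for i in range(nk - 1)):
            raise ValueError("member sets must shrink (weakly) as k grows")

    def peak_k(self, min_members: int = 3) -> int:
        """Level maximizing phi_norm among levels with at least
        ``min_members`` qualifying regions and a defined null mean."""
        if self.phi_norm is None:
            raise ValueError("curve has no null normalization")
        ok = (self.n_gt_k >= min_members) & ~np.isnan(self.phi_norm)
        if self.null_mean is not None:
            ok &= ~np.isnan(self.null_mean)
        if not np.any(ok):
            raise ValueError("no level satisfies the peak-selection rule")
        masked = np.where(ok, self.phi_norm, -np.inf)
        return int(self.ks[int(np.argmax(masked))])

    def members_at(self, k: int) -> tuple[str, ...]:
        idx = np.nonzero(self.ks == k)[0]
        if len(idx) == 0:
            raise KeyError(f"level k={k} not on the curve")
        return self.members[int(idx[0])]


def _curve_levels(c: Connectome):
    deg = c.degrees()
    max_deg = int(deg.max()) if len(deg) else 0
    ks = np.arange(max_deg)
    return deg, ks


def rcc(c: Connectome) -> RichClubCurve:
    """Binary rich-club coefficient phi(k) for k = 0 .. max degree - 1."""
    if c.directed or c.weighted:
        raise ValueError("rcc requires a binary undirected connectome")
    deg, ks = _curve_levels(c)
    adj = c.adjacency_bool()
    phi = np.full(len(ks), np.nan)
    n_gt = np.zeros(len(ks), dtype=int)
    e_gt = np.full(len(ks), np.nan)
    members = []
    for k in ks:
        mask = deg > k
        n = int(mask.sum())
        n_gt[k] = n
        members.append(tuple(lab for lab, m in zip(c.labels, mask) if m))
        if n >= 2:
            e = int(adj[np.ix_(mask, mask)].sum()) // 2
            e_gt[k] = e
            phi[k] = 2.0 * e / (n * (n - 1))
    return RichClubCurve(c.labels, ks, phi, n_gt, e_gt, tuple(members),
                         weighted=False)


def weighted_rcc(c: Connectome) -> RichClubCurve:
    """Weighted rich-club coefficient with degrees on the binary support.

    phi_w(k) = W_>k / (sum of the E_>k largest edge weights network-wide);
    NaN when no edges link the high-degree set.
    """
    if c.directed:
        raise ValueError("weighted_rcc requires an undirected connectome")
    deg, ks = _curve_levels(c)
    w = c.weights
    iu = np.triu_indices(c.n_regions, k=1)
    all_w = w[iu]
    all_w = np.sort(all_w[all_w != 0])[::-1]
    cum = np.concatenate([[0.0], np.cumsum(all_w)])
    phi = np.full(len(ks), np.nan)
    n_gt = np.zeros(len(ks), dtype=int)
    w_gt = np.full(len(ks), np.nan)
    members = []
    for k in ks:
        mask = deg > k
        n = int(mask.sum())
        n_gt[k] = n
        members.append(tuple(lab for lab, m in zip(c.labels, mask) if m))
        if n < 2:
            continue
        sub = w[np.ix_(mask, mask)]
        e = int(np.count_nonzero(np.triu(sub, k=1)))
        if e == 0:
            continue
        w_sum = float(np.triu(sub, k=1).sum())
        w_gt[k] = w_sum
        phi[k] = w_sum / cum[e]
    return RichClubCurve(c.labels, ks, phi, n_gt, w_gt, tuple(members),
                         weighted=True)


def normalized_rcc(c: Connectome, ensemble: NullEnsemble) -> RichClubCurve:
    """Attach null mean/std, phi_norm = phi / mean(phi_null) and per-level
    one-sided empirical p to a rich-club curve.

    ``ensemble.values`` must hold per-draw phi arrays on the same k grid
    (degree-conserving nulls guarantee an identical grid).
    """
    curve = weighted_rcc(c) if c.weighted else rcc(c)
    nulls = np.array([np.asarray(v, dtype=float) for v in ensemble.values])
    if nulls.ndim != 2 or nulls.shape[1] != len(curve.ks):
        raise ValueError("null phi arrays do not align with the observed curve")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN levels
        null_mean = np.nanmean(nulls, axis=0)
        null_std = np.nanstd(nulls, axis=0, ddof=1)
    phi_norm = np.full(len(curve.ks), np.nan)
    p = np.full(len(curve.ks), np.nan)
    for i in range(len(curve.ks)):
        col = nulls[:, i]
        col = col[~np.isnan(col)]
        if np.isnan(curve.phi[i]) or len(col) == 0 or not null_mean[i] > 0:
            continue
        phi_norm[i] = curve.phi[i] / null_mean[i]
        _, p[i] = empirical_stats(curve.phi[i], col.tolist(), side="greater")
    return RichClubCurve(
        curve.labels, curve.ks, curve.phi, curve.n_gt_k, curve.e_or_w_gt_k,
        curve.members, weighted=curve.weighted,
        null_mean=null_mean, null_std=null_std, phi_norm=phi_norm, p=p,
    )


def rich_members(c: Connectome, k: int) -> set[str]:
    """Labels of regions with (binary-support) degree strictly above k."""
    deg = c.degrees()
    return {lab for lab, d in zip(c.labels, deg) if d > k}


def overlap_test(
    a: Connectome, b: Connectome, k_a: int, k_b: int,
    n_draws: int = 10000, seed: int = 0,
) -> tuple[int, float]:
    """Observed rich-set overlap against uniform random region draws.

    The null redraws, ``n_draws`` times, region sets of the observed sizes
    uniformly without replacement (independently per network) and counts the
    overlap; p = (1 + #{null >= observed}) / (1 + n_draws).
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("overlap test requires identical label universes")
    ra, rb = rich_members(a, k_a), rich_members(b, k_b)
    if not ra or not rb:
        raise ValueError("rich member set empty in one of the networks")
    observed = len(ra & rb)
    rng = np.random.default_rng(seed)
    n = len(a.labels)
    na, nb = len(ra), len(rb)
    count = 0
    for _ in range(n_draws):
        da = rng.choice(n, size=na, replace=False)
        db = rng.choice(n, size=nb, replace=False)
        if len(np.intersect1d(da, db)) >= observed:
            count += 1
    p = (1 + count) / (1 + n_draws)
    return observed, p


def rich_vs_nonrich_test(
    m: MetricVector, members: set[str], n_perm: int = 10000,
    seed: int = 0, direction: str = "greater",
) -> float:
    """Permutation test contrasting a metric between a region set and its
    complement.

    The observed statistic is mean(members) - mean(non-members); membership
    labels are randomly reassigned ``n_perm`` times and the one-sided tail
    probability returned with the (1 + count) / (1 + n) convention.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    labels = set(m.labels)
    if not members or not members < labels:
        raise ValueError("members must be a nonempty proper subset of the labels")
    mask = np.array([lab in members for lab in m.labels])
    values = m.values
    observed = float(values[mask].mean() - values[~mask].mean())
    rng = np.random.default_rng(seed)
    n_mem = int(mask.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        stat = perm[:n_mem].mean() - perm[n_mem:].mean()
        if direction == "greater":
            count += stat >= observed
        else:
            count += stat <= observed
    return (1 + count) / (1 + n_perm)
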
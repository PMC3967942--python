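"""End-to-end orchestration of the comparative analysis.

Two arms:

* ``whole_brain_binary`` — binarized networks: edge-set intersection ratio,
  region-wise neighborhood similarity (HCS) and matching-index profile
  similarity (HMIS) against degree-preserving null pairs, centrality and
  clustering with cross-network Spearman correlations, and the normalized
  rich-club analysis with a cross-network member-overlap permutation test.

* ``hemisphere_weighted`` — per-hemisphere weighted networks: weighted HMIS,
  weighted centrality/clustering, and the weighted normalized rich club
  against link-and-weight-reshuffle nulls.  Cross-matrix statistics that mix
  incomparable weight scales (the intersection and HCS) are deliberately
  absent from this arm.

Every number in a report is a deterministic function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    Connectome,
    RegionMetricResult,
    RegionTable,
    average_subjects,
    density,
    read_connectome,
    read_region_table,
    split_hemispheres,
    symmetrize_binarize,
    threshold_to_edge_count,
)
from .nullmodels import (
    PerturbationSpec,
    build_ensemble,
    build_pair_ensemble,
    correct_pvalues,
    empirical_stats,
    perturb,
)
from .richclub import normalized_rcc, overlap_test, rcc, weighted_rcc
from .similarity import hcs_vector, hmis_vector, intersection_ratio, weighted_hmis_vector
from .topology import (
    MetricVector,
    betweenness,
    clustering,
    cross_species_correlation,
    eigenvector_centrality,
    hub_flags,
)

__all__ = [
    "AnalysisConfig",
    "ComparativeReport",
    "run_whole_brain",
    "run_hemisphere_weighted",
    "write_report",
]

log = logging.getLogger("comparanet")

ARMS = ("whole_brain_binary", "hemisphere_weighted")


@dataclass
class AnalysisConfig:
    """Inputs and knobs for one analysis run."""

    species_a: str
    species_b: str | list[str]
    region_table: str
    arm: str = "whole_brain_binary"
    fmt: str = "dense"
    n_null: int = 10000
    n_overlap_draws: int = 10000
    alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 0
    perturbations: list[PerturbationSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        if self.n_null < 1:
            raise ValueError("n_null must be at least 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        perts = [
            p if isinstance(p, PerturbationSpec) else PerturbationSpec(**p)
            for p in raw.pop("perturbations", [])
        ]
        return cls(perturbations=perts, **raw)

    def echo(self) -> dict:
        d = asdict(self)
        d["perturbations"] = [asdict(p) for p in self.perturbations]
        return d


@dataclass
class ComparativeReport:
    """All outputs of one arm; every p-value carries its null model and n."""

    arm: str
    seed: int
    n_null: int
    alpha: float
    correction: str
    null_model: str
    labels: tuple[str, ...]
    intersection: dict | None = None
    hcs: dict[str, RegionMetricResult] | None = None
    hmis: dict[str, RegionMetricResult] | None = None
    topology: dict | None = None
    richclub: dict | None = None
    robustness: dict | None = None
    hemispheres: dict | None = None


# ---------------------------------------------------------------------------
# loading helpers
# ---------------------------------------------------------------------------


def _load_species_a(config: AnalysisConfig, rt: RegionTable) -> Connectome:
    c = read_connectome(config.species_a, config.fmt, rt, species_tag="A")
    return c


def _load_species_b(config: AnalysisConfig, rt: RegionTable) -> Connectome:
    paths = config.species_b
    if isinstance(paths, (list, tuple)):
        subjects = [
            read_connectome(p, config.fmt, rt, species_tag="B") for p in paths
        ]
        return average_subjects(subjects)
    return read_connectome(paths, config.fmt, rt, species_tag="B")


def _region_results(
    labels: tuple[str, ...],
    observed: np.ndarray,
    null_matrix: np.ndarray,
    correction: str,
    alpha: float,
) -> dict[str, RegionMetricResult]:
    """Per-region z/p against a (draws x regions) null matrix, corrected."""
    ps: dict[str, float] = {}
    interim = {}
    for idx, lab in enumerate(labels):
        obs = float(observed[idx])
        col = null_matrix[:, idx]
        col = col[~np.isnan(col)]
        if np.isnan(obs) or len(col) == 0:
            interim[lab] = (obs, float("nan"), float("nan"), float("nan"),
                            float("nan"))
            ps[lab] = float("nan")
            continue
        z, p = empirical_stats(obs, col.tolist(), side="greater")
        interim[lab] = (obs, float(col.mean()),
                        float(col.std(ddof=1)) if len(col) > 1 else 0.0, z, p)
        ps[lab] = p
    flags = correct_pvalues(ps, method=correction, alpha=alpha)
    return {
        lab: RegionMetricResult(lab, *interim[lab], significant=flags[lab])
        for lab in labels
    }


def _topology_block(a: Connectome, b: Connectome, normalized: bool) -> dict:
    out = {}
    metrics = {
        "BC": lambda c: betweenness(c, normalized=normalized),
        "EC": eigenvector_centrality,
        "C": lambda c: clustering(c, normalized=normalized),
    }
    for name, fn in metrics.items():
        ma, mb = fn(a), fn(b)
        rho, p = cross_species_correlation(ma, mb)
        hub_dir = "below" if name == "C" else "above"
        out[name] = {
            "a": ma,
            "b": mb,
            "rho": rho,
            "p": p,
            "hubs_a": hub_flags(ma, hub_dir),
            "hubs_b": hub_flags(mb, hub_dir),
        }
    return out


def _richclub_block(
    a: Connectome, b: Connectome, model: str, n_null: int,
    n_overlap_draws: int, seeds: np.ndarray,
) -> dict:
    phi_of = (lambda g: weighted_rcc(g).phi) if a.weighted else (
        lambda g: rcc(g).phi)
    ens_a = build_ensemble(a, model, n_null, int(seeds[0]), phi_of)
    ens_b = build_ensemble(b, model, n_null, int(seeds[1]), phi_of)
    curve_a = normalized_rcc(a, ens_a)
    curve_b = normalized_rcc(b, ens_b)
    k_a, k_b = curve_a.peak_k(), curve_b.peak_k()
    overlap, p = overlap_test(a, b, k_a, k_b, n_draws=n_overlap_draws,
                              seed=int(seeds[2]))
    return {
        "curve_a": curve_a,
        "curve_b": curve_b,
        "peak_k_a": k_a,
        "peak_k_b": k_b,
        "members_a": curve_a.members_at(k_a),
        "members_b": curve_b.members_at(k_b),
        "overlap": overlap,
        "overlap_p": p,
        "overlap_n_draws": n_overlap_draws,
    }


# ---------------------------------------------------------------------------
# whole-brain binary arm
# ---------------------------------------------------------------------------


def run_whole_brain(config: AnalysisConfig) -> ComparativeReport:
    """Binary whole-network comparison of two same-parcellation connectomes.

    Species B given as a subject list is averaged, thresholded to species
    A's edge count and binarized before comparison.
    """
    if config.arm != "whole_brain_binary":
        raise ValueError("config arm does not match run_whole_brain")
    rt = read_region_table(config.region_table)
    a_raw = _load_species_a(config, rt)
    a = symmetrize_binarize(a_raw) if (a_raw.directed or a_raw.weighted) else a_raw
    b_raw = _load_species_b(config, rt)
    if b_raw.weighted:
        b = threshold_to_edge_count(b_raw, a.n_edges)
    else:
        b = b_raw
    if a.labels != b.labels:
        raise ValueError("species label sequences do not match")
    if a.n_edges != b.n_edges:
        raise ValueError(
            f"edge counts differ after construction ({a.n_edges} vs "
            f"{b.n_edges}); densities are not matched"
        )
    log.info("whole-brain arm: N=%d L=%d density=%.3f seed=%d n_null=%d",
             a.n_regions, a.n_edges, density(a), config.seed, config.n_null)

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    # one paired null ensemble feeds the intersection, HCS and HMIS
    def pair_stat(na: Connectome, nb: Connectome):
        return {
            "ir": intersection_ratio(na, nb),
            "hcs": hcs_vector(na, nb),
            "hmis": hmis_vector(na, nb),
        }

    ens = build_pair_ensemble(a, b, "degree_preserving", config.n_null,
                              int(seeds[0]), pair_stat)
    ir_null = np.array([v["ir"] for v in ens.values])
    hcs_null = np.array([v["hcs"] for v in ens.values])
    hmis_null = np.array([v["hmis"] for v in ens.values])

    ir_obs = intersection_ratio(a, b)
    ir_z, ir_p = empirical_stats(ir_obs, ir_null.tolist(), side="greater")
    intersection = {
        "observed": ir_obs,
        "null_mean": float(ir_null.mean()),
        "null_std": float(ir_null.std(ddof=1)),
        "z": ir_z,
        "p": ir_p,
        "null_model": "degree_preserving",
        "n_null": config.n_null,
    }
    log.info("intersection ratio %.3f (null %.3f±%.3f, p=%.2g)",
             ir_obs, intersection["null_mean"], intersection["null_std"], ir_p)

    hcs_res = _region_results(a.labels, hcs_vector(a, b), hcs_null,
                              config.correction, config.alpha)
    hmis_res = _region_results(a.labels, hmis_vector(a, b), hmis_null,
                               config.correction, config.alpha)

    topo = _topology_block(a, b, normalized=False)
    rc = _richclub_block(a, b, "degree_preserving", config.n_null,
                         config.n_overlap_draws, seeds[1:4])

    robustness = None
    if config.perturbations:
        robustness = {}
        for i, spec in enumerate(config.perturbations):
            pa = perturb(a, spec)
            pb = perturb(b, PerturbationSpec(spec.kind, spec.parameter,
                                             spec.seed + 1))
            p_obs = intersection_ratio(pa, pb)
            p_ens = build_pair_ensemble(
                pa, pb, "degree_preserving", config.n_null,
                int(seeds[4 + i % 4]),
                lambda na, nb: intersection_ratio(na, nb),
            )
            pz, pp = empirical_stats(p_obs, p_ens, side="greater")
            vals = p_ens.as_array()
            robustness[f"{spec.kind}={spec.parameter}"] = {
                "observed": p_obs,
                "null_mean": float(vals.mean()),
                "null_std": float(vals.std(ddof=1)),
                "z": pz,
                "p": pp,
                "edge_count": pa.n_edges,
            }

    return ComparativeReport(
        arm=config.arm, seed=config.seed, n_null=config.n_null,
        alpha=config.alpha, correction=config.correction,
        null_model="degree_preserving", labels=a.labels,
        intersection=intersection, hcs=hcs_res, hmis=hmis_res,
        topology=topo, richclub=rc, robustness=robustness,
    )


# ---------------------------------------------------------------------------
# hemisphere-wise weighted arm
# ---------------------------------------------------------------------------


def run_hemisphere_weighted(config: AnalysisConfig) -> ComparativeReport:
    """Per-hemisphere weighted comparison.

    Species B is thresholded (keeping weights) to species A's hemisphere
    edge count.  The intersection and HCS are not computed in this arm
    because the two weight scales are not comparable.
    """
    if config.arm != "hemisphere_weighted":
        raise ValueError("config arm does not match run_hemisphere_weighted")
    rt = read_region_table(config.region_table)
    a_full = _load_species_a(config, rt)
    b_full = _load_species_b(config, rt)
    for name, c in (("A", a_full), ("B", b_full)):
        if c.directed:
            raise ValueError(
                f"hemisphere arm requires undirected input for {name}"
            )
    # 0/1-valued matrices are treated as unit-weighted
    if not a_full.weighted:
        a_full = Connectome(a_full.labels, a_full.weights, weighted=True,
                            species_tag=a_full.species_tag)
    if not b_full.weighted:
        b_full = Connectome(b_full.labels, b_full.weights, weighted=True,
                            species_tag=b_full.species_tag)
    rng = np.random.default_rng(config.seed)
    hemispheres = {}
    for hemi_idx, hemi in enumerate(("L", "R")):
        a_h = split_hemispheres(a_full, rt)[hemi_idx]
        b_h = split_hemispheres(b_full, rt)[hemi_idx]
        target = a_h.n_edges
        b_h = threshold_to_edge_count(b_h, target, keep_weights=True)
        seeds = rng.integers(0, 2**31 - 1, size=8)
        log.info("hemisphere %s: N=%d L=%d density=%.3f", hemi,
                 a_h.n_regions, target, density(a_h))

        ens = build_pair_ensemble(a_h, b_h, "link_weight_reshuffle",
                                  config.n_null, int(seeds[0]),
                                  lambda na, nb: weighted_hmis_vector(na, nb))
        whmis_null = np.array(ens.values)
        whmis_res = _region_results(a_h.labels, weighted_hmis_vector(a_h, b_h),
                                    whmis_null, config.correction, config.alpha)
        topo = _topology_block(a_h, b_h, normalized=True)
        rc = _richclub_block(a_h, b_h, "link_weight_reshuffle", config.n_null,
                             config.n_overlap_draws, seeds[1:4])
        hemispheres[hemi] = {"hmis": whmis_res, "topology": topo,
                             "richclub": rc, "n_edges": target}

    return ComparativeReport(
        arm=config.arm, seed=config.seed, n_null=config.n_null,
        alpha=config.alpha, correction=config.correction,
        null_model="link_weight_reshuffle", labels=a_full.labels,
        hemispheres=hemispheres,
    )


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def _region_frame(results: dict[str, RegionMetricResult], prefix: str) -> pd.DataFrame:
    rows = {
        f"{prefix}_observed": [r.observed for r in results.values()],
        f"{prefix}_null_mean": [r.null_mean for r in results.values()],
        f"{prefix}_null_std": [r.null_std for r in results.values()],
        f"{prefix}_z": [r.z for r in results.values()],
        f"{prefix}_p": [r.p for r in results.values()],
        f"{prefix}_significant": [r.significant for r in results.values()],
    }
    return pd.DataFrame(rows, index=list(results.keys()))


def _curve_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "k": curve.ks,
            "phi": curve.phi,
            "null_mean": curve.null_mean,
            "null_std": curve.null_std,
            "phi_norm": curve.phi_norm,
            "p": curve.p,
            "n_gt_k": curve.n_gt_k,
            "e_or_w_gt_k": curve.e_or_w_gt_k,
            "members": ["|".join(m) for m in curve.members],
        }
    )


def _topology_frame(topo: dict, labels) -> pd.DataFrame:
    rows = []
    for metric, block in topo.items():
        for species, mv_key, hub_key in (("a", "a", "hubs_a"),
                                         ("b", "b", "hubs_b")):
            mv: MetricVector = block[mv_key]
            for lab, val in zip(mv.labels, mv.values):
                rows.append(
                    {
                        "metric": metric,
                        "species": species,
                        "label": lab,
                        "value": val,
                        "normalized": mv.normalized,
                        "hub": block[hub_key][lab],
                    }
                )
    return pd.DataFrame(rows)


def _write_block(block: dict, outdir: Path, tag: str) -> None:
    parts = []
    if block.get("hmis"):
        parts.append(_region_frame(block["hmis"], "hmis"))
    if parts:
        pd.concat(parts, axis=1).rename_axis("label").to_csv(
            outdir / f"{tag}regions.tsv", sep="\t", float_format=_FLOAT_FMT)
    topo = block.get("topology")
    if topo:
        _topology_frame(topo, None).to_csv(
            outdir / f"{tag}topology.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        pd.DataFrame(
            [
                {"metric": m, "rho": blk["rho"], "p": blk["p"]}
                for m, blk in topo.items()
            ]
        ).to_csv(outdir / f"{tag}topology_correlation.tsv", sep="\t",
                 index=False, float_format=_FLOAT_FMT)
    rc = block.get("richclub")
    if rc:
        _curve_frame(rc["curve_a"]).to_csv(
            outdir / f"{tag}richclub_a.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        _curve_frame(rc["curve_b"]).to_csv(
            outdir / f"{tag}richclub_b.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        pd.DataFrame(
            [
                {
                    "peak_k_a": rc["peak_k_a"],
                    "peak_k_b": rc["peak_k_b"],
                    "overlap": rc["overlap"],
                    "p": rc["overlap_p"],
                    "n_draws": rc["overlap_n_draws"],
                    "members_a": "|".join(rc["members_a"]),
                    "members_b": "|".join(rc["members_b"]),
                }
            ]
        ).to_csv(outdir / f"{tag}richclub_overlap.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)


def write_report(r: ComparativeReport, outdir: str | Path,
                 config: AnalysisConfig | None = None) -> None:
    """Write TSV tables plus a JSON run manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if r.arm == "whole_brain_binary":
        frames = []
        if r.hcs:
            frames.append(_region_frame(r.hcs, "hcs"))
        if r.hmis:
            frames.append(_region_frame(r.hmis, "hmis"))
        if frames:
            pd.concat(frames, axis=1).rename_axis("label").to_csv(
                outdir / "regions.tsv", sep="\t", float_format=_FLOAT_FMT)
        if r.intersection:
            pd.DataFrame([r.intersection]).to_csv(
                outdir / "intersection.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
        _write_block({"topology": r.topology, "richclub": r.richclub},
                     outdir, "")
        if r.robustness:
            pd.DataFrame(
                [{"perturbation": k, **v} for k, v in r.robustness.items()]
            ).to_csv(outdir / "robustness.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    else:
        for hemi, block in (r.hemispheres or {}).items():
            _write_block(block, outdir, f"hemisphere_{hemi}_")

    manifest = {
        "package": "comparanet",
        "version": __version__,
        "numpy": np.__version__,
        "arm": r.arm,
        "seed": r.seed,
        "n_null": r.n_null,
        "alpha": r.alpha,
        "correction": r.correction,
        "null_model": r.null_model,
        "n_regions": len(r.labels),
        "config": config.echo() if config else None,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
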
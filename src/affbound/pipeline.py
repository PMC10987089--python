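"""End-to-end orchestration: tensor in, machine-readable report out.

``run_analysis`` sequences the stages in analysis order — animate
filtering, affordance vectors, the RSM and its clustering, the
neighboring-rank similarity curve, the trough permutation test, the
dependent-correlation comparisons, the real-world size-similarity
control curve, and the object-level boundary scan — and collects
everything in a versioned :class:`Report`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import affordance as aff_mod
from . import boundary as bnd
from .core_io import (
    AffordanceMatrix,
    AnalysisConfig,
    JudgmentDataError,
    ObjectItem,
    ResponseTensor,
    SimilarityMatrix,
    config_to_dict,
    filter_animate,
)

logger = logging.getLogger("affbound")

REPORT_SCHEMA_VERSION = "1"


def size_similarity(d_i: float, d_j: float) -> float:
    """Relative size similarity, ``1 - (d_j - d_i) / d_i``.

    Equals 1 when the sizes match, 0 when ``d_j`` doubles ``d_i``, and
    is deliberately asymmetric: ``d_i`` is the reference (smaller-rank)
    size.
    """
    if d_i <= 0:
        raise ValueError(f"reference size must be positive, got {d_i}")
    return 1.0 - (d_j - d_i) / d_i


def size_similarity_curve(objects: list[ObjectItem]):
    """Size similarity between neighboring ranks' mean diagonal sizes.

    Returns (pairs, values, rank mean sizes by rank).  This is the
    control curve: if it is flat while the affordance curve dips, the
    affordance trough is not a real-world-size artifact.
    """
    ranks = sorted({o.rank for o in objects})
    mean_size = {r: float(np.mean([o.diagonal_cm for o in objects
                                   if o.rank == r])) for r in ranks}
    pairs, values = [], []
    for a, b in zip(ranks[:-1], ranks[1:]):
        if b != a + 1:
            continue
        pairs.append((a, b))
        values.append(size_similarity(mean_size[a], mean_size[b]))
    return pairs, np.array(values), mean_size


@dataclass
class Report:
    """Everything the pipeline computed, JSON-serializable via to_dict."""

    config: AnalysisConfig
    tensor_counts: dict
    affordance: AffordanceMatrix
    similarity: SimilarityMatrix
    clusters: aff_mod.ClusterResult
    rank_means: bnd.RankMeans
    rank_curve: bnd.RankCurve
    comparisons: list[bnd.NeighborComparison]
    size_curve_pairs: list[tuple[int, int]]
    size_curve_values: np.ndarray
    trough: bnd.TroughResult
    pair_scan: bnd.PairScan

    def to_dict(self) -> dict:
        t = self.trough
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": config_to_dict(self.config),
            "counts": dict(self.tensor_counts),
            "objects": [{"name": o.name, "diagonal_cm": o.diagonal_cm,
                         "rank": o.rank, "animate": o.animate}
                        for o in self.affordance.objects],
            "actions": [{"name": a.name, "action_class": a.action_class}
                        for a in self.affordance.actions],
            "affordance_matrix": self.affordance.probs.tolist(),
            "similarity_matrix": [
                [None if not m else float(v)
                 for v, m in zip(row, mrow)]
                for row, mrow in zip(self.similarity.r, self.similarity.mask)],
            "clusters": self.clusters.to_dict(),
            "rank_means": {
                "ranks": [int(r) for r in self.rank_means.ranks],
                "vectors": self.rank_means.vectors.tolist(),
            },
            "rank_curve": {
                "pairs": [list(p) for p in self.rank_curve.pairs],
                "r": _nan_to_none(self.rank_curve.r),
                "se": _nan_to_none(self.rank_curve.se),
                "n_actions": self.rank_curve.n_actions,
            },
            "comparisons": [{
                "pair_a": list(c.pair_a), "pair_b": list(c.pair_b),
                "r_a": c.r_a, "r_b": c.r_b, "r_cross": c.r_cross,
                "z": c.z, "p_one_tailed": c.p_one_tailed, "bf10": c.bf10,
                "zou_interval": list(c.zou_interval),
                "n_actions": c.n_actions,
            } for c in self.comparisons],
            "size_curve": {
                "pairs": [list(p) for p in self.size_curve_pairs],
                "values": self.size_curve_values.tolist(),
            },
            "trough": {
                "site": list(t.site), "t_obs": t.t_obs,
                "p_value": t.p_value, "n_permutations": t.n_permutations,
                "seed": t.seed,
                "null_quantiles": {
                    str(q): float(np.nanquantile(t.null_values, q))
                    for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
            },
            "pair_scan": {
                "rank_window": list(self.pair_scan.rank_window),
                "compositions": _df_records(self.pair_scan.compositions),
                "boundary_composition":
                    list(self.pair_scan.boundary_composition),
                "boundary_estimate_cm": self.pair_scan.boundary_estimate_cm,
                "boundary_ci_cm": list(self.pair_scan.boundary_ci_cm),
                "boundary_ci_normal_cm":
                    list(self.pair_scan.boundary_ci_normal_cm),
            },
        }


def _nan_to_none(arr) -> list:
    return [None if not np.isfinite(v) else float(v) for v in np.asarray(arr)]


def _df_records(df: pd.DataFrame) -> list[dict]:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append({k: (None if isinstance(v, float) and not np.isfinite(v)
                        else (v.item() if isinstance(v, np.generic) else v))
                    for k, v in rec.items()})
    return out


def _stage(name: str):
    logger.info("stage: %s", name)


def run_analysis(tensor: ResponseTensor,
                 config: AnalysisConfig | None = None) -> Report:
    """Run the full boundary analysis on a validated tensor.

    Every random step (permutation test, bootstrap) derives from
    ``config.seed``, so a rerun with the same inputs and config is
    identical.
    """
    config = config or AnalysisConfig()
    try:
        if config.exclude_animate:
            _stage("filter animate objects")
            tensor = filter_animate(tensor)
        counts = {"n_participants": tensor.n_participants,
                  "n_actions": tensor.n_actions,
                  "n_objects": tensor.n_objects}
        _stage("affordance vectors")
        aff = aff_mod.affordance_vectors(tensor)
        _stage("similarity matrix")
        sim = aff_mod.similarity_matrix(aff)
        _stage("clustering")
        clusters = aff_mod.cluster_similarity(sim, k=2)
        _stage("rank curve")
        means = bnd.rank_mean_vectors(aff)
        curve = bnd.neighbor_similarity_curve(means)
        site = config.trough_site or bnd.detect_trough(curve)
        _stage("trough permutation test")
        trough = bnd.permutation_test_trough(aff, site=site, config=config)
        _stage("neighboring-pair comparisons")
        comparisons = [
            bnd.compare_neighbor_correlations(means, pa, pb, config)
            for pa, pb in zip(curve.pairs[:-1], curve.pairs[1:])]
        _stage("size-similarity control curve")
        sc_pairs, sc_values, _ = size_similarity_curve(aff.objects)
        _stage("object-level boundary scan")
        scan = bnd.pairwise_boundary_scan(aff, config.rank_window, config)
    except JudgmentDataError as exc:
        raise type(exc)(f"analysis failed: {exc}") from exc
    return Report(config=config, tensor_counts=counts, affordance=aff,
                  similarity=sim, clusters=clusters, rank_means=means,
                  rank_curve=curve, comparisons=comparisons,
                  size_curve_pairs=sc_pairs, size_curve_values=sc_values,
                  trough=trough, pair_scan=scan)


def group_rank_curves(tensor: ResponseTensor,
                      config: AnalysisConfig | None = None,
                      ) -> dict[str, bnd.RankCurve]:
    """Per-group neighboring-rank curves (no inferential comparison)."""
    if tensor.groups is None:
        raise JudgmentDataError("tensor has no group labels")
    config = config or AnalysisConfig()
    out = {}
    for g in dict.fromkeys(tensor.groups):
        keep = [i for i, gg in enumerate(tensor.groups) if gg == g]
        sub = ResponseTensor(
            participants=[tensor.participants[i] for i in keep],
            actions=list(tensor.actions), objects=list(tensor.objects),
            data=tensor.data[keep], groups=[g] * len(keep))
        if config.exclude_animate:
            sub = filter_animate(sub)
        aff = aff_mod.affordance_vectors(sub)
        out[g] = bnd.neighbor_similarity_curve(bnd.rank_mean_vectors(aff))
    return out


# ---------------------------------------------------------------------------
# Writers

def write_report(report: Report, out_dir) -> None:
    """Write report.json plus the per-stage CSV/JSON side files."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    aff_mod.write_affordance_matrix(report.affordance,
                                    out / "affordance_matrix.csv")
    aff_mod.write_similarity_matrix(report.similarity,
                                    out / "similarity_matrix.csv")
    aff_mod.write_clusters(report.clusters, out / "clusters.json")
    pd.DataFrame({
        "rank_lo": [p[0] for p in report.rank_curve.pairs],
        "rank_hi": [p[1] for p in report.rank_curve.pairs],
        "r": report.rank_curve.r,
        "se": report.rank_curve.se,
    }).to_csv(out / "rank_curve.csv", index=False)
    with open(out / "trough.json", "w") as fh:
        t = report.trough
        json.dump({"site": list(t.site), "t_obs": t.t_obs,
                   "p_value": t.p_value,
                   "n_permutations": t.n_permutations, "seed": t.seed},
                  fh, indent=2)
    report.pair_scan.pairs.to_csv(out / "pair_scan.csv", index=False)
    report.pair_scan.compositions.to_csv(out / "pair_scan_compositions.csv",
                                         index=False)
    pd.DataFrame([{
        "pair_a": f"{c.pair_a[0]}-{c.pair_a[1]}",
        "pair_b": f"{c.pair_b[0]}-{c.pair_b[1]}",
        "r_a": c.r_a, "r_b": c.r_b, "z": c.z,
        "p_one_tailed": c.p_one_tailed, "bf10": c.bf10,
    } for c in report.comparisons]).to_csv(out / "comparisons.csv",
                                           index=False)
    pd.DataFrame({
        "rank_lo": [p[0] for p in report.size_curve_pairs],
        "rank_hi": [p[1] for p in report.size_curve_pairs],
        "size_similarity": report.size_curve_values,
    }).to_csv(out / "size_curve.csv", index=False)
    logger.info("report written to %s", out)
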
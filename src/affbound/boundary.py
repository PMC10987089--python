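"""Rank-wise similarity curve, trough statistic, permutation test, and
object-level boundary localization.

The analysis averages affordance vectors within each size rank,
correlates neighboring rank means, and quantifies the dip ("trough") in
that curve at a candidate boundary site ``(i, i+1)`` as::

    T = (r_{i-1} + r_{i+1}) / 2 - r_i

where ``r_i`` is the affordance similarity between ranks i and i+1.  A
larger T means a deeper trough.  Significance comes from a permutation
test that shuffles the object-to-rank assignment (per-rank counts
preserved), recomputes the curve and T at the same site, and reports
``p = (1/N) * #(T_perm >= T_obs)``.  The object-level scan traverses
all same-rank and adjacent-rank object pairs inside a rank window and
locates the boundary at the mean pair size of the composition with the
lowest mean similarity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .core_io import (
    AffordanceMatrix,
    AnalysisConfig,
    CoverageError,
    DegenerateDataError,
    InsufficientDataError,
)

_PERMUTATION_STREAM = 37
_SCAN_STREAM = 41


# ---------------------------------------------------------------------------
# Rank means and the neighboring-rank similarity curve

@dataclass
class RankMeans:
    """Per-rank unweighted means of member objects' affordance vectors."""

    ranks: np.ndarray            # contiguous, ascending
    vectors: np.ndarray          # (n_ranks, n_actions)

    @property
    def n_actions(self) -> int:
        return self.vectors.shape[1]

    def vector_for(self, rank: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.ranks == rank)[0])
        return self.vectors[idx]


@dataclass
class RankCurve:
    """Affordance similarity between each pair of neighboring size ranks.

    ``r[k]`` is the Pearson correlation between the mean affordance
    vectors of ``pairs[k] = (i, i+1)``, computed over the action
    dimension; ``se`` is the correlation SE ``sqrt((1-r^2)/(n-2))``
    with n = number of actions.  Undefined entries (a constant rank
    mean) are NaN.
    """

    pairs: tuple[tuple[int, int], ...]
    r: np.ndarray
    se: np.ndarray
    n_actions: int

    def site_index(self, site: tuple[int, int]) -> int:
        site = (int(site[0]), int(site[1]))
        if site not in self.pairs:
            raise ValueError(f"site {site} not on the curve {self.pairs}")
        return self.pairs.index(site)


def rank_mean_vectors(aff: AffordanceMatrix) -> RankMeans:
    """Average affordance vectors within each size rank.

    Every rank between the smallest and largest represented rank must
    have at least one object, otherwise the curve would silently skip a
    rank (:class:`CoverageError`).
    """
    obj_ranks = np.array([o.rank for o in aff.objects])
    if obj_ranks.size == 0:
        raise CoverageError("no objects")
    ranks = np.arange(obj_ranks.min(), obj_ranks.max() + 1)
    vectors = np.empty((len(ranks), len(aff.actions)))
    for k, r in enumerate(ranks):
        members = obj_ranks == r
        if not members.any():
            raise CoverageError(f"no objects in size rank {r}")
        vectors[k] = aff.probs[members].mean(axis=0)
    return RankMeans(ranks=ranks, vectors=vectors)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape (..., n) arrays."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc ** 2).sum(axis=-1) * (yc ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


def neighbor_similarity_curve(means: RankMeans) -> RankCurve:
    """Pearson similarity between mean vectors of neighboring ranks."""
    if len(means.ranks) < 2:
        raise InsufficientDataError("need at least 2 ranks for a curve")
    n = means.n_actions
    if n < 3:
        raise InsufficientDataError("need at least 3 actions for a similarity SE")
    r = _pearson_rows(means.vectors[:-1], means.vectors[1:])
    if np.isnan(r).any():
        warnings.warn("constant rank-mean vector: similarity undefined for "
                      "some neighboring pair(s)", stacklevel=2)
    se = np.sqrt((1 - r ** 2) / (n - 2))
    pairs = tuple((int(a), int(a) + 1) for a in means.ranks[:-1])
    return RankCurve(pairs=pairs, r=r, se=se, n_actions=n)


# ---------------------------------------------------------------------------
# Trough statistic

def trough_value(curve: RankCurve, site: tuple[int, int]) -> float:
    """Depth of the curve's dip at ``site`` relative to its two banks."""
    idx = curve.site_index(site)
    if idx == 0 or idx == len(curve.pairs) - 1:
        raise InsufficientDataError(
            f"site {site} has no bank on both sides")
    return float((curve.r[idx - 1] + curve.r[idx + 1]) / 2 - curve.r[idx])


def detect_trough(curve: RankCurve) -> tuple[int, int]:
    """Interior site with the maximal trough value (ties -> smaller rank)."""
    if len(curve.pairs) < 3:
        raise InsufficientDataError("trough detection needs >= 3 curve points")
    banks_prev, banks_next = curve.r[:-2], curve.r[2:]
    t = (banks_prev + banks_next) / 2 - curve.r[1:-1]
    if np.isnan(t).all():
        raise DegenerateDataError("all candidate trough values are undefined")
    best = int(np.nanargmax(t)) + 1  # argmax keeps the first (smaller rank) tie
    return curve.pairs[best]


def permutation_p(t_obs: float, null_values: np.ndarray,
                  smoothed: bool = False) -> float:
    """p = (1/N) * #(T_i >= T_obs); optionally (#+1)/(N+1)."""
    null_values = np.asarray(null_values, dtype=float)
    n = len(null_values)
    with np.errstate(invalid="ignore"):
        count = int(np.sum(null_values >= t_obs))  # NaN compares False
    if smoothed:
        return (count + 1) / (n + 1)
    return count / n


@dataclass
class TroughResult:
    """Observed trough statistic with its permutation null."""

    site: tuple[int, int]
    t_obs: float
    null_values: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None


def _sorted_by_rank(aff: AffordanceMatrix):
    obj_ranks = np.array([o.rank for o in aff.objects])
    order = np.argsort(obj_ranks, kind="stable")
    return aff.probs[order], obj_ranks[order]


def _rank_slices(sorted_ranks: np.ndarray) -> list[slice]:
    uniq, start = np.unique(sorted_ranks, return_index=True)
    bounds = list(start) + [len(sorted_ranks)]
    return [slice(bounds[i], bounds[i + 1]) for i in range(len(uniq))]


def _curves_from_stacks(stacks: np.ndarray) -> np.ndarray:
    """(N, n_ranks, n_actions) rank means -> (N, n_ranks - 1) curves."""
    return _pearson_rows(stacks[:, :-1, :], stacks[:, 1:, :])


def _distinct_label_permutations(sorted_ranks: np.ndarray) -> np.ndarray:
    """All distinct object->rank assignments, as permutation index arrays."""
    n = len(sorted_ranks)
    if n > 9:
        raise ValueError(
            "exhaustive enumeration is limited to <= 9 objects")
    seen = set()
    perms = []
    for perm in itertools.permutations(range(n)):
        assignment = np.empty(n, dtype=int)
        assignment[list(perm)] = sorted_ranks
        key = tuple(assignment)
        if key not in seen:
            seen.add(key)
            perms.append(perm)
    return np.array(perms)


def permutation_test_trough(aff: AffordanceMatrix,
                            site: tuple[int, int] | None = None,
                            config: AnalysisConfig | None = None,
                            exhaustive: bool = False) -> TroughResult:
    """Permutation test of the trough value at a fixed site.

    The default exchange unit shuffles the object-to-rank assignment
    while preserving per-rank object counts (``config.permute ==
    "objects"``); the alternative (``"actions"``) independently
    permutes each object's affordance vector entries, breaking action
    alignment across objects instead.  Each permutation recomputes the
    rank means, the curve, and the trough value at the *same* site.
    With ``exhaustive=True`` all distinct object->rank assignments are
    enumerated (small object sets only) and N is their count.

    If ``site`` is None it is taken from ``config.trough_site`` or, as
    a last resort, detected from the observed curve — in that case the
    permutation p inherits the selection and is no longer calibrated
    under the null.
    """
    config = config or AnalysisConfig()
    means = rank_mean_vectors(aff)
    curve = neighbor_similarity_curve(means)
    if site is None:
        site = config.trough_site or detect_trough(curve)
    site = (int(site[0]), int(site[1]))
    t_obs = trough_value(curve, site)

    probs_sorted, ranks_sorted = _sorted_by_rank(aff)
    slices = _rank_slices(ranks_sorted)
    n_obj = probs_sorted.shape[0]
    if n_obj == len(slices) and np.allclose(
            probs_sorted, probs_sorted[0], atol=1e-12):
        warnings.warn("all ranks are singletons with identical vectors; the "
                      "permutation null is degenerate", stacklevel=2)

    rng = np.random.default_rng([config.seed, _PERMUTATION_STREAM])
    if config.permute == "objects":
        if exhaustive:
            perms = _distinct_label_permutations(ranks_sorted)
        else:
            perms = np.array([rng.permutation(n_obj)
                              for _ in range(config.n_permutations)])
        shuffled = probs_sorted[perms]                      # (N, O, A)
    else:
        n = config.n_permutations
        n_act = probs_sorted.shape[1]
        base = np.broadcast_to(np.arange(n_act), (n, n_obj, n_act))
        idx = rng.permuted(base, axis=2)
        shuffled = np.take_along_axis(
            np.broadcast_to(probs_sorted, (n, n_obj, n_act)), idx, axis=2)

    stacks = np.stack([shuffled[:, sl, :].mean(axis=1) for sl in slices],
                      axis=1)                               # (N, R, A)
    curves = _curves_from_stacks(stacks)
    site_idx = curve.site_index(site)
    t_null = (curves[:, site_idx - 1] + curves[:, site_idx + 1]) / 2 \
        - curves[:, site_idx]
    p = permutation_p(t_obs, t_null, smoothed=config.smoothed_p)
    return TroughResult(site=site, t_obs=t_obs, null_values=t_null,
                        p_value=p, n_permutations=len(t_null),
                        seed=None if exhaustive else config.seed)


# ---------------------------------------------------------------------------
# Dependent-correlation comparison between neighboring curve points

@dataclass
class NeighborComparison:
    """Steiger-type comparison of two overlapping neighboring-rank
    similarities, with a Bayes factor on their Fisher-z difference."""

    pair_a: tuple[int, int]
    pair_b: tuple[int, int]
    r_a: float
    r_b: float
    r_cross: float
    z: float
    p_one_tailed: float
    bf10: float
    zou_interval: tuple[float, float]
    n_actions: int


def compare_neighbor_correlations(means: RankMeans,
                                  pair_a: tuple[int, int],
                                  pair_b: tuple[int, int],
                                  config: AnalysisConfig | None = None,
                                  ) -> NeighborComparison:
    """Compare r(pair_a) with r(pair_b) for pairs sharing a middle rank.

    ``pair_a = (j, k)`` and ``pair_b = (k, h)`` overlap in rank k, so
    the two correlations are dependent with the shared variable being
    rank k's mean vector; Steiger's Z (one-tailed, H1: r_a > r_b)
    accounts for the correlation between the non-shared vectors.  The
    Bayes factor is evaluated on the Fisher-z difference with SE
    ``1/sqrt(n_actions - 3)`` under the configured normal priors, and
    Zou's interval for the raw difference is reported alongside.
    """
    config = config or AnalysisConfig()
    j, k = int(pair_a[0]), int(pair_a[1])
    k2, h = int(pair_b[0]), int(pair_b[1])
    if k != k2:
        raise ValueError(
            f"pairs {pair_a} and {pair_b} must share their middle rank")
    n = means.n_actions
    if n < 4:
        raise InsufficientDataError("comparison requires >= 4 actions")
    m_j, m_k, m_h = (means.vector_for(r) for r in (j, k, h))
    r_a = float(_pearson_rows(m_k[None], m_j[None])[0])
    r_b = float(_pearson_rows(m_k[None], m_h[None])[0])
    r_cross = float(_pearson_rows(m_j[None], m_h[None])[0])
    z, p = stats.steiger_z(r_a, r_b, r_cross, n)
    spec = stats.BayesFactorSpec(h1_mean=config.h1_prior_mean,
                                 h1_sd=config.h1_prior_sd)
    bf10 = stats.bayes_factor_normal(
        stats.fisher_z(r_a) - stats.fisher_z(r_b), stats.fisher_se(n), spec)
    zou = stats.zou_ci(r_a, r_b, r_cross, n, level=config.ci_level)
    return NeighborComparison(pair_a=(j, k), pair_b=(k, h), r_a=r_a, r_b=r_b,
                              r_cross=r_cross, z=z, p_one_tailed=p, bf10=bf10,
                              zou_interval=zou, n_actions=n)


# ---------------------------------------------------------------------------
# Object-level boundary scan

@dataclass
class PairScan:
    """All same-rank / adjacent-rank object pairs inside a rank window.

    ``pairs`` holds one record per admissible pair (object names, rank
    composition, mean real-world size, affordance similarity);
    ``compositions`` aggregates by rank composition with normal 95%
    CIs (NaN when a composition has fewer than 2 pairs).  The boundary
    estimate is the mean pair size of the minimum-similarity
    composition, with a percentile-bootstrap CI over that composition's
    pairs and a normal-approximation CI for reference.
    """

    pairs: pd.DataFrame
    compositions: pd.DataFrame
    boundary_composition: tuple[int, int]
    boundary_estimate_cm: float
    boundary_ci_cm: tuple[float, float]
    boundary_ci_normal_cm: tuple[float, float]
    rank_window: tuple[int, int]


def _normal_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    if len(values) < 2:
        return (float("nan"), float("nan"))
    m = values.mean()
    sem = values.std(ddof=1) / np.sqrt(len(values))
    zcrit = sps.norm.ppf(1 - (1 - level) / 2)
    return (float(m - zcrit * sem), float(m + zcrit * sem))


def pairwise_boundary_scan(aff: AffordanceMatrix,
                           rank_window: tuple[int, int] | None = None,
                           config: AnalysisConfig | None = None) -> PairScan:
    """Traverse all same-rank and adjacent-rank object pairs in a window.

    For each pair the mean real-world size ``(d_a + d_b)/2`` indexes
    the would-be boundary location between the two objects, and the
    Pearson correlation of their affordance vectors measures their
    affordance similarity.  The composition whose mean similarity is
    lowest localizes the boundary.
    """
    config = config or AnalysisConfig()
    if rank_window is None:
        rank_window = config.rank_window
    lo, hi = int(rank_window[0]), int(rank_window[1])
    sel = [i for i, o in enumerate(aff.objects) if lo <= o.rank <= hi]
    if len(sel) < 2:
        raise InsufficientDataError(
            f"need >= 2 objects within rank window {rank_window}")
    objs = [aff.objects[i] for i in sel]
    X = aff.probs[sel]
    records = []
    for ia, ib in itertools.combinations(range(len(objs)), 2):
        a, b = objs[ia], objs[ib]
        if a.rank > b.rank:
            ia, ib, a, b = ib, ia, b, a
        if b.rank - a.rank > 1:
            continue
        r = float(_pearson_rows(X[ia][None], X[ib][None])[0])
        records.append({
            "object_a": a.name, "object_b": b.name,
            "rank_a": a.rank, "rank_b": b.rank,
            "mean_size_cm": (a.diagonal_cm + b.diagonal_cm) / 2,
            "r": r,
        })
    pairs = pd.DataFrame.from_records(records).sort_values(
        ["rank_a", "rank_b", "mean_size_cm"], ignore_index=True)

    comp_rows = []
    for (ra, rb), grp in pairs.groupby(["rank_a", "rank_b"], sort=True):
        sizes = grp["mean_size_cm"].to_numpy()
        rs = grp["r"].to_numpy()
        size_ci = _normal_ci(sizes, config.ci_level)
        r_ci = _normal_ci(rs, config.ci_level)
        comp_rows.append({
            "rank_a": ra, "rank_b": rb, "n_pairs": len(grp),
            "mean_size_cm": sizes.mean(),
            "size_ci_lo": size_ci[0], "size_ci_hi": size_ci[1],
            "mean_r": np.nanmean(rs),
            "r_ci_lo": r_ci[0], "r_ci_hi": r_ci[1],
        })
    comps = pd.DataFrame.from_records(comp_rows)
    best = comps.loc[comps["mean_r"].idxmin()]
    boundary_comp = (int(best["rank_a"]), int(best["rank_b"]))
    best_sizes = pairs.loc[
        (pairs["rank_a"] == boundary_comp[0])
        & (pairs["rank_b"] == boundary_comp[1]), "mean_size_cm"].to_numpy()
    estimate = float(best_sizes.mean())
    if len(best_sizes) >= 2:
        rng = np.random.default_rng([config.seed, _SCAN_STREAM])
        boot_ci = stats.percentile_bootstrap_ci(
            best_sizes, level=config.ci_level, n_boot=config.n_boot, seed=rng)
    else:
        boot_ci = (float("nan"), float("nan"))
    return PairScan(pairs=pairs, compositions=comps,
                    boundary_composition=boundary_comp,
                    boundary_estimate_cm=estimate,
                    boundary_ci_cm=boot_ci,
                    boundary_ci_normal_cm=_normal_ci(best_sizes, config.ci_level),
                    rank_window=(lo, hi))
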
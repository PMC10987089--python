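"""Affordance vectors, the object similarity matrix, and its clustering.

Each object's affordance vector holds, per action, the fraction of
participants who judged the action applicable.  The representational
similarity matrix (RSM) is the Pearson correlation between affordance
vectors for every object pair; hierarchical clustering of its row
profiles (Euclidean distance, complete linkage) exposes the two-cluster
structure that the boundary analysis quantifies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import (
    AffordanceMatrix,
    EmptyResultError,
    InsufficientDataError,
    ObjectItem,
    ResponseTensor,
    SimilarityMatrix,
)


def affordance_vectors(tensor: ResponseTensor) -> AffordanceMatrix:
    """Per-object endorsement proportions over participants."""
    if tensor.n_participants == 0:
        raise EmptyResultError("no participants")
    probs = tensor.data.mean(axis=0).T  # (objects, actions)
    return AffordanceMatrix(
        objects=list(tensor.objects),
        actions=list(tensor.actions),
        probs=probs,
        n_participants=tensor.n_participants,
    )


def similarity_matrix(aff: AffordanceMatrix) -> SimilarityMatrix:
    """Pearson correlation between affordance vectors for all object pairs.

    Cells involving a zero-variance affordance vector are undefined:
    they are NaN in ``r`` and False in ``mask`` (never silently zero).
    """
    if len(aff.actions) < 2:
        raise InsufficientDataError(
            "similarity requires at least 2 actions per affordance vector")
    X = aff.probs
    n = X.shape[0]
    valid = X.std(axis=1) > 0
    r = np.full((n, n), np.nan)
    nv = int(valid.sum())
    if nv == 1:
        i = int(np.flatnonzero(valid)[0])
        r[i, i] = 1.0
    elif nv > 1:
        sub = np.corrcoef(X[valid])
        r[np.ix_(valid, valid)] = np.clip(sub, -1.0, 1.0)
    if nv < n:
        warnings.warn(
            f"{n - nv} object(s) have zero-variance affordance vectors; "
            "their similarity cells are undefined", stacklevel=2)
    mask = np.outer(valid, valid)
    return SimilarityMatrix(objects=list(aff.objects), r=r, mask=mask)


@dataclass
class ClusterResult:
    """A k-cluster cut of the RSM's row profiles plus the full merge tree."""

    objects: list[ObjectItem]
    labels: np.ndarray
    merge_tree: np.ndarray  # scipy linkage matrix
    k: int
    dropped: list[str]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "objects": [o.name for o in self.objects],
            "labels": [int(v) for v in self.labels],
            "merge_tree": [[float(v) for v in row] for row in self.merge_tree],
            "dropped": list(self.dropped),
        }


def cluster_similarity(sim: SimilarityMatrix, k: int = 2) -> ClusterResult:
    """Agglomerative clustering of the similarity matrix's row profiles.

    Rows (each object's vector of similarities to all objects) are
    clustered under Euclidean distance with complete linkage; ``labels``
    gives the k-cluster cut, renumbered 0..k-1 in order of first
    appearance so the output is deterministic.  Objects with undefined
    cells are dropped with a warning.
    """
    valid = sim.mask.diagonal()
    dropped = [o.name for o, v in zip(sim.objects, valid) if not v]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} object(s) with undefined similarity "
            f"from clustering: {dropped}", stacklevel=2)
    objects = [o for o, v in zip(sim.objects, valid) if v]
    rows = sim.r[np.ix_(valid, valid)]
    n = len(objects)
    if n < 2:
        raise InsufficientDataError("clustering requires at least 2 objects")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    tree = linkage(rows, method="complete", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.array([relabel.setdefault(int(c), len(relabel)) for c in raw])
    return ClusterResult(objects=objects, labels=labels, merge_tree=tree,
                         k=k, dropped=dropped)


# ---------------------------------------------------------------------------
# Writers

def write_affordance_matrix(aff: AffordanceMatrix, path) -> None:
    pd.DataFrame(
        aff.probs,
        index=pd.Index([o.name for o in aff.objects], name="object"),
        columns=[a.name for a in aff.actions],
    ).to_csv(path)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    names = [o.name for o in sim.objects]
    pd.DataFrame(sim.r, index=pd.Index(names, name="object"),
                 columns=names).to_csv(path)


def write_clusters(result: ClusterResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
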
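"""Domain types and file I/O for object-action judgment data.

Raw data are long-format CSV tables of binary judgments: one row per
(participant, action, object) triple recording whether the participant
endorsed the action as applicable to the object.  Objects carry their
real-world bounding-box diagonal (cm) and a logarithmic size rank;
actions carry a coarse class, ``manipulation`` (hand-scale: grasp, hold,
throw, ...) or ``whole_body`` (locomotion/posture: sit, stand, climb, ...).

Size ranks use half-open octave bins on the diagonal: rank *r* spans
``[edges[r-2], edges[r-1])`` cm.  The default edges double per rank
(16, 32, 64, 128, 256, 512, 1024) and the top bin is widened to 8192 cm
so that very large structures (airplanes, buildings) still fall in the
largest rank.  These defaults reproduce the published anchor sizes
(17 cm -> rank 2, 77 -> 4, 146 -> 5, 577 -> 7, 5317 -> 8) and place the
rank-4|5 edge at 128 cm, inside the adult human body-size range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("affbound")

ACTION_CLASSES = ("manipulation", "whole_body")

#: Half-open size-rank bin edges in cm; rank ``RANK_START + i`` spans
#: ``[DEFAULT_RANK_EDGES[i], DEFAULT_RANK_EDGES[i+1])``.
DEFAULT_RANK_EDGES: tuple[float, ...] = (
    16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 1024.0, 8192.0)
RANK_START = 2


# ---------------------------------------------------------------------------
# Errors

class JudgmentDataError(Exception):
    """Base class for data-contract violations raised by this package."""


class FormatError(JudgmentDataError):
    """A file is structurally malformed (missing columns, duplicates, gaps)."""


class ResponseValueError(JudgmentDataError):
    """A response value is outside {0, 1}."""


class UnknownNameError(JudgmentDataError):
    """An object or action name cannot be resolved against the metadata."""


class RankRangeError(JudgmentDataError):
    """A diagonal size falls outside the covered rank bins."""


class EmptyResultError(JudgmentDataError):
    """A filter or aggregation produced an empty result."""


class CoverageError(JudgmentDataError):
    """A size rank inside the analyzed range has no objects."""


class InsufficientDataError(JudgmentDataError):
    """Too little data for the requested statistic."""


class DegenerateDataError(JudgmentDataError):
    """Input is degenerate (e.g. zero-variance everywhere)."""


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class ObjectItem:
    """A stimulus object with its real-world size.

    Parameters
    ----------
    name : str
        Unique identifier.
    diagonal_cm : float
        Real-world bounding-box diagonal, in cm.  Must be positive.
    rank : int
        Logarithmic size rank (2..8 under the default binning).
    animate : bool
        Whether the object is an animal; animate objects are excluded
        from the boundary analysis by default.
    """

    name: str
    diagonal_cm: float
    rank: int
    animate: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.diagonal_cm) or self.diagonal_cm <= 0:
            raise ValueError(
                f"object {self.name!r}: diagonal_cm must be positive, "
                f"got {self.diagonal_cm}")


@dataclass(frozen=True)
class ActionItem:
    """An action with its coarse class (manipulation vs whole-body)."""

    name: str
    action_class: str

    def __post_init__(self) -> None:
        if self.action_class not in ACTION_CLASSES:
            raise ValueError(
                f"action {self.name!r}: action_class must be one of "
                f"{ACTION_CLASSES}, got {self.action_class!r}")


@dataclass
class ResponseTensor:
    """Complete participant x action x object array of binary judgments.

    ``data[p, a, o]`` is 1 if participant ``p`` endorsed action ``a`` as
    applicable to object ``o``.  The tensor is complete by contract:
    every cell was judged exactly once.
    """

    participants: list[str]
    actions: list[ActionItem]
    objects: list[ObjectItem]
    data: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.validate()

    def validate(self) -> None:
        expected = (len(self.participants), len(self.actions), len(self.objects))
        if self.data.shape != expected:
            raise FormatError(
                f"data shape {self.data.shape} does not match "
                f"(participants, actions, objects) = {expected}")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.data, (0, 1)))[0]
            raise ResponseValueError(
                f"response at (participant={self.participants[bad[0]]}, "
                f"action={self.actions[bad[1]].name}, "
                f"object={self.objects[bad[2]].name}) is not in {{0, 1}}")
        if self.groups is not None and len(self.groups) != len(self.participants):
            raise FormatError("groups must align with participants")

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def select_objects(self, indices: Sequence[int]) -> "ResponseTensor":
        """Restrict the object axis to ``indices`` (participants/actions kept)."""
        indices = list(indices)
        return ResponseTensor(
            participants=list(self.participants),
            actions=list(self.actions),
            objects=[self.objects[i] for i in indices],
            data=self.data[:, :, indices].copy(),
            groups=None if self.groups is None else list(self.groups),
        )


@dataclass
class AffordanceMatrix:
    """Object x action endorsement proportions.

    Each object's row is its affordance vector: the fraction of
    participants who judged each action applicable.
    """

    objects: list[ObjectItem]
    actions: list[ActionItem]
    probs: np.ndarray
    n_participants: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.objects), len(self.actions)):
            raise FormatError("probs shape must be (objects, actions)")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise FormatError("affordance proportions must lie in [0, 1]")


@dataclass
class SimilarityMatrix:
    """Object x object Pearson similarity of affordance vectors.

    ``mask[i, j]`` is False where the correlation is undefined because
    one of the two affordance vectors has zero variance.
    """

    objects: list[ObjectItem]
    r: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.objects)
        self.r = np.asarray(self.r, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.r.shape != (n, n) or self.mask.shape != (n, n):
            raise FormatError("similarity matrix must be square over objects")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the boundary analysis.

    ``rank_bin_edges`` maps diagonal sizes to ranks starting at
    ``rank_start``; ``trough_site`` fixes the tested rank pair a priori
    (when None the deepest trough is detected from the observed curve);
    ``h1_prior_mean``/``h1_prior_sd`` parameterize the alternative prior
    of the Bayes factor on the Fisher-z scale.
    """

    rank_bin_edges: tuple[float, ...] = DEFAULT_RANK_EDGES
    rank_start: int = RANK_START
    exclude_animate: bool = True
    trough_site: tuple[int, int] | None = None
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    ci_level: float = 0.95
    h1_prior_mean: float = 2.0
    h1_prior_sd: float = 1.0
    permute: str = "objects"
    smoothed_p: bool = False
    rank_window: tuple[int, int] = (3, 6)
    n_boot: int = 1000

    def __post_init__(self) -> None:
        edges = np.asarray(self.rank_bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or not (np.diff(edges) > 0).all():
            raise ValueError("rank_bin_edges must be strictly increasing")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.h1_prior_sd <= 0:
            raise ValueError("h1_prior_sd must be positive")
        if self.permute not in ("objects", "actions"):
            raise ValueError("permute must be 'objects' or 'actions'")
        if self.trough_site is not None:
            i, j = self.trough_site
            if j != i + 1:
                raise ValueError("trough_site must be a neighboring rank pair")


def config_to_dict(config: AnalysisConfig) -> dict:
    """Flatten an :class:`AnalysisConfig` into YAML/JSON-safe scalars."""
    return {
        "rank_bin_edges": [float(e) for e in config.rank_bin_edges],
        "rank_start": config.rank_start,
        "exclude_animate": config.exclude_animate,
        "trough_site": (None if config.trough_site is None
                        else [int(v) for v in config.trough_site]),
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "seed": config.seed,
        "ci_level": config.ci_level,
        "h1_prior_mean": config.h1_prior_mean,
        "h1_prior_sd": config.h1_prior_sd,
        "permute": config.permute,
        "smoothed_p": config.smoothed_p,
        "rank_window": [int(v) for v in config.rank_window],
        "n_boot": config.n_boot,
    }


def config_from_dict(d: Mapping) -> AnalysisConfig:
    d = dict(d)
    if "rank_bin_edges" in d:
        d["rank_bin_edges"] = tuple(float(e) for e in d["rank_bin_edges"])
    if d.get("trough_site") is not None:
        d["trough_site"] = tuple(int(v) for v in d["trough_site"])
    if "rank_window" in d:
        d["rank_window"] = tuple(int(v) for v in d["rank_window"])
    return AnalysisConfig(**d)


def read_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config file {path} must hold a mapping")
    return config_from_dict(raw)


def write_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Rank binning

def assign_rank(diagonal_cm, config: AnalysisConfig | Sequence[float] | None = None,
                rank_start: int | None = None):
    """Map a diagonal size (cm) to its size rank.

    Bins are half-open ``[lower, upper)``, so a size exactly on an edge
    belongs to the higher rank.  Accepts a scalar or an array; raises
    :class:`RankRangeError` for sizes outside the covered range.
    """
    if config is None:
        edges, start = DEFAULT_RANK_EDGES, RANK_START
    elif isinstance(config, AnalysisConfig):
        edges, start = config.rank_bin_edges, config.rank_start
    else:
        edges, start = tuple(config), (RANK_START if rank_start is None else rank_start)
    if rank_start is not None:
        start = rank_start
    edges_arr = np.asarray(edges, dtype=float)
    d = np.asarray(diagonal_cm, dtype=float)
    if np.any(d < edges_arr[0]) or np.any(d >= edges_arr[-1]):
        raise RankRangeError(
            f"diagonal size outside covered range "
            f"[{edges_arr[0]}, {edges_arr[-1]}) cm: {diagonal_cm}")
    rank = start + np.searchsorted(edges_arr, d, side="right") - 1
    return int(rank) if np.isscalar(diagonal_cm) else rank


# ---------------------------------------------------------------------------
# Readers / writers

def read_objects(path, config: AnalysisConfig | None = None) -> list[ObjectItem]:
    """Read object metadata (object, diagonal_cm, rank?, animate?).

    The ``rank`` column is optional; missing ranks are derived from
    ``diagonal_cm`` via the configured bin edges.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"object", "diagonal_cm"}, path)
    items = []
    for _, row in df.iterrows():
        d = float(row["diagonal_cm"])
        if "rank" in df.columns and not pd.isna(row["rank"]):
            rank = int(row["rank"])
        else:
            rank = assign_rank(d, config)
        animate = bool(int(row["animate"])) if "animate" in df.columns else False
        items.append(ObjectItem(str(row["object"]), d, rank, animate))
    names = [o.name for o in items]
    if len(set(names)) != len(names):
        raise FormatError(f"duplicate object names in {path}")
    return items


def read_actions(path) -> list[ActionItem]:
    """Read action metadata (action, action_class)."""
    df = pd.read_csv(path)
    _require_columns(df, {"action", "action_class"}, path)
    items = []
    for _, row in df.iterrows():
        cls = str(row["action_class"])
        if cls not in ACTION_CLASSES:
            raise FormatError(
                f"unknown action_class {cls!r} for action {row['action']!r}")
        items.append(ActionItem(str(row["action"]), cls))
    names = [a.name for a in items]
    if len(set(names)) != len(names):
        raise FormatError(f"duplicate action names in {path}")
    return items


def read_responses(path, objects_path, actions_path,
                   config: AnalysisConfig | None = None) -> ResponseTensor:
    """Read and validate a long-format judgment table into a tensor.

    Rejects missing columns, duplicate (participant, action, object)
    rows, responses outside {0, 1}, names absent from the metadata
    files, and incomplete coverage of the participant x action x object
    grid.
    """
    objects_all = read_objects(objects_path, config)
    actions_all = read_actions(actions_path)
    df = pd.read_csv(path)
    _require_columns(df, {"participant", "action", "object", "response"}, path)

    bad = ~df["response"].isin((0, 1))
    if bad.any():
        row = df[bad].iloc[0]
        raise ResponseValueError(
            f"response {row['response']!r} outside {{0,1}} at row "
            f"{int(df.index[bad][0]) + 2} (participant={row['participant']!r}, "
            f"action={row['action']!r}, object={row['object']!r})")

    obj_names = {o.name for o in objects_all}
    act_names = {a.name for a in actions_all}
    unknown_obj = set(df["object"].astype(str)) - obj_names
    if unknown_obj:
        raise UnknownNameError(f"objects not in metadata: {sorted(unknown_obj)}")
    unknown_act = set(df["action"].astype(str)) - act_names
    if unknown_act:
        raise UnknownNameError(f"actions not in metadata: {sorted(unknown_act)}")

    dup = df.duplicated(subset=["participant", "action", "object"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicate judgment for (participant={row['participant']!r}, "
            f"action={row['action']!r}, object={row['object']!r})")

    participants = list(dict.fromkeys(df["participant"].astype(str)))
    used_objects = set(df["object"].astype(str))
    used_actions = set(df["action"].astype(str))
    objects = [o for o in objects_all if o.name in used_objects]
    actions = [a for a in actions_all if a.name in used_actions]

    p_idx = {p: i for i, p in enumerate(participants)}
    a_idx = {a.name: i for i, a in enumerate(actions)}
    o_idx = {o.name: i for i, o in enumerate(objects)}
    shape = (len(participants), len(actions), len(objects))
    if len(df) != int(np.prod(shape)):
        raise FormatError(
            f"incomplete judgment grid: {len(df)} rows for "
            f"{shape[0]} participants x {shape[1]} actions x "
            f"{shape[2]} objects (expected {int(np.prod(shape))})")

    data = np.zeros(shape, dtype=np.uint8)
    data[
        df["participant"].astype(str).map(p_idx).to_numpy(),
        df["action"].astype(str).map(a_idx).to_numpy(),
        df["object"].astype(str).map(o_idx).to_numpy(),
    ] = df["response"].to_numpy(dtype=np.uint8)

    groups = None
    if "group" in df.columns and df["group"].notna().any():
        per = df.groupby(df["participant"].astype(str))["group"].agg(
            lambda s: s.astype(str).unique())
        if any(len(g) > 1 for g in per):
            raise FormatError("inconsistent group labels within a participant")
        groups = [str(per[p][0]) for p in participants]

    logger.info(
        "read %d judgments: %d participants x %d actions x %d objects",
        len(df), *shape)
    return ResponseTensor(participants, actions, objects, data, groups)


def write_objects(objects: Sequence[ObjectItem], path) -> None:
    pd.DataFrame({
        "object": [o.name for o in objects],
        "diagonal_cm": [o.diagonal_cm for o in objects],
        "rank": [o.rank for o in objects],
        "animate": [int(o.animate) for o in objects],
    }).to_csv(path, index=False)


def write_actions(actions: Sequence[ActionItem], path) -> None:
    pd.DataFrame({
        "action": [a.name for a in actions],
        "action_class": [a.action_class for a in actions],
    }).to_csv(path, index=False)


def write_responses(tensor: ResponseTensor, path) -> None:
    """Write a tensor back to long format (inverse of :func:`read_responses`)."""
    P, A, O = tensor.data.shape
    pi, ai, oi = np.indices((P, A, O))
    df = pd.DataFrame({
        "participant": np.array(tensor.participants)[pi.ravel()],
        "action": np.array([a.name for a in tensor.actions])[ai.ravel()],
        "object": np.array([o.name for o in tensor.objects])[oi.ravel()],
        "response": tensor.data.ravel(),
    })
    if tensor.groups is not None:
        df.insert(1, "group", np.array(tensor.groups)[pi.ravel()])
    df.to_csv(path, index=False)


def filter_animate(tensor: ResponseTensor) -> ResponseTensor:
    """Drop animate objects; participants and actions are untouched."""
    keep = [i for i, o in enumerate(tensor.objects) if not o.animate]
    if not keep:
        raise EmptyResultError("all objects are animate; nothing left to analyze")
    if len(keep) == tensor.n_objects:
        return tensor
    logger.info("excluding %d animate objects, %d retained",
                tensor.n_objects - len(keep), len(keep))
    return tensor.select_objects(keep)


def _require_columns(df: pd.DataFrame, required: set, path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
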
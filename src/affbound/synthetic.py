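"""Synthetic object-action judgment generator with a latent body-size boundary.

The generator emulates the statistical structure the boundary analysis
assumes: an agent of body (bounding-box diagonal) size ``B`` endorses
manipulation-type actions for objects smaller than itself and
whole-body-type actions for objects larger, with a logistic transition
in log-size and a stimulus-independent lapse.  For object diagonal
``d`` and action class sign ``s`` (-1 manipulation, +1 whole-body), the
endorsement probability is::

    x = log2(d / B)
    p = lapse/2 + (1 - lapse) * gain * sigmoid(s * beta * x)

so that ``p = 0.5`` (scaled) exactly at the boundary, and the switch
sharpens as ``beta`` grows.  Responses are independent Bernoulli draws
per participant.  Setting ``agent_size_cm`` to a cat-, human- or
elephant-sized diagonal moves the induced affordance boundary across
the size ranks, which is what the recovery tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .core_io import (
    DEFAULT_RANK_EDGES,
    RANK_START,
    ActionItem,
    ObjectItem,
    ResponseTensor,
)

#: The 14 daily-life actions used by default: seven hand/effector-scale
#: manipulations and seven whole-body/locomotion actions.
DEFAULT_ACTIONS: tuple[ActionItem, ...] = (
    ActionItem("grasp", "manipulation"),
    ActionItem("hold", "manipulation"),
    ActionItem("throw", "manipulation"),
    ActionItem("lift", "manipulation"),
    ActionItem("carry", "manipulation"),
    ActionItem("push", "manipulation"),
    ActionItem("kick", "manipulation"),
    ActionItem("sit", "whole_body"),
    ActionItem("stand", "whole_body"),
    ActionItem("lie", "whole_body"),
    ActionItem("climb", "whole_body"),
    ActionItem("enter", "whole_body"),
    ActionItem("lean", "whole_body"),
    ActionItem("hide", "whole_body"),
)

# Fixed stream offsets so object sampling and response sampling are
# independently reproducible for the same seed.
_OBJECT_STREAM = 11
_RESPONSE_STREAM = 23


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic judgment experiment.

    Defaults mirror the reference behavioral study: 528 participants,
    24 inanimate objects spanning size ranks 2-8, 14 actions, and a
    human-scale agent.  ``agent_size_cm`` is the latent boundary B
    (human ~150, cat 77, elephant 577); ``sharpness_beta`` is the
    logistic slope per octave of size ratio; ``lapse_rate`` the
    probability of a stimulus-independent random response.
    ``action_gain`` (scalar or per-action-name mapping in (0, 1])
    scales base endorsement rates; ``participant_sd`` optionally adds a
    per-participant normal logit offset.
    """

    n_participants: int = 528
    n_objects: int | None = 24
    objects_per_rank: int | None = None
    rank_range: tuple[int, int] = (2, 8)
    agent_size_cm: float = 150.0
    sharpness_beta: float = 4.0
    lapse_rate: float = 0.05
    action_gain: float | Mapping[str, float] = 1.0
    participant_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.objects_per_rank is None and self.n_objects is None:
            raise ValueError("one of n_objects or objects_per_rank is required")
        if self.objects_per_rank is not None and self.objects_per_rank < 1:
            raise ValueError("objects_per_rank must be positive")
        if self.n_objects is not None and self.n_objects < 1:
            raise ValueError("n_objects must be positive")
        lo, hi = self.rank_range
        if lo > hi:
            raise ValueError("rank_range must be a non-empty interval")
        if self.agent_size_cm <= 0:
            raise ValueError("agent_size_cm must be positive")
        if self.sharpness_beta < 0:
            raise ValueError("sharpness_beta must be non-negative")
        if not 0 <= self.lapse_rate < 1:
            raise ValueError("lapse_rate must be in [0, 1)")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be non-negative")
        for g in (self.action_gain.values()
                  if isinstance(self.action_gain, Mapping)
                  else (self.action_gain,)):
            if not 0 < g <= 1:
                raise ValueError("action gains must lie in (0, 1]")


def _rank_counts(config: GeneratorConfig) -> dict[int, int]:
    lo, hi = config.rank_range
    ranks = list(range(lo, hi + 1))
    if config.objects_per_rank is not None:
        return {r: config.objects_per_rank for r in ranks}
    base, extra = divmod(config.n_objects, len(ranks))
    # spread the remainder over the smallest ranks
    return {r: base + (1 if i < extra else 0) for i, r in enumerate(ranks)}


def generate_object_set(config: GeneratorConfig,
                        edges: Sequence[float] = DEFAULT_RANK_EDGES,
                        ) -> list[ObjectItem]:
    """Sample an object set, log-uniform within each rank's size bin.

    Counts per rank follow ``objects_per_rank`` when given, otherwise
    ``n_objects`` spread as evenly as possible (remainder to the
    smallest ranks).  Deterministic given ``config.seed``.
    """
    counts = _rank_counts(config)
    edges = np.asarray(edges, dtype=float)
    rng = np.random.default_rng([config.seed, _OBJECT_STREAM])
    objects: list[ObjectItem] = []
    for rank, count in counts.items():
        i = rank - RANK_START
        if i < 0 or i + 1 >= len(edges):
            raise ValueError(f"rank {rank} not covered by the bin edges")
        lo, hi = edges[i], edges[i + 1]
        sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=count))
        for j, d in enumerate(np.sort(sizes)):
            objects.append(ObjectItem(f"obj_r{rank}_{j:02d}", float(d), rank))
    return objects


def _class_signs(actions: Sequence[ActionItem]) -> np.ndarray:
    return np.array([1.0 if a.action_class == "whole_body" else -1.0
                     for a in actions])


def _gains(actions: Sequence[ActionItem], config: GeneratorConfig) -> np.ndarray:
    if isinstance(config.action_gain, Mapping):
        try:
            return np.array([float(config.action_gain[a.name]) for a in actions])
        except KeyError as exc:
            raise ValueError(f"action_gain missing entry for {exc}") from exc
    return np.full(len(actions), float(config.action_gain))


def _logit_core(logits: np.ndarray) -> np.ndarray:
    """Logistic of possibly infinite logits; 0 * inf at the boundary -> 0.5."""
    with np.errstate(invalid="ignore"):
        core = expit(logits)
    return np.where(np.isnan(logits), 0.5, core)


def _logits(signs: np.ndarray, beta: float, x: np.ndarray) -> np.ndarray:
    # beta may be inf; 0 * inf yields NaN which _logit_core maps to 0.5
    with np.errstate(invalid="ignore"):
        return signs * beta * x


def endorsement_probability(obj: ObjectItem, action: ActionItem,
                            config: GeneratorConfig) -> float:
    """Probability that one participant endorses ``action`` for ``obj``."""
    x = np.log2(obj.diagonal_cm / config.agent_size_cm)
    s = 1.0 if action.action_class == "whole_body" else -1.0
    core = _logit_core(_logits(np.asarray(s), config.sharpness_beta, x))
    gain = (float(config.action_gain[action.name])
            if isinstance(config.action_gain, Mapping)
            else float(config.action_gain))
    lam = config.lapse_rate
    return float(lam / 2 + (1 - lam) * gain * core)


def probability_matrix(objects: Sequence[ObjectItem],
                       actions: Sequence[ActionItem],
                       config: GeneratorConfig) -> np.ndarray:
    """Endorsement probabilities as an (actions, objects) array."""
    x = np.log2([o.diagonal_cm for o in objects]) - np.log2(config.agent_size_cm)
    logits = _logits(_class_signs(actions)[:, None], config.sharpness_beta,
                     x[None, :])
    core = _logit_core(logits)
    lam = config.lapse_rate
    return lam / 2 + (1 - lam) * _gains(actions, config)[:, None] * core


def generate_responses(objects: Sequence[ObjectItem],
                       actions: Sequence[ActionItem],
                       config: GeneratorConfig) -> ResponseTensor:
    """Draw independent Bernoulli judgments for every cell.

    With ``participant_sd > 0`` each participant receives a normal
    logit offset, shifting their personal boundary.  Deterministic
    given ``config.seed``.
    """
    if not objects or not actions:
        raise ValueError("objects and actions must be non-empty")
    P = config.n_participants
    rng = np.random.default_rng([config.seed, _RESPONSE_STREAM])
    x = np.log2([o.diagonal_cm for o in objects]) - np.log2(config.agent_size_cm)
    logits = _logits(_class_signs(actions)[:, None], config.sharpness_beta,
                     x[None, :])
    if config.participant_sd > 0:
        delta = rng.normal(0.0, config.participant_sd, size=P)
        core = _logit_core(logits[None, :, :] + delta[:, None, None])
    else:
        core = np.broadcast_to(_logit_core(logits), (P, *logits.shape))
    lam = config.lapse_rate
    p = lam / 2 + (1 - lam) * _gains(actions, config)[None, :, None] * core
    data = (rng.random(p.shape) < p).astype(np.uint8)
    participants = [f"p{i + 1:04d}" for i in range(P)]
    return ResponseTensor(participants, list(actions), list(objects), data)


def simulate(config: GeneratorConfig,
             actions: Sequence[ActionItem] = DEFAULT_ACTIONS,
             edges: Sequence[float] = DEFAULT_RANK_EDGES) -> ResponseTensor:
    """Generate objects and responses in one step."""
    objects = generate_object_set(config, edges)
    return generate_responses(objects, actions, config)
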
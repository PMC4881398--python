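"""Activation calculus of declarative memory retrieval.

A retrieval is a race between chunks (here: discourse referents) for a set
of weighted feature cues.  Each chunk's momentary activation is the sum of
four components,

    A_i = B_i + sum_j W_j * S_ji + sum_k P * M_ki + eps_i,

where ``B_i = ln(sum_r t_r^-d)`` is the base level from the recency and
frequency of the chunk's mentions, the first summation spreads source
activation over the cues the chunk matches with fan-limited associative
strengths ``S_ji = S - ln(fan_j)``, the second summation penalises each
mismatched cue by ``P * max_difference`` (partial matching), and ``eps_i``
is logistic instantaneous noise.  The chunk with the highest activation is
retrieved if it clears the threshold ``tau``; the retrieval takes
``F * exp(-A_winner)`` seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .params import ModelParams

#: Sentinel winner id for a retrieval in which no chunk reached threshold.
FAILURE = "FAILURE"


class InvalidTimelineError(ValueError):
    """A chunk has a mention age that is not strictly positive."""


@dataclass(frozen=True)
class Chunk:
    """A declarative memory item: one discourse referent.

    ``features`` maps feature names (gender, category, role, clause) to
    values; ``creation_times`` holds the ages, in seconds before the moment
    of retrieval, of the referent's mentions (most recent last).
    """

    id: str
    features: Mapping[str, str]
    creation_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.creation_times:
            raise InvalidTimelineError(f"chunk {self.id!r} has no mentions")
        object.__setattr__(self, "features", dict(self.features))
        object.__setattr__(self, "creation_times", tuple(self.creation_times))


@dataclass(frozen=True)
class CueSet:
    """The retrieval request: required feature values plus per-cue weights.

    Weights default to an even split of the total source activation over
    the cues.
    """

    cues: Mapping[str, str]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.cues:
            raise ValueError("a cue set needs at least one cue")
        if set(self.cues) != set(self.weights):
            raise ValueError("weights must cover exactly the cues")
        object.__setattr__(self, "cues", dict(self.cues))
        object.__setattr__(self, "weights", dict(self.weights))

    @classmethod
    def from_cues(cls, cues: Mapping[str, str], total_source_W: float) -> "CueSet":
        if not cues:
            raise ValueError("a cue set needs at least one cue")
        w = total_source_W / len(cues)
        return cls(cues=dict(cues), weights={k: w for k in cues})


@dataclass(frozen=True)
class ActivationBreakdown:
    """Additive decomposition of one chunk's momentary activation."""

    base: float
    spreading: float
    penalty: float
    noise: float

    @property
    def total(self) -> float:
        return self.base + self.spreading + self.penalty + self.noise


@dataclass(frozen=True)
class RetrievalOutcome:
    """Result of a single retrieval attempt."""

    winner_id: str  # chunk id, or FAILURE
    latency: float  # seconds
    breakdowns: dict[str, ActivationBreakdown] = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.winner_id == FAILURE


def base_level_activation(chunk: Chunk, params: ModelParams) -> float:
    """Base-level activation ``ln(sum_r t_r^-d)`` over the chunk's mentions."""
    if any(t <= 0 for t in chunk.creation_times):
        raise InvalidTimelineError(
            f"chunk {chunk.id!r} has a mention age <= 0 at retrieval"
        )
    return math.log(
        sum(t ** (-params.decay_d) for t in chunk.creation_times)
    )


def fan_of_cue(cue: tuple[str, str], chunks: Sequence[Chunk]) -> int:
    """Number of chunks whose value for the cue's feature equals its value."""
    feature, value = cue
    return sum(1 for c in chunks if c.features.get(feature) == value)


def strength_of_association(
    cue: tuple[str, str], chunks: Sequence[Chunk], params: ModelParams
) -> float:
    """Fan-limited associative strength ``S - ln(fan)`` of a cue.

    A cue matched by no chunk has no association to spread; its strength is
    reported as 0.  Strengths may go negative when ``fan > e^S``.
    """
    fan = fan_of_cue(cue, chunks)
    if fan == 0:
        return 0.0
    return params.max_assoc_strength_S - math.log(fan)


def spreading_activation_sum(
    chunk: Chunk, cue_set: CueSet, chunks: Sequence[Chunk], params: ModelParams
) -> float:
    """Source activation the chunk receives from the cues it matches."""
    total = 0.0
    for feature, value in cue_set.cues.items():
        if chunk.features.get(feature) == value:
            total += cue_set.weights[feature] * strength_of_association(
                (feature, value), chunks, params
            )
    return total


def mismatch_penalty_sum(
    chunk: Chunk, cue_set: CueSet, params: ModelParams
) -> float:
    """Partial-matching penalty: ``P * max_difference`` per mismatched cue."""
    mismatched = sum(
        1
        for feature, value in cue_set.cues.items()
        if chunk.features.get(feature) != value
    )
    return params.match_scale_P * params.max_difference * mismatched


def total_activation(
    chunk: Chunk,
    cue_set: CueSet,
    chunks: Sequence[Chunk],
    params: ModelParams,
    noise_draw: float = 0.0,
) -> ActivationBreakdown:
    """Full activation breakdown of a chunk under a retrieval request.

    ``noise_draw`` is one sample of logistic noise with scale
    ``params.noise_scale_s`` (0 when the scale is 0); drawing it is the
    caller's job so that deterministic analyses stay deterministic.
    """
    return ActivationBreakdown(
        base=base_level_activation(chunk, params),
        spreading=spreading_activation_sum(chunk, cue_set, chunks, params),
        penalty=mismatch_penalty_sum(chunk, cue_set, params),
        noise=noise_draw,
    )


def retrieval_latency(activation: float, params: ModelParams) -> float:
    """Retrieval time ``F * exp(-A)`` in seconds (plus any fixed cost)."""
    return params.latency_factor_F * math.exp(-activation) + params.fixed_cost


def retrieve_once(
    chunks: Sequence[Chunk],
    cue_set: CueSet,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> RetrievalOutcome:
    """Run one retrieval: noisy activations, winner selection, latency.

    One independent logistic noise draw per candidate.  The winner is the
    highest-activation candidate at or above the retrieval threshold; if no
    candidate reaches threshold the retrieval fails after the time a
    threshold-level retrieval would take, ``F * exp(-tau)``.
    """
    if not chunks:
        raise ValueError("retrieve_once needs a non-empty candidate set")
    s = params.noise_scale_s
    if s > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_scale_s > 0")
        draws = rng.logistic(loc=0.0, scale=s, size=len(chunks))
    else:
        draws = np.zeros(len(chunks))
    breakdowns = {
        c.id: total_activation(c, cue_set, chunks, params, float(eps))
        for c, eps in zip(chunks, draws)
    }
    winner = max(breakdowns, key=lambda cid: breakdowns[cid].total)
    best = breakdowns[winner].total
    if best < params.retrieval_threshold_tau:
        return RetrievalOutcome(
            winner_id=FAILURE,
            latency=retrieval_latency(params.retrieval_threshold_tau, params),
            breakdowns=breakdowns,
        )
    return RetrievalOutcome(
        winner_id=winner,
        latency=retrieval_latency(best, params),
        breakdowns=breakdowns,
    )
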
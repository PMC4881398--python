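"""Architecture constants for the declarative-memory retrieval model.

All parameters of the activation calculus live in one frozen dataclass so a
simulation is fully specified by (design, condition, params, seed).  Defaults
follow the convention of prior cue-based retrieval models of sentence
processing: the decay rate, maximum associative strength, maximum-difference
similarity, and retrieval threshold are the values customarily used in that
literature, while the source activation, match scale, noise scale, latency
factor and per-word encoding time are calibrated once so that the model's
four predicted condition means for the classic two-antecedent reflexive
design fall on the published prediction scale (~194-295 ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class ModelParams:
    """Constants of the activation calculus.

    Parameters
    ----------
    decay_d:
        Power-law decay exponent of base-level activation (unitless, > 0).
    max_assoc_strength_S:
        Maximum associative strength ``S``; the strength of a cue-to-chunk
        association is ``S - ln(fan)``.
    max_difference:
        Similarity assigned to a cue/feature mismatch (unitless, <= 0).
    match_scale_P:
        Weight on the partial-matching penalty; each mismatched cue
        contributes ``match_scale_P * max_difference`` to activation.
    noise_scale_s:
        Scale of the logistic instantaneous activation noise (unitless,
        >= 0; 0 disables noise).
    latency_factor_F:
        Latency factor in seconds; retrieval time is ``F * exp(-A)``.
    retrieval_threshold_tau:
        Minimum activation for a successful retrieval.
    total_source_W:
        Total source activation, divided evenly over the retrieval cues.
    per_word_time:
        Seconds of encoding time per word, used to convert word-position
        distances into chunk ages.
    fixed_cost:
        Constant added to every reported retrieval time (seconds); not part
        of the latency equation proper, 0 by default.
    """

    decay_d: float = 0.5
    max_assoc_strength_S: float = 1.5
    max_difference: float = -1.0
    match_scale_P: float = 0.25
    noise_scale_s: float = 0.15
    latency_factor_F: float = 0.313
    retrieval_threshold_tau: float = -1.5
    total_source_W: float = 0.4
    per_word_time: float = 0.3
    fixed_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_d <= 0:
            raise ValueError("decay_d must be > 0")
        if self.max_difference > 0:
            raise ValueError("max_difference must be <= 0")
        if self.noise_scale_s < 0:
            raise ValueError("noise_scale_s must be >= 0")
        if self.latency_factor_F <= 0:
            raise ValueError("latency_factor_F must be > 0")
        if self.per_word_time <= 0:
            raise ValueError("per_word_time must be > 0")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))
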
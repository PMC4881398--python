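"""Experimental designs for reflexive binding, encoded as retrieval problems.

Three two-antecedent designs are shipped.  Each pairs a grammatically
accessible antecedent (the clause-mate subject the reflexive must bind to)
with a grammatically inaccessible one, crossed in a 2x2: whether the
accessible antecedent's (stereotypical) gender matches the reflexive
("match" vs "mismatch") and whether the inaccessible one's does
("interference" vs no interference).

``sturt_exp1``   "He remembered that the surgeon had pricked himself ...":
                 the distractor is the matrix-clause subject pronoun,
                 mentioned earlier in the string than the accessible
                 antecedent.
``sturt_exp2``   "The surgeon who treated Jonathan had pricked himself ...":
                 the distractor sits inside a relative clause as its
                 *object*, so it fails the subject-role retrieval cue.
``modified``     "The tough soldier that Katie treated in the military
                 hospital introduced herself ...": the distractor is a
                 relative-clause *subject* and linearly closer to the
                 reflexive - the maximally interfering configuration.

The retrieval request at the reflexive carries four cues,
{gender, category=noun, role=subject, clause=current}; the structural-only
variant drops the gender cue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .memory import Chunk, CueSet
from .params import ModelParams

CONDITIONS = ("a", "b", "c", "d")
CONDITION_NAMES = {
    "a": "match-interference",
    "b": "match",
    "c": "mismatch-interference",
    "d": "mismatch",
}


@dataclass(frozen=True)
class ReferentSpec:
    """One candidate antecedent: features plus its mention positions.

    ``mention_word_indices`` are 0-based word positions within the critical
    sentence; negative indices denote mentions in a preceding sentence.
    Category is always noun.
    """

    label: str
    gender: str  # "masc" | "fem"
    role: str  # "subject" | "object"
    clause: str  # "current" | "other"
    mention_word_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.mention_word_indices:
            raise ValueError(f"referent {self.label!r} needs a mention")
        object.__setattr__(
            self, "mention_word_indices", tuple(self.mention_word_indices)
        )


@dataclass(frozen=True)
class ConditionSpec:
    """A fully resolved design x condition cell."""

    design: str
    condition: str  # a | b | c | d
    reflexive_gender: str
    accessible: ReferentSpec
    inaccessible: ReferentSpec
    reflexive_word_index: int

    @property
    def referents(self) -> tuple[ReferentSpec, ReferentSpec]:
        return (self.accessible, self.inaccessible)


@dataclass(frozen=True)
class DesignSpec:
    """Condition-independent layout of one experimental design.

    Genders are resolved per condition; ``extra_mentions`` holds earlier
    (preceding-sentence) mention positions of the inaccessible referent,
    used only when ``multi_mention`` encoding is requested.
    """

    name: str
    accessible_label: str
    accessible_index: int
    inaccessible_label: str
    inaccessible_index: int
    inaccessible_role: str
    reflexive_word_index: int
    inaccessible_extra_mentions: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "accessible_label": self.accessible_label,
            "accessible_index": self.accessible_index,
            "inaccessible_label": self.inaccessible_label,
            "inaccessible_index": self.inaccessible_index,
            "inaccessible_role": self.inaccessible_role,
            "reflexive_word_index": self.reflexive_word_index,
            "inaccessible_extra_mentions": list(self.inaccessible_extra_mentions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        d = dict(d)
        d["inaccessible_extra_mentions"] = tuple(
            d.get("inaccessible_extra_mentions", ())
        )
        return cls(**d)


# Word positions read off the example stimuli of each design.  The first
# sentence of the two Sturt designs ("Jonathan was pretty worried at the
# City Hospital.", 8 words) precedes the critical sentence, hence the -8
# extra mention for the distractor referent.
DESIGNS: dict[str, DesignSpec] = {
    "sturt_exp1": DesignSpec(
        name="sturt_exp1",
        accessible_label="surgeon",
        accessible_index=4,
        inaccessible_label="pronoun",
        inaccessible_index=0,
        inaccessible_role="subject",
        reflexive_word_index=7,
        inaccessible_extra_mentions=(-8,),
    ),
    "sturt_exp2": DesignSpec(
        name="sturt_exp2",
        accessible_label="surgeon",
        accessible_index=1,
        inaccessible_label="name",
        inaccessible_index=4,
        inaccessible_role="object",
        reflexive_word_index=7,
        inaccessible_extra_mentions=(-8,),
    ),
    "modified": DesignSpec(
        name="modified",
        accessible_label="soldier",
        accessible_index=2,
        inaccessible_label="name",
        inaccessible_index=4,
        inaccessible_role="subject",
        reflexive_word_index=11,
    ),
}


def _other(gender: str) -> str:
    return "fem" if gender == "masc" else "masc"


def condition_spec(
    design: str,
    condition: str,
    accessible_gender: str = "masc",
    multi_mention: bool = False,
) -> ConditionSpec:
    """Resolve a design/condition pair into referents and a reflexive.

    In the match conditions (a, b) the reflexive agrees with the accessible
    antecedent's gender; in the mismatch conditions (c, d) it does not.  In
    the interference conditions (a, c) the inaccessible antecedent carries
    the reflexive's gender; in (b, d) it carries the other one.
    """
    if design not in DESIGNS:
        raise KeyError(f"unknown design {design!r}; have {sorted(DESIGNS)}")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; use one of a-d")
    spec = DESIGNS[design]
    refl = accessible_gender if condition in ("a", "b") else _other(accessible_gender)
    inacc_gender = refl if condition in ("a", "c") else _other(refl)
    inacc_mentions = (spec.inaccessible_index,)
    if multi_mention:
        inacc_mentions = spec.inaccessible_extra_mentions + inacc_mentions
    accessible = ReferentSpec(
        label=spec.accessible_label,
        gender=accessible_gender,
        role="subject",
        clause="current",
        mention_word_indices=(spec.accessible_index,),
    )
    inaccessible = ReferentSpec(
        label=spec.inaccessible_label,
        gender=inacc_gender,
        role=spec.inaccessible_role,
        clause="other",
        mention_word_indices=inacc_mentions,
    )
    return ConditionSpec(
        design=design,
        condition=condition,
        reflexive_gender=refl,
        accessible=accessible,
        inaccessible=inaccessible,
        reflexive_word_index=spec.reflexive_word_index,
    )


def swap_genders(cond: ConditionSpec) -> ConditionSpec:
    """Flip every gender in the condition (masc <-> fem)."""
    return replace(
        cond,
        reflexive_gender=_other(cond.reflexive_gender),
        accessible=replace(cond.accessible, gender=_other(cond.accessible.gender)),
        inaccessible=replace(
            cond.inaccessible, gender=_other(cond.inaccessible.gender)
        ),
    )


def _referent_chunk(
    ref: ReferentSpec, reflexive_word_index: int, params: ModelParams
) -> Chunk:
    ages = tuple(
        sorted(
            (reflexive_word_index - i) * params.per_word_time
            for i in ref.mention_word_indices
        )
    )
    # creation_times most recent last
    return Chunk(
        id=ref.label,
        features={
            "gender": ref.gender,
            "category": "noun",
            "role": ref.role,
            "clause": ref.clause,
        },
        creation_times=tuple(reversed(ages)),
    )


def encode_condition(
    design: str,
    condition: str,
    params: ModelParams,
    structural_only: bool = False,
    accessible_gender: str = "masc",
    multi_mention: bool = False,
    extra_nps: int = 0,
) -> tuple[list[Chunk], CueSet]:
    """Build the chunk set and retrieval request for one design cell.

    Chunk ages are word distances to the reflexive times the per-word
    encoding time.  ``structural_only`` drops the gender cue, leaving the
    three structural cues {category, role, clause}.  ``extra_nps`` adds
    that many non-candidate noun chunks (inanimate NPs such as "hospital"),
    which only contribute fan, for sensitivity analyses.
    """
    cond = condition_spec(design, condition, accessible_gender, multi_mention)
    chunks = [
        _referent_chunk(ref, cond.reflexive_word_index, params)
        for ref in cond.referents
    ]
    for k in range(extra_nps):
        chunks.append(
            Chunk(
                id=f"np{k}",
                features={
                    "gender": "none",
                    "category": "noun",
                    "role": "oblique",
                    "clause": "other",
                },
                creation_times=((k + 1) * params.per_word_time,),
            )
        )
    cues = {
        "gender": cond.reflexive_gender,
        "category": "noun",
        "role": "subject",
        "clause": "current",
    }
    if structural_only:
        del cues["gender"]
    return chunks, CueSet.from_cues(cues, params.total_source_W)


def _cues_mapping(cue_set) -> dict:
    # accept a CueSet or a plain {feature: value} mapping (possibly empty)
    return cue_set.cues if isinstance(cue_set, CueSet) else dict(cue_set)


def cue_match_count(chunk: Chunk, cue_set) -> int:
    """Number of cues whose required value the chunk's features carry."""
    return sum(
        1
        for feature, value in _cues_mapping(cue_set).items()
        if chunk.features.get(feature) == value
    )


def matched_cues(chunk: Chunk, cue_set) -> frozenset[str]:
    """The cue names the chunk matches (for match-pattern tables)."""
    return frozenset(
        feature
        for feature, value in _cues_mapping(cue_set).items()
        if chunk.features.get(feature) == value
    )


def default_timelines(design: str) -> dict:
    """Mention word indices and reflexive index of a shipped design."""
    spec = DESIGNS[design]
    return {
        "accessible": [spec.accessible_index],
        "inaccessible": [spec.inaccessible_index],
        "reflexive": spec.reflexive_word_index,
    }


def save_designs(path: str | Path, designs: dict[str, DesignSpec] = DESIGNS) -> None:
    Path(path).write_text(
        json.dumps({k: v.to_dict() for k, v in designs.items()}, indent=2) + "\n"
    )


def load_designs(path: str | Path) -> dict[str, DesignSpec]:
    raw = json.loads(Path(path).read_text())
    return {k: DesignSpec.from_dict(v) for k, v in raw.items()}
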
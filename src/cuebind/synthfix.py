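"""Synthetic fixation datasets with controllable condition effects.

Emulates a one-line reading experiment with a 2x2 reflexive-binding design:
items rotate over conditions across four lists by a Latin square, each
participant reads each item once, and the eyes traverse the sentence left
to right with log-normal fixation durations, occasional refixations, and
optional regressions launched from the critical region.

The generator is a test harness for the measure extraction, not an
oculomotor model: per-condition shifts are injected directly into first
fixation durations, regression probabilities, re-reading durations and the
post-region progression speed, so each measure has a known ground truth to
recover.  Saccades are instantaneous at the 1 ms resolution of the
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import CONDITIONS
from .eyemeasures import Fixation, RegionLayout, layout_from_words

DEFAULT_WORDS = (
    "The", "tough", "soldier", "that", "Katie", "treated", "in", "the",
    "military", "hospital", "introduced", "herself", "to", "all", "the",
    "nurses",
)
DEFAULT_CRITICAL = 11


@dataclass(frozen=True)
class ConditionEffects:
    """Ground-truth shifts injected for one condition (relative to baseline)."""

    ffd_shift_ms: float = 0.0
    regression_prob: float = 0.0  # probability of a first-pass regression
    rereading_prob: float = 0.0  # probability of a later re-reading pass
    rereading_shift_ms: float = 0.0
    progression_delay_ms: float = 0.0  # extra dwell before leaving the region
    progression_px: float = 0.0  # extra forward reach after the region

    def __post_init__(self) -> None:
        for p in (self.regression_prob, self.rereading_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study dimensions, layout template and injected effects."""

    n_participants: int = 40
    n_items: int = 24
    words: tuple[str, ...] = DEFAULT_WORDS
    critical_region: int = DEFAULT_CRITICAL
    char_width: float = 11.0
    mean_ffd_ms: float = 220.0
    ffd_sigma: float = 0.25  # log-normal shape of fixation durations
    refixation_prob: float = 0.3
    y_noise_px: float = 5.0
    effects: dict = field(default_factory=dict)  # condition -> ConditionEffects

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_items < 1:
            raise ValueError("need at least one participant and one item")
        if self.ffd_sigma < 0 or self.y_noise_px < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.refixation_prob <= 1.0:
            raise ValueError("refixation_prob must be in [0, 1]")
        eff = {c: ConditionEffects() for c in CONDITIONS}
        for c, e in self.effects.items():
            if c not in CONDITIONS:
                raise KeyError(f"unknown condition {c!r}")
            eff[c] = e if isinstance(e, ConditionEffects) else ConditionEffects(**e)
        object.__setattr__(self, "effects", eff)
        object.__setattr__(self, "words", tuple(self.words))

    def layout(self) -> RegionLayout:
        return layout_from_words(
            self.words, self.critical_region, char_width=self.char_width
        )


def latin_square(n_items: int) -> np.ndarray:
    """Condition index per (list, item): each list sees each item in one
    condition, rotated so conditions are balanced across items."""
    lists = np.arange(4)[:, None]
    items = np.arange(n_items)[None, :]
    return (lists + items) % 4


def _duration(rng, mean_ms: float, sigma: float) -> float:
    if sigma == 0:
        return mean_ms
    return float(mean_ms * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))


def _word_fixation(rng, layout, k, t, dur, y_noise):
    left, right = layout.boxes[k]
    x = rng.uniform(left + 0.2 * (right - left), left + 0.8 * (right - left))
    y = (layout.top + layout.bottom) / 2 + rng.normal(0, y_noise)
    return Fixation(x=float(x), y=float(y), onset=t, duration=dur)


def generate_trial(
    config: GeneratorConfig, condition: str, rng: np.random.Generator
) -> list[Fixation]:
    """One trial's fixation sequence (ordered, non-overlapping)."""
    layout = config.layout()
    eff: ConditionEffects = config.effects[condition]
    crit = config.critical_region
    fixations: list[Fixation] = []
    t = 0.0

    def emit(k, dur):
        nonlocal t
        fixations.append(
            _word_fixation(rng, layout, k, t, dur, config.y_noise_px)
        )
        t += dur + 1.0  # instantaneous saccade; 1 ms keeps onsets ordered

    for k in range(len(layout.words)):
        dur = _duration(rng, config.mean_ffd_ms, config.ffd_sigma)
        if k == crit:
            dur += eff.ffd_shift_ms
        emit(k, dur)
        if k == crit:
            if eff.progression_delay_ms > 0:
                # linger on the region: delays all later forward progress
                emit(k, eff.progression_delay_ms)
            if rng.random() < eff.regression_prob:
                back = max(0, k - 2)
                emit(back, _duration(rng, config.mean_ffd_ms, config.ffd_sigma))
                emit(k - 1, _duration(rng, config.mean_ffd_ms, config.ffd_sigma))
        elif k != crit and rng.random() < config.refixation_prob:
            emit(k, _duration(rng, 0.6 * config.mean_ffd_ms, config.ffd_sigma))
    if rng.random() < eff.rereading_prob:
        emit(crit, _duration(rng, config.mean_ffd_ms + eff.rereading_shift_ms,
                             config.ffd_sigma))
        emit(len(layout.words) - 1, _duration(rng, config.mean_ffd_ms,
                                              config.ffd_sigma))
    if eff.progression_px > 0:
        # one extra far-right fixation widens post-region progression
        last = fixations[-1]
        fixations.append(
            Fixation(
                x=last.x + eff.progression_px,
                y=last.y,
                onset=t,
                duration=_duration(rng, config.mean_ffd_ms, config.ffd_sigma),
            )
        )
    return fixations


def generate_dataset(
    config: GeneratorConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, RegionLayout]:
    """Fixation and trial tables for a full Latin-square study.

    Returns ``(fixations, trials, layout)``: fixations has one row per
    fixation (participant, item, trial, x, y, onset_ms, duration_ms);
    trials maps each trial to its participant, item and condition.
    """
    square = latin_square(config.n_items)
    layout = config.layout()
    fix_rows = []
    trial_rows = []
    trial_id = 0
    for p in range(config.n_participants):
        lst = p % 4
        for item in range(config.n_items):
            cond = CONDITIONS[square[lst, item]]
            rng = np.random.default_rng([seed, p, item])
            for f in generate_trial(config, cond, rng):
                fix_rows.append(
                    {
                        "trial": trial_id,
                        "participant": p,
                        "item": item,
                        "x": f.x,
                        "y": f.y,
                        "onset_ms": f.onset,
                        "duration_ms": f.duration,
                    }
                )
            trial_rows.append(
                {
                    "trial": trial_id,
                    "participant": p,
                    "item": item,
                    "condition": cond,
                }
            )
            trial_id += 1
    return pd.DataFrame(fix_rows), pd.DataFrame(trial_rows), layout


def fixations_from_frame(frame: pd.DataFrame) -> dict[int, list[Fixation]]:
    """Group a fixation table back into per-trial Fixation lists."""
    out: dict[int, list[Fixation]] = {}
    for trial, g in frame.groupby("trial"):
        g = g.sort_values("onset_ms")
        out[int(trial)] = [
            Fixation(x=r.x, y=r.y, onset=r.onset_ms, duration=r.duration_ms)
            for r in g.itertuples()
        ]
    return out
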
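"""Reading-time measures and cumulative progressions from fixation records.

Works on single-line reading displays.  Fixations (x, y in screen pixels,
onset and duration in ms) are first assigned to words: a fixation counts
for a word if it falls inside the word's box, vertically extended 30 px
above and below the line; fixations in the blank space between two words
are split at the midpoint (first half to the preceding word, second half to
the following word); everything else is discarded.

Per region the standard measures are computed:

    FFD   first fixation duration: duration of the first fixation of the
          first pass
    FPRT  first-pass reading time: sum of the consecutive fixations in the
          region from its first entry until the first exit, provided no
          later word was fixated before the entry
    RRT   re-reading time: sum of all region fixations after the first pass
    TRT   total reading time = FPRT + RRT
    FPRP  1 iff the first-pass exit saccade lands on an earlier word
    RRP   1 iff the region is fixated after the first pass

The cumulative progression tracks how far (in pixels) the eyes have moved
rightward from the first fixation in a region of interest, sampled every
2 ms for 1000 ms; regressions never decrease it, so each curve is
monotonically non-decreasing and starts at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VERTICAL_SLACK_PX = 30.0
PROGRESSION_WINDOW_MS = 1000.0
PROGRESSION_DT_MS = 2.0
N_PROGRESSION_SAMPLES = int(PROGRESSION_WINDOW_MS / PROGRESSION_DT_MS) + 1  # 501


@dataclass(frozen=True)
class Fixation:
    x: float  # px
    y: float  # px
    onset: float  # ms from trial start
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be > 0")


@dataclass(frozen=True)
class RegionLayout:
    """Word bounding boxes of a one-line display.

    ``boxes`` are per-word (left, right) pixel edges, half-open [left,
    right), strictly left-to-right with gaps allowed; ``top``/``bottom``
    bound the text line; ``critical_region`` indexes the region of interest
    (the reflexive).
    """

    words: tuple[str, ...]
    boxes: tuple[tuple[float, float], ...]
    top: float
    bottom: float
    critical_region: int

    def __post_init__(self) -> None:
        if len(self.words) != len(self.boxes):
            raise ValueError("one box per word required")
        for (l, r) in self.boxes:
            if r <= l:
                raise ValueError("word box must have right > left")
        for (_, r1), (l2, _) in zip(self.boxes, self.boxes[1:]):
            if l2 < r1:
                raise ValueError("word boxes must be non-overlapping, ordered")
        if not 0 <= self.critical_region < len(self.words):
            raise IndexError("critical_region out of range")
        object.__setattr__(self, "words", tuple(self.words))
        object.__setattr__(self, "boxes", tuple(tuple(b) for b in self.boxes))

    def translate(self, dx: float) -> "RegionLayout":
        return RegionLayout(
            words=self.words,
            boxes=tuple((l + dx, r + dx) for l, r in self.boxes),
            top=self.top,
            bottom=self.bottom,
            critical_region=self.critical_region,
        )


def layout_from_words(
    words: Sequence[str],
    critical_region: int,
    char_width: float = 11.0,
    space_width: float = 11.0,
    left_margin: float = 40.0,
    top: float = 380.0,
    bottom: float = 420.0,
) -> RegionLayout:
    """Monospaced single-line layout helper."""
    boxes = []
    x = left_margin
    for w in words:
        boxes.append((x, x + char_width * len(w)))
        x = boxes[-1][1] + space_width
    return RegionLayout(
        words=tuple(words),
        boxes=tuple(boxes),
        top=top,
        bottom=bottom,
        critical_region=critical_region,
    )


def assign_fixation(fix: Fixation, layout: RegionLayout) -> int | None:
    """Word index for one fixation, or None if it is discarded."""
    if not (layout.top - VERTICAL_SLACK_PX <= fix.y <= layout.bottom + VERTICAL_SLACK_PX):
        return None
    for k, (left, right) in enumerate(layout.boxes):
        if left <= fix.x < right:
            return k
    # blank spaces between consecutive words: split at the midpoint
    for k in range(len(layout.boxes) - 1):
        gap_l = layout.boxes[k][1]
        gap_r = layout.boxes[k + 1][0]
        if gap_l <= fix.x < gap_r:
            mid = (gap_l + gap_r) / 2
            return k if fix.x < mid else k + 1
    return None


def assign_fixations(
    fixations: Iterable[Fixation], layout: RegionLayout
) -> list[tuple[Fixation, int]]:
    """Assign a trial's fixations to words, dropping unassignable ones."""
    out = []
    for f in fixations:
        k = assign_fixation(f, layout)
        if k is not None:
            out.append((f, k))
    return out


@dataclass(frozen=True)
class TrialMeasures:
    """Reading measures for one region of one trial.

    Duration measures are NaN when undefined (region never fixated, or no
    first pass); probabilities are 0/1, with FPRP NaN when there was no
    first pass to regress from.
    """

    FFD: float
    FPRT: float
    RRT: float
    TRT: float
    FPRP: float
    RRP: float


def compute_measures(
    assigned: Sequence[tuple[Fixation, int]], region: int
) -> TrialMeasures:
    """Standard reading measures for one region from assigned fixations.

    The first pass is the run of consecutive fixations in the region
    beginning at its first fixation, provided no word to the right of the
    region was fixated earlier (otherwise the region was skipped during
    first pass and only re-reading measures apply).  The pass ends at the
    first fixation outside the region; a first-pass regression is an exit
    landing on an earlier word.
    """
    words = [k for _, k in assigned]
    durs = [f.duration for f, _ in assigned]
    in_region = [k == region for k in words]
    if not any(in_region):
        return TrialMeasures(
            FFD=np.nan, FPRT=np.nan, RRT=np.nan, TRT=np.nan, FPRP=np.nan, RRP=0.0
        )
    first = in_region.index(True)
    skipped = any(k > region for k in words[:first])
    if skipped:
        rrt = float(sum(d for d, r in zip(durs, in_region) if r))
        return TrialMeasures(
            FFD=np.nan, FPRT=np.nan, RRT=rrt, TRT=rrt, FPRP=np.nan, RRP=1.0
        )
    end = first
    while end < len(words) and words[end] == region:
        end += 1
    fprt = float(sum(durs[first:end]))
    ffd = float(durs[first])
    if end < len(words):
        fprp = 1.0 if words[end] < region else 0.0
    else:
        fprp = 0.0  # trial ended inside the region: no exit saccade
    rrt = float(sum(d for d, k in zip(durs[end:], words[end:]) if k == region))
    return TrialMeasures(
        FFD=ffd,
        FPRT=fprt,
        RRT=rrt,
        TRT=fprt + rrt,
        FPRP=fprp,
        RRP=1.0 if rrt > 0 else 0.0,
    )


def cumulative_progression(
    fixations: Sequence[Fixation],
    layout: RegionLayout,
    region: int | None = None,
    window_ms: float = PROGRESSION_WINDOW_MS,
    dt_ms: float = PROGRESSION_DT_MS,
) -> np.ndarray | None:
    """Forward-only pixel distance from the first fixation in the region.

    Sampled every ``dt_ms`` for ``window_ms`` after the onset of the first
    fixation in the region (501 samples at the defaults).  At each
    timestamp the value is the largest rightward displacement reached by
    any fixation that has started by then; leftward movement and staying
    put leave it unchanged.  Between a fixation's end and the next
    fixation's onset the previous value is carried forward.  Returns None
    if the region is never fixated.
    """
    region = layout.critical_region if region is None else region
    assigned = assign_fixations(fixations, layout)
    entry = next((f for f, k in assigned if k == region), None)
    if entry is None:
        return None
    grid = np.arange(0.0, window_ms + dt_ms / 2, dt_ms)
    curve = np.zeros_like(grid)
    # distance ignores word boundaries: every subsequent eye position counts,
    # whether or not it is assignable to a word
    for f in fixations:
        if f.onset < entry.onset:
            continue
        dist = max(0.0, f.x - entry.x)
        t_rel = f.onset - entry.onset
        mask = grid >= t_rel
        curve[mask] = np.maximum(curve[mask], dist)
    return curve


def progression_difference(
    curves_by_condition: dict[str, Sequence[np.ndarray]],
) -> pd.DataFrame:
    """Per-timestamp effect curves with a pooled 95% band.

    For each of the three effects the condition curves are first averaged
    within condition (pooling participants and items) and the averages are
    then differenced:

        mismatch             mean(a, b) - mean(c, d)
        match-interference   a - b
        mismatch-interference c - d

    The returned frame has columns effect, timestamp_ms, difference_px,
    ci_low, ci_high.  The band pools all trials of a condition, so it
    understates between-participant and between-item variance and is
    exploratory only.
    """
    stats = {}
    for cond, curves in curves_by_condition.items():
        arr = np.asarray(list(curves), dtype=float)
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ValueError(f"condition {cond!r} has no curves")
        stats[cond] = (
            arr.mean(axis=0),
            arr.var(axis=0, ddof=1) / arr.shape[0] if arr.shape[0] > 1 else np.zeros(arr.shape[1]),
        )
    missing = {"a", "b", "c", "d"} - set(stats)
    if missing:
        raise ValueError(f"missing condition(s): {sorted(missing)}")

    n_samples = len(next(iter(stats.values()))[0])
    t = np.arange(n_samples) * PROGRESSION_DT_MS
    effects = {
        "mismatch": (("a", "b"), ("c", "d")),
        "match-interference": (("a",), ("b",)),
        "mismatch-interference": (("c",), ("d",)),
    }
    rows = []
    for name, (plus, minus) in effects.items():
        mean_plus = np.mean([stats[c][0] for c in plus], axis=0)
        mean_minus = np.mean([stats[c][0] for c in minus], axis=0)
        var = np.sum([stats[c][1] for c in plus], axis=0) / len(plus) ** 2
        var = var + np.sum([stats[c][1] for c in minus], axis=0) / len(minus) ** 2
        diff = mean_plus - mean_minus
        half = 1.96 * np.sqrt(var)
        rows.append(
            pd.DataFrame(
                {
                    "effect": name,
                    "timestamp_ms": t,
                    "difference_px": diff,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def nested_contrast_matrix() -> pd.DataFrame:
    """Nested contrast coding of the 2x2 design (conditions a-d).

    Three centred contrasts, with the interference contrasts nested within
    the match/mismatch pairs and signed so that a positive coefficient is
    the model-predicted direction (the model predicts the
    mismatch-interference condition to be *faster* than mismatch, hence
    c = -1/2, d = +1/2 there).
    """
    m = pd.DataFrame(
        {
            "mismatch": [-0.5, -0.5, 0.5, 0.5],
            "match_interference": [0.5, -0.5, 0.0, 0.0],
            "mismatch_interference": [0.0, 0.0, -0.5, 0.5],
        },
        index=pd.Index(["a", "b", "c", "d"], name="condition"),
    )
    return m


def measures_table(
    trials: dict[int, Sequence[tuple[Fixation, int]]],
    region: int,
    conditions: dict[int, str] | None = None,
) -> pd.DataFrame:
    """One row of measures per trial, optionally with condition labels."""
    rows = []
    for trial_id, assigned in trials.items():
        m = compute_measures(assigned, region)
        row = {"trial": trial_id, **vars(m)}
        if conditions is not None:
            row["condition"] = conditions[trial_id]
        rows.append(row)
    return pd.DataFrame(rows)


def model_ready_table(
    measures: pd.DataFrame, measure: str = "FPRT", log_transform: bool = True
) -> pd.DataFrame:
    """Attach nested contrasts to a measures table for mixed-model fitting.

    Keeps trials with a defined value of ``measure``; reading times are log
    transformed by default.  The fitting itself is left to the user's
    statistics package of choice.
    """
    if "condition" not in measures.columns:
        raise ValueError("measures table needs a 'condition' column")
    cm = nested_contrast_matrix()
    out = measures.dropna(subset=[measure]).copy()
    if log_transform:
        if (out[measure] <= 0).any():
            raise ValueError("log transform needs strictly positive values")
        out[f"log_{measure}"] = np.log(out[measure])
    for contrast in cm.columns:
        out[contrast] = out["condition"].map(cm[contrast]).astype(float)
    return out
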
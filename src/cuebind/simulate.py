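"""Monte-Carlo engine: per-condition summaries, effects E1-E5, sweeps.

The simulator runs many independent retrievals per condition and reports
the percentage of runs on which the grammatically inaccessible antecedent
won the race (the retrieval-error rate) together with the mean and SD of
retrieval time over successful runs.  Five derived effects summarise the
2x2 design:

    E1  mismatch effect on retrieval errors      mean RE(c,d) - mean RE(a,b)
    E2  interference effect on retrieval errors  mean RE(a,c) - mean RE(b,d)
    E3  mismatch effect on retrieval time        mean RT(c,d) - mean RT(a,b)
    E4  match-interference effect on time        RT(a) - RT(b)
    E5  mismatch-interference effect on time     RT(c) - RT(d)

The model's predicted pattern is E1..E4 > 0 and E5 < 0.  A parameter sweep
re-runs the four conditions over a grid of (noise, maximum associative
strength, maximum difference) values.

Randomness policy: every (design, condition, sweep-cell) gets its own
deterministic substream derived from the user seed, so results are
reproducible and independent of evaluation order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import CONDITIONS, DESIGNS, encode_condition
from .memory import (
    CueSet,
    base_level_activation,
    mismatch_penalty_sum,
    spreading_activation_sum,
)
from .params import ModelParams

_DESIGN_INDEX = {name: i for i, name in enumerate(DESIGNS)}
_COND_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

EFFECT_NAMES = ("E1", "E2", "E3", "E4", "E5")


@dataclass(frozen=True)
class ConditionSummary:
    """Monte-Carlo outcome for one design x condition cell."""

    design: str
    condition: str
    n_runs: int
    error_pct: float  # % of successful runs retrieving the inaccessible NP
    mean_latency: float  # ms, over successful runs
    sd_latency: float  # ms
    failure_count: int


@dataclass(frozen=True)
class EffectsTable:
    """The five predicted effects of one design/parameterisation."""

    E1: float  # percentage points
    E2: float  # percentage points
    E3: float  # ms
    E4: float  # ms
    E5: float  # ms

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in EFFECT_NAMES}


def _condition_rng(seed: int, design: str, condition: str, cell: int = 0):
    return np.random.default_rng(
        [int(seed), _DESIGN_INDEX[design], _COND_INDEX[condition], int(cell)]
    )


def _deterministic_activations(
    chunks, cue_set: CueSet, params: ModelParams
) -> np.ndarray:
    return np.array(
        [
            base_level_activation(c, params)
            + spreading_activation_sum(c, cue_set, chunks, params)
            + mismatch_penalty_sum(c, cue_set, params)
            for c in chunks
        ]
    )


def simulate_condition(
    design: str,
    condition: str,
    params: ModelParams,
    n_runs: int = 1000,
    seed: int = 0,
    structural_only: bool = False,
    multi_mention: bool = False,
    extra_nps: int = 0,
    _cell: int = 0,
) -> ConditionSummary:
    """Run ``n_runs`` independent retrievals for one condition.

    Vectorised over runs: noise is the only stochastic component, so the
    deterministic activation vector is computed once and ``n_runs`` logistic
    noise matrices decide winners and latencies.  Failures (no candidate at
    threshold) are counted separately and excluded from latency statistics.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    chunks, cue_set = encode_condition(
        design,
        condition,
        params,
        structural_only=structural_only,
        multi_mention=multi_mention,
        extra_nps=extra_nps,
    )
    a0 = _deterministic_activations(chunks, cue_set, params)
    if params.noise_scale_s > 0:
        rng = _condition_rng(seed, design, condition, _cell)
        acts = a0[None, :] + rng.logistic(
            0.0, params.noise_scale_s, size=(n_runs, len(chunks))
        )
    else:
        acts = np.broadcast_to(a0, (n_runs, len(chunks)))
    winner = np.argmax(acts, axis=1)
    winner_act = acts[np.arange(n_runs), winner]
    success = winner_act >= params.retrieval_threshold_tau
    n_fail = int(np.sum(~success))
    lat_s = (
        params.latency_factor_F * np.exp(-winner_act[success]) + params.fixed_cost
    )
    inaccessible = winner[success] == 1  # chunk order: accessible, inaccessible
    n_ok = int(success.sum())
    return ConditionSummary(
        design=design,
        condition=condition,
        n_runs=n_runs,
        error_pct=100.0 * float(inaccessible.sum()) / n_runs,
        mean_latency=1000.0 * float(lat_s.mean()) if n_ok else float("nan"),
        sd_latency=1000.0 * float(lat_s.std(ddof=0)) if n_ok else float("nan"),
        failure_count=n_fail,
    )


def simulate_design(
    design: str,
    params: ModelParams,
    n_runs: int = 1000,
    seed: int = 0,
    **kwargs,
) -> dict[str, ConditionSummary]:
    """Summaries for all four conditions of a design."""
    return {
        c: simulate_condition(design, c, params, n_runs, seed, **kwargs)
        for c in CONDITIONS
    }


def compute_effects(summaries: dict[str, ConditionSummary]) -> EffectsTable:
    """Derive E1-E5 from the four condition summaries of one design."""
    missing = set(CONDITIONS) - set(summaries)
    if missing:
        raise KeyError(f"missing condition(s): {sorted(missing)}")
    re = {c: summaries[c].error_pct for c in CONDITIONS}
    rt = {c: summaries[c].mean_latency for c in CONDITIONS}
    return EffectsTable(
        E1=(re["c"] + re["d"]) / 2 - (re["a"] + re["b"]) / 2,
        E2=(re["a"] + re["c"]) / 2 - (re["b"] + re["d"]) / 2,
        E3=(rt["c"] + rt["d"]) / 2 - (rt["a"] + rt["b"]) / 2,
        E4=rt["a"] - rt["b"],
        E5=rt["c"] - rt["d"],
    )


@dataclass(frozen=True)
class SweepGrid:
    """Grid of (noise, S, max_difference) values for the parameter sweep.

    Defaults cover noise 0.05-0.4 in steps of 0.05, maximum associative
    strength 1-4 in steps of 0.25, and maximum difference -1 to 0 in steps
    of 0.1 (8 x 13 x 11 = 1144 cells); ``include_zero_noise`` prepends a
    noise-0 level (9 x 13 x 11 = 1287 cells).
    """

    noise: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.05, 0.401, 0.05), 10))
    )
    max_assoc_strength: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(1.0, 4.001, 0.25), 10))
    )
    max_difference: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(-1.0, 0.001, 0.1), 10))
    )

    @classmethod
    def table_default(cls, include_zero_noise: bool = False) -> "SweepGrid":
        grid = cls()
        if include_zero_noise:
            grid = cls(noise=(0.0,) + grid.noise)
        return grid

    @classmethod
    def from_dict(cls, d: dict) -> "SweepGrid":
        def axis(spec):
            if isinstance(spec, (list, tuple)):
                return tuple(float(x) for x in spec)
            vals = np.arange(
                spec["min"], spec["max"] + spec["step"] / 2, spec["step"]
            )
            return tuple(np.round(vals, 10))

        return cls(
            noise=axis(d["noise"]),
            max_assoc_strength=axis(d["max_assoc_strength"]),
            max_difference=axis(d["max_difference"]),
        )

    @property
    def n_cells(self) -> int:
        return (
            len(self.noise) * len(self.max_assoc_strength) * len(self.max_difference)
        )

    def cells(self):
        return itertools.product(
            self.noise, self.max_assoc_strength, self.max_difference
        )


def run_sweep(
    design: str,
    grid: SweepGrid,
    params: ModelParams | None = None,
    n_runs: int = 1000,
    seed: int = 0,
    structural_only: bool = False,
) -> pd.DataFrame:
    """One EffectsTable per grid cell, as a long-format DataFrame.

    Columns: noise, max_assoc_strength, max_difference, E1..E5.  Each cell
    uses a cell-indexed substream of the seed, so sweeps over different
    grids agree on shared cells only in distribution, but re-running the
    same grid is bit-identical and order-independent.
    """
    base = params or ModelParams()
    rows = []
    for cell_idx, (s, S, md) in enumerate(grid.cells()):
        p = base.replace(
            noise_scale_s=s, max_assoc_strength_S=S, max_difference=md
        )
        summaries = {
            c: simulate_condition(
                design,
                c,
                p,
                n_runs,
                seed,
                structural_only=structural_only,
                _cell=cell_idx,
            )
            for c in CONDITIONS
        }
        eff = compute_effects(summaries)
        rows.append(
            {
                "noise": s,
                "max_assoc_strength": S,
                "max_difference": md,
                **eff.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def marginal_effect(sweep: pd.DataFrame, effect: str, parameter: str) -> pd.Series:
    """Mean of one effect at each level of one parameter (a sweep curve)."""
    return sweep.groupby(parameter)[effect].mean()


def compare_designs(
    designs: list[str],
    grid: SweepGrid,
    params: ModelParams | None = None,
    n_runs: int = 1000,
    seed: int = 0,
    structural_only: bool = False,
) -> pd.DataFrame:
    """Aligned sweep tables for several designs, plus per-cell deltas.

    Returns the concatenated long-format sweeps with a ``design`` column;
    deltas between designs are a groupby away and the helper
    :func:`effect_deltas` computes them for a pair.
    """
    frames = []
    for d in designs:
        f = run_sweep(d, grid, params, n_runs, seed, structural_only)
        f.insert(0, "design", d)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def effect_deltas(
    comparison: pd.DataFrame, design_a: str, design_b: str
) -> pd.DataFrame:
    """Per-cell effect differences ``design_a - design_b``."""
    keys = ["noise", "max_assoc_strength", "max_difference"]
    a = comparison[comparison["design"] == design_a].set_index(keys)
    b = comparison[comparison["design"] == design_b].set_index(keys)
    return (a[list(EFFECT_NAMES)] - b[list(EFFECT_NAMES)]).reset_index()


def summaries_frame(summaries: dict[str, ConditionSummary]) -> pd.DataFrame:
    """Condition summaries as a tidy DataFrame (one row per condition)."""
    return pd.DataFrame([vars(s) for s in summaries.values()])
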
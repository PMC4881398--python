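"""Activation calculus: formulas, invariants, and a brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuebind import (
    FAILURE,
    Chunk,
    CueSet,
    InvalidTimelineError,
    ModelParams,
    base_level_activation,
    fan_of_cue,
    mismatch_penalty_sum,
    retrieval_latency,
    retrieve_once,
    spreading_activation_sum,
    strength_of_association,
    total_activation,
)


def chunk(id="x", times=(1.0,), **features):
    base = {"gender": "masc", "category": "noun", "role": "subject",
            "clause": "current"}
    base.update(features)
    return Chunk(id=id, features=base, creation_times=tuple(times))


SURGEON = chunk("surgeon", (0.9,))
PRONOUN = chunk("pronoun", (2.1,), clause="other")
FOUR_CUES = {"gender": "masc", "category": "noun", "role": "subject",
             "clause": "current"}


class TestBaseLevel:
    @pytest.mark.parametrize(
        "times, d, expected",
        [
            ((1.0,), 0.5, 0.0),
            ((4.0,), 0.5, -math.log(2)),
            ((1.0, 1.0), 0.5, math.log(2)),
            ((2.0, 8.0), 1.0, math.log(0.5 + 0.125)),
        ],
    )
    def test_power_law_sum(self, times, d, expected):
        p = ModelParams(decay_d=d)
        assert base_level_activation(chunk(times=times), p) == pytest.approx(expected)

    def test_rejects_nonpositive_age(self, params):
        with pytest.raises(InvalidTimelineError):
            base_level_activation(chunk(times=(1.0, 0.0)), params)

    @given(age=st.floats(0.01, 1e4), older=st.floats(1.001, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_recency_monotonic(self, age, older):
        p = ModelParams()
        assert base_level_activation(chunk(times=(age,)), p) > base_level_activation(
            chunk(times=(age * older,)), p
        )

    def test_extra_mention_raises_activation(self, params):
        one = base_level_activation(chunk(times=(2.0,)), params)
        two = base_level_activation(chunk(times=(5.0, 2.0)), params)
        assert two > one


class TestAssociativeStrength:
    def test_fan_counts_matching_chunks(self):
        chunks = [SURGEON, PRONOUN]
        assert fan_of_cue(("category", "noun"), chunks) == 2
        assert fan_of_cue(("gender", "fem"), chunks) == 0
        assert fan_of_cue(("clause", "current"), chunks) == 1

    @pytest.mark.parametrize(
        "S, fan, expected",
        [(1.5, 1, 1.5), (1.5, 2, 1.5 - math.log(2)), (1.0, 3, 1.0 - math.log(3))],
    )
    def test_fan_discounts_strength(self, S, fan, expected):
        p = ModelParams(max_assoc_strength_S=S)
        chunks = [chunk(f"c{i}") for i in range(fan)]
        got = strength_of_association(("gender", "masc"), chunks, p)
        assert got == pytest.approx(expected)

    def test_unmatched_cue_has_zero_strength(self, params):
        assert strength_of_association(("gender", "fem"), [SURGEON], params) == 0.0

    def test_strictly_decreasing_in_fan(self, params):
        strengths = [
            strength_of_association(
                ("category", "noun"), [chunk(f"c{i}") for i in range(n)], params
            )
            for n in range(1, 8)
        ]
        assert all(a > b for a, b in zip(strengths, strengths[1:]))


class TestSpreadingAndPenalty:
    def test_full_match_all_fans_one(self):
        p = ModelParams(total_source_W=1.0, max_assoc_strength_S=1.5)
        cues = CueSet.from_cues(FOUR_CUES, p.total_source_W)
        got = spreading_activation_sum(SURGEON, cues, [SURGEON], p)
        assert got == pytest.approx(4 * 0.25 * 1.5)

    def test_shared_gender_cue_dilutes_boost(self):
        # a second gender-matching chunk halves that cue's strength share
        p = ModelParams(total_source_W=1.0, max_assoc_strength_S=1.5)
        cues = CueSet.from_cues(FOUR_CUES, p.total_source_W)
        other = chunk("distractor", (2.0,), category="verb", role="object",
                      clause="other")
        got = spreading_activation_sum(SURGEON, cues, [SURGEON, other], p)
        assert got == pytest.approx(3 * 0.25 * 1.5 + 0.25 * (1.5 - math.log(2)))

    def test_no_match_no_spreading(self, params):
        cues = CueSet.from_cues(FOUR_CUES, params.total_source_W)
        alien = chunk("alien", (1.0,), gender="fem", category="verb",
                      role="object", clause="other")
        assert spreading_activation_sum(alien, cues, [alien], params) == 0.0

    @pytest.mark.parametrize(
        "features, expected_mismatches",
        [({}, 0), ({"gender": "fem"}, 1), ({"gender": "fem", "clause": "other"}, 2)],
    )
    def test_penalty_counts_mismatched_cues(self, features, expected_mismatches):
        p = ModelParams(match_scale_P=1.0, max_difference=-1.0)
        cues = CueSet.from_cues(FOUR_CUES, p.total_source_W)
        got = mismatch_penalty_sum(chunk(**features), cues, p)
        assert got == pytest.approx(-1.0 * expected_mismatches)
        assert got <= 0


class TestTotalActivation:
    def test_breakdown_is_additive(self, params):
        cues = CueSet.from_cues(FOUR_CUES, params.total_source_W)
        b = total_activation(PRONOUN, cues, [SURGEON, PRONOUN], params, 0.37)
        assert b.total == pytest.approx(b.base + b.spreading + b.penalty + b.noise,
                                        abs=1e-12)
        assert b.noise == 0.37

    def test_hand_computed_sum(self):
        # B = -ln 2, spreading with one diluted cue, one mismatch penalty
        p = ModelParams(total_source_W=1.0, max_assoc_strength_S=1.5,
                        match_scale_P=1.0, max_difference=-1.0)
        target = chunk("t", (4.0,), clause="other")
        other = chunk("o", (1.0,), gender="fem", category="verb",
                      role="object", clause="current")
        cues = CueSet.from_cues(FOUR_CUES, p.total_source_W)
        b = total_activation(target, cues, [target, other], p, 0.0)
        assert b.base == pytest.approx(-math.log(2))
        assert b.spreading == pytest.approx(3 * 0.25 * 1.5)
        assert b.penalty == pytest.approx(-1.0)
        assert b.total == pytest.approx(-math.log(2) + 1.125 - 1.0)


class TestRetrieveOnce:
    def test_winner_and_latency(self):
        p = ModelParams(noise_scale_s=0.0, latency_factor_F=0.14,
                        retrieval_threshold_tau=-1.5, total_source_W=0.5,
                        max_assoc_strength_S=1.0, match_scale_P=0.7,
                        max_difference=-1.0)
        strong = chunk("strong", (1.0,))
        weak = chunk("weak", (1.0,), gender="fem", clause="other")
        cues = CueSet.from_cues(FOUR_CUES, p.total_source_W)
        out = retrieve_once([strong, weak], cues, p)
        assert out.winner_id == "strong"
        assert out.latency == pytest.approx(
            0.14 * math.exp(-out.breakdowns["strong"].total)
        )

    def test_failure_below_threshold(self):
        p = ModelParams(noise_scale_s=0.0, retrieval_threshold_tau=5.0,
                        latency_factor_F=0.14)
        cues = CueSet.from_cues(FOUR_CUES, p.total_source_W)
        out = retrieve_once([SURGEON, PRONOUN], cues, p)
        assert out.winner_id == FAILURE
        assert out.failed
        assert out.latency == pytest.approx(0.14 * math.exp(-5.0))

    def test_empty_candidate_set_rejected(self, quiet_params):
        cues = CueSet.from_cues(FOUR_CUES, quiet_params.total_source_W)
        with pytest.raises(ValueError):
            retrieve_once([], cues, quiet_params)

    def test_noise_free_is_deterministic(self, quiet_params):
        cues = CueSet.from_cues(FOUR_CUES, quiet_params.total_source_W)
        outs = [retrieve_once([SURGEON, PRONOUN], cues, quiet_params)
                for _ in range(5)]
        assert len({o.winner_id for o in outs}) == 1
        assert len({o.latency for o in outs}) == 1

    def test_latency_decreases_with_activation(self, params):
        lats = [retrieval_latency(a, params) for a in np.linspace(-2, 3, 20)]
        assert all(a > b for a, b in zip(lats, lats[1:]))

    @given(
        data=st.data(),
        n_chunks=st.integers(1, 3),
        n_cues=st.integers(1, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_activation_table(self, data, n_chunks, n_cues):
        """Noise-free winner/latency agree with a from-scratch recomputation."""
        features = ["gender", "category", "role", "clause"]
        values = {"gender": ["masc", "fem"], "category": ["noun", "verb"],
                  "role": ["subject", "object"], "clause": ["current", "other"]}
        p = ModelParams(noise_scale_s=0.0)
        chunks = []
        for i in range(n_chunks):
            feats = {f: data.draw(st.sampled_from(values[f]), label=f"{i}.{f}")
                     for f in features}
            times = tuple(
                data.draw(st.floats(0.1, 30.0), label=f"{i}.t{j}")
                for j in range(data.draw(st.integers(1, 2), label=f"{i}.nt"))
            )
            chunks.append(Chunk(id=f"c{i}", features=feats, creation_times=times))
        cue_feats = features[:n_cues]
        cues = CueSet.from_cues(
            {f: data.draw(st.sampled_from(values[f]), label=f"cue.{f}")
             for f in cue_feats},
            p.total_source_W,
        )
        out = retrieve_once(chunks, cues, p)

        # independent oracle: plain-python activation table
        wj = p.total_source_W / n_cues
        table = {}
        for c in chunks:
            a = math.log(sum(t ** -p.decay_d for t in c.creation_times))
            for f, v in cues.cues.items():
                fan = sum(1 for cc in chunks if cc.features[f] == v)
                if c.features[f] == v:
                    a += wj * (p.max_assoc_strength_S - math.log(fan))
                else:
                    a += p.match_scale_P * p.max_difference
            table[c.id] = a
        best = max(table, key=table.get)
        if table[best] >= p.retrieval_threshold_tau:
            assert out.winner_id == best
            assert out.latency == pytest.approx(
                p.latency_factor_F * math.exp(-table[best])
            )
        else:
            assert out.winner_id == FAILURE


class TestParams:
    def test_config_round_trip(self, tmp_path, params):
        path = tmp_path / "params.json"
        tweaked = params.replace(noise_scale_s=0.3, max_difference=-0.5)
        tweaked.save(path)
        assert ModelParams.load(path) == tweaked

    @pytest.mark.parametrize(
        "bad",
        [
            {"decay_d": 0.0},
            {"max_difference": 0.2},
            {"noise_scale_s": -0.1},
            {"latency_factor_F": 0.0},
            {"per_word_time": -1.0},
        ],
    )
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            ModelParams.from_dict({"decay": 0.5})

    def test_cue_weights_sum_to_source_activation(self, params):
        cues = CueSet.from_cues(FOUR_CUES, params.total_source_W)
        assert sum(cues.weights.values()) == pytest.approx(params.total_source_W)
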
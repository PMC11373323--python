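"""P(¬C) aggregation, thresholds, and local odds ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nerblock.blocklists import (
    NameDocScore,
    NameGlobalScore,
    RatioInputs,
    ScoredMatch,
    ThresholdConfig,
    aggregate_doc,
    aggregate_global,
    build_blocklists,
    local_ratio,
    make_global_blocklist,
    make_local_lists,
    score_not_class,
)
from nerblock.consensus import LABELS
from nerblock.tagger import Match

UNIFORM = {lbl: 0.2 for lbl in LABELS}


def _scored(p_not, name="NAME", doc="d1", etype="ggp"):
    probs = {lbl: (1 - p_not) if lbl == etype else p_not / 4 for lbl in LABELS}
    m = Match(doc, 0, len(name), name, etype, frozenset({1}))
    return ScoredMatch(match=m, probs=probs)


class TestScoreNotClass:
    def test_certain(self):
        assert score_not_class({**{l: 0.0 for l in LABELS}, "ggp": 1.0}, "ggp") == 0.0

    def test_impossible(self):
        probs = {l: 0.25 for l in LABELS}
        probs["ggp"] = 0.0
        assert score_not_class(probs, "ggp") == 1.0

    def test_uniform(self):
        assert score_not_class(UNIFORM, "ggp") == pytest.approx(0.8)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            score_not_class(UNIFORM, "tissue")

    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_in_unit_interval_whenever_probs_normalized(self, raw):
        total = sum(raw)
        if total == 0:
            return
        probs = {l: v / total for l, v in zip(LABELS, raw)}
        p = score_not_class(probs, "dis")
        assert -1e-9 <= p <= 1 + 1e-9


class TestAggregateDoc:
    def test_mean(self):
        out = aggregate_doc([_scored(0.2), _scored(0.4)])
        assert out.p_not_class_doc == pytest.approx(0.3)
        assert out.mention_count == 2

    def test_single_identity(self):
        assert aggregate_doc([_scored(0.7)]).p_not_class_doc == pytest.approx(0.7)

    def test_permutation_invariant(self):
        group = [_scored(p) for p in (0.1, 0.5, 0.9)]
        assert aggregate_doc(group) == aggregate_doc(group[::-1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_doc([])

    def test_mixed_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_doc([_scored(0.2, doc="d1"), _scored(0.2, doc="d2")])


class TestAggregateGlobal:
    def _doc_score(self, p, doc):
        return NameDocScore("NAME", doc, "ggp", p, mention_count=1)

    def test_documents_weigh_equally(self):
        a = NameDocScore("NAME", "d1", "ggp", 0.0, mention_count=1)
        b = NameDocScore("NAME", "d2", "ggp", 1.0, mention_count=100)
        out = aggregate_global([a, b])
        assert out.p_not_class_global == pytest.approx(0.5)
        assert out.doc_count == 2

    def test_single_doc(self):
        out = aggregate_global([self._doc_score(0.42, "d1")])
        assert out.p_not_class_global == pytest.approx(0.42)
        assert out.doc_count == 1

    def test_equals_brute_force_mean_and_bounds(self):
        rng = np.random.default_rng(11)
        scores = rng.random(10)
        group = [self._doc_score(p, f"d{i}") for i, p in enumerate(scores)]
        out = aggregate_global(group)
        assert out.p_not_class_global == pytest.approx(float(np.mean(scores)))
        assert min(scores) <= out.p_not_class_global <= max(scores)
        permuted = [group[i] for i in rng.permutation(10)]
        assert aggregate_global(permuted) == out

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_global([])


class TestGlobalBlocklist:
    def _global(self, name, etype, score, docs):
        return NameGlobalScore(name, etype, score, docs)

    def test_threshold_and_class_specific(self):
        scores = [
            self._global("hit", "ggp", 0.6, 2),
            self._global("miss-dis", "dis", 0.6, 5),
            self._global("hit-dis", "dis", 0.9, 5),
        ]
        blocked = {e.name for e in make_global_blocklist(scores)}
        assert blocked == {"hit", "hit-dis"}

    def test_two_document_rule(self):
        scores = [self._global("once", "ggp", 0.99, 1)]
        assert make_global_blocklist(scores) == []

    def test_sorted_by_descending_score(self):
        scores = [
            self._global("b", "ggp", 0.7, 2),
            self._global("a", "ggp", 0.9, 2),
            self._global("c", "ggp", 0.9, 2),
        ]
        assert [e.name for e in make_global_blocklist(scores)] == ["a", "c", "b"]

    def test_raising_threshold_never_grows_list(self):
        rng = np.random.default_rng(5)
        scores = [
            self._global(f"n{i}", "ggp", float(rng.random()), 2) for i in range(50)
        ]
        sizes = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            cfg = ThresholdConfig(
                global_block_threshold={"ggp": thr, "che": 0.5, "org": 0.5, "dis": 0.85}
            )
            sizes.append(len(make_global_blocklist(scores, cfg)))
        assert sizes == sorted(sizes, reverse=True)


class TestLocalRatio:
    def test_symmetry_at_half(self):
        inputs = RatioInputs(0.5, 0.5)
        assert local_ratio(inputs, "allow") == pytest.approx(1.0)
        assert local_ratio(inputs, "block") == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        r = local_ratio(RatioInputs(0.9, 0.99), "allow")
        assert r == pytest.approx((0.9 * 0.99) / (0.1 * 0.01), rel=1e-9)
        assert r == pytest.approx(891.0, rel=1e-9)

    def test_limit_to_infinity(self):
        r = local_ratio(RatioInputs(1.0, 1.0), "allow")
        assert r > 1e20  # clipped at the floor, finite but enormous

    def test_directions_multiply_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            inputs = RatioInputs(float(rng.random()), float(rng.random()))
            prod = local_ratio(inputs, "allow") * local_ratio(inputs, "block")
            assert prod == pytest.approx(1.0, rel=1e-9)

    @given(
        st.floats(0.01, 0.98),
        st.floats(0.01, 0.98),
        st.floats(0.001, 0.01),
    )
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing(self, pn, pl, eps):
        base = local_ratio(RatioInputs(pn, pl), "allow")
        assert local_ratio(RatioInputs(pn + eps, pl), "allow") > base
        assert local_ratio(RatioInputs(pn, pl + eps), "allow") > base

    def test_representable_beyond_1e15(self):
        r = local_ratio(RatioInputs(1 - 1e-9, 1 - 1e-9), "allow")
        assert math.isfinite(r) and r > 1e15

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            local_ratio(RatioInputs(0.5, 0.5), "maybe")


class TestMakeLocalLists:
    def _scenario(self, etype, p_global_not, p_doc_not, on_auto_list=False):
        doc_scores = [NameDocScore("w", "docX", etype, p_doc_not, 3)]
        global_scores = [NameGlobalScore("w", etype, p_global_not, 10)]
        blocklist = (
            [make_global_blocklist(global_scores)[0]]
            if on_auto_list and make_global_blocklist(global_scores)
            else []
        )
        return make_local_lists(doc_scores, global_scores, blocklist)

    def test_local_block_for_ggp(self):
        # globally fine (P(!C|N)=0.3) but locally hopeless: block ratio
        # = (0.3*0.999)/(0.7*0.001) = 428 < 1000; push local harder
        entries = self._scenario("ggp", 0.3, 0.9999)
        assert [e.action for e in entries] == ["block"]
        assert entries[0].scope == "docX"

    def test_disease_not_eligible_for_local_block(self):
        assert self._scenario("dis", 0.3, 0.9999) == []

    def test_local_allow_overrides_global_block(self):
        # globally blocked ggp name, near-certain local evidence for C
        entries = self._scenario("ggp", 0.55, 0.0, on_auto_list=True)
        allows = [e for e in entries if e.action == "allow"]
        assert len(allows) == 1 and allows[0].scope == "docX"

    def test_allow_requires_membership_on_auto_global_list(self):
        entries = self._scenario("ggp", 0.55, 0.0, on_auto_list=False)
        assert all(e.action != "allow" for e in entries)

    def test_chemical_block_eligible_but_not_allow(self):
        blocked = self._scenario("che", 0.3, 0.9999)
        assert [e.action for e in blocked] == ["block"]
        allows = self._scenario("che", 0.55, 0.0, on_auto_list=True)
        assert all(e.action != "allow" for e in allows)


def test_build_blocklists_groups_by_name_class_and_doc():
    scored = [
        _scored(0.9, name="bad", doc="d1"),
        _scored(0.7, name="bad", doc="d1"),
        _scored(0.8, name="bad", doc="d2"),
        _scored(0.1, name="good", doc="d1"),
        _scored(0.1, name="good", doc="d2"),
    ]
    global_list, _ = build_blocklists(scored)
    assert [e.name for e in global_list] == ["bad"]
    # doc d1 mean (0.8), doc d2 (0.8) -> global 0.8
    assert global_list[0].score == pytest.approx(0.8)
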
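"""Consensus intersection, negative sampling, masking and assembly."""

import pytest

from nerblock.consensus import (
    CapacityError,
    AnnotationSet,
    Span,
    assemble_dataset,
    head_of_phrase,
    intersect_annotations,
    make_context,
    noun_phrase_candidates,
    sample_negatives,
)
from nerblock.tagger import Document


def _set(name, *spans):
    return AnnotationSet.from_spans(name, [Span(*s) for s in spans])


SPAN = ("d1", 5, 9, "TP53", "ggp")


class TestIntersectAnnotations:
    def test_full_agreement(self):
        sets = [_set(f"s{i}", SPAN) for i in range(3)]
        (c,) = intersect_annotations(sets)
        assert (c.doc_id, c.start, c.end, c.label) == ("d1", 5, 9, "ggp")

    def test_two_of_three_not_enough(self):
        sets = [_set("s0", SPAN), _set("s1", SPAN), _set("s2")]
        assert intersect_annotations(sets) == []

    def test_type_disagreement_not_enough(self):
        other = ("d1", 5, 9, "TP53", "che")
        sets = [_set("s0", SPAN), _set("s1", SPAN), _set("s2", other)]
        assert intersect_annotations(sets) == []

    def test_boundary_disagreement_not_enough(self):
        shifted = ("d1", 5, 10, "TP53 ", "ggp")
        sets = [_set("s0", SPAN), _set("s1", SPAN), _set("s2", shifted)]
        assert intersect_annotations(sets) == []

    def test_non_positive_types_ignored(self):
        other = ("d1", 20, 24, "cell", "other")
        sets = [_set(f"s{i}", SPAN, other) for i in range(3)]
        assert len(intersect_annotations(sets)) == 1

    @pytest.mark.parametrize("n", [0, 1, 2, 4])
    def test_exactly_three_sets_required(self, n):
        with pytest.raises(ValueError):
            intersect_annotations([_set(f"s{i}", SPAN) for i in range(n)])


class TestHeadOfPhrase:
    # hand-annotated heads for simple noun phrases; the contract is the
    # rightmost token before the first post-modifying preposition
    PHRASES = [
        (["the", "red", "protein"], "protein"),
        (["two", "samples"], "samples"),
        (["inhibitor", "of", "kinases"], "inhibitor"),
        (["activation", "of", "the", "pathway"], "activation"),
        (["genes", "in", "yeast"], "genes"),
        (["the", "cell", "membrane"], "membrane"),
        (["binding", "site", "for", "ATP"], "site"),
        (["Expression", "Levels"], "levels"),
        (["receptor", "on", "the", "surface"], "receptor"),
        (["it"], "it"),
        (["mutations,"], "mutations"),
        (["loss", "of", "function", "of", "p53"], "loss"),
    ]

    @pytest.mark.parametrize("tokens,head", PHRASES)
    def test_hand_annotated_phrases(self, tokens, head):
        assert head_of_phrase(tokens) == head

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            head_of_phrase([])


class TestSampleNegatives:
    def _candidates(self, doc):
        return noun_phrase_candidates(doc)

    def test_filtered_heads_removed(self):
        from nerblock.consensus import NegativeCandidate

        doc = Document("d1", "it binds the soluble cytokine and a marker")
        cands = [
            NegativeCandidate("d1", 0, 2, "it", "it"),  # pronoun head
            NegativeCandidate("d1", 13, 29, "soluble cytokine", "cytokine"),
            NegativeCandidate("d1", 36, 42, "marker", "marker"),
        ]
        kept = sample_negatives([doc], [_set(f"s{i}") for i in range(3)], cands)
        assert [c.head for c in kept] == ["marker"]

    def test_single_dissenting_tagger_bars_location(self):
        doc = Document("d1", "novel marker found")
        cands = self._candidates(doc)
        assert cands  # the chunker proposes something
        one_tagged = [
            _set("s0", ("d1", 6, 12, "marker", "ggp")),
            _set("s1"),
            _set("s2"),
        ]
        kept = sample_negatives([doc], one_tagged, cands)
        assert all(not (c.start < 12 and 6 < c.end) for c in kept)

    def test_other_type_overlap_tolerated(self):
        doc = Document("d1", "novel marker found")
        cands = self._candidates(doc)
        tagged_other = [
            _set(f"s{i}", ("d1", 6, 12, "marker", "other")) for i in range(3)
        ]
        kept = sample_negatives([doc], tagged_other, cands)
        assert any(c.start < 12 and 6 < c.end for c in kept)


class TestMakeContext:
    DOC = Document("d1", "alpha beta gamma delta epsilon")

    def test_focal_span_masked(self):
        ex = make_context(self.DOC, 11, 16, "ggp")
        assert ex.text == "alpha beta [MASK] delta epsilon"
        assert ex.surface == "gamma"

    def test_window_truncates(self):
        ex = make_context(self.DOC, 11, 16, "ggp", window=1)
        assert ex.text == "beta [MASK] delta"

    def test_window_stops_at_document_boundary(self):
        ex = make_context(Document("d", "a b c"), 2, 3, "che", window=100)
        assert ex.text == "a [MASK] c"

    def test_unmask_round_trip(self):
        for window in (1, 2, 100):
            ex = make_context(self.DOC, 11, 16, "ggp", window=window)
            lo = self.DOC.text.index(ex.text.split("[MASK]")[0]) if window < 2 else 0
            restored = ex.text.replace("[MASK]", ex.surface)
            assert restored in self.DOC.text

    def test_exactly_one_mask(self):
        ex = make_context(self.DOC, 0, 5, "dis")
        assert ex.text.count("[MASK]") == 1

    def test_word_counts_equal_window_when_possible(self):
        words = [f"w{i}" for i in range(300)]
        text = " ".join(words)
        start = text.index("w150")
        ex = make_context(Document("d", text), start, start + 4, "org", window=100)
        left, right = ex.text.split("[MASK]")
        assert len(left.split()) == 100
        assert len(right.split()) == 100

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_context(self.DOC, 10, 99, "ggp")

    def test_configurable_mask_token(self):
        ex = make_context(self.DOC, 11, 16, "ggp", mask="<X>")
        assert "<X>" in ex.text and "[MASK]" not in ex.text


class TestAssembleDataset:
    def _pools(self, n_per_class=50):
        docs, positives, negatives = [], [], []
        from nerblock.consensus import ConsensusSpan, NegativeCandidate

        for lbl in ("ggp", "che", "dis", "org"):
            for i in range(n_per_class):
                doc_id = f"{lbl}{i}"
                docs.append(Document(doc_id, f"ctx {lbl}tok{i} ctx"))
                positives.append(
                    ConsensusSpan(doc_id, 4, 4 + len(f"{lbl}tok{i}"), f"{lbl}tok{i}", lbl)
                )
        for i in range(n_per_class):
            doc_id = f"neg{i}"
            docs.append(Document(doc_id, f"ctx negtok{i} ctx"))
            negatives.append(
                NegativeCandidate(doc_id, 4, 4 + len(f"negtok{i}"), f"negtok{i}", "thing")
            )
        return positives, negatives, docs

    def test_requested_counts_delivered(self):
        pos, neg, docs = self._pools()
        splits = assemble_dataset(pos, neg, docs, 10, seed=0)
        labels = [ex.label for ex in splits.all]
        assert len(labels) == 50
        for lbl in ("ggp", "che", "dis", "org", "neg"):
            assert labels.count(lbl) == 10

    def test_same_seed_identical(self):
        pos, neg, docs = self._pools()
        a = assemble_dataset(pos, neg, docs, 10, seed=5)
        b = assemble_dataset(pos, neg, docs, 10, seed=5)
        assert a == b

    def test_different_seed_differs(self):
        pos, neg, docs = self._pools()
        a = assemble_dataset(pos, neg, docs, 10, seed=5)
        b = assemble_dataset(pos, neg, docs, 10, seed=6)
        assert a != b

    def test_partitions_disjoint(self):
        pos, neg, docs = self._pools()
        s = assemble_dataset(pos, neg, docs, 20, seed=1)
        seen = [(ex.doc_id, ex.start, ex.end) for ex in s.all]
        assert len(seen) == len(set(seen))

    def test_capacity_error_names_class(self):
        pos, neg, docs = self._pools(n_per_class=5)
        with pytest.raises(CapacityError, match="ggp"):
            assemble_dataset(pos, neg, docs, {"ggp": 10}, seed=0)
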
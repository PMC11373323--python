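"""Synthetic data generation.

Everything the pipeline consumes can be generated here with no downloads:
corpora with planted names embedded in class-typical contexts, three
pseudo-tool annotation sets with controlled agreement, matching dictionary
files, and a mock probabilistic scorer with configurable confusion.

Each class (ggp, che, dis, org, neg) owns a disjoint vocabulary pool, so a
mention's "contextual class" is well defined and the expected aggregation
scores are analytically computable.  A planted name with ambiguity rate q
appears in a context drawn from a *different* class's pool with
probability q — the synthetic analogue of an ambiguous name like "NO" or
"wingless" that a block list should catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .consensus import LABELS, AnnotationSet, Span
from .tagger import Document, DictionaryEntry, NameRecord

__all__ = [
    "FixtureSpec",
    "PlantedName",
    "TruthRecord",
    "default_vocab",
    "generate_corpus",
    "generate_annotation_sets",
    "dictionary_for",
    "MockScorer",
    "mock_scorer",
]


def default_vocab(pool_size: int = 40) -> dict[str, list[str]]:
    """Disjoint per-class word pools (``ggpword00`` ... ``negword39``)."""
    return {
        lbl: [f"{lbl}word{i:02d}" for i in range(pool_size)] for lbl in LABELS
    }


@dataclass(frozen=True)
class PlantedName:
    name: str
    true_class: str  # dictionary class of the name, one of ggp/che/dis/org
    ambiguity_rate: float = 0.0  # q: P(context drawn from another class)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity rate q must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted mention."""

    doc_id: str
    start: int
    end: int
    name: str
    dictionary_class: str  # the class the dictionary assigns the name
    context_class: str  # the class whose vocabulary surrounds the mention


@dataclass(frozen=True)
class FixtureSpec:
    n_docs: int = 200
    vocab: Mapping[str, Sequence[str]] = field(default_factory=default_vocab)
    planted_names: tuple[PlantedName, ...] = (
        PlantedName("alphaonegene", "ggp", 0.05),
        PlantedName("betatwochem", "che", 0.05),
        PlantedName("gammadisease", "dis", 0.05),
        PlantedName("deltaspecies", "org", 0.05),
        PlantedName("troublegene", "ggp", 0.9),
        PlantedName("troublechem", "che", 0.9),
    )
    agreement_rates: tuple[float, float, float] = (0.8, 0.8, 0.8)
    words_per_side: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        pools = [frozenset(v) for v in self.vocab.values()]
        for i, a in enumerate(pools):
            for b in pools[i + 1 :]:
                if a & b:
                    raise ValueError("class vocabulary pools must be disjoint")
        for a in self.agreement_rates:
            if not 0.0 <= a <= 1.0:
                raise ValueError("agreement rates must be in [0, 1]")


def generate_corpus(
    spec: FixtureSpec,
) -> tuple[list[Document], list[TruthRecord]]:
    """Documents with planted mentions plus a truth table.

    Every document contains one mention of every planted name, each
    surrounded by ``words_per_side`` words drawn (with replacement) from
    the pool of the mention's contextual class.  Mention blocks are
    separated by sentence-final periods, and each document ends with a
    mention-free block of negative-class words (the pool for noun-phrase
    negative candidates).  Byte-identical for equal specs.
    """
    for lbl, pool in spec.vocab.items():
        if not pool:
            raise ValueError(f"empty vocabulary pool for class {lbl!r}")
    rng = np.random.default_rng(spec.seed)
    docs: list[Document] = []
    truth: list[TruthRecord] = []
    classes = list(LABELS)
    for d in range(spec.n_docs):
        doc_id = f"doc{d:04d}"
        parts: list[str] = []
        pos = 0
        records: list[TruthRecord] = []
        for planted in spec.planted_names:
            if rng.random() < planted.ambiguity_rate:
                others = [c for c in classes if c != planted.true_class]
                ctx_class = others[rng.integers(len(others))]
            else:
                ctx_class = planted.true_class
            pool = spec.vocab[ctx_class]
            left = [pool[rng.integers(len(pool))] for _ in range(spec.words_per_side)]
            right = [pool[rng.integers(len(pool))] for _ in range(spec.words_per_side)]
            for w in left:
                parts.append(w)
                pos += len(w) + 1
            start = pos
            parts.append(planted.name)
            pos += len(planted.name) + 1
            records.append(
                TruthRecord(
                    doc_id=doc_id,
                    start=start,
                    end=start + len(planted.name),
                    name=planted.name,
                    dictionary_class=planted.true_class,
                    context_class=ctx_class,
                )
            )
            for w in right:
                parts.append(w)
                pos += len(w) + 1
            parts.append(".")
            pos += 2
        neg_pool = spec.vocab["neg"]
        for _ in range(2 * spec.words_per_side):
            w = neg_pool[rng.integers(len(neg_pool))]
            parts.append(w)
            pos += len(w) + 1
        parts.append(".")
        text = " ".join(parts)
        docs.append(Document(doc_id=doc_id, text=text))
        for r in records:
            assert text[r.start : r.end] == r.name
        truth.extend(records)
    return docs, truth


def _word_bounds(text: str, start: int, end: int) -> tuple[int, int]:
    """Bounds of the whitespace-delimited words adjacent to [start, end)."""
    prev_end = start - 1
    while prev_end > 0 and not text[prev_end - 1].isspace():
        prev_end -= 1
    next_start = end + 1
    while next_start < len(text) and not text[next_start].isspace():
        next_start += 1
    return prev_end, next_start


def generate_annotation_sets(
    corpus: Sequence[Document],
    truth: Sequence[TruthRecord],
    agreement_rates: Sequence[float] = (0.8, 0.8, 0.8),
    seed: int = 0,
) -> list[AnnotationSet]:
    """Three pseudo-tool annotation sets.

    Each source reproduces each truth span exactly with its agreement
    probability; otherwise it either drops the span or perturbs one
    boundary by one word (uniform choice), exercising the exact-boundary
    requirement of consensus intersection.
    """
    texts = {d.doc_id: d.text for d in corpus}
    rng = np.random.default_rng(seed)
    sets: list[AnnotationSet] = []
    for idx, rate in enumerate(agreement_rates):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("agreement rate must be in [0, 1]")
        spans: list[Span] = []
        for r in truth:
            text = texts[r.doc_id]
            u = rng.random()
            if u < rate:
                spans.append(
                    Span(r.doc_id, r.start, r.end, r.name, r.dictionary_class)
                )
            elif rng.random() < 0.5:
                continue  # dropped
            else:
                left_start, right_end = _word_bounds(text, r.start, r.end)
                if rng.random() < 0.5:
                    start, end = min(left_start, r.start - 1), r.end
                else:
                    start, end = r.start, max(right_end, r.end + 1)
                start = max(0, start)
                end = min(len(text), end)
                spans.append(
                    Span(r.doc_id, start, end, text[start:end], r.dictionary_class)
                )
        sets.append(AnnotationSet.from_spans(f"pseudo-tool-{idx + 1}", spans))
    return sets


def dictionary_for(
    spec: FixtureSpec,
) -> tuple[list[DictionaryEntry], list[NameRecord]]:
    """Dictionary files covering the spec's planted names."""
    entries = [
        DictionaryEntry(
            serial=i + 1,
            entity_type=p.true_class,
            identifier=f"FIX:{i + 1:04d}",
        )
        for i, p in enumerate(spec.planted_names)
    ]
    names = [
        NameRecord(name=p.name, serial=i + 1)
        for i, p in enumerate(spec.planted_names)
    ]
    return entries, names


class MockScorer:
    """Stand-in for the trained classifier with configurable fidelity.

    For a mention whose contextual class is K the scorer emits p[K] = f
    and spreads the remaining mass uniformly over the other four classes.
    Deterministic: the probabilities depend only on the truth table.
    """

    def __init__(self, truth: Sequence[TruthRecord], fidelity: float) -> None:
        if not 0.2 < fidelity <= 1.0:
            raise ValueError("fidelity must be in (0.2, 1] (above chance)")
        self.fidelity = fidelity
        self._by_span = {(r.doc_id, r.start, r.end): r for r in truth}

    def probs_for_span(
        self, doc_id: str, start: int, end: int
    ) -> dict[str, float]:
        r = self._by_span.get((doc_id, start, end))
        if r is None:
            raise KeyError(f"no truth record for ({doc_id}, {start}, {end})")
        rest = (1.0 - self.fidelity) / (len(LABELS) - 1)
        return {
            lbl: self.fidelity if lbl == r.context_class else rest
            for lbl in LABELS
        }

    def __call__(self, doc_id: str, start: int, end: int) -> dict[str, float]:
        return self.probs_for_span(doc_id, start, end)


def mock_scorer(truth: Sequence[TruthRecord], fidelity: float) -> MockScorer:
    return MockScorer(truth, fidelity)
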
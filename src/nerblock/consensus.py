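"""Consensus training-set construction.

Builds a labeled masked-context dataset from the agreement of three NER
annotation sources: positives are spans where all three sources agree on
exact boundaries and entity type; negatives are noun-phrase contexts where
no source tagged any of the four positive entity types, filtered by a
head-word stop list (pronouns, numbers, generic type-level terms).
Each example is a context window of up to 100 words on each side of the
mention, with the mention itself replaced by a mask token, so a classifier
trained on it learns what the *context* of each entity type looks like
without seeing the name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .tagger import Document

__all__ = [
    "POSITIVE_TYPES",
    "LABELS",
    "CapacityError",
    "AnnotationSet",
    "Span",
    "ConsensusSpan",
    "NegativeCandidate",
    "ContextExample",
    "DatasetSplits",
    "intersect_annotations",
    "head_of_phrase",
    "noun_phrase_candidates",
    "sample_negatives",
    "make_context",
    "assemble_dataset",
    "DEFAULT_HEAD_FILTER",
]

POSITIVE_TYPES = ("ggp", "dis", "org", "che")
#: label order used everywhere downstream (classifier output columns)
LABELS = ("ggp", "che", "dis", "org", "neg")

MASK_TOKEN = "[MASK]"
CONTEXT_WINDOW = 100  # words on each side of the mask

_WORD_RE = re.compile(r"\S+")


class CapacityError(ValueError):
    """A per-class request exceeds the available example pool."""


@dataclass(frozen=True)
class Span:
    doc_id: str
    start: int
    end: int
    surface: str
    type: str  # one of ggp/dis/org/che/other


@dataclass(frozen=True)
class AnnotationSet:
    """Spans from one NER source, types mapped onto {ggp,dis,org,che,other}."""

    source_name: str
    spans: tuple[Span, ...]

    @classmethod
    def from_spans(cls, source_name: str, spans: Iterable[Span]) -> "AnnotationSet":
        ordered = tuple(sorted(spans, key=lambda s: (s.doc_id, s.start, s.end)))
        return cls(source_name, ordered)


@dataclass(frozen=True)
class ConsensusSpan:
    doc_id: str
    start: int
    end: int
    surface: str
    label: str  # one of the four positive types


@dataclass(frozen=True)
class NegativeCandidate:
    doc_id: str
    start: int
    end: int
    surface: str
    head: str


@dataclass(frozen=True)
class ContextExample:
    label: str  # ggp/che/dis/org/neg
    text: str  # masked context window
    doc_id: str
    start: int
    end: int
    surface: str = ""


def intersect_annotations(sets: Sequence[AnnotationSet]) -> list[ConsensusSpan]:
    """Spans on which all three sources agree exactly (boundaries and type).

    Only the four positive entity types are eligible.  Requires exactly
    three annotation sets.
    """
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 annotation sets, got {len(sets)}")
    keyed = []
    surfaces: dict[tuple[str, int, int, str], str] = {}
    for s in sets:
        keys = set()
        for sp in s.spans:
            if sp.type in POSITIVE_TYPES:
                k = (sp.doc_id, sp.start, sp.end, sp.type)
                keys.add(k)
                surfaces[k] = sp.surface
        keyed.append(keys)
    common = keyed[0] & keyed[1] & keyed[2]
    return [
        ConsensusSpan(doc_id=d, start=a, end=b, surface=surfaces[(d, a, b, t)], label=t)
        for (d, a, b, t) in sorted(common)
    ]


# --- negative candidates -----------------------------------------------------

# Post-modifying prepositions that mark the end of the head region in a
# simple English noun phrase ("inhibitor OF kinases" -> head "inhibitor").
_PREPOSITIONS = frozenset(
    "of in on at by for with from to into onto over under between among".split()
)

# Seed head-filter list: pronouns, number words, and top- or
# intermediate-level terms for the target entity types.  Callers extend or
# replace it; matching is exact on the lowercased head token.
DEFAULT_HEAD_FILTER = frozenset(
    """
    it that this these those they them which who what something anything
    one two three four five six seven eight nine ten
    protein proteins gene genes enzyme enzymes cytokine cytokines
    chemical chemicals compound compounds drug drugs disease diseases
    disorder disorders syndrome syndromes species organism organisms
    cell cells receptor receptors factor factors
    """.split()
)

# Function words that never start or continue the noun run of a candidate
# phrase (POS-light: everything alphabetic that is not a function word is
# treated as a possible noun/adjective token).
_FUNCTION_WORDS = frozenset(
    """
    a an the and or but not no nor so yet is are was were be been being
    have has had do does did will would can could may might shall should
    must as if then than when while because although though
    """.split()
) | _PREPOSITIONS


def head_of_phrase(tokens: Sequence[str]) -> str:
    """Head of a simple noun phrase: the rightmost token that is not part
    of a post-modifier, i.e. the token just before the first preposition,
    or the last token when no preposition occurs.  Lowercased.
    """
    if not tokens:
        raise ValueError("cannot find the head of an empty phrase")
    lowered = [t.lower() for t in tokens]
    for i, tok in enumerate(lowered):
        if i > 0 and tok in _PREPOSITIONS:
            return lowered[i - 1].strip(".,;:!?()[]{}\"'")
    return lowered[-1].strip(".,;:!?()[]{}\"'")


def noun_phrase_candidates(doc: Document) -> list[NegativeCandidate]:
    """Default built-in chunker: determiner/adjective* noun+ heuristic.

    A candidate is a maximal run of non-function-word tokens, optionally
    preceded by a determiner (which is not included in the span).  This is
    a POS-light stand-in behind the pluggable chunker interface.
    """
    candidates: list[NegativeCandidate] = []
    run: list[re.Match[str]] = []

    def flush() -> None:
        if not run:
            return
        start, end = run[0].start(), run[-1].end()
        tokens = [m.group(0) for m in run]
        candidates.append(
            NegativeCandidate(
                doc_id=doc.doc_id,
                start=start,
                end=end,
                surface=doc.text[start:end],
                head=head_of_phrase(tokens),
            )
        )
        run.clear()

    for m in _WORD_RE.finditer(doc.text):
        token = m.group(0).strip(".,;:!?()[]{}\"'")
        if not token or token.lower() in _FUNCTION_WORDS or not any(
            c.isalpha() for c in token
        ):
            flush()
            continue
        run.append(m)
    flush()
    return candidates


Chunker = Callable[[Document], list[NegativeCandidate]]


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def sample_negatives(
    corpus: Iterable[Document],
    sets: Sequence[AnnotationSet],
    candidates: Iterable[NegativeCandidate],
    filter_list: frozenset[str] | set[str] = DEFAULT_HEAD_FILTER,
) -> list[NegativeCandidate]:
    """Filter negative candidates.

    A candidate survives iff (a) its span shares no character position with
    a positive-type span from ANY single source (even one dissenting tagger
    bars the location), (b) overlap with spans tagged as types outside the
    four positives is tolerated, and (c) its head token is not in the
    filter list.
    """
    positive_spans: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for sp in s.spans:
            if sp.type in POSITIVE_TYPES:
                positive_spans.setdefault(sp.doc_id, []).append((sp.start, sp.end))
    kept = []
    for cand in candidates:
        if cand.head in filter_list:
            continue
        blocked = positive_spans.get(cand.doc_id, ())
        if any(_overlaps(cand.start, cand.end, s, e) for (s, e) in blocked):
            continue
        kept.append(cand)
    return kept


# --- context windows ---------------------------------------------------------


def make_context(
    doc: Document,
    start: int,
    end: int,
    label: str,
    window: int = CONTEXT_WINDOW,
    mask: str = MASK_TOKEN,
) -> ContextExample:
    """Mask the focal span and keep up to ``window`` words on each side.

    Words are maximal runs of non-whitespace; the window never crosses the
    document boundary.  Replacing the mask token with the original surface
    reproduces the original window text exactly.
    """
    if not (0 <= start < end <= len(doc.text)):
        raise ValueError(
            f"span [{start}, {end}) out of bounds for document {doc.doc_id!r}"
        )
    left_text = doc.text[:start]
    right_text = doc.text[end:]
    left_words = list(_WORD_RE.finditer(left_text))
    right_words = list(_WORD_RE.finditer(right_text))
    w_start = left_words[-window].start() if len(left_words) > window else 0
    w_end = (
        end + right_words[window - 1].end()
        if len(right_words) > window
        else len(doc.text)
    )
    text = doc.text[w_start:start] + mask + doc.text[end:w_end]
    return ContextExample(
        label=label,
        text=text,
        doc_id=doc.doc_id,
        start=start,
        end=end,
        surface=doc.text[start:end],
    )


# --- dataset assembly --------------------------------------------------------


@dataclass(frozen=True)
class DatasetSplits:
    train: tuple[ContextExample, ...]
    dev: tuple[ContextExample, ...]
    test: tuple[ContextExample, ...]

    @property
    def all(self) -> tuple[ContextExample, ...]:
        return self.train + self.dev + self.test


def assemble_dataset(
    positives: Sequence[ConsensusSpan],
    negatives: Sequence[NegativeCandidate],
    corpus: Iterable[Document] | Mapping[str, Document],
    per_class: int | Mapping[str, int],
    seed: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    window: int = CONTEXT_WINDOW,
    mask: str = MASK_TOKEN,
) -> DatasetSplits:
    """Draw per-class example counts, mask contexts, and split.

    Deterministic given ``seed``; no example appears in two partitions.
    Raises :class:`CapacityError` naming the class when a request exceeds
    the available pool.
    """
    if isinstance(corpus, Mapping):
        docs = dict(corpus)
    else:
        docs = {d.doc_id: d for d in corpus}
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    wanted: dict[str, int]
    if isinstance(per_class, int):
        wanted = {lbl: per_class for lbl in LABELS}
    else:
        wanted = dict(per_class)

    pools: dict[str, list[tuple[str, int, int, str]]] = {lbl: [] for lbl in LABELS}
    for p in positives:
        pools[p.label].append((p.doc_id, p.start, p.end, p.label))
    for c in negatives:
        pools["neg"].append((c.doc_id, c.start, c.end, "neg"))

    rng = np.random.default_rng(seed)
    train: list[ContextExample] = []
    dev: list[ContextExample] = []
    test: list[ContextExample] = []
    for lbl in LABELS:
        n = wanted.get(lbl, 0)
        pool = sorted(pools[lbl])
        if n > len(pool):
            raise CapacityError(
                f"class {lbl!r}: requested {n} examples, pool has {len(pool)}"
            )
        chosen = [pool[i] for i in rng.permutation(len(pool))[:n]]
        examples = [
            make_context(docs[d], s, e, label, window=window, mask=mask)
            for (d, s, e, label) in chosen
        ]
        n_dev = int(n * fractions[1])
        n_test = int(n * fractions[2])
        n_train = n - n_dev - n_test
        train.extend(examples[:n_train])
        dev.extend(examples[n_train : n_train + n_dev])
        test.extend(examples[n_train + n_dev :])
    # one global shuffle per partition, still seed-deterministic
    for part in (train, dev, test):
        order = rng.permutation(len(part))
        part[:] = [part[i] for i in order]
    return DatasetSplits(tuple(train), tuple(dev), tuple(test))
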
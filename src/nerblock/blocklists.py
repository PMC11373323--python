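"""Block/allow-list generation from per-mention class probabilities.

For every tagger match the classifier yields a distribution over the five
classes; the mass not on the tagger-assigned class, P(¬C), measures how
unlikely the context makes the assignment.  Scores are aggregated in two
stages — an unweighted mean of P(¬C) over a name's mentions within each
document, then an unweighted mean of those document scores across the
corpus (documents are treated as independent and weigh equally regardless
of how many mentions they contain).

A name goes on the corpus-wide (global) block list when its global P(¬C)
reaches the class threshold (0.5 for genes/gene products, species and
chemicals; 0.85 for diseases) and it appears in at least two documents.
Document-specific (local) decisions use the odds ratio

    ratio = [P(C|N) * P(C|L)] / [P(notC|N) * P(notC|L)]

where P(C|N) is the name's global score of belonging to its class and
P(C|L) the within-document score.  The allow direction (as written above)
can override even a very high global block score for one document; the
block direction swaps C and notC.  Local blocks are generated for genes
and chemicals at ratio >= 1000; local allows only for genes at
ratio >= 1e15.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .tagger import ENTITY_TYPES, ListEntry, Match

__all__ = [
    "ScoredMatch",
    "NameDocScore",
    "NameGlobalScore",
    "ThresholdConfig",
    "RatioInputs",
    "score_not_class",
    "aggregate_doc",
    "aggregate_global",
    "aggregate_scores",
    "make_global_blocklist",
    "local_ratio",
    "make_local_lists",
    "build_blocklists",
]


def score_not_class(probs: Mapping[str, float], assigned: str) -> float:
    """P(¬C): total probability mass off the tagger-assigned class,
    including the negative class."""
    if assigned not in probs:
        raise ValueError(f"assigned class {assigned!r} not in label set")
    return 1.0 - probs[assigned]


@dataclass(frozen=True)
class ScoredMatch:
    match: Match
    probs: Mapping[str, float]

    @property
    def p_not_class(self) -> float:
        return score_not_class(self.probs, self.match.entity_type)


@dataclass(frozen=True)
class NameDocScore:
    name: str  # case-preserved surface form
    doc_id: str
    entity_type: str
    p_not_class_doc: float  # unweighted mean over the doc's mentions
    mention_count: int


@dataclass(frozen=True)
class NameGlobalScore:
    name: str
    entity_type: str
    p_not_class_global: float  # unweighted mean over documents
    doc_count: int


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds governing list membership (inclusive comparisons)."""

    global_block_threshold: Mapping[str, float] = field(
        default_factory=lambda: {"ggp": 0.5, "che": 0.5, "org": 0.5, "dis": 0.85}
    )
    min_docs: int = 2
    local_block_ratio: float = 1000.0
    local_block_classes: frozenset[str] = frozenset({"ggp", "che"})
    local_allow_ratio: float = 1e15
    local_allow_classes: frozenset[str] = frozenset({"ggp"})
    # floor only guards against log(0); it must sit far below 1/local_allow_ratio
    # or near-certain local evidence could never clear the allow cutoff
    probability_floor: float = 1e-30

    def __post_init__(self) -> None:
        for cls, thr in self.global_block_threshold.items():
            if cls not in ENTITY_TYPES or not (0.0 < thr < 1.0):
                raise ValueError(f"bad threshold {thr!r} for class {cls!r}")
        if self.local_block_ratio <= 1 or self.local_allow_ratio <= 1:
            raise ValueError("ratio cutoffs must exceed 1")
        if self.probability_floor <= 0:
            raise ValueError("probability floor must be positive")


def aggregate_doc(scored: Sequence[ScoredMatch]) -> NameDocScore:
    """Unweighted mean of P(¬C) over one name's mentions in one document.

    All inputs must share (surface, doc_id, resolved class).
    """
    if not scored:
        raise ValueError("cannot aggregate an empty mention group")
    keys = {(s.match.surface, s.match.doc_id, s.match.entity_type) for s in scored}
    if len(keys) != 1:
        raise ValueError(f"mixed (name, doc, class) groups: {sorted(keys)}")
    (name, doc_id, etype) = keys.pop()
    # fsum: the mean must be exactly invariant to mention order
    mean = math.fsum(s.p_not_class for s in scored) / len(scored)
    return NameDocScore(name, doc_id, etype, mean, len(scored))


def aggregate_global(doc_scores: Sequence[NameDocScore]) -> NameGlobalScore:
    """Unweighted mean of per-document scores: every document counts once,
    however many mentions it contributed."""
    if not doc_scores:
        raise ValueError("cannot aggregate an empty document group")
    keys = {(d.name, d.entity_type) for d in doc_scores}
    if len(keys) != 1:
        raise ValueError(f"mixed (name, class) groups: {sorted(keys)}")
    (name, etype) = keys.pop()
    docs = {d.doc_id for d in doc_scores}
    if len(docs) != len(doc_scores):
        raise ValueError("duplicate document scores in group")
    mean = math.fsum(d.p_not_class_doc for d in doc_scores) / len(doc_scores)
    return NameGlobalScore(name, etype, mean, len(doc_scores))


def aggregate_scores(
    scored: Iterable[ScoredMatch],
) -> tuple[list[NameDocScore], list[NameGlobalScore]]:
    """Group scored matches by (name, doc, class) and (name, class) and run
    both aggregation stages."""
    groups: dict[tuple[str, str, str], list[ScoredMatch]] = defaultdict(list)
    for s in scored:
        groups[(s.match.surface, s.match.doc_id, s.match.entity_type)].append(s)
    doc_scores = [aggregate_doc(g) for g in groups.values()]
    by_name: dict[tuple[str, str], list[NameDocScore]] = defaultdict(list)
    for d in doc_scores:
        by_name[(d.name, d.entity_type)].append(d)
    global_scores = [aggregate_global(g) for g in by_name.values()]
    return doc_scores, global_scores


def make_global_blocklist(
    globals_: Iterable[NameGlobalScore], cfg: ThresholdConfig | None = None
) -> list[ListEntry]:
    """Corpus-wide automatic block list.

    A name is blocked iff it was seen in at least ``min_docs`` documents
    and its global P(¬C) reaches the class threshold.  Sorted by
    descending score, then name, so the ranked list can be inspected when
    choosing thresholds.
    """
    cfg = cfg or ThresholdConfig()
    picked = [
        g
        for g in globals_
        if g.doc_count >= cfg.min_docs
        and g.p_not_class_global >= cfg.global_block_threshold[g.entity_type]
    ]
    picked.sort(key=lambda g: (-g.p_not_class_global, g.name))
    return [
        ListEntry(
            name=g.name,
            action="block",
            provenance="auto",
            scope=None,
            score=g.p_not_class_global,
        )
        for g in picked
    ]


@dataclass(frozen=True)
class RatioInputs:
    """Global and local class probabilities entering the odds ratio."""

    p_c_global: float  # P(C|N)
    p_c_local: float  # P(C|L)


def local_ratio(
    inputs: RatioInputs,
    direction: str = "allow",
    floor: float = 1e-30,
) -> float:
    """Odds ratio combining global and local class scores.

    ``allow`` direction: [P(C|N)·P(C|L)] / [P(¬C|N)·P(¬C|L)], monotone
    increasing in both probabilities.  ``block`` direction swaps C and ¬C
    (the reciprocal).  Each probability and its complement are floored at
    ``floor`` and the ratio is computed in log space, so cutoffs like 1e15
    are representable without overflow or division by zero.
    """
    if direction not in ("allow", "block"):
        raise ValueError(f"direction must be allow|block, got {direction!r}")
    for p in (inputs.p_c_global, inputs.p_c_local):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    pn, qn = max(inputs.p_c_global, floor), max(1.0 - inputs.p_c_global, floor)
    pl, ql = max(inputs.p_c_local, floor), max(1.0 - inputs.p_c_local, floor)
    log_ratio = math.log(pn) + math.log(pl) - math.log(qn) - math.log(ql)
    if direction == "block":
        log_ratio = -log_ratio
    return math.exp(log_ratio)


def make_local_lists(
    doc_scores: Iterable[NameDocScore],
    global_scores: Iterable[NameGlobalScore],
    global_blocklist: Iterable[ListEntry],
    cfg: ThresholdConfig | None = None,
) -> list[ListEntry]:
    """Document-specific block and allow entries.

    Local BLOCK: classes ggp/che whose block-direction ratio reaches
    ``local_block_ratio`` in a document.  Local ALLOW: ggp names already on
    the automatic global block list whose allow-direction ratio reaches
    ``local_allow_ratio`` — the document-level evidence must overwhelm a
    very confident global block.
    """
    cfg = cfg or ThresholdConfig()
    global_by_name = {(g.name, g.entity_type): g for g in global_scores}
    auto_blocked = {
        e.name for e in global_blocklist if e.scope is None and e.provenance == "auto"
    }
    entries: list[ListEntry] = []
    for d in sorted(doc_scores, key=lambda d: (d.doc_id, d.name)):
        g = global_by_name.get((d.name, d.entity_type))
        if g is None:
            continue
        inputs = RatioInputs(
            p_c_global=1.0 - g.p_not_class_global,
            p_c_local=1.0 - d.p_not_class_doc,
        )
        if d.entity_type in cfg.local_block_classes:
            r = local_ratio(inputs, "block", cfg.probability_floor)
            if r >= cfg.local_block_ratio:
                entries.append(
                    ListEntry(
                        name=d.name,
                        action="block",
                        provenance="auto",
                        scope=d.doc_id,
                        score=r,
                    )
                )
                continue
        if d.entity_type in cfg.local_allow_classes and d.name in auto_blocked:
            r = local_ratio(inputs, "allow", cfg.probability_floor)
            if r >= cfg.local_allow_ratio:
                entries.append(
                    ListEntry(
                        name=d.name,
                        action="allow",
                        provenance="auto",
                        scope=d.doc_id,
                        score=r,
                    )
                )
    return entries


def build_blocklists(
    scored: Iterable[ScoredMatch], cfg: ThresholdConfig | None = None
) -> tuple[list[ListEntry], list[ListEntry]]:
    """End-to-end aggregation: scored matches -> (global list, local list)."""
    cfg = cfg or ThresholdConfig()
    doc_scores, global_scores = aggregate_scores(scored)
    global_list = make_global_blocklist(global_scores, cfg)
    local_list = make_local_lists(doc_scores, global_scores, global_list, cfg)
    return global_list, local_list
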
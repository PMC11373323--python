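"""Precision/recall accounting for block-list effects, plus co-occurrence
relation-extraction benchmarking.

The manual-audit calculus works from two labeled samples: a random sample
of A matches from the curated-lists-only run (each judged TP or FP), and a
sample of matches removed by the automatic block list (each judged TP —
wrongly removed — or FP — correctly removed).  With

    prec_curated  = TP_curated / (TP_curated + FP_curated)
    prec_blocking = FP_blocked / (TP_blocked + FP_blocked)
    x             = class-specific block rate (fraction of matches removed)

the removed mass A·x splits into weighted counts

    TP_w = A · x · (1 − prec_blocking)      (good matches lost)
    FP_w = A · x · prec_blocking            (bad matches removed)

giving the post-blocking precision and the relative recall change:

    prec_c+a = (TP_curated − TP_w) / [(TP_curated − TP_w) + (FP_curated − FP_w)]
    rec_diff = −TP_w / TP_curated

Co-occurrence evaluation ranks co-mentioned identifier pairs by a pluggable
score (default: number of co-mentioning documents) and walks the ranking
against a gold standard, accumulating TP/FP counts into a step curve.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

from .tagger import DictionaryEntry, Match

__all__ = [
    "InconsistentAuditError",
    "UndefinedRateError",
    "LabeledSample",
    "BlockRate",
    "PrecisionRecallEffect",
    "GoldStandard",
    "precision_curated",
    "precision_blocking",
    "blocking_effect",
    "block_rate",
    "cooccurrence_pairs",
    "cumulative_tp_fp",
    "as_percent",
]


class InconsistentAuditError(ValueError):
    """Block rate implies more removals than the sample contains."""


class UndefinedRateError(ZeroDivisionError):
    """Block rate undefined: no matches before blocking."""


def as_percent(fraction: float, decimals: int = 1) -> float:
    """Display rounding: percentage, half-away-from-zero."""
    q = Decimal(10) ** -decimals
    d = Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class LabeledSample:
    """Manually judged matches; verdicts are 'TP' or 'FP', exhaustive."""

    items: tuple[tuple[object, str], ...]

    def __post_init__(self) -> None:
        bad = {v for _, v in self.items} - {"TP", "FP"}
        if bad:
            raise ValueError(f"verdicts must be TP|FP, got {sorted(bad)}")

    @property
    def sample_size(self) -> int:
        return len(self.items)

    @property
    def tp(self) -> int:
        return sum(1 for _, v in self.items if v == "TP")

    @property
    def fp(self) -> int:
        return sum(1 for _, v in self.items if v == "FP")


def precision_curated(sample: LabeledSample) -> float:
    """TP / (TP + FP) over the curated-only sample."""
    if sample.sample_size == 0:
        raise ValueError("empty sample")
    return sample.tp / sample.sample_size


def precision_blocking(audit: LabeledSample | Sequence[tuple[object, str]]) -> float:
    """Fraction of removed matches that were genuine FPs (correct blocks)."""
    if not isinstance(audit, LabeledSample):
        audit = LabeledSample(tuple(audit))
    if audit.sample_size == 0:
        raise ValueError("empty blocking audit")
    return audit.fp / audit.sample_size


@dataclass(frozen=True)
class PrecisionRecallEffect:
    prec_curated: float
    sample_size: float  # A
    block_rate: float  # x
    prec_blocking: float
    tp_curated: float
    fp_curated: float
    tp_w: float
    fp_w: float
    prec_curated_plus_auto: float
    rec_diff: float  # relative recall change, always <= 0


def blocking_effect(
    prec_curated: float,
    sample_size: float,
    block_rate: float,
    prec_blocking: float,
) -> PrecisionRecallEffect:
    """Propagate a blocking audit through the weighted-count calculus."""
    for name, v in (
        ("prec_curated", prec_curated),
        ("block_rate", block_rate),
        ("prec_blocking", prec_blocking),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if sample_size <= 0:
        raise ValueError("sample size A must be positive")
    tp_c = sample_size * prec_curated
    fp_c = sample_size - tp_c
    removed = sample_size * block_rate
    if removed > tp_c + fp_c + 1e-9:
        raise InconsistentAuditError(
            f"block rate {block_rate} removes more matches ({removed}) than "
            f"the sample holds ({sample_size})"
        )
    tp_w = removed * (1.0 - prec_blocking)
    fp_w = removed * prec_blocking
    denom = (tp_c - tp_w) + (fp_c - fp_w)
    prec_after = (tp_c - tp_w) / denom if denom else 1.0
    rec_diff = -tp_w / tp_c if tp_c else 0.0
    return PrecisionRecallEffect(
        prec_curated=prec_curated,
        sample_size=sample_size,
        block_rate=block_rate,
        prec_blocking=prec_blocking,
        tp_curated=tp_c,
        fp_curated=fp_c,
        tp_w=tp_w,
        fp_w=fp_w,
        prec_curated_plus_auto=prec_after,
        rec_diff=rec_diff,
    )


@dataclass(frozen=True)
class BlockRate:
    entity_type: str
    removed: int
    before: int

    @property
    def x(self) -> float:
        return self.removed / self.before


def block_rate(
    run_before: Iterable[Match] | int,
    run_after: Iterable[Match] | int,
    entity_type: str | None = None,
) -> BlockRate:
    """Fraction of matches removed between two runs.

    Accepts either match iterables (counted, optionally restricted to one
    class) or raw counts.
    """

    def _count(run) -> int:
        if isinstance(run, int):
            return run
        return sum(
            1
            for m in run
            if entity_type is None or m.entity_type == entity_type
        )

    before = _count(run_before)
    after = _count(run_after)
    if before == 0:
        raise UndefinedRateError("no matches before blocking; rate undefined")
    return BlockRate(entity_type or "all", before - after, before)


# --- co-occurrence relation extraction ---------------------------------------

Pair = tuple[str, str]
PairScorer = Callable[[Pair, frozenset], float]


def _default_scorer(pair: Pair, doc_ids: frozenset) -> float:
    # raw co-mention document count; the significance scoring used by
    # production co-occurrence pipelines can be plugged in instead
    return float(len(doc_ids))


def cooccurrence_pairs(
    matches: Iterable[Match],
    entries: Mapping[int, DictionaryEntry] | None = None,
    scorer: PairScorer | None = None,
) -> list[tuple[Pair, float]]:
    """Unordered identifier pairs co-mentioned within documents, ranked by
    score (descending; ties broken by pair lexicographic order).

    Identifiers come from the matches' dictionary serials via ``entries``;
    without ``entries`` the serials themselves (stringified) are used.
    """
    scorer = scorer or _default_scorer
    per_doc: dict[str, set[str]] = defaultdict(set)
    for m in matches:
        for s in m.serials:
            ident = entries[s].identifier if entries is not None else str(s)
            per_doc[m.doc_id].add(ident)
    pair_docs: dict[Pair, set[str]] = defaultdict(set)
    for doc_id, idents in per_doc.items():
        ordered = sorted(idents)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pair_docs[(a, b)].add(doc_id)
    ranked = [
        (pair, scorer(pair, frozenset(docs))) for pair, docs in pair_docs.items()
    ]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


class GoldStandard:
    """Unordered identifier pairs labeled true/false."""

    def __init__(self, labeled: Mapping[frozenset, bool] | None = None) -> None:
        self._pairs: dict[frozenset, bool] = dict(labeled or {})

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, bool]]) -> "GoldStandard":
        pairs: dict[frozenset, bool] = {}
        for a, b, truth in records:
            key = frozenset((a, b))
            if key in pairs and pairs[key] != truth:
                raise ValueError(f"pair {sorted(key)} labeled both true and false")
            pairs[key] = truth
        return cls(pairs)

    def lookup(self, pair: Pair) -> bool | None:
        return self._pairs.get(frozenset(pair))

    def __len__(self) -> int:
        return len(self._pairs)


def cumulative_tp_fp(
    ranked: Sequence[tuple[Pair, float]], gold: GoldStandard
) -> list[tuple[int, int]]:
    """Walk the ranking, counting gold-true pairs as TPs and gold-false as
    FPs; pairs absent from the gold standard are skipped."""
    curve: list[tuple[int, int]] = []
    tp = fp = 0
    for pair, _score in ranked:
        verdict = gold.lookup(pair)
        if verdict is None:
            continue
        if verdict:
            tp += 1
        else:
            fp += 1
        curve.append((tp, fp))
    return curve
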
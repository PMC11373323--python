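"""Reference dictionary tagger.

Elastic, case-insensitive longest-match tagging of typed dictionary names in
plain text, with entity-type clash resolution and case-sensitive application
of global (corpus-wide) and local (document-specific) block/allow lists.

The matcher is deliberately simple and transparent rather than fast: names
are indexed by a normalized key (casefolded, with spaces and hyphens
removed), so "BRCA1", "BRCA-1" and "BRCA 1" all hit the same dictionary
entry.  A candidate only counts when it is delimited by non-alphanumeric
characters (or the string boundary) on both sides; among overlapping
candidates the longest wins, ties broken leftmost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ENTITY_TYPES",
    "TYPE_PRIORITY",
    "ConfigurationError",
    "ReferentialIntegrityError",
    "DictionaryEntry",
    "NameRecord",
    "Document",
    "Match",
    "ListEntry",
    "normalize_name",
    "build_matcher",
    "Matcher",
    "find_matches",
    "resolve_clash",
    "apply_lists",
    "apply_regex_blocks",
]

# Entity-type codes: disease, species (organism), gene or gene product,
# chemical.  The clash-resolution priority is total and fixed:
# dis > org > ggp > che.
ENTITY_TYPES = ("dis", "org", "ggp", "che")
TYPE_PRIORITY: Mapping[str, int] = {t: i for i, t in enumerate(ENTITY_TYPES)}

# Characters that may be freely inserted or deleted inside a name:
# ASCII space, no-break space, hyphen-minus, Unicode hyphen, en-dash.
ELASTIC_CHARS = frozenset("  -‐–")


class ConfigurationError(ValueError):
    """Conflicting block/allow list entries at equal precedence."""


class ReferentialIntegrityError(KeyError):
    """A name record points at a serial with no dictionary entry."""


@dataclass(frozen=True)
class DictionaryEntry:
    serial: int
    entity_type: str
    identifier: str

    def __post_init__(self) -> None:
        if self.entity_type not in TYPE_PRIORITY:
            raise ValueError(f"unknown entity type: {self.entity_type!r}")
        if not self.identifier:
            raise ValueError("identifier must be non-empty")


@dataclass(frozen=True)
class NameRecord:
    name: str
    serial: int

    @property
    def key(self) -> str:
        return normalize_name(self.name)


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


@dataclass(frozen=True)
class Match:
    """A typed, offset-anchored mention.

    Offsets are 0-based, half-open, in Unicode code points;
    ``surface == document.text[start:end]`` always holds.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    entity_type: str
    serials: frozenset[int] = field(default_factory=frozenset)


@dataclass(frozen=True)
class ListEntry:
    """One block/allow decision.

    ``scope`` is ``None`` for global (corpus-wide) entries, otherwise the
    doc_id the entry is local to.  Matching against ``name`` is
    case-SENSITIVE: blocking "bad" does not affect "BAD".
    """

    name: str
    action: str  # "block" | "allow"
    provenance: str = "auto"  # "curated" | "auto"
    scope: str | None = None  # None = global, else doc_id
    score: float | None = None  # global score or local ratio, for reporting

    def __post_init__(self) -> None:
        if self.action not in ("block", "allow"):
            raise ValueError(f"action must be block|allow, got {self.action!r}")
        if self.provenance not in ("curated", "auto"):
            raise ValueError(
                f"provenance must be curated|auto, got {self.provenance!r}"
            )


def normalize_name(surface: str) -> str:
    """Normalize a surface form to its dictionary lookup key.

    Casefolds and strips every space/hyphen character, so lookup is
    case-insensitive and tolerant of arbitrary insertion or deletion of
    spaces and hyphens.  Idempotent.
    """
    if not surface:
        raise ValueError("cannot normalize an empty surface form")
    return "".join(c for c in surface.casefold() if c not in ELASTIC_CHARS)


class Matcher:
    """Lookup structure from normalized keys to dictionary serials."""

    def __init__(
        self,
        key_to_serials: Mapping[str, frozenset[int]],
        entries: Mapping[int, DictionaryEntry],
    ) -> None:
        self._keys = dict(key_to_serials)
        self._entries = dict(entries)
        self._max_key_len = max((len(k) for k in self._keys), default=0)

    @property
    def keys(self) -> Mapping[str, frozenset[int]]:
        return self._keys

    @property
    def entries(self) -> Mapping[int, DictionaryEntry]:
        return self._entries

    @property
    def max_key_len(self) -> int:
        return self._max_key_len

    def serials_for(self, key: str) -> frozenset[int] | None:
        return self._keys.get(key)


def build_matcher(
    names: Iterable[NameRecord], entries: Iterable[DictionaryEntry]
) -> Matcher:
    """Index dictionary names by normalized key.

    Raises :class:`ReferentialIntegrityError` if any name points at a
    serial absent from ``entries``.
    """
    by_serial: dict[int, DictionaryEntry] = {}
    for entry in entries:
        if entry.serial in by_serial:
            raise ValueError(f"duplicate serial {entry.serial}")
        by_serial[entry.serial] = entry
    key_map: dict[str, set[int]] = {}
    for rec in names:
        if rec.serial not in by_serial:
            raise ReferentialIntegrityError(
                f"name {rec.name!r} references unknown serial {rec.serial}"
            )
        key_map.setdefault(rec.key, set()).add(rec.serial)
    return Matcher(
        {k: frozenset(v) for k, v in key_map.items()}, by_serial
    )


def resolve_clash(serials: Iterable[int], entries: Mapping[int, DictionaryEntry]) -> str:
    """Resolve a type clash among serials sharing one name.

    Diseases take precedence over species, then genes or gene products,
    then chemicals — so a name shared by a gene and a chemical dictionary
    (e.g. "NO") is tagged as a gene.
    """
    serials = set(serials)
    if not serials:
        raise ValueError("cannot resolve a clash for an empty serial set")
    types = {entries[s].entity_type for s in serials}
    return min(types, key=TYPE_PRIORITY.__getitem__)


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def _candidate_spans(text: str, matcher: Matcher) -> list[tuple[int, int, str]]:
    """All delimited spans whose normalized form is a dictionary key."""
    out: list[tuple[int, int, str]] = []
    n = len(text)
    max_len = matcher.max_key_len
    if max_len == 0:
        return out
    for i in range(n):
        if not _is_word_char(text[i]):
            continue
        if i > 0 and _is_word_char(text[i - 1]):
            continue  # not at a word start
        key_parts: list[str] = []
        key_len = 0
        j = i
        while j < n and key_len <= max_len:
            ch = text[j]
            if ch not in ELASTIC_CHARS:
                folded = ch.casefold()
                key_parts.append(folded)
                key_len += len(folded)
            j += 1
            # a candidate must end on a word character and be delimited
            if (
                key_len <= max_len
                and _is_word_char(text[j - 1])
                and (j == n or not _is_word_char(text[j]))
            ):
                key = "".join(key_parts)
                if matcher.serials_for(key) is not None:
                    out.append((i, j, key))
    return out


def select_longest_leftmost(
    spans: Sequence[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    """Greedy non-overlapping selection: longest first, leftmost on ties."""
    chosen: list[tuple[int, int, str]] = []
    for span in sorted(spans, key=lambda s: (-(s[1] - s[0]), s[0], s[1])):
        if all(span[1] <= c[0] or span[0] >= c[1] for c in chosen):
            chosen.append(span)
    chosen.sort(key=lambda s: s[0])
    return chosen


def find_matches(doc: Document, matcher: Matcher) -> list[Match]:
    """Tag a document, returning non-overlapping matches in text order.

    A candidate matches only when delimited by non-alphanumeric characters
    (or string boundaries) on both sides; adjacent punctuation is permitted
    but never part of the surface.  Any number of spaces/hyphens inside the
    candidate is tolerated (see :func:`normalize_name`).
    """
    matches: list[Match] = []
    for start, end, key in select_longest_leftmost(
        _candidate_spans(doc.text, matcher)
    ):
        serials = matcher.serials_for(key)
        assert serials is not None
        surface = doc.text[start:end]
        matches.append(
            Match(
                doc_id=doc.doc_id,
                start=start,
                end=end,
                surface=surface,
                entity_type=resolve_clash(serials, matcher.entries),
                serials=serials,
            )
        )
    return matches


# --- block/allow list application -------------------------------------------

# Decision precedence per (surface, doc), highest first.  A local allow
# overrides a global block for that document only; curated entries outrank
# automatic ones; at the global level an allow outranks a block of the same
# provenance (curated allows protect against auto-blocking mistakes).
_LOCAL_LEVELS = ("curated", "auto")
_GLOBAL_LEVELS = (
    ("curated", "allow"),
    ("curated", "block"),
    ("auto", "allow"),
    ("auto", "block"),
)


def _index_lists(
    lists: Iterable[ListEntry],
) -> tuple[dict, dict]:
    local: dict[tuple[str, str, str], str] = {}  # (doc, name, prov) -> action
    glob: dict[tuple[str, str, str], bool] = {}  # (name, prov, action) -> present
    for e in lists:
        if e.scope is None:
            key = (e.name, e.provenance, e.action)
            glob[key] = True
        else:
            key = (e.scope, e.name, e.provenance)
            if key in local and local[key] != e.action:
                raise ConfigurationError(
                    f"conflicting local {e.provenance} entries for "
                    f"{e.name!r} in document {e.scope}"
                )
            local[key] = e.action
    return local, glob


def apply_lists(matches: Iterable[Match], lists: Iterable[ListEntry]) -> list[Match]:
    """Filter matches through block/allow lists (case-sensitive on surface).

    Precedence: local-curated > local-auto > global-curated-allow >
    global-curated-block > global-auto-allow > global-auto-block > keep.
    Surviving matches are returned in input order.
    """
    local, glob = _index_lists(lists)
    kept: list[Match] = []
    for m in matches:
        decision = "keep"
        for prov in _LOCAL_LEVELS:
            action = local.get((m.doc_id, m.surface, prov))
            if action is not None:
                decision = action
                break
        else:
            for prov, action in _GLOBAL_LEVELS:
                if (m.surface, prov, action) in glob:
                    decision = action
                    break
        if decision != "block":
            kept.append(m)
    return kept


def apply_regex_blocks(
    matches: Iterable[Match], patterns: Iterable[str]
) -> list[Match]:
    """Drop matches whose surface fully matches any pre-filter regex.

    Stands in for the tagger's built-in regular-expression pre-filters;
    pass an empty pattern list to disable them (the no-block-list run).
    """
    compiled = [re.compile(p) for p in patterns]
    return [
        m
        for m in matches
        if not any(rx.fullmatch(m.surface) for rx in compiled)
    ]
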
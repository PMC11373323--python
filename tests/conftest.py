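"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from nerblock.tagger import (
    DictionaryEntry,
    Document,
    NameRecord,
    build_matcher,
    normalize_name,
)


def brute_force_matches(text: str, keys, max_len: int = 60):
    """Independent matcher oracle: enumerate every substring, keep those
    that are delimited on both sides, start/end on a word character, and
    normalize to a dictionary key; then select non-overlapping spans
    longest-first, leftmost on ties."""
    n = len(text)
    candidates = []
    for i in range(n):
        if not text[i].isalnum() or (i > 0 and text[i - 1].isalnum()):
            continue
        for j in range(i + 1, min(n, i + max_len) + 1):
            if not text[j - 1].isalnum():
                continue
            if j < n and text[j].isalnum():
                continue
            key = normalize_name(text[i:j])
            if key in keys:
                candidates.append((i, j))
    chosen: list[tuple[int, int]] = []
    for c in sorted(candidates, key=lambda c: (c[0] - c[1], c[0])):
        if all(c[1] <= d[0] or c[0] >= d[1] for d in chosen):
            chosen.append(c)
    return sorted(chosen)


def random_matcher_instance(rng: np.random.Generator):
    """A small random dictionary plus a random text that embeds some of the
    names (with elastic-character damage) among junk."""
    alphabet = list("abcdefgXYZ0123")
    n_names = int(rng.integers(3, 10))
    names = []
    for _ in range(n_names):
        length = int(rng.integers(2, 7))
        names.append("".join(rng.choice(alphabet, size=length)))
    entries = [
        DictionaryEntry(serial=i + 1, entity_type="ggp", identifier=f"X:{i + 1}")
        for i in range(len(names))
    ]
    records = [NameRecord(name=nm, serial=i + 1) for i, nm in enumerate(names)]
    matcher = build_matcher(records, entries)

    pieces = []
    fillers = ["foo", "ba-r", "q", "7", "zz z", ",", ".", "(", ")", "-"]
    for _ in range(int(rng.integers(5, 20))):
        if rng.random() < 0.5:
            nm = names[int(rng.integers(len(names)))]
            if rng.random() < 0.4 and len(nm) > 2:
                cut = int(rng.integers(1, len(nm)))
                sep = "-" if rng.random() < 0.5 else " "
                nm = nm[:cut] + sep + nm[cut:]
            if rng.random() < 0.3:
                nm = nm.upper()
            pieces.append(nm)
        else:
            pieces.append(fillers[int(rng.integers(len(fillers)))])
    text = " ".join(pieces)
    return matcher, Document(doc_id="rand", text=text)


@pytest.fixture
def tiny_dictionary():
    entries = [
        DictionaryEntry(1, "ggp", "ENSP1"),
        DictionaryEntry(2, "che", "CID1"),
        DictionaryEntry(3, "dis", "DOID1"),
        DictionaryEntry(4, "org", "TAX1"),
        DictionaryEntry(5, "ggp", "ENSP2"),
    ]
    names = [
        NameRecord("BRCA1", 1),
        NameRecord("NO", 1),
        NameRecord("NO", 2),
        NameRecord("asthma", 3),
        NameRecord("E. coli", 4),
        NameRecord("insulin receptor", 5),
    ]
    return entries, names


@pytest.fixture
def tiny_matcher(tiny_dictionary):
    entries, names = tiny_dictionary
    return build_matcher(names, entries)
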
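"""Plain-text readers and writers for the pipeline's file formats.

All files are UTF-8, tab-separated, headerless:

* dictionary: ``<prefix>entities.tsv`` (serial, type, identifier) and
  ``<prefix>names.tsv`` (serial, name)
* corpus: ``documents.tsv`` (doc_id, text) or PubTator title/abstract
  blocks (``PMID|t|...`` / ``PMID|a|...`` separated by blank lines)
* annotations: PubTator-style TSV (doc_id, start, end, surface, type
  [, identifier])
* lists: global (name, block|allow, curated|auto) and local
  (doc_id, name, block|allow)
* matches: (doc_id, start, end, surface, type, serials comma-joined)
* datasets: (label, masked_text) with a sidecar (label, doc_id, start, end)
* probabilities: (example_id, p_ggp, p_che, p_dis, p_org, p_neg)
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consensus import LABELS, AnnotationSet, ContextExample, Span
from .tagger import Document, DictionaryEntry, ListEntry, Match, NameRecord

__all__ = [
    "read_documents_tsv",
    "read_pubtator",
    "write_documents_tsv",
    "read_dictionary",
    "write_dictionary",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_global_list",
    "read_local_list",
    "write_global_list",
    "write_local_list",
    "read_matches_tsv",
    "write_matches_tsv",
    "read_dataset_tsv",
    "write_dataset_tsv",
    "read_probs_tsv",
    "write_probs_tsv",
    "read_gold_tsv",
]


def _lines(path: str | Path) -> Iterable[str]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                yield line


def read_documents_tsv(path: str | Path) -> list[Document]:
    docs = []
    for line in _lines(path):
        doc_id, text = line.split("\t", 1)
        docs.append(Document(doc_id=doc_id, text=text))
    return docs


def write_documents_tsv(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.text}\n")


def read_pubtator(path: str | Path) -> list[Document]:
    """PubTator title/abstract blocks; title and abstract are joined with a
    single space, offsets therefore run over title + " " + abstract."""
    docs: list[Document] = []
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    order: list[str] = []
    for line in _lines(path):
        if "|t|" in line:
            pmid, _, title = line.split("|", 2)
            if pmid not in titles and pmid not in abstracts:
                order.append(pmid)
            titles[pmid] = title
        elif "|a|" in line:
            pmid, _, abstract = line.split("|", 2)
            if pmid not in titles and pmid not in abstracts:
                order.append(pmid)
            abstracts[pmid] = abstract
    for pmid in order:
        pieces = [p for p in (titles.get(pmid), abstracts.get(pmid)) if p]
        docs.append(Document(doc_id=pmid, text=" ".join(pieces)))
    return docs


def read_dictionary(
    prefix: str | Path,
) -> tuple[list[DictionaryEntry], list[NameRecord]]:
    prefix = str(prefix)
    entries = []
    for line in _lines(prefix + "entities.tsv"):
        serial, etype, identifier = line.split("\t")
        entries.append(
            DictionaryEntry(
                serial=int(serial), entity_type=etype, identifier=identifier
            )
        )
    names = []
    for line in _lines(prefix + "names.tsv"):
        serial, name = line.split("\t", 1)
        names.append(NameRecord(name=name, serial=int(serial)))
    return entries, names


def write_dictionary(
    entries: Iterable[DictionaryEntry],
    names: Iterable[NameRecord],
    prefix: str | Path,
) -> None:
    prefix = str(prefix)
    with open(prefix + "entities.tsv", "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"{e.serial}\t{e.entity_type}\t{e.identifier}\n")
    with open(prefix + "names.tsv", "w", encoding="utf-8") as fh:
        for n in names:
            fh.write(f"{n.serial}\t{n.name}\n")


def read_annotations_tsv(path: str | Path, source_name: str | None = None) -> AnnotationSet:
    spans = []
    for line in _lines(path):
        fields = line.split("\t")
        doc_id, start, end, surface, etype = fields[:5]
        spans.append(
            Span(
                doc_id=doc_id,
                start=int(start),
                end=int(end),
                surface=surface,
                type=etype,
            )
        )
    return AnnotationSet.from_spans(source_name or Path(path).stem, spans)


def write_annotations_tsv(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in annotations.spans:
            fh.write(f"{s.doc_id}\t{s.start}\t{s.end}\t{s.surface}\t{s.type}\n")


def read_global_list(path: str | Path) -> list[ListEntry]:
    out = []
    for line in _lines(path):
        name, action, provenance = line.split("\t")[:3]
        out.append(
            ListEntry(name=name, action=action, provenance=provenance, scope=None)
        )
    return out


def read_local_list(path: str | Path) -> list[ListEntry]:
    out = []
    for line in _lines(path):
        doc_id, name, action = line.split("\t")[:3]
        out.append(
            ListEntry(name=name, action=action, provenance="auto", scope=doc_id)
        )
    return out


def write_global_list(entries: Iterable[ListEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            cols = [e.name, e.action, e.provenance]
            if e.score is not None:
                cols.append(f"{e.score:.6g}")
            fh.write("\t".join(cols) + "\n")


def write_local_list(entries: Iterable[ListEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            cols = [e.scope or "", e.name, e.action]
            if e.score is not None:
                cols.append(f"{e.score:.6g}")
            fh.write("\t".join(cols) + "\n")


def read_matches_tsv(path: str | Path) -> list[Match]:
    out = []
    for line in _lines(path):
        doc_id, start, end, surface, etype, serials = line.split("\t")[:6]
        out.append(
            Match(
                doc_id=doc_id,
                start=int(start),
                end=int(end),
                surface=surface,
                entity_type=etype,
                serials=frozenset(
                    int(s) for s in serials.split(",") if s
                ),
            )
        )
    return out


def write_matches_tsv(matches: Iterable[Match], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in matches:
            serials = ",".join(str(s) for s in sorted(m.serials))
            fh.write(
                f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.entity_type}\t{serials}\n"
            )


def read_dataset_tsv(
    path: str | Path, sidecar: str | Path | None = None
) -> list[ContextExample]:
    rows = [line.split("\t", 1) for line in _lines(path)]
    meta: list[tuple[str, int, int]] = []
    if sidecar is not None:
        for line in _lines(sidecar):
            _, doc_id, start, end = line.split("\t")[:4]
            meta.append((doc_id, int(start), int(end)))
    out = []
    for i, (label, text) in enumerate(rows):
        doc_id, start, end = meta[i] if meta else ("", 0, 1)
        out.append(
            ContextExample(
                label=label, text=text, doc_id=doc_id, start=start, end=end
            )
        )
    return out


def write_dataset_tsv(
    examples: Iterable[ContextExample],
    path: str | Path,
    sidecar: str | Path | None = None,
) -> None:
    examples = list(examples)
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(f"{ex.label}\t{ex.text}\n")
    if sidecar is not None:
        with open(sidecar, "w", encoding="utf-8") as fh:
            for ex in examples:
                fh.write(f"{ex.label}\t{ex.doc_id}\t{ex.start}\t{ex.end}\n")


def read_probs_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    """example_id -> class probabilities (columns in LABELS order)."""
    out = {}
    for line in _lines(path):
        fields = line.split("\t")
        out[fields[0]] = {
            lbl: float(v) for lbl, v in zip(LABELS, fields[1:6])
        }
    return out


def write_probs_tsv(
    probs: Mapping[str, Mapping[str, float]] | Sequence[Mapping[str, float]],
    path: str | Path,
) -> None:
    if not isinstance(probs, Mapping):
        probs = {str(i): p for i, p in enumerate(probs)}
    with open(path, "w", encoding="utf-8") as fh:
        for ex_id, p in probs.items():
            cols = [ex_id] + [f"{p[lbl]:.6f}" for lbl in LABELS]
            fh.write("\t".join(cols) + "\n")


def read_gold_tsv(path: str | Path):
    from .evaluation import GoldStandard

    records = []
    for line in _lines(path):
        a, b, verdict = line.split("\t")[:3]
        records.append((a, b, verdict.strip().lower() == "true"))
    return GoldStandard.from_records(records)
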
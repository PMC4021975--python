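"""Readers and writers for the pipeline's plain-text formats.

Formats:

* gene-list standoff annotations, one record per line::

      ID | start end | surface

* lexicon TSV: ``concept_id<TAB>term``
* frequency-list TSV: ``term<TAB>count`` with an optional third
  ``doc_freq`` column (a ``#n_docs<TAB>N`` header line carries the
  document count)
* corpus manifest: a flat key-value (YAML) file naming the corpus, its
  offset dialect, document text files and annotation files.

All files are UTF-8.  Round-trips are value-identical and, for ASCII
gene-list records, byte-exact.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union
from xml.sax.saxutils import escape

import yaml

from .model import (
    AnnotatedCorpus,
    Annotation,
    Document,
    FrequencyList,
    Lexicon,
    OffsetDialect,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class GenelistParseError(ValueError):
    """A malformed gene-list line, reported with its line number."""


def parse_genelist_line(
    line: str,
    dialect: OffsetDialect = OffsetDialect.CANONICAL,
    lineno: int = 0,
) -> Annotation:
    """Parse one ``ID | start end | surface`` record.

    Offsets are stored verbatim under the given dialect tag; no offset
    conversion happens here.
    """
    parts = line.rstrip("\n").split(" | ")
    if len(parts) != 3:
        # fall back to permissive splitting on bare pipes
        parts = [p.strip() for p in line.rstrip("\n").split("|")]
    if len(parts) != 3:
        raise GenelistParseError(
            f"line {lineno}: expected 3 '|'-separated fields, got {len(parts)}"
        )
    doc_id = parts[0].strip()
    offs = parts[1].split()
    if len(offs) != 2:
        raise GenelistParseError(
            f"line {lineno}: offset field must be two integers, got {parts[1]!r}"
        )
    try:
        start, end = int(offs[0]), int(offs[1])
    except ValueError as exc:
        raise GenelistParseError(
            f"line {lineno}: non-integer offset in {parts[1]!r}"
        ) from exc
    return Annotation(
        doc_id=doc_id, start=start, end=end, surface=parts[2], dialect=dialect
    )


def format_genelist_line(ann: Annotation) -> str:
    return f"{ann.doc_id} | {ann.start} {ann.end} | {ann.surface}"


def read_genelist(
    path: PathLike, dialect: OffsetDialect = OffsetDialect.CANONICAL
) -> List[Annotation]:
    anns = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            anns.append(parse_genelist_line(line, dialect=dialect, lineno=lineno))
    return anns


def write_genelist(
    annotations: Iterable[Annotation],
    path: PathLike,
    dialect: Optional[OffsetDialect] = None,
) -> None:
    """Write annotations in gene-list layout, one record per line.

    If ``dialect`` is given it is recorded as intent only; annotations must
    already carry offsets in the requested dialect (conversion needs the
    document text and belongs to the caller).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            if dialect is not None and ann.dialect != dialect:
                raise ValueError(
                    f"annotation carries {ann.dialect.value} offsets, "
                    f"writer asked for {dialect.value}"
                )
            fh.write(format_genelist_line(ann) + "\n")


def read_lexicon(path: PathLike, name: Optional[str] = None) -> Lexicon:
    """Read a ``concept_id<TAB>term`` TSV; duplicate rows are deduplicated."""
    entries: Dict[str, set] = {}
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            cid, term = fields[0].strip(), fields[1].strip()
            if not term:
                raise ValueError(f"{path}:{lineno}: empty term")
            if (cid, term) in seen:
                logger.warning("%s:%d: duplicate row (%s, %s)", path, lineno, cid, term)
                continue
            seen.add((cid, term))
            entries.setdefault(cid, set()).add(term)
    return Lexicon(name=name or Path(path).stem, entries=entries)


def write_lexicon(lexicon: Lexicon, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, term in lexicon.items():
            fh.write(f"{cid}\t{term}\n")


def read_frequency_list(path: PathLike) -> FrequencyList:
    """Read ``term<TAB>count[<TAB>doc_freq]`` rows (``#n_docs`` header)."""
    counts: Dict[str, int] = {}
    doc_freqs: Dict[str, int] = {}
    n_docs = 0
    has_df = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#n_docs\t"):
                n_docs = int(line.split("\t")[1])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields")
            term = fields[0]
            counts[term] = counts.get(term, 0) + int(fields[1])
            if len(fields) == 3:
                has_df = True
                doc_freqs[term] = int(fields[2])
    return FrequencyList(
        counts=counts,
        doc_freqs=doc_freqs if has_df else None,
        n_docs=n_docs,
    )


def write_frequency_list(freq: FrequencyList, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if freq.doc_freqs is not None:
            fh.write(f"#n_docs\t{freq.n_docs}\n")
        for term in sorted(freq.counts):
            row = f"{term}\t{freq.counts[term]}"
            if freq.doc_freqs is not None:
                row += f"\t{freq.doc_freqs.get(term, 0)}"
            fh.write(row + "\n")


def read_corpus(manifest_path: PathLike) -> AnnotatedCorpus:
    """Load a corpus from a manifest file.

    Manifest keys: ``name``, ``dialect`` (canonical | space-free),
    ``documents`` (mapping doc_id -> text file path), ``gold`` (gene-list
    file), optional ``alternatives`` (gene-list file).  Relative paths are
    resolved against the manifest's directory.  Annotations in the
    space-free dialect are converted to canonical offsets on load.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    dialect = OffsetDialect(manifest.get("dialect", "canonical"))
    documents = []
    for doc_id, rel in manifest["documents"].items():
        text = (base / rel).read_text(encoding="utf-8")
        documents.append(Document(doc_id=str(doc_id), text=text))
    texts = {d.doc_id: d.text for d in documents}

    def _load(rel: str, source: str) -> List[Annotation]:
        from dataclasses import replace as _replace

        anns = read_genelist(base / rel, dialect=dialect)
        if dialect != OffsetDialect.CANONICAL:
            from .model import convert_offsets

            anns = [
                convert_offsets(a, texts[a.doc_id], dialect, OffsetDialect.CANONICAL)
                for a in anns
            ]
        return [_replace(a, source=source) for a in anns]

    gold = _load(manifest["gold"], "gold")
    alternatives = (
        _load(manifest["alternatives"], "alt") if manifest.get("alternatives") else []
    )
    corpus = AnnotatedCorpus(
        name=manifest.get("name", manifest_path.stem),
        documents=documents,
        gold=gold,
        alternatives=alternatives,
    )
    expected = manifest.get("n_annotations")
    if expected is not None and len(gold) != int(expected):
        raise ValueError(
            f"manifest declares {expected} annotations, gene list has {len(gold)}"
        )
    return corpus


def write_corpus(corpus: AnnotatedCorpus, out_dir: PathLike) -> Path:
    """Write a corpus (texts, gene lists, manifest) under ``out_dir``.

    Returns the manifest path.  Offsets are written canonically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc_map = {}
    for doc in corpus.documents:
        rel = f"{doc.doc_id}.txt"
        (out / rel).write_text(doc.text, encoding="utf-8")
        doc_map[doc.doc_id] = rel
    write_genelist(corpus.gold, out / "gold.genelist")
    manifest = {
        "name": corpus.name,
        "dialect": "canonical",
        "documents": doc_map,
        "gold": "gold.genelist",
        "n_annotations": len(corpus.gold),
    }
    if corpus.alternatives:
        write_genelist(corpus.alternatives, out / "alternatives.genelist")
        manifest["alternatives"] = "alternatives.genelist"
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def write_inline_xml(doc: Document, annotations: Sequence[Annotation], path: PathLike) -> None:
    """Write a document with entity mentions wrapped in inline elements.

    Convenience interoperability export (IeXML-flavoured); the standoff
    gene-list files remain the system of record and no round-trip reader is
    provided.  Overlapping annotations are rejected.
    """
    anns = sorted(
        (a for a in annotations if a.doc_id == doc.doc_id),
        key=lambda a: (a.start, a.end),
    )
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.start < prev.end:
            raise ValueError("inline XML export requires non-overlapping spans")
    pieces = ["<document id=%s>" % _quote(doc.doc_id)]
    cursor = 0
    for a in anns:
        pieces.append(escape(doc.text[cursor : a.start]))
        ids = ",".join(sorted(a.concept_ids))
        pieces.append(
            f'<e src={_quote(a.source)} ids={_quote(ids)}>'
            f"{escape(doc.text[a.start : a.end])}</e>"
        )
        cursor = a.end
    pieces.append(escape(doc.text[cursor:]))
    pieces.append("</document>\n")
    Path(path).write_text("".join(pieces), encoding="utf-8")


def _quote(value: str) -> str:
    return '"%s"' % escape(value, {'"': "&quot;"})
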
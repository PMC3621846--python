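"""File I/O: N-Triples label files, LF tables, and owl:sameAs output.

Label files follow the DBpedia convention — one ``rdfs:label`` triple per
line with a language-tagged literal object, optionally bz2-compressed
(detected by the ``.bz2`` extension).  Accepted links are published as
``owl:sameAs`` N-Triples.  LF tables are plain TSV:
``lf_text <TAB> frequency [<TAB> lf_uri]``.
"""

from __future__ import annotations

import bz2
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple, Union
from urllib.parse import quote

from rdflib import Literal, URIRef
from rdflib.plugins.parsers import ntriples as _nt

from .matcher import Link, Title

__all__ = [
    "LFRecord",
    "NTriplesError",
    "LFTableError",
    "OWL_SAMEAS",
    "read_ntriples_labels",
    "read_lf_table",
    "write_sameas_ntriples",
    "read_sameas_pairs",
]

OWL_SAMEAS = URIRef("http://www.w3.org/2002/07/owl#sameAs")
RDFS_LABEL = URIRef("http://www.w3.org/2000/01/rdf-schema#label")


class NTriplesError(ValueError):
    """Malformed N-Triples content, reported with a line number."""


class LFTableError(ValueError):
    """Malformed LF table row."""


@dataclass(frozen=True)
class LFRecord:
    """A long form with its literature occurrence frequency.

    ``frequency`` counts occurrences in MEDLINE titles/abstracts (or any
    corpus standing in for it); ``lf_uri`` is the subject IRI to publish
    links under, minted downstream when absent.
    """

    lf_text: str
    frequency: int
    lf_uri: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.lf_text:
            raise ValueError("lf_text must be non-empty")
        if self.frequency < 0:
            raise ValueError(f"frequency must be >= 0, got {self.frequency}")


def _open_text(path: Path) -> io.TextIOBase:
    if path.suffix == ".bz2":
        return bz2.open(path, "rt", encoding="utf-8")
    return path.open(encoding="utf-8")


class _TripleSink:
    def __init__(self) -> None:
        self.triples: List[tuple] = []

    def triple(self, s, p, o) -> None:
        self.triples.append((s, p, o))


def _parse_ntriples_lines(path: Path) -> Iterator[Tuple[int, tuple]]:
    sink = _TripleSink()
    parser = _nt.W3CNTriplesParser(sink)
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sink.triples.clear()
            try:
                parser.parsestring(raw)
            except _nt.ParseError as exc:
                raise NTriplesError(f"{path}:{lineno}: malformed triple: {exc}") from exc
            for triple in sink.triples:
                yield lineno, triple


def read_ntriples_labels(
    path: Union[str, Path],
    language: Optional[str] = "en",
    include_untagged: bool = False,
) -> Iterator[Title]:
    """Yield one :class:`Title` per label triple with a matching language tag.

    Literal escapes (``\\"``, ``\\\\``, ``\\n``, ``\\t``, ``\\uXXXX``) are
    decoded by the N-Triples parser.  Triples whose object is not a
    literal, or whose language tag differs from *language*, are skipped;
    untagged literals are included only when *include_untagged* is set
    (or when *language* is None, which disables the filter entirely).
    Comments and blank lines are skipped; a malformed line raises
    :class:`NTriplesError` with its line number.
    """
    path = Path(path)
    for _lineno, (s, _p, o) in _parse_ntriples_lines(path):
        if not isinstance(o, Literal):
            continue
        if language is not None:
            if o.language != language and not (o.language is None and include_untagged):
                continue
        yield Title(label=str(o), resource_uri=str(s))


def read_lf_table(path: Union[str, Path], header: bool = False) -> List[LFRecord]:
    """Read a TSV LF table: ``lf_text <TAB> frequency [<TAB> lf_uri]``.

    Records are returned in file order.  A non-integer or negative
    frequency, an empty LF text, or a wrong column count raises
    :class:`LFTableError` with the offending line number.
    """
    path = Path(path)
    records: List[LFRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise LFTableError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(cols)}")
            lf_text = cols[0]
            if not lf_text:
                raise LFTableError(f"{path}:{lineno}: empty LF text")
            try:
                freq = int(cols[1])
            except ValueError:
                raise LFTableError(f"{path}:{lineno}: non-integer frequency {cols[1]!r}") from None
            if freq < 0:
                raise LFTableError(f"{path}:{lineno}: negative frequency {freq}")
            uri = cols[2] if len(cols) == 3 and cols[2] else None
            records.append(LFRecord(lf_text, freq, uri))
    return records


def mint_lf_uri(lf_text: str, base_iri: str) -> str:
    """Mint a subject IRI for an LF without one: base IRI + percent-encoded text."""
    return base_iri + quote(lf_text, safe="")


def _check_iri(iri: str) -> URIRef:
    # N-Triples IRIREF forbids space, quotes, angle brackets and controls.
    bad = set(' <>"{}|^`\\') | {chr(c) for c in range(0x21)}
    if any(ch in bad for ch in iri):
        raise ValueError(f"IRI contains characters not encodable in N-Triples: {iri!r}")
    return URIRef(iri)


def write_sameas_ntriples(
    links: Sequence[Link],
    path: Union[str, Path],
    base_iri: str = "http://example.org/lf/",
) -> Path:
    """Write one ``owl:sameAs`` triple per link, sorted by LF text.

    Links without an ``lf_uri`` get one minted from *base_iri* with the LF
    text percent-encoded.  Output is deterministic and ends with a
    trailing newline (empty link list gives an empty file).
    """
    path = Path(path)
    lines = []
    for link in sorted(links, key=lambda l: (l.lf_text, l.title.resource_uri)):
        subj = link.lf_uri if link.lf_uri else mint_lf_uri(link.lf_text, base_iri)
        s = _check_iri(subj)
        o = _check_iri(link.title.resource_uri)
        lines.append(f"{s.n3()} {OWL_SAMEAS.n3()} {o.n3()} .\n")
    path.write_text("".join(lines), encoding="utf-8")
    return path


def read_sameas_pairs(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """Read back (subject, object) IRI pairs of owl:sameAs triples, in file order."""
    pairs = []
    for _lineno, (s, p, o) in _parse_ntriples_lines(Path(path)):
        if p == OWL_SAMEAS:
            pairs.append((str(s), str(o)))
    return pairs


def write_lf_table(records: Sequence[LFRecord], path: Union[str, Path]) -> Path:
    """Write an LF table TSV (inverse of :func:`read_lf_table`, no header)."""
    path = Path(path)
    lines = []
    for rec in records:
        if "\t" in rec.lf_text or "\n" in rec.lf_text:
            raise LFTableError(f"LF text contains tab/newline: {rec.lf_text!r}")
        cols = [rec.lf_text, str(rec.frequency)]
        if rec.lf_uri:
            cols.append(rec.lf_uri)
        lines.append("\t".join(cols) + "\n")
    path.write_text("".join(lines), encoding="utf-8")
    return path


def write_ntriples_labels(
    titles: Sequence[Title], path: Union[str, Path], language: str = "en"
) -> Path:
    """Write titles as rdfs:label N-Triples with language-tagged literals."""
    path = Path(path)
    lines = []
    for t in titles:
        s = _check_iri(t.resource_uri)
        o = Literal(t.label, lang=language)
        lines.append(f"{s.n3()} {RDFS_LABEL.n3()} {o.n3()} .\n")
    path.write_text("".join(lines), encoding="utf-8")
    return path
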
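"""Keyed title indexes and per-long-form link selection.

The matcher links each long form (LF) to at most one title.  Titles are
indexed once per keyer; an LF's candidates are the titles sharing its key
(or, for the exact baseline, the titles whose label is string-identical).
When several candidates share a key the tie-break order is: shortest
label, then case ratio closest to the LF's, then lexicographically
smallest label — a total order, so linking is deterministic.

The *combined* method accepts a link if either the fingerprint or the
n-gram fingerprint keyer finds a match; when the two keyers disagree the
same tie-break order decides between their winners.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence
from urllib.parse import urlsplit

from .keying import Keyer, fingerprint_key, ngram_fingerprint_key
from .normalise import Lexicon, normalise_term

__all__ = [
    "Method",
    "Title",
    "TitleIndex",
    "Link",
    "LinkOutcome",
    "build_title_index",
    "match_with_method",
    "select_best_title",
    "combined_link",
    "link_one",
    "link_dataset",
    "case_ratio",
]


class Method(str, enum.Enum):
    EXACT = "exact"
    FINGERPRINT = "fingerprint"
    NGRAM = "ngram"
    COMBINED = "combined"


@dataclass(frozen=True)
class Title:
    """An encyclopedia entry label and its resource IRI."""

    label: str
    resource_uri: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("title label must be non-empty")
        parts = urlsplit(self.resource_uri)
        if not parts.scheme or not (parts.netloc or parts.path):
            raise ValueError(f"not a valid absolute IRI: {self.resource_uri!r}")


@dataclass(frozen=True)
class Link:
    """An accepted (LF, title) pair, serialisable as owl:sameAs."""

    lf_text: str
    lf_uri: Optional[str]
    title: Title
    method: Method


@dataclass(frozen=True)
class LinkOutcome:
    """Per-LF result: the record plus its accepted link, if any."""

    lf_text: str
    frequency: int
    lf_uri: Optional[str]
    link: Optional[Link]

    @property
    def linked(self) -> bool:
        return self.link is not None


class TitleIndex:
    """Per-keyer hash indexes over a title collection.

    Labels are normalised through the lexicon (when one is supplied)
    before keying; the raw labels are always retained for the exact
    baseline, which compares normalised strings verbatim.
    """

    def __init__(
        self,
        titles: Sequence[Title],
        keyers: Iterable[Keyer] = (Keyer.FINGERPRINT, Keyer.NGRAM_FINGERPRINT),
        lexicon: Optional[Lexicon] = None,
        n: int = 2,
    ) -> None:
        titles = list(titles)
        if not titles:
            raise ValueError("cannot index an empty title list")
        if n < 1:
            raise ValueError(f"n-gram size must be >= 1, got {n}")
        self.lexicon = lexicon
        self.n = n
        self.keyers = frozenset(keyers)
        self.n_titles = len(titles)
        self._exact: Dict[str, List[Title]] = {}
        self._by_key: Dict[Keyer, Dict[str, List[Title]]] = {k: {} for k in self.keyers}
        for title in titles:
            label = normalise_term(title.label, lexicon)
            self._exact.setdefault(label, []).append(title)
            if Keyer.FINGERPRINT in self.keyers:
                key = fingerprint_key(label)
                self._by_key[Keyer.FINGERPRINT].setdefault(key, []).append(title)
            if Keyer.NGRAM_FINGERPRINT in self.keyers:
                key = ngram_fingerprint_key(label, n)
                self._by_key[Keyer.NGRAM_FINGERPRINT].setdefault(key, []).append(title)

    def candidates(self, lf_text: str, method: Method) -> List[Title]:
        """All titles matching *lf_text* under *method* (unordered)."""
        lf = normalise_term(lf_text, self.lexicon)
        if method is Method.EXACT:
            return list(self._exact.get(lf, []))
        if method is Method.FINGERPRINT:
            keyer = Keyer.FINGERPRINT
            key = fingerprint_key(lf)
        elif method is Method.NGRAM:
            keyer = Keyer.NGRAM_FINGERPRINT
            key = ngram_fingerprint_key(lf, self.n)
        else:
            raise ValueError("candidates() takes a single-keyer method; use combined_link")
        if keyer not in self.keyers:
            raise ValueError(f"index was not built with keyer {keyer.value}")
        return list(self._by_key[keyer].get(key, []))


def build_title_index(
    titles: Sequence[Title],
    keyers: Iterable[Keyer] = (Keyer.FINGERPRINT, Keyer.NGRAM_FINGERPRINT),
    lexicon: Optional[Lexicon] = None,
    n: int = 2,
) -> TitleIndex:
    """Build a :class:`TitleIndex` (thin functional wrapper)."""
    return TitleIndex(titles, keyers=keyers, lexicon=lexicon, n=n)


def match_with_method(lf_text: str, index: TitleIndex, method: Method) -> List[Title]:
    """Candidate titles for *lf_text*; selection is left to select_best_title."""
    return index.candidates(lf_text, method)


def case_ratio(s: str) -> float:
    """Uppercase letters as a proportion of alphabetic letters (0 if none).

    A proportion rather than an upper:lower quotient so that all-caps
    strings are well-defined; it induces the same ordering wherever the
    quotient is defined.
    """
    alpha = sum(1 for ch in s if ch.isalpha())
    if alpha == 0:
        return 0.0
    return sum(1 for ch in s if ch.isupper()) / alpha


def select_best_title(candidates: Sequence[Title], lf_text: str) -> Title:
    """Pick one title: shortest label, then case ratio closest to the LF's,
    then lexicographically smallest label."""
    if not candidates:
        raise ValueError("select_best_title requires at least one candidate")
    target = case_ratio(lf_text)
    return min(
        candidates,
        key=lambda t: (len(t.label), abs(case_ratio(t.label) - target), t.label),
    )


def link_one(
    lf_text: str,
    index: TitleIndex,
    method: Method,
    lf_uri: Optional[str] = None,
) -> Optional[Link]:
    """Link a single LF under *method*, or return None if no match."""
    if method is Method.COMBINED:
        return combined_link(lf_text, index, lf_uri=lf_uri)
    cands = index.candidates(lf_text, method)
    if not cands:
        return None
    return Link(lf_text, lf_uri, select_best_title(cands, lf_text), method)


def combined_link(
    lf_text: str, index: TitleIndex, lf_uri: Optional[str] = None
) -> Optional[Link]:
    """Accept a link if either keyer matches; resolve disagreements by the
    shortest-label / case-ratio / lexicographic tie-break."""
    fp_cands = index.candidates(lf_text, Method.FINGERPRINT)
    ng_cands = index.candidates(lf_text, Method.NGRAM)
    best_fp = select_best_title(fp_cands, lf_text) if fp_cands else None
    best_ng = select_best_title(ng_cands, lf_text) if ng_cands else None
    if best_fp is None and best_ng is None:
        return None
    if best_fp is None:
        chosen = best_ng
    elif best_ng is None or best_fp == best_ng:
        chosen = best_fp
    else:
        chosen = select_best_title([best_fp, best_ng], lf_text)
    return Link(lf_text, lf_uri, chosen, Method.COMBINED)


def link_dataset(lfs: Sequence, index: TitleIndex, method: Method) -> List[LinkOutcome]:
    """Link every LF record, producing one outcome per record in input order.

    *lfs* is any sequence of objects with ``lf_text``, ``frequency`` and
    ``lf_uri`` attributes (see :class:`lflink.rdf_io.LFRecord`).
    """
    outcomes = []
    for rec in lfs:
        link = link_one(rec.lf_text, index, method, lf_uri=rec.lf_uri)
        outcomes.append(LinkOutcome(rec.lf_text, rec.frequency, rec.lf_uri, link))
    return outcomes
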
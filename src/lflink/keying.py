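"""Key-collision keying functions.

A key-collision method reduces every string to a canonical *key*; two
strings are considered a match iff their keys are byte-identical.  This
makes approximate matching linear in the number of strings: build a hash
map from key to strings, and every bucket is a match group.

Two keyers are provided:

* **fingerprint** — whitespace-token based: lowercase, strip punctuation,
  transliterate to ASCII, then sort and de-duplicate the tokens.  Invariant
  to token order, letter case, punctuation and token repetition.
* **n-gram fingerprint** — character n-gram based: the key is the sorted,
  de-duplicated set of character n-grams of the cleaned, whitespace-free
  string, concatenated.  More permissive than the token fingerprint (it
  also absorbs small internal rearrangements and repeated-letter runs).
"""

from __future__ import annotations

import enum
import unicodedata
from dataclasses import dataclass
from typing import Optional

__all__ = ["Keyer", "KeyedString", "fingerprint_key", "ngram_fingerprint_key"]


class Keyer(str, enum.Enum):
    """Available key-collision keyers."""

    FINGERPRINT = "fingerprint"
    NGRAM_FINGERPRINT = "ngram_fingerprint"


def _is_punct_or_control(ch: str) -> bool:
    # All Unicode punctuation categories (P*) plus control/format/other (C*).
    return unicodedata.category(ch)[0] in "PC"


def _asciify(s: str) -> str:
    # NFKD-decompose so accented letters split into base letter + combining
    # mark, then drop everything that does not survive ASCII encoding.
    return unicodedata.normalize("NFKD", s).encode("ascii", "ignore").decode("ascii")


def fingerprint_key(term: str) -> str:
    """Return the whitespace-token fingerprint key of *term*.

    Steps, in order: trim; lowercase; remove punctuation and control
    characters; transliterate accented letters to ASCII; split on
    whitespace runs; sort tokens; remove duplicate tokens; join with a
    single space.  Total on all unicode strings; the empty string keys
    to the empty string.

    >>> fingerprint_key("RNA polymerase II")
    'ii polymerase rna'
    """
    s = term.strip().lower()
    s = "".join(ch for ch in s if not _is_punct_or_control(ch))
    s = _asciify(s)
    return " ".join(sorted(set(s.split())))


def ngram_fingerprint_key(term: str, n: int = 2) -> str:
    """Return the character n-gram fingerprint key of *term*.

    Steps: lowercase; remove punctuation, control characters and all
    whitespace; transliterate to ASCII; enumerate contiguous character
    n-grams; sort; de-duplicate; concatenate.  If the cleaned string is
    shorter than ``n`` the cleaned string itself is the key, so very
    short strings do not all collide on an empty key.

    >>> ngram_fingerprint_key("RNA polymerase II", 2)
    'apaseieriilymenaolporarnseym'
    """
    if n < 1:
        raise ValueError(f"n-gram size must be >= 1, got {n}")
    s = term.lower()
    s = "".join(ch for ch in s if not (_is_punct_or_control(ch) or ch.isspace()))
    s = _asciify(s)
    if len(s) < n:
        return s
    return "".join(sorted({s[i : i + n] for i in range(len(s) - n + 1)}))


@dataclass(frozen=True)
class KeyedString:
    """A string together with its key under a chosen keyer."""

    original: str
    key: str
    keyer: Keyer
    n: Optional[int] = None

    @classmethod
    def make(cls, original: str, keyer: Keyer, n: int = 2) -> "KeyedString":
        if keyer is Keyer.FINGERPRINT:
            return cls(original, fingerprint_key(original), keyer)
        return cls(original, ngram_fingerprint_key(original, n), keyer, n)
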
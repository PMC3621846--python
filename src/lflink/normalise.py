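"""Lexicon-based term normalisation.

Biomedical terms vary by inflection ("kinases" vs "kinase") and regional
spelling ("oesophageal" vs "esophageal").  A variant lexicon — a table of
(variant, base form) pairs in the style of the UMLS SPECIALIST Lexicon
agreement/inflection and spelling-variant files — maps such variants to a
single base form before keying, so that variant pairs collide.

Normalisation is two-stage: if the whole (lowercased) term is a known
variant it is replaced outright; otherwise each whitespace-separated token
that is a known variant is replaced individually, preserving everything
else byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple, Union

__all__ = ["Lexicon", "LexiconError", "load_lexicon", "normalise_term"]

_WS_SPLIT = re.compile(r"(\s+)")


class LexiconError(ValueError):
    """Raised for malformed, conflicting or cyclic lexicon content."""


@dataclass
class Lexicon:
    """Variant -> base-form mapping with chains resolved to fixed points.

    Keys of :attr:`base_of` are lowercased variant strings; values keep the
    base form's stored casing.  After construction no value's lowercase is
    itself a key, so lookup never needs to iterate.
    """

    base_of: Dict[str, str] = field(default_factory=dict)
    source_path: Optional[Path] = None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[Tuple[str, str]],
        source_path: Optional[Path] = None,
        max_hops: int = 16,
    ) -> "Lexicon":
        raw: Dict[str, str] = {}
        for variant, base in pairs:
            v = variant.strip().lower()
            b = base.strip()
            if not v or not b:
                raise LexiconError(f"empty variant or base in pair ({variant!r}, {base!r})")
            if v == b.lower():
                raise LexiconError(f"variant {variant!r} maps to itself")
            if v in raw and raw[v] != b:
                raise LexiconError(
                    f"conflicting bases for variant {variant!r}: {raw[v]!r} vs {b!r}"
                )
            raw[v] = b
        resolved = {v: _resolve_chain(v, raw, max_hops) for v in raw}
        return cls(resolved, source_path)

    def lookup(self, term: str) -> Optional[str]:
        """Base form of *term* if its lowercase is a known variant, else None."""
        return self.base_of.get(term.lower())

    def __len__(self) -> int:
        return len(self.base_of)


def _resolve_chain(variant: str, raw: Dict[str, str], max_hops: int) -> str:
    seen = {variant}
    base = raw[variant]
    hops = 1
    while base.lower() in raw:
        nxt = base.lower()
        if nxt in seen:
            raise LexiconError(f"cyclic variant chain through {variant!r}")
        if hops >= max_hops:
            raise LexiconError(f"variant chain from {variant!r} exceeds {max_hops} hops")
        seen.add(nxt)
        base = raw[nxt]
        hops += 1
    return base


def load_lexicon(path: Union[str, Path], max_hops: int = 16) -> Lexicon:
    """Load a two-column TSV lexicon (variant <TAB> base form).

    UTF-8; blank lines and lines starting with ``#`` are skipped.  Chains
    (a->b, b->c) are resolved to their terminal base form at load time;
    cycles and conflicting duplicate rows are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    pairs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            cols = stripped.split("\t")
            if len(cols) != 2:
                raise LexiconError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            pairs.append((cols[0], cols[1]))
    try:
        return Lexicon.from_pairs(pairs, source_path=path, max_hops=max_hops)
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from exc


def normalise_term(term: str, lexicon: Optional[Lexicon]) -> str:
    """Map *term* to its base form using *lexicon*.

    Stage 1: whole-string lookup on the lowercased term.  Stage 2 (only if
    stage 1 misses): replace each whitespace-separated token whose
    lowercase is a known variant by its base form, keeping token order and
    all whitespace unchanged.  A term with no lexicon hits is returned
    unchanged.  Idempotent for lexicons whose chains are closed.
    """
    if lexicon is None or not lexicon.base_of:
        return term
    whole = lexicon.lookup(term)
    if whole is not None:
        return whole
    parts = _WS_SPLIT.split(term)
    out = []
    hit = False
    for part in parts:
        if part and not part.isspace():
            base = lexicon.lookup(part)
            if base is not None:
                out.append(base)
                hit = True
                continue
        out.append(part)
    return "".join(out) if hit else term
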
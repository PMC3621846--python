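"""Synthetic gold-standard corpora for the linking pipeline.

Real inputs (a MEDLINE-derived long-form table, a DBpedia-style label
file, a SPECIALIST-style variant lexicon) are large and licence-bound, so
every stage of the pipeline is exercised instead on generated corpora with
known gold links.  Each synthetic *concept* yields one LF; with a
bin-dependent presence probability the concept also yields a title,
derived from the LF by one of the lexical-variant operators observed in
real LF/title pairs:

* ``identical`` — the title equals the LF verbatim.
* ``case_change`` — letter cases flipped (recoverable by any keyer).
* ``token_reorder`` — word order permuted (recoverable: fingerprint keys
  sort tokens).
* ``punctuation_change`` — hyphens inserted or removed (recoverable:
  keyers strip punctuation).
* ``inflection`` — one token replaced by an inflected form listed in the
  generated lexicon (recoverable only with normalisation on).
* ``additive_term`` — a domain head noun appended ("... syndrome",
  "... protein"); not recoverable by key collision.
* ``abbreviation_substitution`` — the title is the initialism of the LF;
  not recoverable by key collision.
* ``synonym_swap`` — one token replaced by an unrelated word; not
  recoverable without a synonym resource.

The presence probability follows the absence model
``1 - y = exp(-(a*x + b))`` in the merged frequency-bin index x, and
frequencies are drawn from a discretised Pareto tail, so the binning /
link-ratio / regression stages can be validated end to end.  All
randomness flows from a single seed; equal seeds give byte-identical
corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple
from urllib.parse import quote

from .analysis import assign_bin, presence_probability
from .keying import fingerprint_key, ngram_fingerprint_key
from .matcher import Title
from .normalise import Lexicon, normalise_term
from .rdf_io import LFRecord, write_lf_table, write_ntriples_labels

__all__ = [
    "VARIANT_CLASSES",
    "RECOVERABLE_CLASSES",
    "SyntheticConfig",
    "GoldCorpus",
    "generate_corpus",
    "apply_variant",
    "write_corpus",
]

VARIANT_CLASSES: Tuple[str, ...] = (
    "identical",
    "case_change",
    "token_reorder",
    "punctuation_change",
    "inflection",
    "additive_term",
    "abbreviation_substitution",
    "synonym_swap",
)

#: Strata a key-collision matcher (with the lexicon) recovers completely.
RECOVERABLE_CLASSES = frozenset(
    {"identical", "case_change", "token_reorder", "punctuation_change", "inflection"}
)

#: Default mix: variant classes that key collision absorbs dominate, with a
#: modest tail of the harder categories (additive terms, abbreviations,
#: synonyms) that account for most residual false negatives in practice.
DEFAULT_VARIANT_MIX: Dict[str, float] = {
    "identical": 0.25,
    "case_change": 0.15,
    "token_reorder": 0.15,
    "punctuation_change": 0.15,
    "inflection": 0.10,
    "additive_term": 0.08,
    "abbreviation_substitution": 0.07,
    "synonym_swap": 0.05,
}

_SYLLABLES = (
    "ba", "cro", "din", "fex", "gly", "lom", "mer", "nix", "pro", "sta",
    "tri", "vex", "zym", "cul", "ost", "ren", "pla", "qui", "dor", "mul",
)

_ADDITIVE_TERMS = ("syndrome", "protein", "cell", "receptor", "pathway", "factor")


@dataclass
class SyntheticConfig:
    """Parameters of the corpus generator.

    ``presence_a`` and ``presence_b`` are the coefficients of the absence
    model exp(-(a*x + b)) over the merged bin index; ``pareto_alpha``
    shapes the heavy-tailed occurrence-frequency sampler over
    [``freq_min``, ``freq_max``].
    """

    n_concepts: int = 600
    seed: int = 0
    variant_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VARIANT_MIX))
    presence_a: float = 0.2
    presence_b: float = 0.92
    frequency_model: str = "pareto"  # "pareto" (realistic tail) or "stratified" (equal bins)
    pareto_alpha: float = 0.8
    freq_min: int = 10
    freq_max: int = 5000
    n_distractors: Optional[int] = None  # default: n_concepts // 2
    lf_base_iri: str = "http://example.org/lf/"
    title_base_iri: str = "http://example.org/title/"

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        unknown = set(self.variant_mix) - set(VARIANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown variant classes: {sorted(unknown)}")
        if any(p < 0 for p in self.variant_mix.values()):
            raise ValueError("variant-mix proportions must be non-negative")
        total = sum(self.variant_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant-mix proportions must sum to 1, got {total}")
        if self.frequency_model not in ("pareto", "stratified"):
            raise ValueError(f"unknown frequency model: {self.frequency_model!r}")


@dataclass
class GoldCorpus:
    """A generated corpus plus its ground truth."""

    lfs: List[LFRecord]
    titles: List[Title]
    lexicon: Lexicon
    lexicon_pairs: List[Tuple[str, str]]
    gold_links: Set[Tuple[str, str]]
    strata: Dict[str, str]  # lf_text -> variant class
    config: SyntheticConfig


def _random_word(rng: random.Random, n_syllables: Tuple[int, int] = (2, 3)) -> str:
    k = rng.randint(*n_syllables)
    return "".join(rng.choice(_SYLLABLES) for _ in range(k))


def _build_vocab(rng: random.Random, size: int, taken: Set[str]) -> List[str]:
    """Distinct words, none of which is another's plural (+'s') form."""
    vocab: List[str] = []
    seen = set(taken)
    while len(vocab) < size:
        w = _random_word(rng)
        if w in seen or (w + "s") in seen or (w.endswith("s") and w[:-1] in seen):
            continue
        seen.add(w)
        vocab.append(w)
    return vocab


def apply_variant(
    term: str,
    op: str,
    rng: random.Random,
    inflection_pairs: Optional[Mapping[str, str]] = None,
) -> str:
    """Apply one lexical-variant operator to *term*.

    *inflection_pairs* maps base token -> inflected token; when absent the
    inflection operator pluralises a random token with ``+"s"``.
    """
    tokens = term.split(" ")
    if op == "identical":
        return term
    if op == "case_change":
        flipped = "".join(
            ch.swapcase() if ch.isalpha() and rng.random() < 0.5 else ch for ch in term
        )
        return flipped if flipped != term else term.swapcase()
    if op == "token_reorder":
        if len(set(tokens)) < 2:
            return term
        perm = tokens[:]
        while perm == tokens:
            rng.shuffle(perm)
        return " ".join(perm)
    if op == "punctuation_change":
        if "-" in term:
            return term.replace("-", "")
        # hyphenate inside a multi-character token
        idx = [i for i, t in enumerate(tokens) if len(t) >= 2]
        if not idx:
            return term + "-"
        i = rng.choice(idx)
        t = tokens[i]
        pos = rng.randint(1, len(t) - 1)
        tokens[i] = t[:pos] + "-" + t[pos:]
        return " ".join(tokens)
    if op == "inflection":
        if inflection_pairs:
            for i, t in enumerate(tokens):
                if t in inflection_pairs:
                    tokens[i] = inflection_pairs[t]
                    return " ".join(tokens)
            return term
        i = rng.randrange(len(tokens))
        tokens[i] = tokens[i] + "s"
        return " ".join(tokens)
    if op == "additive_term":
        return term + " " + rng.choice(_ADDITIVE_TERMS)
    if op == "abbreviation_substitution":
        return "".join(t[0] for t in tokens if t).upper()
    if op == "synonym_swap":
        i = rng.randrange(len(tokens))
        tokens[i] = _random_word(rng)
        return " ".join(tokens)
    raise ValueError(f"unknown variant operator: {op!r}")


_BIN_RANGES = (
    (10, 49), (50, 99), (100, 199), (200, 299), (300, 399), (400, 499),
    (500, 599), (600, 699), (700, 799), (800, 899), (900, 999), (1000, None),
)


def _sample_frequency(rng: random.Random, cfg: SyntheticConfig, concept_idx: int) -> int:
    if cfg.frequency_model == "stratified":
        # Equal occupancy per bin: bin by round-robin, uniform within range.
        lo, hi = _BIN_RANGES[concept_idx % len(_BIN_RANGES)]
        return rng.randint(lo, hi if hi is not None else max(cfg.freq_max, 1000))
    # Discretised Pareto: P(F >= f) = (f/freq_min)^-alpha, capped at freq_max.
    u = rng.random()
    f = int(cfg.freq_min * (1.0 - u) ** (-1.0 / cfg.pareto_alpha))
    return min(max(f, cfg.freq_min), cfg.freq_max)


def _merged_x(frequency: int) -> int:
    b = assign_bin(frequency)
    return 0 if b <= 2 else b - 2


def generate_corpus(config: SyntheticConfig) -> GoldCorpus:
    """Generate a corpus with known gold links, deterministically by seed.

    Concept base terms are built from a synthetic vocabulary under two
    uniqueness guarantees: no two concepts share a fingerprint or bigram
    fingerprint key, and distractor titles collide with no LF under
    either keyer.  False positives against the gold standard can
    therefore arise only from the variant operators themselves.
    """
    rng = random.Random(config.seed)
    n_distract = (
        config.n_distractors if config.n_distractors is not None else config.n_concepts // 2
    )

    vocab = _build_vocab(rng, max(40, config.n_concepts // 4), taken=set(_ADDITIVE_TERMS))

    # Concept base terms: 2-4 distinct tokens, unique under both keyers.
    concepts: List[str] = []
    used_fp: Set[str] = set()
    used_ng: Set[str] = set()
    attempts = 0
    while len(concepts) < config.n_concepts:
        attempts += 1
        if attempts > 200 * config.n_concepts:
            raise RuntimeError("vocabulary too small to generate distinct concepts")
        k = rng.randint(2, 4)
        tokens = rng.sample(vocab, k)
        term = " ".join(tokens)
        fp, ng = fingerprint_key(term), ngram_fingerprint_key(term, 2)
        if fp in used_fp or ng in used_ng:
            continue
        used_fp.add(fp)
        used_ng.add(ng)
        concepts.append(term)

    lexicon_pairs: List[Tuple[str, str]] = []
    pair_set: Set[Tuple[str, str]] = set()
    used_labels: Set[str] = set()
    lfs: List[LFRecord] = []
    titles: List[Title] = []
    gold_links: Set[Tuple[str, str]] = set()
    strata: Dict[str, str] = {}
    classes = list(config.variant_mix.keys())
    weights = [config.variant_mix[c] for c in classes]

    for i, term in enumerate(concepts):
        stratum = rng.choices(classes, weights=weights, k=1)[0]
        freq = _sample_frequency(rng, config, i)
        lf_uri = config.lf_base_iri + quote(term, safe="")
        lfs.append(LFRecord(term, freq, lf_uri))
        strata[term] = stratum
        y = presence_probability(_merged_x(freq), config.presence_a, config.presence_b)
        if rng.random() >= y:
            continue  # concept absent from the encyclopedia
        if stratum == "inflection":
            tok = rng.choice(term.split(" "))
            inflected = tok + "s"
            label = apply_variant(term, stratum, rng, inflection_pairs={tok: inflected})
            if (inflected, tok) not in pair_set:
                pair_set.add((inflected, tok))
                lexicon_pairs.append((inflected, tok))
        else:
            label = apply_variant(term, stratum, rng)
        # Distinct concepts can share an initialism; disambiguate the label
        # (real encyclopedias do the same) while keeping it key-distinct.
        k = 2
        base_label = label
        while label in used_labels:
            label = f"{base_label}-{k}"
            k += 1
        used_labels.add(label)
        uri = config.title_base_iri + quote(label.replace(" ", "_"), safe="")
        titles.append(Title(label, uri))
        gold_links.add((term, uri))

    lexicon = Lexicon.from_pairs(lexicon_pairs)

    # Distractor titles from a disjoint vocabulary, keyed apart from every LF.
    distractor_vocab = _build_vocab(rng, max(30, n_distract // 3), taken=set(vocab))
    guard = 0
    n_added = 0
    while n_added < n_distract:
        guard += 1
        if guard > 200 * max(n_distract, 1):
            raise RuntimeError("could not generate enough non-colliding distractors")
        k = rng.randint(1, 3)
        label = " ".join(rng.sample(distractor_vocab, k)).capitalize()
        norm = normalise_term(label, lexicon)
        fp, ng = fingerprint_key(norm), ngram_fingerprint_key(norm, 2)
        if fp in used_fp or ng in used_ng or label in used_labels:
            continue
        used_labels.add(label)
        used_fp.add(fp)
        used_ng.add(ng)
        uri = config.title_base_iri + quote(label.replace(" ", "_"), safe="")
        titles.append(Title(label, uri))
        n_added += 1

    return GoldCorpus(
        lfs=lfs,
        titles=titles,
        lexicon=lexicon,
        lexicon_pairs=lexicon_pairs,
        gold_links=gold_links,
        strata=strata,
        config=config,
    )


def write_corpus(corpus: GoldCorpus, outdir) -> Dict[str, Path]:
    """Write the corpus in the pipeline's input formats plus gold files.

    Produces ``lfs.tsv``, ``titles.nt``, ``lexicon.tsv``,
    ``gold_links.tsv`` and ``strata.tsv`` under *outdir*.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lfs": outdir / "lfs.tsv",
        "titles": outdir / "titles.nt",
        "lexicon": outdir / "lexicon.tsv",
        "gold_links": outdir / "gold_links.tsv",
        "strata": outdir / "strata.tsv",
    }
    write_lf_table(corpus.lfs, paths["lfs"])
    write_ntriples_labels(corpus.titles, paths["titles"])
    lex_lines = [f"{v}\t{b}\n" for v, b in sorted(corpus.lexicon_pairs)]
    paths["lexicon"].write_text("".join(lex_lines), encoding="utf-8")
    gold_lines = [f"{lf}\t{uri}\n" for lf, uri in sorted(corpus.gold_links)]
    paths["gold_links"].write_text("".join(gold_lines), encoding="utf-8")
    strata_lines = [f"{lf}\t{cls}\n" for lf, cls in sorted(corpus.strata.items())]
    paths["strata"].write_text("".join(strata_lines), encoding="utf-8")
    return paths
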
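"""Title indexing, tie-breaking and link production."""

import pytest

import lflink as L
from lflink.keying import Keyer
from lflink.matcher import (
    Link,
    Method,
    Title,
    build_title_index,
    case_ratio,
    combined_link,
    link_dataset,
    link_one,
    match_with_method,
    select_best_title,
)
from lflink.normalise import Lexicon
from lflink.rdf_io import LFRecord

U = "http://example.org/title/"


def _titles(*labels):
    return [Title(lab, U + lab.replace(" ", "_")) for lab in labels]


def test_title_validation():
    with pytest.raises(ValueError):
        Title("", U + "x")
    with pytest.raises(ValueError):
        Title("ok", "not an iri")


def test_empty_title_list_rejected():
    with pytest.raises(ValueError):
        build_title_index([])


def test_index_retrieves_shared_fingerprint_bucket():
    idx = build_title_index(_titles("B A", "a b", "c"))
    cands = match_with_method("A B", idx, Method.FINGERPRINT)
    assert {t.label for t in cands} == {"B A", "a b"}


def test_index_with_lexicon_keys_normalised_label():
    lex = Lexicon.from_pairs([("kinases", "kinase")])
    idx = build_title_index(_titles("Mitogen-activated protein kinases"), lexicon=lex)
    cands = match_with_method("mitogen-activated protein kinase kinase", idx, Method.FINGERPRINT)
    assert len(cands) == 1


@pytest.mark.parametrize("method", [Method.EXACT, Method.FINGERPRINT, Method.NGRAM])
def test_additive_and_abbreviation_pairs_never_match(method):
    """Additive-term and abbreviation/LF variant pairs lie beyond key collision."""
    idx = build_title_index(_titles("C-Fos", "PD-1", "Bronchiolitis obliterans"))
    assert match_with_method("c-fos protein", idx, method) == []
    assert match_with_method("Programmed death-1", idx, method) == []
    assert match_with_method("bronchiolitis obliterans syndrome", idx, method) == []


def test_repeated_letter_words_collide_under_bigrams_only():
    idx = build_title_index(_titles("Rna polymerase iii"))
    assert [t.label for t in match_with_method("RNA polymerase II", idx, Method.NGRAM)] == [
        "Rna polymerase iii"
    ]
    assert match_with_method("RNA polymerase II", idx, Method.FINGERPRINT) == []


def test_exact_is_verbatim_and_case_sensitive():
    idx = build_title_index(_titles("RNA polymerase II"))
    assert match_with_method("RNA polymerase II", idx, Method.EXACT)
    assert match_with_method("rna polymerase ii", idx, Method.EXACT) == []


def test_select_best_title_prefers_shorter():
    cands = _titles("Natural killer T cell", "NKT")
    assert select_best_title(cands, "natural killer T").label == "NKT"


def test_select_best_title_breaks_length_tie_by_case_ratio():
    # LF ratio 5/15; "RNA Polymerase II" 6/15 beats "Rna polymerase ii" 1/15
    cands = _titles("Rna polymerase ii", "RNA Polymerase II")
    assert select_best_title(cands, "RNA polymerase II").label == "RNA Polymerase II"


def test_select_best_title_final_lexicographic_tie_break():
    cands = _titles("abc", "abd")  # equal length, equal (zero-upper) case ratio
    assert select_best_title(cands, "xyz").label == "abc"


def test_select_best_title_rejects_empty():
    with pytest.raises(ValueError):
        select_best_title([], "x")


def test_case_ratio_total_on_all_caps_and_no_letters():
    assert case_ratio("NKT") == 1.0
    assert case_ratio("123-") == 0.0


def test_combined_produces_the_kinase_false_positive():
    """The doubled-token LF is linked to the plural title — a known FP of the method."""
    lex = Lexicon.from_pairs([("kinases", "kinase")])
    idx = build_title_index(_titles("Mitogen-activated protein kinases"), lexicon=lex)
    link = combined_link("mitogen-activated protein kinase kinase", idx)
    assert link is not None
    assert link.title.label == "Mitogen-activated protein kinases"
    assert link.method is Method.COMBINED


def test_combined_none_when_no_keyer_matches():
    idx = build_title_index(_titles("Bronchiolitis obliterans"))
    assert combined_link("bronchiolitis obliterans syndrome", idx) is None


def test_combined_takes_single_method_result():
    idx = build_title_index(_titles("Rna polymerase iii"))  # ngram-only match
    link = combined_link("RNA polymerase II", idx)
    assert link is not None and link.title.label == "Rna polymerase iii"


def test_combined_disagreement_resolved_by_shorter_title():
    # fingerprint finds the reordered long title; bigrams also match the
    # whitespace-free short one; shorter wins.
    t_long = Title("polymerase RNA II", U + "long")
    t_short = Title("RNAPOLYMERASEII", U + "short")
    idx = build_title_index([t_long, t_short])
    link = combined_link("RNA polymerase II", idx)
    assert link is not None and link.title == t_short


def _records(corpus):
    return corpus.lfs


def test_link_dataset_order_and_one_link_per_lf(mixed_corpus, mixed_index):
    outcomes = link_dataset(_records(mixed_corpus), mixed_index, Method.COMBINED)
    assert [o.lf_text for o in outcomes] == [r.lf_text for r in mixed_corpus.lfs]
    assert len([o for o in outcomes if o.linked]) <= len(outcomes)


@pytest.mark.parametrize("single", [Method.FINGERPRINT, Method.NGRAM])
def test_combined_links_superset_of_single_keyers(mixed_corpus, mixed_index, single):
    combined = {
        o.lf_text for o in link_dataset(_records(mixed_corpus), mixed_index, Method.COMBINED)
        if o.linked
    }
    alone = {
        o.lf_text for o in link_dataset(_records(mixed_corpus), mixed_index, single)
        if o.linked
    }
    assert alone <= combined


def test_exact_links_subset_of_fingerprint(mixed_corpus, mixed_index):
    exact = {
        o.lf_text for o in link_dataset(_records(mixed_corpus), mixed_index, Method.EXACT)
        if o.linked
    }
    fp = {
        o.lf_text
        for o in link_dataset(_records(mixed_corpus), mixed_index, Method.FINGERPRINT)
        if o.linked
    }
    assert exact <= fp


def test_linking_is_deterministic(mixed_corpus, mixed_index):
    a = link_dataset(_records(mixed_corpus), mixed_index, Method.COMBINED)
    b = link_dataset(_records(mixed_corpus), mixed_index, Method.COMBINED)
    assert a == b


def test_index_without_requested_keyer_errors():
    idx = build_title_index(_titles("x y"), keyers=[Keyer.FINGERPRINT])
    with pytest.raises(ValueError):
        match_with_method("x", idx, Method.NGRAM)
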
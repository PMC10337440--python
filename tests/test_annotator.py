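"""Rule-based annotation scheme: worked examples, precedence, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paincorpus.annotator import (
    NA,
    annotate_document,
    classify_relevance,
    context_window,
    default_gazetteers,
    validate_annotation,
)
from paincorpus.lexicon import Document, default_lexicon, find_mentions

from conftest import ANNOTATION_EXAMPLES

LEX = default_lexicon()
GAZ = default_gazetteers()


def annotate_sentence(text):
    doc = Document(doc_id="d", text=text)
    anns = annotate_document(doc, LEX, GAZ)
    assert len(anns) >= 1
    return anns


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "sentence,keyword,labels", ANNOTATION_EXAMPLES,
        ids=[e[0][:30] for e in ANNOTATION_EXAMPLES])
    def test_example_sentences_reproduce_label_rows(
            self, sentence, keyword, labels):
        """Each guideline example yields exactly its documented labels."""
        anns = annotate_sentence(sentence)
        assert len(anns) == 1
        a = anns[0]
        assert a.mention.surface == keyword
        got = (a.correct, a.relevance, a.anatomy, a.character, a.management)
        assert got == labels

    def test_two_sentence_document(self):
        """Negated compound mention then a chronic located one."""
        anns = annotate_sentence("No headache today. Chronic back pain persists.")
        assert len(anns) == 2
        first, second = anns
        assert (first.relevance, first.anatomy, first.anatomy_location) == (
            "negated", "mentioned", "head")
        assert (second.relevance, second.anatomy_location,
                second.character) == ("relevant", "back", "chronic")

    def test_question_mark_mention_not_relevant(self):
        anns = annotate_sentence("?migraine")
        assert anns[0].relevance == "not_relevant"

    def test_pain_clinic_is_other_management(self):
        anns = annotate_sentence(
            "He was referred to the pain clinic for ongoing back pain")
        assert all(a.management == "other" for a in anns)
        # "ongoing" is never chronic
        assert all(a.character != "chronic" for a in anns)

    def test_sore_thumb_idiom_not_relevant(self):
        anns = annotate_sentence("He sticks out like a sore thumb")
        assert anns[0].relevance == "not_relevant"

    def test_period_pain_is_other_character(self):
        a = annotate_sentence("She reports period pain this week")[0]
        assert a.relevance == "relevant"
        assert a.character == "other"

    def test_inanimate_burn_referent(self):
        a = annotate_sentence("There were burn marks on the door")[0]
        assert a.correct == "no"
        assert a.relevance == NA


class TestContextWindow:
    def _mention(self, doc):
        return find_mentions(doc, LEX)[0]

    def test_bounded_both_sides(self):
        doc = Document(
            doc_id="d", text="Seen today. She is in constant pain. Plan made.")
        w = context_window(doc, self._mention(doc))
        assert w.text == "She is in constant pain."

    def test_single_sentence_is_whole_text(self):
        doc = Document(doc_id="d", text="She is in constant pain")
        w = context_window(doc, self._mention(doc))
        assert w.text == doc.text

    def test_unbroken_line_capped_at_300(self):
        doc = Document(doc_id="d", text="x" * 500 + " pain " + "y" * 500)
        w = context_window(doc, self._mention(doc))
        assert w.mention_start <= 300
        assert len(w.text) - w.mention_end <= 300

    def test_newline_is_boundary(self):
        doc = Document(doc_id="d", text="no issues\nchronic pain noted")
        m = self._mention(doc)
        w = context_window(doc, m)
        assert w.text == "chronic pain noted"

    def test_foreign_mention_rejected(self):
        doc = Document(doc_id="d", text="pain")
        other = Document(doc_id="e", text="worse pain")
        m = self._mention(other)
        with pytest.raises(ValueError, match="does not belong"):
            context_window(doc, m)


class TestPrecedence:
    def _relevance(self, text):
        doc = Document(doc_id="d", text=text)
        m = find_mentions(doc, LEX)[0]
        return classify_relevance(m, context_window(doc, m), GAZ)

    def test_uncertainty_outranks_negation(self):
        # both a "?" and a negation trigger: uncertainty wins
        assert self._relevance("not sure, ?pain") == "not_relevant"

    def test_experiencer_outranks_hypothetical_and_negation(self):
        assert self._relevance("his mother is not in pain") == "not_relevant"

    def test_negation_window_is_six_tokens(self):
        assert self._relevance("no sign at all of further pain") == "negated"
        assert self._relevance(
            "no x x x x x x pain") == "relevant"  # trigger 7 tokens back

    def test_negation_frames(self):
        assert self._relevance("denies chest pain") == "negated"
        assert self._relevance("she is pain free") == "negated"


# an independent interpreter of the relevance rules, used as oracle
def oracle_relevance(text, start, end, gaz):
    import re as _re

    before_text, after_text = text[:start], text[end:]
    if before_text.rstrip()[-1:] == "?" or after_text.lstrip()[:1] == "?":
        return "not_relevant"
    tok = [(m.group(0).lower(), m.start()) for m in
           _re.finditer(r"[^\W\d_]+", text)]
    idx = next(i for i, (_, s) in enumerate(tok) if s == start)
    before = [t for t, _ in tok[:idx]]
    if set(before) & gaz.experiencer_triggers:
        return "not_relevant"
    lowered = text.lower()
    for trig in gaz.hypothetical_triggers:
        present = trig in lowered if " " in trig else trig in [t for t, _ in tok]
        if present:
            return "not_relevant"
    singles = {t for t in gaz.negation_triggers if " " not in t}
    if set(before[-gaz.negation_window:]) & singles:
        return "negated"
    if any(t in lowered for t in gaz.negation_triggers if " " in t):
        return "negated"
    after = [t for t, _ in tok[idx + 1:]]
    if "no" in before and "reported" in after[:2]:
        return "negated"
    if after[:1] == ["free"]:
        return "negated"
    return "relevant"


TOKEN_POOL = ["no", "not", "denies", "if", "afraid", "mother", "friend",
              "reported", "free", "the", "patient", "reports", "ongoing",
              "today", "again", "severe", "clinic", "review", "stable"]


@settings(max_examples=300, deadline=None)
@given(
    before=st.lists(st.sampled_from(TOKEN_POOL), max_size=9),
    after=st.lists(st.sampled_from(TOKEN_POOL), max_size=9),
    qmark=st.sampled_from(["", "?", "? "]),
)
def test_relevance_matches_exhaustive_interpreter(before, after, qmark):
    """classify_relevance agrees with an independent rule interpreter on
    short windows built from every trigger/position combination."""
    text = " ".join(before + ["pain"]) + qmark
    if after:
        text += ("" if qmark else " ") + " ".join(after)
    doc = Document(doc_id="d", text=text)
    mentions = [m for m in find_mentions(doc, LEX) if m.surface == "pain"]
    m = mentions[0]
    w = context_window(doc, m)
    # restrict to windows that span the whole text so both sides see
    # identical context
    if w.text != text:
        return
    assert classify_relevance(m, w, GAZ) == oracle_relevance(
        text, m.start, m.end, GAZ)


RELEVANT_TEMPLATES = [
    "She reports ongoing pain today",
    "The patient describes severe backache",
    "He complains of soreness again",
]


@pytest.mark.parametrize("sentence", RELEVANT_TEMPLATES)
def test_negation_monotonicity(sentence):
    """Prepending "There is no " flips a trigger-free relevant mention to
    negated and never changes correctness."""
    base = annotate_sentence(sentence)[0]
    assert base.relevance == "relevant"
    flipped = annotate_sentence("There is no " + sentence.lower())[0]
    assert flipped.correct == base.correct == "yes"
    assert flipped.relevance == "negated"


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_structural_zeroing_on_random_corpora(seed):
    """correct == no forces every downstream attribute to n/a."""
    from paincorpus.synthetic import SyntheticConfig, generate_corpus

    corpus = generate_corpus(SyntheticConfig(
        seed=seed, n_patients=2, words_per_doc_mean=60.0, incorrect_rate=0.4))
    for doc in corpus.documents:
        for a in annotate_document(doc, LEX, GAZ):
            validate_annotation(a)
            if a.correct == "no":
                assert (a.relevance, a.anatomy, a.character,
                        a.management) == (NA, NA, NA, NA)
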
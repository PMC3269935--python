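"""Segmentation, matching, scoring and evidence selection."""

import pytest

from piare.imt_dictionary import (
    DictionaryEntry,
    build_dictionary,
    parse_interaction_branch,
)
from piare.imt_pipeline import (
    EvidenceRecord,
    Hit,
    ScoredHit,
    SentenceRecord,
    crop_to_evidence,
    focus_score,
    match,
    match_tokens,
    normalize_and_filter,
    resolve_overlaps,
    score1,
    score2,
    score3,
    segment_and_strip,
    select_evidence,
)


@pytest.fixture
def dictionary(obo_path):
    return build_dictionary(parse_interaction_branch(obo_path))


def _sentence(text, index=0, is_method=False):
    return SentenceRecord(
        index=index, text=text, stemmed=match_tokens(text), is_method=is_method
    )


class TestSegmentAndStrip:
    def test_references_heading_drops_tail(self):
        text = (
            "We measured binding. The assay was repeated.\n"
            "References\n"
            "Smith J, Doe A (2004) Old paper. J Biol 1:1-2.\n"
            "Jones B (2005) Другая. Proc 2:3-4.\n"
        )
        sentences = segment_and_strip(text)
        assert [s.text for s in sentences] == [
            "We measured binding.", "The assay was repeated.",
        ]
        assert [s.index for s in sentences] == [0, 1]

    def test_author_list_regex_fallback(self):
        text = (
            "We measured binding.\n"
            "Smith J, Doe AB, Roe C. (2004) A reference without heading.\n"
        )
        sentences = segment_and_strip(text)
        assert [s.text for s in sentences] == ["We measured binding."]

    def test_single_sentence_passthrough(self):
        sentences = segment_and_strip("Binding was observed.")
        assert len(sentences) == 1
        assert sentences[0].text == "Binding was observed."

    def test_empty_text(self):
        assert segment_and_strip("") == []

    def test_focus_labels_attached_by_index(self):
        text = "First sentence here. Second sentence here."
        sentences = segment_and_strip(text, focus={1: True})
        assert [s.is_method for s in sentences] == [False, True]

    def test_focus_callable(self):
        text = "The assay was performed. Results follow."
        sentences = segment_and_strip(
            text, focus=lambda s: "assay" in s.lower()
        )
        assert [s.is_method for s in sentences] == [True, False]


class TestMatch:
    def test_longest_match_wins(self, dictionary):
        s = _sentence("Colocalization by fluorescent probes cloning was not used.")
        # obsolete term excluded: no MI:0021 entry at all
        assert all(h.mi_id != "MI:0021" for h in match(s, dictionary))

    def test_trigram_subsumes_its_bigrams(self, dictionary):
        s = _sentence("We used classical two hybrid screening.")
        hits = [h for h in match(s, dictionary) if h.mi_id == "MI:0018"]
        assert len(hits) == 1
        assert hits[0].matched_words == 3  # "classic two hybrid"

    def test_anti_tag_exact_beats_generic_after_resolution(self, dictionary):
        s = _sentence("Anti tag immunoprecipitation experiments were performed.")
        hits = match(s, dictionary)
        mi_ids = {h.mi_id for h in hits}
        assert "MI:0007" in mi_ids  # the injected exact synonym
        scored = [
            ScoredHit(hit=h, score1=0, score2=0, score3=0, focus=0) for h in hits
        ]
        kept = {sh.hit.mi_id for sh in resolve_overlaps(scored)}
        assert "MI:0007" in kept
        assert "MI:0019" not in kept  # generic immunoprecipitation loses

    def test_no_dictionary_words(self, dictionary):
        assert match(_sentence("Nothing relevant appears here."), dictionary) == []

    def test_hyphenated_text_matches_split_variant(self, dictionary):
        s = _sentence("A yeast two-hybrid screen identified the partner.")
        hits = [h for h in match(s, dictionary) if h.mi_id == "MI:0018"]
        assert hits and hits[0].matched_words == 3

    def test_matched_chars_exclude_spaces(self, dictionary):
        s = _sentence("A pull down assay confirmed this.")
        hits = [h for h in match(s, dictionary) if h.mi_id == "MI:0096"]
        assert hits[0].matched_chars == len("pull") + len("down")


def _entry(avg_words_synonyms):
    e = DictionaryEntry(mi_id="MI:9999")
    e.synonyms = avg_words_synonyms
    return e


class TestScore3:
    def test_full_length_match_rewarded(self):
        entry = _entry([("alpha", "trap")])
        hit = Hit("MI:9999", 0, 2, 9, ("alpha", "trap"), True, (0, 2))
        assert score3(hit, entry) == 4.0

    def test_sub_half_match_penalized(self):
        entry = _entry([("a1", "b2", "c3", "d4")])
        hit = Hit("MI:9999", 0, 1, 2, ("a1", "b2", "c3", "d4"), False, (0, 1))
        assert score3(hit, entry) == -1.0

    def test_intermediate_ratio_returned(self):
        entry = _entry([("a1", "b2", "c3")])
        hit = Hit("MI:9999", 0, 2, 4, ("a1", "b2", "c3"), False, (0, 2))
        assert score3(hit, entry) == pytest.approx(2 / 3)

    def test_range_invariant(self):
        entry = _entry([("w1", "w2", "w3", "w4")])
        for n in range(1, 6):
            hit = Hit("MI:9999", 0, n, 2 * n, ("w1",), False, (0, n))
            v = score3(hit, entry)
            assert v == -1.0 or v == 4.0 or 0.5 <= v < 1.0


class TestScore1Score2:
    def _hit(self, chars):
        return Hit("MI:9999", 0, 2, chars, ("a", "b"), True, (0, 2))

    def test_score1_rewards_longer_matches(self):
        assert score1(self._hit(20), 5, 100) > score1(self._hit(10), 5, 100)

    def test_score1_discounts_frequent_methods(self):
        assert score1(self._hit(15), 1, 100) > score1(self._hit(15), 100, 100)

    def test_score1_zero_frequency_finite(self):
        import math

        assert math.isfinite(score1(self._hit(15), 0, 100))

    def test_score2_discounts_short_word_entries(self):
        long_entry = _entry([("longerwordsabc", "longerwordxyz")])
        short_entry = _entry([("ab", "cd")])
        hit = self._hit(12)
        assert score2(hit, long_entry) >= score2(hit, short_entry)

    def test_score2_rewards_longer_matches(self):
        entry = _entry([("medium", "words")])
        assert score2(self._hit(20), entry) > score2(self._hit(10), entry)


class TestFocusScore:
    @pytest.mark.parametrize(
        "flags,i,expected",
        [
            ((False, True, False), 1, 1.0),   # method, no method neighbors
            ((False, False, True), 1, 0.5),   # next is method
            ((True, False, False), 1, 0.5),   # previous is method
            ((True, True, False), 1, 1.5),    # method with method neighbor
            ((False, False, False), 1, 0.0),
            ((True, False), 0, 1.0),          # boundary: no previous
        ],
    )
    def test_all_values(self, flags, i, expected):
        sentences = [
            _sentence(f"s{j}", index=j, is_method=f) for j, f in enumerate(flags)
        ]
        assert focus_score(sentences, i) == expected

    def test_range(self):
        sentences = [
            _sentence(f"s{j}", index=j, is_method=j % 2 == 0) for j in range(6)
        ]
        for i in range(6):
            assert focus_score(sentences, i) in {0.0, 0.5, 1.0, 1.5}


def _scored(mi, sent, words, chars, rscore, span=None):
    hit = Hit(mi, sent, words, chars, ("x",) * words, True, span or (0, words))
    return ScoredHit(hit=hit, score1=rscore, score2=0, score3=0, focus=0)


class TestResolveAndSelect:
    def test_more_words_wins_overlap(self):
        a = _scored("MI:0200", 0, 3, 12, 1.0, span=(0, 3))
        b = _scored("MI:0100", 0, 2, 20, 1.0, span=(2, 4))
        kept = resolve_overlaps([a, b])
        assert [sh.hit.mi_id for sh in kept] == ["MI:0200"]

    def test_chars_break_word_ties(self):
        a = _scored("MI:0200", 0, 2, 18, 1.0, span=(0, 2))
        b = _scored("MI:0100", 0, 2, 12, 1.0, span=(1, 3))
        kept = resolve_overlaps([a, b])
        assert [sh.hit.mi_id for sh in kept] == ["MI:0200"]

    def test_lower_mi_breaks_full_ties(self):
        a = _scored("MI:0200", 0, 2, 12, 1.0, span=(0, 2))
        b = _scored("MI:0100", 0, 2, 12, 1.0, span=(1, 3))
        kept = resolve_overlaps([a, b])
        assert [sh.hit.mi_id for sh in kept] == ["MI:0100"]

    def test_non_overlapping_hits_coexist(self):
        a = _scored("MI:0200", 0, 2, 12, 1.0, span=(0, 2))
        b = _scored("MI:0100", 0, 2, 12, 1.0, span=(3, 5))
        assert len(resolve_overlaps([a, b])) == 2

    def test_best_sentence_selected_per_method(self):
        sentences = [_sentence("s0.", 0), _sentence("s1.", 1)]
        low = _scored("MI:0100", 0, 2, 10, 5.1)
        high = _scored("MI:0100", 1, 2, 10, 7.3)
        records = select_evidence("doc", sentences, [low, high])
        assert len(records) == 1
        assert records[0].sentence_index == 1
        assert records[0].rscore == pytest.approx(7.3)

    def test_earliest_sentence_on_score_tie(self):
        sentences = [_sentence("s0.", 0), _sentence("s1.", 1)]
        a = _scored("MI:0100", 1, 2, 10, 6.0)
        b = _scored("MI:0100", 0, 2, 10, 6.0)
        records = select_evidence("doc", sentences, [a, b])
        assert records[0].sentence_index == 0

    def test_ranks_contiguous_and_sorted(self):
        sentences = [_sentence(f"s{i}.", i) for i in range(3)]
        hits = [
            _scored("MI:0100", 0, 2, 10, 3.0),
            _scored("MI:0200", 1, 2, 10, 9.0),
            _scored("MI:0300", 2, 2, 10, 6.0),
        ]
        records = select_evidence("doc", sentences, hits)
        assert [r.rank for r in records] == [1, 2, 3]
        assert [r.mi_id for r in records] == ["MI:0200", "MI:0300", "MI:0100"]

    def test_agrees_with_bruteforce_oracle_on_random_articles(self):
        """Greedy pipeline selection equals an independently coded
        enumeration over all (method, sentence) hit pairs."""
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(25):
            n_sent = int(rng.integers(1, 10))
            sentences = [_sentence(f"s{i}.", i) for i in range(n_sent)]
            hits = []
            for _ in range(int(rng.integers(0, 12))):
                sent = int(rng.integers(0, n_sent))
                start = int(rng.integers(0, 6))
                words = int(rng.integers(1, 4))
                mi = f"MI:{int(rng.integers(1, 40)):04d}"
                chars = int(rng.integers(3, 25))
                hit = Hit(mi, sent, words, chars, ("x",) * words, True,
                          (start, start + words))
                hits.append(
                    ScoredHit(hit=hit, score1=float(rng.normal()), score2=0,
                              score3=0, focus=0)
                )
            got = select_evidence("d", sentences, hits)
            expected = _oracle_select("d", sentences, hits)
            assert [(r.mi_id, r.sentence_index, r.rank) for r in got] == [
                (r[0], r[1], i + 1) for i, r in enumerate(expected)
            ]


def _oracle_select(doc_id, sentences, scored):
    """Literal restatement of the selection rules, coded independently."""
    by_sent = {}
    for sh in scored:
        by_sent.setdefault(sh.hit.sentence_index, []).append(sh)
    survivors = []
    for idx, group in by_sent.items():
        remaining = list(group)
        while remaining:
            best = min(
                remaining,
                key=lambda sh: (
                    -sh.hit.matched_words,
                    -sh.hit.matched_chars,
                    sh.hit.mi_number,
                    sh.hit.span,
                ),
            )
            survivors.append(best)
            remaining = [
                sh
                for sh in remaining
                if sh is not best
                and not (
                    sh.hit.span[0] < best.hit.span[1]
                    and best.hit.span[0] < sh.hit.span[1]
                )
            ]
            # drop everything overlapping any survivor of this sentence
            remaining = [
                sh
                for sh in remaining
                if not any(
                    sh.hit.span[0] < sv.hit.span[1]
                    and sv.hit.span[0] < sh.hit.span[1]
                    for sv in survivors
                    if sv.hit.sentence_index == idx
                )
            ]
    per_mi = {}
    for sh in survivors:
        key = sh.hit.mi_id
        cur = per_mi.get(key)
        if cur is None or (sh.rscore, -sh.hit.sentence_index) > (
            cur.rscore, -cur.hit.sentence_index
        ):
            per_mi[key] = sh
    ordered = sorted(
        per_mi.values(), key=lambda sh: (-sh.rscore, sh.hit.mi_number)
    )
    return [(sh.hit.mi_id, sh.hit.sentence_index) for sh in ordered]


class TestNormalizeAndFilter:
    def _records(self, rscores, doc="d"):
        return [
            EvidenceRecord(
                doc_id=doc, mi_id=f"MI:{i:04d}", rank=i + 1, rscore=r,
                score=0.0, sentence_index=i, sentence=f"s{i}",
            )
            for i, r in enumerate(sorted(rscores, reverse=True))
        ]

    def test_max_normalizes_to_one(self):
        out = normalize_and_filter(self._records([7.2, 6.4, 5.9]), "all")
        assert out[0].score == 1.0
        assert all(0 < r.score <= 1 for r in out)
        assert sum(r.score == 1.0 for r in out) == 1

    def test_threshold_filter(self):
        out = normalize_and_filter(self._records([7.2, 6.4, 5.9]), "rscore_ge:6")
        assert len(out) == 2
        assert [r.rank for r in out] == [1, 2]

    def test_top40(self):
        out = normalize_and_filter(self._records(range(45)), "top40")
        assert len(out) == 40

    def test_run_modes_nest(self):
        """Looser runs report supersets of stricter runs."""
        records = self._records([8.5, 7.4, 6.6, 5.0, 2.2])
        def pairs(mode):
            return {
                (r.doc_id, r.mi_id) for r in normalize_and_filter(records, mode)
            }
        assert pairs("rscore_ge:7") <= pairs("rscore_ge:6") <= pairs("top40") <= pairs("all")

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            normalize_and_filter(self._records([1.0]), "bogus")


class TestCrop:
    def test_unique_sentences_in_document_order(self):
        sentences = [_sentence(f"S{i} text.", i) for i in range(4)]
        records = [
            EvidenceRecord("d", "MI:0001", 1, 9.0, 1.0, 3, "S3 text."),
            EvidenceRecord("d", "MI:0002", 2, 8.0, 0.9, 1, "S1 text."),
            EvidenceRecord("d", "MI:0003", 3, 7.0, 0.8, 3, "S3 text."),
        ]
        assert crop_to_evidence(sentences, records) == "S1 text. S3 text."

    def test_no_records_empty(self):
        assert crop_to_evidence([_sentence("S.", 0)], []) == ""

    def test_cropped_never_longer_than_original(self):
        sentences = [_sentence(f"Sentence number {i}.", i) for i in range(8)]
        records = [
            EvidenceRecord("d", "MI:0001", 1, 5.0, 1.0, i, sentences[i].text)
            for i in (1, 4)
        ]
        original = " ".join(s.text for s in sentences)
        assert len(crop_to_evidence(sentences, records)) <= len(original)
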
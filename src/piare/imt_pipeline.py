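"""Evidence pipeline: find and score sentences supporting PSI-MI methods.

Stages, per article: (1) sentence segmentation with bibliographic-reference
stripping; (2) left-to-right dictionary matching of stemmed n-grams,
longest match first, full-synonym matches preferred, standalone stopwords
suppressed; (3) scoring of every (sentence, method) hit with

    RScore = Score1 + Score2 + Score3 + FocusScore

where Score1 rewards long matches but discounts methods that match all
over the corpus, Score2 rewards long matches but discounts methods whose
synonyms are made of short words (cheap to hit by chance), Score3 compares
the number of matched words to the method's average synonym length (−1
below half, the ratio itself between 0.5 and 1, a flat 4 at or above 1),
and FocusScore reflects whether the sentence — or a direct neighbor — was
labeled as discussing methods; (4) overlap resolution and evidence
selection: one method per overlapping text span, one best sentence per
method; (5) per-article score normalization to (0, 1] and run filtering
(everything / top-40 methods / raw-score thresholds). Finally the article
can be cropped to its evidence sentences for cheaper downstream NER.

Sentence focus labels are pluggable input (an external sentence classifier
in production; a naive keyword labeler ships for fixtures).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .corpus_io import STOPWORDS
from .imt_dictionary import DictionaryEntry
from .stemming import porter_stem

# ---------------------------------------------------------------------------
# Segmentation and reference stripping

_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\[])")
_REFERENCES_HEADING_RE = re.compile(r"^\s*references?\s*$", re.IGNORECASE)
# author-list + publication-date fallback, e.g. "Smith J, Doe AB (2004) ..."
_AUTHOR_LIST_RE = re.compile(
    r"(?:[A-Z][a-z]+\s+[A-Z]{1,3}[,.].*?){2,}\(\d{4}\)"
)
_WORD_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@dataclass
class SentenceRecord:
    index: int
    text: str
    stemmed: list[str]
    is_method: bool = False


def match_tokens(text: str) -> list[str]:
    """Stemmed token stream used for dictionary matching.

    Mirrors dictionary preprocessing: lowercase, hyphenated words split
    into their parts, Porter stemming. Stopwords stay in the stream (they
    may sit inside multi-word method names) but can never match alone.
    """
    out = []
    for w in _WORD_RE.findall(text.lower()):
        for part in w.split("-"):
            if part:
                out.append(porter_stem(part))
    return out


def naive_method_labeler(sentence: str) -> bool:
    """Keyword stand-in for the external sentence-focus classifier.

    Only intended for fixtures and demos: flags sentences that contain
    typical methods-section verbs.
    """
    lowered = sentence.lower()
    return any(
        kw in lowered for kw in ("performed", "assay", "incubated", "using")
    )


def segment_and_strip(
    text: str,
    focus: Optional[Mapping[int, bool] | Callable[[str], bool]] = None,
) -> list[SentenceRecord]:
    """Split an article into sentences and drop bibliographic references.

    If a line consisting of a References heading exists, every sentence
    after it is dropped; otherwise sentences matching an author-list/date
    pattern are dropped. Indices are contiguous after stripping. ``focus``
    supplies is_method flags either per (post-strip) sentence index or as a
    per-sentence-text callable.
    """
    if not text.strip():
        return []
    lines = text.splitlines()
    for i, line in enumerate(lines):
        if _REFERENCES_HEADING_RE.match(line):
            lines = lines[:i]
            break
    else:
        lines = [l for l in lines if not _AUTHOR_LIST_RE.search(l)]
    sentences: list[str] = []
    for block in "\n".join(lines).split("\n\n"):
        flat = " ".join(block.split())
        if flat:
            sentences.extend(s for s in _SENT_SPLIT_RE.split(flat) if s.strip())
    records = [
        SentenceRecord(index=i, text=s, stemmed=match_tokens(s))
        for i, s in enumerate(sentences)
    ]
    if callable(focus):
        for r in records:
            r.is_method = bool(focus(r.text))
    elif focus is not None:
        for r in records:
            r.is_method = bool(focus.get(r.index, False))
    return records


# ---------------------------------------------------------------------------
# Matching


@dataclass(frozen=True)
class Hit:
    mi_id: str
    sentence_index: int
    matched_words: int
    matched_chars: int
    source_synonym: tuple[str, ...]
    perfect: bool
    span: tuple[int, int]  # [start, end) word offsets in the sentence

    @property
    def mi_number(self) -> int:
        return int(self.mi_id.split(":")[1])


def match(
    sentence: SentenceRecord, dictionary: Sequence[DictionaryEntry]
) -> list[Hit]:
    """Dictionary hits in one sentence.

    Scans the stemmed stream left to right; at each position each method
    takes its longest matching n-gram (full-synonym matches win ties), and
    the matched words are consumed for that method so sub-grams of a longer
    match do not re-fire. Matched characters exclude inter-word spaces.
    """
    tokens = sentence.stemmed
    hits: list[Hit] = []
    for entry in dictionary:
        i = 0
        while i < len(tokens):
            best: Optional[tuple[int, bool]] = None  # (n, is_full)
            for n in (3, 2, 1):
                if i + n > len(tokens):
                    continue
                gram = tuple(tokens[i : i + n])
                info = entry.ngrams.get(gram)
                if info is None:
                    continue
                is_full = info[1]
                if best is None or (n, is_full) > best:
                    best = (n, is_full)
            if best is None:
                i += 1
                continue
            n, _ = best
            gram = tuple(tokens[i : i + n])
            source, is_full = entry.ngrams[gram]
            hits.append(
                Hit(
                    mi_id=entry.mi_id,
                    sentence_index=sentence.index,
                    matched_words=n,
                    matched_chars=sum(len(t) for t in gram),
                    source_synonym=source,
                    perfect=is_full,
                    span=(i, i + n),
                )
            )
            i += n
    return hits


# ---------------------------------------------------------------------------
# Scoring


def score3(hit: Hit, entry: DictionaryEntry) -> float:
    """Matched-words vs expected synonym length.

    R1 = matched_words / avg_words; −1 when R1 < 0.5 (sub-half partial
    match), 4 when R1 ≥ 1 (match covers a whole typical synonym), else R1.
    """
    r1 = hit.matched_words / entry.avg_words
    if r1 < 0.5:
        return -1.0
    if r1 >= 1.0:
        return 4.0
    return r1


def score1(hit: Hit, mi_frequency: int, n_articles: int) -> float:
    """Length reward discounted by corpus-wide match frequency.

    0.5·ln((1+|Hit|)·|D| / (1+freq_j)): grows with the number of matched
    characters, shrinks as the method's synonyms match more often across
    the article set; +1 smoothing keeps zero-frequency methods finite.
    """
    return 0.5 * math.log(
        (1 + hit.matched_chars) * max(1, n_articles) / (1 + mi_frequency)
    )


def score2(hit: Hit, entry: DictionaryEntry) -> float:
    """Length reward discounted for methods with typically short words.

    0.5·ln(1 + |Hit|·avg_word_len/4): methods whose synonyms are built of
    short words are easier to hit by chance and score lower at equal
    matched length.
    """
    return 0.5 * math.log(1 + hit.matched_chars * entry.avg_word_len / 4.0)


def focus_score(sentences: Sequence[SentenceRecord], i: int) -> float:
    """Method-focus context of sentence i.

    1 if the sentence itself is a method sentence, else 0; plus a 0.5 bonus
    when either direct neighbor is a method sentence (out-of-range
    neighbors count as non-method). Range {0, 0.5, 1, 1.5}.
    """
    base = 1.0 if sentences[i].is_method else 0.0
    prev_m = i > 0 and sentences[i - 1].is_method
    next_m = i + 1 < len(sentences) and sentences[i + 1].is_method
    return base + (0.5 if (prev_m or next_m) else 0.0)


@dataclass(frozen=True)
class ScoredHit:
    hit: Hit
    score1: float
    score2: float
    score3: float
    focus: float

    @property
    def rscore(self) -> float:
        return self.score1 + self.score2 + self.score3 + self.focus


def score_hits(
    sentences: Sequence[SentenceRecord],
    hits: Sequence[Hit],
    entries: Mapping[str, DictionaryEntry],
    mi_frequency: Mapping[str, int],
    n_articles: int,
) -> list[ScoredHit]:
    """RScore components for every hit of one article."""
    out = []
    for h in hits:
        entry = entries[h.mi_id]
        out.append(
            ScoredHit(
                hit=h,
                score1=score1(h, mi_frequency.get(h.mi_id, 0), n_articles),
                score2=score2(h, entry),
                score3=score3(h, entry),
                focus=focus_score(sentences, h.sentence_index),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Evidence selection


@dataclass(frozen=True)
class EvidenceRecord:
    doc_id: str
    mi_id: str
    rank: int
    rscore: float
    score: float  # normalized (0, 1]
    sentence_index: int
    sentence: str


def resolve_overlaps(scored: Sequence[ScoredHit]) -> list[ScoredHit]:
    """Within each sentence, hits sharing a word keep only the best method:
    most matched words, then most matched characters, then the lower MI
    number."""
    kept: list[ScoredHit] = []
    by_sentence: dict[int, list[ScoredHit]] = {}
    for sh in scored:
        by_sentence.setdefault(sh.hit.sentence_index, []).append(sh)
    for idx in sorted(by_sentence):
        group = sorted(
            by_sentence[idx],
            key=lambda sh: (
                -sh.hit.matched_words,
                -sh.hit.matched_chars,
                sh.hit.mi_number,
                sh.hit.span,
            ),
        )
        taken: list[tuple[int, int]] = []
        for sh in group:
            s, e = sh.hit.span
            if any(s < te and ts < e for ts, te in taken):
                continue
            taken.append((s, e))
            kept.append(sh)
    return kept


def select_evidence(
    doc_id: str,
    sentences: Sequence[SentenceRecord],
    scored: Sequence[ScoredHit],
) -> list[EvidenceRecord]:
    """One evidence sentence per surviving method, ranked by raw score.

    For each method the sentence with the highest RScore wins (earliest
    sentence on ties); records are ordered by RScore descending (MI number
    ascending on ties) and ranks run 1..n without gaps. Normalized scores
    are filled by :func:`normalize_and_filter`.
    """
    surviving = resolve_overlaps(scored)
    best: dict[str, ScoredHit] = {}
    for sh in surviving:
        cur = best.get(sh.hit.mi_id)
        if (
            cur is None
            or sh.rscore > cur.rscore
            or (sh.rscore == cur.rscore
                and sh.hit.sentence_index < cur.hit.sentence_index)
        ):
            best[sh.hit.mi_id] = sh
    ordered = sorted(
        best.values(), key=lambda sh: (-sh.rscore, sh.hit.mi_number)
    )
    return [
        EvidenceRecord(
            doc_id=doc_id,
            mi_id=sh.hit.mi_id,
            rank=rank,
            rscore=sh.rscore,
            score=0.0,
            sentence_index=sh.hit.sentence_index,
            sentence=sentences[sh.hit.sentence_index].text,
        )
        for rank, sh in enumerate(ordered, start=1)
    ]


def normalize_and_filter(
    records: Sequence[EvidenceRecord], mode: str = "all"
) -> list[EvidenceRecord]:
    """Normalize per article and apply the run filter.

    Scores divide by the article's maximum raw score, so exactly the top
    record reaches 1. Modes: ``all``, ``top40`` (40 best-scoring methods
    per article), ``rscore_ge:T`` (keep raw score ≥ T; the run presets use
    T of 4.5, 6 and 7). Ranks are reassigned after filtering.
    """
    by_doc: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_doc.setdefault(r.doc_id, []).append(r)
    out: list[EvidenceRecord] = []
    for doc_id in sorted(by_doc):
        group = sorted(by_doc[doc_id], key=lambda r: r.rank)
        max_rscore = max(r.rscore for r in group)
        group = [replace(r, score=r.rscore / max_rscore) for r in group]
        if mode == "top40":
            group = group[:40]
        elif mode.startswith("rscore_ge:"):
            tau = float(mode.split(":", 1)[1])
            group = [r for r in group if r.rscore >= tau]
        elif mode != "all":
            raise ValueError(f"unknown filter mode {mode!r}")
        out.extend(replace(r, rank=i) for i, r in enumerate(group, start=1))
    return out


def crop_to_evidence(
    sentences: Sequence[SentenceRecord], records: Sequence[EvidenceRecord]
) -> str:
    """Concatenate the unique evidence sentences in document order."""
    indices = sorted({r.sentence_index for r in records})
    return " ".join(sentences[i].text for i in indices)


# ---------------------------------------------------------------------------
# Whole-corpus driver


@dataclass
class ArticleResult:
    doc_id: str
    sentences: list[SentenceRecord]
    records: list[EvidenceRecord] = field(default_factory=list)


def run_pipeline(
    articles: Mapping[str, str],
    dictionary: Sequence[DictionaryEntry],
    focus: Optional[
        Mapping[str, Mapping[int, bool]] | Callable[[str], bool]
    ] = None,
    mode: str = "all",
) -> list[ArticleResult]:
    """Run the full evidence pipeline over a set of articles.

    ``focus`` is either {doc_id: {sentence_index: is_method}} or a callable
    applied to each sentence's text. The corpus-frequency discount of
    Score1 uses hit counts aggregated over this article set, so the
    pipeline makes one matching pass before scoring.
    """
    entries = {e.mi_id: e for e in dictionary}
    per_article: dict[str, tuple[list[SentenceRecord], list[Hit]]] = {}
    mi_frequency: dict[str, int] = {}
    for doc_id, text in articles.items():
        doc_focus = focus.get(doc_id, {}) if isinstance(focus, Mapping) else focus
        sentences = segment_and_strip(text, doc_focus)
        hits = [h for s in sentences for h in match(s, dictionary)]
        for h in hits:
            mi_frequency[h.mi_id] = mi_frequency.get(h.mi_id, 0) + 1
        per_article[doc_id] = (sentences, hits)

    n_articles = len(articles)
    results = []
    all_records: list[EvidenceRecord] = []
    for doc_id, (sentences, hits) in per_article.items():
        scored = score_hits(sentences, hits, entries, mi_frequency, n_articles)
        records = select_evidence(doc_id, sentences, scored)
        results.append(ArticleResult(doc_id=doc_id, sentences=sentences))
        all_records.extend(records)
    filtered = normalize_and_filter(all_records, mode)
    by_doc: dict[str, list[EvidenceRecord]] = {}
    for r in filtered:
        by_doc.setdefault(r.doc_id, []).append(r)
    for res in results:
        res.records = by_doc.get(res.doc_id, [])
    return results


def format_records(records: Iterable[EvidenceRecord]) -> str:
    """Submission-format lines: PMID MI rank normalized-score sentence."""
    return "\n".join(
        f"{r.doc_id} {r.mi_id} {r.rank} {r.score} {r.sentence}" for r in records
    )
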
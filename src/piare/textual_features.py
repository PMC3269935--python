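"""Textual feature selection: S-scored words, SP word-pairs and bigrams.

The single-word score S(w) = |p_P(w) − p_N(w)| is the absolute difference
between the fraction of positive and negative documents (of the *balanced*
training corpus) containing w at least once. *Short-window pairs* (SP) are
ordered pairs of consecutive words in a document after all words outside the
top-K vocabulary W have been removed — so SP pairs may bridge gaps in the
original text. *Bigrams* are consecutive pairs in the full preprocessed
stream, with no vocabulary restriction. Both feature kinds carry per-class
document probabilities used by the classifier's cosine/sine contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus_io import Corpus


@dataclass(frozen=True)
class WordStat:
    word: str
    p_P: float
    p_N: float

    @property
    def S(self) -> float:
        return abs(self.p_P - self.p_N)


@dataclass
class PairFeatureTable:
    """Word-pair features with per-class document probabilities.

    ``entries`` maps the ordered pair (w_i, w_j) to (p_P, p_N); order is
    significant: (a, b) and (b, a) are distinct features. For SP tables,
    ``vocabulary`` is the top-K word set W and both pair members lie in it.
    """

    kind: str  # "SP" | "bigram"
    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    vocabulary: Optional[frozenset[str]] = None
    K: Optional[int] = None

    def lookup(self, pair: tuple[str, str]) -> Optional[tuple[float, float]]:
        return self.entries.get(pair)

    def s_score(self, pair: tuple[str, str]) -> float:
        p_P, p_N = self.entries[pair]
        return abs(p_P - p_N)

    def write_tsv(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("w_i\tw_j\tp_P\tp_N\tS\n")
            for (wi, wj), (pp, pn) in sorted(
                self.entries.items(), key=lambda kv: (-abs(kv[1][0] - kv[1][1]), kv[0])
            ):
                fh.write(f"{wi}\t{wj}\t{pp:.6g}\t{pn:.6g}\t{abs(pp - pn):.6g}\n")

    @classmethod
    def read_tsv(cls, path: Path, kind: str = "SP") -> "PairFeatureTable":
        entries: dict[tuple[str, str], tuple[float, float]] = {}
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            wi, wj, pp, pn, _s = line.split("\t")
            entries[(wi, wj)] = (float(pp), float(pn))
        vocab = frozenset(w for pair in entries for w in pair) if kind == "SP" else None
        return cls(kind=kind, entries=entries, vocabulary=vocab)


def score_words(corpus: Corpus) -> list[WordStat]:
    """Score every unique word of the balanced corpus by S = |p_P − p_N|.

    Probabilities are document fractions over title+abstract text; repeats
    introduced by oversampling count in both numerator and denominator.
    Result is sorted by S descending, ties broken lexicographically.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    n_pos = sum(1 for d in corpus if d.label == "positive")
    n_neg = sum(1 for d in corpus if d.label == "negative")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("corpus must contain both classes")
    pos_counts: dict[str, int] = {}
    neg_counts: dict[str, int] = {}
    for doc in corpus:
        target = pos_counts if doc.label == "positive" else neg_counts
        for w in set(doc.tokens()):
            target[w] = target.get(w, 0) + 1
    words = set(pos_counts) | set(neg_counts)
    stats = [
        WordStat(w, pos_counts.get(w, 0) / n_pos, neg_counts.get(w, 0) / n_neg)
        for w in words
    ]
    stats.sort(key=lambda s: (-s.S, s.word))
    return stats


def top_vocabulary(corpus: Corpus, K: int = 1000) -> frozenset[str]:
    """The top-K word set W by S score (ties lexicographic)."""
    return frozenset(s.word for s in score_words(corpus)[:K])


def to_ordered_list(tokens: Sequence[str], W: frozenset[str]) -> list[str]:
    """Project a token stream onto the vocabulary W, preserving order and
    repetition. Adjacent elements of the result need not be adjacent in the
    original text."""
    return [t for t in tokens if t in W]


def _pairs(tokens: Sequence[str]) -> set[tuple[str, str]]:
    return {(tokens[i], tokens[i + 1]) for i in range(len(tokens) - 1)}


def doc_sp_pairs(tokens: Sequence[str], W: frozenset[str]) -> set[tuple[str, str]]:
    """Unique SP pairs of one document: consecutive elements of its
    W-filtered ordered list."""
    return _pairs(to_ordered_list(tokens, W))


def doc_bigrams(tokens: Sequence[str]) -> set[tuple[str, str]]:
    """Unique bigrams of one document: consecutive tokens of the raw
    preprocessed stream."""
    return _pairs(tokens)


def _pair_table(corpus: Corpus, pair_fn, kind: str, **meta) -> PairFeatureTable:
    n_pos = sum(1 for d in corpus if d.label == "positive")
    n_neg = sum(1 for d in corpus if d.label == "negative")
    pos_counts: dict[tuple[str, str], int] = {}
    neg_counts: dict[tuple[str, str], int] = {}
    for doc in corpus:
        target = pos_counts if doc.label == "positive" else neg_counts
        for pair in pair_fn(doc.tokens()):
            target[pair] = target.get(pair, 0) + 1
    entries = {
        pair: (pos_counts.get(pair, 0) / n_pos, neg_counts.get(pair, 0) / n_neg)
        for pair in set(pos_counts) | set(neg_counts)
    }
    return PairFeatureTable(kind=kind, entries=entries, **meta)


def extract_sp_table(
    corpus: Corpus, K: int = 1000, W: Optional[frozenset[str]] = None
) -> PairFeatureTable:
    """Build the SP pair table on a balanced corpus.

    W defaults to the top-K words by S score computed on the same corpus;
    passing W explicitly supports cross-validation folds where the
    vocabulary comes from the training split only.
    """
    if W is None:
        W = top_vocabulary(corpus, K)
    return _pair_table(
        corpus, lambda toks: doc_sp_pairs(toks, W), "SP", vocabulary=W, K=K
    )


def extract_bigram_table(corpus: Corpus) -> PairFeatureTable:
    """Build the bigram pair table (no vocabulary restriction)."""
    return _pair_table(corpus, doc_bigrams, "bigram")
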
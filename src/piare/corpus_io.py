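"""Corpus reading, preprocessing and class balancing.

A *labeled document* is one article (PMID-like id, title/abstract always,
figure captions and full text when the article has a PubMed Central record)
with a relevance label: positive = relevant to protein-protein interaction,
negative = irrelevant. Preprocessing is the fixed pipeline used throughout:
lowercase, tokenize (keeping intra-word hyphens so compounds like
``two-hybrid`` survive), drop the fixed stopword list, Porter-stem.

Class balance matters because feature probabilities are document fractions
per class; the minority class is oversampled (documents repeated, chosen
uniformly with replacement, seeded) until the classes are equal-sized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .stemming import porter_stem

#: The fixed stopword list. Note that "with" and "between" are deliberately
#: not stopwords: they carry interaction signal ("interacts with",
#: "interaction between").
STOPWORDS = frozenset(
    """i a about an are as at be by for from how in is it of on or that the
    this to was what when where who will and we were""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def preprocess(raw: str) -> list[str]:
    """Lowercase, tokenize, remove stopwords, Porter-stem.

    Returns the token stream in original text order. Empty input yields an
    empty list.
    """
    tokens = _TOKEN_RE.findall(raw.lower())
    return [porter_stem(t) for t in tokens if t not in STOPWORDS]


@dataclass(frozen=True)
class LabeledDocument:
    doc_id: str
    title: str = ""
    abstract: str = ""
    captions: Optional[str] = None
    fulltext: Optional[str] = None
    label: str = "unknown"  # positive | negative | unknown

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not (self.title or self.abstract):
            raise ValueError(
                f"document {self.doc_id!r}: need at least one of title/abstract"
            )

    @property
    def has_fulltext(self) -> bool:
        return self.fulltext is not None

    def tokens(self) -> list[str]:
        """Preprocessed title+abstract token stream (textual-feature text)."""
        return preprocess(self.title + " " + self.abstract)


@dataclass
class Corpus:
    """An ordered collection of labeled documents.

    After oversampling, repeated documents carry distinct internal keys
    (``pmid#1``, ``pmid#2``...) so that document-fraction denominators count
    repeats, while ``doc_id`` still exposes the original id.
    """

    documents: list[LabeledDocument] = field(default_factory=list)
    keys: list[str] = field(default_factory=list)  # parallel, unique

    def __post_init__(self) -> None:
        if not self.keys:
            self.keys = [d.doc_id for d in self.documents]
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate document keys in corpus")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def subset(self, indices: Iterable[int]) -> "Corpus":
        idx = list(indices)
        return Corpus(
            [self.documents[i] for i in idx], [self.keys[i] for i in idx]
        )

    @property
    def positives(self) -> list[LabeledDocument]:
        return [d for d in self.documents if d.label == "positive"]

    @property
    def negatives(self) -> list[LabeledDocument]:
        return [d for d in self.documents if d.label == "negative"]


_SECTION_HEADERS = {
    "#TITLE": "title",
    "#ABSTRACT": "abstract",
    "#CAPTIONS": "captions",
    "#FULLTEXT": "fulltext",
}


def read_document_file(path: Path, doc_id: str, label: str = "unknown") -> LabeledDocument:
    """Parse a sectioned plain-text document file.

    Sections are introduced by ``#TITLE``, ``#ABSTRACT``, ``#CAPTIONS``,
    ``#FULLTEXT`` header lines; missing captions/fulltext stay absent.
    """
    sections: dict[str, list[str]] = {}
    current: Optional[str] = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        header = _SECTION_HEADERS.get(line.strip())
        if header is not None:
            current = header
            sections.setdefault(current, [])
        elif current is not None:
            sections[current].append(line)
    join = lambda k: "\n".join(sections[k]).strip() if k in sections else None
    return LabeledDocument(
        doc_id=doc_id,
        title=join("title") or "",
        abstract=join("abstract") or "",
        captions=join("captions"),
        fulltext=join("fulltext"),
        label=label,
    )


def load_labeled_corpus(label_file: Path, text_dir: Path) -> Corpus:
    """Load a corpus from a ``doc_id<TAB>label`` TSV plus one text file per id.

    Labels are 1 (relevant) or 0 (irrelevant). A listed id without a
    ``<doc_id>.txt`` file, or a label outside {0,1}, is an error naming the
    offender.
    """
    label_file, text_dir = Path(label_file), Path(text_dir)
    docs: list[LabeledDocument] = []
    for row_no, line in enumerate(
        label_file.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ValueError(
                f"{label_file}: malformed label row {row_no}: {line!r}"
            )
        doc_id, label = parts[0], ("positive" if parts[1] == "1" else "negative")
        text_path = text_dir / f"{doc_id}.txt"
        if not text_path.exists():
            raise FileNotFoundError(
                f"no text file for document {doc_id!r} (expected {text_path})"
            )
        docs.append(read_document_file(text_path, doc_id, label))
    return Corpus(docs)


def balance_by_oversampling(corpus: Corpus, seed: int) -> Corpus:
    """Equalize class sizes by repeating minority-class documents.

    Repeats are drawn uniformly with replacement from the minority class
    (seeded). All originals are retained; the majority class is untouched.
    """
    pos_idx = [i for i, d in enumerate(corpus.documents) if d.label == "positive"]
    neg_idx = [i for i, d in enumerate(corpus.documents) if d.label == "negative"]
    if not pos_idx or not neg_idx:
        raise ValueError("both classes must be non-empty to balance")
    if len(pos_idx) == len(neg_idx):
        return corpus
    minority = pos_idx if len(pos_idx) < len(neg_idx) else neg_idx
    deficit = abs(len(pos_idx) - len(neg_idx))
    rng = np.random.default_rng(seed)
    extra = rng.choice(np.asarray(minority), size=deficit, replace=True)
    docs = list(corpus.documents)
    keys = list(corpus.keys)
    counter: dict[str, int] = {}
    for i in extra:
        d = corpus.documents[int(i)]
        counter[d.doc_id] = counter.get(d.doc_id, 0) + 1
        docs.append(replace(d))
        keys.append(f"{d.doc_id}#{counter[d.doc_id]}")
    return Corpus(docs, keys)
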
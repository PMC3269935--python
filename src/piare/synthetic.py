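"""Seeded synthetic corpora with known ground truth.

Two generators cover the two pipelines. The article-classification
generator emits labeled abstracts over a Zipf-distributed background
vocabulary (2000 words, mimicking the long-tailed S-score histogram of
real corpora) into which *signal words* are planted with class-dependent
document probabilities; the planted words of a document are inserted as
one contiguous run so discriminative word pairs arise the way topical
phrases do in real abstracts. Entity counts are drawn per class from
Poisson distributions (defaults 8 for relevant vs 2 for irrelevant
documents, echoing the separation real protein-mention counts show).

The method-evidence generator builds articles from sentence templates with
planted full or partial synonym mentions of a miniature method ontology,
method/non-method focus flags and a references tail, recording the gold
(article, method) pairs for end-to-end checks.

All randomness flows through one seeded generator; neither generator
attempts realistic biomedical prose or NER error models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Corpus, LabeledDocument

DEFAULT_VOCAB_SIZE = 2000
DEFAULT_DOC_LENGTH = 80
DEFAULT_ZIPF_EXPONENT = 1.2

#: Default planted conditions: strongly class-separated signal words and
#: Poisson entity counts with means 8 (relevant) vs 2 (irrelevant).
DEFAULT_SIGNAL_WORDS: tuple[tuple[str, float, float], ...] = (
    ("bindq", 0.8, 0.1),
    ("complexq", 0.8, 0.1),
    ("interactq", 0.8, 0.1),
    ("domainq", 0.7, 0.1),
    ("kinaseq", 0.7, 0.15),
    ("twohybridq", 0.6, 0.05),
)
DEFAULT_ENTITY_SPECS: tuple[tuple[str, str, float, float], ...] = (
    ("protein_mentions_abstract", "abstract", 8.0, 2.0),
)


@dataclass
class ActConfig:
    n_pos: int = 500
    n_neg: int = 500
    signal_words: Sequence[tuple[str, float, float]] = DEFAULT_SIGNAL_WORDS
    entity_specs: Sequence[tuple[str, str, float, float]] = DEFAULT_ENTITY_SPECS
    vocab_size: int = DEFAULT_VOCAB_SIZE
    doc_length: int = DEFAULT_DOC_LENGTH
    zipf_exponent: float = DEFAULT_ZIPF_EXPONENT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one document per class")
        if not self.signal_words:
            raise ValueError("signal word list must be non-empty")
        for w, p_P, p_N in self.signal_words:
            if not (0 <= p_P <= 1 and 0 <= p_N <= 1):
                raise ValueError(f"probabilities for {w!r} outside [0,1]")


@dataclass
class ActCorpus:
    corpus: Corpus
    counts: dict[str, dict[str, int]]  # feature -> doc_id -> count
    labels: dict[str, str]


def _background_vocab(size: int) -> list[str]:
    return [f"bg{i:04d}" for i in range(size)]


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def generate_act_corpus(config: ActConfig) -> ActCorpus:
    """Labeled abstracts plus per-document entity counts, reproducible per
    seed."""
    rng = np.random.default_rng(config.seed)
    vocab = _background_vocab(config.vocab_size)
    probs = _zipf_probs(config.vocab_size, config.zipf_exponent)
    docs: list[LabeledDocument] = []
    counts: dict[str, dict[str, int]] = {
        name: {} for name, *_ in config.entity_specs
    }
    labels: dict[str, str] = {}
    n_total = config.n_pos + config.n_neg
    for i in range(n_total):
        positive = i < config.n_pos
        doc_id = f"{'P' if positive else 'N'}{i:06d}"
        body = [
            vocab[j]
            for j in rng.choice(config.vocab_size, size=config.doc_length, p=probs)
        ]
        planted = [
            w
            for w, p_P, p_N in config.signal_words
            if rng.random() < (p_P if positive else p_N)
        ]
        if planted:
            # contiguous insertion: planted words behave like a topical phrase
            pos = int(rng.integers(0, len(body) + 1))
            body[pos:pos] = planted
        label = "positive" if positive else "negative"
        docs.append(
            LabeledDocument(
                doc_id=doc_id,
                title=f"synthetic article {doc_id}",
                abstract=" ".join(body),
                label=label,
            )
        )
        labels[doc_id] = label
        for name, _scope, mean_pos, mean_neg in config.entity_specs:
            lam = mean_pos if positive else mean_neg
            counts[name][doc_id] = int(rng.poisson(lam))
    return ActCorpus(corpus=Corpus(docs), counts=counts, labels=labels)


def write_act_corpus(act: ActCorpus, out_dir) -> None:
    """Materialize a generated corpus as label TSV, text files and counts
    TSV in the formats the loaders expect."""
    from pathlib import Path

    out = Path(out_dir)
    (out / "texts").mkdir(parents=True, exist_ok=True)
    with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
        for doc in act.corpus:
            fh.write(f"{doc.doc_id}\t{1 if doc.label == 'positive' else 0}\n")
            (out / "texts" / f"{doc.doc_id}.txt").write_text(
                f"#TITLE\n{doc.title}\n#ABSTRACT\n{doc.abstract}\n",
                encoding="utf-8",
            )
    with open(out / "counts.tsv", "w", encoding="utf-8") as fh:
        for name, per_doc in act.counts.items():
            for doc_id, n in per_doc.items():
                fh.write(f"{doc_id}\t{name}\t{n}\n")


# ---------------------------------------------------------------------------
# Method-evidence articles

# synonyms of one method share a word count so a planted full mention
# always covers the method's average synonym length
DEFAULT_MINI_ONTOLOGY: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("MI:1001", ("alpha capture assay", "alpha trap assay")),
    ("MI:1002", ("beta crosslink spectrometry", "beta crosslink imaging")),
    ("MI:1003", ("gamma resonance imaging",)),
    ("MI:1004", ("delta blot",)),
)

_FILLER_SENTENCES = (
    "The cells were cultured overnight in standard medium.",
    "Expression levels varied across the tested conditions.",
    "These results suggest a regulatory role in signaling.",
    "Samples were collected at the indicated time points.",
    "The observed phenotype was consistent between replicates.",
)

_REFERENCE_TAIL = (
    "References",
    "Smith J, Doe A (2004) A study of binding. J Mol Biol 12:34-56.",
    "Jones B, Roe C (2008) Crosslinking advances. Proteomics 8:100-110.",
)


@dataclass
class ImtConfig:
    n_articles: int = 10
    mini_ontology: Sequence[tuple[str, tuple[str, ...]]] = DEFAULT_MINI_ONTOLOGY
    mentions_per_article: tuple[int, int] = (1, 3)  # inclusive range
    partial_fraction: float = 0.0  # fraction of mentions planted truncated
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mini_ontology) < 2:
            raise ValueError("mini ontology needs at least two methods")


@dataclass
class ImtArticles:
    articles: dict[str, str]
    focus: dict[str, dict[int, bool]]  # indices refer to post-strip sentences
    gold: set[tuple[str, str]]  # (doc_id, mi_id) planted as full mentions
    obo_text: str = ""


def mini_ontology_obo(
    mini_ontology: Sequence[tuple[str, tuple[str, ...]]]
) -> str:
    """Render the miniature method ontology as an OBO document whose terms
    all descend from the interaction-detection-method root."""
    blocks = [
        "format-version: 1.2",
        "ontology: mi",
        "",
        "[Term]",
        "id: MI:0001",
        "name: interaction detection method",
    ]
    for mi_id, synonyms in mini_ontology:
        name, *extra = synonyms
        blocks += ["", "[Term]", f"id: {mi_id}", f"name: {name}"]
        blocks += [f'synonym: "{s}" EXACT []' for s in extra]
        blocks += ["is_a: MI:0001 ! interaction detection method"]
    return "\n".join(blocks) + "\n"


def generate_imt_articles(config: ImtConfig) -> ImtArticles:
    """Articles with planted method mentions, focus labels, a references
    tail, and the gold (article, method) pairs."""
    rng = np.random.default_rng(config.seed)
    articles: dict[str, str] = {}
    focus: dict[str, dict[int, bool]] = {}
    gold: set[tuple[str, str]] = set()
    methods = list(config.mini_ontology)
    lo, hi = config.mentions_per_article
    for a in range(config.n_articles):
        doc_id = f"10{a:06d}"
        sentences: list[str] = []
        flags: dict[int, bool] = {}
        n_filler = int(rng.integers(3, 6))
        for _ in range(n_filler):
            sentences.append(str(rng.choice(_FILLER_SENTENCES)))
        n_mentions = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(methods), size=min(n_mentions, len(methods)),
                            replace=False)
        for mi in chosen:
            mi_id, synonyms = methods[int(mi)]
            synonym = str(rng.choice(list(synonyms)))
            partial = rng.random() < config.partial_fraction
            words = synonym.split()
            if partial and len(words) > 1:
                mention = words[0]
            else:
                mention = synonym
                gold.add((doc_id, mi_id))
            idx = len(sentences)
            sentences.append(
                f"Interactions were examined by {mention} experiments."
            )
            flags[idx] = True
        text = "\n".join([" ".join(sentences), *_REFERENCE_TAIL])
        articles[doc_id] = text
        focus[doc_id] = flags
    return ImtArticles(
        articles=articles,
        focus=focus,
        gold=gold,
        obo_text=mini_ontology_obo(config.mini_ontology),
    )
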
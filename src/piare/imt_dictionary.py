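"""Method-identifier dictionary from the PSI-MI ontology.

Interaction *detection methods* live under the MI:0001 ("interaction
detection method") branch of the PSI-MI ontology. Every descendant term
contributes its name and synonyms; each synonym is lowercased,
Porter-stemmed and expanded into hyphen variants — a hyphenated word is
entered both with the hyphen replaced by a space and with the hyphen
removed (one composite word) so either free-text rendering matches. All
unigrams, bigrams and trigrams of consecutive stemmed words within each
variant become dictionary entries linked back to their source synonym;
stopwords never stand alone as unigram entries (they would otherwise match
ubiquitous English words).

Three special synonyms compensate for artefacts observed in converted
full-text: ``orescence`` (a PDF-conversion mangling of "fluorescence") for
fluorescence microscopy (MI:0416), and ``anti tag immunoprecipitation`` /
``anti bait immunoprecipitation`` for MI:0007 / MI:0006, so those frequent
renderings score as exact matches to the specific method rather than as
partial matches to the generic "immunoprecipitation" (MI:0019).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet

from .corpus_io import STOPWORDS
from .stemming import porter_stem

ROOT_MI = "MI:0001"

SPECIAL_SYNONYMS = (
    ("MI:0416", "orescence"),
    ("MI:0007", "anti tag immunoprecipitation"),
    ("MI:0006", "anti bait immunoprecipitation"),
)

_SYNONYM_RE = re.compile(r'"(?P<text>(?:[^"\\]|\\.)*)"\s+(?P<scope>\w+)')
_WORD_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@dataclass(frozen=True)
class Term:
    mi_id: str
    name: str
    exact_synonyms: tuple[str, ...] = ()
    related_synonyms: tuple[str, ...] = ()


@dataclass
class DictionaryEntry:
    mi_id: str
    #: stemmed word sequences (hyphen variants included)
    synonyms: list[tuple[str, ...]] = field(default_factory=list)
    #: ngram -> (source synonym, is_full_synonym)
    ngrams: dict[tuple[str, ...], tuple[tuple[str, ...], bool]] = field(
        default_factory=dict
    )

    @property
    def mi_number(self) -> int:
        return int(self.mi_id.split(":")[1])

    @property
    def avg_words(self) -> float:
        return sum(len(s) for s in self.synonyms) / len(self.synonyms)

    @property
    def avg_word_len(self) -> float:
        words = [w for s in self.synonyms for w in s]
        return sum(len(w) for w in words) / len(words)


def parse_interaction_branch(obo_path: Path) -> list[Term]:
    """All descendant terms of MI:0001 (is_a closure), obsoletes excluded.

    Raises if the ontology lacks the interaction-detection-method root.
    """
    graph = obonet.read_obo(str(obo_path))
    if ROOT_MI not in graph:
        raise ValueError(f"{obo_path}: ontology does not contain {ROOT_MI}")
    isa = nx.DiGraph(
        (u, v)
        for u, v, key in graph.edges(keys=True)
        if key == "is_a"
    )
    isa.add_nodes_from(graph.nodes)
    descendants = nx.ancestors(isa, ROOT_MI)  # edges point child -> parent
    terms = []
    for node in sorted(descendants | {ROOT_MI}):
        data = graph.nodes[node]
        if data.get("is_obsolete") == "true":
            continue
        exact, related = [], []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if not m:
                continue
            text, scope = m.group("text"), m.group("scope").upper()
            if scope == "EXACT":
                exact.append(text)
            elif scope == "RELATED":
                related.append(text)
        terms.append(
            Term(
                mi_id=node,
                name=data.get("name", ""),
                exact_synonyms=tuple(exact),
                related_synonyms=tuple(related),
            )
        )
    return terms


def synonym_variants(text: str) -> list[tuple[str, ...]]:
    """Stemmed word-sequence variants of one synonym string.

    Hyphenated words produce two variants (hyphen → space; hyphen removed);
    variants multiply across hyphenated words.
    """
    words = _WORD_RE.findall(text.lower())
    variants: list[list[str]] = [[]]
    for w in words:
        if "-" in w:
            parts = [p for p in w.split("-") if p]
            split_form = [porter_stem(p) for p in parts]
            concat_form = [porter_stem("".join(parts))]
            variants = [v + split_form for v in variants] + [
                v + concat_form for v in variants
            ]
        else:
            stemmed = porter_stem(w)
            variants = [v + [stemmed] for v in variants]
    out, seen = [], set()
    for v in variants:
        t = tuple(v)
        if t and t not in seen:
            seen.add(t)
            out.append(t)
    return out


def _add_synonym(entry: DictionaryEntry, text: str, stopwords) -> None:
    for variant in synonym_variants(text):
        if variant in entry.synonyms:
            continue
        entry.synonyms.append(variant)
        n_words = len(variant)
        for n in (1, 2, 3):
            for i in range(n_words - n + 1):
                gram = variant[i : i + n]
                if n == 1 and gram[0] in stopwords:
                    continue  # stopwords never match alone
                key = tuple(gram)
                is_full = n == n_words
                prev = entry.ngrams.get(key)
                # prefer marking as full synonym if any source makes it one
                if prev is None or (is_full and not prev[1]):
                    entry.ngrams[key] = (variant, is_full)


def build_dictionary(
    terms: Iterable[Term],
    allowed_ids: Optional[set[str]] = None,
    include_related: bool = False,
    stopwords: frozenset[str] = STOPWORDS,
) -> list[DictionaryEntry]:
    """Build stemmed n-gram entries, one per MI term.

    ``allowed_ids`` restricts the output (e.g. to a task-provided reduced
    method list); the special-case synonyms are always injected for their
    terms when present.
    """
    entries: dict[str, DictionaryEntry] = {}
    for term in terms:
        entry = DictionaryEntry(mi_id=term.mi_id)
        sources = [term.name, *term.exact_synonyms]
        if include_related:
            sources.extend(term.related_synonyms)
        for text in sources:
            if text:
                _add_synonym(entry, text, stopwords)
        if entry.synonyms:
            entries[term.mi_id] = entry
    for mi_id, text in SPECIAL_SYNONYMS:
        if mi_id in entries:
            _add_synonym(entries[mi_id], text, stopwords)
    out = [
        e
        for mi_id, e in sorted(entries.items())
        if allowed_ids is None or mi_id in allowed_ids
    ]
    return out


def read_allowed_ids(path: Path) -> set[str]:
    """One MI identifier per line."""
    return {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


def write_dictionary_tsv(entries: Iterable[DictionaryEntry], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mi_id\tngram\tsource_synonym\tn\n")
        for entry in entries:
            for gram, (source, _full) in sorted(entry.ngrams.items()):
                fh.write(
                    f"{entry.mi_id}\t{' '.join(gram)}\t{' '.join(source)}\t{len(gram)}\n"
                )
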
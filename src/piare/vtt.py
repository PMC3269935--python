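"""The Variable Trigonometric Threshold (VTT) linear classifier.

Each word-pair feature w occurring in a document contributes a unit vector
on the p_P/p_N plane: cos θ_w = p_P/√(p_P²+p_N²) to the positive sum P(d)
and sin θ_w = p_N/√(p_P²+p_N²) to the negative sum N(d). The document is
placed at

    x(d) = P(d) / N(d)
    y(d) = 1 + (1/M) · [ Σ_π (n_π(d) − β_π)/β_π  −  Σ_ν (n_ν(d) − β_ν)/β_ν ]

where π ranges over entity-count features positively correlated with the
relevant class, ν over those correlated with the irrelevant class, M is the
number of configured entity features, and β is each feature's neutral
point. The decision surface is the line x = λ − y: a document is relevant
iff x(d) > T(d) = λ − y(d) (strict; the boundary is irrelevant). When every
count sits at its β, y = 1 and the decision degenerates to the purely
textual x > λ − 1. A count above β for a π-feature raises y, i.e. lowers
the threshold; for a ν-feature it raises the threshold.

Degenerate textual cases: P = N = 0 (no known feature occurs) puts the
document on the boundary of the neutral decision, x = λ − 1, so entity
counts alone decide; N = 0 < P uses x = (λ − 1)·P.

Confidence is the distance to the surface, δ(d) = |x − T|, normalized by
the maximum δ seen on training data and clipped to [0, 1]. The ranking
lists predicted positives by decreasing confidence, then predicted
negatives by increasing confidence.

Classifier variants differ only in configuration: no entity features
(textual only), a single abstract-protein-count feature, three
abstract-scope features, or all five including caption and full-text
features; documents without full text take the neutral β for full-text
scoped features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .corpus_io import LabeledDocument
from .textual_features import PairFeatureTable, doc_bigrams, doc_sp_pairs

#: Sentinel for "this document lacks the section this count is measured on".
ABSENT = None


@dataclass
class VTTModel:
    lam: float
    table: PairFeatureTable
    positive_betas: dict[str, float] = field(default_factory=dict)  # EP
    negative_betas: dict[str, float] = field(default_factory=dict)  # EN
    max_delta_train: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        for name, b in {**self.positive_betas, **self.negative_betas}.items():
            if b <= 0:
                raise ValueError(f"beta for {name!r} must be positive")
        if set(self.positive_betas) & set(self.negative_betas):
            raise ValueError("EP and EN must be disjoint")

    @property
    def M(self) -> int:
        return len(self.positive_betas) + len(self.negative_betas)

    @property
    def feature_kind(self) -> str:
        return self.table.kind

    def save(self, path: Path, table_path: Path) -> None:
        self.table.write_tsv(table_path)
        payload = {
            "lambda": self.lam,
            "betas": {**self.positive_betas},
            "negative_betas": {**self.negative_betas},
            "feature_kind": self.table.kind,
            "table_path": str(table_path),
            "max_delta_train": self.max_delta_train,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: Path) -> "VTTModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        table = PairFeatureTable.read_tsv(
            Path(payload["table_path"]), kind=payload.get("feature_kind", "SP")
        )
        return cls(
            lam=payload["lambda"],
            table=table,
            positive_betas=dict(payload.get("betas", {})),
            negative_betas=dict(payload.get("negative_betas", {})),
            max_delta_train=payload.get("max_delta_train", 1.0),
        )


@dataclass(frozen=True)
class DecisionRecord:
    doc_id: str
    P: float
    N: float
    x: float
    y: float
    T: float
    label: str  # relevant | irrelevant
    delta: float
    C: float = 0.0


def doc_pairs(doc: LabeledDocument, table: PairFeatureTable) -> set[tuple[str, str]]:
    """The unique word-pair features of a document under the table's kind."""
    tokens = doc.tokens()
    if table.kind == "SP":
        assert table.vocabulary is not None
        return doc_sp_pairs(tokens, table.vocabulary)
    return doc_bigrams(tokens)


def contributions(
    pairs: Iterable[tuple[str, str]], table: PairFeatureTable
) -> tuple[float, float]:
    """Cosine/sine sums (P, N) over the document's occurring features.

    Each unique feature counts once; unknown pairs and pairs with
    p_P = p_N = 0 contribute nothing.
    """
    P = N = 0.0
    for pair in pairs:
        probs = table.lookup(pair)
        if probs is None:
            continue
        p_P, p_N = probs
        norm = math.hypot(p_P, p_N)
        if norm == 0.0:
            continue
        P += p_P / norm
        N += p_N / norm
    return P, N


def coordinates(
    P: float,
    N: float,
    counts: Mapping[str, Optional[float]],
    model: VTTModel,
) -> tuple[float, float]:
    """Place a document on the decision plane.

    ``counts`` maps each configured entity feature to its count, or to
    ``ABSENT`` (None) when the document lacks the feature's section; absent
    counts take the neutral β. Missing keys are likewise neutral.
    """
    if N > 0:
        x = P / N
    elif P > 0:
        x = (model.lam - 1.0) * P
    else:
        x = model.lam - 1.0
    y = 1.0
    if model.M:
        adj = 0.0
        for name, beta in model.positive_betas.items():
            n = counts.get(name, ABSENT)
            n = beta if n is ABSENT else n
            adj += (n - beta) / beta
        for name, beta in model.negative_betas.items():
            n = counts.get(name, ABSENT)
            n = beta if n is ABSENT else n
            adj -= (n - beta) / beta
        y += adj / model.M
    return x, y


def classify(
    doc: LabeledDocument,
    model: VTTModel,
    counts: Optional[Mapping[str, Optional[float]]] = None,
) -> DecisionRecord:
    """Classify one document: relevant iff x(d) > T(d) = λ − y(d)."""
    P, N = contributions(doc_pairs(doc, model.table), model.table)
    x, y = coordinates(P, N, counts or {}, model)
    T = model.lam - y
    delta = abs(x - T)
    return DecisionRecord(
        doc_id=doc.doc_id,
        P=P,
        N=N,
        x=x,
        y=y,
        T=T,
        label="relevant" if x > T else "irrelevant",
        delta=delta,
    )


def confidence_and_rank(
    records: Sequence[DecisionRecord], max_delta_train: float
) -> list[DecisionRecord]:
    """Attach clipped confidences and produce the submission ordering.

    C = min(1, δ/max_delta_train). Predicted positives come first by
    decreasing C, then predicted negatives by increasing C, so the list
    reads from most-confidently-relevant to most-confidently-irrelevant.
    """
    if max_delta_train <= 0:
        raise ValueError("max_delta_train must be positive")
    import dataclasses

    scored = [
        dataclasses.replace(r, C=min(1.0, r.delta / max_delta_train))
        for r in records
    ]
    positives = sorted(
        (r for r in scored if r.label == "relevant"),
        key=lambda r: (-r.C, r.doc_id),
    )
    negatives = sorted(
        (r for r in scored if r.label == "irrelevant"),
        key=lambda r: (r.C, r.doc_id),
    )
    return positives + negatives


def max_delta(records: Iterable[DecisionRecord]) -> float:
    """Training-set normalizer for the confidence measure."""
    return max((r.delta for r in records), default=0.0)
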
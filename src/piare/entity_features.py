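"""Entity-count features: cumulative class curves and feature screening.

An entity-count feature is a per-document mention count produced by an NER
or dictionary tool (e.g. protein mentions in the abstract). For each count
threshold x, the cumulative curves p_P(n ≥ x) and p_N(n ≥ x) give the
fraction of positive/negative documents with at least x mentions. A feature
is kept only when the curves separate: max over x ≥ 1 of |p_P − p_N|
strictly exceeds 0.3. The maximizing x becomes the feature's *neutral
point* β — the count at which the feature exerts no threshold adjustment in
the classifier — and the sign of the difference there decides whether the
feature correlates with the relevant or the irrelevant class.

Counts are consumed from TSV (``doc_id<TAB>feature_name<TAB>count``); the
tools themselves are out of scope. A document lacking the feature's text
scope (e.g. no full text) has no count at all — downstream the classifier
substitutes β for it — whereas a document with the scope but no row counts
as 0 mentions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

SELECTION_THRESHOLD = 0.3


@dataclass
class EntityCountFeature:
    name: str
    scope: str = "abstract"  # abstract | captions | fulltext
    counts: dict[str, int] = field(default_factory=dict)
    sign: str = "rejected"  # positive_with_P | positive_with_N | rejected
    beta_init: Optional[int] = None


@dataclass
class CumulativeCurve:
    """p_P(n ≥ x) and p_N(n ≥ x) over the integer grid x = 0..max count."""

    x: np.ndarray
    pP_ge: np.ndarray
    pN_ge: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.pP_ge - self.pN_ge

    def write_tsv(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("x\tp_P_ge\tp_N_ge\tdiff\n")
            for xi, pp, pn in zip(self.x, self.pP_ge, self.pN_ge):
                fh.write(f"{xi}\t{pp:.6g}\t{pn:.6g}\t{pp - pn:.6g}\n")


def read_counts_tsv(path: Path) -> dict[str, dict[str, int]]:
    """Read ``doc_id<TAB>feature<TAB>count`` into {feature: {doc_id: n}}."""
    out: dict[str, dict[str, int]] = {}
    for row_no, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed counts row {row_no}: {line!r}")
        doc_id, feat, count = parts
        n = int(count)
        if n < 0:
            raise ValueError(f"{path}: negative count at row {row_no}")
        out.setdefault(feat, {})[doc_id] = n
    return out


def cumulative_curve(
    counts: Mapping[str, int], labels: Mapping[str, str]
) -> CumulativeCurve:
    """Cumulative class curves for one feature.

    ``labels`` maps doc_id → positive/negative and defines the denominators
    (restrict it to the documents possessing the feature's scope). Missing
    counts are treated as 0.
    """
    pos_ids = [d for d, lab in labels.items() if lab == "positive"]
    neg_ids = [d for d, lab in labels.items() if lab == "negative"]
    if not pos_ids and not neg_ids:
        raise ValueError("no labeled documents")
    pos = np.array([counts.get(d, 0) for d in pos_ids], dtype=int)
    neg = np.array([counts.get(d, 0) for d in neg_ids], dtype=int)
    max_n = int(max(pos.max(initial=0), neg.max(initial=0)))
    x = np.arange(max_n + 1)
    pP = np.array([(pos >= xi).mean() if len(pos) else 0.0 for xi in x])
    pN = np.array([(neg >= xi).mean() if len(neg) else 0.0 for xi in x])
    return CumulativeCurve(x=x, pP_ge=pP, pN_ge=pN)


def select_feature(
    feature: EntityCountFeature,
    labels: Mapping[str, str],
    threshold: float = SELECTION_THRESHOLD,
) -> EntityCountFeature:
    """Screen one feature: selected iff max_{x≥1} |p_P−p_N| > threshold.

    Sets ``sign`` from the sign of the difference at the maximizing x and
    ``beta_init`` to that x (smallest x on ties).
    """
    curve = cumulative_curve(feature.counts, labels)
    if len(curve.x) < 2:
        feature.sign, feature.beta_init = "rejected", None
        return feature
    diff = curve.diff[1:]  # x >= 1 (x=0 is degenerate: both probabilities 1)
    best = int(np.argmax(np.abs(diff)))
    if abs(diff[best]) > threshold:
        feature.sign = "positive_with_P" if diff[best] > 0 else "positive_with_N"
        feature.beta_init = int(curve.x[1:][best])
    else:
        feature.sign, feature.beta_init = "rejected", None
    return feature


def select_features(
    features: list[EntityCountFeature],
    labels: Mapping[str, str],
    threshold: float = SELECTION_THRESHOLD,
) -> list[EntityCountFeature]:
    """Screen a feature list; returns only the selected features."""
    out = []
    for f in features:
        f = select_feature(f, labels, threshold)
        if f.sign != "rejected":
            out.append(f)
    return out


def plot_curve(curve: CumulativeCurve, name: str, out_path: Path) -> None:
    """Diagnostic chart of the two cumulative curves and their difference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.x, curve.pP_ge, color="green", label=r"$p_P(n \geq x)$")
    ax.plot(curve.x, curve.pN_ge, color="red", label=r"$p_N(n \geq x)$")
    ax.plot(curve.x, np.abs(curve.diff), color="blue", label=r"$|p_P - p_N|$")
    ax.set_xlabel("number of mentions x")
    ax.set_ylabel("probability of documents with ≥ x mentions")
    ax.set_title(name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
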
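"""Evaluation metrics and the robust rank-product grid search.

Classification quality is summarised by the balanced F-score, accuracy and
Matthews correlation coefficient; ranking quality by the area under the
interpolated precision-recall curve (AUCiP/R). Runs are compared by the
*rank product*: each run is ranked on every measure (1 = best, ties share
the minimal rank) and the ranks are multiplied, so a low product demands
consistently strong performance across measures. RP4 is the rank product
over AUCiP/R, F1, MCC and accuracy.

Training is an exhaustive parameter search with 4-fold (non-stratified)
cross-validation: per fold the feature table is built from 75% of the
documents and every (λ, β...) grid point is evaluated on the held-out 25%.
Parameter sets are compared by the rank product of the fold-mean F1,
accuracy and MCC. The search then refines: it collects the modal parameter
values over the *top echelon* (all sets sharing the minimal rank product),
re-grids finely around them and repeats — rewarding parameter regions whose
performance is robust to perturbation of the other parameters, not just the
single best point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus_io import Corpus
from .textual_features import (
    PairFeatureTable,
    extract_bigram_table,
    extract_sp_table,
)
from .vtt import VTTModel, classify, max_delta


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def f1(c: ConfusionCounts) -> float:
    denom = 2 * c.TP + c.FP + c.FN
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return 2 * c.TP / denom if denom else 0.0


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation; a zero denominator (degenerate margin) gives 0."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    denom = math.sqrt(
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / denom


def confusion(
    predicted: Mapping[str, str], gold: Mapping[str, str]
) -> ConfusionCounts:
    """Confusion counts from doc_id → relevant/irrelevant maps."""
    tp = tn = fp = fn = 0
    for doc_id, g in gold.items():
        p = predicted[doc_id]
        if g == "positive":
            tp, fn = (tp + 1, fn) if p == "relevant" else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if p == "relevant" else (fp, tn + 1)
    return ConfusionCounts(tp, tn, fp, fn)


def auc_ipr(ranked_ids: Sequence[str], gold_positive: set[str]) -> float:
    """Area under the interpolated precision-recall curve.

    Interpolated precision at recall r is the maximum precision at any
    recall ≥ r; the area is the mean of the interpolated precision at the
    recall points of the positives (step integration, one step of height
    p_int per positive).
    """
    if not gold_positive:
        raise ValueError("no positive documents in gold standard")
    precisions = []
    hits = 0
    for rank, doc_id in enumerate(ranked_ids, start=1):
        if doc_id in gold_positive:
            hits += 1
            precisions.append(hits / rank)
    if hits < len(gold_positive):
        raise ValueError("ranking does not cover all gold positives")
    interp = np.maximum.accumulate(np.asarray(precisions)[::-1])[::-1]
    return float(interp.mean())


def rank_product(metric_table: np.ndarray) -> np.ndarray:
    """Rank product per run over a runs × measures table (higher = better).

    Ranks are 1 = best; ties share the minimal rank. Lower products win.
    """
    table = np.asarray(metric_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise ValueError("metric table must be runs × measures")
    products = np.ones(table.shape[0])
    for j in range(table.shape[1]):
        col = table[:, j]
        # min-rank ("competition") ranking: rank = 1 + #strictly better
        ranks = np.array([1 + int((col > v).sum()) for v in col], dtype=float)
        products *= ranks
    return products


def rp4(metric_table: np.ndarray) -> np.ndarray:
    """Rank product over the four measures AUCiP/R, F1, MCC, Accuracy."""
    table = np.asarray(metric_table, dtype=float)
    if table.shape[1] != 4:
        raise ValueError("RP4 expects exactly four measures")
    return rank_product(table)


# ---------------------------------------------------------------------------
# Grid search


@dataclass
class SearchConfig:
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: [round(1.0 + 0.1 * i, 2) for i in range(21)]
    )
    #: multiplicative steps applied to each feature's beta_init
    beta_factors: Sequence[float] = field(
        default_factory=lambda: [0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0]
    )
    k_folds: int = 4
    refinement_rounds: int = 2
    seed: int = 0
    feature_kind: str = "SP"
    K: int = 1000

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if not self.lambda_grid:
            raise ValueError("lambda grid must be non-empty")


def _beta_grid(beta_init: float, factors: Sequence[float]) -> list[int]:
    vals = sorted({max(1, int(round(beta_init * f))) for f in factors})
    return vals


def _build_table(corpus: Corpus, config: SearchConfig) -> PairFeatureTable:
    if config.feature_kind == "SP":
        return extract_sp_table(corpus, K=config.K)
    return extract_bigram_table(corpus)


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def _eval_params(
    lam: float,
    betas: dict[str, float],
    fold_data: list[tuple[list, Mapping]],
    table_stub: PairFeatureTable,
) -> tuple[float, float, float]:
    """Fold-mean (F1, Acc, MCC) for one parameter set.

    fold_data holds, per fold, the precomputed held-out documents as
    (label, P, N, counts) tuples.
    """
    from .vtt import VTTModel as _M, coordinates

    model = _M(lam=lam, table=table_stub, positive_betas=dict(betas))
    f1s, accs, mccs = [], [], []
    for docs, _ in fold_data:
        tp = tn = fp = fn = 0
        for label, P, N, counts in docs:
            x, y = coordinates(P, N, counts, model)
            pred = x > model.lam - y
            if label == "positive":
                tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
        c = ConfusionCounts(tp, tn, fp, fn)
        f1s.append(f1(c))
        accs.append(accuracy(c))
        mccs.append(mcc(c))
    return float(np.mean(f1s)), float(np.mean(accs)), float(np.mean(mccs))


def _modal(values: Sequence[float]) -> float:
    uniq, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return float(uniq[np.argmax(counts)])  # ties -> smallest value


@dataclass
class SearchReport:
    rounds: list[list[dict]] = field(default_factory=list)

    def best_rows(self) -> list[dict]:
        return self.rounds[-1] if self.rounds else []


def grid_search(
    corpus: Corpus,
    counts_by_doc: Mapping[str, Mapping[str, Optional[float]]],
    beta_inits: Mapping[str, float],
    config: SearchConfig,
) -> tuple[VTTModel, SearchReport]:
    """Robust 5-step search over (λ, β...) with k-fold cross-validation.

    ``counts_by_doc`` maps doc_id → {feature: count or None (absent
    section)}; ``beta_inits`` gives each positive entity feature's initial
    neutral point (from the cumulative-curve maximizer). Returns the fitted
    model — feature table rebuilt on the full corpus, confidence normalizer
    included — and the per-round search report.
    """
    rng = np.random.default_rng(config.seed)
    folds = _fold_assignment(len(corpus), config.k_folds, rng)
    feat_names = sorted(beta_inits)

    # Per fold: build the table on the training 75%, precompute (P, N) and
    # counts for every held-out document. Parameter evaluation then never
    # touches raw text again.
    empty_stub: Optional[PairFeatureTable] = None
    fold_data: list[tuple[list, Mapping]] = []
    from .vtt import contributions, doc_pairs

    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([folds[j] for j in range(len(folds)) if j != i])
        table = _build_table(corpus.subset(train_idx), config)
        if empty_stub is None:
            empty_stub = table
        docs = []
        for idx in test_idx:
            doc = corpus.documents[int(idx)]
            P, N = contributions(doc_pairs(doc, table), table)
            doc_counts = counts_by_doc.get(doc.doc_id, {})
            docs.append((doc.label, P, N, doc_counts))
        fold_data.append((docs, table))

    lam_grid = list(config.lambda_grid)
    beta_grids = {
        name: _beta_grid(beta_inits[name], config.beta_factors)
        for name in feat_names
    }
    lam_step = (
        min(np.diff(sorted(set(lam_grid)))) if len(set(lam_grid)) > 1 else 0.1
    )

    report = SearchReport()
    best_overall: Optional[tuple] = None  # (-mcc, params) within final echelon

    for round_no in range(config.refinement_rounds + 1):
        param_sets = [
            (lam, dict(zip(feat_names, combo)))
            for lam in lam_grid
            for combo in itertools.product(
                *(beta_grids[n] for n in feat_names)
            )
        ] if feat_names else [(lam, {}) for lam in lam_grid]

        metrics = np.array(
            [
                _eval_params(lam, betas, fold_data, empty_stub)
                for lam, betas in param_sets
            ]
        )
        if not np.isfinite(metrics).all():
            raise RuntimeError("grid search produced non-finite metrics")
        rps = rank_product(metrics)
        rows = [
            {
                "lambda": lam,
                **{f"beta_{n}": betas[n] for n in feat_names},
                "F1": m[0],
                "Accuracy": m[1],
                "MCC": m[2],
                "rank_product": rp,
            }
            for (lam, betas), m, rp in zip(param_sets, metrics, rps)
        ]
        report.rounds.append(rows)

        top = rps.min()
        echelon = [i for i, r in enumerate(rps) if r == top]
        # Step 5: the pick comes from the final round's top echelon, ties
        # broken by higher fold-mean MCC then lexicographic parameters.
        best_overall = None
        for i in echelon:
            lam, betas = param_sets[i]
            key = (-metrics[i][2], (lam, *(betas[n] for n in feat_names)))
            if best_overall is None or key < best_overall[0]:
                best_overall = (key, lam, dict(betas))

        if round_no == config.refinement_rounds:
            break
        # Step 3-4: modal parameter values over the top echelon, refine.
        lam_modal = _modal([param_sets[i][0] for i in echelon])
        lam_step /= 2.0
        lam_grid = sorted(
            {round(max(lam_step, lam_modal + k * lam_step), 6) for k in range(-3, 4)}
        )
        for n in feat_names:
            b_modal = _modal([param_sets[i][1][n] for i in echelon])
            spread = max(1, int(round(b_modal * 0.25)) >> round_no)
            beta_grids[n] = sorted(
                {max(1, int(round(b_modal + k * max(1, spread // 2))))
                 for k in range(-3, 4)}
            )

    assert best_overall is not None
    _, lam_best, betas_best = best_overall

    final_table = _build_table(corpus, config)
    model = VTTModel(
        lam=lam_best, table=final_table, positive_betas=betas_best
    )
    train_records = [
        classify(doc, model, counts_by_doc.get(doc.doc_id, {})) for doc in corpus
    ]
    md = max_delta(train_records)
    model.max_delta_train = md if md > 0 else 1.0
    return model, report
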
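"""Cross-validation and performance evaluation.

k-fold CV with full per-fold retraining (no leakage: enrichment tables,
motifs and LR tables are all re-estimated from the training folds only),
the TP/FP-ratio cutoff curve, ROC/AUROC with a Hanley-McNeil 95% CI, the
C1/C2/C3 pair-input test partition, and a one-tailed Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .bayes_engine import (
    EvidenceInputs,
    TrainedModel,
    pair_set_fingerprint,
    predict,
    train_model,
)
from .config import ModelConfig
from .core_io import ESIPair, GoldStandard


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldAssignment:
    """pair -> fold index (1..k), assigned separately for each label so every
    fold preserves the positive:negative ratio."""

    folds: Mapping[ESIPair, int]
    k: int
    seed: int

    def fold_of(self, pair: ESIPair) -> int:
        return self.folds[pair]

    def members(self, fold: int, pairs: Iterable[ESIPair]) -> list[ESIPair]:
        return [p for p in pairs if self.folds[p] == fold]


def assign_folds(gold: GoldStandard, k: int, seed: int) -> FoldAssignment:
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: dict[ESIPair, int] = {}
    for pairs in (gold.positives, gold.negatives):
        ordered = sorted(pairs)
        if len(ordered) < k:
            raise ValueError(f"cannot split {len(ordered)} pairs into {k} folds")
        perm = rng.permutation(len(ordered))
        for rank, idx in enumerate(perm):
            folds[ordered[idx]] = rank % k + 1
    return FoldAssignment(folds, k, seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVRecord:
    pair: ESIPair
    label: int          # 1 = positive, 0 = negative
    lr_comp: float
    score: float
    fold: int


@dataclass
class CVOutcome:
    records: list[CVRecord]
    assignment: FoldAssignment
    #: per fold: fingerprints of the training positives, for leakage audits
    train_fingerprints: dict[int, str] = field(default_factory=dict)
    models: dict[int, TrainedModel] = field(default_factory=dict)


def kfold_cross_validate(
    gold: GoldStandard,
    inputs: EvidenceInputs,
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    *,
    keep_models: bool = False,
) -> CVOutcome:
    """Score every gold pair exactly once, by a model trained without it."""
    config = config or ModelConfig()
    gold.require_nonempty()
    assignment = assign_folds(gold, k, seed)
    records: list[CVRecord] = []
    outcome = CVOutcome([], assignment)
    for fold in range(1, k + 1):
        train_pos = frozenset(
            p for p in gold.positives if assignment.fold_of(p) != fold
        )
        train_neg = frozenset(
            p for p in gold.negatives if assignment.fold_of(p) != fold
        )
        fold_gold = GoldStandard(train_pos, train_neg)
        model = train_model(fold_gold, inputs, config, seed=seed * 1000 + fold)
        outcome.train_fingerprints[fold] = pair_set_fingerprint(train_pos | train_neg)
        if keep_models:
            outcome.models[fold] = model
        for label, pairs in ((1, gold.positives), (0, gold.negatives)):
            for pair in sorted(assignment.members(fold, pairs)):
                pred = predict(pair, model, inputs, with_provenance=False)
                records.append(
                    CVRecord(pair, label, pred.lr_comp, pred.score, fold)
                )
    outcome.records = records
    return outcome


def holdout_evaluate(
    train_gold: GoldStandard,
    test_pos: Iterable[ESIPair],
    test_neg: Iterable[ESIPair],
    inputs: EvidenceInputs,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> CVOutcome:
    """Independent-test-set protocol: train once, score a disjoint test set."""
    model = train_model(train_gold, inputs, config, seed=seed)
    assignment = FoldAssignment({}, k=1, seed=seed)
    records = []
    for label, pairs in ((1, test_pos), (0, test_neg)):
        for pair in sorted(pairs):
            pred = predict(pair, model, inputs, with_provenance=False)
            records.append(CVRecord(pair, label, pred.lr_comp, pred.score, 1))
    outcome = CVOutcome(records, assignment)
    outcome.train_fingerprints[1] = pair_set_fingerprint(
        train_gold.positives | train_gold.negatives
    )
    outcome.models[1] = model
    return outcome


# ---------------------------------------------------------------------------
# cutoff curves and ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CutoffPoint:
    lr_cutoff: float
    tp: int
    fp: int
    sensitivity: float
    specificity: float
    tp_fp_ratio: float      # inf when fp == 0 and tp > 0; nan when both 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.tp_fp_ratio)


def tp_fp_curve(
    records: Sequence[CVRecord], cutoffs: Sequence[float] | None = None
) -> list[CutoffPoint]:
    """TP/FP ratio as a function of LR cutoff, pooled across folds.

    A pair is called positive when its composite LR is >= the cutoff.  The
    default cutoff grid is every distinct observed LR.
    """
    if not records:
        raise ValueError("no records")
    t = sum(1 for r in records if r.label == 1)
    f = len(records) - t
    if t == 0 or f == 0:
        raise ValueError("need both labels to draw a cutoff curve")
    if cutoffs is None:
        cutoffs = sorted({r.lr_comp for r in records})
    pos_scores = np.sort([r.lr_comp for r in records if r.label == 1])
    neg_scores = np.sort([r.lr_comp for r in records if r.label == 0])
    points = []
    for cutoff in cutoffs:
        tp = int(len(pos_scores) - np.searchsorted(pos_scores, cutoff, side="left"))
        fp = int(len(neg_scores) - np.searchsorted(neg_scores, cutoff, side="left"))
        if fp > 0:
            ratio = tp / fp
        elif tp > 0:
            ratio = math.inf
        else:
            ratio = math.nan
        points.append(
            CutoffPoint(cutoff, tp, fp, tp / t, 1.0 - fp / f, ratio)
        )
    return points


@dataclass(frozen=True)
class ROCReport:
    points: tuple[CutoffPoint, ...]
    auroc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


def _auroc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUROC with ties counted 1/2."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    n1, n2 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n2))


def _hanley_mcneil_ci(a: float, n1: int, n2: int) -> tuple[float, float]:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    se = math.sqrt(max(var, 0.0))
    return (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))


def roc_auroc(records: Sequence[CVRecord]) -> ROCReport:
    """ROC sweep over all observed LR cutoffs plus the rank-statistic AUROC
    with its Hanley-McNeil 95% CI."""
    pos = np.array([r.lr_comp for r in records if r.label == 1], dtype=float)
    neg = np.array([r.lr_comp for r in records if r.label == 0], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both positive and negative records")
    auroc = _auroc_rank(pos, neg)
    ci = _hanley_mcneil_ci(auroc, len(pos), len(neg))
    points = tuple(tp_fp_curve(records))
    return ROCReport(points, auroc, ci, len(pos), len(neg))


# ---------------------------------------------------------------------------
# pair-input C1/C2/C3 partition
# ---------------------------------------------------------------------------


def park_partition(
    test: Iterable[ESIPair], train: Iterable[ESIPair]
) -> dict[ESIPair, str]:
    """Classify test pairs by component overlap with the training pairs.

    C1: both the E3 and the substrate occur in training pairs; C2: exactly
    one does; C3: neither does.
    """
    train_e3s = {p.e3 for p in train}
    train_subs = {p.substrate for p in train}
    out = {}
    for pair in test:
        seen = (pair.e3 in train_e3s) + (pair.substrate in train_subs)
        out[pair] = {2: "C1", 1: "C2", 0: "C3"}[seen]
    return out


def partition_cv_records(outcome: CVOutcome, gold: GoldStandard) -> dict[str, list[CVRecord]]:
    """Split CV records into C1/C2/C3 against each fold's training positives."""
    by_class: dict[str, list[CVRecord]] = {"C1": [], "C2": [], "C3": []}
    assignment = outcome.assignment
    for fold in range(1, assignment.k + 1):
        train_pos = [p for p in gold.positives if assignment.fold_of(p) != fold]
        fold_records = [r for r in outcome.records if r.fold == fold]
        classes = park_partition((r.pair for r in fold_records), train_pos)
        for record in fold_records:
            by_class[classes[record.pair]].append(record)
    return by_class


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The tail is taken in the direction of the observed deviation from
    independence (the smaller of the two hypergeometric tails; at exact
    independence both tails coincide).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be >= 0")
    if a + b == 0 or c + d == 0:
        raise ValueError("degenerate table: an entire row is zero")
    if a + c == 0 or b + d == 0:
        raise ValueError("degenerate table: an entire column is zero")
    n = a + b + c + d
    rv = stats.hypergeom(n, a + c, a + b)  # X = top-left cell count
    lower = float(rv.cdf(a))
    upper = float(rv.sf(a - 1))
    return min(lower, upper)
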
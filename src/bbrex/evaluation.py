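"""Relation-level scoring and the multi-seed robustness protocol.

Scores are relation-level precision / recall / F1 on the percent scale.
Gold positives carry an intra/inter-sentence flag: an inter-sentence gold
relation can never be predicted by an intra-sentence model, so it counts
as a false negative unconditionally.  Model robustness is summarized by
training the same architecture under many random seeds and reporting
mean / SD / min / max F1; two models are compared with Welch's two-sided
two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

logger = logging.getLogger(__name__)

__all__ = [
    "PRF",
    "SeedSummary",
    "f1_from_precision_recall",
    "prf_scores",
    "instance_prf",
    "seed_protocol",
    "compare_models_t_test",
    "precision_recall_sweep",
    "DEFAULT_CUTOFFS",
]

# 0.025 steps: includes the highlighted operating points 0.025, 0.5, 0.975
DEFAULT_CUTOFFS: tuple[float, ...] = tuple(round(0.025 * k, 3) for k in range(1, 40))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean on the percent scale; 0 when both rates are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        return f1_from_precision_recall(self.precision, self.recall)


@dataclass(frozen=True)
class SeedSummary:
    scores: tuple[float, ...]
    mean: float
    sd: float
    min: float
    max: float


def prf_scores(
    gold_relations: Iterable[tuple[Hashable, bool]],
    predicted_positive_pairs: Iterable[Hashable],
) -> PRF:
    """Relation-level counts against gold positives.

    ``gold_relations`` is an iterable of ``(pair_key, is_intra_sentence)``
    for the gold positives; ``predicted_positive_pairs`` is an iterable of
    pair keys.  Duplicate predictions collapse with a warning.  Every
    inter-sentence gold positive is a false negative unconditionally.
    """
    gold_intra: set = set()
    n_inter = 0
    for key, intra in gold_relations:
        if intra:
            gold_intra.add(key)
        else:
            n_inter += 1
    predicted = list(predicted_positive_pairs)
    pred_set = set(predicted)
    if len(pred_set) != len(predicted):
        logger.warning("%d duplicate predicted pairs collapsed", len(predicted) - len(pred_set))
    tp = len(pred_set & gold_intra)
    fp = len(pred_set - gold_intra)
    fn = len(gold_intra - pred_set) + n_inter
    return PRF(tp=tp, fp=fp, fn=fn)


def instance_prf(labels: Sequence[str], decisions: Sequence[str]) -> PRF:
    """Instance-level counts from aligned gold labels and decisions."""
    if len(labels) != len(decisions):
        raise ValueError("labels and decisions must align")
    tp = sum(1 for y, d in zip(labels, decisions) if y == "positive" and d == "positive")
    fp = sum(1 for y, d in zip(labels, decisions) if y != "positive" and d == "positive")
    fn = sum(1 for y, d in zip(labels, decisions) if y == "positive" and d != "positive")
    return PRF(tp=tp, fp=fp, fn=fn)


def seed_protocol(
    train_and_score: Callable[[int], float], n_seeds: int, base_seed: int = 0
) -> SeedSummary:
    """Mean-F1 robustness protocol over ``n_seeds`` consecutive seeds.

    ``train_and_score`` maps a seed to an F1 score (it trains a fresh model
    and evaluates it).  The sample standard deviation (n-1 denominator)
    requires at least two seeds.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds for a standard deviation")
    scores = tuple(float(train_and_score(seed)) for seed in range(base_seed, base_seed + n_seeds))
    arr = np.asarray(scores)
    return SeedSummary(
        scores=scores,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def compare_models_t_test(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Welch's two-sided two-sample t-test on F1 score samples.

    Two degenerate zero-variance samples with equal means give (0, 1) by
    convention; with unequal means the difference is certain, so p = 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 scores")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = _scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def precision_recall_sweep(
    prediction_records: Iterable[tuple[Hashable, float]],
    gold_relations: Iterable[tuple[Hashable, bool]],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[tuple[float, PRF]]:
    """PRF at every cutoff: a pair is predicted positive iff p >= cutoff.

    ``prediction_records`` is an iterable of ``(pair_key, p_positive)``.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff list")
    records = list(prediction_records)
    gold = list(gold_relations)
    out = []
    for cutoff in cutoffs:
        predicted = [key for key, p in records if p >= cutoff]
        out.append((cutoff, prf_scores(gold, predicted)))
    return out
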
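"""Repeated case-foil validation and rank-based evaluation.

The study design holds out one SICH case together with 9 non-SICH foils
(a realistic ~10% SICH frequency in each test set) and trains on the
remaining subjects; with 16 cases and 110 distinct foil sets per case this
gives 1760 train/test splits of 106/10.  For each split the model's signed
distances are ranked (rank 1 = most SICH-like); a case counts as
*identified* when its modal rank across its splits is 1.  A single ROC is
built per model from the pooled distances using ten evenly spaced
thresholds, and the probability of reaching a given identified count by
chance follows an exact binomial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class SplitPlan:
    """Case-foil splits: every test set is 1 SICH + 9 foils; the train set
    is everyone else."""

    splits: list[tuple[tuple[int, ...], tuple[int, ...]]]   # (train, test) ids
    case_ids: list[int]
    per_case_index: dict[int, list[int]]                    # case -> split rows
    seed: int | None = None

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_split_plan(is_sich: Sequence[bool], foil_sets_per_case: int = 110,
                    seed: int = 0, foils_per_set: int = 9) -> SplitPlan:
    """Build the repeated case-foil split plan.

    For each SICH case, ``foil_sets_per_case`` mutually distinct sets of
    ``foils_per_set`` controls are drawn uniformly without replacement
    within a set.  Deterministic given the seed.
    """
    y = np.asarray(is_sich, dtype=bool)
    cases = np.flatnonzero(y)
    controls = np.flatnonzero(~y)
    if len(controls) < foils_per_set:
        raise ValueError(f"need at least {foils_per_set} non-SICH subjects")
    capacity = comb(len(controls), foils_per_set)
    if foil_sets_per_case > capacity:
        raise ValueError(
            f"{foil_sets_per_case} distinct foil sets requested but only "
            f"{capacity} exist")
    rng = np.random.default_rng(seed)
    all_ids = set(range(len(y)))
    splits: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    per_case: dict[int, list[int]] = {}
    for case in cases:
        seen: set[frozenset] = set()
        rows = []
        attempts = 0
        while len(seen) < foil_sets_per_case:
            attempts += 1
            if attempts > 200 * foil_sets_per_case + 1000:
                raise RuntimeError("could not draw enough distinct foil sets")
            foils = rng.choice(controls, size=foils_per_set, replace=False)
            key = frozenset(int(f) for f in foils)
            if key in seen:
                continue
            seen.add(key)
            test = tuple(sorted([int(case)] + [int(f) for f in foils]))
            train = tuple(sorted(all_ids - set(test)))
            rows.append(len(splits))
            splits.append((train, test))
        per_case[int(case)] = rows
    return SplitPlan(splits=splits, case_ids=[int(c) for c in cases],
                     per_case_index=per_case, seed=seed)


def rank_test_set(distances: Sequence[float],
                  subject_ids: Sequence[int] | None = None) -> np.ndarray:
    """Ranks 1..n over a test set, rank 1 = most SICH-like (most negative
    distance).  Ties break by subject id order, so the result is a
    deterministic permutation."""
    d = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite decision distance")
    ids = np.arange(len(d)) if subject_ids is None else np.asarray(subject_ids)
    order = np.lexsort((ids, d))
    ranks = np.empty(len(d), dtype=int)
    ranks[order] = np.arange(1, len(d) + 1)
    return ranks


@dataclass
class EvaluationResult:
    plan: SplitPlan
    distances: np.ndarray           # (n_splits, 10)
    ranks: np.ndarray               # (n_splits, 10)
    case_rank_per_split: np.ndarray  # rank of the SICH subject in each split
    modal_rank: dict[int, int]      # case id -> modal rank
    identified: int                 # cases with modal rank 1
    auc: float
    pooled_distances: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)


def modal_rank_summary(plan: SplitPlan,
                       case_rank_per_split: np.ndarray) -> tuple[dict[int, int], int]:
    """Most frequent rank of each case across its splits (ties toward the
    smaller rank) and the count of cases with modal rank 1."""
    modal: dict[int, int] = {}
    for case, rows in plan.per_case_index.items():
        if not rows:
            raise ValueError(f"case {case} has no splits")
        ranks = case_rank_per_split[rows]
        counts = np.bincount(ranks)
        modal[case] = int(np.argmax(counts))   # argmax takes the smaller rank on ties
    identified = sum(1 for r in modal.values() if r == 1)
    return modal, identified


def auc_ten_thresholds(distances: Sequence[float], is_sich: Sequence[bool],
                       n_thresholds: int = 10) -> float:
    """AUC from a ten-point ROC: thresholds evenly spaced over the pooled
    distance range; a subject is called SICH when its distance is at or
    below the threshold (negative = SICH-like).  The trapezoid runs over the
    threshold points augmented with (0,0) and (1,1)."""
    d = np.asarray(distances, dtype=float)
    y = np.asarray(is_sich, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need both outcome classes among pooled predictions")
    lo, hi = d.min(), d.max()
    if lo == hi:
        warnings.warn("degenerate pooled distance range; AUC is chance level")
        return 0.5
    thresholds = np.linspace(lo, hi, n_thresholds)
    pred = d[None, :] <= thresholds[:, None]
    tpr = (pred & y).sum(axis=1) / y.sum()
    fpr = (pred & ~y).sum(axis=1) / (~y).sum()
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def evaluate(plan: SplitPlan, is_sich: Sequence[bool],
             distance_fn: Callable[[tuple[int, ...], tuple[int, ...]], np.ndarray]
             ) -> EvaluationResult:
    """Run a model over every split of a plan.

    ``distance_fn(train_ids, test_ids)`` returns the signed distances of the
    test subjects (in test-id order); training-free models (prognostic
    scores) simply ignore the train ids.
    """
    y = np.asarray(is_sich, dtype=bool)
    n_test = len(plan.splits[0][1])
    distances = np.empty((plan.n_splits, n_test))
    ranks = np.empty((plan.n_splits, n_test), dtype=int)
    case_rank = np.empty(plan.n_splits, dtype=int)
    for k, (train, test) in enumerate(plan.splits):
        d = np.asarray(distance_fn(train, test), dtype=float)
        distances[k] = d
        ranks[k] = rank_test_set(d, subject_ids=test)
        case_pos = [p for p, t in enumerate(test) if y[t]]
        case_rank[k] = ranks[k][case_pos[0]]
    modal, identified = modal_rank_summary(plan, case_rank)
    pooled = distances.ravel()
    pooled_labels = np.concatenate([y[list(test)] for _, test in plan.splits])
    auc = auc_ten_thresholds(pooled, pooled_labels)
    return EvaluationResult(plan=plan, distances=distances, ranks=ranks,
                            case_rank_per_split=case_rank, modal_rank=modal,
                            identified=identified, auc=auc,
                            pooled_distances=pooled, pooled_labels=pooled_labels)


def binomial_chance_probability(n_tests: int, n_hits: int, p: float) -> float:
    """Exact binomial point mass P(X = k), X ~ Binomial(n, p), with the
    binomial coefficient computed in exact integer arithmetic."""
    if not 0 <= n_hits <= n_tests:
        raise ValueError("n_hits must lie in [0, n_tests]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    pf = Fraction(p)
    mass = comb(n_tests, n_hits) * pf ** n_hits * (1 - pf) ** (n_tests - n_hits)
    return float(mass)


def binomial_tail_probability(n_tests: int, n_hits: int, p: float) -> float:
    """P(X >= k) under the same exact binomial."""
    if not 0 <= n_hits <= n_tests:
        raise ValueError("n_hits must lie in [0, n_tests]")
    pf = Fraction(p)
    total = sum(comb(n_tests, k) * pf ** k * (1 - pf) ** (n_tests - k)
                for k in range(n_hits, n_tests + 1))
    return float(total)


def _case_subset_auc(result: EvaluationResult, case_rows: np.ndarray) -> float:
    d = result.distances[case_rows].ravel()
    y = result.pooled_labels.reshape(result.distances.shape)[case_rows].ravel()
    if y.all() or not y.any() or d.min() == d.max():
        return 0.5
    return auc_ten_thresholds(d, y)


def compare_models(results: Mapping[str, EvaluationResult],
                   n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Table-2-shaped comparison of evaluated models.

    AUC confidence intervals and pairwise p-values against the first
    (reference) model come from a paired bootstrap over SICH cases: cases
    are resampled with replacement, each model's pooled ten-threshold AUC is
    recomputed on the resampled splits, and the two-sided p-value is the
    bootstrap tail probability of the AUC difference crossing zero.  The
    pairing (same resampled cases for all models) is what makes the
    comparison honest on a shared split plan.
    """
    names = list(results)
    if len(names) < 1:
        raise ValueError("no models to compare")
    ref = results[names[0]]
    case_list = ref.plan.case_ids
    for name in names[1:]:
        if results[name].plan.splits != ref.plan.splits:
            raise ValueError("models were evaluated on different split plans")

    rng = np.random.default_rng(seed)
    boot_aucs = {name: np.empty(n_boot) for name in names}
    rows_by_case = {c: np.asarray(ref.plan.per_case_index[c]) for c in case_list}
    for b in range(n_boot):
        sampled = rng.choice(case_list, size=len(case_list), replace=True)
        rows = np.concatenate([rows_by_case[c] for c in sampled])
        for name in names:
            boot_aucs[name][b] = _case_subset_auc(results[name], rows)

    out = []
    for name in names:
        res = results[name]
        diffs = boot_aucs[names[0]] - boot_aucs[name]
        if name == names[0]:
            p = 1.0
        else:
            p_low = float(np.mean(diffs <= 0))
            p_high = float(np.mean(diffs >= 0))
            p = min(1.0, 2.0 * min(p_low, p_high))
        row = {
            "model": name,
            "auc": res.auc,
            "auc_ci_low": float(np.quantile(boot_aucs[name], 0.025)),
            "auc_ci_high": float(np.quantile(boot_aucs[name], 0.975)),
            "identified": res.identified,
            "p_vs_reference": p,
        }
        for c in case_list:
            row[f"modal_rank_case_{c}"] = res.modal_rank[c]
        out.append(row)
    df = pd.DataFrame(out)
    df.attrs["note"] = ("p_vs_reference is a paired case-bootstrap surrogate; "
                        "the original comparison procedure is not specified")
    return df
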
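"""Performance metrics, jackknife and k-fold protocols, and the parameter
grid search that selects the ten ensemble members.

Metrics follow the error-rate formulation common in this literature:
Sn = 1 - FN/N+, Sp = 1 - FP/N-, Acc = 1 - (FN+FP)/(N+ + N-), and the
Matthews correlation coefficient in its reformulated shape

    MCC = [1 - (FN/N+ + FP/N-)] / sqrt[(1 + (FP-FN)/N+) * (1 + (FN-FP)/N-)]

which is algebraically the textbook (TP*TN - FP*FN)/sqrt(...) form. AUC is
the rank-based (midrank-tied) area under the ROC curve, equal to the
normalised Mann-Whitney U statistic.

The jackknife (leave-one-out) protocol retrains the supplied pipeline for
every held-out sample and pools the left-out scores, so the result is unique
for a fixed dataset and fixed seeds. For parameter optimisation, stratified
5-fold cross-validation is used instead, at much lower cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import (
    NumericDegeneracyError,
    ParameterSequenceError,
    PsekgccParams,
    encode_matrix,
    partition_windows,
)
from .model import BasicPredictor, ForestConfig, predict_proba, train_forest
from .seqio import DnaRecord

logger = logging.getLogger(__name__)

# pipeline signature: (X_train, y_train, X_test) -> positive-class scores
Pipeline = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts at a fixed threshold: N+, N-, and the two error counts."""

    n_pos: int
    n_neg: int
    false_neg: int  # positives predicted negative
    false_pos: int  # negatives predicted positive

    def __post_init__(self) -> None:
        if not (0 <= self.false_neg <= self.n_pos):
            raise ValueError(f"false_neg={self.false_neg} outside [0, {self.n_pos}]")
        if not (0 <= self.false_pos <= self.n_neg):
            raise ValueError(f"false_pos={self.false_pos} outside [0, {self.n_neg}]")

    @classmethod
    def from_predictions(
        cls, labels: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(predicted, dtype=int)
        return cls(
            n_pos=int((y == 1).sum()),
            n_neg=int((y == 0).sum()),
            false_neg=int(((y == 1) & (p == 0)).sum()),
            false_pos=int(((y == 0) & (p == 1)).sum()),
        )


@dataclass(frozen=True)
class Metrics:
    """Sn/Sp/Acc in [0,1], MCC in [-1,1], optional AUC; ``mcc_degenerate`` is
    set when the MCC denominator vanished and 0 was reported by convention."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float | None = None
    mcc_degenerate: bool = False

    def as_dict(self) -> dict:
        d = {"sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        if self.mcc_degenerate:
            d["mcc_degenerate"] = True
        return d


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sn, Sp, Acc and MCC from confusion counts (AUC needs scores, not counts)."""
    n_pos, n_neg = counts.n_pos, counts.n_neg
    fn, fp = counts.false_neg, counts.false_pos
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be present")
    sn = 1.0 - fn / n_pos
    sp = 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    denom_sq = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
    num = 1.0 - (fn / n_pos + fp / n_neg)
    degenerate = denom_sq <= 0
    # denom_sq == 0 iff a predicted class is empty (TP+FP == 0 or TN+FN == 0)
    mcc = 0.0 if degenerate else num / np.sqrt(denom_sq)
    if degenerate:
        logger.warning("degenerate prediction (one predicted class empty); MCC set to 0")
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=float(mcc), mcc_degenerate=degenerate)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC with midrank tie handling."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def metrics_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Threshold scores (strictly greater than) and attach the AUC."""
    predicted = (np.asarray(scores) > threshold).astype(int)
    counts = ConfusionCounts.from_predictions(labels, predicted)
    m = compute_metrics(counts)
    return Metrics(
        sn=m.sn, sp=m.sp, acc=m.acc, mcc=m.mcc,
        auc=compute_auc(scores, labels), mcc_degenerate=m.mcc_degenerate,
    )


@dataclass(frozen=True)
class CvPlan:
    """Cross-validation plan. The jackknife has no randomness of its own;
    k-fold shuffling is controlled by ``seed``."""

    scheme: str = "kfold"  # "jackknife" | "kfold"
    n_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("jackknife", "kfold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic row order independent of input ordering: sort by label,
    then lexicographically by feature bytes. Makes retrained forests (whose
    bootstrap draws are index-based) invariant to dataset row permutations."""
    keys = [tuple(row) for row in np.column_stack([y[:, None], X])]
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))


def jackknife_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    pipeline: Pipeline,
    threshold: float = 0.5,
) -> tuple[Metrics, np.ndarray]:
    """Leave-one-out evaluation: retrain the pipeline on the other N-1 samples
    for every sample, then pool the left-out scores.

    Training rows are put in a canonical order before each fit so the result
    is unique for a dataset regardless of row order. Returns (metrics,
    per-sample scores in input order).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = X.shape[0]
    if n < 2 or len(np.unique(y)) < 2:
        raise ValueError("jackknife needs >= 2 samples with both classes")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        order = _canonical_order(X_tr, y_tr)
        try:
            scores[i] = float(pipeline(X_tr[order], y_tr[order], X[i : i + 1])[0])
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on jackknife fold {i}: {exc}") from exc
    return metrics_from_scores(scores, y, threshold), scores


def kfold_evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    pipeline: Pipeline,
    plan: CvPlan | None = None,
    threshold: float = 0.5,
) -> tuple[Metrics, np.ndarray]:
    """Stratified k-fold evaluation pooling out-of-fold scores.

    Deterministic given ``plan.seed``; if a training fold ever lacks a class
    the folds are reshuffled once (seed+1) before giving up.
    """
    plan = plan or CvPlan()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    for attempt, seed in enumerate((plan.seed, plan.seed + 1)):
        skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=seed)
        scores = np.empty(X.shape[0])
        ok = True
        for tr, te in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                ok = False
                break
            scores[te] = pipeline(X[tr], y[tr], X[te])
        if ok:
            return metrics_from_scores(scores, y, threshold), scores
    raise ValueError("a training fold lacks one class even after reshuffling")


def forest_pipeline(config: ForestConfig | None = None) -> Pipeline:
    """Standard pipeline closure: fit one forest, return positive probabilities."""
    fc = config or ForestConfig()

    def run(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray) -> np.ndarray:
        return predict_proba(train_forest(X_tr, y_tr, fc), X_te)

    return run


def _frange(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for the five encoder parameters.

    Defaults: epsilon 0.15..0.50 step 0.05 (8), delta 0.55..0.85 step 0.05
    (7), k 3..7 (5), lambda {1, 4, 7, 10}, w 0.1..1.0 step 0.1 (10) —
    11 200 combinations before validity filtering.
    """

    epsilons: tuple = tuple(_frange(0.15, 0.50, 0.05))
    deltas: tuple = tuple(_frange(0.55, 0.85, 0.05))
    ks: tuple = (3, 4, 5, 6, 7)
    lams: tuple = (1, 4, 7, 10)
    ws: tuple = tuple(_frange(0.1, 1.0, 0.1))

    def combinations(self) -> list[PsekgccParams]:
        return [
            PsekgccParams(epsilon=e, delta=d, k=k, lam=lam, w=w)
            for e, d, k, lam, w in product(
                self.epsilons, self.deltas, self.ks, self.lams, self.ws
            )
        ]

    @property
    def size(self) -> int:
        return (
            len(self.epsilons) * len(self.deltas) * len(self.ks)
            * len(self.lams) * len(self.ws)
        )

    @classmethod
    def reduced(cls) -> "GridSpec":
        """Coarse grid for quick runs; defaults reproduce the full search."""
        return cls(
            epsilons=(0.15, 0.25, 0.35, 0.5),
            deltas=(0.55, 0.7, 0.85),
            ks=(3, 5),
            lams=(1, 4),
            ws=(0.1, 0.5, 1.0),
        )


def params_valid_for_lengths(params: PsekgccParams, lengths: Sequence[int]) -> bool:
    """True iff every sequence length supports (epsilon, delta, k, lambda)."""
    for L in set(lengths):
        try:
            part = partition_windows(L, params.epsilon, params.delta)
        except ValueError:
            return False
        wmin = min(part.window_lengths)
        if wmin < params.k or params.lam > wmin:
            return False
    return True


@dataclass
class GridResult:
    params: PsekgccParams
    metrics: Metrics


def grid_search(
    records: Sequence[DnaRecord],
    labels: np.ndarray,
    grid: GridSpec | None = None,
    plan: CvPlan | None = None,
    forest_config: ForestConfig | None = None,
) -> list[GridResult]:
    """Evaluate every valid parameter combination with stratified 5-fold CV.

    Each combination trains a single (non-ensemble) forest per fold;
    combinations that violate the window/k or lambda constraints for any
    sequence are skipped with a log line. Results are ranked by AUC, ties
    broken by Acc.
    """
    grid = grid or GridSpec()
    plan = plan or CvPlan()
    combos = grid.combinations()
    if not combos:
        raise ValueError("empty parameter grid")
    y = np.asarray(labels, dtype=int)
    lengths = [r.length for r in records]
    pipeline = forest_pipeline(forest_config)
    results: list[GridResult] = []
    n_skipped = 0
    for params in combos:
        if not params_valid_for_lengths(params, lengths):
            n_skipped += 1
            logger.info("skipping invalid combination %s", params)
            continue
        try:
            X = encode_matrix(records, params).to_numpy()
        except NumericDegeneracyError as exc:
            n_skipped += 1
            logger.info("skipping degenerate combination %s (%s)", params, exc)
            continue
        metrics, _ = kfold_evaluate(X, y, pipeline, plan)
        results.append(GridResult(params=params, metrics=metrics))
    if not results:
        raise ValueError(
            "no valid parameter combination: window/k or lambda constraints "
            f"exclude all {len(combos)} combinations for these sequence lengths"
        )
    logger.info("grid search: %d evaluated, %d skipped", len(results), n_skipped)
    results.sort(key=lambda r: (-(r.metrics.auc or 0.0), -r.metrics.acc))
    return results


def select_top_members(ranked: Sequence[GridResult], n: int = 10) -> list[PsekgccParams]:
    """The n best distinct parameter combinations, preserving rank order."""
    if len(ranked) < n:
        raise ValueError(f"need at least {n} ranked combinations, got {len(ranked)}")
    params = [r.params for r in ranked]
    if len(set(params)) != len(params):
        raise ValueError("duplicate parameter combinations in ranked input")
    return params[:n]
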
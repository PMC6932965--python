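"""Evaluation protocols and performance statistics.

Provides the four standard binary-classification statistics (sensitivity,
specificity, accuracy, Matthews correlation coefficient), leave-one-out
(jackknife) evaluation with full ensemble retraining per fold, single-pass
independent-set evaluation, and nested grid-search calibration over feature
parameters (k, lambda, omega) and SVM hyperparameters (c, gamma, w).

MCC uses the standard denominator sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when
any factor is zero the statistic is undefined and reported as None with a
flag rather than silently coerced to 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ensemble import (NEGATIVE, POSITIVE, EnsembleModel, LabeledDataset,
                       SVMParams, predict_vote, train_ensemble)
from .pseaac import (FeatureParams, PropertyScale, SequenceTooShortError,
                     featurize_table)
from .seqio import ProteinSequence, ResidueProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class PerformanceReport:
    """Sen/Spe/Acc/MCC; a statistic is None when its denominator vanishes."""

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    mcc: float | None
    undefined: tuple[str, ...] = ()

    def as_percent(self) -> dict[str, float | None]:
        """Rates as percentages rounded to one decimal (MCC included)."""
        def pct(x):
            return None if x is None else round(100 * x, 1)
        return {"sensitivity": pct(self.sensitivity),
                "specificity": pct(self.specificity),
                "accuracy": pct(self.accuracy),
                "mcc": pct(self.mcc)}


def counts_from_predictions(labels: np.ndarray,
                            predictions: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    return ConfusionCounts(
        TP=int(((labels == POSITIVE) & (predictions == POSITIVE)).sum()),
        TN=int(((labels == NEGATIVE) & (predictions == NEGATIVE)).sum()),
        FP=int(((labels == NEGATIVE) & (predictions == POSITIVE)).sum()),
        FN=int(((labels == POSITIVE) & (predictions == NEGATIVE)).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Sensitivity, specificity, accuracy and MCC from confusion counts."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    undefined: list[str] = []
    n_pos = counts.TP + counts.FN
    n_neg = counts.TN + counts.FP
    sen = counts.TP / n_pos if n_pos else None
    spe = counts.TN / n_neg if n_neg else None
    if sen is None:
        undefined.append("sensitivity")
    if spe is None:
        undefined.append("specificity")
    acc = (counts.TP + counts.TN) / counts.total
    factors = [counts.TP + counts.FP, counts.TP + counts.FN,
               counts.TN + counts.FP, counts.TN + counts.FN]
    if any(f == 0 for f in factors):
        mcc = None
        undefined.append("mcc")
    else:
        mcc = (counts.TP * counts.TN - counts.FP * counts.FN) / \
            math.sqrt(math.prod(float(f) for f in factors))
    return PerformanceReport(counts=counts, sensitivity=sen, specificity=spe,
                             accuracy=acc, mcc=mcc,
                             undefined=tuple(undefined))


def jackknife(data: LabeledDataset, hyperparams: SVMParams,
              feature_params: FeatureParams, seed: int,
              reshuffle_per_fold: bool = True
              ) -> tuple[PerformanceReport, pd.DataFrame]:
    """Leave-one-out evaluation with full retraining per fold.

    For each sample i the ensemble is retrained on the remaining n-1
    samples and predicts sample i.  By default the negative partition is
    re-derived per fold from the fold-indexed seed ``seed + i``; with
    ``reshuffle_per_fold=False`` every fold reuses ``seed``.  A fold whose
    training remainder lacks a class is flagged and skipped; the run
    continues.  Deterministic given ``seed``.
    """
    n = data.features.shape[0]
    if n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("jackknife needs both classes present")
    records = []
    predictions = np.full(n, -1)
    for i in range(n):
        keep = np.setdiff1d(np.arange(n), [i])
        fold = data.subset(keep)
        if fold.n_pos == 0 or fold.n_neg == 0:
            logger.warning("fold %d leaves a single-class training set; "
                           "flagged and skipped", i)
            records.append((data.ids[i], int(data.labels[i]), None))
            continue
        fold_seed = (seed + i) % (2 ** 31) if reshuffle_per_fold else seed
        model = train_ensemble(fold, hyperparams, feature_params, fold_seed)
        pred, _ = predict_vote(model, data.features[i])
        predictions[i] = pred[0]
        records.append((data.ids[i], int(data.labels[i]), int(pred[0])))
    evaluated = predictions >= 0
    counts = counts_from_predictions(data.labels[evaluated],
                                     predictions[evaluated])
    table = pd.DataFrame(records, columns=["id", "label", "prediction"])
    return compute_metrics(counts), table


def independent_test(model: EnsembleModel,
                     test: LabeledDataset) -> PerformanceReport:
    """Single prediction pass of a trained ensemble over a held-out set."""
    if test.features.shape[0] == 0:
        raise ValueError("independent test set is empty")
    if test.features.shape[1] != model.n_features:
        raise ValueError("test feature dimension does not match the model")
    predictions, _ = predict_vote(model, test.features)
    return compute_metrics(counts_from_predictions(test.labels, predictions))


@dataclass(frozen=True)
class GridSpec:
    """Search grids for the nested calibration.

    The documented benchmark grid is k in {0, 0.01, 0.1, 1, 1.5}, lambda
    2..20 step 1, omega 0.05..0.95 step 0.05, with an inner (c, gamma, w)
    search; full replication is compute-heavy, so callers typically pass a
    reduced subset.
    """

    k_values: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0, 1.5)
    lambda_values: tuple[int, ...] = tuple(range(2, 21))
    omega_values: tuple[float, ...] = tuple(
        round(0.05 * i, 2) for i in range(1, 20))
    c_values: tuple[float, ...] = (1000.0,)
    gamma_values: tuple[float, ...] = (0.01,)
    w_values: tuple[float, ...] = (1.2,)
    objective: str = "accuracy"

    def __post_init__(self) -> None:
        for name in ("k_values", "lambda_values", "omega_values",
                     "c_values", "gamma_values", "w_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if any(l < 1 or int(l) != l for l in self.lambda_values):
            raise ValueError("lambda values must be integers >= 1")
        if self.objective not in ("accuracy", "sensitivity", "specificity",
                                  "mcc"):
            raise ValueError(f"unknown objective {self.objective!r}")


def grid_search(seqs: list[ProteinSequence], profiles: list[ResidueProfile],
                labels: np.ndarray, grid: GridSpec,
                scales: tuple[PropertyScale, PropertyScale], seed: int,
                reshuffle_per_fold: bool = True
                ) -> tuple[dict, pd.DataFrame]:
    """Nested grid search optimizing the jackknife objective.

    The outer loop recomputes features for each (k, lambda, omega) combo;
    the inner loop scans (c, gamma, w).  Combos whose lambda reaches the
    shortest sequence length are skipped with a warning.  Ties break to the
    first combo encountered in declared grid order.  Returns the best
    parameter combo (with its report) and the full results table.
    """
    labels = np.asarray(labels)
    ids = [s.id for s in seqs]
    rows = []
    best: dict | None = None
    for k, lam, omega in itertools.product(grid.k_values, grid.lambda_values,
                                           grid.omega_values):
        fp = FeatureParams(k=k, lam=int(lam), omega=omega)
        try:
            table = featurize_table(seqs, profiles, fp, scales)
        except SequenceTooShortError as exc:
            logger.warning("skipping combo k=%s lambda=%s omega=%s: %s",
                           k, lam, omega, exc)
            continue
        data = LabeledDataset(table.to_numpy(), labels, ids)
        for c, gamma, w in itertools.product(grid.c_values,
                                             grid.gamma_values,
                                             grid.w_values):
            hp = SVMParams(c=c, gamma=gamma, w=w)
            report, _ = jackknife(data, hp, fp, seed,
                                  reshuffle_per_fold=reshuffle_per_fold)
            score = getattr(report, grid.objective)
            rows.append({"k": k, "lambda": int(lam), "omega": omega,
                         "c": c, "gamma": gamma, "w": w,
                         "sensitivity": report.sensitivity,
                         "specificity": report.specificity,
                         "accuracy": report.accuracy, "mcc": report.mcc})
            if score is not None and (best is None or score > best["score"]):
                best = {"feature_params": fp, "svm_params": hp,
                        "score": score, "report": report}
    if best is None:
        raise ValueError("no grid combination could be evaluated")
    return best, pd.DataFrame(rows)
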
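"""Cross-validation protocol, precision-recall evaluation, and case-study ranking.

Three cross-validation settings are supported, mirroring the standard DTI
benchmarking protocol:

* ``cv1_pairs``   — folds partition the d*t drug-target *cells*; held-out
  cells are hidden from training through a binary weight mask on the
  likelihood (regularizers unaffected), so no test label leaks into the fit.
* ``cv2_drugs``   — folds partition drug rows; test drugs are removed from
  the training matrix entirely and scored cold-start via a similarity-
  weighted average of the K most similar training drugs' latent vectors.
* ``cv3_targets`` — the symmetric setting over target columns.

Each fold is scored by the area under the precision-recall curve (AUPR),
computed by the step-wise average-precision rule over distinct score
thresholds (tied scores are processed as one block, so a constant score
vector scores exactly the positive rate). Per-fold AUPRs are averaged within
a repetition, and results aggregate as mean +/- standard deviation over
repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve

from .core import (
    HyperParams,
    InteractionMatrix,
    PredictionMatrix,
    SimilarityMatrix,
    fit,
    infer_new_latent,
    logistic_prob,
)

logger = logging.getLogger("dlgrlmf")

__all__ = [
    "CVPlan",
    "PRCurve",
    "CVResult",
    "make_cv_plan",
    "evaluate_fold",
    "run_cv",
    "top_k_predictions",
    "random_cell_mask",
]

_SETTINGS = ("cv1_pairs", "cv2_drugs", "cv3_targets")


@dataclass
class CVPlan:
    """Cross-validation configuration: setting, fold count, repetitions, seed."""

    setting: str = "cv1_pairs"
    folds: int = 10
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in _SETTINGS:
            raise ValueError(f"setting must be one of {_SETTINGS}, got {self.setting!r}")
        if self.folds < 2:
            raise ValueError("at least 2 folds are required")
        if self.repetitions < 1:
            raise ValueError("at least 1 repetition is required")


@dataclass
class PRCurve:
    """Precision-recall points (recall non-decreasing) and the area under them."""

    points: list[tuple[float, float]]
    aupr: float


@dataclass
class CVResult:
    """Per-fold AUPRs with mean +/- std aggregated over repetitions."""

    setting: str
    per_fold_aupr: list[list[float]]  # [repetition][fold]
    per_repetition_mean: list[float]
    mean_aupr: float
    std_aupr: float
    pooled_aupr: list[float] = field(default_factory=list)  # one pooled-prediction AUPR per repetition


def make_cv_plan(A: InteractionMatrix | np.ndarray, plan: CVPlan) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Build reproducible train/test boolean cell masks, [repetition][fold] -> (train, test).

    cv1 partitions all d*t cells into near-equal disjoint folds; cv2
    partitions drug rows; cv3 partitions target columns. Within one
    repetition the test folds are disjoint and exhaustive.
    """
    Av = A.values if isinstance(A, InteractionMatrix) else np.asarray(A)
    d, t = Av.shape
    if plan.setting == "cv2_drugs" and d < plan.folds:
        raise ValueError(f"cv2 needs at least as many drugs ({d}) as folds ({plan.folds})")
    if plan.setting == "cv3_targets" and t < plan.folds:
        raise ValueError(f"cv3 needs at least as many targets ({t}) as folds ({plan.folds})")
    rng = np.random.default_rng(plan.seed)
    reps: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for _ in range(plan.repetitions):
        folds: list[tuple[np.ndarray, np.ndarray]] = []
        if plan.setting == "cv1_pairs":
            cells = rng.permutation(d * t)
            for chunk in np.array_split(cells, plan.folds):
                test = np.zeros(d * t, dtype=bool)
                test[chunk] = True
                test = test.reshape(d, t)
                folds.append((~test, test))
        elif plan.setting == "cv2_drugs":
            rows = rng.permutation(d)
            for chunk in np.array_split(rows, plan.folds):
                test = np.zeros((d, t), dtype=bool)
                test[chunk, :] = True
                folds.append((~test, test))
        else:  # cv3_targets
            cols = rng.permutation(t)
            for chunk in np.array_split(cols, plan.folds):
                test = np.zeros((d, t), dtype=bool)
                test[:, chunk] = True
                folds.append((~test, test))
        reps.append(folds)
    return reps


def evaluate_fold(scores: np.ndarray, truth: np.ndarray) -> PRCurve:
    """Precision-recall curve and AUPR for one fold's test cells.

    Requires at least one positive and one negative label. AUPR is the
    step-wise average precision sum_k (R_k - R_{k-1}) P_k over the distinct
    score thresholds, which handles tied scores as blocks.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if scores.shape != truth.shape:
        raise ValueError(f"scores ({scores.shape}) and truth ({truth.shape}) differ in length")
    npos = int(truth.sum())
    if npos == 0:
        raise ValueError("fold has no positive test cells; AUPR is undefined")
    if npos == truth.size:
        raise ValueError("fold has no negative test cells; AUPR is undefined")
    precision, recall, _ = precision_recall_curve(truth, scores)
    aupr = float(average_precision_score(truth, scores))
    points = sorted(zip(recall.tolist(), precision.tolist()))
    return PRCurve(points=[(float(r), float(p)) for r, p in points], aupr=aupr)


def _fold_aupr_cv1(A: np.ndarray, DS, TS, hp: HyperParams, train: np.ndarray, test: np.ndarray):
    res = fit(A, DS, TS, hp, weight_mask=train.astype(float))
    probs = logistic_prob(res.factors.U @ res.factors.V.T)
    return probs[test], A[test]


def _fold_aupr_entities(A: np.ndarray, DS: np.ndarray, TS: np.ndarray, hp: HyperParams,
                        test: np.ndarray, axis: int):
    """cv2 (axis=0, drugs) / cv3 (axis=1, targets): drop test entities, fit, score cold-start."""
    test_idx = np.where(test.any(axis=1 - axis))[0]
    keep = np.setdiff1d(np.arange(A.shape[axis]), test_idx)
    if axis == 0:
        res = fit(A[keep, :], DS[np.ix_(keep, keep)], TS, hp)
        U_new = np.vstack([
            infer_new_latent(DS[r, keep], res.factors.U, hp.K) for r in test_idx
        ])
        probs = logistic_prob(U_new @ res.factors.V.T)
        return probs.ravel(), A[test_idx, :].ravel()
    res = fit(A[:, keep], DS, TS[np.ix_(keep, keep)], hp)
    V_new = np.vstack([
        infer_new_latent(TS[c, keep], res.factors.V, hp.K) for c in test_idx
    ])
    probs = logistic_prob(res.factors.U @ V_new.T)
    return probs.ravel(), A[:, test_idx].ravel()


def run_cv(
    A: InteractionMatrix | np.ndarray,
    DS: SimilarityMatrix | np.ndarray,
    TS: SimilarityMatrix | np.ndarray,
    hp: HyperParams,
    plan: CVPlan,
) -> CVResult:
    """Run the full repeated cross-validation protocol and aggregate AUPRs.

    Per fold, test information is masked from training (cv1: binary weight
    mask on the likelihood; cv2/cv3: test rows/columns removed and scored by
    cold-start inference), the model is fitted, and AUPR is computed on the
    fold's test cells. Folds without a positive test cell are skipped with a
    logged warning. The repetition score is the mean over its valid folds;
    the headline value is mean +/- std over repetition scores. A pooled
    AUPR per repetition (all test cells of the repetition ranked together)
    is also reported.
    """
    Av = A.values if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)
    DSv = DS.values if isinstance(DS, SimilarityMatrix) else np.asarray(DS, dtype=float)
    TSv = TS.values if isinstance(TS, SimilarityMatrix) else np.asarray(TS, dtype=float)
    masks = make_cv_plan(Av, plan)
    per_fold: list[list[float]] = []
    rep_means: list[float] = []
    pooled: list[float] = []
    for rep, folds in enumerate(masks):
        fold_scores: list[float] = []
        all_s: list[np.ndarray] = []
        all_y: list[np.ndarray] = []
        for fold, (train, test) in enumerate(folds):
            hp_fold = replace(hp, seed=hp.seed + 7919 * rep + fold)
            if plan.setting == "cv1_pairs":
                s, y = _fold_aupr_cv1(Av, DSv, TSv, hp_fold, train, test)
            else:
                s, y = _fold_aupr_entities(Av, DSv, TSv, hp_fold, test, axis=0 if plan.setting == "cv2_drugs" else 1)
            all_s.append(s)
            all_y.append(y)
            if y.sum() == 0 or y.sum() == y.size:
                logger.warning("repetition %d fold %d has no positive (or no negative) test cells; skipped", rep, fold)
                continue
            fold_scores.append(evaluate_fold(s, y).aupr)
        per_fold.append(fold_scores)
        rep_means.append(float(np.mean(fold_scores)))
        pooled.append(evaluate_fold(np.concatenate(all_s), np.concatenate(all_y)).aupr)
    return CVResult(
        setting=plan.setting,
        per_fold_aupr=per_fold,
        per_repetition_mean=rep_means,
        mean_aupr=float(np.mean(rep_means)),
        std_aupr=float(np.std(rep_means)),
        pooled_aupr=pooled,
    )


def top_k_predictions(
    preds: PredictionMatrix,
    drug_id: str,
    k: int,
    known: InteractionMatrix | None = None,
) -> list[tuple[str, float, bool]]:
    """The k highest-scoring targets for one drug, ties broken by target index.

    Returns (target_id, score, validated_flag) triples in descending score
    order; the flag marks targets already recorded as interacting in the
    known matrix (the check marks of published case-study tables).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    try:
        row = preds.drug_ids.index(drug_id)
    except ValueError:
        raise KeyError(f"unknown drug identifier {drug_id!r}") from None
    scores = preds.probs[row]
    order = np.argsort(-scores, kind="stable")[:k]
    flags = np.zeros(len(preds.target_ids), dtype=bool)
    if known is not None:
        kr = known.drug_ids.index(drug_id) if drug_id in known.drug_ids else None
        if kr is not None:
            pos = {tid: i for i, tid in enumerate(known.target_ids)}
            for j, tid in enumerate(preds.target_ids):
                if tid in pos:
                    flags[j] = known.values[kr, pos[tid]] == 1
    return [(preds.target_ids[j], float(scores[j]), bool(flags[j])) for j in order]


def random_cell_mask(d: int, t: int, holdout_fraction: float, seed: int) -> np.ndarray:
    """Boolean d x t mask with ~holdout_fraction of cells True (the held-out set)."""
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = d * t
    idx = rng.choice(n, size=max(1, int(round(holdout_fraction * n))), replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask.reshape(d, t)
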
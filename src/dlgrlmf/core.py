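"""Dual Laplacian graph regularized logistic matrix factorization (DLGrLMF).

The model represents each drug i and target j by k-dimensional latent row
vectors u_i, v_j and models the interaction probability as the logistic
function of their inner product,

    p_ij = exp(u_i v_j^T) / (1 + exp(u_i v_j^T)).

Experimentally validated interactions (a_ij = 1) are weighted by a constant
n > 1 in the likelihood; unknown pairs enter with weight 1. Two graph
Laplacians — one over the drug chemical-structure similarity graph, one over
the target sequence similarity graph — regularize the factors so that similar
entities receive similar latent vectors. The graphs use *second-order*
affinities: the K-nearest-neighbor sparsified similarity matrix M is turned
into W = M^T M (inner products of sparsified similarity profiles), and
L = D - W with D the diagonal degree matrix.

The training objective minimized here is

    F(U, V) = sum_ij [ (1 + n a_ij - a_ij) ln(1 + e^{u_i v_j^T})
                       - n a_ij u_i v_j^T ]
              + alpha Tr(U^T (L_D + I) U) + beta Tr(V^T (L_T + I) V),

with gradients

    dF/dU = [P + (n-1)(A ⊙ P) - n A] V + 2 alpha (I + L_D) U,
    dF/dV = [P + (n-1)(A ⊙ P) - n A]^T U + 2 beta (I + L_T) V,

where P is the logistic of the score matrix U V^T and ⊙ the Hadamard
product (the factor 2 is the derivative of the quadratic regularizer;
dropping it would only rescale the effective regularization weight but
would break the exact gradient/objective correspondence). An optional binary weight mask restricts the likelihood sums to a
subset of cells (used to hide held-out cells during cross-validation on
pairs); the regularizers are unaffected by the mask.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("dlgrlmf")

__all__ = [
    "InteractionMatrix",
    "SimilarityMatrix",
    "NeighborGraph",
    "LaplacianPair",
    "LatentFactors",
    "HyperParams",
    "PredictionMatrix",
    "FitResult",
    "logistic_prob",
    "neighbor_sparsify",
    "second_order_affinity",
    "build_laplacian",
    "build_laplacian_pair",
    "objective_value",
    "gradients",
    "fit",
    "predict_scores",
    "infer_new_latent",
    "save_model",
    "load_model",
]

_SYM_TOL = 1e-8
_DIAG_TOL = 1e-6


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")
    return ids


@dataclass
class InteractionMatrix:
    """Binary drug x target adjacency; 1 marks an experimentally validated DTI."""

    values: np.ndarray
    drug_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"interaction matrix must be 2-D and non-empty, got shape {self.values.shape}")
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"interaction matrix entries must be 0 or 1; found {self.values[i, j]!r} at row {i}, column {j}"
            )
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.target_ids = _check_unique(self.target_ids, "target")
        d, t = self.values.shape
        if len(self.drug_ids) != d or len(self.target_ids) != t:
            raise ValueError(
                f"label/shape mismatch: {len(self.drug_ids)} drug ids, {len(self.target_ids)} target ids "
                f"for a {d}x{t} matrix"
            )

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_targets(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityMatrix:
    """Square symmetric nonnegative similarity matrix with unit diagonal, entries in [0, 1]."""

    values: np.ndarray
    entity_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"similarity matrix must be square, got shape {v.shape}")
        asym = np.abs(v - v.T)
        if asym.max(initial=0.0) > _SYM_TOL:
            i, j = map(int, np.argwhere(asym > _SYM_TOL)[0])
            raise ValueError(f"similarity matrix is asymmetric at ({i}, {j}): {v[i, j]} vs {v[j, i]}")
        if (v < -1e-12).any():
            i, j = map(int, np.argwhere(v < -1e-12)[0])
            raise ValueError(f"negative similarity {v[i, j]} at ({i}, {j})")
        diag_err = np.abs(np.diag(v) - 1.0)
        if diag_err.max(initial=0.0) > _DIAG_TOL:
            i = int(np.argmax(diag_err))
            raise ValueError(f"self-similarity of entity {i} is {v[i, i]}, expected 1")
        self.entity_ids = _check_unique(self.entity_ids, "entity")
        if len(self.entity_ids) != v.shape[0]:
            raise ValueError(f"{len(self.entity_ids)} identifiers for a {v.shape[0]}x{v.shape[1]} matrix")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighborGraph:
    """K-NN sparsified similarity and the second-order affinity built from it."""

    sparse_sim: np.ndarray
    affinity: np.ndarray
    K: int


@dataclass
class LaplacianPair:
    """Graph Laplacians L = D - W for the drug and target affinity graphs."""

    L_D: np.ndarray
    L_T: np.ndarray
    D_D: np.ndarray
    D_T: np.ndarray


@dataclass
class LatentFactors:
    """Latent representations: row i of U is drug i, row j of V is target j."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError(f"U and V must be 2-D with a common latent dimension; got {self.U.shape}, {self.V.shape}")
        if self.U.shape[1] < 1:
            raise ValueError("latent dimension must be at least 1")
        if not (np.isfinite(self.U).all() and np.isfinite(self.V).all()):
            raise ValueError("latent factors contain non-finite entries")

    @property
    def k(self) -> int:
        return self.U.shape[1]


@dataclass
class HyperParams:
    """Model and optimizer settings.

    Parameters
    ----------
    k : latent dimension (clamped to min(d, t) at fit time).
    n_weight : importance weight n > 1 on validated (positive) interactions.
    K : neighbor count for similarity-graph sparsification.
    alpha, beta : nonnegative weights of the drug / target graph regularizers
        (each multiplies Tr(X^T (L + I) X), i.e. Laplacian plus Tikhonov).
    sigma_u2, sigma_v2 : Gaussian prior variances; used only as the scale of
        the synthetic generator (the regularization weight is alpha/beta).
    optimizer : "adagrad" (per-coordinate adaptive step) or "plain_gd"
        (fixed-step gradient descent; provably non-increasing for small steps).
    learning_rate : base step size.
    max_iter, tol : stop after max_iter updates or when the relative change
        of the objective drops below tol.
    seed : controls the random initialization of U and V.
    """

    k: int = 50
    n_weight: float = 5.0
    K: int = 5
    alpha: float = 0.1
    beta: float = 0.1
    sigma_u2: float = 1.0
    sigma_v2: float = 1.0
    optimizer: str = "adagrad"
    learning_rate: float = 0.2
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weight <= 1:
            raise ValueError(f"positive-pair weight n must exceed 1, got {self.n_weight}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.K < 1:
            raise ValueError("neighbor count K must be at least 1")
        if self.k < 1:
            raise ValueError("latent dimension k must be at least 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.optimizer not in ("adagrad", "plain_gd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}; use 'adagrad' or 'plain_gd'")


@dataclass
class PredictionMatrix:
    """Posterior interaction probabilities, strictly inside (0, 1)."""

    probs: np.ndarray
    drug_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.isfinite(self.probs).all():
            raise ValueError("prediction matrix contains non-finite entries")
        if (self.probs <= 0).any() or (self.probs >= 1).any():
            raise ValueError("prediction probabilities must be strictly inside (0, 1)")


@dataclass
class FitResult:
    """Fitted factors plus optimization diagnostics."""

    factors: LatentFactors
    objective_trace: list[float]
    n_iter: int
    converged: bool
    laplacians: LaplacianPair = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# probability map
# ---------------------------------------------------------------------------

def logistic_prob(scores: np.ndarray) -> np.ndarray:
    """Elementwise logistic e^x / (1 + e^x), overflow-safe, output in open (0, 1)."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        idx = tuple(map(int, np.argwhere(~np.isfinite(np.atleast_1d(scores)))[0]))
        raise ValueError(f"non-finite score at index {idx}")
    with np.errstate(over="ignore", invalid="ignore"):
        # np.where evaluates both branches; each saturates harmlessly on its off-branch side
        p = np.where(scores >= 0, 1.0 / (1.0 + np.exp(-scores)), np.exp(scores) / (1.0 + np.exp(scores)))
    # keep strictly inside (0, 1) even where float rounding saturates
    return np.clip(p, np.finfo(float).tiny, np.nextafter(1.0, 0.0))


# ---------------------------------------------------------------------------
# neighbor graphs and Laplacians
# ---------------------------------------------------------------------------

def neighbor_sparsify(sim: np.ndarray | SimilarityMatrix, K: int) -> np.ndarray:
    """Keep, per column j, the similarities of the K nearest neighbors of entity j.

    The neighborhood excludes the entity itself; ties in similarity are broken
    by lower row index. Entry (i, j) of the result equals sim[i, j] when
    entity i is among the K most similar entities to j, else 0.
    """
    S = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    m = S.shape[0]
    if S.ndim != 2 or S.shape[1] != m:
        raise ValueError(f"similarity matrix must be square, got {S.shape}")
    if not (1 <= K <= m - 1):
        raise ValueError(f"neighbor count K={K} out of range [1, {m - 1}] for {m} entities")
    out = np.zeros_like(S)
    for j in range(m):
        # stable argsort on negated column: descending similarity, ties -> lower index
        order = np.argsort(-S[:, j], kind="stable")
        order = order[order != j][:K]
        out[order, j] = S[order, j]
    return out


def second_order_affinity(sparse_sim: np.ndarray) -> np.ndarray:
    """Affinity W with W_ij the inner product of columns i and j of the sparsified similarity.

    W = M^T M is symmetric positive semidefinite even though the K-NN
    sparsified matrix M is generally asymmetric.
    """
    M = np.asarray(sparse_sim, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"sparsified similarity must be square, got {M.shape}")
    W = M.T @ M
    return (W + W.T) / 2.0  # remove float round-off asymmetry


def build_laplacian(affinity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Graph Laplacian L = D - W with D_ii = sum_j W_ij. Returns (L, D)."""
    W = np.asarray(affinity, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"affinity must be square, got {W.shape}")
    asym = np.abs(W - W.T).max(initial=0.0)
    if asym > _SYM_TOL:
        raise ValueError(f"affinity is asymmetric (max |W - W^T| = {asym:.3g})")
    D = np.diag(W.sum(axis=1))
    return D - W, D


def build_neighbor_graph(sim: SimilarityMatrix | np.ndarray, K: int) -> NeighborGraph:
    sparse = neighbor_sparsify(sim, K)
    return NeighborGraph(sparse_sim=sparse, affinity=second_order_affinity(sparse), K=K)


def build_laplacian_pair(DS: SimilarityMatrix | np.ndarray, TS: SimilarityMatrix | np.ndarray, K: int) -> LaplacianPair:
    """Sparsify both similarity matrices, form second-order affinities, return both Laplacians."""
    gd = build_neighbor_graph(DS, K)
    gt = build_neighbor_graph(TS, K)
    L_D, D_D = build_laplacian(gd.affinity)
    L_T, D_T = build_laplacian(gt.affinity)
    return LaplacianPair(L_D=L_D, L_T=L_T, D_D=D_D, D_T=D_T)


# ---------------------------------------------------------------------------
# objective and gradients
# ---------------------------------------------------------------------------

def _as_A(A: InteractionMatrix | np.ndarray) -> np.ndarray:
    return A.values if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)


def _check_shapes(A: np.ndarray, U: np.ndarray, V: np.ndarray, L_D: np.ndarray, L_T: np.ndarray) -> None:
    d, t = A.shape
    if U.shape[0] != d:
        raise ValueError(f"U has {U.shape[0]} rows but A has {d} drugs")
    if V.shape[0] != t:
        raise ValueError(f"V has {V.shape[0]} rows but A has {t} targets")
    if U.shape[1] != V.shape[1]:
        raise ValueError(f"latent dimension mismatch: U is {U.shape}, V is {V.shape}")
    if L_D.shape != (d, d):
        raise ValueError(f"drug Laplacian shape {L_D.shape} does not match {d} drugs")
    if L_T.shape != (t, t):
        raise ValueError(f"target Laplacian shape {L_T.shape} does not match {t} targets")


def objective_value(
    A: InteractionMatrix | np.ndarray,
    factors: LatentFactors,
    laplacians: LaplacianPair,
    hp: HyperParams,
    weight_mask: np.ndarray | None = None,
) -> float:
    """Weighted logistic-loss objective with dual graph regularization.

    F = sum_ij w_ij [ (1 + n a_ij - a_ij) ln(1 + e^{s_ij}) - n a_ij s_ij ]
        + alpha [Tr(U^T L_D U) + ||U||_F^2] + beta [Tr(V^T L_T V) + ||V||_F^2]

    where s = U V^T and w is the optional binary cell mask (all ones when
    absent). The log term is computed as a numerically safe softplus.
    """
    A = _as_A(A)
    U, V = factors.U, factors.V
    _check_shapes(A, U, V, laplacians.L_D, laplacians.L_T)
    n = hp.n_weight
    with np.errstate(over="ignore", invalid="ignore"):  # divergent iterates surface as a non-finite total
        S = U @ V.T
        softplus = np.logaddexp(0.0, S)
        cell = (1.0 + (n - 1.0) * A) * softplus - n * A * S
        if weight_mask is not None:
            cell = cell * weight_mask
        reg_u = hp.alpha * (np.trace(U.T @ laplacians.L_D @ U) + np.sum(U * U))
        reg_v = hp.beta * (np.trace(V.T @ laplacians.L_T @ V) + np.sum(V * V))
        return float(cell.sum() + reg_u + reg_v)


def gradients(
    A: InteractionMatrix | np.ndarray,
    factors: LatentFactors,
    laplacians: LaplacianPair,
    hp: HyperParams,
    weight_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the objective with respect to U and V."""
    A = _as_A(A)
    U, V = factors.U, factors.V
    _check_shapes(A, U, V, laplacians.L_D, laplacians.L_T)
    n = hp.n_weight
    P = logistic_prob(U @ V.T)
    Z = P + (n - 1.0) * (A * P) - n * A
    if weight_mask is not None:
        Z = Z * weight_mask
    gU = Z @ V + 2.0 * hp.alpha * (U + laplacians.L_D @ U)
    gV = Z.T @ U + 2.0 * hp.beta * (V + laplacians.L_T @ V)
    return gU, gV


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def fit(
    A: InteractionMatrix | np.ndarray,
    DS: SimilarityMatrix | np.ndarray,
    TS: SimilarityMatrix | np.ndarray,
    hp: HyperParams,
    weight_mask: np.ndarray | None = None,
) -> FitResult:
    """Fit the factor model by gradient descent.

    Builds the K-NN neighbor graphs, second-order affinities and Laplacians
    from ``DS``/``TS``, initializes U, V from a zero-mean Gaussian with
    standard deviation 1/sqrt(k) (the origin is a stationary point, so a
    random start is required), then iterates AdaGrad or plain gradient
    descent, recording the objective after every update.
    """
    Av = _as_A(A)
    d, t = Av.shape
    DSv = DS.values if isinstance(DS, SimilarityMatrix) else np.asarray(DS, dtype=float)
    TSv = TS.values if isinstance(TS, SimilarityMatrix) else np.asarray(TS, dtype=float)
    if DSv.shape != (d, d):
        raise ValueError(f"drug similarity is {DSv.shape} but A has {d} drugs (axis 0)")
    if TSv.shape != (t, t):
        raise ValueError(f"target similarity is {TSv.shape} but A has {t} targets (axis 1)")
    if weight_mask is not None and weight_mask.shape != (d, t):
        raise ValueError(f"weight mask shape {weight_mask.shape} does not match A {Av.shape}")

    k = min(hp.k, d, t)
    if k != hp.k:
        logger.info("clamping latent dimension k from %d to min(d, t) = %d", hp.k, k)
    K = min(hp.K, min(d, t) - 1)
    lap = build_laplacian_pair(DSv, TSv, K)

    rng = np.random.default_rng(hp.seed)
    scale = 1.0 / np.sqrt(k)
    factors = LatentFactors(U=rng.normal(0.0, scale, size=(d, k)), V=rng.normal(0.0, scale, size=(t, k)))

    trace = [objective_value(Av, factors, lap, hp, weight_mask)]
    grad_sq_u = np.zeros_like(factors.U)
    grad_sq_v = np.zeros_like(factors.V)
    eps = 1e-8
    converged = False
    for it in range(hp.max_iter):
        gU, gV = gradients(Av, factors, lap, hp, weight_mask)
        if hp.optimizer == "adagrad":
            grad_sq_u += gU * gU
            grad_sq_v += gV * gV
            factors.U -= hp.learning_rate * gU / np.sqrt(grad_sq_u + eps)
            factors.V -= hp.learning_rate * gV / np.sqrt(grad_sq_v + eps)
        else:  # plain_gd
            factors.U -= hp.learning_rate * gU
            factors.V -= hp.learning_rate * gV
        with np.errstate(over="ignore"):
            F = objective_value(Av, factors, lap, hp, weight_mask) if np.isfinite(factors.U).all() and np.isfinite(factors.V).all() else np.inf
        if not np.isfinite(F):
            raise FloatingPointError(
                f"objective diverged to a non-finite value at iteration {it + 1}; try a smaller learning rate"
            )
        trace.append(F)
        if abs(trace[-2] - F) / max(abs(F), 1.0) < hp.tol:
            converged = True
            break
    logger.debug("fit finished after %d iterations (converged=%s, F=%.6g)", len(trace) - 1, converged, trace[-1])
    return FitResult(factors=factors, objective_trace=trace, n_iter=len(trace) - 1, converged=converged, laplacians=lap)


def predict_scores(factors: LatentFactors, drug_ids: Sequence[str] | None = None,
                   target_ids: Sequence[str] | None = None) -> PredictionMatrix:
    """Interaction probabilities p_hat = logistic(U V^T) for fitted factors."""
    probs = logistic_prob(factors.U @ factors.V.T)
    d, t = probs.shape
    if drug_ids is None:
        drug_ids = [f"drug_{i}" for i in range(d)]
    if target_ids is None:
        target_ids = [f"target_{j}" for j in range(t)]
    return PredictionMatrix(probs=probs, drug_ids=list(drug_ids), target_ids=list(target_ids))


def infer_new_latent(sim_to_train: np.ndarray, train_factors: np.ndarray, K: int) -> np.ndarray:
    """Cold-start latent vector: similarity-weighted mean of the K nearest training entities.

    u_new = sum_{i in topK} s_i u_i / sum_{i in topK} s_i using the original
    first-order similarities of the new entity to the training entities.
    Returns the zero vector (probability 0.5 everywhere) when every
    similarity is zero.
    """
    s = np.asarray(sim_to_train, dtype=float)
    Utr = np.asarray(train_factors, dtype=float)
    if Utr.shape[0] == 0:
        raise ValueError("cannot infer a latent vector from an empty training set")
    if s.shape != (Utr.shape[0],):
        raise ValueError(f"similarity vector length {s.shape} does not match {Utr.shape[0]} training entities")
    order = np.argsort(-s, kind="stable")[: min(K, len(s))]
    order = order[s[order] > 0]
    if order.size == 0:
        return np.zeros(Utr.shape[1])
    w = s[order]
    return (w[:, None] * Utr[order]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# model serialization (JSON; float repr round-trips IEEE doubles exactly)
# ---------------------------------------------------------------------------

def save_model(path: str | Path, factors: LatentFactors, drug_ids: Sequence[str],
               target_ids: Sequence[str], hp: HyperParams) -> None:
    payload = {
        "format": "dlgrlmf-model-v1",
        "drug_ids": list(drug_ids),
        "target_ids": list(target_ids),
        "hyperparams": dataclasses.asdict(hp),
        "U": factors.U.tolist(),
        "V": factors.V.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> tuple[LatentFactors, list[str], list[str], HyperParams]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "dlgrlmf-model-v1":
        raise ValueError(f"{path} is not a recognized model archive")
    factors = LatentFactors(U=np.array(payload["U"], dtype=float), V=np.array(payload["V"], dtype=float))
    hp = HyperParams(**payload["hyperparams"])
    return factors, payload["drug_ids"], payload["target_ids"], hp
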
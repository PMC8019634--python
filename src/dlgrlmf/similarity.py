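"""Similarity formulas for building drug and target similarity inputs.

Drug chemical-structure similarity follows the SIMCOMP convention: the
similarity of two compounds is the Jaccard ratio |c1 ∩ c2| / |c1 ∪ c2| of
their discrete substructure feature sets. Target sequence similarity is the
normalized Smith–Waterman score: the raw local-alignment score of a protein
pair divided by the geometric mean of the two self-alignment scores, which
gives a unit diagonal. Alignment engines and fingerprint generators are
upstream of this package — these functions operate on pre-computed raw
scores or feature sets.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import SimilarityMatrix

logger = logging.getLogger("dlgrlmf")

__all__ = ["jaccard_similarity", "normalize_sw", "read_feature_sets", "similarity_from_feature_sets"]


def jaccard_similarity(c1: Iterable, c2: Iterable) -> float:
    """Jaccard similarity |c1 ∩ c2| / |c1 ∪ c2| of two feature sets."""
    s1, s2 = set(c1), set(c2)
    union = s1 | s2
    if not union:
        raise ValueError("Jaccard similarity is undefined for two empty feature sets (0/0)")
    return len(s1 & s2) / len(union)


def normalize_sw(raw: np.ndarray, entity_ids: list[str] | None = None) -> SimilarityMatrix:
    """Normalize a raw pairwise alignment-score matrix to unit-diagonal similarities.

    S_pq = raw_pq / sqrt(raw_pp * raw_qq). Raw scores occasionally exceed the
    geometric-mean bound in real data; such values are clipped to 1 with a
    logged warning so the output stays in the model's assumed [0, 1] range.
    The result is invariant to global positive scaling of the raw matrix.
    """
    R = np.asarray(raw, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"raw score matrix must be square, got {R.shape}")
    m = R.shape[0]
    if entity_ids is None:
        entity_ids = [f"entity_{i}" for i in range(m)]
    diag = np.diag(R)
    if (diag <= 0).any():
        i = int(np.argmax(diag <= 0))
        raise ValueError(f"self-alignment score of entity {entity_ids[i]!r} is {diag[i]}; must be positive")
    S = R / np.sqrt(np.outer(diag, diag))
    over = S > 1.0 + 1e-12
    if over.any():
        logger.warning(
            "%d raw scores exceed the geometric-mean bound sqrt(raw_pp*raw_qq); clipping normalized values to 1",
            int(over.sum()),
        )
        S = np.minimum(S, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, entity_ids=list(entity_ids))


def read_feature_sets(path: str | Path) -> dict[str, set[str]]:
    """Read feature sets: one line per entity, whitespace-separated tokens after the identifier."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        ident, feats = tokens[0], tokens[1:]
        if ident in sets:
            raise ValueError(f"{path}:{lineno}: duplicate entity identifier {ident!r}")
        sets[ident] = set(feats)
    return sets


def similarity_from_feature_sets(sets: dict[str, set[str]]) -> SimilarityMatrix:
    """Pairwise Jaccard similarity matrix over a dictionary of feature sets."""
    ids = list(sets)
    m = len(ids)
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            S[i, j] = S[j, i] = jaccard_similarity(sets[ids[i]], sets[ids[j]])
    return SimilarityMatrix(values=S, entity_ids=ids)
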
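"""Reading, writing, aligning and summarizing benchmark DTI matrices.

The on-disk dialect is labeled tab-delimited text: first row holds column
identifiers, first column holds row identifiers, cells are floating point.
The public gold-standard files (nuclear receptor, GPCR, ion channel, enzyme
sets) store the adjacency as targets x drugs; the internal convention is
drugs x targets, so the reader accepts an orientation flag and, by default,
auto-transposes interaction files whose row labels match the target
similarity matrix.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InteractionMatrix, SimilarityMatrix

logger = logging.getLogger("dlgrlmf")

__all__ = [
    "DatasetBundle",
    "DatasetStats",
    "read_matrix",
    "write_matrix",
    "read_interactions",
    "read_similarity",
    "align_bundle",
    "compute_stats",
    "round_half_away",
]


@dataclass
class DatasetBundle:
    """An interaction matrix with its drug and target similarity matrices, identifier-aligned."""

    interactions: InteractionMatrix
    drug_sim: SimilarityMatrix
    target_sim: SimilarityMatrix
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.interactions.drug_ids != self.drug_sim.entity_ids:
            raise ValueError(f"bundle {self.name!r}: drug identifiers of A and DS differ (use align_bundle)")
        if self.interactions.target_ids != self.target_sim.entity_ids:
            raise ValueError(f"bundle {self.name!r}: target identifiers of A and TS differ (use align_bundle)")


@dataclass
class DatasetStats:
    """Summary statistics of an interaction matrix."""

    n_drugs: int
    n_targets: int
    n_interactions: int
    avg_drugs_per_target: float
    avg_targets_per_drug: float
    sparsity_pct: float

    def rounded(self, ndigits: int = 2) -> "DatasetStats":
        """Display copy with ratios rounded half-away-from-zero."""
        return DatasetStats(
            n_drugs=self.n_drugs,
            n_targets=self.n_targets,
            n_interactions=self.n_interactions,
            avg_drugs_per_target=round_half_away(self.avg_drugs_per_target, ndigits),
            avg_targets_per_drug=round_half_away(self.avg_targets_per_drug, ndigits),
            sparsity_pct=round_half_away(self.sparsity_pct, ndigits),
        )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (3.465 -> 3.47), unlike banker's rounding."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _read_frame(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse labeled tab-delimited matrix: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no data cells")
    values = np.empty(df.shape, dtype=float)
    for r, (row_id, row) in enumerate(df.iterrows()):
        for c, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(f"{path}: missing cell at row {row_id!r}, column {df.columns[c]!r} (ragged file?)")
            try:
                values[r, c] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_id!r}, column {df.columns[c]!r}"
                ) from exc
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def read_matrix(path: str | Path, expect: str = "similarity", orientation: str = "as_is") -> pd.DataFrame:
    """Read and validate a labeled tab-delimited matrix.

    Parameters
    ----------
    expect : "binary" validates entries in {0, 1}; "similarity" validates a
        square symmetric matrix with entries in [0, 1] and unit diagonal.
    orientation : "as_is" or "transpose"; "transpose" flips a targets x drugs
        interaction file into the internal drugs x targets layout.
    """
    if expect not in ("binary", "similarity"):
        raise ValueError(f"expect must be 'binary' or 'similarity', got {expect!r}")
    if orientation not in ("as_is", "transpose"):
        raise ValueError(f"orientation must be 'as_is' or 'transpose', got {orientation!r}")
    df = _read_frame(path)
    if orientation == "transpose":
        df = df.T
    v = df.to_numpy()
    if expect == "binary":
        bad = ~np.isin(v, (0.0, 1.0))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValueError(f"{path}: entry at row {df.index[r]!r}, column {df.columns[c]!r} is {v[r, c]}, not 0/1")
    else:
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"{path}: similarity matrix must be square, got {df.shape}")
        asym = np.abs(v - v.T)
        if asym.max(initial=0.0) > 1e-6:
            r, c = map(int, np.argwhere(asym > 1e-6)[0])
            raise ValueError(
                f"{path}: similarity not symmetric at ({df.index[r]!r}, {df.columns[c]!r}): "
                f"{v[r, c]} vs {v[c, r]}"
            )
        if (v < -1e-9).any() or (v > 1 + 1e-9).any():
            r, c = map(int, np.argwhere((v < -1e-9) | (v > 1 + 1e-9))[0])
            raise ValueError(f"{path}: similarity {v[r, c]} at row {df.index[r]!r} outside [0, 1]")
    return df


def write_matrix(path: str | Path, values: np.ndarray, row_ids: list[str], col_ids: list[str]) -> None:
    """Write a labeled tab-delimited matrix; float repr keeps round trips lossless."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    buf = io.StringIO()
    df.to_csv(buf, sep="\t")
    Path(path).write_text(buf.getvalue())


def read_interactions(path: str | Path, orientation: str = "as_is") -> InteractionMatrix:
    df = read_matrix(path, expect="binary", orientation=orientation)
    return InteractionMatrix(values=df.to_numpy(), drug_ids=list(df.index), target_ids=list(df.columns))


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = read_matrix(path, expect="similarity")
    # symmetrize tiny float asymmetries within the 1e-6 validation band
    v = df.to_numpy()
    return SimilarityMatrix(values=(v + v.T) / 2.0, entity_ids=list(df.index))


def align_bundle(
    interactions: InteractionMatrix,
    drug_sim: SimilarityMatrix,
    target_sim: SimilarityMatrix,
    name: str = "dataset",
) -> DatasetBundle:
    """Reorder/subset both similarity matrices onto the interaction matrix's identifier order.

    Entities present in a similarity matrix but absent from the interaction
    matrix are dropped with a logged notice; an interaction identifier missing
    from a similarity matrix is an error.
    """

    def _subset(sim: SimilarityMatrix, wanted: list[str], axis_name: str) -> SimilarityMatrix:
        pos = {e: i for i, e in enumerate(sim.entity_ids)}
        missing = [w for w in wanted if w not in pos]
        if missing:
            raise ValueError(f"{axis_name} identifiers missing from the similarity matrix: {missing[:10]}")
        dropped = [e for e in sim.entity_ids if e not in set(wanted)]
        if dropped:
            logger.info("align_bundle: dropping %d %s entities absent from the interaction matrix: %s%s",
                        len(dropped), axis_name, dropped[:5], "..." if len(dropped) > 5 else "")
        idx = np.array([pos[w] for w in wanted])
        return SimilarityMatrix(values=sim.values[np.ix_(idx, idx)], entity_ids=wanted)

    return DatasetBundle(
        interactions=interactions,
        drug_sim=_subset(drug_sim, interactions.drug_ids, "drug"),
        target_sim=_subset(target_sim, interactions.target_ids, "target"),
        name=name,
    )


def compute_stats(bundle: DatasetBundle | InteractionMatrix) -> DatasetStats:
    """Counts, per-entity interaction averages, and sparsity percentage.

    avg_drugs_per_target = interactions / targets, avg_targets_per_drug =
    interactions / drugs, sparsity_pct = 100 (1 - interactions / (d t)).
    """
    A = bundle.interactions if isinstance(bundle, DatasetBundle) else bundle
    d, t = A.values.shape
    m = int(A.values.sum())
    return DatasetStats(
        n_drugs=d,
        n_targets=t,
        n_interactions=m,
        avg_drugs_per_target=m / t if t else 0.0,
        avg_targets_per_drug=m / d if d else 0.0,
        sparsity_pct=100.0 * (1.0 - m / (d * t)) if d * t else 100.0,
    )
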
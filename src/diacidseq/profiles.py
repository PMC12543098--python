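"""Fitness-profile comparison: masked correlation, k-NN imputation, and the
sequence-identity vs fitness-correlation join.

Fitness vectors routinely have missing conditions (experiments that failed
quality metrics or were never run for an organism), so the Pearson
correlation is computed over the conditions observed in *both* vectors, and
the matrix handed to a nonlinear embedding is first completed by k-nearest-
neighbour imputation (k = 2) over masked Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

__all__ = [
    "masked_pearson",
    "knn_impute",
    "identity_correlation_join",
    "embedding_prep",
    "EmbeddingParams",
]

MIN_SHARED_CONDITIONS = 3
E_VALUE_CUTOFF = 0.001


def masked_pearson(x, y, min_shared: int = MIN_SHARED_CONDITIONS) -> float | None:
    """Pearson r over conditions unmasked (non-NaN) in both vectors.

    Returns None when fewer than ``min_shared`` conditions are co-observed or
    either restricted vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fitness vectors must share the same condition index")
    shared = ~np.isnan(x) & ~np.isnan(y)
    if shared.sum() < min_shared:
        return None
    xs, ys = x[shared], y[shared]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def knn_impute(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Complete a masked locus x condition matrix by k-NN imputation.

    Each missing cell becomes the mean of that column in the k nearest rows
    by masked Euclidean distance (squared differences averaged over
    co-observed columns and rescaled by the total column count — the
    nan-Euclidean convention). Observed cells are never altered. A row with
    no observed cell is rejected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = matrix.to_numpy(dtype=float)
    empty_rows = np.isnan(values).all(axis=1)
    if empty_rows.any():
        bad = matrix.index[empty_rows].tolist()
        raise ValueError(f"rows with no observed cells cannot be imputed: {bad[:5]}")
    if not np.isnan(values).any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values)
    # KNNImputer drops all-NaN columns; reassemble if that ever happens
    if filled.shape[1] != values.shape[1]:
        raise ValueError("columns with no observed cells cannot be imputed")
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def identity_correlation_join(
    identity: pd.DataFrame,
    fitness_matrix: pd.DataFrame,
    e_value_cutoff: float = E_VALUE_CUTOFF,
    min_shared: int = MIN_SHARED_CONDITIONS,
) -> pd.DataFrame:
    """Attach masked Pearson r to each retained homolog pair.

    ``identity`` needs columns locus_a, locus_b, percent_identity, e_value
    (an aligner's output, consumed as input). Pairs failing the E-value
    cutoff are dropped; pairs naming loci absent from the fitness matrix are
    logged and skipped.
    """
    required = {"locus_a", "locus_b", "percent_identity", "e_value"}
    if not required <= set(identity.columns):
        raise ValueError(f"identity table missing columns {required - set(identity.columns)}")
    kept = identity[identity["e_value"] <= e_value_cutoff].copy()
    known = set(fitness_matrix.index)
    in_matrix = kept["locus_a"].isin(known) & kept["locus_b"].isin(known)
    n_skipped = int((~in_matrix).sum())
    if n_skipped:
        logger.warning("%d identity pairs name unknown loci (skipped)", n_skipped)
    kept = kept[in_matrix]

    rows = []
    for _, pair in kept.iterrows():
        x = fitness_matrix.loc[pair["locus_a"]].to_numpy(dtype=float)
        y = fitness_matrix.loc[pair["locus_b"]].to_numpy(dtype=float)
        shared = int((~np.isnan(x) & ~np.isnan(y)).sum())
        rows.append(
            {
                "locus_a": pair["locus_a"],
                "locus_b": pair["locus_b"],
                "pearson_r": masked_pearson(x, y, min_shared),
                "n_shared_conditions": shared,
                "percent_identity": float(pair["percent_identity"]),
                "e_value": float(pair["e_value"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_a", "locus_b", "pearson_r", "n_shared_conditions", "percent_identity", "e_value"],
    )


@dataclass(frozen=True)
class EmbeddingParams:
    """Settings recorded for the delegated t-SNE call."""

    perplexity: float = 25.0
    n_iter: int = 50_000
    early_exaggeration: float = 100.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EmbeddingParams":
        return cls(**d)


def embedding_prep(matrix: pd.DataFrame, k: int = 2, params: EmbeddingParams | None = None):
    """Imputed matrix plus the parameter record for a downstream embedding.

    The embedding itself (t-SNE or similar) is visualization plumbing and is
    delegated to the caller; this stage guarantees a complete matrix and a
    serializable parameter record.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty gene set: nothing to embed")
    return knn_impute(matrix, k=k), params or EmbeddingParams()
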
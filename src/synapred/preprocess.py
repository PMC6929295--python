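"""Adult-only filtering and per-gene max normalization of expression matrices.

The feature vector used downstream is each gene's temporal profile rescaled
to [0, 1] by its own maximum, so only the *shape* of the series matters.
Genes expressed above zero only during adult life carry no developmental
shape information and are removed first; genes that are zero everywhere are
removed with them because they cannot be normalized.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from synapred.simulate import ConfigurationError

__all__ = ["filter_adult_only", "max_normalize", "validate_matrix"]


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Check the expression-matrix contract: unique gene IDs, no negatives."""
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (matrix.to_numpy() < 0).any():
        bad = matrix.index[(matrix < 0).any(axis=1)][0]
        raise ValueError(f"negative expression value for gene {bad!r}")


def filter_adult_only(
    matrix: pd.DataFrame,
    adult_stage_indices: Sequence[int],
    zero_threshold: float = 0.0,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Drop genes expressed only during adult life (and all-zero genes).

    A gene is excluded iff all its non-adult values are <= ``zero_threshold``.
    That covers both genes with some adult expression (the adult-only class)
    and genes silent everywhere, which could not be max-normalized anyway.

    Returns the retained matrix (row order preserved) and the excluded IDs.
    """
    validate_matrix(matrix)
    n_stages = matrix.shape[1]
    adult = sorted(set(int(i) for i in adult_stage_indices))
    if not adult:
        raise ConfigurationError("adult_stage_indices must be non-empty")
    if any(i < 0 or i >= n_stages for i in adult):
        raise ConfigurationError(f"adult stage index out of range [0, {n_stages})")
    if len(adult) == n_stages:
        raise ConfigurationError("adult_stage_indices must be a proper subset of stages")

    non_adult_cols = [c for i, c in enumerate(matrix.columns) if i not in adult]
    silent_outside_adult = (matrix[non_adult_cols] <= zero_threshold).all(axis=1)
    excluded = frozenset(matrix.index[silent_outside_adult])
    return matrix.loc[~silent_outside_adult], excluded


def max_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's series by its maximum, yielding profiles in [0, 1].

    Every retained gene ends with at least one entry exactly equal to 1; ties
    at the maximum stay as multiple 1.0 entries.  A gene whose maximum is not
    positive is an error (it should have been removed by the adult-only /
    all-zero filter first).
    """
    validate_matrix(matrix)
    maxima = matrix.max(axis=1)
    if (maxima <= 0).any():
        bad = matrix.index[maxima <= 0][0]
        raise ValueError(
            f"gene {bad!r} has non-positive maximum; run filter_adult_only first"
        )
    return matrix.div(maxima, axis=0)
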
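"""Qualitative presence/absence analysis: per-condition detection sets and Venn partition."""

from __future__ import annotations

import warnings

import pandas as pd

from .io import MatrixError, QuantMatrix

__all__ = ["detection_sets", "venn_partition"]


def detection_sets(matrix: QuantMatrix, min_reps_detected: int = 1) -> dict[str, frozenset]:
    """Per-condition detected-protein sets from a biological-replicate matrix.

    A protein counts as detected in a condition iff it is observed
    (non-missing) in at least ``min_reps_detected`` biological replicates of
    that condition.
    """
    if matrix.level != "bio_rep":
        raise MatrixError("detection_sets expects a bio_rep-level matrix")
    groups = matrix.data.columns.get_level_values("group")
    out: dict[str, frozenset] = {}
    for g in pd.unique(groups):
        sub = matrix.data.loc[:, groups == g]
        if min_reps_detected > sub.shape[1]:
            warnings.warn(
                f"min_reps_detected={min_reps_detected} exceeds the {sub.shape[1]} "
                f"replicates of group {g!r}; detection set is empty",
                stacklevel=2,
            )
        n_obs = sub.notna().sum(axis=1)
        out[g] = frozenset(matrix.data.index[n_obs >= min_reps_detected].astype(str))
    return out


def venn_partition(set_a, set_b) -> tuple[frozenset, frozenset, frozenset]:
    """Disjoint partition (only_a, shared, only_b) of two id sets.

    The three regions are pairwise disjoint and their union is set_a | set_b.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    return a - b, a & b, b - a
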
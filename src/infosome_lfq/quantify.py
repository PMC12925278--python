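"""Run-level intensities -> normalized, imputed biological-replicate log2 matrix.

The aggregation scheme follows the fractionated gel-based design: technical
replicates of one fraction are repeated injections of the same digest, so a
fraction is represented by the arithmetic mean of its observed technical
replicates; fractions partition a biological replicate's material, so the
biological replicate is the sum of its observed fraction values. Both steps
use observed values only — a cell is missing only when every contributor is
missing — because summing with missing-as-zero would conflate non-detection
with low abundance while the mean step does not.

Downstream steps, in pipeline order: group-wise missingness filtering
(retain a protein if at least one group has <= 70 % missing biological
replicates), per-protein within-group median imputation on the linear scale,
then log2 transform and per-sample median alignment to the sample with the
highest median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MatrixError, QuantMatrix, RunDesign

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_technical",
    "aggregate_fractions",
    "filter_missingness",
    "impute_median",
    "log2_and_normalize",
    "quantify_pipeline",
]


def _require_level(matrix: QuantMatrix, level: str) -> None:
    if matrix.level != level:
        raise MatrixError(f"expected level={level!r} matrix, got {matrix.level!r}")


def aggregate_technical(matrix: QuantMatrix, design: RunDesign) -> QuantMatrix:
    """Collapse technical replicates: each fraction = mean of observed injections.

    Missing iff all technical replicates of the fraction are missing.
    """
    _require_level(matrix, "run")
    coords = design.run_coordinates()
    unknown = [c for c in matrix.data.columns if c not in coords]
    if unknown:
        raise MatrixError(f"runs without design rows: {unknown}")
    keys = [coords[c][:3] for c in matrix.data.columns]  # (group, bio_rep, fraction)
    # preserve first-appearance order of fraction keys
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    groups: dict[tuple, list] = {}
    for col, k in zip(matrix.data.columns, keys):
        groups.setdefault(k, []).append(col)
    out = {}
    for k in sorted(order, key=order.get):
        out[k] = matrix.data[groups[k]].mean(axis=1, skipna=True)
    agg = pd.DataFrame(out)
    agg.columns = pd.MultiIndex.from_tuples(agg.columns, names=["group", "bio_rep", "fraction"])
    return QuantMatrix(agg, level="fraction")


def aggregate_fractions(matrix: QuantMatrix, design: RunDesign) -> QuantMatrix:
    """Collapse fractions: each biological replicate = sum of observed fractions.

    Supports unequal fraction counts per group (e.g. 2 for control, 4 for
    treatment). Missing iff all fractions are missing.
    """
    _require_level(matrix, "fraction")
    lvl = matrix.data.columns
    keys = [(g, b) for g, b, _f in lvl]
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    cols: dict[tuple, list] = {}
    for tup, k in zip(lvl, keys):
        cols.setdefault(k, []).append(tup)
    out = {}
    for k in sorted(order, key=order.get):
        # min_count=1 keeps all-missing sums as missing instead of 0
        out[k] = matrix.data[cols[k]].sum(axis=1, skipna=True, min_count=1)
    agg = pd.DataFrame(out)
    agg.columns = pd.MultiIndex.from_tuples(agg.columns, names=["group", "bio_rep"])
    return QuantMatrix(agg, level="bio_rep")


def filter_missingness(
    matrix: QuantMatrix, max_missing_frac: float = 0.70
) -> tuple[QuantMatrix, list[str]]:
    """Group-wise missingness filter on the biological-replicate matrix.

    A protein is retained iff in at least one group the fraction of missing
    biological replicates is <= ``max_missing_frac``; with the default 0.70
    this excludes proteins missing in more than 70 % of a group's samples in
    every group.

    Returns the filtered matrix and the list of excluded protein ids.
    """
    _require_level(matrix, "bio_rep")
    groups = matrix.data.columns.get_level_values("group")
    keep = pd.Series(False, index=matrix.data.index)
    for g in pd.unique(groups):
        sub = matrix.data.loc[:, groups == g]
        if sub.shape[1] == 0:
            raise MatrixError(f"group {g!r} has no biological replicates")
        miss_frac = sub.isna().sum(axis=1) / sub.shape[1]
        keep |= miss_frac <= max_missing_frac
    excluded = matrix.data.index[~keep].tolist()
    return QuantMatrix(matrix.data.loc[keep], level="bio_rep", log2=matrix.log2), excluded


def impute_median(matrix: QuantMatrix) -> QuantMatrix:
    """Impute each missing cell with the protein's within-group observed median.

    If a protein has no observation in a group, fall back to the median of its
    observed values across all samples. A protein with no observation anywhere
    is an error (it should have been removed by the missingness filter).
    """
    _require_level(matrix, "bio_rep")
    data = matrix.data.copy()
    none_observed = data.isna().all(axis=1)
    if none_observed.any():
        raise MatrixError(
            f"proteins with zero observations: {data.index[none_observed].tolist()}"
        )
    groups = data.columns.get_level_values("group")
    overall_median = data.median(axis=1, skipna=True)
    for g in pd.unique(groups):
        cols = groups == g
        sub = data.loc[:, cols]
        med = sub.median(axis=1, skipna=True)
        med = med.fillna(overall_median)  # cross-sample fallback for empty groups
        filled = sub.apply(lambda col: col.fillna(med))
        data.loc[:, cols] = filled.to_numpy()
    out = QuantMatrix(data, level="bio_rep", log2=matrix.log2)
    assert out.n_missing == 0
    return out


def log2_and_normalize(matrix: QuantMatrix) -> tuple[QuantMatrix, pd.Series]:
    """Log2-transform and align every sample's median to the highest pre-shift median.

    Central-tendency normalization: after log2, each sample (column) receives
    an additive shift equal to ``max_j median_j - median_i`` so that all
    post-shift medians equal the maximum pre-shift median; the reference
    sample's shift is 0 (ties broken by first column order, which leaves the
    shift magnitudes unchanged).

    Returns the log2-scale matrix and the per-sample shifts.
    """
    _require_level(matrix, "bio_rep")
    vals = matrix.data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise MatrixError("matrix contains missing values; impute before normalization")
    if (vals <= 0).any():
        raise MatrixError("non-positive intensity; log2 normalization requires values > 0")
    log2d = np.log2(matrix.data)
    medians = log2d.median(axis=0)
    shifts = medians.max() - medians
    normalized = log2d + shifts
    return QuantMatrix(normalized, level="bio_rep", log2=True), shifts


@dataclass(frozen=True)
class QuantifyResult:
    """Output bundle of the quantification pipeline."""

    matrix: QuantMatrix          # normalized log2 bio-rep matrix, complete
    shifts: pd.Series            # per-sample normalization shifts (log2)
    excluded: list               # protein ids removed by the missingness filter
    biorep_raw: QuantMatrix      # linear-scale bio-rep matrix before filtering


def quantify_pipeline(
    matrix: QuantMatrix,
    design: RunDesign,
    max_missing_frac: float = 0.70,
    accepted_ids=None,
) -> QuantifyResult:
    """Full quantification chain: aggregate -> filter -> impute -> log2 + normalize.

    ``accepted_ids``, when given, restricts the matrix to the identification-
    filtered protein list before aggregation.
    """
    if accepted_ids is not None:
        keep = matrix.data.index.isin(set(accepted_ids))
        matrix = QuantMatrix(matrix.data.loc[keep], level=matrix.level)
    fractions = aggregate_technical(matrix, design)
    bioreps = aggregate_fractions(fractions, design)
    filtered, excluded = filter_missingness(bioreps, max_missing_frac=max_missing_frac)
    if excluded:
        logger.info("missingness filter excluded %d proteins", len(excluded))
    imputed = impute_median(filtered)
    normalized, shifts = log2_and_normalize(imputed)
    return QuantifyResult(matrix=normalized, shifts=shifts, excluded=excluded,
                          biorep_raw=bioreps)
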
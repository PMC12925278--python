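"""Per-protein Welch's t-test and fold-change classification.

Differential abundance between two groups of log2-scale biological-replicate
intensities is assessed protein by protein with Welch's unequal-variance
t-test; the effect size is the difference of group means of log2 values, so
a log2 fold change of 1 corresponds to a twofold change on the linear scale.
A protein is called "up" when log2FC >= 1 (inclusive) with p < 0.05
(strict), "down" for the mirrored rule, otherwise "ns". Benjamini–Hochberg
q-values are reported alongside but selection uses the raw p-value.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DesignError, MatrixError, QuantMatrix

logger = logging.getLogger(__name__)

__all__ = ["welch_t", "classify", "run_differential"]

#: Smallest representable positive double, reported for the degenerate case of
#: two zero-variance groups with unequal means.
_P_FLOOR = float(np.nextafter(0.0, 1.0))


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with t = (mean_b - mean_a) / sqrt(s_a^2/n_a +
    s_b^2/n_b), Welch–Satterthwaite degrees of freedom, and the two-sided
    p-value from the Student-t distribution.

    Degenerate inputs: when both groups have zero variance the statistic is
    undefined; equal means give (0, n_a+n_b-2, 1.0) and unequal means give an
    infinite statistic with the smallest representable positive p (logged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in test input")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / a.size, vb / b.size
    se2 = sa + sb
    if se2 == 0.0:
        df = float(a.size + b.size - 2)
        if ma == mb:
            return 0.0, df, 1.0
        logger.warning("degenerate Welch test: zero variance, unequal means")
        return math.copysign(math.inf, mb - ma), df, _P_FLOOR
    t = (mb - ma) / math.sqrt(se2)
    df = se2**2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def classify(log2fc: float, p_value: float,
             fc_min_log2: float = 1.0, p_max: float = 0.05) -> str:
    """Volcano status: 'up' iff log2FC >= threshold (inclusive) and p strictly below p_max.

    'down' mirrors the rule at -threshold; anything else is 'ns'.
    """
    if not (math.isfinite(log2fc) or math.isinf(log2fc)) or not math.isfinite(p_value):
        raise ValueError("classify requires finite p and finite-or-infinite log2fc")
    if p_value < p_max:
        if log2fc >= fc_min_log2:
            return "up"
        if log2fc <= -fc_min_log2:
            return "down"
    return "ns"


def run_differential(
    matrix: QuantMatrix,
    control_group: str,
    treatment_group: str,
    fc_min_log2: float = 1.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Welch-t / fold-change table over a complete, normalized log2 matrix.

    Returns one row per protein with columns protein_id, log2fc, t, df,
    p_value, q_value (Benjamini–Hochberg over all tested proteins) and
    status, sorted by p ascending with lexicographic id tie-break.
    """
    if matrix.level != "bio_rep" or not matrix.log2:
        raise MatrixError("run_differential expects a bio_rep-level log2 matrix")
    if matrix.data.isna().any().any():
        raise MatrixError("matrix contains missing values; impute first")
    groups = matrix.data.columns.get_level_values("group")
    for g in (control_group, treatment_group):
        if g not in set(groups):
            raise DesignError(f"group {g!r} absent from matrix columns")
    a = matrix.data.loc[:, groups == control_group].to_numpy(dtype=float)
    b = matrix.data.loc[:, groups == treatment_group].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DesignError("each group needs >= 2 biological replicates")

    # vectorized Welch over proteins; mirrors welch_t including degeneracies
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa = a.var(ddof=1, axis=1) / a.shape[1]
    sb = b.var(ddof=1, axis=1) / b.shape[1]
    se2 = sa + sb
    log2fc = mb - ma
    t = np.full(len(ma), 0.0)
    df = np.full(len(ma), float(a.shape[1] + b.shape[1] - 2))
    p = np.ones(len(ma))
    ok = se2 > 0.0
    t[ok] = log2fc[ok] / np.sqrt(se2[ok])
    df[ok] = se2[ok] ** 2 / (sa[ok] ** 2 / (a.shape[1] - 1) + sb[ok] ** 2 / (b.shape[1] - 1))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degen = (~ok) & (log2fc != 0.0)
    if degen.any():
        logger.warning("%d degenerate zero-variance proteins with unequal means", degen.sum())
        t[degen] = np.sign(log2fc[degen]) * np.inf
        p[degen] = _P_FLOOR

    q = multipletests(p, method="fdr_bh")[1]
    status = np.where(
        (p < p_max) & (log2fc >= fc_min_log2), "up",
        np.where((p < p_max) & (log2fc <= -fc_min_log2), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "protein_id": matrix.data.index.astype(str),
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    )
    out = out.sort_values(["p_value", "protein_id"], kind="mergesort").reset_index(drop=True)
    counts = out["status"].value_counts()
    logger.info(
        "differential: %d up, %d down, %d ns",
        counts.get("up", 0), counts.get("down", 0), counts.get("ns", 0),
    )
    return out
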
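"""Livak 2^-ΔΔCt relative quantification for qPCR validation data.

Per sample: ΔCt = Ct_target − Ct_reference; ΔΔCt = ΔCt − mean(ΔCt over the
calibrator condition); relative expression = 2^(−ΔΔCt). Summarizing the
calibrator by the arithmetic mean of ΔCt (the geometric mean of fold
changes) makes the calibrator group's geometric-mean relative expression
exactly 1. Assumes ~100 % amplification efficiency for both primers
(efficiency-corrected models are out of scope).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["ddct"]


def ddct(ct: pd.DataFrame, target: str, reference: str,
         calibrator_condition: str) -> pd.DataFrame:
    """Relative expression of ``target`` vs ``reference`` gene, per sample.

    Parameters
    ----------
    ct
        Long-format Ct table with columns sample, condition, gene, ct; every
        sample needs one Ct for the target and one for the reference gene.
    calibrator_condition
        Condition label whose mean ΔCt anchors ΔΔCt = 0.

    Returns
    -------
    DataFrame with columns sample, condition, delta_ct, delta_delta_ct,
    rel_expr, in input sample order.
    """
    sub = ct[ct["gene"].isin([target, reference])]
    cond = ct.drop_duplicates("sample").set_index("sample")["condition"]
    wide = sub.pivot_table(index="sample", columns="gene", values="ct", aggfunc="mean")
    for gene in (target, reference):
        if gene not in wide.columns:
            raise ValueError(f"no Ct values for gene {gene!r}")
        missing = wide.index[wide[gene].isna()].tolist()
        if missing:
            raise ValueError(f"missing {gene!r} Ct for samples: {missing}")
    # keep input sample order
    order = ct["sample"].drop_duplicates().tolist()
    wide = wide.loc[order]
    delta = wide[target] - wide[reference]
    calib = delta[cond.loc[order].to_numpy() == calibrator_condition]
    if calib.empty:
        raise ValueError(f"calibrator condition {calibrator_condition!r} has no samples")
    dd = delta - calib.mean()
    return pd.DataFrame(
        {
            "sample": order,
            "condition": cond.loc[order].to_numpy(),
            "delta_ct": delta.to_numpy(),
            "delta_delta_ct": dd.to_numpy(),
            "rel_expr": (2.0 ** (-dd)).to_numpy(),
        }
    )
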
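"""Qualitative presence/absence overlap between conditions (Venn partition).

A protein is "detected" in a condition when observed in at least one
biological replicate before imputation; the partition splits detected
proteins into condition-unique and shared compartments.
"""

from pathlib import Path

import pandas as pd

from infosome_lfq.io import QuantMatrix
from infosome_lfq.setops import detection_sets, venn_partition

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = QuantMatrix.from_tsv(RESULTS / "biorep_raw.tsv", level="bio_rep")
    sets = detection_sets(matrix, min_reps_detected=1)
    control, ln = sets["Control"], sets["LN"]
    only_control, shared, only_ln = venn_partition(control, ln)
    rows = [("only_Control", len(only_control), ";".join(sorted(only_control))),
            ("shared", len(shared), ";".join(sorted(shared))),
            ("only_LN", len(only_ln), ";".join(sorted(only_ln)))]
    out = RESULTS / "venn.tsv"
    pd.DataFrame(rows, columns=["region", "count", "protein_ids"]).to_csv(
        out, sep="\t", index=False)
    print(f"detected in Control: {len(control)}; in LN: {len(ln)}")
    print(f"  shared: {len(shared)}; only Control: {len(only_control)}; "
          f"only LN: {len(only_ln)}")
    print(f"  wrote {out}")


if __name__ == "__main__":
    main()
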
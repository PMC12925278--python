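"""Welch-t / fold-change differential abundance between LN and Control.

A protein is called up (down) when log2FC >= 1 (<= -1) with p < 0.05;
Benjamini-Hochberg q-values are reported alongside.
"""

from pathlib import Path

from infosome_lfq.differential import run_differential
from infosome_lfq.io import QuantMatrix, write_results_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = QuantMatrix.from_tsv(RESULTS / "biorep_log2.tsv", level="bio_rep",
                                  log2=True)
    de = run_differential(matrix, control_group="Control", treatment_group="LN")
    out = RESULTS / "differential.tsv"
    write_results_table(de, out)
    counts = de["status"].value_counts()
    print(f"tested {len(de)} proteins (Welch's t, two-sided)")
    print(f"  up in LN:   {counts.get('up', 0)}")
    print(f"  down in LN: {counts.get('down', 0)}")
    print(f"  not significant: {counts.get('ns', 0)}")
    top = de.head(3)[["protein_id", "log2fc", "p_value", "status"]]
    print("  strongest calls:")
    for _, r in top.iterrows():
        print(f"    {r.protein_id}: log2FC {r.log2fc:+.2f}, p {r.p_value:.2e} "
              f"({r.status})")
    print(f"  wrote {out}")


if __name__ == "__main__":
    main()
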
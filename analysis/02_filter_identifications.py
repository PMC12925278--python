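"""Apply the identification stringency criteria to the simulated search output.

Accepts a protein only at probability > 99 % with >= 2 unique peptides and
>= 2 total and >= 2 unique spectral counts; writes the accepted list that
gates every downstream step.
"""

from pathlib import Path

from infosome_lfq.id_filter import filter_identifications
from infosome_lfq.io import read_id_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_id_table(RESULTS / "sim" / "ids.tsv")
    report = filter_identifications(records)
    out = RESULTS / "accepted_proteins.txt"
    out.write_text("\n".join(sorted(report.accepted)) + "\n")
    print(f"accepted {report.n_accepted} of {report.n_input} proteins")
    print(f"  failed probability > 0.99:   {report.rejected_probability}")
    print(f"  failed unique peptides >= 2: {report.rejected_unique_peptides}")
    print(f"  failed total spectra >= 2:   {report.rejected_total_spectra}")
    print(f"  failed unique spectra >= 2:  {report.rejected_unique_spectra}")
    print(f"  wrote {out}")


if __name__ == "__main__":
    main()
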
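"""Identification stringency filtering.

Protein identifications are accepted only above a probability threshold
(strict inequality, default >0.99) with at least two unique peptides, and —
as an additional stringency criterion — at least two total and two unique
spectral counts. The accepted set gates every downstream quantitative and
qualitative analysis. A peptide-level probability filter (strict >0.95) is
provided for workflows whose search-engine export is not pre-aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["FilterReport", "filter_identifications", "filter_peptide_level"]


@dataclass(frozen=True)
class FilterReport:
    """Accepted protein ids plus per-criterion rejection tallies.

    A protein failing several criteria is counted once per criterion it fails,
    so tallies may sum to more than the number of rejected proteins.
    """

    accepted: frozenset
    n_input: int
    rejected_probability: int
    rejected_unique_peptides: int
    rejected_total_spectra: int
    rejected_unique_spectra: int

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def filter_identifications(
    records: pd.DataFrame,
    protein_prob_min: float = 0.99,
    min_unique_peptides: int = 2,
    min_total_spectra: int = 2,
    min_unique_spectra: int = 2,
) -> FilterReport:
    """Apply the protein-level stringency criteria.

    A protein is accepted iff probability > ``protein_prob_min`` (strictly)
    AND unique_peptides >= ``min_unique_peptides`` AND total_spectra >=
    ``min_total_spectra`` AND unique_spectra >= ``min_unique_spectra``.

    Parameters
    ----------
    records
        Identification table with columns protein_id, protein_probability,
        unique_peptides, total_spectra, unique_spectra; one row per protein.

    Returns
    -------
    FilterReport
        Accepted id set and per-criterion rejection counts for logging.
    """
    ids = records["protein_id"].astype(str)
    dups = ids[ids.duplicated()].tolist()
    if dups:
        raise ValueError(f"duplicate protein_id in records: {sorted(set(dups))}")

    ok_prob = records["protein_probability"] > protein_prob_min
    ok_pep = records["unique_peptides"] >= min_unique_peptides
    ok_tot = records["total_spectra"] >= min_total_spectra
    ok_uni = records["unique_spectra"] >= min_unique_spectra
    ok = ok_prob & ok_pep & ok_tot & ok_uni
    return FilterReport(
        accepted=frozenset(ids[ok]),
        n_input=len(records),
        rejected_probability=int((~ok_prob).sum()),
        rejected_unique_peptides=int((~ok_pep).sum()),
        rejected_total_spectra=int((~ok_tot).sum()),
        rejected_unique_spectra=int((~ok_uni).sum()),
    )


def filter_peptide_level(peptide_probs, peptide_prob_min: float = 0.95) -> list[bool]:
    """Flag peptide identifications accepted at probability strictly above threshold."""
    flags = []
    for p in peptide_probs:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"peptide probability {p} outside [0, 1]")
        flags.append(p > peptide_prob_min)
    return flags
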
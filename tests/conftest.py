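import numpy as np
import pandas as pd
import pytest

from infosome_lfq.io import QuantMatrix, RunDesign
from infosome_lfq.simulate import SimulationConfig, simulate


def make_design(rows):
    """rows: iterable of (run_id, group, bio_rep, fraction, tech_rep)."""
    return RunDesign(pd.DataFrame(rows, columns=["run_id", "group", "bio_rep",
                                                 "fraction", "tech_rep"]))


def biorep_matrix(values, groups, bio_reps, protein_ids=None, log2=False):
    """Build a bio_rep-level QuantMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    cols = pd.MultiIndex.from_tuples(list(zip(groups, bio_reps)),
                                     names=["group", "bio_rep"])
    return QuantMatrix(pd.DataFrame(values, index=protein_ids, columns=cols),
                       level="bio_rep", log2=log2)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated experiment shared by read-only tests."""
    return simulate(SimulationConfig(n_proteins=300, seed=11))


@pytest.fixture()
def two_group_design():
    rows = []
    for g, n_frac, n_tech in [("Control", 2, 2), ("LN", 4, 2)]:
        for r in ("r1", "r2", "r3"):
            for f in range(1, n_frac + 1):
                for t in range(1, n_tech + 1):
                    rows.append((f"{g}_{r}_f{f}_t{t}", g, r, f, t))
    return make_design(rows)
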
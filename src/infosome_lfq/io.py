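"""Data model and TSV/GMT readers and writers.

All tabular interchange is tab-separated text with a single header row.
Intensity matrices use an explicit missing marker internally (NaN); on disk,
empty cells, ``NA`` and literal ``0`` all denote a missing measurement —
search-engine exports commonly write 0 for non-detection, which must not be
confused with a measured zero-abundance value.

Grouping of runs never relies on column order: every run column is mapped to
its (group, biological replicate, fraction, technical replicate) coordinates
through a :class:`RunDesign` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents interpreted as a missing measurement in quantification TSVs.
MISSING_TOKENS = ("", "NA", "NaN", "nan")

DESIGN_COLUMNS = ("run_id", "group", "bio_rep", "fraction", "tech_rep")

#: Separator used to flatten (group, bio_rep[, fraction]) column keys when an
#: aggregated matrix is written to disk.
COLUMN_SEP = "/"


class DesignError(ValueError):
    """Raised when a run-design table violates its contract."""


class MatrixError(ValueError):
    """Raised when a quantification matrix violates its contract."""


@dataclass(frozen=True)
class RunDesign:
    """Maps each LC-MS run to (group, biological replicate, fraction, technical replicate).

    Parameters
    ----------
    table
        DataFrame with columns ``run_id, group, bio_rep, fraction, tech_rep``.
        ``run_id`` values must be unique, as must the full
        (group, bio_rep, fraction, tech_rep) coordinate tuples.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise DesignError(f"design table lacks columns: {missing}")
        t = self.table.loc[:, list(DESIGN_COLUMNS)].copy()
        t["run_id"] = t["run_id"].astype(str)
        t["group"] = t["group"].astype(str)
        t["bio_rep"] = t["bio_rep"].astype(str)
        t["fraction"] = t["fraction"].astype(int)
        t["tech_rep"] = t["tech_rep"].astype(int)
        if (t["fraction"] < 1).any() or (t["tech_rep"] < 1).any():
            raise DesignError("fraction and tech_rep indices must be >= 1")
        dup_runs = t["run_id"][t["run_id"].duplicated()].tolist()
        if dup_runs:
            raise DesignError(f"duplicate run_id values: {sorted(set(dup_runs))}")
        coords = list(zip(t["group"], t["bio_rep"], t["fraction"], t["tech_rep"]))
        if len(set(coords)) != len(coords):
            seen, dups = set(), set()
            for c in coords:
                (dups if c in seen else seen).add(c)
            raise DesignError(f"duplicate design coordinates: {sorted(dups)}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- lookups ---------------------------------------------------------

    @property
    def run_ids(self) -> list[str]:
        return self.table["run_id"].tolist()

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.table["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def bio_reps(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        seen: dict[str, None] = {}
        for b in sub["bio_rep"]:
            seen.setdefault(b, None)
        return list(seen)

    def run_coordinates(self) -> Mapping[str, tuple[str, str, int, int]]:
        """run_id -> (group, bio_rep, fraction, tech_rep)."""
        return {
            r.run_id: (r.group, r.bio_rep, r.fraction, r.tech_rep)
            for r in self.table.itertuples(index=False)
        }

    def require_group(self, group: str) -> None:
        if group not in set(self.table["group"]):
            raise DesignError(f"group {group!r} not present in design (has {self.groups})")

    @classmethod
    def from_tsv(cls, path) -> "RunDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class QuantMatrix:
    """Protein x sample intensity matrix with an explicit missing marker.

    ``data`` holds proteins as rows. Column labels depend on ``level``:

    * ``run``      — run_id strings matching a :class:`RunDesign`;
    * ``fraction`` — MultiIndex (group, bio_rep, fraction);
    * ``bio_rep``  — MultiIndex (group, bio_rep).

    Missing measurements are NaN. On the linear-intensity scale all present
    values must be finite and >= 0; after log2 transformation (``log2=True``)
    values may be negative.
    """

    data: pd.DataFrame
    level: str = "run"
    log2: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("run", "fraction", "bio_rep"):
            raise MatrixError(f"unknown level {self.level!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate protein ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixError(f"duplicate column ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if not np.isfinite(vals[present]).all():
            raise MatrixError("non-finite intensity present")
        if not self.log2 and (vals[present] < 0).any():
            raise MatrixError("negative intensity on the linear scale")

    @property
    def protein_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        if isinstance(out.columns, pd.MultiIndex):
            out.columns = [COLUMN_SEP.join(str(p) for p in tup) for tup in out.columns]
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, level: str = "run", log2: bool = False) -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
                         keep_default_na=False, float_precision="round_trip")
        df = df.astype(float)
        if not log2:
            # exported 0 means non-detection, not a measured zero
            df = df.mask(df == 0.0)
        if level == "bio_rep":
            df.columns = pd.MultiIndex.from_tuples(
                [tuple(c.split(COLUMN_SEP, 1)) for c in df.columns],
                names=["group", "bio_rep"],
            )
        elif level == "fraction":
            tuples = []
            for c in df.columns:
                g, b, f = c.split(COLUMN_SEP, 2)
                tuples.append((g, b, int(f)))
            df.columns = pd.MultiIndex.from_tuples(tuples, names=["group", "bio_rep", "fraction"])
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df, level=level, log2=log2)


def read_quant_table(path, design_path) -> tuple[QuantMatrix, RunDesign]:
    """Read a run-level quantification TSV together with its run design.

    The matrix file has protein accessions in the first column and one column
    per run. Cells that are empty, ``NA`` or ``0`` become the missing marker.
    Every matrix column must have exactly one design row and vice versa; a
    mismatch raises :class:`DesignError` listing the symmetric difference.
    """
    design = RunDesign.from_tsv(design_path)
    raw = pd.read_csv(path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
                      keep_default_na=False, float_precision="round_trip")
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise MatrixError(f"duplicate protein ids in {path}: {dups}")
    matrix_cols = set(map(str, raw.columns))
    design_runs = set(design.run_ids)
    if matrix_cols != design_runs:
        only_matrix = sorted(matrix_cols - design_runs)
        only_design = sorted(design_runs - matrix_cols)
        raise DesignError(
            "matrix columns and design run_ids differ; "
            f"only in matrix: {only_matrix}; only in design: {only_design}"
        )
    df = raw.astype(float)
    df = df.mask(df == 0.0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    # order columns as in the design for reproducible output
    df = df.loc[:, design.run_ids]
    return QuantMatrix(df, level="run"), design


# ---------------------------------------------------------------------------
# identification tables
# ---------------------------------------------------------------------------

ID_COLUMNS = ("protein_id", "protein_probability", "unique_peptides",
              "total_spectra", "unique_spectra")


def read_id_table(path) -> pd.DataFrame:
    """Read per-protein search-engine evidence used by the stringency filter.

    Columns: protein_id, protein_probability (fraction in [0, 1]),
    unique_peptides, total_spectra, unique_spectra.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"identification table lacks columns: {missing}")
    df = df.loc[:, list(ID_COLUMNS)].copy()
    df["protein_id"] = df["protein_id"].astype(str)
    dups = df["protein_id"][df["protein_id"].duplicated()].tolist()
    if dups:
        raise ValueError(f"duplicate protein_id in identification table: {sorted(set(dups))}")
    for c in ID_COLUMNS[1:]:
        df[c] = pd.to_numeric(df[c])
    bad_prob = df[(df["protein_probability"] < 0) | (df["protein_probability"] > 1)]
    if len(bad_prob):
        raise ValueError(f"protein_probability outside [0,1] for {bad_prob['protein_id'].tolist()}")
    bad_spectra = df[df["unique_spectra"] > df["total_spectra"]]
    if len(bad_spectra):
        raise ValueError(
            f"unique_spectra exceeds total_spectra for {bad_spectra['protein_id'].tolist()}"
        )
    return df


def write_id_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(ID_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe for over-representation tests.

    ``universe`` defaults to the union of all set members; enrichment callers
    normally override it with the experiment's quantified protein list.
    """

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.universe:
            u: set = set()
            for members in self.sets.values():
                u |= set(members)
            self.universe = frozenset(u)

    def restricted(self, universe: Iterable) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop emptied sets with a warning."""
        uni = frozenset(universe)
        kept: dict[str, frozenset] = {}
        for name, members in self.sets.items():
            inter = frozenset(members) & uni
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %r empty after universe restriction; dropped", name)
        return GeneSetCollection(kept, uni)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>member...``.

    Duplicate member ids within a line are collapsed; a duplicated set name or
    a line with fewer than three fields is an error naming the offender.
    """
    sets: dict[str, frozenset] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = frozenset(m for m in fields[2:] if m)
    if n_lines == 0:
        warnings.warn(f"GMT file {path} is empty", stacklevel=2)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_results_table(results: pd.DataFrame, path, id_column: str | None = None) -> None:
    """Write a result table deterministically ordered and losslessly round-trippable.

    Rows are sorted by ``p_value`` ascending, ties broken lexicographically on
    the identifier column (the first column when not given). Floats use
    shortest round-trip representation.
    """
    if results is None:
        raise ValueError("results must not be None")
    out = results.copy()
    if id_column is None:
        id_column = out.columns[0]
    if "p_value" in out.columns and len(out):
        out = out.sort_values(["p_value", id_column], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Ct tables for relative quantification
# ---------------------------------------------------------------------------

CT_COLUMNS = ("sample", "condition", "gene", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table: sample, condition, gene, ct.

    Ct values must be finite cycle numbers in (0, 60).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    df = df.loc[:, list(CT_COLUMNS)].copy()
    df["ct"] = pd.to_numeric(df["ct"])
    bad = df[~np.isfinite(df["ct"]) | (df["ct"] <= 0) | (df["ct"] >= 60)]
    if len(bad):
        raise ValueError(f"Ct values outside (0, 60): {bad.to_dict('records')}")
    return df
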
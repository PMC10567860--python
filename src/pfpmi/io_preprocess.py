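"""Reading, validation and preprocessing of quantified-metabolite tables.

The pipeline starts from a samples x metabolites concentration table (mM),
as exported by targeted profiling of 1H NMR spectra, together with a
per-sample metadata table (sex, age, post-mortem interval, cause of death,
protein-removal protocol).  This module provides the table containers, the
CSV/TSV readers and writers, removal of exogenous metabolites, the
autoscaling transform used before every multivariate step, and the packaged
24-autopsy cohort metadata fixture.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationTable",
    "ScaledTable",
    "DEFAULT_EXOGENOUS",
    "METADATA_COLUMNS",
    "read_concentration_table",
    "write_concentration_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "load_table1_fixture",
    "exclude_exogenous",
    "autoscale",
]

#: metabolites stripped from every panel before modelling (matched
#: case-insensitively); drug names found in a cohort are appended by callers.
DEFAULT_EXOGENOUS = ("ethanol", "caffeine")

METADATA_COLUMNS = ("sample_id", "sex", "age_years", "pmi_hours", "cause_of_death")

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass
class ConcentrationTable:
    """Samples x metabolites matrix of concentrations in mM.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (rows).
    metabolite_names : ordered metabolite names (columns).
    values : (n_samples, n_metabolites) array, non-negative and finite.
    protocol : optional protein-removal protocol tag ("U" or "LLE").
    """

    sample_ids: list[str]
    metabolite_names: list[str]
    values: np.ndarray
    protocol: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.metabolite_names):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.sample_ids)} "
                f"samples x {len(self.metabolite_names)} metabolites"
            )
        names = [str(m) for m in self.metabolite_names]
        if len(set(names)) != len(names):
            dup = sorted({m for m in names if names.count(m) > 1})
            raise ValueError(f"duplicated metabolite name(s): {dup}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite concentration at sample {self.sample_ids[i]!r}, "
                f"metabolite {names[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative concentration at sample {self.sample_ids[i]!r}, "
                f"metabolite {names[j]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_names = names

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.metabolite_names
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, protocol: str | None = None) -> "ConcentrationTable":
        return cls(
            sample_ids=[str(i) for i in df.index],
            metabolite_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            protocol=protocol,
        )

    def select(self, metabolites: Sequence[str]) -> "ConcentrationTable":
        """Column subset preserving the given order."""
        idx = [self.metabolite_names.index(m) for m in metabolites]
        return ConcentrationTable(
            sample_ids=list(self.sample_ids),
            metabolite_names=list(metabolites),
            values=self.values[:, idx],
            protocol=self.protocol,
        )


@dataclass
class ScaledTable:
    """Autoscaled (unit-variance, zero-mean) view of a concentration table."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    metabolite_names: list[str] = field(default_factory=list)

    def inverse(self) -> np.ndarray:
        """Map scaled values back to concentrations (mM)."""
        return self.values * self.column_sds + self.column_means


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return "," if dialect == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_concentration_table(
    path: str | Path,
    dialect: str | None = None,
    protocol: str | None = None,
) -> ConcentrationTable:
    """Read a concentration table (first column sample ids, header metabolites).

    Raises ``ValueError`` naming the offending cell for missing or
    non-numeric entries, and for duplicated metabolite names.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    names = [h.strip() for h in header[1:]]
    if len(set(names)) != len(names):
        dup = sorted({m for m in names if names.count(m) > 1})
        raise ValueError(f"duplicated metabolite name(s) in header: {dup}")

    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = names
    sample_ids = [str(i) for i in raw.index]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw.iloc[:, j]):
            text = cell.strip()
            try:
                if text == "" or text.upper() in ("NA", "NAN"):
                    raise ValueError
                values[i, j] = float(text)
            except ValueError:
                kind = "missing" if text in ("", "NA", "NaN", "nan", "na") else "non-numeric"
                raise ValueError(
                    f"{kind} value {cell!r} at sample {sample_ids[i]!r}, "
                    f"metabolite {col!r}"
                ) from None
    return ConcentrationTable(sample_ids, names, values, protocol=protocol)


def write_concentration_table(
    table: ConcentrationTable, path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    sep = _infer_sep(path, dialect)
    table.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-metadata invariants; returns the frame unchanged."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    ids = meta["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicated sample_id in metadata")
    bad_sex = set(meta["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be M or F, got {sorted(bad_sex)}")
    if (meta["age_years"] <= 0).any():
        raise ValueError("age_years must be positive")
    if (meta["pmi_hours"] <= 0).any():
        raise ValueError("pmi_hours must be positive")
    if "protocol" in meta.columns:
        bad = set(meta["protocol"].dropna()) - {"U", "LLE", "untreated"}
        if bad:
            raise ValueError(f"unknown protocol tag(s): {sorted(bad)}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"sample_id": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 24-autopsy cohort (sex, age, PMI, cause of death).

    PMI spans 16-170 h; 17 males and 7 females aged 20-87 y.
    """
    text = resources.files("pfpmi").joinpath("data/table1_cohort.csv").read_text()
    meta = pd.read_csv(io.StringIO(text), dtype={"sample_id": str})
    return validate_metadata(meta)


def exclude_exogenous(
    table: ConcentrationTable,
    exclusion_list: Sequence[str] = DEFAULT_EXOGENOUS,
) -> ConcentrationTable:
    """Drop exogenous metabolites (ethanol, caffeine, drugs) by name.

    Matching is case-insensitive; names absent from the panel are ignored.
    """
    drop = {str(m).lower() for m in exclusion_list}
    keep = [m for m in table.metabolite_names if m.lower() not in drop]
    if not keep:
        raise ValueError("empty panel: exclusion list removes every metabolite")
    if len(keep) == len(table.metabolite_names):
        return table
    return table.select(keep)


def autoscale(
    table: ConcentrationTable | np.ndarray,
    reference: ScaledTable | None = None,
    ddof: int = 1,
) -> ScaledTable:
    """Center each metabolite to mean 0 and scale to unit SD (n-1 denominator).

    With ``reference`` given (training-set statistics), the table is projected
    using the reference means and SDs instead — the test-set transform.
    Zero-variance columns are dropped with a warning when self-scaling.
    """
    if isinstance(table, ConcentrationTable):
        X = table.values
        names = list(table.metabolite_names)
        ids = list(table.sample_ids)
    else:
        X = np.asarray(table, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
        ids = [str(i) for i in range(X.shape[0])]

    if reference is not None:
        if reference.metabolite_names and names != reference.metabolite_names:
            idx = []
            for m in reference.metabolite_names:
                if m not in names:
                    raise ValueError(f"metabolite {m!r} missing from table")
                idx.append(names.index(m))
            X = X[:, idx]
            names = list(reference.metabolite_names)
        scaled = (X - reference.column_means) / reference.column_sds
        return ScaledTable(scaled, reference.column_means.copy(),
                           reference.column_sds.copy(), ids, names)

    if X.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 rows (or a reference)")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    # relative tolerance: a constant column's SD is O(eps * |mean|), not 0
    keep = sds > 1e-12 * np.maximum(np.abs(means), 1.0)
    if not np.all(keep):
        dropped = [names[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance column(s): {dropped}")
        X, means, sds = X[:, keep], means[keep], sds[keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("no columns left after dropping zero-variance ones")
    return ScaledTable((X - means) / sds, means, sds, ids, names)
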
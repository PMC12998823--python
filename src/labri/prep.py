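"""Cohort preparation: exclusions, antibody classification, stratification,
and per-subgroup Tukey outlier filtering.

All tabular operations work on a pandas DataFrame with the cohort CSV
columns (see :data:`COHORT_COLUMNS`); missing analyte values are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ANALYZERS",
    "SEXES",
    "ANALYTES",
    "COHORT_COLUMNS",
    "AntibodyCutoffs",
    "SubgroupKey",
    "FilterReport",
    "apply_exclusions",
    "classify_antibody",
    "classify_antibody_frame",
    "stratify_subgroups",
    "quantile",
    "tukey_filter",
]

ANALYZERS = ("Abbott", "Beckman", "Roche", "Siemens")
SEXES = ("M", "F")
ANALYTES = ("TSH", "fT4", "fT3")

#: column carrying each analyte's concentration in the cohort CSV
ANALYTE_COLUMNS = {"TSH": "tsh", "fT4": "ft4", "fT3": "ft3"}

COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "analyzer",
    "tsh",
    "ft4",
    "ft3",
    "tg_ab",
    "tpo_ab",
    "pregnant",
    "inpatient",
    "thyroid_dx_or_med",
]

FLAG_COLUMNS = ("pregnant", "inpatient", "thyroid_dx_or_med")


@dataclass(frozen=True)
class AntibodyCutoffs:
    """Per-analyzer Tg-Ab / TPO-Ab positivity cutoffs (analyzer units)."""

    cutoffs: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for analyzer in ANALYZERS:
            if analyzer not in self.cutoffs:
                raise ValueError(f"missing cutoffs for analyzer {analyzer!r}")
        for analyzer, (tg, tpo) in self.cutoffs.items():
            if tg <= 0 or tpo <= 0:
                raise ValueError(f"non-positive cutoff for {analyzer!r}")

    def tg(self, analyzer: str) -> float:
        return self.cutoffs[analyzer][0]

    def tpo(self, analyzer: str) -> float:
        return self.cutoffs[analyzer][1]

    @classmethod
    def defaults(cls) -> "AntibodyCutoffs":
        """Manufacturer kit-insert cutoffs for the four platforms."""
        return cls(
            {
                "Abbott": (4.11, 5.61),
                "Beckman": (1.0, 10.0),
                "Roche": (115.0, 34.0),
                "Siemens": (4.5, 60.0),
            }
        )

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.cutoffs.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AntibodyCutoffs":
        return cls({k: (float(v[0]), float(v[1])) for k, v in d.items()})


@dataclass(frozen=True, order=True)
class SubgroupKey:
    """Address of one analysis cell: analyzer x sex stratum x antibody stratum x analyte."""

    analyzer: str
    sex_stratum: str  # "M", "F" or "M+F"
    antibody_stratum: str  # "neg", "pos" or "all"
    analyte: str

    def __post_init__(self) -> None:
        if self.analyzer not in ANALYZERS:
            raise ValueError(f"unknown analyzer {self.analyzer!r}")
        if self.sex_stratum not in ("M", "F", "M+F"):
            raise ValueError(f"unknown sex stratum {self.sex_stratum!r}")
        if self.antibody_stratum not in ("neg", "pos", "all"):
            raise ValueError(f"unknown antibody stratum {self.antibody_stratum!r}")
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")

    def label(self) -> str:
        return f"{self.analyzer}/{self.sex_stratum}/{self.antibody_stratum}/{self.analyte}"


@dataclass
class FilterReport:
    """Exclusion tallies (non-exclusive) plus per-subgroup Tukey removal fractions."""

    n_input: int = 0
    n_retained: int = 0
    excluded_age: int = 0
    excluded_missing_hormones: int = 0
    excluded_pregnant: int = 0
    excluded_inpatient: int = 0
    excluded_thyroid_dx_or_med: int = 0
    tukey_removed_fraction: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded_age": self.excluded_age,
            "excluded_missing_hormones": self.excluded_missing_hormones,
            "excluded_pregnant": self.excluded_pregnant,
            "excluded_inpatient": self.excluded_inpatient,
            "excluded_thyroid_dx_or_med": self.excluded_thyroid_dx_or_med,
            "tukey_removed_fraction": {
                k.label() if isinstance(k, SubgroupKey) else str(k): v
                for k, v in self.tukey_removed_fraction.items()
            },
        }
        return d


def apply_exclusions(
    records: pd.DataFrame, age_min: float = 18.0, age_max: float = 50.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain records with in-window age, complete hormone panel and no flags.

    A record may be tallied under several exclusion criteria; the retained
    set is independent of tally order.
    """
    if age_min >= age_max:
        raise ValueError("age_min must be < age_max")
    report = FilterReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), report

    age_ok = (records["age"] >= age_min) & (records["age"] <= age_max)
    hormones_ok = records[["tsh", "ft4", "ft3"]].notna().all(axis=1)
    pregnant = records["pregnant"].astype(bool)
    inpatient = records["inpatient"].astype(bool)
    thyroid = records["thyroid_dx_or_med"].astype(bool)

    report.excluded_age = int((~age_ok).sum())
    report.excluded_missing_hormones = int((~hormones_ok).sum())
    report.excluded_pregnant = int(pregnant.sum())
    report.excluded_inpatient = int(inpatient.sum())
    report.excluded_thyroid_dx_or_med = int(thyroid.sum())

    keep = age_ok & hormones_ok & ~pregnant & ~inpatient & ~thyroid
    retained = records.loc[keep].copy()
    report.n_retained = len(retained)
    return retained, report


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def classify_antibody(record, cutoffs: AntibodyCutoffs) -> str:
    """Classify one record as ``pos``, ``neg`` or ``indeterminate``.

    Positive iff any antibody exceeds its analyzer cutoff (a missing value
    never exceeds); negative iff both antibodies are present and at or below
    cutoff; indeterminate otherwise (an antibody is missing and the present
    one does not exceed).
    """
    analyzer = record["analyzer"]
    if analyzer not in cutoffs.cutoffs:
        raise KeyError(f"unknown analyzer {analyzer!r}")
    tg, tpo = record["tg_ab"], record["tpo_ab"]
    tg_missing, tpo_missing = _is_missing(tg), _is_missing(tpo)
    if (not tg_missing and tg > cutoffs.tg(analyzer)) or (
        not tpo_missing and tpo > cutoffs.tpo(analyzer)
    ):
        return "pos"
    if not tg_missing and not tpo_missing:
        return "neg"
    return "indeterminate"


def classify_antibody_frame(records: pd.DataFrame, cutoffs: AntibodyCutoffs) -> pd.Series:
    """Vectorized :func:`classify_antibody` over a cohort frame."""
    unknown = set(records["analyzer"].unique()) - set(cutoffs.cutoffs)
    if unknown:
        raise KeyError(f"unknown analyzer(s): {sorted(unknown)}")
    tg_cut = records["analyzer"].map(lambda a: cutoffs.tg(a))
    tpo_cut = records["analyzer"].map(lambda a: cutoffs.tpo(a))
    tg, tpo = records["tg_ab"], records["tpo_ab"]
    pos = (tg > tg_cut) | (tpo > tpo_cut)  # NaN comparisons are False
    neg = tg.notna() & tpo.notna() & (tg <= tg_cut) & (tpo <= tpo_cut)
    out = pd.Series("indeterminate", index=records.index)
    out[neg] = "neg"
    out[pos] = "pos"
    return out


def stratify_subgroups(
    records: pd.DataFrame, cutoffs: AntibodyCutoffs
) -> dict[SubgroupKey, np.ndarray]:
    """Split records into per-(analyzer, analyte) subgroup value vectors.

    Elementary cells are sex x antibody state; union cells
    (``antibody_stratum="all"``, ``sex_stratum="M+F"``) are exact
    concatenations of their members.  Indeterminate antibody records
    contribute only to ``all`` cells.
    """
    ab = classify_antibody_frame(records, cutoffs)
    out: dict[SubgroupKey, np.ndarray] = {}
    for analyzer in ANALYZERS:
        on_analyzer = records["analyzer"] == analyzer
        if not on_analyzer.any():
            continue
        for analyte in ANALYTES:
            col = ANALYTE_COLUMNS[analyte]
            elem: dict[tuple[str, str], np.ndarray] = {}
            for sex in SEXES:
                for state in ("neg", "pos", "indeterminate"):
                    mask = on_analyzer & (records["sex"] == sex) & (ab == state)
                    vals = records.loc[mask, col].dropna().to_numpy(dtype=float)
                    elem[(sex, state)] = vals
            _assemble_cells(out, analyzer, analyte, elem)
    return out


def _assemble_cells(
    out: dict[SubgroupKey, np.ndarray],
    analyzer: str,
    analyte: str,
    elem: Mapping[tuple[str, str], np.ndarray],
) -> None:
    """Build the nine table cells for one analyzer x analyte from elementary vectors."""
    for sex in SEXES:
        out[SubgroupKey(analyzer, sex, "neg", analyte)] = elem[(sex, "neg")]
        out[SubgroupKey(analyzer, sex, "pos", analyte)] = elem[(sex, "pos")]
        out[SubgroupKey(analyzer, sex, "all", analyte)] = np.concatenate(
            [elem[(sex, "neg")], elem[(sex, "pos")], elem[(sex, "indeterminate")]]
        )
    for stratum in ("neg", "pos"):
        out[SubgroupKey(analyzer, "M+F", stratum, analyte)] = np.concatenate(
            [elem[("M", stratum)], elem[("F", stratum)]]
        )
    out[SubgroupKey(analyzer, "M+F", "all", analyte)] = np.concatenate(
        [
            out[SubgroupKey(analyzer, "M", "all", analyte)],
            out[SubgroupKey(analyzer, "F", "all", analyte)],
        ]
    )


def quantile(values, p: float) -> float:
    """Linear-interpolation quantile with plotting position ``(k-1)/(n-1)``.

    Matches numpy's default ``method="linear"``; implemented directly so the
    convention used by the Tukey fences and the bootstrap percentiles is
    pinned down in one place.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("quantile of empty vector")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if arr.size == 1:
        return float(arr[0])
    pos = p * (arr.size - 1)
    k = int(np.floor(pos))
    frac = pos - k
    if k + 1 >= arr.size:
        return float(arr[-1])
    return float(arr[k] + frac * (arr[k + 1] - arr[k]))


def tukey_filter(values, k: float = 1.5) -> tuple[np.ndarray, float]:
    """Drop values outside the Tukey fences ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Returns the retained values (input order preserved) and the removed
    fraction.  Removal above 5% of the subgroup triggers a warning, not an
    error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("tukey_filter requires at least 4 values")
    if k <= 0:
        raise ValueError("fence multiplier k must be > 0")
    q1 = quantile(arr, 0.25)
    q3 = quantile(arr, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (arr >= lo) & (arr <= hi)
    removed_fraction = float((~keep).sum()) / arr.size
    if removed_fraction > 0.05:
        warnings.warn(
            f"Tukey filter removed {removed_fraction:.1%} of the subgroup (> 5%)",
            stacklevel=2,
        )
    return arr[keep], removed_fraction


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (empty fields are missing values)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str, "analyzer": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype(bool)
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)
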
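"""End-to-end orchestration: generate/load -> exclude -> stratify -> Tukey
filter -> estimate -> compare, with deterministic seeding and a provenance
block so a run can be reproduced byte-for-byte."""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compare import DEFAULT_BR_THRESHOLD, BiasRatioResult, bias_ratio
from .errors import EstimationError, InverseDomainError, DegenerateDataError
from .estimate import EstimatorSettings, ReferenceInterval, bootstrap_ci
from .prep import (
    ANALYTES,
    ANALYZERS,
    SEXES,
    ANALYTE_COLUMNS,
    AntibodyCutoffs,
    FilterReport,
    SubgroupKey,
    _assemble_cells,
    apply_exclusions,
    classify_antibody_frame,
    read_cohort_csv,
    tukey_filter,
)
from .synthetic import SyntheticCohortConfig, generate_cohort

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_ri_table",
           "prepare_subgroups", "default_comparison_plan"]


def _key_to_str(key: SubgroupKey) -> str:
    return "|".join((key.analyzer, key.sex_stratum, key.antibody_stratum, key.analyte))


def _key_from_str(s: str) -> SubgroupKey:
    analyzer, sex, ab, analyte = s.split("|")
    return SubgroupKey(analyzer, sex, ab, analyte)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``synthetic`` / ``cohort_csv`` supplies the cohort.
    ``subgroups`` / ``comparisons`` default to every table cell and the
    antibody pos-vs-neg plan per analyzer, sex and analyte.
    """

    synthetic: Optional[SyntheticCohortConfig] = None
    cohort_csv: Optional[str] = None
    cutoffs: AntibodyCutoffs = field(default_factory=AntibodyCutoffs.defaults)
    age_min: float = 18.0
    age_max: float = 50.0
    estimator: EstimatorSettings = field(default_factory=EstimatorSettings)
    tukey_k: float = 1.5
    br_threshold: float = DEFAULT_BR_THRESHOLD
    subgroups: Optional[Sequence[SubgroupKey]] = None
    comparisons: Optional[Sequence[tuple]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.cohort_csv is None):
            raise ValueError("exactly one of synthetic/cohort_csv must be set")

    def to_dict(self) -> dict:
        d: dict = {
            "cutoffs": self.cutoffs.to_dict(),
            "age_min": self.age_min,
            "age_max": self.age_max,
            "estimator": {
                "lambda_grid": list(self.estimator.lambda_grid),
                "central_coverage": self.estimator.central_coverage,
                "ci_level": self.estimator.ci_level,
                "bootstrap_reps": self.estimator.bootstrap_reps,
                "hist_min_bins": self.estimator.hist_min_bins,
                "hist_max_bins": self.estimator.hist_max_bins,
                "gof_alpha": self.estimator.gof_alpha,
                "min_n": self.estimator.min_n,
                "warn_n": self.estimator.warn_n,
            },
            "tukey_k": self.tukey_k,
            "br_threshold": self.br_threshold,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        if self.cohort_csv is not None:
            d["cohort_csv"] = str(self.cohort_csv)
        if self.subgroups is not None:
            d["subgroups"] = [_key_to_str(k) for k in self.subgroups]
        if self.comparisons is not None:
            d["comparisons"] = [[_key_to_str(t), _key_to_str(r)] for t, r in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        est = d.get("estimator", {})
        settings = EstimatorSettings(
            lambda_grid=tuple(est.get("lambda_grid", EstimatorSettings().lambda_grid)),
            central_coverage=est.get("central_coverage", 0.95),
            ci_level=est.get("ci_level", 0.90),
            bootstrap_reps=est.get("bootstrap_reps", 250),
            hist_min_bins=est.get("hist_min_bins", 30),
            hist_max_bins=est.get("hist_max_bins", 200),
            gof_alpha=est.get("gof_alpha", 0.01),
            min_n=est.get("min_n", 400),
            warn_n=est.get("warn_n", 1000),
        )
        return cls(
            synthetic=SyntheticCohortConfig.from_dict(d["synthetic"]) if "synthetic" in d else None,
            cohort_csv=d.get("cohort_csv"),
            cutoffs=AntibodyCutoffs.from_dict(d["cutoffs"]) if "cutoffs" in d
            else AntibodyCutoffs.defaults(),
            age_min=d.get("age_min", 18.0),
            age_max=d.get("age_max", 50.0),
            estimator=settings,
            tukey_k=d.get("tukey_k", 1.5),
            br_threshold=d.get("br_threshold", DEFAULT_BR_THRESHOLD),
            subgroups=[_key_from_str(s) for s in d["subgroups"]] if "subgroups" in d else None,
            comparisons=[( _key_from_str(t), _key_from_str(r)) for t, r in d["comparisons"]]
            if "comparisons" in d else None,
            seed=d.get("seed", 0),
        )

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunReport:
    filter_report: FilterReport
    intervals: list
    comparisons: list
    skipped: list  # (subgroup label or pair, reason)
    provenance: dict
    log_lines: list = field(default_factory=list)


def _child_seed(global_seed: int, label: str) -> int:
    """Stable per-subgroup seed so stages can be re-run in isolation."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0])


def prepare_subgroups(
    records: pd.DataFrame,
    cutoffs: AntibodyCutoffs,
    tukey_k: float = 1.5,
) -> tuple[dict, dict]:
    """Stratify and Tukey-filter the six elementary cells (sex x antibody
    state) per analyzer/analyte, then build union cells from the filtered
    members.  Returns (cells, removed_fraction per elementary cell label)."""
    ab = classify_antibody_frame(records, cutoffs)
    cells: dict[SubgroupKey, np.ndarray] = {}
    removed: dict[str, float] = {}
    for analyzer in ANALYZERS:
        on_analyzer = records["analyzer"] == analyzer
        if not on_analyzer.any():
            continue
        for analyte in ANALYTES:
            col = ANALYTE_COLUMNS[analyte]
            elem = {}
            for sex in SEXES:
                for state in ("neg", "pos", "indeterminate"):
                    mask = on_analyzer & (records["sex"] == sex) & (ab == state)
                    vals = records.loc[mask, col].dropna().to_numpy(dtype=float)
                    if vals.size >= 4:
                        vals, frac = tukey_filter(vals, tukey_k)
                        removed[f"{analyzer}/{sex}/{state}/{analyte}"] = frac
                    elem[(sex, state)] = vals
            _assemble_cells(cells, analyzer, analyte, elem)
    return cells, removed


def default_subgroup_plan(cells: dict) -> list:
    return sorted(cells.keys())


def default_comparison_plan(keys) -> list:
    """Antibody pos-vs-neg per analyzer, sex and analyte (Ab- as reference)."""
    keys = set(keys)
    plan = []
    for analyzer in ANALYZERS:
        for sex in SEXES:
            for analyte in ANALYTES:
                test = SubgroupKey(analyzer, sex, "pos", analyte)
                ref = SubgroupKey(analyzer, sex, "neg", analyte)
                if test in keys and ref in keys:
                    plan.append((test, ref))
    return plan


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Execute all stages deterministically under ``config.seed``."""
    log: list[str] = []

    if config.synthetic is not None:
        synth = replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(synth)
        log.append(f"generated synthetic cohort n={len(cohort)} (seed={config.seed})")
    else:
        cohort = read_cohort_csv(config.cohort_csv)
        log.append(f"loaded cohort n={len(cohort)} from {config.cohort_csv}")

    retained, filt = apply_exclusions(cohort, config.age_min, config.age_max)
    log.append(
        f"exclusions: {filt.n_input} -> {filt.n_retained} retained "
        f"(age={filt.excluded_age}, missing={filt.excluded_missing_hormones}, "
        f"pregnant={filt.excluded_pregnant}, inpatient={filt.excluded_inpatient}, "
        f"thyroid={filt.excluded_thyroid_dx_or_med})"
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cells, removed = prepare_subgroups(retained, config.cutoffs, config.tukey_k)
    for w in caught:
        log.append(f"warning: {w.message}")
    filt.tukey_removed_fraction = removed

    plan = list(config.subgroups) if config.subgroups is not None else default_subgroup_plan(cells)
    intervals: list[ReferenceInterval] = []
    skipped: list[tuple[str, str]] = []
    estimated: dict[SubgroupKey, ReferenceInterval] = {}
    for key in plan:
        values = cells.get(key)
        label = _key_to_str(key)
        if values is None or values.size == 0:
            skipped.append((label, "empty subgroup"))
            log.append(f"skip {label}: empty subgroup")
            continue
        settings = replace(config.estimator, seed=_child_seed(config.seed, label))
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                ri = bootstrap_ci(values, settings, subgroup=key)
            for w in caught:
                log.append(f"warning [{label}]: {w.message}")
        except (EstimationError, InverseDomainError, DegenerateDataError, ValueError) as exc:
            skipped.append((label, str(exc)))
            log.append(f"skip {label}: {exc}")
            continue
        estimated[key] = ri
        intervals.append(ri)
        log.append(
            f"estimated {label}: n={ri.n} LL={ri.ll:.4g} UL={ri.ul:.4g} "
            f"lambda={ri.model.lambda_hat}"
        )
    if not intervals:
        raise EstimationError("no estimable subgroups")

    cplan = (list(config.comparisons) if config.comparisons is not None
             else default_comparison_plan(estimated.keys()))
    comparisons: list[BiasRatioResult] = []
    for test_key, ref_key in cplan:
        pair = f"{_key_to_str(test_key)} vs {_key_to_str(ref_key)}"
        if test_key not in estimated or ref_key not in estimated:
            skipped.append((pair, "one side not estimated"))
            log.append(f"skip comparison {pair}")
            continue
        comparisons.append(
            bias_ratio(estimated[test_key], estimated[ref_key], config.br_threshold)
        )

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "subgroup_n": {_key_to_str(k): int(v.n) for k, v in estimated.items()},
    }
    report = RunReport(
        filter_report=filt,
        intervals=intervals,
        comparisons=comparisons,
        skipped=skipped,
        provenance=provenance,
        log_lines=log,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def intervals_frame(intervals) -> pd.DataFrame:
    rows = []
    for ri in intervals:
        k = ri.subgroup
        rows.append(
            {
                "analyzer": k.analyzer if k else "",
                "sex_stratum": k.sex_stratum if k else "",
                "antibody_stratum": k.antibody_stratum if k else "",
                "analyte": k.analyte if k else "",
                "n": ri.n,
                "LL": ri.ll,
                "UL": ri.ul,
                "LL_ci_low": ri.ll_ci[0] if ri.ll_ci else np.nan,
                "LL_ci_high": ri.ll_ci[1] if ri.ll_ci else np.nan,
                "UL_ci_low": ri.ul_ci[0] if ri.ul_ci else np.nan,
                "UL_ci_high": ri.ul_ci[1] if ri.ul_ci else np.nan,
                "lambda_hat": ri.model.lambda_hat,
            }
        )
    return pd.DataFrame(rows)


def comparisons_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "test_key": _key_to_str(c.test_key) if c.test_key else "",
                "ref_key": _key_to_str(c.ref_key) if c.ref_key else "",
                "sd_ri": c.sd_ri,
                "br_ll": c.br_ll,
                "br_ul": c.br_ul,
                "sig_ll": c.sig_ll,
                "sig_ul": c.sig_ul,
                "flags": c.flags(),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: RunReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    intervals_frame(report.intervals).to_csv(out / "intervals.csv", index=False)
    comparisons_frame(report.comparisons).to_csv(out / "comparisons.csv", index=False)
    blob = {
        "provenance": report.provenance,
        "filter_report": report.filter_report.to_dict(),
        "intervals": intervals_frame(report.intervals).to_dict(orient="records"),
        "comparisons": comparisons_frame(report.comparisons).to_dict(orient="records"),
        "skipped": report.skipped,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True)
    if report.intervals:
        (out / "table.txt").write_text(render_ri_table(report.intervals, report.comparisons))
    (out / "run.log").write_text("\n".join(report.log_lines) + "\n")


def render_ri_table(intervals, comparisons=()) -> str:
    """Fixed-column text table mirroring the antibody-stratified RI layout.

    Columns: Analyzer, Analyte, Gender, Antibody, N, RI (2 decimals), per-limit
    CIs, lambda, and the star-flag string of any comparison in which the row
    is the test group.
    """
    if not intervals:
        raise ValueError("render_ri_table requires at least one interval")
    flag_by_test = {}
    for c in comparisons:
        if c.test_key is not None:
            flag_by_test[c.test_key] = c.flags()
    header = ["Analyzer", "Analyte", "Gender", "Antibody", "N", "RI",
              "CI(LL)", "CI(UL)", "lambda", "BiasRatio"]
    rows = [header]
    for ri in intervals:
        k = ri.subgroup
        ab = {"neg": "-", "pos": "+", "all": "+,-"}.get(k.antibody_stratum, "") if k else ""
        ci_ll = f"{ri.ll_ci[0]:.2f}-{ri.ll_ci[1]:.2f}" if ri.ll_ci else ""
        ci_ul = f"{ri.ul_ci[0]:.2f}-{ri.ul_ci[1]:.2f}" if ri.ul_ci else ""
        rows.append([
            k.analyzer if k else "",
            k.analyte if k else "",
            k.sex_stratum if k else "",
            ab,
            str(ri.n),
            f"{ri.ll:.2f}-{ri.ul:.2f}",
            ci_ll,
            ci_ul,
            f"{ri.model.lambda_hat:g}",
            flag_by_test.get(k, ""),
        ])
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    return "\n".join(lines) + "\n"
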
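"""Synthetic laboratory cohorts with known ground truth.

Each (analyzer, sex, analyte) cell mixes a dominant non-pathological
component with low/high tail contamination; every component is a normal
distribution on a Box-Cox transformed scale, so the cell's true central-95%
limits are available in closed form for estimator recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InverseDomainError
from .prep import ANALYTES, ANALYZERS, COHORT_COLUMNS, SEXES, AntibodyCutoffs
from .transforms import box_cox, inverse_box_cox

__all__ = [
    "Z_CENTRAL_95",
    "ComponentSpec",
    "CellSpec",
    "SyntheticCohortConfig",
    "default_config",
    "generate_cohort",
    "true_limits",
]

#: standard-normal quantile at 0.975 (central 95% coverage)
Z_CENTRAL_95 = 1.959964

#: share of tail contamination assigned to the low component.  Mostly-low
#: contamination keeps per-subgroup Tukey removal on the raw (right-skewed)
#: scale below the 5% bound the exclusion procedure is expected to satisfy:
#: low-tail values never fall outside Tukey fences on a positive scale,
#: while a separated high tail is removed almost entirely.
LOW_TAIL_SHARE = 0.85


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component: normal(mu, sigma) on the Box-Cox(lam) scale."""

    lam: float
    mu: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")


@dataclass(frozen=True)
class CellSpec:
    """Mixture for one (analyzer, sex, analyte) cell."""

    healthy: ComponentSpec
    path_low: ComponentSpec
    path_high: ComponentSpec

    def __post_init__(self) -> None:
        total = self.healthy.weight + self.path_low.weight + self.path_high.weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell component weights sum to {total}, expected 1")


@dataclass
class SyntheticCohortConfig:
    """Full generative model for a cohort.

    ``cells`` maps (analyzer, sex, analyte) to a :class:`CellSpec`.  Antibody
    positivity is a latent Bernoulli state; positive individuals get an
    additive location shift (and optional scale inflation) on the healthy
    component of the transformed-scale distribution, per analyte.
    """

    n: int
    seed: int
    cells: dict = field(default_factory=dict)
    antibody_prevalence: float = 0.15
    antibody_shift: dict = field(
        default_factory=lambda: {"TSH": 0.40, "fT4": 0.0, "fT3": 0.0}
    )
    antibody_scale: dict = field(
        default_factory=lambda: {"TSH": 1.10, "fT4": 1.0, "fT3": 1.0}
    )
    exclusion_rates: dict = field(
        default_factory=lambda: {
            "pregnant": 0.04,
            "inpatient": 0.03,
            "thyroid_dx_or_med": 0.05,
            "missing": 0.02,
            "age_out_of_range": 0.03,
        }
    )
    analyzer_weights: dict = field(
        default_factory=lambda: {a: 0.25 for a in ANALYZERS}
    )
    female_fraction: float = 0.5
    age_range: tuple = (18.0, 50.0)
    cutoffs: AntibodyCutoffs = field(default_factory=AntibodyCutoffs.defaults)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for rate in (self.antibody_prevalence, self.female_fraction, *self.exclusion_rates.values()):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and fractions must lie in [0, 1]")
        for key in self.cells:
            analyzer, sex, analyte = key
            if analyzer not in ANALYZERS or sex not in SEXES or analyte not in ANALYTES:
                raise ValueError(f"unknown cell key {key!r}")

    @property
    def analyzers(self) -> tuple:
        return tuple(sorted({k[0] for k in self.cells}, key=ANALYZERS.index))

    # ----- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        def comp(c: ComponentSpec) -> dict:
            return {"lam": c.lam, "mu": c.mu, "sigma": c.sigma, "weight": c.weight}

        return {
            "n": self.n,
            "seed": self.seed,
            "cells": {
                "|".join(key): {
                    "healthy": comp(cell.healthy),
                    "path_low": comp(cell.path_low),
                    "path_high": comp(cell.path_high),
                }
                for key, cell in self.cells.items()
            },
            "antibody_prevalence": self.antibody_prevalence,
            "antibody_shift": dict(self.antibody_shift),
            "antibody_scale": dict(self.antibody_scale),
            "exclusion_rates": dict(self.exclusion_rates),
            "analyzer_weights": dict(self.analyzer_weights),
            "female_fraction": self.female_fraction,
            "age_range": list(self.age_range),
            "cutoffs": self.cutoffs.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticCohortConfig":
        def comp(c: Mapping) -> ComponentSpec:
            return ComponentSpec(c["lam"], c["mu"], c["sigma"], c["weight"])

        cells = {
            tuple(key.split("|")): CellSpec(
                comp(cell["healthy"]), comp(cell["path_low"]), comp(cell["path_high"])
            )
            for key, cell in d["cells"].items()
        }
        return cls(
            n=int(d["n"]),
            seed=int(d["seed"]),
            cells=cells,
            antibody_prevalence=float(d.get("antibody_prevalence", 0.15)),
            antibody_shift=dict(d.get("antibody_shift", {"TSH": 0.40, "fT4": 0.0, "fT3": 0.0})),
            antibody_scale=dict(d.get("antibody_scale", {"TSH": 1.10, "fT4": 1.0, "fT3": 1.0})),
            exclusion_rates=dict(d["exclusion_rates"]) if "exclusion_rates" in d else
            {"pregnant": 0.04, "inpatient": 0.03, "thyroid_dx_or_med": 0.05,
             "missing": 0.02, "age_out_of_range": 0.03},
            analyzer_weights=dict(d.get("analyzer_weights", {a: 0.25 for a in ANALYZERS})),
            female_fraction=float(d.get("female_fraction", 0.5)),
            age_range=tuple(d.get("age_range", (18.0, 50.0))),
            cutoffs=AntibodyCutoffs.from_dict(d["cutoffs"]) if "cutoffs" in d
            else AntibodyCutoffs.defaults(),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Base healthy / contamination parameters per analyte (transformed scale).
# TSH is right-skewed (lam=0, lognormal); fT4/fT3 near-symmetric (lam=1,
# i.e. a unit-shifted normal).  Contamination components sit in the tails.
_BASE = {
    "TSH": dict(lam=0.0, mu=0.2, sigma=0.45, lo_mu=-2.3, lo_sigma=0.5, hi_mu=2.6, hi_sigma=0.5),
    "fT4": dict(lam=1.0, mu=14.0, sigma=2.0, lo_mu=9.5, lo_sigma=1.5, hi_mu=22.0, hi_sigma=2.0),
    "fT3": dict(lam=1.0, mu=4.0, sigma=0.6, lo_mu=2.7, lo_sigma=0.4, hi_mu=7.2, hi_sigma=0.6),
}

# Location / scale adjustments so subgroup medians differ across platforms
# (additive on transformed location in units of the healthy sigma;
# multiplicative on sigma).
_ANALYZER_ADJUST = {
    "Abbott": (0.00, 1.00),
    "Beckman": (0.12, 1.04),
    "Roche": (0.25, 0.97),
    "Siemens": (0.35, 1.06),
}
_SEX_ADJUST = {"M": (0.08, 1.0), "F": (-0.04, 1.0)}


def default_config(
    n: int = 20_000,
    seed: int = 0,
    healthy_weight: float = 0.90,
    analyzers=ANALYZERS,
    **overrides,
) -> SyntheticCohortConfig:
    """Config with plausible per-cell mixtures for the requested analyzers.

    Tail contamination (``1 - healthy_weight``) splits equally between the
    low and high components.
    """
    if not 0.0 < healthy_weight <= 1.0:
        raise ValueError("healthy_weight must be in (0, 1]")
    contamination = 1.0 - healthy_weight
    lo_w = LOW_TAIL_SHARE * contamination
    hi_w = contamination - lo_w
    cells = {}
    for analyzer in analyzers:
        d_mu, f_sigma = _ANALYZER_ADJUST[analyzer]
        for sex in SEXES:
            s_mu, s_sigma = _SEX_ADJUST[sex]
            for analyte, base in _BASE.items():
                sigma = base["sigma"] * f_sigma * s_sigma
                mu = base["mu"] + (d_mu + s_mu) * base["sigma"]
                cells[(analyzer, sex, analyte)] = CellSpec(
                    healthy=ComponentSpec(base["lam"], mu, sigma, healthy_weight),
                    path_low=ComponentSpec(base["lam"], base["lo_mu"], base["lo_sigma"], lo_w),
                    path_high=ComponentSpec(base["lam"], base["hi_mu"], base["hi_sigma"], hi_w),
                )
        weights = {a: 1.0 / len(analyzers) for a in analyzers}
    return SyntheticCohortConfig(n=n, seed=seed, cells=cells,
                                 analyzer_weights=weights, **overrides)


def _healthy_params(config: SyntheticCohortConfig, analyzer: str, sex: str,
                    analyte: str, ab_positive: bool) -> tuple[float, float, float]:
    """(lam, mu, sigma) of the healthy component for one latent stratum."""
    cell = config.cells[(analyzer, sex, analyte)]
    comp = cell.healthy
    mu, sigma = comp.mu, comp.sigma
    if ab_positive:
        mu += config.antibody_shift.get(analyte, 0.0)
        sigma *= config.antibody_scale.get(analyte, 1.0)
    return comp.lam, mu, sigma


def true_limits(
    config: SyntheticCohortConfig,
    analyzer: str,
    sex: str,
    analyte: str,
    antibody: str = "neg",
) -> tuple[float, float]:
    """Closed-form 2.5th/97.5th percentiles of a cell's healthy component.

    ``antibody`` selects the latent stratum ("neg" or "pos"); positives see
    the configured shift/scale on the healthy component.
    """
    if (analyzer, sex, analyte) not in config.cells:
        raise KeyError(f"no cell for {(analyzer, sex, analyte)!r}")
    if antibody not in ("neg", "pos"):
        raise ValueError("antibody must be 'neg' or 'pos'")
    lam, mu, sigma = _healthy_params(config, analyzer, sex, analyte, antibody == "pos")
    ll = inverse_box_cox(mu - Z_CENTRAL_95 * sigma, lam)
    ul = inverse_box_cox(mu + Z_CENTRAL_95 * sigma, lam)
    return float(ll), float(ul)


def _draw_component(rng: np.random.Generator, n: int, lam: float, mu: float,
                    sigma: float) -> np.ndarray:
    """Draw positive values: inverse Box-Cox of N(mu, sigma), redrawing the
    (rare) normal deviates that fall outside the inverse domain."""
    y = mu + sigma * rng.standard_normal(n)
    if lam != 0.0:
        for _ in range(100):
            bad = 1.0 + lam * y <= 0
            if not bad.any():
                break
            y[bad] = mu + sigma * rng.standard_normal(int(bad.sum()))
        else:
            raise InverseDomainError(
                "component places too much mass outside the inverse Box-Cox domain"
            )
    return np.asarray(inverse_box_cox(y, lam), dtype=float)


def generate_cohort(
    config: SyntheticCohortConfig, return_latent: bool = False
):
    """Generate ``config.n`` laboratory records.

    Deterministic for a fixed config/seed.  With ``return_latent=True`` also
    returns a frame of latent states (antibody positivity, and the mixture
    component -- "healthy"/"low"/"high" -- each analyte value came from) for
    oracle checks in tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    analyzers = config.analyzers
    if n > 0 and not analyzers:
        raise ValueError("config defines no cells")

    if n == 0:
        empty = pd.DataFrame(columns=COHORT_COLUMNS)
        latent = pd.DataFrame(columns=["ab_positive"] + [f"component_{a}" for a in ANALYTES])
        return (empty, latent) if return_latent else empty

    w = np.array([config.analyzer_weights.get(a, 0.0) for a in analyzers], dtype=float)
    if w.sum() <= 0:
        raise ValueError("analyzer weights must have positive total")
    analyzer = rng.choice(np.array(analyzers, dtype=object), size=n, p=w / w.sum())
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M").astype(object)
    lo_age, hi_age = config.age_range
    age = np.round(rng.uniform(lo_age, hi_age, size=n), 1)
    ab_positive = rng.random(n) < config.antibody_prevalence

    values = {a: np.empty(n) for a in ANALYTES}
    component = {a: np.empty(n, dtype=object) for a in ANALYTES}
    comp_names = ("healthy", "low", "high")
    for analyte in ANALYTES:
        u = rng.random(n)
        z_reserve = None  # draws happen per cell for clarity; rng order is fixed
        for az in analyzers:
            for sx in SEXES:
                mask = (analyzer == az) & (sex == sx)
                m = int(mask.sum())
                if m == 0:
                    continue
                cell = config.cells[(az, sx, analyte)]
                w_h = cell.healthy.weight
                w_l = cell.path_low.weight
                comp_idx = np.full(m, 2)
                u_cell = u[mask]
                comp_idx[u_cell < w_h + w_l] = 1
                comp_idx[u_cell < w_h] = 0
                vals = np.empty(m)
                for ci, comp in enumerate((cell.healthy, cell.path_low, cell.path_high)):
                    sel = comp_idx == ci
                    k = int(sel.sum())
                    if k == 0:
                        continue
                    if ci == 0:
                        ab_sel = ab_positive[mask][sel]
                        for state in (False, True):
                            ss = ab_sel == state
                            kk = int(ss.sum())
                            if kk == 0:
                                continue
                            lam, mu, sg = _healthy_params(config, az, sx, analyte, state)
                            sub = vals[sel]
                            sub[ss] = _draw_component(rng, kk, lam, mu, sg)
                            vals[sel] = sub
                    else:
                        vals[sel] = _draw_component(rng, k, comp.lam, comp.mu, comp.sigma)
                values[analyte][mask] = vals
                cnames = np.array(comp_names, dtype=object)[comp_idx]
                component[analyte][mask] = cnames

    tg_ab, tpo_ab = _draw_antibody_concentrations(rng, analyzer, ab_positive, config.cutoffs)

    rates = config.exclusion_rates
    pregnant = (sex == "F") & (rng.random(n) < rates.get("pregnant", 0.0))
    inpatient = rng.random(n) < rates.get("inpatient", 0.0)
    thyroid = rng.random(n) < rates.get("thyroid_dx_or_med", 0.0)

    missing = rng.random(n) < rates.get("missing", 0.0)
    which = rng.integers(0, 3, size=n)
    for i, analyte in enumerate(ANALYTES):
        values[analyte][missing & (which == i)] = np.nan

    age_out = rng.random(n) < rates.get("age_out_of_range", 0.0)
    age[age_out] = np.round(rng.uniform(hi_age + 1.0, 90.0, size=int(age_out.sum())), 1)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "analyzer": analyzer,
            "tsh": values["TSH"],
            "ft4": values["fT4"],
            "ft3": values["fT3"],
            "tg_ab": tg_ab,
            "tpo_ab": tpo_ab,
            "pregnant": pregnant,
            "inpatient": inpatient,
            "thyroid_dx_or_med": thyroid,
        }
    )
    if not return_latent:
        return df
    latent = pd.DataFrame(
        {
            "ab_positive": ab_positive,
            "component_TSH": component["TSH"],
            "component_fT4": component["fT4"],
            "component_fT3": component["fT3"],
        }
    )
    return df, latent


def _draw_antibody_concentrations(
    rng: np.random.Generator,
    analyzer: np.ndarray,
    ab_positive: np.ndarray,
    cutoffs: AntibodyCutoffs,
) -> tuple[np.ndarray, np.ndarray]:
    """Two separated lognormals per analyzer keyed to the latent state.

    Negatives draw both antibodies around cutoff/4; positives draw TPO-Ab
    around 4x its cutoff (so at least one antibody exceeds).  With sdlog 0.4
    the dichotomized classification reproduces the latent state with
    probability > 0.999.
    """
    n = analyzer.shape[0]
    tg = np.empty(n)
    tpo = np.empty(n)
    sdlog = 0.4
    z_tg = rng.standard_normal(n)
    z_tpo = rng.standard_normal(n)
    for az in np.unique(analyzer):
        cut_tg, cut_tpo = cutoffs.tg(az), cutoffs.tpo(az)
        mask = analyzer == az
        neg = mask & ~ab_positive
        pos = mask & ab_positive
        tg[neg] = np.exp(np.log(cut_tg / 4.0) + sdlog * z_tg[neg])
        tpo[neg] = np.exp(np.log(cut_tpo / 4.0) + sdlog * z_tpo[neg])
        tg[pos] = np.exp(np.log(cut_tg / 4.0) + sdlog * z_tg[pos])
        tpo[pos] = np.exp(np.log(cut_tpo * 4.0) + sdlog * z_tpo[pos])
    return tg, tpo
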
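"""Indirect reference-interval estimation from mixed populations.

The estimator Box-Cox transforms the data over a grid of exponents, anchors
a histogram window at the modal bin, expands the window outward in
probability-mass balance while a truncated-normal fit of the in-window data
keeps passing a chi-square goodness-of-fit test, and back-transforms the
central 95% of the accepted normal model to the original scale.  Percentile
bootstrap (with the exponent frozen) supplies confidence intervals for both
limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import chdtrc, ndtr, ndtri

from .errors import DegenerateDataError, EstimationError, InverseDomainError
from .prep import SubgroupKey, quantile
from .transforms import box_cox, inverse_box_cox

__all__ = [
    "EstimatorSettings",
    "CentralModel",
    "ReferenceInterval",
    "build_histogram",
    "fit_truncated_normal",
    "fit_central_model",
    "estimate_ri",
    "bootstrap_ci",
    "box_cox",
    "inverse_box_cox",
]

_DEFAULT_LAMBDA_GRID = tuple(round(0.1 * i, 1) for i in range(16))  # 0.0 .. 1.5


@dataclass(frozen=True)
class EstimatorSettings:
    """Tuning knobs of the indirect estimator (defaults follow the pipeline's
    published configuration: central 95% interval, 90% CIs from 250
    percentile-bootstrap replicates)."""

    lambda_grid: Sequence[float] = _DEFAULT_LAMBDA_GRID
    central_coverage: float = 0.95
    ci_level: float = 0.90
    bootstrap_reps: int = 250
    hist_min_bins: int = 30
    hist_max_bins: int = 200
    gof_alpha: float = 0.01
    gof_scale: float = 1.0
    min_n: int = 400
    warn_n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.central_coverage < 1.0:
            raise ValueError("central_coverage must be in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")
        if not 0 < self.hist_min_bins <= self.hist_max_bins:
            raise ValueError("invalid histogram bin clamp")


@dataclass
class CentralModel:
    """Accepted fit of the central (non-pathological) distribution."""

    lambda_hat: float
    mu_hat: float
    sigma_hat: float
    window: tuple  # (a, b) on the transformed scale
    nonpath_fraction_hat: float
    gof_stat: float  # chi-square per degree of freedom at the accepted window
    in_window_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma_hat <= 0:
            raise ValueError("sigma_hat must be > 0")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy a < b")
        if not 0.0 < self.nonpath_fraction_hat <= 1.0:
            raise ValueError("nonpath_fraction_hat must be in (0, 1]")


@dataclass
class ReferenceInterval:
    """Estimated limits for one subgroup, optionally with bootstrap CIs."""

    subgroup: Optional[SubgroupKey]
    n: int
    ll: float
    ul: float
    model: CentralModel
    ll_ci: Optional[tuple] = None
    ul_ci: Optional[tuple] = None
    bootstrap_ll: Optional[np.ndarray] = field(default=None, repr=False)
    bootstrap_ul: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.ll < self.ul:
            raise ValueError("reference interval requires LL < UL")
        for ci in (self.ll_ci, self.ul_ci):
            if ci is not None and ci[0] > ci[1]:
                raise ValueError("CI bounds out of order")


# --------------------------------------------------------------------------
# histogram
# --------------------------------------------------------------------------

def build_histogram(
    values, settings: EstimatorSettings = EstimatorSettings()
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram with Freedman-Diaconis width, bin count clamped
    to ``[hist_min_bins, hist_max_bins]``; edges span [min, max]."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 30:
        raise ValueError("histogram requires at least 30 values")
    iqr = quantile(arr, 0.75) - quantile(arr, 0.25)
    if iqr <= 0:
        raise DegenerateDataError("zero IQR: histogram bin width undefined")
    h = 2.0 * iqr * arr.size ** (-1.0 / 3.0)
    span = float(arr.max() - arr.min())
    if span <= 0:
        raise DegenerateDataError("constant input")
    nbins = int(np.clip(math.ceil(span / h), settings.hist_min_bins, settings.hist_max_bins))
    edges = np.linspace(arr.min(), arr.max(), nbins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return edges, counts


# --------------------------------------------------------------------------
# truncated-normal maximum likelihood
# --------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


def _truncnorm_mle(
    nw: float,
    mean_w: float,
    var_w: float,
    a: float,
    b: float,
    sigma_floor: float,
    sigma_cap: float,
    init: Optional[tuple] = None,
) -> tuple[float, float]:
    """MLE of a normal truncated to (a, b) from in-window sufficient stats.

    Solves the score equations by the moment fixed point
    ``mu = m - sigma*r1``, ``sigma^2 = v / r2`` (m, v: in-window sample mean
    and variance; r1, r2 the truncated-normal mean/variance factors), with a
    damped update and a Nelder-Mead fallback when the fixed point stalls.
    """
    if init is not None:
        mu, sigma = init
        sigma = min(max(sigma, sigma_floor), sigma_cap)
    else:
        mu = mean_w
        sigma = max(math.sqrt(max(var_w, 1e-300)), sigma_floor)
    for _ in range(60):
        alpha = (a - mu) / sigma if not math.isinf(a) else -math.inf
        beta = (b - mu) / sigma if not math.isinf(b) else math.inf
        pa = math.exp(-0.5 * alpha * alpha) * _INV_SQRT_2PI if not math.isinf(alpha) else 0.0
        pb = math.exp(-0.5 * beta * beta) * _INV_SQRT_2PI if not math.isinf(beta) else 0.0
        z = _phi(beta) - _phi(alpha)
        if z <= 1e-12:
            break
        r1 = (pa - pb) / z
        apa = alpha * pa if not math.isinf(alpha) else 0.0
        bpb = beta * pb if not math.isinf(beta) else 0.0
        r2 = 1.0 + (apa - bpb) / z - r1 * r1
        if r2 <= 1e-6:
            sigma = sigma_cap
            mu = mean_w - sigma * r1
            break
        sigma_new = min(max(math.sqrt(var_w / r2), sigma_floor), sigma_cap)
        mu_new = mean_w - sigma_new * r1
        if abs(sigma_new - sigma) < 1e-9 * sigma and abs(mu_new - mu) < 1e-9 * max(1.0, abs(mu)):
            return mu_new, sigma_new
        mu, sigma = 0.5 * (mu + mu_new), 0.5 * (sigma + sigma_new)

    # Newton refinement on (mu, log sigma) with the analytic score; the
    # damped fixed point converges slowly under severe truncation.
    s1 = nw * mean_w
    s2 = nw * (var_w + mean_w * mean_w)

    def nll_grad(m: float, ls: float):
        s = math.exp(ls)
        al = (a - m) / s if not math.isinf(a) else -math.inf
        be = (b - m) / s if not math.isinf(b) else math.inf
        pa = math.exp(-0.5 * al * al) * _INV_SQRT_2PI if not math.isinf(al) else 0.0
        pb = math.exp(-0.5 * be * be) * _INV_SQRT_2PI if not math.isinf(be) else 0.0
        zz = _phi(be) - _phi(al)
        if zz <= 1e-300:
            return 1e300, 0.0, 0.0
        quad = (s2 - 2 * m * s1 + nw * m * m) / (2 * s * s)
        val = nw * ls + quad + nw * math.log(zz)
        g_mu = (nw * m - s1) / (s * s) + nw * (pa - pb) / (s * zz)
        apa = al * pa if not math.isinf(al) else 0.0
        bpb = be * pb if not math.isinf(be) else 0.0
        g_sigma = nw / s - 2 * quad / s + nw * (apa - bpb) / (s * zz)
        return val, g_mu, g_sigma * s  # gradient wrt (mu, log sigma)

    ls = math.log(min(max(sigma, sigma_floor), sigma_cap))
    m = mu
    val, g1, g2 = nll_grad(m, ls)
    converged = False
    for _ in range(60):
        if abs(g1) * max(1.0, abs(m)) < 1e-8 * nw and abs(g2) < 1e-8 * nw:
            converged = True
            break
        h1 = 1e-6 * max(1.0, abs(m))
        h2 = 1e-6
        _, g1p, g2p = nll_grad(m + h1, ls)
        _, g1m, g2m = nll_grad(m - h1, ls)
        _, g1q, g2q = nll_grad(m, ls + h2)
        _, g1r, g2r = nll_grad(m, ls - h2)
        h11 = (g1p - g1m) / (2 * h1)
        h21 = (g2p - g2m) / (2 * h1)
        h12 = (g1q - g1r) / (2 * h2)
        h22 = (g2q - g2r) / (2 * h2)
        det = h11 * h22 - h12 * h21
        if not math.isfinite(det) or abs(det) < 1e-300 or h11 <= 0 or h22 <= 0:
            break
        step_m = (h22 * g1 - h12 * g2) / det
        step_ls = (h11 * g2 - h21 * g1) / det
        # trust clipping keeps the iterate inside a sane region
        step_ls = min(max(step_ls, -1.0), 1.0)
        lim = sigma_cap  # generous absolute clip on the location step
        step_m = min(max(step_m, -lim), lim)
        t = 1.0
        for _ in range(20):
            val_new, g1n, g2n = nll_grad(m - t * step_m, ls - t * step_ls)
            if val_new < val:
                m, ls, val, g1, g2 = m - t * step_m, ls - t * step_ls, val_new, g1n, g2n
                break
            t *= 0.5
        else:
            break
    if converged:
        return float(m), float(min(max(math.exp(ls), sigma_floor), sigma_cap))

    # last resort: derivative-free minimization
    def nll(theta):
        return nll_grad(theta[0], theta[1])[0]

    res = minimize(
        nll,
        x0=np.array([m, ls]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
    )
    m, ls = res.x
    return float(m), float(min(max(math.exp(ls), sigma_floor), sigma_cap))


def fit_truncated_normal(values, window: tuple) -> tuple[float, float]:
    """ML fit of a normal truncated to ``window = (a, b)``.

    Only values inside the window enter the likelihood; at least 30 are
    required.  With an unbounded window this reduces to the sample mean and
    root-mean-squared deviation.
    """
    a, b = window
    if not a < b:
        raise ValueError("window requires a < b")
    arr = np.asarray(values, dtype=float)
    inside = arr[(arr >= a) & (arr <= b)]
    if inside.size < 2:
        raise ValueError("window excludes (almost) all data")
    mean_w = float(inside.mean())
    var_w = float(inside.var())
    if not np.isfinite(a) and not np.isfinite(b):
        if var_w <= 0:
            raise DegenerateDataError("zero variance inside window")
        return mean_w, math.sqrt(var_w)
    if inside.size < 30:
        raise ValueError("need at least 30 values inside the window")
    if var_w <= 0:
        raise DegenerateDataError("zero variance inside window")
    spread = float(arr.std()) or math.sqrt(var_w)
    return _truncnorm_mle(inside.size, mean_w, var_w, a, b,
                          sigma_floor=1e-6 * spread, sigma_cap=50.0 * spread)


# --------------------------------------------------------------------------
# mode-anchored window expansion
# --------------------------------------------------------------------------

def _gof(counts_w: np.ndarray, probs_w: np.ndarray, nw: int) -> Optional[tuple[float, int, float]]:
    """Chi-square GOF of observed window-bin counts vs the fitted model.

    Bins are pooled left-to-right until each pooled cell has expected count
    >= 5.  Returns (stat, df, p) with df = cells - 3 (two fitted parameters
    plus the normalization), or None when the comparison is untestable.
    """
    z = probs_w.sum()
    if z <= 0:
        return None
    expected = nw * probs_w / z
    obs_cells, exp_cells = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(counts_w, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_cells.append(o_acc)
            exp_cells.append(e_acc)
            o_acc = e_acc = 0.0
    if o_acc or e_acc:
        if exp_cells:
            obs_cells[-1] += o_acc
            exp_cells[-1] += e_acc
        else:
            return None
    df = len(exp_cells) - 3
    if df < 1:
        return None
    obs_arr = np.asarray(obs_cells)
    exp_arr = np.asarray(exp_cells)
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    return stat, df, float(chdtrc(df, stat))


@dataclass
class _LambdaFit:
    lam: float
    mu: float
    sigma: float
    a: float
    b: float
    frac: float  # in-window share of the data
    gof_per_df: float
    gof_df: int
    nw: int
    z_window: float  # modeled in-window probability


def _expand_fit(y: np.ndarray, edges: np.ndarray, counts: np.ndarray,
                settings: EstimatorSettings) -> Optional[_LambdaFit]:
    """Expand a window around the modal bin while the truncated-normal fit
    keeps passing the chi-square test; return the last accepted fit."""
    n = y.size
    nbins = counts.size
    order = np.sort(y)
    cum1 = np.concatenate([[0.0], np.cumsum(order)])
    cum2 = np.concatenate([[0.0], np.cumsum(order * order)])
    spread = float(order.std()) or 1.0
    sigma_floor, sigma_cap = 1e-6 * spread, 50.0 * spread

    mode = int(np.argmax(counts))
    lo = hi = mode
    blocked_left = blocked_right = False
    # a side is blocked only after this many consecutive rejections, so a
    # single chance-level bin fluctuation cannot freeze the expansion early
    max_streak = 3
    streak_left = streak_right = 0
    accepted: Optional[_LambdaFit] = None

    def window_stats(l: int, h: int):
        # a window covering every bin applies no truncation at all
        if l == 0 and h == nbins - 1:
            a, b = -math.inf, math.inf
            return a, b, n, float(cum1[-1] / n), float(cum2[-1] / n - (cum1[-1] / n) ** 2)
        a, b = float(edges[l]), float(edges[h + 1])
        i0 = int(np.searchsorted(order, a, side="left"))
        i1 = int(np.searchsorted(order, b, side="right"))
        nw = i1 - i0
        if nw < 2:
            return a, b, nw, 0.0, 0.0
        s1 = cum1[i1] - cum1[i0]
        s2 = cum2[i1] - cum2[i0]
        mean_w = s1 / nw
        var_w = max(s2 / nw - mean_w * mean_w, 0.0)
        return a, b, nw, mean_w, var_w

    def try_window(l: int, h: int):
        """Fit + test a candidate window. Returns (_LambdaFit|None, passed)."""
        a, b, nw, mean_w, var_w = window_stats(l, h)
        small = nw < 30 or (h - l + 1) < 6
        if nw < 30 or var_w <= 0:
            return None, small  # nothing to fit; only acceptable while tiny
        mu, sigma = _truncnorm_mle(nw, mean_w, var_w, a, b, sigma_floor, sigma_cap)
        edge_z = (edges[l : h + 2] - mu) / sigma
        cdf = ndtr(edge_z)
        probs_w = np.diff(cdf)
        z_window = float(cdf[-1] - cdf[0])
        gof = _gof(counts[l : h + 1], probs_w, nw) if z_window > 1e-3 else None
        if gof is None:
            # untestable: provisional accept only while the window is small;
            # a large window that cannot be validated is rejected outright
            stat_per_df, df, passed = float("inf"), 0, small
        else:
            stat, df, p = gof
            # gof_scale > 1 deflates the statistic (bootstrap resamples carry
            # roughly twice the multinomial count variance of fresh data)
            p = float(chdtrc(df, stat / settings.gof_scale))
            stat_per_df, passed = stat / df, p >= settings.gof_alpha
        # The modeled central component is the majority of the data by
        # assumption: rejections are not binding until the window holds at
        # least half of it (prevents collapse onto a sliver of the mode on
        # noisy/resampled inputs).
        if not passed and gof is not None and nw < 0.5 * n:
            passed = True
        fit = _LambdaFit(float("nan"), mu, sigma, a, b, nw / n, stat_per_df, df, nw, z_window)
        return (fit, passed) if passed else (None, False)

    fit, _ = try_window(lo, hi)
    if fit is not None:
        accepted = fit
    lo_acc, hi_acc = lo, hi  # window of the last accepted (or initial) state
    while True:
        can_left = lo > 0 and not blocked_left
        can_right = hi < nbins - 1 and not blocked_right
        if not can_left and not can_right:
            break
        if can_left and can_right:
            left_mass = counts[lo:mode].sum()
            right_mass = counts[mode + 1 : hi + 1].sum()
            go_left = left_mass <= right_mass
        else:
            go_left = can_left
        l2, h2 = (lo - 1, hi) if go_left else (lo, hi + 1)
        fit, passed = try_window(l2, h2)
        lo, hi = l2, h2  # pointer advances even while probing a rejecting side
        if not passed:
            if go_left:
                streak_left += 1
                if streak_left >= max_streak:
                    blocked_left = True
                    lo = lo_acc  # drop the probed bins from the window
            else:
                streak_right += 1
                if streak_right >= max_streak:
                    blocked_right = True
                    hi = hi_acc
            continue
        if go_left:
            streak_left = 0
        else:
            streak_right = 0
        lo_acc, hi_acc = lo, hi
        if fit is not None:
            accepted = fit
    return accepted


def fit_central_model(values, settings: EstimatorSettings = EstimatorSettings()) -> CentralModel:
    """Model the central distribution over the Box-Cox exponent grid.

    Per exponent: transform, histogram, mode-anchored window expansion with
    truncated-normal refits and chi-square stopping.  The winner is the
    exponent with the smallest per-degree-of-freedom GOF statistic among
    those whose accepted window retains a competitive share of the data
    (within 0.10 of the best; guards against trivially small windows winning
    on chance-level GOF); ties break toward the smaller exponent.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 50:
        raise EstimationError(f"subgroup too small to model (n={n})")
    if np.any(arr <= 0):
        raise ValueError("analyte values must be strictly positive")
    if n < settings.min_n:
        warnings.warn(
            f"subgroup n={n} below min_n={settings.min_n}; estimate is unreliable",
            stacklevel=2,
        )
    elif n < settings.warn_n:
        warnings.warn(f"subgroup n={n} below {settings.warn_n}; wide uncertainty expected",
                      stacklevel=2)

    fits: list[_LambdaFit] = []
    for lam in settings.lambda_grid:
        y = np.asarray(box_cox(arr, lam), dtype=float)
        try:
            edges, counts = build_histogram(y, settings)
        except DegenerateDataError:
            continue
        fit = _expand_fit(y, edges, counts, settings)
        if fit is None:
            continue
        fit.lam = float(lam)
        fits.append(fit)
    # drop fits whose implied limits leave the inverse-transform domain
    z = float(ndtri(0.5 + settings.central_coverage / 2.0))
    fits = [
        f for f in fits
        if f.lam == 0.0
        or (1.0 + f.lam * (f.mu - z * f.sigma) > 0 and 1.0 + f.lam * (f.mu + z * f.sigma) > 0)
    ]
    if not fits:
        raise EstimationError("no Box-Cox exponent produced an accepted central fit")

    tested = [f for f in fits if np.isfinite(f.gof_per_df)]
    pool = tested if tested else fits
    # the correct exponent keeps the largest share of the data in an
    # accepted window; per-df GOF statistics from windows of different size
    # are not comparable, so fraction is compared first (0.02 tolerance)
    best_frac = max(f.frac for f in pool)
    candidates = [f for f in pool if f.frac >= best_frac - 0.02]
    best = min(candidates, key=lambda f: (f.gof_per_df, f.lam))
    # candidates within one standard error of the best per-df statistic
    # (sd of chi2/df ~ sqrt(2/df)) are statistical ties: take the smallest
    # exponent among them rather than chasing grid noise
    tie_margin = math.sqrt(2.0 / best.gof_df) if best.gof_df > 0 else 0.0
    winner = min(
        (f for f in candidates if f.gof_per_df <= best.gof_per_df + tie_margin),
        key=lambda f: f.lam,
    )

    nonpath = winner.nw / (n * winner.z_window) if winner.z_window > 0 else 1.0
    nonpath = min(nonpath, 1.0)
    gof = winner.gof_per_df if np.isfinite(winner.gof_per_df) else float("nan")
    return CentralModel(
        lambda_hat=winner.lam,
        mu_hat=winner.mu,
        sigma_hat=winner.sigma,
        window=(winner.a, winner.b),
        nonpath_fraction_hat=nonpath,
        gof_stat=gof,
        in_window_fraction=winner.frac,
    )


# --------------------------------------------------------------------------
# reference limits and bootstrap CIs
# --------------------------------------------------------------------------

def _limits_from_model(model: CentralModel, central_coverage: float) -> tuple[float, float]:
    z = float(ndtri(0.5 + central_coverage / 2.0))
    try:
        ll = inverse_box_cox(model.mu_hat - z * model.sigma_hat, model.lambda_hat)
        ul = inverse_box_cox(model.mu_hat + z * model.sigma_hat, model.lambda_hat)
    except InverseDomainError as exc:
        raise InverseDomainError(
            f"fitted limits fall outside the inverse Box-Cox domain: {exc}"
        ) from exc
    return float(ll), float(ul)


def estimate_ri(
    values,
    settings: EstimatorSettings = EstimatorSettings(),
    subgroup: Optional[SubgroupKey] = None,
) -> ReferenceInterval:
    """Point reference limits: the central-coverage quantiles of the fitted
    model, back-transformed to the original scale."""
    arr = np.asarray(values, dtype=float)
    model = fit_central_model(arr, settings)
    ll, ul = _limits_from_model(model, settings.central_coverage)
    return ReferenceInterval(subgroup=subgroup, n=arr.size, ll=ll, ul=ul, model=model)


def bootstrap_ci(
    values,
    settings: EstimatorSettings = EstimatorSettings(),
    subgroup: Optional[SubgroupKey] = None,
) -> ReferenceInterval:
    """Point limits plus percentile-bootstrap CIs at ``settings.ci_level``.

    Resamples with replacement; each resample is re-estimated with the
    exponent frozen at the full-sample ``lambda_hat``.  Failed resamples are
    skipped; more than 10% failures aborts.
    """
    arr = np.asarray(values, dtype=float)
    point = estimate_ri(arr, settings, subgroup)
    fixed = replace(settings, lambda_grid=(point.model.lambda_hat,), gof_scale=2.0)
    rng = np.random.default_rng(settings.seed)
    boot_ll, boot_ul = [], []
    failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(settings.bootstrap_reps):
            resample = arr[rng.integers(0, arr.size, arr.size)]
            try:
                model = fit_central_model(resample, fixed)
                ll, ul = _limits_from_model(model, settings.central_coverage)
            except (EstimationError, InverseDomainError, DegenerateDataError, ValueError):
                failures += 1
                continue
            if not (np.isfinite(ll) and np.isfinite(ul)):
                failures += 1
                continue
            boot_ll.append(ll)
            boot_ul.append(ul)
    if failures > 0.10 * settings.bootstrap_reps:
        raise EstimationError(
            f"{failures}/{settings.bootstrap_reps} bootstrap resamples failed"
        )
    lo_p = (1.0 - settings.ci_level) / 2.0
    hi_p = (1.0 + settings.ci_level) / 2.0
    ll_arr, ul_arr = np.asarray(boot_ll), np.asarray(boot_ul)
    return ReferenceInterval(
        subgroup=subgroup,
        n=arr.size,
        ll=point.ll,
        ul=point.ul,
        model=point.model,
        ll_ci=(quantile(ll_arr, lo_p), quantile(ll_arr, hi_p)),
        ul_ci=(quantile(ul_arr, lo_p), quantile(ul_arr, hi_p)),
        bootstrap_ll=ll_arr,
        bootstrap_ul=ul_arr,
    )
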
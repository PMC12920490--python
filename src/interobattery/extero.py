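"""Exteroceptive / multisensory battery scoring.

Fourteen step-2 predictors come from this module:

* ``delta_ar`` — body-image discrepancy: mean BMI of the silhouettes chosen as
  one's own physique minus the real BMI.
* ``c_che``/``c_arm`` — two-point-discrimination percent correct per site.
* ``hit`` — finger-localisation correct-response count.
* ``auc_av``/``auc_at``/``auc_vt`` — race-model-inequality violation area for
  each bimodal reaction-time condition.
* ``jnd_sj`` — width of the Gaussian bump fitted to simultaneity judgments.
* ``pse_pps`` — Spearman-Kaerber midpoint of the peripersonal-space function.
* ``jnd_toju``/``jnd_tojc`` — 75%-point JND from cumulative-Gaussian fits to
  temporal-order judgments (uncrossed / crossed hands).
* ``sc`` — "sum of confusion": accumulated absolute divergence between the
  crossed and uncrossed fitted TOJ curves.
* ``mre_lh``/``mre_rh`` — mental-rotation slope (ms per degree) per hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BodyImageInput",
    "PsychometricTable",
    "RtConditionTable",
    "GaussianFit",
    "ExteroScores",
    "RT_CONDITIONS",
    "BIMODAL_PAIRS",
    "body_image_delta",
    "percent_correct",
    "race_model_auc",
    "fit_gaussian_bump",
    "spearman_karber_pse",
    "fit_cumulative_gaussian",
    "sum_of_confusion",
    "mental_rotation_slope",
]

RT_CONDITIONS = ("A", "T", "V", "AT", "AV", "VT")
BIMODAL_PAIRS = {"AT": ("A", "T"), "AV": ("A", "V"), "VT": ("V", "T")}

#: JND convention for cumulative-Gaussian fits: the 75%-25% half spread.
Z75 = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class BodyImageInput:
    weight: float  # kg
    height: float  # m
    silhouette_bmi_values: tuple  # ordered silhouette -> BMI map
    perceived_actual_ratings: tuple  # silhouette indices chosen as own physique

    def __post_init__(self):
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        for idx in self.perceived_actual_ratings:
            if not 0 <= idx < len(self.silhouette_bmi_values):
                raise IndexError(f"silhouette index {idx} outside the BMI map")


@dataclass
class PsychometricTable:
    """Rows of (stimulus level, n presented, n positive responses)."""

    levels: np.ndarray
    n_presented: np.ndarray
    n_positive: np.ndarray

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_presented = np.asarray(self.n_presented, dtype=int)
        self.n_positive = np.asarray(self.n_positive, dtype=int)
        if not (self.levels.size == self.n_presented.size == self.n_positive.size):
            raise ValueError("columns must have equal length")
        if np.unique(self.levels).size != self.levels.size:
            raise ValueError("stimulus levels must be unique")
        if np.any(self.n_positive < 0) or np.any(self.n_positive > self.n_presented):
            raise ValueError("need 0 <= n_positive <= n_presented")
        order = np.argsort(self.levels)
        self.levels = self.levels[order]
        self.n_presented = self.n_presented[order]
        self.n_positive = self.n_positive[order]

    @property
    def proportions(self) -> np.ndarray:
        return self.n_positive / np.maximum(self.n_presented, 1)


@dataclass
class RtConditionTable:
    """Reaction times (ms) per condition (A, T, V, AT, AV, VT)."""

    rts: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for cond, values in self.rts.items():
            if cond not in RT_CONDITIONS:
                raise KeyError(f"unknown RT condition {cond!r}")
            arr = np.asarray(values, dtype=float)
            if np.any(arr <= 0):
                raise ValueError(f"non-positive RT in condition {cond}")
            clean[cond] = arr
        self.rts = clean

    def __getitem__(self, cond: str) -> np.ndarray:
        if cond not in self.rts:
            raise KeyError(f"condition {cond!r} missing from RT table")
        return self.rts[cond]


@dataclass(frozen=True)
class ExteroScores:
    """The fourteen step-2 predictors for one participant."""

    delta_ar: float  # BMI units
    c_che: float  # % correct
    c_arm: float  # % correct
    hit: int  # count
    auc_av: float
    auc_at: float
    auc_vt: float
    jnd_sj: float  # ms
    pse_pps: float  # stimulus units
    jnd_toju: float  # ms
    jnd_tojc: float  # ms
    sc: float
    mre_lh: float  # ms/degree
    mre_rh: float  # ms/degree

    def __post_init__(self):
        for name in ("c_che", "c_arm"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        for name in ("jnd_sj", "jnd_toju", "jnd_tojc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("auc_av", "auc_at", "auc_vt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GaussianFit:
    mu: float
    sigma: float
    lapse: float = 0.0
    amplitude: float = 1.0
    goodness: float = float("nan")  # binomial deviance
    fallback: bool = False  # True when the ridge-penalised refit was used


# --------------------------------------------------------------------------- #
# Body image and accuracies
# --------------------------------------------------------------------------- #

def body_image_delta(inp: BodyImageInput) -> float:
    """Perceived-actual BMI (mean over chosen silhouettes) minus real BMI."""
    if len(inp.perceived_actual_ratings) == 0:
        raise ValueError("perceived-actual ratings are empty")
    bmi_r = inp.weight / inp.height**2
    bmi_a = float(
        np.mean([inp.silhouette_bmi_values[i] for i in inp.perceived_actual_ratings])
    )
    return bmi_a - bmi_r


def percent_correct(n_correct: int, n_total: int) -> float:
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("need 0 <= n_correct <= n_total")
    return 100.0 * n_correct / n_total


# --------------------------------------------------------------------------- #
# Race-model inequality
# --------------------------------------------------------------------------- #

def _ecdf(sorted_x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_x, t, side="right") / sorted_x.size


def race_model_auc(
    rts: RtConditionTable,
    pair: str,
    *,
    percentiles: np.ndarray | None = None,
) -> float:
    """Violation area of the race-model inequality for one bimodal condition.

    Empirical CDFs of the bimodal condition and its two unimodal parents are
    evaluated at the bimodal condition's percentile grid (5th-100th in steps
    of 5, linear-interpolated quantiles).  The race bound is
    ``min(1, F_uni1 + F_uni2)``; positive excess of the bimodal CDF over the
    bound, integrated (trapezoid) over the percentile axis expressed as
    fractions, is the AUC.  Time-shift invariant by construction.
    """
    if pair not in BIMODAL_PAIRS:
        raise KeyError(f"pair must be one of {sorted(BIMODAL_PAIRS)}")
    u1, u2 = BIMODAL_PAIRS[pair]
    bi = np.sort(rts[pair])
    a = np.sort(rts[u1])
    b = np.sort(rts[u2])
    for name, arr in ((pair, bi), (u1, a), (u2, b)):
        if arr.size < 10:
            raise ValueError(f"condition {name} needs >= 10 RTs, got {arr.size}")
    if percentiles is None:
        percentiles = np.arange(0.05, 1.0001, 0.05)
    t = np.quantile(bi, percentiles, method="linear")
    actual = _ecdf(bi, t)
    predicted = np.minimum(1.0, _ecdf(a, t) + _ecdf(b, t))
    violation = np.maximum(0.0, actual - predicted)
    return float(np.trapezoid(violation, percentiles))


# --------------------------------------------------------------------------- #
# Psychometric fits
# --------------------------------------------------------------------------- #

def _binom_nll(p: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _deviance(p: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    sat = k / np.maximum(n, 1)
    return 2.0 * (_binom_nll(p, k, n) - _binom_nll(sat, k, n))


def fit_gaussian_bump(table: PsychometricTable) -> tuple[GaussianFit, float]:
    """Gaussian-bump fit for simultaneity judgments; returns (fit, jnd).

    ``p(simultaneous | SOA) = a * exp(-(SOA - mu)^2 / (2 sigma^2))`` with
    amplitude ``a`` in (0, 1], fitted by binomial maximum likelihood.  The JND
    is the fitted ``sigma``.
    """
    x, k, n = table.levels, table.n_positive, table.n_presented
    if x.size < 5:
        raise ValueError("need at least 5 stimulus levels")
    if k.sum() == 0:
        raise ValueError("all-zero responses: bump amplitude is degenerate")
    prop = table.proportions
    span = float(x.max() - x.min())
    mu0 = float(x[np.argmax(prop)])
    a0 = float(np.clip(prop.max(), 0.05, 0.999))
    above = x[prop >= a0 / 2]
    sigma0 = max(float(above.max() - above.min()) / 2.355, span / 20) if above.size else span / 4

    def nll(theta):
        a, mu, sig = theta
        p = a * np.exp(-((x - mu) ** 2) / (2 * sig**2))
        return _binom_nll(p, k, n)

    res = optimize.minimize(
        nll,
        x0=[a0, mu0, sigma0],
        method="L-BFGS-B",
        bounds=[(1e-3, 1.0), (x.min() - span, x.max() + span), (span / 200, 5 * span)],
    )
    if not res.success:
        raise RuntimeError(f"Gaussian-bump fit did not converge: {res.message}")
    a, mu, sigma = res.x
    p_hat = a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
    fit = GaussianFit(
        mu=float(mu), sigma=float(sigma), amplitude=float(a),
        goodness=_deviance(p_hat, k, n),
    )
    return fit, float(sigma)


def _pava_increasing(p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pooled-adjacent-violators: weighted isotonic (non-decreasing) fit."""
    p = p.astype(float).copy()
    w = w.astype(float).copy()
    # block representation: value, weight, count
    vals: list[float] = []
    wts: list[float] = []
    cnt: list[int] = []
    for pi, wi in zip(p, w):
        vals.append(pi)
        wts.append(wi)
        cnt.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            cnt[-2] += cnt[-1]
            vals[-2] = v
            vals.pop()
            wts.pop()
            cnt.pop()
    out = np.empty_like(p)
    i = 0
    for v, c in zip(vals, cnt):
        out[i : i + c] = v
        i += c
    return out


def spearman_karber_pse(table: PsychometricTable) -> float:
    """Spearman-Kaerber midpoint estimate of the point of subjective equality.

    Proportions are made monotone non-decreasing by pooled-adjacent-violators,
    then extended with p=0 / p=1 at levels extrapolated one step beyond the
    tested range, and the classic midpoint estimator
    ``PSE = sum_i (x_i + x_{i+1})/2 * (p_{i+1} - p_i)`` is applied.
    """
    x = table.levels
    if x.size < 3:
        raise ValueError("need at least 3 stimulus levels")
    p = _pava_increasing(table.proportions, table.n_presented.astype(float))
    step_lo = x[1] - x[0]
    step_hi = x[-1] - x[-2]
    x_ext = np.concatenate(([x[0] - step_lo], x, [x[-1] + step_hi]))
    p_ext = np.concatenate(([0.0], p, [1.0]))
    mids = (x_ext[:-1] + x_ext[1:]) / 2.0
    dp = np.diff(p_ext)
    return float(np.sum(mids * dp))


def fit_cumulative_gaussian(table: PsychometricTable) -> tuple[GaussianFit, float]:
    """Cumulative-Gaussian (probit) psychometric fit; returns (fit, jnd).

    ``p(positive | SOA) = Phi((SOA - mu) / sigma)`` by binomial maximum
    likelihood; the JND is the 75%-25% half spread ``sigma * Phi^-1(0.75)``.
    On non-convergence or perfect separation the fit falls back to a
    ridge-penalised probit (small quadratic penalty on the slope), flagged via
    ``fit.fallback``.
    """
    x, k, n = table.levels, table.n_positive, table.n_presented
    if x.size < 4:
        raise ValueError("need at least 4 stimulus levels")
    prop = table.proportions
    if prop.min() >= 0.5 or prop.max() <= 0.5:
        raise ValueError("responses must span both sides of p = 0.5")
    span = float(x.max() - x.min())
    mu0 = float(np.interp(0.5, prop + 1e-9 * np.arange(prop.size), x))
    sigma0 = span / 4

    def nll(theta, ridge=0.0):
        mu, log_sig = theta
        sig = np.exp(log_sig)
        p = stats.norm.cdf((x - mu) / sig)
        pen = ridge * (span / sig) ** 2  # penalises runaway slopes (sigma -> 0)
        return _binom_nll(p, k, n) + pen

    res = optimize.minimize(nll, x0=[mu0, np.log(sigma0)], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    fallback = False
    if (not res.success) or sigma < span / 1e4 or sigma > span * 1e3:
        res = optimize.minimize(lambda th: nll(th, ridge=1e-3), x0=[mu0, np.log(sigma0)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        fallback = True
    p_hat = stats.norm.cdf((x - mu) / sigma)
    fit = GaussianFit(mu=float(mu), sigma=sigma, goodness=_deviance(p_hat, k, n),
                      fallback=fallback)
    return fit, sigma * Z75


def sum_of_confusion(
    fit_uncrossed: GaussianFit,
    fit_crossed: GaussianFit,
    grid: np.ndarray | None = None,
) -> float:
    """Accumulated |crossed - uncrossed| divergence of the fitted TOJ curves.

    Evaluated on a fixed symmetric SOA grid (default -400..400 ms, 10 ms
    steps).  Zero iff the two curves coincide on the grid.
    """
    if grid is None:
        grid = np.arange(-400.0, 400.0 + 1e-9, 10.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    pu = stats.norm.cdf((grid - fit_uncrossed.mu) / fit_uncrossed.sigma)
    pc = stats.norm.cdf((grid - fit_crossed.mu) / fit_crossed.sigma)
    return float(np.sum(np.abs(pc - pu)))


def mental_rotation_slope(trials) -> float:
    """Mental-rotation efficiency: OLS slope of median correct-trial RT vs angle.

    *trials* is an iterable of ``(angle_degrees, rt_ms, correct)``.  RTs of
    correct trials are aggregated to a per-angle median before the regression;
    the slope is in ms per degree (smaller = more efficient rotation).
    """
    by_angle: dict[float, list[float]] = {}
    for angle, rt, correct in trials:
        if correct:
            by_angle.setdefault(float(angle), []).append(float(rt))
    if len(by_angle) < 2:
        raise ValueError("need correct trials at >= 2 distinct angles")
    angles = np.array(sorted(by_angle))
    med = np.array([np.median(by_angle[a]) for a in angles])
    slope = np.polyfit(angles, med, 1)[0]
    return float(slope)
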
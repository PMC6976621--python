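"""Measurement and inference layer.

Implements the task's bespoke analyses: per-subject aim points (A_i, A_c,
A_o), risk-sensitivity (mean endpoint minus optimal aim), the relative-aim
scatter and its two-half regression compared by bootstrap resampling with a
permutation-style count, linear-versus-quadratic model comparison by
information criteria, paired effect sizes, and exact noncentral-t power
analysis for the matched-pairs design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (DegenerateDataError, InsufficientDataError,
                     ParameterError, SchemaError)
from .gain import GainFunction, optimal_aim

__all__ = ["AimPoints", "SlopeTestResult", "compute_aim_points",
           "risk_sensitivity", "baseline_risk_sensitivity",
           "window_risk_sensitivity", "relative_aims", "split_slopes",
           "bootstrap_permutation_slopes", "fit_linear_quadratic",
           "paired_cohens_d", "required_sample_size", "paired_t_and_ci",
           "one_sample_t"]


@dataclass
class AimPoints:
    """Per-subject individual aim ``A_i`` and per-block competitive aims."""

    A_i: pd.Series                 # indexed by subject_id
    blocks: pd.DataFrame           # columns subject_id, block, A_c, A_o


@dataclass
class SlopeTestResult:
    slope_left: float
    slope_right: float
    boot_left: np.ndarray
    boot_right: np.ndarray
    ci_left: tuple
    ci_right: tuple
    p_perm: float
    n_boot: int
    n_redrawn: int


# ---------------------------------------------------------------- aim points

def compute_aim_points(trials: pd.DataFrame, baseline_window: str = "baseline",
                       competition_session: str = "competition") -> AimPoints:
    """A_i per subject and per-block A_c / A_o from a trial table.

    ``baseline_window`` selects how A_i is defined: ``"baseline"`` (mean of
    the subject's baseline-session endpoints, 50 trials) or ``"last50"``
    (the last 50 individual-task reaches before the competition started).
    """
    for col in ("subject_id", "session", "block", "role", "endpoint_cm"):
        if col not in trials.columns:
            raise SchemaError(f"trial table lacks required column {col!r}")
    comp = trials[trials.session == competition_session]
    if comp.empty:
        raise InsufficientDataError(
            f"no {competition_session!r} session in the trial table")
    ai = {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        if baseline_window == "baseline":
            base = sub[(sub.session == "baseline") & (sub.role == "subject")]
            if base.empty:
                raise InsufficientDataError(f"no baseline trials for {sid}")
            ai[sid] = base.endpoint_cm.mean()
        elif baseline_window == "last50":
            pre = sub[(sub.role == "subject")
                      & (sub.session != competition_session)]
            comp_idx = sub.index[sub.session == competition_session].min()
            pre = pre[pre.index < comp_idx]
            if len(pre) < 50:
                raise InsufficientDataError(
                    f"fewer than 50 pre-competition trials for {sid}")
            ai[sid] = pre.endpoint_cm.tail(50).mean()
        else:
            raise ParameterError(f"unknown baseline_window {baseline_window!r}")
    subj = comp[comp.role == "subject"].groupby(["subject_id", "block"])
    opp = comp[comp.role == "opponent"].groupby(["subject_id", "block"])
    blocks = pd.DataFrame({"A_c": subj.endpoint_cm.mean(),
                           "A_o": opp.endpoint_cm.mean()}).reset_index()
    return AimPoints(A_i=pd.Series(ai, name="A_i"), blocks=blocks)


def risk_sensitivity(mean_endpoint: float, sigma: float,
                     gf: GainFunction | None = None) -> float:
    """Mean endpoint minus the optimal aim: positive = risk-seeking."""
    return float(mean_endpoint) - optimal_aim(sigma, gf or GainFunction())


def _window_rs(endpoints: np.ndarray, gf: GainFunction) -> float:
    if endpoints.size < 10:
        raise InsufficientDataError("risk-sensitivity window needs >= 10 trials")
    sigma = float(np.std(endpoints, ddof=1))
    return risk_sensitivity(float(np.mean(endpoints)), sigma, gf)


def baseline_risk_sensitivity(trials: pd.DataFrame,
                              gf: GainFunction | None = None) -> pd.Series:
    """Per-subject risk-sensitivity over the baseline session (50 trials)."""
    gf = gf or GainFunction()
    base = trials[(trials.session == "baseline") & (trials.role == "subject")]
    if base.empty:
        raise InsufficientDataError("no baseline session in the trial table")
    return base.groupby("subject_id").endpoint_cm.apply(
        lambda e: _window_rs(e.to_numpy(), gf)).rename("risk_sensitivity")


def window_risk_sensitivity(trials: pd.DataFrame, session: str,
                            blocks=None,
                            gf: GainFunction | None = None) -> pd.Series:
    """Per-subject risk-sensitivity over a block window of one session.

    ``blocks=None`` selects the last 5 blocks present in the session (the
    final 50 trials for standard 12-block competition protocols).
    """
    gf = gf or GainFunction()
    sess = trials[(trials.session == session) & (trials.role == "subject")]
    if blocks is None:
        present = sorted(sess.block.unique())
        blocks = present[-5:]
    win = sess[sess.block.isin(list(blocks))]
    if win.empty:
        raise InsufficientDataError(f"no trials in session {session!r} blocks")
    return win.groupby("subject_id").endpoint_cm.apply(
        lambda e: _window_rs(e.to_numpy(), gf)).rename("risk_sensitivity")


def relative_aims(aps: AimPoints, blocks=range(2, 13)) -> pd.DataFrame:
    """Scatter of subject vs opponent relative aims, one row per
    subject x block: ``x = A_o - A_i``, ``y = A_c - A_i``.

    Block 1 is excluded by default (transient inhibition at competition onset).
    """
    df = aps.blocks[aps.blocks.block.isin(list(blocks))].copy()
    ai = aps.A_i
    df["x"] = df.A_o.to_numpy() - ai.loc[df.subject_id].to_numpy()
    df["y"] = df.A_c.to_numpy() - ai.loc[df.subject_id].to_numpy()
    return df[["subject_id", "block", "x", "y"]].reset_index(drop=True)


# ------------------------------------------------------------- slope testing

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    sx, sy = x.sum(), y.sum()
    den = n * (x * x).sum() - sx * sx
    if den <= 0:
        raise InsufficientDataError("degenerate x values on one side")
    return float((n * (x * y).sum() - sx * sy) / den)


def split_slopes(x, y, split_at: float = 0.0):
    """OLS slopes (with intercept) fitted separately to the two halves
    ``x < split_at`` and ``x >= split_at``; each needs >= 3 points."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    left = x < split_at
    if left.sum() < 3 or (~left).sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points on each side of {split_at} "
            f"(got {int(left.sum())} / {int((~left).sum())})")
    return _ols_slope(x[left], y[left]), _ols_slope(x[~left], y[~left])


def _vectorised_split_slopes(xb, yb, split_at):
    """Both half-slopes for each resample row; invalid rows -> NaN."""
    m = xb < split_at
    out = []
    for mask in (m, ~m):
        n = mask.sum(axis=1)
        sx = np.where(mask, xb, 0.0).sum(axis=1)
        sy = np.where(mask, yb, 0.0).sum(axis=1)
        sxx = np.where(mask, xb * xb, 0.0).sum(axis=1)
        sxy = np.where(mask, xb * yb, 0.0).sum(axis=1)
        den = n * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (n * sxy - sx * sy) / den
        slope[(n < 3) | (den <= 1e-12)] = np.nan
        out.append(slope)
    return out


def bootstrap_permutation_slopes(x, y, n_boot: int = 50_000, seed=None,
                                 split_at: float = 0.0,
                                 tie_rule: str = "geq") -> SlopeTestResult:
    """Bootstrap the two half-slopes and count sign flips.

    The pooled points are resampled with replacement ``n_boot`` times; both
    half-slopes are recomputed per resample, and the p-value is the fraction
    of resamples in which the left slope is >= the right slope (``tie_rule =
    "geq"``, conservative; ``"strict"`` uses >).  Resamples leaving fewer than
    3 points on a side are redrawn (their count is reported).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sl, sr = split_slopes(x, y, split_at)   # also validates the input
    rng = np.random.default_rng(seed)
    n = x.size
    boot_l = np.empty(n_boot)
    boot_r = np.empty(n_boot)
    filled, redrawn = 0, 0
    while filled < n_boot:
        m = min(20_000, n_boot - filled + 1000)
        idx = rng.integers(0, n, size=(m, n))
        bl, br = _vectorised_split_slopes(x[idx], y[idx], split_at)
        ok = ~(np.isnan(bl) | np.isnan(br))
        redrawn += int((~ok).sum())
        take = min(int(ok.sum()), n_boot - filled)
        boot_l[filled:filled + take] = bl[ok][:take]
        boot_r[filled:filled + take] = br[ok][:take]
        filled += take
    if tie_rule == "geq":
        p = float(np.mean(boot_l >= boot_r))
    elif tie_rule == "strict":
        p = float(np.mean(boot_l > boot_r))
    else:
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    ci = lambda b: tuple(np.percentile(b, [2.5, 97.5]))
    return SlopeTestResult(slope_left=sl, slope_right=sr,
                           boot_left=boot_l, boot_right=boot_r,
                           ci_left=ci(boot_l), ci_right=ci(boot_r),
                           p_perm=p, n_boot=n_boot, n_redrawn=redrawn)


# --------------------------------------------------------- model comparison

def fit_linear_quadratic(x, y) -> dict:
    """Fit ``y = b0 x + b1`` and ``y = b0 x + b1 x^2 + b2`` by OLS and report
    Gaussian-likelihood information criteria.

    ``k`` counts the regression coefficients plus the residual-variance
    parameter, and the full Gaussian log-likelihood (constants included) is
    used, so AIC magnitudes are comparable across software.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = {}
    for name, X in (("linear", np.column_stack([np.ones_like(x), x])),
                    ("quadratic", np.column_stack([np.ones_like(x), x, x * x]))):
        n, p = X.shape
        k = p + 1
        if n <= k + 2:
            raise InsufficientDataError("too few points for AICc")
        if np.linalg.matrix_rank(X) < p:
            raise DegenerateDataError("singular design matrix")
        res = sm.OLS(y, X).fit()
        aic = -2.0 * res.llf + 2.0 * k
        out[name] = {
            "AIC": aic,
            "BIC": -2.0 * res.llf + np.log(n) * k,
            "AICc": aic + 2.0 * k * (k + 1) / (n - k - 1),
            "adj_R2": float(res.rsquared_adj),
            "coefficients": res.params.tolist(),
        }
    return out


# ------------------------------------------------------ effect size & power

def paired_cohens_d(m1: float, s1: float, m2: float, s2: float,
                    r: float) -> float:
    """Effect size of two paired samples from summary statistics:
    ``d = (m1 - m2) / sqrt(s1^2 + s2^2 - 2 r s1 s2)``."""
    if s1 <= 0 or s2 <= 0:
        raise ParameterError("standard deviations must be positive")
    if abs(r) > 1:
        raise ParameterError("|r| must be <= 1")
    var = s1 * s1 + s2 * s2 - 2.0 * r * s1 * s2
    if var <= 0:
        raise DegenerateDataError("zero variance of the paired difference")
    return (m1 - m2) / np.sqrt(var)


def _paired_power(d: float, n: int, alpha: float, tails: int) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        power = float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    else:
        tcrit = sps.t.ppf(1.0 - alpha, df)
        power = float(sps.nct.sf(tcrit, df, nc))
    if not np.isfinite(power):
        # scipy's noncentral t loses accuracy at large noncentrality; use the
        # standard Gaussian approximation (Johnson & Kotz), accurate there
        power = float(sps.norm.sf((tcrit * (1 - 1 / (4 * df)) - nc)
                                  / np.sqrt(1 + tcrit * tcrit / (2 * df))))
    return min(max(power, 0.0), 1.0)


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                         tails: int = 2, design: str = "paired",
                         n_max: int = 1_000_000) -> int:
    """Smallest n with exact noncentral-t power >= ``power`` for a
    matched-pairs (one-sample-of-differences) t-test at effect size ``d``."""
    if d <= 0 or not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("require d > 0, 0 < alpha < 1, 0 < power < 1")
    if design != "paired":
        raise ParameterError("only the paired/matched design is implemented")
    for n in range(2, n_max + 1):
        if _paired_power(d, n, alpha, tails) >= power:
            return n
    raise ParameterError(f"power {power} unattainable for n <= {n_max}")


# ------------------------------------------------------------------ t-tests

def _t_summary(diff: np.ndarray, confidence: float = 0.95) -> dict:
    n = diff.size
    if n < 2:
        raise InsufficientDataError("need at least 2 observations")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            # identical pairs: defined limit of a vanishing effect
            return {"t": 0.0, "df": n - 1, "p": 1.0, "mean_diff": 0.0,
                    "ci95": (0.0, 0.0), "d": 0.0}
        raise DegenerateDataError("zero variance with non-zero mean difference")
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * se
    return {"t": float(t), "df": n - 1, "p": p, "mean_diff": mean,
            "ci95": (mean - half, mean + half), "d": float(mean / sd)}


def paired_t_and_ci(sample1, sample2) -> dict:
    """Two-tailed paired-samples t-test with 95% CI of the mean difference
    and ``d`` = mean difference / SD of differences."""
    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    if a.shape != b.shape:
        raise ParameterError("paired samples must have equal length")
    return _t_summary(a - b)


def one_sample_t(sample, mu0: float = 0.0) -> dict:
    """Two-tailed one-sample t-test of the mean against ``mu0``."""
    return _t_summary(np.asarray(sample, float) - mu0)
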
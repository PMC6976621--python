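"""End-to-end analysis pipeline: trial table in, study statistics out."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .gain import GainFunction
from . import stats as st

__all__ = ["analyze_cohort", "tidy_results"]


def analyze_cohort(trials: pd.DataFrame, gf: GainFunction | None = None,
                   n_boot: int = 50_000, seed=None,
                   baseline_window: str = "baseline", split_at: float = 0.0,
                   tie_rule: str = "geq",
                   competition_session: str = "competition") -> dict:
    """Run the full measurement/inference chain on one cohort.

    Returns a dict with per-subject risk-sensitivities, the baseline and
    late-competition one-sample t-tests, the baseline-vs-late paired test,
    the relative-aim scatter with its two-half slope comparison, and the
    linear/quadratic model comparison.  The slope test is skipped (with an
    explanatory note) when one side of the split has fewer than 3 points.
    """
    gf = gf or GainFunction()
    out = {}
    rs_base = st.baseline_risk_sensitivity(trials, gf)
    rs_late = st.window_risk_sensitivity(trials, competition_session,
                                         blocks=None, gf=gf)
    out["rs_baseline"] = rs_base
    out["rs_late"] = rs_late
    out["t_baseline_vs_0"] = st.one_sample_t(rs_base.to_numpy())
    out["t_late_vs_0"] = st.one_sample_t(rs_late.to_numpy())
    common = rs_base.index.intersection(rs_late.index)
    out["t_baseline_vs_late"] = st.paired_t_and_ci(
        rs_base.loc[common].to_numpy(), rs_late.loc[common].to_numpy())
    aps = st.compute_aim_points(trials, baseline_window=baseline_window,
                                competition_session=competition_session)
    pts = st.relative_aims(aps)
    out["aim_points"] = aps
    out["relative_aims"] = pts
    try:
        out["slope_test"] = st.bootstrap_permutation_slopes(
            pts.x.to_numpy(), pts.y.to_numpy(), n_boot=n_boot, seed=seed,
            split_at=split_at, tie_rule=tie_rule)
    except InsufficientDataError as err:
        out["slope_test"] = None
        out["slope_test_note"] = str(err)
    out["model_comparison"] = st.fit_linear_quadratic(pts.x.to_numpy(),
                                                      pts.y.to_numpy())
    return out


def tidy_results(results: dict) -> pd.DataFrame:
    """Flatten an :func:`analyze_cohort` result into one tidy row per test."""
    rows = []
    for name in ("t_baseline_vs_0", "t_late_vs_0", "t_baseline_vs_late"):
        r = results[name]
        rows.append(dict(test=name, statistic=r["t"], df=r["df"], p=r["p"],
                         effect_size=r["d"], estimate=r["mean_diff"],
                         ci_low=r["ci95"][0], ci_high=r["ci95"][1]))
    sl = results.get("slope_test")
    if sl is not None:
        rows.append(dict(test="slope_left", statistic=sl.slope_left,
                         df=np.nan, p=sl.p_perm, effect_size=np.nan,
                         estimate=float(sl.boot_left.mean()),
                         ci_low=sl.ci_left[0], ci_high=sl.ci_left[1]))
        rows.append(dict(test="slope_right", statistic=sl.slope_right,
                         df=np.nan, p=sl.p_perm, effect_size=np.nan,
                         estimate=float(sl.boot_right.mean()),
                         ci_low=sl.ci_right[0], ci_high=sl.ci_right[1]))
    for model, m in results["model_comparison"].items():
        rows.append(dict(test=f"fit_{model}", statistic=m["AICc"], df=np.nan,
                         p=np.nan, effect_size=m["adj_R2"], estimate=m["AIC"],
                         ci_low=np.nan, ci_high=np.nan))
    return pd.DataFrame(rows)
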
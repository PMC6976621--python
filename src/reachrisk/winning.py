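"""Monte-Carlo chance of winning a 10-trial block.

The block totals of the two players are sums of ten gain-transformed Gaussian
endpoints; the gain nonlinearity (zero beyond the boundary) makes the totals
non-Gaussian, so win probabilities are estimated by simulation: two samples of
``n_trials`` endpoints are drawn, scored, totalled, and the comparison is
repeated ``n_reps`` times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .gain import GainFunction, gain

__all__ = ["chance_of_winning", "winning_grid", "WinChanceGrid"]


@dataclass
class WinChanceGrid:
    """Binned map of win chance over the relative-aim plane."""

    table: pd.DataFrame      # columns x_bin, y_bin, chance, n_points
    bin_width: float


def chance_of_winning(aim_s: float, sigma_s: float, aim_o: float,
                      sigma_o: float, gf: GainFunction | None = None,
                      n_trials: int = 10, n_reps: int = 10_000,
                      tie_rule: str = "half", seed=None) -> float:
    """Probability that a player aiming at ``aim_s`` beats an opponent aiming
    at ``aim_o`` over one ``n_trials``-trial block.

    Ties in the block totals get half credit by default (``tie_rule="half"``),
    which preserves the symmetry chance(a, b) + chance(b, a) = 1; ``"strict"``
    counts only outright wins.
    """
    gf = gf or GainFunction()
    if sigma_s <= 0 or sigma_o <= 0:
        raise ParameterError("sigmas must be positive")
    if n_trials < 1 or n_reps < 1:
        raise ParameterError("n_trials and n_reps must be >= 1")
    if tie_rule not in ("half", "strict"):
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    rng = np.random.default_rng(seed)
    tot_s = gain(rng.normal(aim_s, sigma_s, (n_reps, n_trials)), gf).sum(axis=1)
    tot_o = gain(rng.normal(aim_o, sigma_o, (n_reps, n_trials)), gf).sum(axis=1)
    wins = float(np.mean(tot_s > tot_o))
    if tie_rule == "half":
        wins += 0.5 * float(np.mean(tot_s == tot_o))
    return wins


def winning_grid(block_contexts, aim_range=(-6.0, 4.0), step: float = 0.25,
                 n_reps: int = 10_000, gf: GainFunction | None = None,
                 n_trials: int = 10, seed=None) -> WinChanceGrid:
    """Win chance over a grid of candidate aim points, averaged in 0.25-cm
    bins of the relative-aim plane.

    ``block_contexts`` is an iterable of dicts with keys ``opp_aim``,
    ``opp_sigma``, ``subj_sigma`` and ``ref_aim`` (the subject's individual
    aim A_i, the origin of the relative coordinates).  For each context the
    candidate aims ``ref_aim + r`` for r over ``aim_range`` are evaluated and
    the resulting (x, y) = (opp_aim - ref_aim, r) points are binned on a
    half-open grid [edge, edge + step).
    """
    contexts = list(block_contexts)
    if not contexts:
        raise ConfigError("no block contexts supplied")
    rel = np.arange(aim_range[0], aim_range[1] + step / 2, step)
    if rel.size == 0:
        raise ConfigError("empty aim grid")
    gf = gf or GainFunction()
    rng = np.random.default_rng(seed)
    recs = []
    for ctx in contexts:
        x = ctx["opp_aim"] - ctx["ref_aim"]
        for r in rel:
            c = chance_of_winning(ctx["ref_aim"] + r, ctx["subj_sigma"],
                                  ctx["opp_aim"], ctx["opp_sigma"], gf,
                                  n_trials=n_trials, n_reps=n_reps,
                                  seed=rng.integers(2**31))
            recs.append((x, r, c))
    df = pd.DataFrame(recs, columns=["x", "y", "chance"])
    df["x_bin"] = np.floor(df.x / step) * step
    df["y_bin"] = np.floor(df.y / step) * step
    out = (df.groupby(["x_bin", "y_bin"])
             .agg(chance=("chance", "mean"), n_points=("chance", "size"))
             .reset_index())
    return WinChanceGrid(table=out, bin_width=step)
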
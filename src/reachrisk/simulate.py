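"""Trial/block/session state machine for the reaching tasks.

A session is a sequence of 10-trial blocks of one task kind:

* ``individual`` — the subject alone maximises the block total.
* ``competition`` — subject and virtual opponent alternate reaches; whoever
  has the higher 10-trial total wins the block.
* ``observation`` — identical stimulus stream to competition (opponent trials
  are shown and logged) but the subject's goal is its own total.
* ``threshold`` — no opponent; the subject must exceed a pre-computed total
  equal to the expected block total of the risk-averse opponent.
* ``presentation`` — opponent-only demonstration trials before a competition.

Opponent variance is re-estimated before each block from the subject's last
40 reaches (``rolling_40``) or frozen at the late-baseline value
(``frozen_baseline``), and the opponent aims at ``alpha * E*(sigma)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import (OpponentSchedule, SubjectModel, estimate_sigma,
                     sample_opponent_endpoint, subject_block_aim)
from .errors import ConfigError, ParameterError
from .gain import GainFunction, expected_gain, gain, optimal_aim

__all__ = ["Session", "Protocol", "BlockSummary", "run_individual_block",
           "run_competitive_block", "run_experiment", "threshold_for_block",
           "TRIAL_COLUMNS", "SUMMARY_COLUMNS"]

TRIALS_PER_BLOCK = 10

TRIAL_COLUMNS = ["subject_id", "group", "session", "block", "trial", "role",
                 "endpoint_cm", "score", "mistrial"]
SUMMARY_COLUMNS = ["subject_id", "group", "session", "block", "A", "A_o",
                   "E_star", "sigma_hat", "subject_total", "opponent_total",
                   "winner"]


@dataclass(frozen=True)
class Session:
    name: str          # e.g. "baseline", "competition", "washout"
    task: str          # individual | competition | observation | threshold | presentation
    n_blocks: int
    schedule: OpponentSchedule | None = None

    def __post_init__(self):
        if self.task not in ("individual", "competition", "observation",
                             "threshold", "presentation"):
            raise ConfigError(f"unknown task {self.task!r}")
        needs_opponent = self.task in ("competition", "observation",
                                       "threshold", "presentation")
        if needs_opponent and self.schedule is None:
            raise ConfigError(f"task {self.task!r} requires an opponent schedule")
        if needs_opponent and len(self.schedule.alpha_by_block) < self.n_blocks:
            raise ConfigError("opponent schedule shorter than the session")


@dataclass(frozen=True)
class Protocol:
    name: str
    sessions: tuple

    @classmethod
    def preset(cls, name: str) -> "Protocol":
        ind = lambda s, n: Session(s, "individual", n)
        try:
            return {
                "exp1a": cls("exp1a", (ind("baseline", 5),
                                       Session("competition", "competition", 12,
                                               OpponentSchedule.preset("exp1a")),
                                       ind("washout", 5))),
                "exp1b": cls("exp1b", (ind("baseline", 5),
                                       Session("competition", "competition", 12,
                                               OpponentSchedule.preset("exp1b")),
                                       ind("washout", 5))),
                "exp1c": cls("exp1c", (ind("baseline", 5),
                                       ind("individual", 17),
                                       Session("competition", "competition", 4,
                                               OpponentSchedule.preset("exp1c_tail")))),
                "exp2": cls("exp2", (ind("baseline", 5),
                                     Session("presentation", "presentation", 1,
                                             OpponentSchedule.preset("exp2")),
                                     Session("competition", "competition", 12,
                                             OpponentSchedule.preset("exp2")),
                                     ind("washout", 5))),
                "exp4": cls("exp4", (ind("baseline", 5),
                                     Session("competition", "competition", 12,
                                             OpponentSchedule.preset("exp4")),
                                     ind("washout", 5))),
                "exp5_observation": cls("exp5_observation",
                                        (ind("baseline", 5),
                                         Session("observation", "observation", 12,
                                                 OpponentSchedule.preset("exp1b")),
                                         ind("washout", 5))),
                "exp5_threshold": cls("exp5_threshold",
                                      (ind("baseline", 5),
                                       Session("threshold", "threshold", 12,
                                               OpponentSchedule.preset("exp1b")),
                                       ind("washout", 5))),
            }[name]
        except KeyError:
            raise ConfigError(f"unknown protocol preset {name!r}") from None


def threshold_for_block(alpha: float, E_star: float, sigma: float,
                        gf: GainFunction | None = None) -> int:
    """Expected 10-trial total of an ``alpha``-scaled opponent, rounded to
    integer points (scores shown to subjects were integers)."""
    gf = gf or GainFunction()
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    return int(round(TRIALS_PER_BLOCK * expected_gain(alpha * E_star, sigma, gf)))


def _winner(subject_total: float, opponent_total: float) -> str:
    if subject_total > opponent_total:
        return "subject"
    if subject_total < opponent_total:
        return "opponent"
    return "tie"


def _trial_row(sid, group, session, block, trial, role, endpoint, gf):
    score = gain(endpoint, gf)
    mistrial = not (gf.dead_zone < endpoint <= gf.boundary)
    return (sid, group, session, block, trial, role, endpoint, score, mistrial)


def run_individual_block(model: SubjectModel, gf: GainFunction, sigma: float,
                         E_star: float, rng: np.random.Generator,
                         sid="S01", group="", session="baseline", block=1):
    """One 10-trial individual block; returns the list of trial rows."""
    jitter = rng.normal(0.0, model.response_noise) if model.response_noise > 0 else 0.0
    aim = subject_block_aim(model, E_star, None, block_index=block, jitter=jitter)
    endpoints = rng.normal(aim, sigma, size=TRIALS_PER_BLOCK) if sigma > 0 \
        else np.full(TRIALS_PER_BLOCK, aim)
    return [_trial_row(sid, group, session, block, t + 1, "subject", e, gf)
            for t, e in enumerate(endpoints)]


def run_competitive_block(model: SubjectModel, alpha: float, gf: GainFunction,
                          sigma_subject: float, sigma_hat: float,
                          base_E_star: float, rng: np.random.Generator,
                          block: int = 1, respond: bool = True,
                          sid="S01", group="", session="competition"):
    """One competitive (or observation) block: 20 alternating trial rows plus
    the block summary dict.

    ``sigma_hat`` is the opponent's (subject-matched) endpoint SD;
    ``base_E_star`` the mean optimal aim of the subject's baseline blocks, so
    that ``base_E_star + bias`` is the subject's baseline reference aim.
    """
    E_star_opp = optimal_aim(sigma_hat, gf)
    opp_aim = alpha * E_star_opp
    x = opp_aim - (base_E_star + model.baseline_bias) if respond else None
    jitter = rng.normal(0.0, model.response_noise) if model.response_noise > 0 else 0.0
    rows = []
    subj_pts, opp_pts = [], []
    for t in range(1, TRIALS_PER_BLOCK + 1):
        aim = subject_block_aim(model, base_E_star, x, block_index=block,
                                trial_index=t, jitter=jitter)
        e_s = rng.normal(aim, sigma_subject) if sigma_subject > 0 else aim
        e_o = sample_opponent_endpoint(alpha, E_star_opp, sigma_hat, rng)
        rows.append(_trial_row(sid, group, session, block, t, "subject", e_s, gf))
        rows.append(_trial_row(sid, group, session, block, t, "opponent", e_o, gf))
        subj_pts.append(e_s)
        opp_pts.append(e_o)
    st = float(sum(r[7] for r in rows if r[5] == "subject"))
    ot = float(sum(r[7] for r in rows if r[5] == "opponent"))
    summary = dict(subject_id=sid, group=group, session=session, block=block,
                   A=float(np.mean(subj_pts)), A_o=float(np.mean(opp_pts)),
                   E_star=E_star_opp, sigma_hat=sigma_hat,
                   subject_total=st, opponent_total=ot, winner=_winner(st, ot))
    return rows, summary


def run_experiment(protocol: Protocol, subjects, gf: GainFunction | None = None):
    """Run every subject through the protocol's sessions.

    ``subjects`` is an iterable of ``(subject_id, SubjectModel, rng)``.
    Returns ``(trials, summaries)`` as DataFrames (empty cohorts give empty,
    correctly-typed frames).
    """
    gf = gf or GainFunction()
    all_rows, all_summaries = [], []
    for sid, model, rng in subjects:
        history = []            # the subject's own reaches, in order
        block_seq = 0           # global block counter across sessions
        baseline_E_stars = []   # optimal aims of the baseline blocks
        frozen_sigma = None
        for sess in protocol.sessions:
            for k in range(1, sess.n_blocks + 1):
                if sess.task in ("individual", "threshold"):
                    block_seq += 1
                sigma_now = model.sigma_at(max(block_seq, 1))
                if sess.task == "individual":
                    E_now = optimal_aim(sigma_now, gf)
                    if sess.name == "baseline":
                        baseline_E_stars.append(E_now)
                    rows = run_individual_block(model, gf, sigma_now, E_now, rng,
                                                sid=sid, group=protocol.name,
                                                session=sess.name, block=k)
                    all_rows += rows
                    st = float(sum(r[7] for r in rows))
                    all_summaries.append(dict(
                        subject_id=sid, group=protocol.name, session=sess.name,
                        block=k, A=float(np.mean([r[6] for r in rows])),
                        A_o=np.nan, E_star=E_now, sigma_hat=sigma_now,
                        subject_total=st, opponent_total=np.nan, winner=""))
                    history += [r[6] for r in rows]
                elif sess.task == "presentation":
                    sigma_hat = estimate_sigma(history)
                    alpha = sess.schedule.alpha_by_block[k - 1]
                    E_star_opp = optimal_aim(sigma_hat, gf)
                    for t in range(1, TRIALS_PER_BLOCK + 1):
                        e_o = sample_opponent_endpoint(alpha, E_star_opp,
                                                       sigma_hat, rng)
                        all_rows.append(_trial_row(sid, protocol.name, sess.name,
                                                   k, t, "opponent", e_o, gf))
                elif sess.task == "threshold":
                    # threshold computed before the block from the history so far
                    sigma_hat = estimate_sigma(history)
                    alpha = sess.schedule.alpha_by_block[k - 1]
                    thr = threshold_for_block(alpha, optimal_aim(sigma_hat, gf),
                                              sigma_hat, gf)
                    E_now = optimal_aim(sigma_now, gf)
                    rows = run_individual_block(model, gf, sigma_now, E_now, rng,
                                                sid=sid, group=protocol.name,
                                                session=sess.name, block=k)
                    all_rows += rows
                    st = float(sum(r[7] for r in rows))
                    all_summaries.append(dict(
                        subject_id=sid, group=protocol.name, session=sess.name,
                        block=k, A=float(np.mean([r[6] for r in rows])),
                        A_o=np.nan, E_star=E_now, sigma_hat=sigma_hat,
                        subject_total=st, opponent_total=float(thr),
                        winner=_winner(st, thr)))
                    history += [r[6] for r in rows]
                else:  # competition or observation
                    block_seq += 1
                    sigma_now = model.sigma_at(block_seq)
                    if sess.schedule.sigma_mode == "frozen_baseline":
                        if frozen_sigma is None:
                            frozen_sigma = estimate_sigma(history)
                        sigma_hat = frozen_sigma
                    else:
                        sigma_hat = estimate_sigma(history)
                    alpha = sess.schedule.alpha_by_block[k - 1]
                    base_E = float(np.mean(baseline_E_stars)) \
                        if baseline_E_stars else optimal_aim(sigma_now, gf)
                    rows, summary = run_competitive_block(
                        model, alpha, gf, sigma_now, sigma_hat, base_E, rng,
                        block=k, respond=(sess.task == "competition"),
                        sid=sid, group=protocol.name, session=sess.name)
                    all_rows += rows
                    all_summaries.append(summary)
                    history += [r[6] for r in rows if r[5] == "subject"]
    trials = pd.DataFrame(all_rows, columns=TRIAL_COLUMNS)
    summaries = pd.DataFrame(all_summaries, columns=SUMMARY_COLUMNS)
    return trials, summaries
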
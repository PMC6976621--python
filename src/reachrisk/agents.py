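"""Synthetic actors: the alpha-scaled virtual opponent and generative subjects.

The virtual opponent implements the experimental manipulation: before each
competitive block its endpoint variance ``sigma^2`` is set to the subject's own
reaching variance (over the past 40 trials, or frozen from the late baseline),
and its endpoints are drawn from ``N(alpha * E*(sigma), sigma^2)``.  The risk
coefficient ``alpha`` scales the opponent's mean from optimal (``alpha = 1``,
risk-neutral) toward the start position (``alpha < 1``, risk-averse).

The synthetic subject is a generative stand-in for the human participants.
It is *not* a theory of the participants; it is the minimal rule that reproduces
the statistical structure the analysis pipeline measures:

* a risk-seeking baseline bias ``b`` (aim = E* + b, b ~ +0.7 to +1.2 cm),
* a transient aim decrease of ~1 cm over the first ~5 competitive trials,
* a piecewise-linear (two-slope) response of the block aim to the opponent's
  relative aim, steeper for opponents above the subject's baseline than below,
* slow practice-driven shrinkage of the motor SD (0.985 per block, matching a
  0.73x reduction over ~21 blocks of practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, InsufficientHistoryError, ParameterError

__all__ = [
    "OpponentSchedule",
    "SubjectModel",
    "estimate_sigma",
    "sample_opponent_endpoint",
    "subject_block_aim",
    "generate_cohort",
]

# exp1b: alpha = 1 for blocks 1-4, then linear interpolation 1.000 -> 0.925 in
# steps of 0.015 across blocks 5-8, and 0.925 for blocks 9-12.
_ALPHA_RISK_AVERSE = (1.0, 1.0, 1.0, 1.0, 0.985, 0.970, 0.955, 0.940,
                      0.925, 0.925, 0.925, 0.925)


@dataclass(frozen=True)
class OpponentSchedule:
    """Per-block opponent risk coefficients and the variance-estimation mode."""

    alpha_by_block: tuple
    sigma_mode: str = "rolling_40"  # or "frozen_baseline"

    def __post_init__(self):
        if any(a <= 0 for a in self.alpha_by_block):
            raise ParameterError("all alpha must be positive")
        if self.sigma_mode not in ("rolling_40", "frozen_baseline"):
            raise ParameterError(f"unknown sigma_mode {self.sigma_mode!r}")

    @classmethod
    def preset(cls, name: str) -> "OpponentSchedule":
        presets = {
            "exp1a": cls((1.0,) * 12),
            "exp1b": cls(_ALPHA_RISK_AVERSE),
            "exp1c_tail": cls((1.0,) * 4),
            "exp2": cls((1.0,) * 12),
            "exp4": cls((0.925,) * 12, sigma_mode="frozen_baseline"),
        }
        try:
            return presets[name]
        except KeyError:
            raise ConfigError(f"unknown opponent schedule preset {name!r}") from None


@dataclass(frozen=True)
class SubjectModel:
    """Generative parameters of one synthetic subject.

    ``baseline_bias`` is the subject's risk-sensitivity b (cm above E*);
    ``sigma0`` the motor SD at the first block; ``sigma_block_ratio`` the
    per-block SD shrink factor (1.0 disables learning) with ``sigma_floor``
    as a lower bound; ``inhibition`` the initial competitive aim decrease that
    decays linearly to zero over ``inhibition_decay_trials``; ``slope_pos`` /
    ``slope_neg`` the aim-response slopes for opponents above / below the
    subject's baseline; ``response_noise`` the block-to-block aim jitter SD.
    """

    baseline_bias: float = 1.0
    sigma0: float = 2.2
    sigma_block_ratio: float = 0.985
    sigma_floor: float = 1.0
    inhibition: float = 1.0
    inhibition_decay_trials: int = 5
    slope_pos: float = 0.63
    slope_neg: float = 0.21
    response_noise: float = 0.3

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ParameterError("sigma0 must be positive")
        if self.inhibition < 0:
            raise ParameterError("inhibition must be non-negative")

    def sigma_at(self, block_seq: int) -> float:
        """Motor SD at 1-based global block index ``block_seq``."""
        return max(self.sigma_floor,
                   self.sigma0 * self.sigma_block_ratio ** (block_seq - 1))


def estimate_sigma(endpoints, window: int = 40) -> float:
    """Sample SD (ddof=1) of the last ``window`` endpoints."""
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.size < window:
        raise InsufficientHistoryError(
            f"need at least {window} endpoints, got {endpoints.size}")
    return float(np.std(endpoints[-window:], ddof=1))


def sample_opponent_endpoint(alpha: float, E_star: float, sigma: float,
                             rng: np.random.Generator, size=None):
    """Draw opponent endpoint(s) from ``N(alpha * E_star, sigma^2)``."""
    if sigma <= 0:
        raise ParameterError("opponent sigma must be positive "
                             "(zero-variance history is degenerate)")
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    return rng.normal(alpha * E_star, sigma, size=size)


def subject_block_aim(model: SubjectModel, E_star: float,
                      opp_relative_aim: float | None = None,
                      block_index: int = 1, trial_index: int = 1,
                      rng: np.random.Generator | None = None,
                      jitter: float = 0.0) -> float:
    """Aim point of a synthetic subject for one trial.

    Baseline/individual blocks (``opp_relative_aim is None``): ``E* + b``.
    Competitive blocks: the baseline aim shifted by the two-slope response to
    the opponent's relative aim, minus the decaying inhibition term in the
    first competitive block.  ``jitter`` is the block's aim perturbation; if
    ``rng`` is given it is drawn from ``N(0, response_noise^2)`` instead.
    """
    if block_index < 1:
        raise ParameterError("block_index is 1-based")
    if rng is not None:
        jitter = rng.normal(0.0, model.response_noise)
    aim = E_star + model.baseline_bias + jitter
    if opp_relative_aim is not None:
        x = opp_relative_aim
        slope = model.slope_pos if x >= 0 else model.slope_neg
        aim += slope * x
        if block_index == 1:
            decay = max(0.0, 1.0 - (trial_index - 1) / model.inhibition_decay_trials)
            aim -= model.inhibition * decay
    return float(aim)


def generate_cohort(protocol, n_subjects: int, model: SubjectModel | None = None,
                    seed: int = 0, bias_sd: float = 0.65,
                    sigma0_cv: float = 0.15, gf=None):
    """Simulate a full synthetic cohort and return ``(trials, block_summaries)``.

    ``protocol`` is a preset name (exp1a, exp1b, exp1c, exp2, exp4,
    exp5_observation, exp5_threshold) or a :class:`reachrisk.simulate.Protocol`.
    Subject parameters are drawn per subject from the population template
    ``model``: baseline bias ~ N(b, bias_sd^2) (0.65 cm is the reference
    between-subject SD of baseline risk-sensitivity) and sigma0
    log-normal with coefficient of variation ``sigma0_cv``.  One root seed
    spawns an independent child stream per subject, so enlarging the cohort
    never perturbs earlier subjects.
    """
    from .simulate import Protocol, run_experiment

    if isinstance(protocol, str):
        protocol = Protocol.preset(protocol)
    model = model or SubjectModel()
    root = np.random.SeedSequence(seed)
    children = root.spawn(max(n_subjects, 1))
    subjects = []
    for j in range(n_subjects):
        rng = np.random.default_rng(children[j])
        b = rng.normal(model.baseline_bias, bias_sd)
        s0 = model.sigma0 * float(np.exp(rng.normal(0.0, sigma0_cv))) \
            if sigma0_cv > 0 else model.sigma0
        subjects.append((f"S{j + 1:02d}",
                         replace(model, baseline_bias=b, sigma0=s0),
                         np.random.default_rng(children[j].spawn(1)[0])))
    return run_experiment(protocol, subjects, gf=gf)
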
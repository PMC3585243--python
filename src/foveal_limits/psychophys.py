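"""Adaptive threshold estimation: QUEST and a transformed up-down staircase.

Resolution thresholds (minimum angle of resolution, MAR) are estimated with
QUEST: a Bayesian adaptive procedure that maintains a posterior over the log
stimulus size at a fixed criterion level of proportion correct (82.5% for
the 4AFC tumbling-E task), places every trial at the posterior mode, and
reports the posterior mean after a fixed number of trials.  Contrast
thresholds use a 3-down/1-up transformed staircase in 0.1 log-unit steps,
which converges at the 79.4% correct point (0.5 ** (1/3)).

Stimulus convention for the tumbling-E task: the letter is a 5 x 5 grid
with stroke width equal to the MAR, so letter height = 5 x MAR.  The
adaptive procedures track MAR directly; the letter geometry matters only
when rendering stimuli onto a mosaic (see :mod:`foveal_limits.stimmodel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from foveal_limits.synthgen import Observer

ORIENTATIONS_4AFC = ("up", "down", "left", "right")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    stimulus: float  # size in arcmin, or contrast for the staircase
    orientation: str
    response: str
    correct: bool


@dataclass(frozen=True)
class QuestRun:
    """One QUEST run: final threshold plus the trial-by-trial record."""

    threshold: float  # stimulus at the criterion proportion correct
    criterion: float
    trials: tuple[TrialRecord, ...]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Threshold at a location: mean over runs, with per-run values kept."""

    per_run: tuple[float, ...]
    n_trials_per_run: int
    criterion: float
    runs: tuple[QuestRun, ...] = field(default=(), repr=False)

    @property
    def mar(self) -> float:
        return float(np.mean(self.per_run))


def _criterion_offset(criterion: float, guess: float, lapse: float, beta: float) -> float:
    """log10 offset from the Weibull scale to the criterion-level stimulus."""
    k = -math.log((1.0 - lapse - criterion) / (1.0 - lapse - guess))
    return math.log10(k) / beta


def _simulate_trial(
    observer: Observer, stimulus: float, trial_index: int, orientations: Sequence[str]
) -> TrialRecord:
    orientation = orientations[int(observer.rng.integers(len(orientations)))]
    correct = observer.respond(stimulus)
    if correct:
        response = orientation
    else:
        wrong = [o for o in orientations if o != orientation]
        response = wrong[int(observer.rng.integers(len(wrong)))]
    return TrialRecord(trial_index, stimulus, orientation, response, correct)


def quest_run(
    observer: Observer,
    n_trials: int = 40,
    criterion: float = 0.825,
    prior_mean: float = math.log10(2.0),
    prior_sd: float = 0.5,
    beta: float = 3.5,
    lapse: float = 0.01,
    grid_halfwidth: float = 2.5,
    grid_step: float = 0.005,
) -> QuestRun:
    """One QUEST run against a simulated observer.

    The posterior is over ``t``: the log10 stimulus at which the assumed
    Weibull psychometric function (slope ``beta``, observer's guess rate,
    lapse ``lapse``) crosses ``criterion`` proportion correct.  Each trial is
    placed at the posterior mode; the returned threshold is ``10**E[t]``.

    ``prior_mean``/``prior_sd`` are in log10 stimulus units.
    """
    guess = observer.spec.guess_rate
    if criterion <= guess:
        raise ValueError(f"criterion {criterion} must exceed guess rate {guess}")
    if criterion >= 1.0 - lapse:
        raise ValueError(f"criterion {criterion} must be below 1 - lapse")
    t_grid = np.arange(
        prior_mean - grid_halfwidth, prior_mean + grid_halfwidth + grid_step, grid_step
    )
    log_post = -0.5 * ((t_grid - prior_mean) / prior_sd) ** 2
    offset = _criterion_offset(criterion, guess, lapse, beta)
    k_p = 10.0 ** (beta * offset)  # so p(x=t) = criterion by construction

    trials: list[TrialRecord] = []
    for i in range(n_trials):
        t_hat = t_grid[int(np.argmax(log_post))]
        stimulus = 10.0**t_hat
        rec = _simulate_trial(observer, stimulus, i, ORIENTATIONS_4AFC)
        trials.append(rec)
        x = math.log10(stimulus)
        p = guess + (1.0 - guess - lapse) * (
            1.0 - np.exp(-k_p * 10.0 ** (beta * (x - t_grid)))
        )
        p = np.clip(p, 1e-10, 1.0 - 1e-10)
        log_post = log_post + (np.log(p) if rec.correct else np.log1p(-p))
        log_post -= log_post.max()

    post = np.exp(log_post)
    post /= post.sum()
    t_mean = float(np.sum(t_grid * post))
    return QuestRun(threshold=10.0**t_mean, criterion=criterion, trials=tuple(trials))


def measure_threshold(
    observer: Observer, n_runs: int = 2, n_trials: int = 40, **quest_kwargs
) -> ThresholdEstimate:
    """Threshold at a location: the mean of ``n_runs`` QUEST runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = tuple(quest_run(observer, n_trials=n_trials, **quest_kwargs) for _ in range(n_runs))
    return ThresholdEstimate(
        per_run=tuple(r.threshold for r in runs),
        n_trials_per_run=n_trials,
        criterion=runs[0].criterion,
        runs=runs,
    )


def staircase_run(
    observer: Observer,
    start_contrast: float,
    step_log: float = 0.1,
    n_down: int = 3,
    n_trials: int = 50,
    n_reversals_avg: int = 6,
    floor_log_drop: float = 3.0,
) -> float:
    """Transformed n-down/1-up contrast staircase (default 3-down/1-up).

    Contrast moves in ``step_log`` log10-unit steps: ``n_down`` consecutive
    correct responses lower it, any incorrect response raises it.  The
    threshold is the mean of the last ``n_reversals_avg`` reversal contrasts
    (in log units), targeting the 0.5**(1/n_down) correct point — 79.4% for
    the 3-down/1-up rule with a 2IFC observer.

    Raises if the staircase produces too few reversals within the trial
    budget or descends monotonically to the floor (``floor_log_drop`` log
    units below the start), as happens for an error-free observer.
    """
    if step_log <= 0:
        raise ValueError("step_log must be positive (degenerate staircase)")
    if n_down < 1 or n_trials < 1:
        raise ValueError("n_down and n_trials must be positive")
    log_c = math.log10(start_contrast)
    floor = log_c - floor_log_drop
    reversals: list[float] = []
    streak = 0
    last_direction = 0  # +1 up, -1 down
    for _ in range(n_trials):
        if log_c < floor:
            raise RuntimeError(
                "staircase descended to floor without reversing; observer "
                "appears error-free over the tested range"
            )
        correct = observer.respond(10.0**log_c)
        if correct:
            streak += 1
            if streak >= n_down:
                streak = 0
                if last_direction == +1:
                    reversals.append(log_c)
                last_direction = -1
                log_c -= step_log
        else:
            streak = 0
            if last_direction == -1:
                reversals.append(log_c)
            last_direction = +1
            log_c += step_log
    if len(reversals) < n_reversals_avg:
        raise RuntimeError(
            f"only {len(reversals)} reversals in {n_trials} trials; "
            f"need {n_reversals_avg}"
        )
    return 10.0 ** float(np.mean(reversals[-n_reversals_avg:]))


def staircase_convergence_point(observer: Observer, n_down: int = 3) -> float:
    """Analytic contrast the staircase targets: P(correct) = 0.5**(1/n_down)."""
    return observer.criterion_size(0.5 ** (1.0 / n_down))
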
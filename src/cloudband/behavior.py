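"""Weighted up-down staircase, simulated observers, and threshold estimation.

The staircase lowers the orientation difference by ``step_down`` degrees
after a correct response and raises it by ``step_up`` after an error.  The
zero-drift point of that random walk sits where accuracy p satisfies
``p * step_down = (1 - p) * step_up``, i.e.

    p* = step_up / (step_up + step_down)

— 8 / (8 + 3) = 72.7% for the 3-down/8-up rule — so the difficulty hovers
around the 72.7%-correct point of the observer's psychometric function.
Session thresholds are extracted as the mean difficulty at the last
reversals (terminal difficulty is emitted alongside), and a side/repetition
bias-correction rule steers target placement toward the non-preferred side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ExtrapolationError, InsufficientDataError

__all__ = [
    "StaircaseConfig",
    "Observer",
    "TrialLog",
    "ThresholdEstimate",
    "staircase_step",
    "equilibrium_accuracy",
    "simulate_session",
    "threshold_estimate",
    "psychometric_summary",
    "bias_correction",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Step sizes and difficulty bounds of the weighted up-down procedure."""

    step_down_deg: float = 3.0
    step_up_deg: float = 8.0
    start_deg: float = 60.0
    floor_deg: float = 0.0
    ceiling_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.step_down_deg <= 0 or self.step_up_deg <= 0:
            raise ValueError("step sizes must be > 0")
        if not (self.floor_deg < self.start_deg <= self.ceiling_deg):
            raise ValueError("need floor < start <= ceiling")
        if self.floor_deg < 0 or self.ceiling_deg > 90:
            raise ValueError("difficulty bounds must lie in [0, 90] degrees")


@dataclass(frozen=True)
class Observer:
    """Logistic psychometric observer for two-alternative discrimination.

    p(correct | difference d) = 0.5 + (0.5 - lapse) / (1 + exp(-slope*(d - threshold)))

    so performance rises from near chance (0.5) to 1 - lapse as the
    orientation difference grows; ``threshold_deg`` is the midpoint of the
    rising part.
    """

    threshold_deg: float = 45.0
    slope: float = 0.15
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def p_correct(self, difference_deg: float) -> float:
        import math

        z = -self.slope * (difference_deg - self.threshold_deg)
        return 0.5 + (0.5 - self.lapse) / (1.0 + math.exp(z))

    def difficulty_at(self, p: float) -> float:
        """Invert the psychometric: difference where p(correct) = p."""
        if not (0.5 < p < 1.0 - self.lapse):
            raise ValueError("p must lie strictly between 0.5 and 1 - lapse")
        q = (0.5 - self.lapse) / (p - 0.5) - 1.0
        return self.threshold_deg - np.log(q) / self.slope


@dataclass(frozen=True)
class TrialLog:
    """Per-trial record of one staircase session."""

    table: pd.DataFrame  # difficulty_deg, target_side, chosen_side, correct, reversal
    config: StaircaseConfig
    seed: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def reversal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.table["reversal"].to_numpy())


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_deg: float
    method: str
    n_reversals_used: int


def staircase_step(current_deg: float, correct: bool, config: StaircaseConfig) -> float:
    """Next difficulty: down ``step_down`` if correct, up ``step_up`` if not,
    clamped to [floor, ceiling]."""
    nxt = current_deg - config.step_down_deg if correct else current_deg + config.step_up_deg
    return float(min(max(nxt, config.floor_deg), config.ceiling_deg))


def equilibrium_accuracy(config: StaircaseConfig) -> float:
    """Stationary proportion correct: step_up / (step_up + step_down)."""
    return config.step_up_deg / (config.step_up_deg + config.step_down_deg)


def simulate_session(
    observer: Observer,
    config: StaircaseConfig | None = None,
    n_trials: int = 400,
    seed: int = 0,
    use_bias_correction: bool = False,
) -> TrialLog:
    """Seeded simulation of one staircase session.

    Choices are Bernoulli draws from the observer's psychometric at the
    running difficulty; the chosen side is the target's side when correct,
    the other side when wrong.  With ``use_bias_correction`` the target side
    follows :func:`bias_correction` (after ten fully random trials);
    otherwise sides are random.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    u_correct = rng.random(n_trials)
    u_side = rng.random(n_trials)

    difficulty = np.empty(n_trials)
    target = np.empty(n_trials, dtype="U5")
    chosen = np.empty(n_trials, dtype="U5")
    correct = np.empty(n_trials, dtype=bool)

    d = float(config.start_deg)
    for i in range(n_trials):
        difficulty[i] = d
        if use_bias_correction and i >= 10:
            p_right = bias_correction(target[:i], chosen[:i])
        else:
            p_right = 0.5
        target[i] = "right" if u_side[i] < p_right else "left"
        correct[i] = u_correct[i] < observer.p_correct(d)
        chosen[i] = target[i] if correct[i] else ("left" if target[i] == "right" else "right")
        d = staircase_step(d, bool(correct[i]), config)

    # a reversal is a trial where the response direction flips
    reversal = np.zeros(n_trials, dtype=bool)
    reversal[1:] = correct[1:] != correct[:-1]
    table = pd.DataFrame({
        "difficulty_deg": difficulty, "target_side": target, "chosen_side": chosen,
        "correct": correct, "reversal": reversal,
    })
    return TrialLog(table=table, config=config, seed=seed)


def threshold_estimate(
    log: TrialLog, n_reversals: int = 8, discard_first: int = 2
) -> ThresholdEstimate:
    """Session threshold: mean difficulty at the last ``n_reversals``
    reversal points (after discarding the first ``discard_first``)."""
    rev = log.reversal_indices
    if len(rev) < n_reversals + discard_first:
        raise InsufficientDataError(
            f"need at least {n_reversals + discard_first} reversals, got {len(rev)}"
        )
    used = rev[discard_first:][-n_reversals:]
    thr = float(log.table["difficulty_deg"].to_numpy()[used].mean())
    return ThresholdEstimate(threshold_deg=thr, method="last-reversals",
                             n_reversals_used=n_reversals)


def terminal_threshold(log: TrialLog) -> ThresholdEstimate:
    """Alternative estimator: the staircase's final difficulty."""
    thr = float(log.table["difficulty_deg"].iloc[-1])
    return ThresholdEstimate(threshold_deg=thr, method="terminal", n_reversals_used=0)


def psychometric_summary(
    trials: pd.DataFrame,
    bin_edges_deg=None,
    criterion: float = 8.0 / 11.0,
) -> tuple[pd.DataFrame, float]:
    """Binned percent correct and the interpolated criterion crossing.

    ``trials`` needs ``difficulty_deg`` and ``correct`` columns.  Default
    bins are 10-degree-wide (so one bin pools all trials between 40 and 50
    degrees, the pooling used for cross-session comparisons).  The crossing
    is found by linear interpolation of percent-correct against bin centers;
    a criterion outside the observed range raises.
    """
    diff = trials["difficulty_deg"].to_numpy(dtype=float)
    corr = trials["correct"].to_numpy(dtype=bool)
    if bin_edges_deg is None:
        bin_edges_deg = np.arange(0.0, 91.0, 10.0)
    edges = np.asarray(bin_edges_deg, dtype=float)
    idx = np.digitize(diff, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.sum() == 0:
            continue
        rows.append(((edges[b] + edges[b + 1]) / 2.0, int(m.sum()), float(corr[m].mean())))
    summary = pd.DataFrame(rows, columns=["bin_center_deg", "n_trials", "p_correct"])
    if len(summary) == 0:
        raise InsufficientDataError("no populated difficulty bins")
    if len(summary) == 1:
        # a single pooled bin (e.g. the 40-50 deg pool) has no crossing
        return summary, float("nan")
    x = summary["bin_center_deg"].to_numpy()
    y = summary["p_correct"].to_numpy()
    order = np.argsort(x)
    x, y = x[order], y[order]
    if criterion < y.min() or criterion > y.max():
        raise ExtrapolationError("criterion lies outside the observed accuracy range")
    crossing = None
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - criterion) * (y1 - criterion) <= 0 and y0 != y1:
            crossing = x[i] + (criterion - y0) / (y1 - y0) * (x[i + 1] - x[i])
            break
    if crossing is None:  # criterion exactly equal to a flat stretch
        crossing = float(x[np.argmin(np.abs(y - criterion))])
    return summary, float(crossing)


def bias_correction(
    target_sides,
    chosen_sides,
    window: int = 20,
    alpha: float = 0.05,
    push: float = 0.8,
) -> float:
    """Probability of placing the next target on the right.

    A side bias is a significant (binomial test at ``alpha``) imbalance of
    chosen sides over the trailing ``window`` trials: the target is then
    pushed toward the non-preferred side with probability ``push``.  A
    repetition (stay) bias raises the probability of switching the target
    side relative to the previous trial.  Without evidence of bias the
    placement stays at 0.5.  Callers should randomize the first ten trials
    before activating the correction.
    """
    chosen = np.asarray(chosen_sides)
    targets = np.asarray(target_sides)
    if len(chosen) < 10:
        return 0.5
    recent = chosen[-window:]
    n = len(recent)
    k_right = int(np.sum(recent == "right"))
    side_p = stats.binomtest(k_right, n, 0.5).pvalue
    if side_p < alpha:
        # push the target to the side the animal does NOT prefer
        prefers_right = k_right > n - k_right
        return 1.0 - push if prefers_right else push
    # repetition bias: staying on the previously chosen side too often
    if len(chosen) >= 2:
        stays = chosen[-window:][1:] == chosen[-window:][:-1]
        if len(stays) >= 5:
            rep_p = stats.binomtest(int(stays.sum()), len(stays), 0.5,
                                    alternative="greater").pvalue
            if rep_p < alpha:
                return 1.0 - push if targets[-1] == "right" else push
    return 0.5
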
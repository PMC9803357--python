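"""Synthetic stop-signal behavior from the race model.

Generates staircase-tracked stop-signal sessions from known ex-Gaussian
go/stop parameters, a trigger-failure probability, and deadline censoring,
so that every downstream stage (likelihoods, samplers, non-parametric SSRT,
EEG burst windows) is testable without any download.

Trial tables are pandas DataFrames with one row per trial:

====================  =====================================================
column                meaning
====================  =====================================================
``trial``             0-based trial index
``trial_type``        ``"go"`` or ``"stop"``
``side``              ``"left"`` / ``"right"`` (go-stimulus direction)
``ssd_ms``            the staircase's current SSD; recorded on every trial
                      (on go trials: the SSD a stop-signal would have used)
``rt_ms``             response time in ms, NaN if no response was emitted
``correct``           response matched the go stimulus (NaN rows: True)
``outcome``           ``go_response`` / ``go_omission`` / ``signal_respond``
                      / ``successful_stop``
====================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .exgauss import exg_rvs
from .race import PARAM_NAMES, ExGaussParams, ParameterSet

__all__ = [
    "TaskDesign",
    "PopulationSpec",
    "simulate_participant",
    "simulate_group",
    "simulate_races",
    "staircase_equilibrium_ssd",
]


@dataclass(frozen=True)
class TaskDesign:
    """Stop-signal session layout and staircase settings (ms)."""

    n_trials: int = 480
    stop_proportion: float = 1.0 / 3.0
    ssd_start: float = 200.0
    ssd_step: float = 50.0
    deadline: float = 1000.0
    staircase_scope: str = "per_side"  # or "pooled"
    go_lapse_prob: float = 0.0         # optional robustness knob
    choice_error_prob: float = 0.0     # wrong-key presses; rare in practice

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 < self.stop_proportion < 1.0:
            raise ValueError("stop_proportion must be in (0, 1)")
        if self.ssd_step <= 0 or self.deadline <= 0:
            raise ValueError("ssd_step and deadline must be positive")
        if self.staircase_scope not in ("per_side", "pooled"):
            raise ValueError("staircase_scope must be 'per_side' or 'pooled'")

    @property
    def n_stop(self) -> int:
        return int(round(self.n_trials * self.stop_proportion))

    @property
    def n_go(self) -> int:
        return self.n_trials - self.n_stop

    @property
    def ssd_ceiling(self) -> float:
        # Staircase is floored at 0 and capped 50 ms below the deadline.
        return self.deadline - 50.0


_DEFAULT_LOWER = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 1.0, -6.0])
_DEFAULT_UPPER = np.array([2000.0, 1000.0, 1000.0, 2000.0, 1000.0, 1000.0, 6.0])


@dataclass(frozen=True)
class PopulationSpec:
    """Truncated-normal population distributions of the seven race parameters.

    Order follows :data:`stoprace.race.PARAM_NAMES`; ``p_tf`` location and
    scale are on the probit (z) scale and participant draws are mapped back
    to (0, 1) with the normal CDF.
    """

    location: np.ndarray
    scale: np.ndarray
    lower: np.ndarray = field(default_factory=lambda: _DEFAULT_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: _DEFAULT_UPPER.copy())

    def __post_init__(self):
        for name in ("location", "scale", "lower", "upper"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if any(getattr(self, n).shape != (7,)
               for n in ("location", "scale", "lower", "upper")):
            raise ValueError("all PopulationSpec fields must have length 7")
        if np.any(self.scale < 0):
            raise ValueError("scales must be nonnegative")
        if np.any(self.lower >= self.upper):
            raise ValueError("infeasible truncation bounds (lower >= upper)")
        if np.any(self.location < self.lower) or np.any(self.location > self.upper):
            raise ValueError("locations must lie inside the truncation bounds")

    def draw(self, n_subjects: int, rng) -> np.ndarray:
        """Draw (n_subjects, 7) parameter vectors (p_tf on probability scale)."""
        out = np.empty((n_subjects, 7))
        for j in range(7):
            loc, sc = self.location[j], self.scale[j]
            if sc == 0:
                out[:, j] = loc
            else:
                a = (self.lower[j] - loc) / sc
                b = (self.upper[j] - loc) / sc
                out[:, j] = truncnorm.rvs(a, b, loc=loc, scale=sc,
                                          size=n_subjects, random_state=rng)
        out[:, 6] = ndtr(out[:, 6])  # probit scale -> probability
        return out


def _require_valid(params: ParameterSet):
    vec = params.to_vector()
    if not np.all(np.isfinite(vec)):
        raise ValueError("race parameters must be finite")


def simulate_participant(params: ParameterSet, design: TaskDesign = TaskDesign(),
                         seed=None, rng=None) -> pd.DataFrame:
    """Simulate one participant's staircase-tracked stop-signal session.

    Stop trials draw a trigger failure with probability ``p_tf``; when the
    stop runner is triggered its finishing time is ex-Gaussian, and a
    response is emitted iff the go finishing time beats both
    ``SSD + stop`` and the deadline.  The SSD staircase moves up 1 step
    after a successful stop and down 1 step after a failed stop, tracked
    separately per response side by default.
    """
    _require_valid(params)
    if rng is None:
        rng = np.random.default_rng(seed)

    n_stop = design.n_stop
    is_stop = np.zeros(design.n_trials, dtype=bool)
    is_stop[rng.choice(design.n_trials, size=n_stop, replace=False)] = True
    sides = np.where(rng.random(design.n_trials) < 0.5, "left", "right")

    g, s = params.go, params.stop
    go_ft = exg_rvs(g.mu, g.sigma, g.tau, design.n_trials, rng, nonnegative=True)
    stop_ft = exg_rvs(s.mu, s.sigma, s.tau, design.n_trials, rng, nonnegative=True)
    tf = rng.random(design.n_trials) < params.p_tf
    lapse = rng.random(design.n_trials) < design.go_lapse_prob
    wrong = rng.random(design.n_trials) < design.choice_error_prob

    ssd_tracker = {"left": design.ssd_start, "right": design.ssd_start,
                   "pooled": design.ssd_start}
    rows = []
    for i in range(design.n_trials):
        key = "pooled" if design.staircase_scope == "pooled" else sides[i]
        ssd = ssd_tracker[key]
        if is_stop[i]:
            stops = not tf[i]
            threshold = min(ssd + stop_ft[i], design.deadline) if stops \
                else design.deadline
            responded = (go_ft[i] < threshold) and not lapse[i]
            if responded:
                rt, outcome = go_ft[i], "signal_respond"
                ssd_new = max(ssd - design.ssd_step, 0.0)
            else:
                rt, outcome = np.nan, "successful_stop"
                ssd_new = min(ssd + design.ssd_step, design.ssd_ceiling)
            ssd_tracker[key] = ssd_new
        else:
            responded = (go_ft[i] < design.deadline) and not lapse[i]
            rt = go_ft[i] if responded else np.nan
            outcome = "go_response" if responded else "go_omission"
        rows.append(
            (i, "stop" if is_stop[i] else "go", sides[i], ssd, rt,
             bool(not wrong[i]) if responded else True, outcome)
        )

    return pd.DataFrame(
        rows,
        columns=["trial", "trial_type", "side", "ssd_ms", "rt_ms",
                 "correct", "outcome"],
    )


def simulate_group(pop: PopulationSpec, n_subjects: int,
                   design: TaskDesign = TaskDesign(), seed=None):
    """Draw participants from the population model and simulate each session.

    Returns a list of ``(ParameterSet, trial_table)`` pairs; the true
    parameter values are returned so recovery can be checked.  A single
    integer seed expands into independent per-participant streams.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    pop_rng = np.random.default_rng(ss.spawn(1)[0])
    thetas = pop.draw(n_subjects, pop_rng)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects + 1)[1:]):
        ps = ParameterSet.from_vector(thetas[i])
        out.append((ps, simulate_participant(ps, design,
                                             rng=np.random.default_rng(child))))
    return out


def simulate_races(params: ParameterSet, ssd: float, n: int, rng,
                   deadline: float = 1000.0):
    """Vectorised fixed-SSD races (no staircase): Monte-Carlo oracle helper.

    Returns ``(responded, rts)`` where ``rts`` holds go finishing times for
    responded trials (NaN otherwise).
    """
    g, s = params.go, params.stop
    go_ft = exg_rvs(g.mu, g.sigma, g.tau, n, rng, nonnegative=True)
    stop_ft = exg_rvs(s.mu, s.sigma, s.tau, n, rng, nonnegative=True)
    tf = rng.random(n) < params.p_tf
    threshold = np.where(tf, deadline, np.minimum(ssd + stop_ft, deadline))
    responded = go_ft < threshold
    rts = np.where(responded, go_ft, np.nan)
    return responded, rts


def staircase_equilibrium_ssd(params: ParameterSet, deadline: float = 1000.0,
                              ssd_grid=None):
    """Brute-force P(respond | SSD) on a grid and the ~50% tracking point.

    Independent of the trial-level simulator: evaluates the response
    probability curve by quadrature and returns ``(ssd_grid, p_respond,
    ssd_at_half)`` where ``ssd_at_half`` interpolates P(respond) = 0.5 (NaN
    if the curve never crosses 0.5 on the grid).
    """
    from .race import CensoringRule, prob_respond_stop

    if ssd_grid is None:
        ssd_grid = np.arange(0.0, deadline - 49.0, 25.0)
    cens = CensoringRule(deadline=deadline)
    p = np.array([prob_respond_stop(s, params, cens) for s in ssd_grid])
    cross = np.where((p[:-1] - 0.5) * (p[1:] - 0.5) <= 0)[0]
    if len(cross):
        i = cross[0]
        if p[i + 1] == p[i]:
            ssd_half = float(ssd_grid[i])
        else:
            frac = (0.5 - p[i]) / (p[i + 1] - p[i])
            ssd_half = float(ssd_grid[i] + frac * (ssd_grid[i + 1] - ssd_grid[i]))
    else:
        ssd_half = float("nan")
    return np.asarray(ssd_grid, dtype=float), p, ssd_half
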
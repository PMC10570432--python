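"""Prospect valence learning model with decay-reinforcement learning (PVL-DecayRI).

The model turns each trial's net gain x(t) into a subjective valence through
a prospect-theory power utility,

    u(t) = x(t)^alpha          if x(t) >= 0
    u(t) = -lam * |x(t)|^alpha if x(t) < 0,

decays every deck's expectancy each trial while reinforcing the chosen deck,

    E_j(t) = A * E_j(t-1) + I_j(t) * u(t),

and chooses the next deck through a softmax whose sharpness is set by the
response-consistency parameter c via theta = 3^c - 1:

    Pr[D(t+1) = j] = exp(theta * E_j) / sum_k exp(theta * E_k).

Parameters: feedback sensitivity alpha in [0, 1], loss aversion lam in
[0, 5], recency A in (0, 1), response consistency c in [0, 5].  Expectancies
start at zero, so the first choice is always uniform; c = 0 gives theta = 0
and a uniform chooser on every trial.

Outcomes are divided by the schedule's scale divisor before entering the
utility, mapping 10,000 yen to 1.0 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

import numpy as np

from .igt_task import (
    DECK_INDEX,
    DECKS,
    PayoffSchedule,
    TrialRecord,
    TrialSequence,
    draw_outcome,
)

PARAM_NAMES = ("alpha", "lam", "A", "c")
PARAM_BOUNDS = {"alpha": (0.0, 1.0), "lam": (0.0, 5.0), "A": (0.0, 1.0), "c": (0.0, 5.0)}


@dataclass(frozen=True)
class PVLParameters:
    """The (alpha, lam, A, c) quadruple with box constraints.

    Boundary values are accepted (they make useful analytic limits); the
    inference module keeps its estimates strictly inside the boxes.
    """

    alpha: float
    lam: float
    A: float
    c: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not (lo <= v <= hi) or not np.isfinite(v):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam, self.A, self.c], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PVLParameters":
        a, l, A, c = (float(v) for v in arr)
        return cls(alpha=a, lam=l, A=A, c=c)


@dataclass
class ModelState:
    """Deck expectancies E_j and the trial counter."""

    expectancies: np.ndarray = field(default_factory=lambda: np.zeros(4))
    trial: int = 0

    def __post_init__(self) -> None:
        self.expectancies = np.asarray(self.expectancies, dtype=float)
        if self.expectancies.shape != (4,):
            raise ValueError("expectancies must have exactly four entries")


def utility(x, alpha: float, lam: float):
    """Prospect utility of a (scaled) net gain; vectorised over x.

    u(0) = 0 for every alpha, including alpha = 0 where the power alone
    would give 0^0 = 1.
    """
    _check_bound("alpha", alpha)
    _check_bound("lam", lam)
    x = np.asarray(x, dtype=float)
    mag = np.abs(x) ** alpha
    u = np.where(x > 0, mag, np.where(x < 0, -lam * mag, 0.0))
    return float(u) if u.ndim == 0 else u


def _check_bound(name: str, value: float) -> None:
    lo, hi = PARAM_BOUNDS[name]
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


def update_expectancies(state: ModelState, chosen: str, u: float, A: float) -> ModelState:
    """Decay all expectancies by A; add utility u to the chosen deck's.

    E_j <- A * E_j + I_j * u, where I_j indicates the chosen deck.
    """
    _check_bound("A", A)
    e = A * state.expectancies
    e[DECK_INDEX[chosen]] += u
    return ModelState(expectancies=e, trial=state.trial + 1)


def choice_distribution(state, c: float) -> np.ndarray:
    """Softmax choice probabilities over theta * E with theta = 3^c - 1.

    Accepts a :class:`ModelState` or a length-4 array of expectancies.
    Max-subtraction keeps the exponentials bounded for any c and E.
    """
    _check_bound("c", c)
    e = state.expectancies if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    theta = 3.0**c - 1.0
    z = theta * e
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def _loglik(choices: list[int], u: np.ndarray, A: float, c: float) -> float:
    """Log-likelihood of a choice sequence given precomputed utilities.

    Hot path for fitting: plain-float inner loop, no array allocation per
    trial.  `choices` are deck indices 0..3; `u` holds the realised utility
    of each trial's outcome.
    """
    theta = 3.0**c - 1.0
    e0 = e1 = e2 = e3 = 0.0
    ll = 0.0
    for t, j in enumerate(choices):
        m = e0
        if e1 > m:
            m = e1
        if e2 > m:
            m = e2
        if e3 > m:
            m = e3
        s = exp(theta * (e0 - m)) + exp(theta * (e1 - m)) + exp(theta * (e2 - m)) + exp(
            theta * (e3 - m)
        )
        ej = (e0, e1, e2, e3)[j]
        ll += theta * (ej - m) - log(s)
        ut = u[t]
        e0 *= A
        e1 *= A
        e2 *= A
        e3 *= A
        if j == 0:
            e0 += ut
        elif j == 1:
            e1 += ut
        elif j == 2:
            e2 += ut
        else:
            e3 += ut
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


def trial_utilities(params: PVLParameters, seq: TrialSequence, schedule: PayoffSchedule) -> np.ndarray:
    """Utility of each realised outcome, after scaling by the schedule divisor."""
    x = seq.net_gains / schedule.scale_divisor
    return utility(x, params.alpha, params.lam)


def sequence_log_likelihood(
    params: PVLParameters, seq: TrialSequence, schedule: PayoffSchedule
) -> float:
    """Sum over trials of log P(choice_t | expectancies before t).

    The first trial is evaluated at the all-zero initial state (uniform
    probability 1/4); the state is then updated with that trial's realised
    net gain.  Any non-finite intermediate raises FloatingPointError.
    """
    choices = [DECK_INDEX[d] for d in seq.choices]
    u = trial_utilities(params, seq, schedule)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite utility in sequence")
    return _loglik(choices, u, params.A, params.c)


def simulate_agent(
    params: PVLParameters,
    schedule: PayoffSchedule,
    n_trials: int = 100,
    seed=None,
    subject_id: str = "agent",
    block_size: int = 20,
) -> TrialSequence:
    """Forward-simulate a PVL-DecayRI agent on the task.

    Each trial the agent samples a deck from its softmax choice distribution,
    receives the deterministic outcome at that deck's next draw position, and
    updates its expectancies.  Reproducible for a fixed seed; `seed` may also
    be a ``numpy.random.Generator``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = ModelState()
    positions = dict.fromkeys(DECKS, 0)
    records = []
    for t in range(1, n_trials + 1):
        p = choice_distribution(state, params.c)
        deck = DECKS[rng.choice(4, p=p)]
        positions[deck] += 1
        win, loss = draw_outcome(schedule, deck, positions[deck])
        records.append(TrialRecord(trial=t, deck=deck, win=win, loss=loss))
        u = utility((win + loss) / schedule.scale_divisor, params.alpha, params.lam)
        state = update_expectancies(state, deck, u, params.A)
    return TrialSequence(subject_id=subject_id, records=records, block_size=block_size)
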
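"""Iowa Gambling Task economy: payoff schedule, trial logs, net scores.

The task presents four card decks labelled A-D.  Decks A and B pay a large
reward on every card but carry penalties that make them net-losing over
time; decks C and D pay half as much per card but their penalties are small
enough that they are net-winning.  Performance is summarised by the *net
score*: advantageous picks (C+D) minus disadvantageous picks (A+B), per
block of 20 trials and in total.

This module implements the Japanese-yen variant of the task: +10,000 per
card on A/B with 125,000 yen lost per 10-card cycle, +5,000 per card on C/D
with 25,000 lost per cycle, and a starting loan of 200,000 yen.  Losses are
stored as non-positive numbers throughout, so the net gain of a trial is
simply ``win + loss``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

DECKS: tuple[str, ...] = ("A", "B", "C", "D")
DECK_INDEX: dict[str, int] = {d: i for i, d in enumerate(DECKS)}

DEFAULT_BLOCK_SIZE = 20
DEFAULT_N_TRIALS = 100


class TrialLogError(ValueError):
    """Raised when a trial log fails validation; carries the offending row."""


@dataclass(frozen=True)
class PayoffSchedule:
    """Deterministic per-deck gain/loss schedule over a repeating cycle.

    Parameters
    ----------
    gains
        Gain per card for each deck, in currency units.
    losses
        Per-deck ordered loss list over one cycle; entries are non-positive
        currency amounts (0 = no penalty on that card).  Positions beyond
        one cycle wrap around, so decks never run out of cards.
    cycle_length
        Number of cards per penalty cycle (10 in the standard task).
    endowment
        Starting loan handed to the participant.
    scale_divisor
        Divisor applied to outcomes before they reach the cognitive model;
        the power-law utility is unit-sensitive, so raw yen amounts are
        mapped to O(1) magnitudes (10,000 yen -> 1.0 by default).
    """

    gains: dict[str, float]
    losses: dict[str, tuple[float, ...]]
    cycle_length: int = 10
    endowment: float = 200_000.0
    scale_divisor: float = 10_000.0

    def __post_init__(self) -> None:
        if set(self.gains) != set(DECKS) or set(self.losses) != set(DECKS):
            raise ValueError(f"decks must be exactly {DECKS}")
        object.__setattr__(
            self, "losses", {d: tuple(float(v) for v in self.losses[d]) for d in DECKS}
        )
        for d in DECKS:
            if len(self.losses[d]) != self.cycle_length:
                raise ValueError(
                    f"deck {d}: loss list has {len(self.losses[d])} entries, "
                    f"expected cycle_length={self.cycle_length}"
                )
            if any(v > 0 for v in self.losses[d]):
                raise ValueError(f"deck {d}: losses must be non-positive")
        if self.scale_divisor <= 0:
            raise ValueError("scale_divisor must be positive")

    def cycle_loss_total(self, deck: str) -> float:
        """Total penalty magnitude over one cycle of `deck` (positive number)."""
        return -sum(self.losses[deck])

    def loss_count(self, deck: str) -> int:
        """Number of penalty-carrying cards per cycle of `deck`."""
        return sum(1 for v in self.losses[deck] if v != 0)

    def cycle_net(self, deck: str) -> float:
        """Net outcome of drawing one full cycle from `deck`."""
        return self.cycle_length * self.gains[deck] - self.cycle_loss_total(deck)

    def shuffled_losses(self, seed: int) -> "PayoffSchedule":
        """Return a copy with each deck's loss positions permuted within the cycle.

        Totals and loss counts per cycle are unchanged; only the card indices
        at which penalties fall move.
        """
        rng = np.random.default_rng(seed)
        new_losses = {
            d: tuple(rng.permutation(np.asarray(self.losses[d]).astype(float)))
            for d in DECKS
        }
        return replace(self, losses=new_losses)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gains": {d: float(self.gains[d]) for d in DECKS},
            "losses": {d: list(self.losses[d]) for d in DECKS},
            "cycle_length": self.cycle_length,
            "endowment": float(self.endowment),
            "scale_divisor": float(self.scale_divisor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PayoffSchedule":
        return cls(
            gains=dict(d["gains"]),
            losses={k: tuple(v) for k, v in d["losses"].items()},
            cycle_length=int(d.get("cycle_length", 10)),
            endowment=float(d.get("endowment", 200_000.0)),
            scale_divisor=float(d.get("scale_divisor", 10_000.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PayoffSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_default_schedule() -> PayoffSchedule:
    """The Japanese-version schedule: the original Bechara deck layout x100.

    Gains are +10,000 yen/card on A and B, +5,000 on C and D.  Penalties over
    each 10-card cycle total 125,000 yen on A and B (spread over 5 cards on A,
    one card on B) and 25,000 yen on C and D (5 cards on C, one on D).  Loss
    positions within the cycle follow the original deck layout.
    """
    zero = [0.0] * 10

    def lay(positions_amounts: dict[int, float]) -> tuple[float, ...]:
        out = list(zero)
        for pos, amount in positions_amounts.items():
            out[pos - 1] = -amount
        return tuple(out)

    return PayoffSchedule(
        gains={"A": 10_000.0, "B": 10_000.0, "C": 5_000.0, "D": 5_000.0},
        losses={
            "A": lay({3: 15_000, 5: 30_000, 7: 20_000, 9: 25_000, 10: 35_000}),
            "B": lay({9: 125_000}),
            "C": lay({3: 5_000, 5: 5_000, 7: 5_000, 9: 2_500, 10: 7_500}),
            "D": lay({10: 25_000}),
        },
    )


def draw_outcome(schedule: PayoffSchedule, deck: str, position: int) -> tuple[float, float]:
    """Gain and loss for the `position`-th draw (1-based) from `deck`.

    Positions beyond one cycle wrap cyclically; the draw is deterministic.
    Returns ``(win, loss)`` with ``loss <= 0``.
    """
    if deck not in DECK_INDEX:
        raise KeyError(f"unknown deck label {deck!r}; decks are {DECKS}")
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    idx = (position - 1) % schedule.cycle_length
    return schedule.gains[deck], schedule.losses[deck][idx]


@dataclass(frozen=True)
class TrialRecord:
    """One card selection: trial index (1-based), deck, win (>=0), loss (<=0)."""

    trial: int
    deck: str
    win: float
    loss: float

    def __post_init__(self) -> None:
        if self.deck not in DECK_INDEX:
            raise ValueError(f"unknown deck label {self.deck!r}")
        if self.win < 0:
            raise ValueError("win must be >= 0")
        if self.loss > 0:
            raise ValueError("loss must be stored as a non-positive value")

    @property
    def net(self) -> float:
        """Net gain x(t) = win - |loss|."""
        return self.win + self.loss


@dataclass
class TrialSequence:
    """One subject's ordered trial records."""

    subject_id: str
    records: list[TrialRecord]
    block_size: int = DEFAULT_BLOCK_SIZE

    def __len__(self) -> int:
        return len(self.records)

    @property
    def choices(self) -> list[str]:
        return [r.deck for r in self.records]

    @property
    def net_gains(self) -> np.ndarray:
        return np.array([r.net for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial": [r.trial for r in self.records],
                "deck": [r.deck for r in self.records],
                "win": [r.win for r in self.records],
                "loss": [r.loss for r in self.records],
            }
        )


@dataclass(frozen=True)
class NetScoreTable:
    """Per-block and total net scores for one subject."""

    block_scores: tuple[int, ...]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.block_scores):
            raise ValueError("total must equal the sum of block scores")


def compute_net_scores(seq: TrialSequence) -> NetScoreTable:
    """Net score per block: (C+D picks) - (A+B picks), and their total.

    The sequence length must be divisible by the block size (20 trials per
    block by default, giving 5 blocks over the standard 100-trial task).
    """
    n, bs = len(seq), seq.block_size
    if n % bs != 0:
        raise ValueError(f"sequence length {n} not divisible by block size {bs}")
    scores = []
    for start in range(0, n, bs):
        block = seq.records[start : start + bs]
        adv = sum(1 for r in block if r.deck in ("C", "D"))
        scores.append(2 * adv - bs)  # adv - (bs - adv)
    return NetScoreTable(block_scores=tuple(scores), total=sum(scores))


def bankroll_trajectory(seq: TrialSequence, schedule: PayoffSchedule) -> list[float]:
    """Running money total, starting at the endowment, adding win + loss each trial."""
    out = [float(schedule.endowment)]
    for r in seq.records:
        out.append(out[-1] + r.win + r.loss)
    return out


# -- trial-log I/O --------------------------------------------------------

TRIAL_LOG_COLUMNS = ("subject_id", "trial", "deck", "win", "loss")


def write_trial_logs(sequences: list[TrialSequence], path) -> None:
    """Write trial logs for one or more subjects as a single CSV."""
    frames = [s.to_frame() for s in sequences]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trial_logs(path, block_size: int = DEFAULT_BLOCK_SIZE) -> list[TrialSequence]:
    """Read a trial-log CSV back into per-subject sequences.

    The file must have a header with columns ``subject_id, trial, deck, win,
    loss``; deck labels must be in A-D, wins non-negative and losses
    non-positive.  Malformed rows raise :class:`TrialLogError` naming the row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "deck": str})
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise TrialLogError(f"trial log {path}: missing columns {sorted(missing)}")
    sequences: list[TrialSequence] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        records = []
        for row in sub.itertuples():
            rownum = row.Index + 2  # 1-based with header line
            if row.deck not in DECK_INDEX:
                raise TrialLogError(f"row {rownum}: unknown deck label {row.deck!r}")
            try:
                win, loss, trial = float(row.win), float(row.loss), int(row.trial)
            except (TypeError, ValueError) as exc:
                raise TrialLogError(f"row {rownum}: non-numeric field ({exc})") from exc
            if not np.isfinite(win) or not np.isfinite(loss):
                raise TrialLogError(f"row {rownum}: non-finite outcome")
            if win < 0 or loss > 0:
                raise TrialLogError(
                    f"row {rownum}: expected win >= 0 and loss <= 0 "
                    f"(got win={win}, loss={loss})"
                )
            records.append(TrialRecord(trial=trial, deck=row.deck, win=win, loss=loss))
        sequences.append(TrialSequence(subject_id=str(sid), records=records, block_size=block_size))
    return sequences
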
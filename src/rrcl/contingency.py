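"""Task structure of the three-location serial reaction time task.

A dot appears at one of three screen positions (left, middle, right) and the
participant presses the matching key.  Successive positions follow a biased
first-order Markov process: a position is never repeated, and of the two
remaining positions one is the *high-probability* successor (chosen with
probability ``p_hi``, .8 in the reference design) and the other the
*low-probability* successor (``1 - p_hi``).  Two mirror-image contingency
sets exist so that the assignment of high/low successors can be
counterbalanced across participants.

This module defines the contingency scheme, the trial-sequence generator and
the classification of a response transition as a high-frequency (``hf``) or
low-frequency (``lf``) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
import numpy as np
import pandas as pd

__all__ = [
    "Position",
    "ContingencyScheme",
    "build_scheme",
    "next_position",
    "classify_pair",
    "generate_session",
    "PLAN_COLUMNS",
]


class Position(IntEnum):
    """Screen location of the dot (identical to the response-key mapping).

    Totally ordered ``LEFT < MIDDLE < RIGHT`` so that serialization is
    deterministic.
    """

    LEFT = 0
    MIDDLE = 1
    RIGHT = 2

    @property
    def label(self) -> str:
        return POSITION_LABELS[int(self)]

    @classmethod
    def from_label(cls, label: str) -> "Position":
        try:
            return cls(POSITION_LABELS.index(label))
        except ValueError:
            raise ValueError(
                f"unknown position label {label!r}; expected one of {POSITION_LABELS}"
            ) from None


POSITION_LABELS: tuple[str, str, str] = ("left", "middle", "right")

#: High-probability successor of (left, middle, right) under contingency set 1:
#: left->middle, middle->right, right->left.  Set 2 is the mirror image.
_SET1_HI: tuple[int, int, int] = (1, 2, 0)

PLAN_COLUMNS = ("participant", "block", "trial", "practice", "stimulus")


@dataclass(frozen=True)
class ContingencyScheme:
    """Assignment of high-/low-probability successors to each position.

    Parameters
    ----------
    set_id:
        1 or 2; set 2 swaps the high and low successors of set 1.
    hi_successor, lo_successor:
        Length-3 tuples indexed by ``Position`` giving the successor position.
    p_hi:
        Probability of the high-probability successor, in (0.5, 1).
    """

    set_id: int
    hi_successor: tuple[Position, Position, Position]
    lo_successor: tuple[Position, Position, Position]
    p_hi: float

    def __post_init__(self) -> None:
        for p in Position:
            hi, lo = self.hi_successor[p], self.lo_successor[p]
            if hi == p or lo == p:
                raise ValueError(f"successor of {p.label} may not be {p.label} itself")
            if hi == lo:
                raise ValueError(f"high and low successors of {p.label} coincide")
        if not (0.5 < self.p_hi < 1.0):
            raise ValueError(f"p_hi must lie in (0.5, 1), got {self.p_hi}")

    @property
    def p_lo(self) -> float:
        return 1.0 - self.p_hi

    def hi(self, pos: Position) -> Position:
        return self.hi_successor[pos]

    def lo(self, pos: Position) -> Position:
        return self.lo_successor[pos]


def build_scheme(set_id: int, p_hi: float = 0.8) -> ContingencyScheme:
    """Return contingency set 1 or 2 with the given transition bias.

    Set 1 makes left->middle, middle->right and right->left the likely
    transitions; set 2 swaps high and low successors, so the two sets are
    each other's duals.
    """
    if set_id not in (1, 2):
        raise ValueError(f"set_id must be 1 or 2, got {set_id!r}")
    if not (0.5 < p_hi < 1.0):
        raise ValueError(f"p_hi must lie in (0.5, 1), got {p_hi!r}")
    hi = tuple(Position(s) for s in _SET1_HI)
    lo = tuple(Position(3 - int(p) - int(s)) for p, s in zip(Position, hi))
    if set_id == 2:
        hi, lo = lo, hi
    return ContingencyScheme(set_id=set_id, hi_successor=hi, lo_successor=lo, p_hi=p_hi)


def _step(prev: int, u: float, hi: tuple, lo: tuple, p_hi: float) -> int:
    """One draw of the transition process given a uniform variate ``u``."""
    return int(hi[prev]) if u < p_hi else int(lo[prev])


def next_position(
    current: Position, scheme: ContingencyScheme, rng: np.random.Generator
) -> Position:
    """Draw the next dot position from the biased transition process.

    Returns the high-probability successor of ``current`` with probability
    ``scheme.p_hi`` and the low-probability successor otherwise; never
    ``current`` itself.
    """
    return Position(
        _step(int(current), rng.random(), scheme.hi_successor, scheme.lo_successor, scheme.p_hi)
    )


def classify_pair(prev: Position, curr: Position, scheme: ContingencyScheme) -> str:
    """Classify the transition ``prev -> curr`` as ``"hf"`` or ``"lf"``.

    Raises if ``prev == curr`` (repetitions cannot occur by design).
    """
    if prev == curr:
        raise ValueError(
            f"repetition {Position(prev).label}->{Position(curr).label} cannot occur: "
            "the task never repeats a position"
        )
    return "hf" if scheme.hi_successor[prev] == curr else "lf"


def generate_session(
    participant_id,
    scheme: ContingencyScheme,
    n_blocks: int = 3,
    n_practice: int = 10,
    n_test: int = 300,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one participant's trial plan.

    Each block starts from a uniformly drawn position and then follows the
    biased transition process in one unbroken chain through its practice and
    test trials; the chain restarts at every block boundary (blocks are
    separated by self-paced breaks).  Trials are numbered 1-based within
    block, practice trials first.

    Returns a DataFrame with columns
    ``participant, block, trial, practice, stimulus``.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    if n_practice < 0:
        raise ValueError(f"n_practice must be >= 0, got {n_practice}")
    if n_test < 1:
        raise ValueError(f"n_test must be >= 1, got {n_test}")
    if rng is None:
        rng = np.random.default_rng()

    n_per_block = n_practice + n_test
    hi, lo, p_hi = scheme.hi_successor, scheme.lo_successor, scheme.p_hi
    frames = []
    for b in range(1, n_blocks + 1):
        stim = np.empty(n_per_block, dtype=np.int8)
        stim[0] = rng.integers(0, 3)
        u = rng.random(n_per_block - 1)
        for t in range(1, n_per_block):
            stim[t] = _step(stim[t - 1], u[t - 1], hi, lo, p_hi)
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant_id,
                    "block": b,
                    "trial": np.arange(1, n_per_block + 1),
                    "practice": (np.arange(n_per_block) < n_practice).astype(int),
                    "stimulus": [POSITION_LABELS[s] for s in stim],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def stationary_distribution(scheme: ContingencyScheme) -> np.ndarray:
    """Stationary distribution of the 3-state transition chain.

    Uniform (1/3, 1/3, 1/3) for both standard sets by symmetry; computed
    from the transition matrix so that non-standard schemes are handled too.
    """
    P = np.zeros((3, 3))
    for p in Position:
        P[p, scheme.hi_successor[p]] = scheme.p_hi
        P[p, scheme.lo_successor[p]] = scheme.p_lo
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()
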
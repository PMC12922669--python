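"""Per-trial condition coding for the contingency-learning analysis.

Each analysed trial ``n`` is the second element of the response pair
``(n-1, n)`` and gets four condition labels:

``cl``
    Contingency of the current pair: ``hf`` if the current stimulus is the
    high-probability successor of the previous stimulus, else ``lf``.
    Undefined on each block's first trial.
``pcl``
    Contingency of the immediately preceding pair, i.e. ``cl`` of trial
    ``n-1``; undefined on a block's first two trials.
``er``
    Recency-based episodic retrieval: the most recent earlier pair in the
    block that *started with the same response* as the current pair is
    retrieved; ``match`` if its second response equals the current response,
    ``mismatch`` otherwise.  Undefined when the current pair is the first in
    the block to start with this response.  The search runs over executed
    responses (which differ from stimuli on error trials) and includes the
    block's practice trials.
``ca``
    Contingency awareness: whether the participant classified the frequency
    of the current ordered stimulus pair correctly at the end of the session.

``rev`` additionally marks reversal pairs (the stimulus returns to where it
was two trials back), which is exactly the hf–lf / lf–hf cell of cl x pcl.

Contrasts use weighted effect coding: a two-level predictor with ``n_hi``
high and ``n_lo`` low trials is coded ``+n_lo/N`` vs ``-n_hi/N``, giving a
mean of exactly zero over the analysis set and a weight difference of
exactly 1, so regression coefficients are condition differences in ms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contingency import ContingencyScheme, POSITION_LABELS

__all__ = [
    "code_trials",
    "code_cl",
    "code_pcl",
    "code_er",
    "code_ca",
    "build_contrasts",
    "HIGH_LEVEL",
    "LOW_LEVEL",
    "CODED_COLUMNS",
]

#: Label treated as the "high" (positive-weight) level of each predictor.
HIGH_LEVEL = {"cl": "hf", "pcl": "hf", "er": "match", "ca": "correct", "rev": "reversal"}
LOW_LEVEL = {"cl": "lf", "pcl": "lf", "er": "mismatch", "ca": "incorrect", "rev": "nonreversal"}

CODED_COLUMNS = ("cl", "pcl", "er", "rev", "ca", "er_source_trial")

_POS_INDEX = {lab: i for i, lab in enumerate(POSITION_LABELS)}


def _require_ordered(trials: pd.DataFrame) -> None:
    """Reject input whose trials are not contiguously ordered within block."""
    for (pid, block), g in trials.groupby(["participant", "block"], sort=False):
        t = g["trial"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise ValueError(
                f"trials of participant {pid!r} block {block} are not ordered "
                "contiguously (expected consecutive 1-based trial numbers)"
            )


def _pos_codes(col: pd.Series) -> np.ndarray:
    return col.map(_POS_INDEX).to_numpy(dtype=np.int8)


def _block_cl(stim: np.ndarray, hi: tuple) -> list:
    out: list = [None] * len(stim)
    for t in range(1, len(stim)):
        out[t] = "hf" if int(hi[stim[t - 1]]) == stim[t] else "lf"
    return out


def _block_er(resp: np.ndarray, trial_no: np.ndarray) -> tuple[list, np.ndarray]:
    """Recency-based retrieval coding for one block of responses.

    For trial index ``i`` (0-based) with predecessor response ``r``, finds the
    largest ``m <= i-2`` with ``resp[m] == r``; the retrieved pair is
    ``(m, m+1)``.
    """
    n = len(resp)
    er: list = [None] * n
    src = np.full(n, np.nan)
    last_seen: dict[int, int] = {}
    for i in range(1, n):
        r = int(resp[i - 1])
        m = last_seen.get(r)
        if m is not None:
            er[i] = "match" if resp[m + 1] == resp[i] else "mismatch"
            src[i] = trial_no[m]
        last_seen[r] = i - 1
    return er, src


def code_cl(trials: pd.DataFrame, scheme: ContingencyScheme) -> pd.Series:
    """Contingency label of each trial's current pair (``hf``/``lf``/NA)."""
    _require_ordered(trials)
    out = pd.Series(np.nan, index=trials.index, dtype=object)
    for _, g in trials.groupby(["participant", "block"], sort=False):
        out.loc[g.index] = _block_cl(_pos_codes(g["stimulus"]), scheme.hi_successor)
    return out


def code_pcl(trials: pd.DataFrame, scheme: ContingencyScheme) -> pd.Series:
    """Contingency label of the preceding pair: ``cl`` shifted by one trial."""
    cl = code_cl(trials, scheme)
    out = pd.Series(np.nan, index=trials.index, dtype=object)
    for _, g in trials.groupby(["participant", "block"], sort=False):
        out.loc[g.index] = cl.loc[g.index].shift(1)
    return out


def code_er(trials: pd.DataFrame) -> pd.DataFrame:
    """Episodic-retrieval labels and the retrieved pair's first trial number.

    Returns a DataFrame with columns ``er`` (``match``/``mismatch``/NA) and
    ``er_source_trial`` (within-block trial number of the retrieved pair's
    first trial, NaN when undefined).
    """
    _require_ordered(trials)
    er = pd.Series(np.nan, index=trials.index, dtype=object)
    src = pd.Series(np.nan, index=trials.index, dtype=float)
    for _, g in trials.groupby(["participant", "block"], sort=False):
        labels, sources = _block_er(_pos_codes(g["response"]), g["trial"].to_numpy())
        er.loc[g.index] = labels
        src.loc[g.index] = sources
    return pd.DataFrame({"er": er, "er_source_trial": src})


def code_ca(
    trials: pd.DataFrame, awareness: pd.DataFrame, scheme: ContingencyScheme
) -> pd.Series:
    """Awareness label per trial from the participant's sequence judgments.

    ``awareness`` must hold, per participant, one row for each of the six
    ordered position pairs with a boolean/0-1 ``correct`` column.  The label
    of trial ``n`` is determined by the ordered stimulus pair
    ``(stimulus(n-1), stimulus(n))`` and is undefined wherever ``cl`` is.
    """
    _require_ordered(trials)
    lookup: dict = {}
    for row in awareness.itertuples(index=False):
        lookup[(row.participant, row.seq_first, row.seq_second)] = bool(row.correct)
    out = pd.Series(np.nan, index=trials.index, dtype=object)
    for (pid, _), g in trials.groupby(["participant", "block"], sort=False):
        stim = g["stimulus"].to_numpy()
        labels: list = [None] * len(g)
        for t in range(1, len(g)):
            key = (pid, stim[t - 1], stim[t])
            if key not in lookup:
                raise ValueError(
                    f"awareness table has no judgment for participant {pid!r}, "
                    f"sequence {stim[t - 1]}->{stim[t]}"
                )
            labels[t] = "correct" if lookup[key] else "incorrect"
        out.loc[g.index] = labels
    return out


def code_trials(
    trials: pd.DataFrame,
    scheme: ContingencyScheme,
    awareness: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach all condition codes to a trial log.

    Adds ``cl``, ``pcl``, ``er``, ``rev``, ``er_source_trial`` and — when an
    awareness table is supplied — ``ca``.  Coding is pure: the input frame is
    not modified and re-coding the same log yields identical output.
    """
    _require_ordered(trials)
    coded = trials.copy()
    coded["cl"] = code_cl(trials, scheme)
    coded["pcl"] = code_pcl(trials, scheme)

    rev = pd.Series(np.nan, index=trials.index, dtype=object)
    for _, g in trials.groupby(["participant", "block"], sort=False):
        stim = _pos_codes(g["stimulus"])
        labels: list = [None] * len(g)
        for t in range(2, len(g)):
            labels[t] = "reversal" if stim[t] == stim[t - 2] else "nonreversal"
        rev.loc[g.index] = labels
    coded["rev"] = rev

    if "response" in trials.columns:
        er = code_er(trials)
        coded["er"] = er["er"]
        coded["er_source_trial"] = er["er_source_trial"]
    if awareness is not None:
        coded["ca"] = code_ca(trials, awareness, scheme)
    return coded


def contrast_weights(labels: pd.Series, predictor: str) -> tuple[float, float]:
    """Weighted-effect-coding weights (high, low) for one predictor.

    With ``n_hi`` high-level and ``n_lo`` low-level trials (N total) the
    weights are ``(+n_lo/N, -n_hi/N)``: mean zero over the set, difference 1.
    """
    hi, lo = HIGH_LEVEL[predictor], LOW_LEVEL[predictor]
    n_hi = int((labels == hi).sum())
    n_lo = int((labels == lo).sum())
    bad = labels.dropna()
    unknown = set(bad.unique()) - {hi, lo}
    if unknown:
        raise ValueError(f"unexpected {predictor} labels: {sorted(unknown)}")
    if n_hi == 0 or n_lo == 0:
        raise ValueError(
            f"predictor {predictor!r} has a single level in the analysis set "
            f"(n_{hi}={n_hi}, n_{lo}={n_lo}); its contrast is undefined"
        )
    n = n_hi + n_lo
    return n_lo / n, -n_hi / n


def build_contrasts(
    coded: pd.DataFrame,
    main_effects: tuple[str, ...],
    interactions: tuple[tuple[str, str], ...] = (),
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centered contrast columns for an analysis set.

    Every requested predictor must be defined (non-missing) on all rows of
    ``coded``.  Interaction columns are products of the centered main-effect
    columns.  Returns the design columns and the per-predictor weights.
    """
    X = pd.DataFrame(index=coded.index)
    weights: dict[str, tuple[float, float]] = {}
    for pred in main_effects:
        labels = coded[pred]
        if labels.isna().any():
            raise ValueError(
                f"predictor {pred!r} is undefined on {int(labels.isna().sum())} "
                "rows of the analysis set; drop them before building contrasts"
            )
        w_hi, w_lo = contrast_weights(labels, pred)
        weights[pred] = (w_hi, w_lo)
        X[pred] = np.where(labels == HIGH_LEVEL[pred], w_hi, w_lo)
    for a, b in interactions:
        for p in (a, b):
            if p not in X.columns:
                raise ValueError(f"interaction {a}:{b} needs main effect {p!r} first")
        X[f"{a}:{b}"] = X[a] * X[b]
    return X, weights
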
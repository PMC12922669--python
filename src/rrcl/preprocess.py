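"""Exclusion cascade and descriptive statistics of the valid RT distribution.

Analysis trials are the non-practice trials.  Four criteria are applied in a
fixed cascade, each trial being tagged with the *first* criterion it
triggers, so the per-criterion counts are disjoint and sum with the valid
count to the number of test trials:

``current_pair_error``
    The current response is an error.  (Trials following an error but
    answered correctly are retained; their pair-level codes are computed
    from the executed responses.)
``first_pair_in_block``
    The trial's pair is the first in the block to start with its initial
    response, so no episode can be retrieved (``er`` undefined) — or, in
    designs without practice trials, the block-initial trial whose pair
    contingency is undefined.
``prior_pair_error``
    An error occurred on either trial of the retrieved pair, contaminating
    the retrieval code.
``rt_outlier``
    RT below a fixed 100 ms floor or above Tukey's upper fence
    (Q3 + 1.5 * IQR) of the participant's own distribution of trials that
    survived the previous criteria; quartiles use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CASCADE",
    "ExclusionReport",
    "DescriptiveStats",
    "apply_exclusions",
    "rt_outlier_bounds",
    "describe",
]

CASCADE = (
    "current_pair_error",
    "first_pair_in_block",
    "prior_pair_error",
    "rt_outlier",
)

RT_FLOOR_MS = 100.0
IQR_MULTIPLIER = 1.5


@dataclass(frozen=True)
class ExclusionReport:
    """Disjoint per-criterion exclusion counts for one dataset."""

    n_total: int
    n_excluded: dict[str, int]
    n_valid: int
    rt_floor_ms: float = RT_FLOOR_MS
    iqr_multiplier: float = IQR_MULTIPLIER
    quartile_method: str = "linear interpolation"

    def __post_init__(self) -> None:
        if self.n_valid + sum(self.n_excluded.values()) != self.n_total:
            raise ValueError("exclusion counts do not add up to the total")

    def percent(self, criterion: str) -> float:
        """Percent of all test trials removed by one criterion."""
        return 100.0 * self.n_excluded[criterion] / self.n_total

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": c, "n": self.n_excluded[c], "percent": self.percent(c)}
            for c in CASCADE
        ]
        rows.append(
            {
                "criterion": "valid",
                "n": self.n_valid,
                "percent": 100.0 * self.valid_fraction,
            }
        )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"Exclusion cascade over {self.n_total} test trials "
            f"(RT floor {self.rt_floor_ms:g} ms, upper fence Q3 + "
            f"{self.iqr_multiplier:g} IQR per participant, quartiles by "
            f"{self.quartile_method}):"
        ]
        labels = {
            "current_pair_error": "error on the current response",
            "first_pair_in_block": "first pair with this starting response in block",
            "prior_pair_error": "error in the retrieved pair",
            "rt_outlier": "RT outlier",
        }
        for c in CASCADE:
            lines.append(
                f"  {labels[c]:<48s} {self.n_excluded[c]:>7d}  ({self.percent(c):.1f}%)"
            )
        lines.append(
            f"  {'valid trials entering analysis':<48s} {self.n_valid:>7d}  "
            f"({100 * self.valid_fraction:.1f}%)"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class DescriptiveStats:
    """Moments of a valid-RT sample (SD with n-1 denominator, g1/g2 moments)."""

    mean: float
    sd: float
    min: float
    max: float
    skewness: float
    kurtosis_excess: float
    n: int

    def to_text(self) -> str:
        return (
            f"M = {self.mean:.0f} ms, SD = {self.sd:.0f} ms, "
            f"range = [{self.min:.0f} ms, {self.max:.0f} ms], "
            f"skewness = {self.skewness:.2f}, "
            f"kurtosis (excess) = {self.kurtosis_excess:.2f}, n = {self.n}"
        )


def rt_outlier_bounds(rts) -> tuple[float, float]:
    """Per-participant outlier bounds: fixed 100 ms floor, Tukey upper fence.

    The upper fence is Q3 + 1.5 * (Q3 - Q1) with quartiles computed by
    linear interpolation between order statistics.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4:
        raise ValueError(
            f"need at least 4 observations to estimate quartiles, got {rts.size}"
        )
    q1, q3 = np.percentile(rts, [25.0, 75.0])
    return RT_FLOOR_MS, float(q3 + IQR_MULTIPLIER * (q3 - q1))


def apply_exclusions(coded: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the four-criterion cascade to a coded trial set.

    Practice trials are dropped from the candidate set first (they are never
    analysis trials) but remain visible to the retrieval bookkeeping done at
    coding time.  Returns the surviving trials and a report; use
    :func:`tag_exclusions` when the per-trial tag table itself is needed.
    """
    tagged = tag_exclusions(coded)
    counts = {c: int((tagged["excl_reason"] == c).sum()) for c in CASCADE}
    valid = tagged[~tagged["excluded"]].drop(columns=["excluded", "excl_reason"])
    report = ExclusionReport(
        n_total=len(tagged), n_excluded=counts, n_valid=len(valid)
    )
    return valid.reset_index(drop=True), report


def tag_exclusions(coded: pd.DataFrame) -> pd.DataFrame:
    """Tag every test trial with its first triggering exclusion criterion.

    Requires a coded trial table (``er``/``er_source_trial`` present along
    the raw log columns).  Returns the test trials with two extra columns:
    boolean ``excluded`` and ``excl_reason`` (one of the cascade names, or
    missing for valid trials).
    """
    if len(coded) == 0:
        raise ValueError("cannot apply exclusions to an empty trial set")
    for col in ("er", "er_source_trial", "accuracy", "rt_ms"):
        if col not in coded.columns:
            raise ValueError(f"coded trial table lacks required column {col!r}")

    pieces = []
    for _, g in coded.groupby(["participant", "block"], sort=False):
        g = g.reset_index(drop=True)
        # accuracy by within-block trial number, practice included: needed to
        # look up errors inside retrieved pairs that sit in the practice run
        acc = dict(zip(g["trial"].to_numpy(), g["accuracy"].to_numpy()))
        test = g[g["practice"] == 0].copy()
        reason = np.array([None] * len(test), dtype=object)

        a = test["accuracy"].to_numpy() == 0
        reason[a] = "current_pair_error"

        undefined = test["er"].isna().to_numpy() | test["cl"].isna().to_numpy()
        b = undefined & (reason == None)  # noqa: E711
        reason[b] = "first_pair_in_block"

        src = test["er_source_trial"].to_numpy()
        prior_err = np.zeros(len(test), dtype=bool)
        for i, m in enumerate(src):
            if np.isfinite(m):
                prior_err[i] = acc[int(m)] == 0 or acc[int(m) + 1] == 0
        c = prior_err & (reason == None)  # noqa: E711
        reason[c] = "prior_pair_error"

        test["excl_reason"] = reason
        pieces.append(test)

    tagged = pd.concat(pieces, ignore_index=True)

    # criterion (d): per-participant bounds over trials surviving (a)-(c)
    for pid, g in tagged.groupby("participant", sort=False):
        surviving = g[g["excl_reason"].isna()]
        lo, hi = rt_outlier_bounds(surviving["rt_ms"].to_numpy())
        rt = surviving["rt_ms"].to_numpy()
        out = (rt < lo) | (rt > hi)
        tagged.loc[surviving.index[out], "excl_reason"] = "rt_outlier"

    tagged["excluded"] = tagged["excl_reason"].notna()
    return tagged


def describe(rts) -> DescriptiveStats:
    """Sample moments of a valid RT collection."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot describe an empty RT sample")
    return DescriptiveStats(
        mean=float(np.mean(rts)),
        sd=float(np.std(rts, ddof=1)) if rts.size > 1 else 0.0,
        min=float(np.min(rts)),
        max=float(np.max(rts)),
        skewness=float(stats.skew(rts)),
        kurtosis_excess=float(stats.kurtosis(rts)),
        n=int(rts.size),
    )
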
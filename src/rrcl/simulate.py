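"""Synthetic participants: responses, errors, reaction times and awareness.

The simulator turns trial plans from the transition process into full trial
logs under a known ground-truth effect model, so that the whole downstream
pipeline (coding, exclusions, multilevel fits) can be validated by parameter
recovery without any external data.

Two features of the generative model matter for validity of the downstream
checks:

* The condition codes entering the RT mean are computed from the *actual
  generated history* with the same coding rules used at analysis time.  In
  particular the episodic-retrieval status is never injected independently;
  it emerges from the sequence, which is what creates the natural
  confounding between pair contingency and retrieval (a high-frequency pair
  usually retrieves a matching episode, a low-frequency pair a mismatching
  one).
* Residual noise is a zero-mean, unit-calibrated shifted lognormal, giving
  the right-skewed RT distributions typical of speeded keypress tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .coding import code_trials
from .config import GroundTruth, SimConfig
from .contingency import (
    ContingencyScheme,
    POSITION_LABELS,
    build_scheme,
    classify_pair,
    generate_session,
)

__all__ = [
    "ParticipantProfile",
    "StudyData",
    "sample_profile",
    "simulate_trial_log",
    "generate_study",
    "awareness_frame",
    "fixed_mean",
    "truncated_noise_mean",
    "signed_code",
    "TRIAL_COLUMNS",
    "AWARENESS_COLUMNS",
]

TRIAL_COLUMNS = (
    "participant",
    "block",
    "trial",
    "practice",
    "stimulus",
    "response",
    "accuracy",
    "rt_ms",
)
AWARENESS_COLUMNS = (
    "participant",
    "seq_first",
    "seq_second",
    "true_label",
    "judged_label",
    "correct",
)

#: The six ordered non-repeating position pairs, in deterministic order.
SEQUENCE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    p for p in permutations(POSITION_LABELS, 2)
)

_HALF = {
    "cl": {"hf": 0.5, "lf": -0.5},
    "pcl": {"hf": 0.5, "lf": -0.5},
    "rev": {"reversal": 0.5, "nonreversal": -0.5},
    "er": {"match": 0.5, "mismatch": -0.5},
    "ca": {"correct": 0.5, "incorrect": -0.5},
}


@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic participant: baseline offset and awareness judgments."""

    participant_id: object
    intercept_dev: float
    awareness: dict  # (first_label, second_label) -> judged correctly?

    def __post_init__(self) -> None:
        if set(self.awareness) != set(SEQUENCE_PAIRS):
            raise ValueError("awareness must hold exactly the 6 ordered pairs")


@dataclass(frozen=True)
class StudyData:
    """A complete simulated study: trial logs plus awareness tables.

    ``profiles`` retains the ground-truth participant draws (intercept
    deviations, awareness judgments) so that validation harnesses can build
    oracle quantities; analysis code never reads it.
    """

    trials: pd.DataFrame
    awareness: pd.DataFrame
    config: SimConfig
    profiles: dict | None = None


def signed_code(labels: pd.Series, predictor: str) -> np.ndarray:
    """Signed half-difference code: +1/2 high level, -1/2 low, 0 undefined."""
    return labels.map(_HALF[predictor]).fillna(0.0).to_numpy(dtype=float)


def sample_profile(
    ground_truth: GroundTruth, participant_id, rng: np.random.Generator
) -> ParticipantProfile:
    """Draw a participant's intercept deviation and awareness judgments.

    The intercept deviation is Normal(0, tau); each of the six sequence
    judgments is independently correct with probability ``pi_ca``.
    """
    dev = float(rng.normal(0.0, ground_truth.tau)) if ground_truth.tau > 0 else 0.0
    correct = rng.random(len(SEQUENCE_PAIRS)) < ground_truth.pi_ca
    awareness = {pair: bool(c) for pair, c in zip(SEQUENCE_PAIRS, correct)}
    return ParticipantProfile(participant_id, dev, awareness)


def awareness_frame(
    profile: ParticipantProfile, scheme: ContingencyScheme
) -> pd.DataFrame:
    """Serialize a profile's judgments in the awareness-table schema."""
    rows = []
    for (first, second), correct in profile.awareness.items():
        true_label = (
            "frequent"
            if classify_pair(
                _pos(first), _pos(second), scheme
            ) == "hf"
            else "infrequent"
        )
        judged = true_label if correct else (
            "infrequent" if true_label == "frequent" else "frequent"
        )
        rows.append(
            {
                "participant": profile.participant_id,
                "seq_first": first,
                "seq_second": second,
                "true_label": true_label,
                "judged_label": judged,
                "correct": int(correct),
            }
        )
    return pd.DataFrame(rows, columns=list(AWARENESS_COLUMNS))


def _pos(label: str):
    from .contingency import Position

    return Position.from_label(label)


def _residual_noise(
    rng: np.random.Generator, n: int, sigma: float, shape: float, family: str
) -> np.ndarray:
    """Zero-mean residuals with SD ``sigma``.

    ``shifted_lognormal``: sigma * (exp(shape*Z) - E) / SD(exp(shape*Z)),
    a lognormal shifted and scaled to mean 0 and SD sigma; its skewness is
    (w + 2) * sqrt(w - 1) with w = exp(shape^2).
    """
    if sigma == 0 or n == 0:
        return np.zeros(n)
    z = rng.normal(size=n)
    if family == "normal" or shape == 0:
        return sigma * z
    w = np.exp(shape**2)
    return sigma * (np.exp(shape * z) - np.sqrt(w)) / np.sqrt(w * (w - 1.0))


def truncated_noise_mean(
    c, sigma: float, shape: float, family: str = "shifted_lognormal"
) -> np.ndarray:
    """E[eps | eps <= c] for the residual-noise distribution (vectorized).

    Used by validation harnesses to predict how upper-fence RT trimming
    shifts the conditional mean of surviving trials.  ``c`` is the cutoff on
    the noise scale (fence minus the trial's noiseless mean).
    """
    from scipy.stats import norm

    c = np.asarray(c, dtype=float)
    if sigma == 0:
        return np.zeros_like(c)
    if family == "normal" or shape == 0:
        a = c / sigma
        return -sigma * norm.pdf(a) / np.clip(norm.cdf(a), 1e-300, None)
    w = np.exp(shape**2)
    s_w = np.sqrt(w * (w - 1.0))
    # eps <= c  <=>  lognormal factor L = exp(shape*Z) <= k
    k = c * s_w / sigma + np.sqrt(w)
    k = np.clip(k, 1e-12, None)
    a = np.log(k) / shape
    frac = norm.cdf(a - shape) / np.clip(norm.cdf(a), 1e-300, None)
    return sigma * np.sqrt(w) / s_w * (frac - 1.0)


def fixed_mean(coded: pd.DataFrame, ground_truth: GroundTruth) -> np.ndarray:
    """Expected RT of each coded trial, excluding the participant intercept.

    Undefined condition labels contribute 0 (the trial sits at the grand
    mean for that factor).
    """
    gt = ground_truth
    s = {k: signed_code(coded[k], k) for k in ("cl", "pcl", "rev", "er", "ca")}
    return (
        gt.mu0
        + gt.b_cl * s["cl"]
        + gt.b_pcl * s["pcl"]
        + gt.b_rev * s["rev"]
        + gt.b_er * s["er"]
        + gt.b_ca * s["ca"]
        + 2.0 * gt.b_cl_ca * s["cl"] * s["ca"]
        + 2.0 * gt.b_er_ca * s["er"] * s["ca"]
    )


def simulate_trial_log(
    plan: pd.DataFrame,
    profile: ParticipantProfile,
    ground_truth: GroundTruth,
    scheme: ContingencyScheme,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one participant's responses, errors and RTs for a trial plan.

    The response equals the stimulus with probability ``1 - err_rate`` and is
    otherwise one of the two remaining keys, uniformly.  The RT mean is the
    ground-truth fixed part evaluated at the trial's *actual* condition codes
    plus the participant's intercept deviation; residuals are floored so
    that ``rt_ms >= 1``.
    """
    if plan["participant"].nunique() != 1:
        raise ValueError("plan must contain trials of a single participant")
    gt = ground_truth
    n = len(plan)
    stim = plan["stimulus"].map(
        {lab: i for i, lab in enumerate(POSITION_LABELS)}
    ).to_numpy(dtype=np.int8)

    resp = stim.copy()
    err = rng.random(n) < gt.err_rate
    offsets = rng.integers(1, 3, size=n).astype(np.int8)
    resp[err] = (stim[err] + offsets[err]) % 3

    log = plan.copy()
    log["response"] = [POSITION_LABELS[r] for r in resp]
    log["accuracy"] = (resp == stim).astype(int)

    coded = code_trials(log, scheme, awareness_frame(profile, scheme))
    mu = fixed_mean(coded, gt) + profile.intercept_dev
    eps = _residual_noise(rng, n, gt.sigma, gt.noise_shape, gt.noise_family)
    log["rt_ms"] = np.maximum(mu + eps, 1.0)
    return log[list(TRIAL_COLUMNS)]


def generate_study(config: SimConfig) -> StudyData:
    """Simulate a complete study under a configuration.

    Contingency sets 1 and 2 alternate across participants (counterbalanced:
    odd participant numbers get set 1).  Randomness is drawn from one
    per-participant substream derived from the master seed, so adding
    participants never perturbs earlier ones and a fixed seed reproduces the
    dataset exactly.
    """
    trials = []
    awareness = []
    profiles: dict = {}
    for i in range(1, config.n_participants + 1):
        scheme = build_scheme(1 if i % 2 == 1 else 2, config.p_hi)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        plan = generate_session(
            i, scheme, config.n_blocks, config.n_practice, config.n_test, rng
        )
        profile = sample_profile(config.ground_truth, i, rng)
        profiles[i] = profile
        trials.append(simulate_trial_log(plan, profile, config.ground_truth, scheme, rng))
        awareness.append(awareness_frame(profile, scheme))
    return StudyData(
        trials=pd.concat(trials, ignore_index=True),
        awareness=pd.concat(awareness, ignore_index=True),
        config=config,
        profiles=profiles,
    )


def scheme_for_participant(config: SimConfig, participant: int) -> ContingencyScheme:
    """Contingency set assigned to a participant under counterbalancing."""
    return build_scheme(1 if participant % 2 == 1 else 2, config.p_hi)


def code_study(study: StudyData) -> pd.DataFrame:
    """Condition-code every participant's trial log of a simulated study."""
    coded = []
    for pid, g in study.trials.groupby("participant", sort=False):
        scheme = scheme_for_participant(study.config, int(pid))
        aware = study.awareness[study.awareness["participant"] == pid]
        coded.append(code_trials(g.reset_index(drop=True), scheme, aware))
    return pd.concat(coded, ignore_index=True)
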
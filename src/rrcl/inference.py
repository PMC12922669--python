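"""Random-intercept multilevel regressions, power, and parameter recovery.

The stepwise decomposition fits three nested linear mixed models to the
valid trials, all with a participant-specific random intercept and maximum
likelihood estimation (ML rather than REML so that BIC values are
comparable across fixed-effect structures):

* Model 1: ``cl + pcl + cl:pcl`` — the raw contingency-learning effect.
* Model 2: ``+ er`` — retrieval-adjusted; the CL coefficient is the
  *residual* contingency effect after controlling recency-based retrieval.
* Model 3: ``+ ca + cl:ca + er:ca`` — awareness modulation.

Because the retrieved episode is a high-frequency pair with probability
``p_hi`` on hf trials but only ``p_lo`` on lf trials, omitting ER inflates
the Model-1 CL coefficient by ``(p_hi - p_lo) * beta_ER`` — an
omitted-variable identity that :func:`decomposition_check` measures
directly.

Fixed-effect t statistics use the residual-degrees-of-freedom convention
``df = n_obs - p_fixed``; with tens of thousands of trials this is
indistinguishable from finer-grained approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coding import build_contrasts
from .config import GroundTruth, SimConfig
from .preprocess import rt_outlier_bounds, tag_exclusions
from .simulate import code_study, fixed_mean, generate_study, truncated_noise_mean

__all__ = [
    "MODEL_TERMS",
    "ModelFit",
    "StepwiseFits",
    "AwarenessTest",
    "PowerSpec",
    "RecoveryReport",
    "fit_random_intercept",
    "run_stepwise",
    "decomposition_check",
    "subgroup_residual_cl",
    "test_awareness",
    "power_one_sample_t",
    "recover_parameters",
    "implied_coefficients",
]

#: Fixed-effect terms of the three stepwise models (strictly nested).
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("cl", "pcl", "cl:pcl"),
    2: ("cl", "pcl", "cl:pcl", "er"),
    3: ("cl", "pcl", "cl:pcl", "er", "ca", "cl:ca", "er:ca"),
}


class ConvergenceError(RuntimeError):
    """Raised when the mixed-model optimizer fails to converge."""


@dataclass(frozen=True)
class ModelFit:
    """One random-intercept fit: coefficients, uncertainty, variances, BIC."""

    terms: tuple[str, ...]          # fixed effects including "Intercept"
    coef: dict[str, float]          # ms per unit contrast
    se: dict[str, float]
    tvalues: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    df_resid: int
    var_participant: float          # ms^2
    var_residual: float             # ms^2
    llf: float
    bic: float
    n_obs: int
    n_participants: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            lo, hi = self.ci95[t]
            p = 2.0 * stats.t.sf(abs(self.tvalues[t]), self.df_resid)
            rows.append(
                {
                    "term": t,
                    "coef_ms": self.coef[t],
                    "se_ms": self.se[t],
                    "t": self.tvalues[t],
                    "df": self.df_resid,
                    "p": p,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepwiseFits:
    """Fits of the nested models on one common analysis set."""

    fits: dict[int, ModelFit]
    n_obs: int

    @property
    def delta_bic(self) -> dict[int, float]:
        """BIC(step k) - BIC(step k-1) for consecutive fitted steps."""
        steps = sorted(self.fits)
        return {
            k: self.fits[k].bic - self.fits[prev].bic
            for prev, k in zip(steps, steps[1:])
        }

    def to_text(self) -> str:
        steps = sorted(self.fits)
        terms = list(
            dict.fromkeys(t for k in steps for t in self.fits[k].terms)
        )
        width = max(len(t) for t in terms) + 2
        header = "Predictor".ljust(width) + "".join(
            f"Model {k}".center(26) for k in steps
        )
        lines = [header, "-" * len(header)]
        for t in terms:
            cells = []
            for k in steps:
                f = self.fits[k]
                if t in f.coef:
                    lo, hi = f.ci95[t]
                    cells.append(f"{f.coef[t]:8.1f} [{lo:7.1f},{hi:7.1f}]")
                else:
                    cells.append(" " * 26)
            lines.append(t.ljust(width) + "".join(c.center(26) for c in cells))
        lines.append(
            "BIC".ljust(width)
            + "".join(f"{self.fits[k].bic:12.0f}".center(26) for k in steps)
        )
        dbic = self.delta_bic
        lines.append(
            "dBIC".ljust(width)
            + "".join(
                (f"{dbic[k]:12.0f}" if k in dbic else " " * 12).center(26)
                for k in steps
            )
        )
        lines.append(f"n = {self.n_obs} trials")
        return "\n".join(lines)


@dataclass(frozen=True)
class AwarenessTest:
    """One-sample t test of mean judgment accuracy against chance (.5)."""

    n_participants: int
    mean_accuracy: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class PowerSpec:
    """Power of a one-sample t test at effect size d."""

    d: float
    n: int
    alpha: float
    tails: int
    power: float


def _analysis_terms(terms: tuple[str, ...]) -> tuple[tuple[str, ...], tuple]:
    mains = tuple(t for t in terms if ":" not in t)
    inters = tuple(tuple(t.split(":")) for t in terms if ":" in t)
    return mains, inters


def fit_random_intercept(
    data: pd.DataFrame,
    predictors: tuple[str, ...],
    response: str = "rt_ms",
    groups: str = "participant",
) -> ModelFit:
    """ML fit of a linear mixed model with one random intercept per group.

    ``data`` must already contain the centered contrast columns named in
    ``predictors``.  Collinear designs are rejected naming the offending
    columns; optimizer failure raises :class:`ConvergenceError`.
    """
    if data[groups].nunique() < 2:
        raise ValueError("need at least 2 participants for a multilevel fit")
    X = data[list(predictors)].astype(float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("predictor columns contain non-finite values")
    Xc = sm.add_constant(X, prepend=True, has_constant="raise")
    Xc = Xc.rename(columns={"const": "Intercept"})

    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        _, sv, vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
        null_mask = np.abs(vt[-1]) > 1e-8
        offending = [c for c, m in zip(Xc.columns, null_mask) if m]
        raise ValueError(
            f"singular design: columns {offending} are collinear"
        )

    y = data[response].to_numpy(dtype=float)

    # exactly noiseless data: the ML objective is unbounded, so no optimizer
    # can converge; the coefficients are the exact interpolating solution
    ols_beta, *_ = np.linalg.lstsq(Xc.to_numpy(), y, rcond=None)
    ols_resid = y - Xc.to_numpy() @ ols_beta
    if float(np.mean(ols_resid**2)) < 1e-12 * max(float(np.mean(y**2)), 1.0):
        names = list(Xc.columns)
        coef = dict(zip(names, ols_beta))
        zero = {t: 0.0 for t in names}
        inf_t = {t: np.inf if coef[t] != 0 else 0.0 for t in names}
        return ModelFit(
            terms=tuple(names),
            coef=coef,
            se=zero,
            tvalues=inf_t,
            ci95={t: (coef[t], coef[t]) for t in names},
            df_resid=len(y) - len(names),
            var_participant=0.0,
            var_residual=0.0,
            llf=float("nan"),
            bic=float("nan"),
            n_obs=len(y),
            n_participants=int(data[groups].nunique()),
            converged=True,
        )

    model = sm.MixedLM(y, Xc, groups=data[groups].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False)
        if not result.converged:
            result = model.fit(reml=False, method="lbfgs")
        if not result.converged:
            raise ConvergenceError(
                f"mixed-model fit did not converge (n={len(y)}, "
                f"predictors={list(predictors)})"
            )
        fe = np.asarray(result.fe_params, dtype=float)
        bse = np.asarray(result.bse_fe, dtype=float)

    names = list(Xc.columns)
    k_fixed = len(names)
    n = len(y)
    coef = dict(zip(names, fe))
    se = dict(zip(names, bse))
    df_resid = n - k_fixed
    tcrit = stats.t.ppf(0.975, df_resid)
    tvals = {t: coef[t] / se[t] for t in names}
    ci = {t: (coef[t] - tcrit * se[t], coef[t] + tcrit * se[t]) for t in names}
    # BIC from the ML deviance; parameter count = fixed effects + intercept
    # variance + residual variance (constant additions cancel in deltas)
    bic = -2.0 * result.llf + (k_fixed + 2) * np.log(n)
    return ModelFit(
        terms=tuple(names),
        coef=coef,
        se=se,
        tvalues=tvals,
        ci95=ci,
        df_resid=df_resid,
        var_participant=float(np.asarray(result.cov_re)[0, 0]),
        var_residual=float(result.scale),
        llf=float(result.llf),
        bic=float(bic),
        n_obs=n,
        n_participants=int(data[groups].nunique()),
        converged=bool(result.converged),
    )


def _analysis_set(valid: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    labels = sorted({p for t in terms for p in t.split(":")})
    missing = [c for c in labels if c not in valid.columns]
    if missing:
        raise ValueError(
            f"coded data lack columns {missing} required by the requested models"
        )
    return valid.dropna(subset=labels)


def run_stepwise(
    valid: pd.DataFrame, models: tuple[int, ...] = (1, 2, 3)
) -> StepwiseFits:
    """Fit the nested models on one common analysis set.

    The analysis set is restricted to trials with every label of the largest
    requested model defined, so the BIC values of all steps refer to the same
    observations; contrasts are (re)centered on that set.
    """
    largest = MODEL_TERMS[max(models)]
    df = _analysis_set(valid, largest)
    fits: dict[int, ModelFit] = {}
    for k in sorted(models):
        mains, inters = _analysis_terms(MODEL_TERMS[k])
        X, _ = build_contrasts(df, mains, inters)
        data = pd.concat(
            [df[["participant", "rt_ms"]].reset_index(drop=True),
             X.reset_index(drop=True)],
            axis=1,
        )
        fits[k] = fit_random_intercept(data, tuple(X.columns))
    return StepwiseFits(fits=fits, n_obs=len(df))


def decomposition_check(fits: StepwiseFits, p_hi: float) -> float:
    """Residual of the omitted-variable identity linking Models 1 and 2.

    Returns ``beta_CL(M1) - [beta_CL(M2) + (p_hi - p_lo) * beta_ER(M2)]``;
    on large simulated datasets this tends to zero because the probability
    of retrieving a matching episode differs by exactly ``p_hi - p_lo``
    between hf and lf trials.
    """
    if 1 not in fits.fits or 2 not in fits.fits:
        raise ValueError("decomposition check needs Models 1 and 2")
    m1, m2 = fits.fits[1], fits.fits[2]
    p_lo = 1.0 - p_hi
    return m1.coef["cl"] - (m2.coef["cl"] + (p_hi - p_lo) * m2.coef["er"])


def subgroup_residual_cl(valid: pd.DataFrame) -> dict[str, ModelFit]:
    """Retrieval-adjusted CL effect separately for aware/unaware sequences.

    Splits the analysis set by the awareness label and fits
    ``cl + pcl + cl:pcl + er`` (contrasts recentered per subset); each
    subset's ``cl`` coefficient is the residual contingency effect for that
    awareness condition.
    """
    df = _analysis_set(valid, MODEL_TERMS[3])
    out: dict[str, ModelFit] = {}
    for level in ("correct", "incorrect"):
        sub = df[df["ca"] == level]
        if sub.empty:
            raise ValueError(f"no trials with awareness level {level!r}")
        mains, inters = _analysis_terms(MODEL_TERMS[2])
        X, _ = build_contrasts(sub, mains, inters)
        data = pd.concat(
            [sub[["participant", "rt_ms"]].reset_index(drop=True),
             X.reset_index(drop=True)],
            axis=1,
        )
        out[level] = fit_random_intercept(data, tuple(X.columns))
    return out


def test_awareness(awareness: pd.DataFrame) -> AwarenessTest:
    """Test per-participant judgment accuracy against chance (50%)."""
    props = awareness.groupby("participant")["correct"].mean().to_numpy(dtype=float)
    if len(props) < 2:
        raise ValueError("need at least 2 participants for the awareness test")
    mean = float(props.mean())
    if float(props.std(ddof=1)) == 0.0:
        # degenerate: every participant exactly at the same accuracy
        t = 0.0 if mean == 0.5 else float(np.sign(mean - 0.5) * np.inf)
        p = 1.0 if mean == 0.5 else 0.0
    else:
        res = stats.ttest_1samp(props, 0.5)
        t, p = float(res.statistic), float(res.pvalue)
    return AwarenessTest(
        n_participants=len(props),
        mean_accuracy=mean,
        t=t,
        df=len(props) - 1,
        p=p,
    )


def power_one_sample_t(
    d: float, n: int, alpha: float = 0.05, tails: int = 1
) -> PowerSpec:
    """Exact power of a one-sample t test from the noncentral t distribution.

    Noncentrality is ``d * sqrt(n)`` with ``n - 1`` degrees of freedom; the
    default is one-tailed (directional hypothesis).
    """
    if d <= 0:
        raise ValueError(f"d must be > 0, got {d}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if tails not in (1, 2):
        raise ValueError(f"tails must be 1 or 2, got {tails}")
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = float(stats.nct.sf(tcrit, df, nc))
    else:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    return PowerSpec(d=d, n=n, alpha=alpha, tails=tails, power=power)


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate bias / RMSE / CI coverage over replicate simulated studies."""

    table: pd.DataFrame          # one row per fixed-effect term
    n_reps: int
    n_failed: int
    tau_mean: float              # mean recovered participant SD (ms)
    sigma_mean: float            # mean recovered residual SD (ms)

    def to_text(self) -> str:
        cols = [
            "term", "injected", "target_mean", "estimate_mean",
            "bias_vs_injected", "bias_vs_target", "rmse", "coverage",
        ]
        body = self.table[cols].to_string(
            index=False, float_format=lambda v: f"{v:8.2f}"
        )
        return (
            f"{body}\n"
            f"replicates: {self.n_reps} ({self.n_failed} failed fits)\n"
            f"mean recovered participant SD: {self.tau_mean:.1f} ms; "
            f"mean recovered residual SD: {self.sigma_mean:.1f} ms"
        )


def injected_regression_values(gt: GroundTruth) -> dict[str, float]:
    """Ground-truth effects mapped to the regression parameterization.

    Main-effect contrasts estimate the corresponding ``b`` directly; the
    ``cl:pcl`` product column encodes the reversal cost as ``-2 * b_rev``
    and the awareness product columns carry twice the modulation parameters
    (the generative interaction terms are ``2 * b * s(.) * s(.)``).
    """
    return {
        "Intercept": gt.mu0,
        "cl": gt.b_cl,
        "pcl": gt.b_pcl,
        "cl:pcl": -2.0 * gt.b_rev,
        "er": gt.b_er,
        "ca": gt.b_ca,
        "cl:ca": 2.0 * gt.b_cl_ca,
        "er:ca": 2.0 * gt.b_er_ca,
    }


def implied_coefficients(
    df: pd.DataFrame, X: pd.DataFrame, gt: GroundTruth
) -> dict[str, float]:
    """Design-implied estimands: projection of the noiseless mean surface.

    Weighted effect coding shifts contrast columns by a constant relative to
    the generative +-1/2 codes; with product interactions under imbalance
    this moves the main-effect estimand slightly away from the injected
    ``b``.  The exact estimand of each coefficient is the least-squares
    projection of the injected fixed-effect surface onto the realized
    design, computed here per replicate.
    """
    mu = fixed_mean(df, gt)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(Xc, mu, rcond=None)
    return dict(zip(["Intercept", *X.columns], beta))


def oracle_targets(
    df: pd.DataFrame,
    X: pd.DataFrame,
    gt: GroundTruth,
    intercept_dev: dict,
    fence: dict,
) -> dict[str, float]:
    """Selection-aware estimands of the regression coefficients.

    Upper-fence RT trimming removes the slowest surviving trials of each
    participant; conditions whose mean lies closer to the fence (mismatching
    retrievals, infrequent transitions) lose more of their right tail, so
    every fitted coefficient is attenuated relative to the injected effect.
    The estimand of the regression on trimmed data is therefore the
    projection of the *conditional* mean ``E[rt | X, rt <= fence]`` — the
    injected surface plus the closed-form truncated mean of the residual
    noise at each trial's cutoff — onto the realized design (with centered
    participant indicators standing in for the random intercepts).

    Requires the ground-truth participant intercepts and the per-participant
    fences actually used; both are available to the recovery harness.
    """
    mu_fix = fixed_mean(df, gt)
    u = df["participant"].map(intercept_dev).to_numpy(dtype=float)
    hi = df["participant"].map(fence).to_numpy(dtype=float)
    eps_mean = truncated_noise_mean(
        hi - mu_fix - u, gt.sigma, gt.noise_shape, gt.noise_family
    )
    y_oracle = mu_fix + u + eps_mean

    pid = pd.Categorical(df["participant"])
    dummies = pd.get_dummies(pid, drop_first=True).to_numpy(dtype=float)
    dummies -= dummies.mean(axis=0, keepdims=True)
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float), dummies])
    beta, *_ = np.linalg.lstsq(Xc, y_oracle, rcond=None)
    return dict(zip(["Intercept", *X.columns], beta[: X.shape[1] + 1]))


def recover_parameters(
    ground_truth: GroundTruth,
    config: SimConfig,
    n_reps: int,
    seed: int | None = None,
    model: int = 3,
) -> RecoveryReport:
    """Simulate -> code -> exclude -> fit, repeatedly; summarize recovery.

    Each replicate runs the full pipeline on a fresh study drawn under
    ``ground_truth`` and measures the fixed effects of the requested model
    against both the injected values (regression scale) and the
    selection-aware estimands of :func:`oracle_targets`.  Coverage is the
    fraction of replicates whose 95% CI contains the estimand.  Failed fits
    are counted, not dropped silently.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    base_seed = config.seed if seed is None else int(seed)
    cfg = replace(config, ground_truth=ground_truth)
    terms = ["Intercept", *MODEL_TERMS[model]]
    injected = injected_regression_values(ground_truth)

    estimates: dict[str, list[float]] = {t: [] for t in terms}
    targets: dict[str, list[float]] = {t: [] for t in terms}
    covered: dict[str, list[bool]] = {t: [] for t in terms}
    taus, sigmas = [], []
    n_failed = 0
    for r in range(n_reps):
        rep_seed = int(
            np.random.SeedSequence(entropy=base_seed, spawn_key=(r,)).generate_state(1)[0]
            % (2**31)
        )
        study = generate_study(cfg.with_seed(rep_seed))
        coded = code_study(study)
        tagged = tag_exclusions(coded)
        # per-participant fences over trials surviving the error criteria,
        # identical to the ones the cascade applied
        fence = {
            pid: rt_outlier_bounds(
                g.loc[
                    g["excl_reason"].isna() | (g["excl_reason"] == "rt_outlier"),
                    "rt_ms",
                ].to_numpy()
            )[1]
            for pid, g in tagged.groupby("participant", sort=False)
        }
        valid = tagged[~tagged["excluded"]].drop(columns=["excluded", "excl_reason"])
        df = _analysis_set(valid, MODEL_TERMS[model])
        mains, inters = _analysis_terms(MODEL_TERMS[model])
        try:
            X, _ = build_contrasts(df, mains, inters)
            data = pd.concat(
                [df[["participant", "rt_ms"]].reset_index(drop=True),
                 X.reset_index(drop=True)],
                axis=1,
            )
            fit = fit_random_intercept(data, tuple(X.columns))
        except (ValueError, ConvergenceError):
            n_failed += 1
            continue
        intercept_dev = {
            pid: prof.intercept_dev for pid, prof in study.profiles.items()
        }
        target = oracle_targets(df, X, ground_truth, intercept_dev, fence)
        for t in terms:
            estimates[t].append(fit.coef[t])
            targets[t].append(target[t])
            lo, hi = fit.ci95[t]
            covered[t].append(lo <= target[t] <= hi)
        taus.append(np.sqrt(max(fit.var_participant, 0.0)))
        sigmas.append(np.sqrt(fit.var_residual))

    rows = []
    for t in terms:
        est = np.asarray(estimates[t])
        tgt = np.asarray(targets[t])
        rows.append(
            {
                "term": t,
                "injected": injected[t],
                "target_mean": float(tgt.mean()) if len(tgt) else np.nan,
                "estimate_mean": float(est.mean()) if len(est) else np.nan,
                "bias_vs_injected": float(est.mean() - injected[t]) if len(est) else np.nan,
                "bias_vs_target": float((est - tgt).mean()) if len(est) else np.nan,
                "rmse": float(np.sqrt(((est - tgt) ** 2).mean())) if len(est) else np.nan,
                "coverage": float(np.mean(covered[t])) if covered[t] else np.nan,
                "n_ok": len(est),
            }
        )
    return RecoveryReport(
        table=pd.DataFrame(rows),
        n_reps=n_reps,
        n_failed=n_failed,
        tau_mean=float(np.mean(taus)) if taus else np.nan,
        sigma_mean=float(np.mean(sigmas)) if sigmas else np.nan,
    )
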
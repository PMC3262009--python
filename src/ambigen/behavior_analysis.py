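"""Behavioral model comparison on simulated cohorts.

Per subject, trial-by-trial guesses are regressed (logistic) on the purple
values predicted by one or more learning models plus a constant; group-level
inference uses the summary-statistic approach: a two-tailed one-sample
t-test on the per-subject coefficients (df = n - 1), and a Pearson
correlation between the generalization-model (M1) coefficient and each
subject's total reward.

Predictors are z-scored within subject before fitting (a conditioning
choice, declared in the output).  Subjects whose fit fails to converge even
under the penalized fallback are dropped with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import baseline_models as bm
from . import dp_generalization as dp
from . import task_paradigm as tp

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectDataset",
    "LogisticFit",
    "CohortResult",
    "logistic_fit",
    "analyze_cohort",
    "reward_correlation",
    "simulate_cohort",
]

MODEL_NAMES = ("M1", "M2", "M3", "M4", "M5")


@dataclass
class SubjectDataset:
    """One simulated subject: choices plus aligned per-model value streams."""

    subject_id: str
    trials: pd.DataFrame
    values: pd.DataFrame  # columns = model names, one row per trial
    total_reward: int

    def __post_init__(self) -> None:
        if len(self.values) != len(self.trials):
            raise ValueError("value trajectories must align with the trial table")


@dataclass
class LogisticFit:
    """Coefficients of one within-subject logistic regression."""

    coefs: pd.Series  # index: predictor names + 'const'
    converged: bool
    penalized: bool
    condition_number: float


def _ridge_irls(
    X: np.ndarray, y: np.ndarray, lam: float = 1e-3, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, bool]:
    """Quadratic-penalty IRLS fallback used on separation/rank problems."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = lam * np.eye(p)
    pen[-1, -1] = 0.0  # intercept unpenalized (last column)
    prev_obj = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        beta = np.linalg.solve(X.T @ (X * w[:, None]) + pen, X.T @ (w * z))
        ll = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, None, 30)))))
        obj = ll - 0.5 * float(beta @ pen @ beta)
        if abs(obj - prev_obj) < tol:
            return beta, True
        prev_obj = obj
    return beta, False


def logistic_fit(
    choices,
    predictors: pd.DataFrame,
    standardize: bool = True,
    penalty: float = 1e-3,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of choices on model values.

    Fitting is Newton/IRLS to a log-likelihood tolerance of 1e-8; if the fit
    separates or the design is rank-deficient, the model is refit with a
    small quadratic penalty and flagged ``penalized=True``.  A zero-variance
    predictor is an error naming the offending column.
    """
    y = np.asarray(choices, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("choices must be binary 0/1")
    cols = list(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    zero_var = [c for c, s in zip(cols, sd) if s == 0.0]
    if zero_var:
        raise ValueError(f"zero-variance predictor column(s): {zero_var}")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    Xd = np.column_stack([X, np.ones(len(y))])
    cond = float(np.linalg.cond(Xd))
    names = cols + ["const"]

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    rank_deficient = np.linalg.matrix_rank(Xd) < Xd.shape[1]
    beta = None
    converged = False
    penalized = False
    if not rank_deficient:
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, Xd).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
            if res.mle_retvals.get("converged", False) and np.all(
                np.abs(res.params) < 1e3
            ):
                beta, converged = res.params, True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
    if beta is None:
        beta, converged = _ridge_irls(Xd, y, lam=penalty)
        penalized = True
    return LogisticFit(
        coefs=pd.Series(beta, index=names),
        converged=converged,
        penalized=penalized,
        condition_number=cond,
    )


@dataclass
class CohortResult:
    """Group-level summary of per-subject logistic regressions."""

    coefficients: pd.DataFrame  # rows = subjects, columns = predictors + const
    tests: pd.DataFrame  # columns: t, df, p, degenerate per coefficient
    reward_correlation: tuple[float, float]  # (r, two-tailed p) for M1 coef
    total_rewards: pd.Series
    dropped: dict = field(default_factory=dict)


def _one_sample_tests(coefs: pd.DataFrame) -> pd.DataFrame:
    n = len(coefs)
    rows = {}
    for col in coefs.columns:
        x = coefs[col].to_numpy()
        if np.allclose(x.std(ddof=1), 0.0):
            # all subjects identical: t-test degenerates; p = 0 unless mean is 0
            p = 1.0 if np.allclose(x.mean(), 0.0) else 0.0
            rows[col] = {"t": np.inf if p == 0.0 else 0.0, "df": n - 1, "p": p, "degenerate": True}
            continue
        t, p = stats.ttest_1samp(x, 0.0)
        rows[col] = {"t": float(t), "df": n - 1, "p": float(p), "degenerate": False}
    return pd.DataFrame(rows).T


def reward_correlation(coefs, rewards) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between coefficients and total rewards."""
    coefs = np.asarray(coefs, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    if len(coefs) < 3:
        raise ValueError("need at least 3 subjects")
    if coefs.std() == 0 or rewards.std() == 0:
        raise ValueError("correlation undefined for constant vectors")
    r, p = stats.pearsonr(coefs, rewards)
    return float(r), float(p)


def analyze_cohort(
    cohort: list[SubjectDataset],
    models: tuple[str, ...] = MODEL_NAMES,
    correlate: str = "M1",
) -> CohortResult:
    """Per-subject logistic fits plus group t-tests and the reward correlation.

    ``models`` selects the value columns entering each regression (plus a
    constant); pass ``("M1",)`` for the generalization-model-only analysis.
    """
    if len(cohort) < 3:
        raise ValueError("cohort needs at least 3 subjects")
    rows, rewards, dropped = {}, {}, {}
    for subj in cohort:
        try:
            fit = logistic_fit(subj.trials["choice"], subj.values.loc[:, list(models)])
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("subject %s dropped: %s", subj.subject_id, err)
            dropped[subj.subject_id] = str(err)
            continue
        if not fit.converged:
            logger.warning("subject %s dropped: no convergence", subj.subject_id)
            dropped[subj.subject_id] = "no convergence"
            continue
        rows[subj.subject_id] = fit.coefs
        rewards[subj.subject_id] = subj.total_reward
    if len(rows) < 3:
        raise ValueError("fewer than 3 subjects survived fitting")
    coefs = pd.DataFrame(rows).T
    rewards = pd.Series(rewards)
    tests = _one_sample_tests(coefs)
    try:
        corr = reward_correlation(coefs[correlate], rewards.loc[coefs.index])
    except ValueError:  # constant coefficients or rewards
        corr = (float("nan"), float("nan"))
    return CohortResult(
        coefficients=coefs,
        tests=tests,
        reward_correlation=corr,
        total_rewards=rewards,
        dropped=dropped,
    )


def compute_value_streams(
    trials: pd.DataFrame,
    chain_config: dp.DPConfig,
    models=("M1", "M4", "M5"),
    rw_rate: float = 0.3,
) -> dict[str, np.ndarray]:
    """Per-trial purple-value streams for choice-independent models.

    M2/M3 streams (learning rate ``rw_rate``) are included only on request
    since analysis normally re-fits their rates per subject.
    """
    streams: dict[str, np.ndarray] = {}
    for name in models:
        if name == "M1":
            cfg = replace(chain_config, pool_contexts=False)
            streams["M1"] = dp.run_m1_trajectory(trials, cfg)["value"].to_numpy()
        elif name == "M4":
            cfg = replace(chain_config, pool_contexts=True, seed=chain_config.seed + 1)
            streams["M4"] = dp.run_m1_trajectory(trials, cfg)["value"].to_numpy()
        elif name == "M5":
            streams["M5"] = bm.run_m5_trajectory(trials)
        elif name == "M2":
            streams["M2"] = bm.run_m2_trajectory(trials, rw_rate)
        elif name == "M3":
            streams["M3"] = bm.run_m3_trajectory(trials, rw_rate)
        else:
            raise ValueError(f"unknown model {name!r}")
    return streams


def simulate_cohort(
    task_config: tp.TaskConfig | None = None,
    n_subjects: int = 19,
    betas=5.0,
    generating_model: str = "M1",
    chain_config: dp.DPConfig | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
    seed: int = 0,
    trials: pd.DataFrame | None = None,
    streams: dict[str, np.ndarray] | None = None,
) -> list[SubjectDataset]:
    """Simulate a cohort of agents on one shared task realization.

    All subjects experience the same outcome sequence (as in the original
    paradigm) so the model value streams are computed once; each subject's
    guesses are drawn from the generating model's values with its own choice
    precision (``betas`` may be a scalar or one value per subject).  M2/M3
    predictor streams use learning rates re-fit to each subject's own
    choices, mirroring how those free parameters are handled in analysis.
    Precomputed ``trials``/``streams`` may be passed to share one task
    across several cohorts.
    """
    if trials is None:
        trials, _ = tp.generate_task(task_config or tp.TaskConfig(seed=seed))
    chain = chain_config or dp.DPConfig(n_samples=500, burn_in=100, seed=seed)
    need = [
        m for m in dict.fromkeys(list(models) + [generating_model]) if m not in ("M2", "M3")
    ]
    if generating_model in ("M2", "M3"):
        need.append(generating_model)
    streams = dict(streams or {})
    todo = [m for m in need if m not in streams]
    streams.update(compute_value_streams(trials, chain, todo))

    betas = np.broadcast_to(np.asarray(betas, dtype=float), (n_subjects,))
    ss = np.random.SeedSequence(seed, spawn_key=(7,))
    subj_seeds = ss.generate_state(n_subjects) % (2**31)

    cohort = []
    for s in range(n_subjects):
        agent = tp.AgentConfig(
            model_name=generating_model, beta=float(betas[s]), seed=int(subj_seeds[s])
        )
        done = tp.simulate_agent(trials, agent, streams[generating_model])
        vals = {}
        for name in models:
            if name == "M2":
                rate = bm.fit_learning_rate(done, "M2").best_rate
                vals["M2"] = bm.run_m2_trajectory(done, rate)
            elif name == "M3":
                rate = bm.fit_learning_rate(done, "M3").best_rate
                vals["M3"] = bm.run_m3_trajectory(done, rate)
            else:
                vals[name] = streams[name]
        cohort.append(
            SubjectDataset(
                subject_id=f"sub-{s + 1:02d}",
                trials=done,
                values=pd.DataFrame(vals, columns=list(models)),
                total_reward=int(done["reward"].sum()),
            )
        )
    return cohort
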
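"""Bayes-optimal generalization: a Dirichlet-process mixture of Binomial
preference models (M1) and its context-pooling variant (M4).

Each individual (cue) i has a hidden preference theta_i, the probability it
chooses purple.  Observed counts (k_i purple outcomes out of n_i trials) are
Binomial(n_i, theta_i).  The prior over the theta_i is a Dirichlet process
with concentration ``alpha`` and a uniform Beta(1, 1) base distribution, so
cues cluster into hidden subgroups sharing a preference: a new cue joins an
existing atom with probability 1/(m + alpha) per conditioning cue, or draws a
fresh preference with probability alpha/(m + alpha) (the Chinese-restaurant
predictive rule).  Posterior inference is by Gibbs sampling over the joint
theta vector; predictive uncertainty about a new cue — the model's ambiguity
signal — is summarized by the Shannon entropy of binned posterior-predictive
samples.

M1 runs this learner independently within each context; M4 pools all cues
into one meta-population and hence over-generalizes across contexts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaln

from ._gibbs import gibbs_chain

__all__ = [
    "DPConfig",
    "CueCounts",
    "PosteriorEnsemble",
    "NEW",
    "beta_binomial_marginal",
    "crp_predictive_weights",
    "gibbs_sweep",
    "run_chain",
    "shannon_entropy",
    "expected_value",
    "run_m1_trajectory",
    "exact_partition_posterior",
    "TRAJECTORY_COLUMNS",
]

NEW = "NEW"

TRAJECTORY_COLUMNS = [
    "trial",
    "cue_id",
    "context",
    "value",
    "entropy",
    "surprise",
    "prediction_error",
    "risk",
    "n_clusters_mean",
]


@dataclass
class DPConfig:
    """Sampler and model settings for the DP-mixture learner.

    ``concentration`` is the DP concentration parameter alpha (prior
    trade-off between reusing a known subgroup and positing a new one); the
    base distribution is fixed at the uninformative Beta(1, 1).
    ``pool_contexts=False`` gives M1 (independent learning per context),
    ``True`` gives M4 (one meta-population).  ``risk_measure`` selects the
    risk regressor: Bernoulli outcome variance v(1 - v) at the posterior-mean
    preference (default) or the posterior variance of theta itself.
    """

    concentration: float = 1.0
    n_samples: int = 2000
    burn_in: int = 500
    thinning: int = 1
    entropy_bins: int = 10
    pool_contexts: bool = False
    risk_measure: str = "outcome_variance"  # or "posterior_variance"
    seed: int = 0

    def validate(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.burn_in < 0 or self.thinning < 1:
            raise ValueError("burn_in must be >= 0 and thinning >= 1")
        if self.entropy_bins < 1:
            raise ValueError("entropy_bins must be >= 1")
        if self.risk_measure not in ("outcome_variance", "posterior_variance"):
            raise ValueError("unknown risk_measure")


class CueCounts:
    """Per-cue sufficient statistics: k_i purple outcomes out of n_i trials."""

    def __init__(self) -> None:
        self._k: dict[str, int] = {}
        self._n: dict[str, int] = {}
        self._order: list[str] = []

    def observe(self, cue: str, outcome: int) -> None:
        if outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        if cue not in self._k:
            self._k[cue] = 0
            self._n[cue] = 0
            self._order.append(cue)
        self._k[cue] += outcome
        self._n[cue] += 1

    @property
    def cues(self) -> list[str]:
        return list(self._order)

    def counts(self, cue: str) -> tuple[int, int]:
        return self._k.get(cue, 0), self._n.get(cue, 0)

    def arrays(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        cues = self.cues
        k = np.array([self._k[c] for c in cues], dtype=float)
        n = np.array([self._n[c] for c in cues], dtype=float)
        return cues, k, n

    def __len__(self) -> int:
        return len(self._order)


@dataclass
class PosteriorEnsemble:
    """S joint Monte-Carlo draws of the preference vector (theta_1..theta_m)."""

    samples: np.ndarray  # shape (S, m)
    cue_ids: list[str]
    alpha: float
    n_samples: int

    @property
    def n_clusters_per_sample(self) -> np.ndarray:
        if self.samples.shape[1] == 0:
            return np.zeros(self.n_samples, dtype=int)
        srt = np.sort(self.samples, axis=1)
        return 1 + (np.diff(srt, axis=1) > 0).sum(axis=1)

    def predictive_samples(
        self, cue: str = NEW, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Posterior-predictive theta draws for an observed cue or a new one.

        For a new cue each joint sample contributes one draw from the CRP
        predictive: an existing atom with probability 1/(m + alpha) each, a
        fresh Beta(1, 1) draw with probability alpha/(m + alpha).
        """
        if cue != NEW:
            try:
                j = self.cue_ids.index(cue)
            except ValueError:
                raise KeyError(f"cue {cue!r} not in ensemble (use NEW for unseen cues)")
            return self.samples[:, j].copy()
        rng = np.random.default_rng() if rng is None else rng
        S, m = self.samples.shape[0], self.samples.shape[1]
        if m == 0:
            return rng.beta(1.0, 1.0, size=self.n_samples)
        fresh = rng.random(S) < self.alpha / (m + self.alpha)
        cols = rng.integers(0, m, size=S)
        draws = self.samples[np.arange(S), cols]
        draws = np.where(fresh, rng.beta(1.0, 1.0, size=S), draws)
        return draws


def beta_binomial_marginal(k: int, n: int) -> float:
    """Marginal likelihood of k purple outcomes in n trials under Beta(1, 1).

    Closed form C(n, k) * B(k + 1, n - k + 1) = 1 / (n + 1); computed via
    log-gammas for numerical symmetry with the general Beta case.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    log_c = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    return float(math.exp(log_c + betaln(k + 1, n - k + 1)))


def crp_predictive_weights(existing_thetas, alpha: float) -> np.ndarray:
    """Chinese-restaurant predictive weights over existing atoms plus a fresh draw.

    Returns an array of length m + 1: each of the m conditioning cues' atoms
    gets weight 1/(m + alpha); the last entry, alpha/(m + alpha), is the mass
    on a new draw from the base distribution.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    m = len(existing_thetas)
    w = np.full(m + 1, 1.0 / (m + alpha))
    w[m] = alpha / (m + alpha)
    return w


def _chain_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


def gibbs_sweep(
    thetas: np.ndarray,
    counts: CueCounts,
    config: DPConfig,
    seed: int = 0,
    n_sweeps: int = 1,
) -> np.ndarray:
    """Run ``n_sweeps`` full-conditional sweeps from the given state.

    Exposed mainly for inspection/testing; :func:`run_chain` is the usual
    entry point.  Empty state is a no-op.
    """
    config.validate()
    cues, k, n = counts.arrays()
    thetas = np.asarray(thetas, dtype=float)
    if len(cues) == 0:
        return thetas.copy()
    if thetas.shape != (len(cues),):
        raise ValueError("one theta per observed cue required")
    rng = np.random.default_rng(seed)
    state = thetas.copy()
    alpha = config.concentration
    m = len(cues)
    for _ in range(n_sweeps):
        for i in range(m):
            logw = np.full(m + 1, -np.inf)
            logw[m] = math.log(alpha) + math.log(beta_binomial_marginal(int(k[i]), int(n[i]))) - (
                math.lgamma(n[i] + 1) - math.lgamma(k[i] + 1) - math.lgamma(n[i] - k[i] + 1)
            )
            for j in range(m):
                if j == i:
                    continue
                tj = min(max(state[j], 1e-300), 1 - 1e-16)
                logw[j] = k[i] * math.log(tj) + (n[i] - k[i]) * math.log(1 - tj)
            w = np.exp(logw - logw.max())
            w /= w.sum()
            pick = rng.choice(m + 1, p=w)
            if pick == m:
                state[i] = rng.beta(1.0 + k[i], 1.0 + n[i] - k[i])
            else:
                state[i] = state[pick]
    return state


def run_chain(counts: CueCounts, config: DPConfig, seed: int | None = None) -> PosteriorEnsemble:
    """Sample the joint posterior over cue preferences by Gibbs sampling.

    ``burn_in`` sweeps are discarded, then ``n_samples`` states retained every
    ``thinning`` sweeps.  Deterministic given the seed (``config.seed`` unless
    overridden).
    """
    config.validate()
    cues, k, n = counts.arrays()
    s = config.seed if seed is None else seed
    if len(cues) == 0:
        return PosteriorEnsemble(
            samples=np.empty((config.n_samples, 0)),
            cue_ids=[],
            alpha=config.concentration,
            n_samples=config.n_samples,
        )
    samples = gibbs_chain(
        k,
        n,
        config.concentration,
        config.n_samples,
        config.burn_in,
        config.thinning,
        int(s) % (2**31),
    )
    return PosteriorEnsemble(
        samples=samples,
        cue_ids=cues,
        alpha=config.concentration,
        n_samples=config.n_samples,
    )


def shannon_entropy(samples, n_bins: int = 10) -> float:
    """Binned Shannon entropy (nats) of posterior-predictive theta samples.

    Samples are histogrammed into ``n_bins`` equal-width bins on [0, 1]
    (half-open, last bin closed) and H = -sum p_b ln p_b computed with the
    convention 0 ln 0 = 0.  Bounded by ln(n_bins).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot compute entropy of an empty sample")
    if samples.min() < 0 or samples.max() > 1:
        raise ValueError("samples must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, _ = np.histogram(samples, bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / samples.size
    return float(-(p * np.log(p)).sum())


def expected_value(samples) -> float:
    """Posterior-predictive probability of purple: the sample mean of theta."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot average an empty sample")
    return float(samples.mean())


def run_m1_trajectory(trials: pd.DataFrame, config: DPConfig) -> pd.DataFrame:
    """Trial-by-trial predictive value, ambiguity and teaching signals.

    Before each trial the chain is re-run from a fresh state on the counts of
    all outcomes strictly prior to that trial — restricted to the current
    context's cues for M1, or pooled across contexts for M4
    (``config.pool_contexts``).  Per trial the output records:

    - ``value``: posterior-predictive probability the individual chooses
      purple (pre-feedback),
    - ``entropy``: binned Shannon entropy of the predictive theta samples
      (the ambiguity signal, pre-feedback),
    - ``surprise``: -ln of the probability assigned to the realized outcome,
    - ``prediction_error``: realized reward minus the choice-conditioned
      value (NaN where choices are missing),
    - ``risk``: v(1 - v) (or posterior theta variance, per config),
    - ``n_clusters_mean``: mean number of inferred subgroups.
    """
    config.validate()
    if not trials["trial"].is_monotonic_increasing:
        raise ValueError("trials must be ordered by trial index")
    counts_by_scope: dict[str, CueCounts] = {}
    rows = []
    eps = 1e-12
    have_choices = trials["choice"].notna().all() and len(trials) > 0
    for t, row in enumerate(trials.itertuples(index=False)):
        scope = "ALL" if config.pool_contexts else row.context
        counts = counts_by_scope.setdefault(scope, CueCounts())
        ens = run_chain(counts, config, seed=_chain_seed(config.seed, t))
        rng = np.random.default_rng(_chain_seed(config.seed, t, 1))
        k_cue, n_cue = counts.counts(row.cue_id)
        cue_key = row.cue_id if n_cue > 0 else NEW
        theta = ens.predictive_samples(cue_key, rng=rng)
        v = expected_value(theta)
        H = shannon_entropy(theta, config.entropy_bins)
        lam = int(row.outcome)
        p_outcome = v if lam == 1 else 1.0 - v
        surprise = -math.log(max(p_outcome, eps))
        if config.risk_measure == "outcome_variance":
            risk = v * (1.0 - v)
        else:
            risk = float(theta.var())
        if have_choices:
            c = int(row.choice)
            conditioned = v if c == 1 else 1.0 - v
            reward = 1.0 if c == lam else 0.0
            pe = reward - conditioned
        else:
            pe = np.nan
        rows.append(
            {
                "trial": row.trial,
                "cue_id": row.cue_id,
                "context": row.context,
                "value": v,
                "entropy": H,
                "surprise": surprise,
                "prediction_error": pe,
                "risk": risk,
                "n_clusters_mean": float(ens.n_clusters_per_sample.mean())
                if len(counts)
                else 0.0,
            }
        )
        counts.observe(row.cue_id, lam)
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


# ---------------------------------------------------------------------------
# Exact small-m oracle: enumeration over set partitions


def _set_partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield [[first]] + part


def exact_partition_posterior(
    k: np.ndarray, n: np.ndarray, alpha: float
) -> dict:
    """Exact posterior by exhaustive enumeration over set partitions of cues.

    Feasible only for small m (Bell(m) partitions).  Each partition scores
    CRP prior alpha^B * prod (|b| - 1)! / rising(alpha, m) times the product
    of per-block Beta-Binomial marginals.  Returns partition probabilities,
    the co-clustering matrix, per-cue posterior predictive means, the cluster
    -count pmf, and the predictive mean for an unseen cue.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    m = len(k)
    parts = list(_set_partitions(list(range(m))))
    log_scores = []
    for part in parts:
        ls = len(part) * math.log(alpha)
        for block in part:
            ls += math.lgamma(len(block))
            kb, nb = k[block].sum(), n[block].sum()
            # block marginal: prod C(n_i, k_i) * B(kb + 1, nb - kb + 1)
            for i in block:
                ls += (
                    math.lgamma(n[i] + 1)
                    - math.lgamma(k[i] + 1)
                    - math.lgamma(n[i] - k[i] + 1)
                )
            ls += betaln(kb + 1, nb - kb + 1)
        log_scores.append(ls)
    log_scores = np.array(log_scores)
    probs = np.exp(log_scores - log_scores.max())
    probs /= probs.sum()

    cocluster = np.zeros((m, m))
    pred_mean = np.zeros(m)
    n_clusters_pmf: dict[int, float] = {}
    pred_new = 0.0
    for part, p in zip(parts, probs):
        n_clusters_pmf[len(part)] = n_clusters_pmf.get(len(part), 0.0) + p
        new_mass = alpha / (m + alpha) * 0.5
        for block in part:
            kb, nb = k[block].sum(), n[block].sum()
            block_mean = (1 + kb) / (2 + nb)
            for i in block:
                pred_mean[i] += p * block_mean
                for j in block:
                    cocluster[i, j] += p
            new_mass += len(block) / (m + alpha) * block_mean
        pred_new += p * new_mass
    return {
        "partitions": [tuple(frozenset(b) for b in part) for part in parts],
        "probs": probs,
        "cocluster": cocluster,
        "predictive_mean": pred_mean,
        "n_clusters_pmf": n_clusters_pmf,
        "predictive_mean_new": pred_new,
    }
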
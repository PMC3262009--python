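"""Rival learning models: Rescorla-Wagner variants and an independent
Beta-Binomial learner.

All models track the value of guessing purple per cue, with the blue value
tied to its complement (counterfactual coupling: exactly one option is
correct, so every outcome informs the unchosen option too).

- M2: per-face Rescorla-Wagner, V <- V + lr * (outcome - V), V0 = 0.5.
- M3: contextual RW over face *and* group cues; only cues present on a trial
  are updated, and the trial value is the mean of the two present cues'
  values (which keeps values in [0, 1] and the naive prediction at 0.5).
- M5: each cue learned independently with a uniform Beta prior, value
  (1 + k) / (2 + n) — uncertainty without generalization.

Free learning rates for M2/M3 are fit to a subject's guesses by exhaustive
grid search on a squared-error objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rw_update",
    "run_m2_trajectory",
    "run_m3_trajectory",
    "run_m5_trajectory",
    "fit_learning_rate",
    "FitResult",
    "MODEL_REGISTRY",
]


def rw_update(value: float, outcome: int, learning_rate: float) -> float:
    """One delta-rule step: V' = V + lr * (outcome - V)."""
    if not (0.0 <= value <= 1.0):
        raise ValueError("value must lie in [0, 1]")
    if not (0.0 <= learning_rate <= 1.0):
        raise ValueError("learning rate must lie in [0, 1]")
    return value + learning_rate * (outcome - value)


def _grid_values(trials: pd.DataFrame, rates: np.ndarray, contextual: bool) -> np.ndarray:
    """Per-trial purple value for every learning rate at once, shape (T, R)."""
    R = len(rates)
    V: dict[str, np.ndarray] = {}
    out = np.empty((len(trials), R))
    cues = trials["cue_id"].to_numpy()
    ctxs = trials["context"].to_numpy()
    lams = trials["outcome"].to_numpy(dtype=float)
    for t in range(len(trials)):
        face = V.setdefault(cues[t], np.full(R, 0.5))
        if contextual:
            ctx = V.setdefault("CTX:" + ctxs[t], np.full(R, 0.5))
            out[t] = 0.5 * (face + ctx)
            face += rates * (lams[t] - face)
            ctx += rates * (lams[t] - ctx)
        else:
            out[t] = face
            face += rates * (lams[t] - face)
    return out


def run_m2_trajectory(trials: pd.DataFrame, learning_rate: float) -> np.ndarray:
    """Per-trial purple value under per-face RW learning (pre-update)."""
    return _grid_values(trials, np.array([learning_rate]), contextual=False)[:, 0]


def run_m3_trajectory(trials: pd.DataFrame, learning_rate: float) -> np.ndarray:
    """Per-trial purple value under contextual RW (face + group cues)."""
    return _grid_values(trials, np.array([learning_rate]), contextual=True)[:, 0]


def run_m5_trajectory(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial purple value (1 + k) / (2 + n) from the cue's own history."""
    k: dict[str, int] = {}
    n: dict[str, int] = {}
    out = np.empty(len(trials))
    for t, (cue, lam) in enumerate(
        zip(trials["cue_id"].to_numpy(), trials["outcome"].to_numpy())
    ):
        out[t] = (1 + k.get(cue, 0)) / (2 + n.get(cue, 0))
        k[cue] = k.get(cue, 0) + int(lam)
        n[cue] = n.get(cue, 0) + 1
    return out


@dataclass
class FitResult:
    """Grid-search fit of a learning rate to choice data."""

    best_rate: float
    error_curve: dict[float, float]
    grid_step: float


def fit_learning_rate(
    trials: pd.DataFrame, model: str = "M2", grid_step: float = 0.01
) -> FitResult:
    """Fit the RW learning rate by minimizing sum_t (c_t - V_t)^2 on a grid.

    Choices are coded 1 for a purple guess; the grid covers [0, 1] in steps of
    ``grid_step``; ties break toward the smaller rate.
    """
    if model not in ("M2", "M3"):
        raise ValueError("learning-rate fitting applies to M2 or M3")
    if trials["choice"].isna().any():
        raise ValueError("trials must contain choices to fit a learning rate")
    n_steps = int(round(1.0 / grid_step))
    rates = np.linspace(0.0, 1.0, n_steps + 1)
    values = _grid_values(trials, rates, contextual=(model == "M3"))
    c = trials["choice"].to_numpy(dtype=float)[:, None]
    errors = ((c - values) ** 2).sum(axis=0)
    best = int(np.argmin(errors))  # argmin returns the first (smallest) rate on ties
    return FitResult(
        best_rate=float(rates[best]),
        error_curve={float(r): float(e) for r, e in zip(rates, errors)},
        grid_step=grid_step,
    )


#: Where each rival model's values come from (M1/M4 live in dp_generalization).
MODEL_REGISTRY = {
    "M1": "dp_generalization.run_m1_trajectory (pool_contexts=False)",
    "M2": "baseline_models.run_m2_trajectory",
    "M3": "baseline_models.run_m3_trajectory",
    "M4": "dp_generalization.run_m1_trajectory (pool_contexts=True)",
    "M5": "baseline_models.run_m5_trajectory",
}
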
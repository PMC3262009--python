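"""Synthetic two-context preference-guessing task.

Two groups of individuals each complete a block of trials in which a subject
guesses whether the individual will choose ``purple`` or ``blue``.  Every
individual prefers one color and chooses it with a fixed probability.  In the
*generalization context* (GC) all individuals share one preferred color, so
group membership alone predicts a new individual's behavior; in the
*ambiguous context* (AC) the group splits half/half between the two colors,
so group membership is uninformative.  Blocks alternate between the two
contexts, with a fresh individual (cue) per block.

Color coding: purple = 1 everywhere; blue is its complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "AgentConfig",
    "TRIAL_COLUMNS",
    "generate_task",
    "simulate_agent",
    "write_trials",
    "read_trials",
    "write_events",
]

#: Canonical trial-table column order (serialization contract).
TRIAL_COLUMNS = [
    "trial",
    "block",
    "within_block",
    "cue_id",
    "context",
    "outcome",
    "choice",
    "reward",
    "choice_onset",
    "outcome_onset",
]

GC, AC = "GC", "AC"


class TaskConfigError(ValueError):
    """Invalid task configuration."""


class TrialFormatError(ValueError):
    """Malformed trial table on disk."""


@dataclass
class TaskConfig:
    """Parameters of the two-context guessing task.

    Defaults reproduce the study conditions: 2 contexts x 30 individuals x
    10 trials = 600 trials, each individual choosing its preferred color 80%
    of the time, blocks alternating GC/AC starting with GC.
    """

    n_groups: int = 2
    n_individuals_per_group: int = 30
    n_trials_per_individual: int = 10
    preference_prob: float = 0.8
    gc_shared_color: str = "purple"
    outcome_mode: str = "bernoulli"  # or "balanced"
    block_order: str = "alternating"  # or "custom"
    custom_blocks: Sequence[str] | None = None
    iti: float = 4.0  # choice-onset spacing, seconds
    outcome_delay: float = 1.5  # outcome onset relative to choice, seconds
    seed: int = 0

    def validate(self) -> None:
        if not (0.5 < self.preference_prob <= 1.0):
            raise TaskConfigError("preference_prob must lie in (0.5, 1]")
        if self.n_groups not in (1, 2):
            raise TaskConfigError("n_groups must be 1 (GC only) or 2")
        if self.n_groups == 2 and self.n_individuals_per_group % 2:
            raise TaskConfigError(
                "AC requires an even n_individuals_per_group for a half/half split"
            )
        if self.gc_shared_color not in ("purple", "blue"):
            raise TaskConfigError("gc_shared_color must be 'purple' or 'blue'")
        if self.outcome_mode not in ("bernoulli", "balanced"):
            raise TaskConfigError("outcome_mode must be 'bernoulli' or 'balanced'")
        if self.outcome_delay >= self.iti:
            raise TaskConfigError("outcome_delay must be shorter than the ITI")

    @property
    def n_trials(self) -> int:
        return (
            self.n_groups
            * self.n_individuals_per_group
            * self.n_trials_per_individual
        )


@dataclass
class AgentConfig:
    """A simulated subject: which model drives its values and how noisily it acts.

    ``beta`` is the inverse temperature of the sigmoid choice rule; beta = 0
    gives uniform guessing, large beta approaches deterministic choice of the
    higher-valued option.
    """

    model_name: str = "M1"
    beta: float = 5.0
    choice_rule: str = "sigmoid"  # or "matching": P(purple) = value, beta ignored
    model_params: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.beta < 0:
            raise TaskConfigError("choice precision beta must be >= 0")
        if self.choice_rule not in ("sigmoid", "matching"):
            raise TaskConfigError("choice_rule must be 'sigmoid' or 'matching'")


def _make_individuals(config: TaskConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    other = "blue" if config.gc_shared_color == "purple" else "purple"
    for g in range(config.n_groups):
        group = GC if g == 0 else AC
        n = config.n_individuals_per_group
        if group == GC:
            colors = [config.gc_shared_color] * n
        else:
            colors = [config.gc_shared_color] * (n // 2) + [other] * (n // 2)
            colors = list(rng.permutation(colors))
        for i, color in enumerate(colors):
            rows.append(
                {
                    "cue_id": f"{group}{i + 1:02d}",
                    "group": group,
                    "preferred_color": color,
                    "preference_prob": config.preference_prob,
                }
            )
    return pd.DataFrame(rows, columns=["cue_id", "group", "preferred_color", "preference_prob"])


def _block_outcomes(
    config: TaskConfig, p_purple: float, rng: np.random.Generator
) -> np.ndarray:
    n = config.n_trials_per_individual
    if config.outcome_mode == "bernoulli":
        return (rng.random(n) < p_purple).astype(int)
    # balanced: exact preferred-color frequency round(p * n), shuffled order
    n_pref = int(round(config.preference_prob * n))
    pref_is_purple = p_purple >= 0.5
    n_purple = n_pref if pref_is_purple else n - n_pref
    out = np.zeros(n, dtype=int)
    out[:n_purple] = 1
    return rng.permutation(out)


def generate_task(config: TaskConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the trial table and individual roster for one task realization.

    Returns ``(trials, individuals)``.  Choice and reward columns are left
    missing; :func:`simulate_agent` fills them.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_out = (np.random.default_rng(s) for s in ss.spawn(2))
    individuals = _make_individuals(config, rng_assign)

    # Block schedule: alternate contexts, new cue per block.
    per_group = {
        g: list(individuals.loc[individuals["group"] == g, "cue_id"])
        for g in individuals["group"].unique()
    }
    if config.block_order == "alternating":
        order: list[str] = []
        groups = [GC, AC][: config.n_groups]
        for i in range(config.n_individuals_per_group):
            for g in groups:
                order.append(g)
    else:
        if config.custom_blocks is None:
            raise TaskConfigError("block_order='custom' requires custom_blocks")
        order = list(config.custom_blocks)

    pref_lookup = individuals.set_index("cue_id")["preferred_color"].to_dict()
    rows = []
    t = 0
    next_idx = {g: 0 for g in per_group}
    for b, group in enumerate(order):
        cue = per_group[group][next_idx[group]]
        next_idx[group] += 1
        p_purple = (
            config.preference_prob
            if pref_lookup[cue] == "purple"
            else 1.0 - config.preference_prob
        )
        outcomes = _block_outcomes(config, p_purple, rng_out)
        for w, lam in enumerate(outcomes, start=1):
            onset = t * config.iti
            rows.append(
                {
                    "trial": t,
                    "block": b,
                    "within_block": w,
                    "cue_id": cue,
                    "context": group,
                    "outcome": int(lam),
                    "choice": np.nan,
                    "reward": np.nan,
                    "choice_onset": onset,
                    "outcome_onset": onset + config.outcome_delay,
                }
            )
            t += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return trials, individuals


class AlignmentError(ValueError):
    """Value stream does not line up with the trial table."""


def simulate_agent(
    trials: pd.DataFrame,
    agent: AgentConfig,
    model_values: np.ndarray | Sequence[float],
) -> pd.DataFrame:
    """Fill in stochastic guesses and rewards from a per-trial value stream.

    ``model_values[t]`` is the agent's predicted probability that trial t's
    individual chooses purple, evaluated before feedback on that trial (the
    generating model is updated on-line after each outcome; because model
    values depend only on observed outcomes, a precomputed stream is exact).
    The guess is purple with probability sigmoid(beta * (V_purple - V_blue)),
    or with probability V_purple itself for a probability-matching agent.
    """
    agent.validate()
    values = np.asarray(model_values, dtype=float)
    if values.shape != (len(trials),):
        raise AlignmentError(
            f"value stream length {values.shape} does not match {len(trials)} trials"
        )
    if len(values) and (values.min() < 0 or values.max() > 1):
        raise AlignmentError("model values must lie in [0, 1]")
    rng = np.random.default_rng(agent.seed)
    if agent.choice_rule == "matching":
        p_purple = values
    else:
        # V_purple - V_blue = 2v - 1 under counterfactual coupling
        from scipy.special import expit

        p_purple = expit(agent.beta * (2.0 * values - 1.0))
    choices = (rng.random(len(values)) < p_purple).astype(int)
    out = trials.copy()
    out["choice"] = choices
    out["reward"] = (choices == out["outcome"].to_numpy()).astype(int)
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    """Serialize a trial table as TSV; missing choices become empty fields."""
    df = trials.loc[:, TRIAL_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    """Read a TSV trial table, validating columns and binary codes."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"trial table lacks required columns: {missing}")
    for col in ("outcome",):
        bad = df.index[~df[col].isin([0, 1])]
        if len(bad):
            raise TrialFormatError(
                f"non-binary {col!r} code at row {int(bad[0])}"
            )
    for col in ("choice", "reward"):
        present = df[col].notna()
        bad = df.index[present & ~df.loc[present, col].isin([0, 1])]
        if len(bad):
            raise TrialFormatError(
                f"non-binary {col!r} code at row {int(bad[0])}"
            )
    return df.loc[:, TRIAL_COLUMNS]


def write_events(
    trials: pd.DataFrame,
    modulators: pd.DataFrame,
    path,
) -> None:
    """Write a BIDS-style events TSV (onset, duration, trial_type, modulator).

    ``modulators`` is a long-format frame with columns
    ``onset, modulator_name, modulator_value`` (duration 0 delta events).
    """
    ev = modulators.copy()
    ev.insert(1, "duration", 0.0)
    ev.insert(2, "trial_type", ev["modulator_name"])
    ev = ev.loc[:, ["onset", "duration", "trial_type", "modulator_name", "modulator_value"]]
    ev.to_csv(path, sep="\t", index=False)
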
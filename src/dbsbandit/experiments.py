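"""Declarative experiment harness: sweeps, accuracy reports, ensembles.

Reproduces the simulation-study design used to compare optimizers: for each
cell of a sweep (blocksize, trial budget, problem size, state-noise/SNR
level, or discriminability ladder) a number of independent replicates are
run; each replicate draws a fresh synthetic participant, shuffles the
position of the optimal site, runs the closed loop, and records whether the
declared site equals the known optimum.  Accuracy is the fraction of correct
replicates, with a binomial standard error.

Reproducibility contract: every replicate derives its own random generator
from the base seed and its (cell, replicate) position via
``np.random.SeedSequence`` spawn keys, so reports are deterministic under a
fixed base seed and invariant to execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bandits import ALGORITHMS, majority_vote, run_closed_loop
from .pool import SURFACES, ParticipantArchetype, StimProblem, sample_participant

__all__ = [
    "ExperimentConfig",
    "AccuracyReport",
    "snr_db",
    "run_replicate",
    "run_sweep",
    "run_ensemble",
]


def snr_db(b_diff: float, sigma: float) -> float:
    """Signal-to-noise ratio in decibels: ``20*log10(b_diff/sigma)``.

    ``b_diff`` is the gap between the best and second-best site effects
    (log-seconds); ``sigma`` the state-noise standard deviation.
    """
    if b_diff <= 0 or sigma <= 0:
        raise ValueError("b_diff and sigma must be > 0")
    return 20.0 * math.log10(b_diff / sigma)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Declarative sweep specification.

    ``sweep`` chooses the varied axis: ``"blocksize"``, ``"budget"``,
    ``"sites"``, ``"snr"``, ``"discriminability"``, or ``"none"`` (single
    cell).  ``values`` are the sweep values (blocksizes, budgets, problem
    labels, sigma levels, or ladder labels b1-b7); ignored for ``"none"``.
    """

    algorithms: Sequence[str] = ("ucb1", "brute_force")
    replicates: int = 200
    n_trials: int = 600
    blocksize: int = 15
    problem: str = "8-site"
    sweep: str = "none"
    values: Sequence = ()
    ensemble: int = 1
    outcome_mode: str = "sensor"
    base_seed: int = 0
    archetype: ParticipantArchetype = field(default_factory=ParticipantArchetype)
    noise_jitter_sd: float = 0.01   # per-replicate perturbation of overridden sigma

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if self.replicates < 1 or self.n_trials < 1 or self.blocksize < 1 or self.ensemble < 1:
            raise ValueError("all sweep sizes must be positive")
        if self.sweep not in ("none", "blocksize", "budget", "sites", "snr", "discriminability"):
            raise ValueError(f"unknown sweep kind {self.sweep!r}")
        if self.problem not in SURFACES:
            raise ValueError(f"unresolvable problem label {self.problem!r}")
        if self.sweep in ("sites", "discriminability"):
            for v in self.values:
                if v not in SURFACES:
                    raise ValueError(f"unresolvable problem label {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        arch = raw.pop("archetype", None)
        cfg = cls(**raw)
        if arch:
            cfg = replace(cfg, archetype=ParticipantArchetype(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in arch.items()
            }))
        return cfg


@dataclass
class AccuracyReport:
    """Tidy accuracy table: one row per algorithm x sweep cell."""

    frame: pd.DataFrame

    def accuracy(self, algorithm: str, value=None) -> float:
        df = self.frame[self.frame.algorithm == algorithm]
        if value is not None:
            df = df[df.value == value]
        if df.empty:
            raise KeyError((algorithm, value))
        return float(df.accuracy.iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Replicates and sweeps
# ---------------------------------------------------------------------------

def _cell_rng(base_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))


def run_replicate(config: ExperimentConfig, algorithm: str, problem: StimProblem,
                  rng: np.random.Generator, n_trials: Optional[int] = None,
                  blocksize: Optional[int] = None,
                  sigma_override: Optional[float] = None):
    """One accuracy replicate: fresh participant, shuffled optimum, one run
    per ensemble vote (fresh sensor each), hard majority vote."""
    shuffled = problem.shuffled(rng)
    sig = None
    if sigma_override is not None:
        jitter = rng.normal(0.0, config.noise_jitter_sd)
        s = max(sigma_override + jitter, 1e-6)
        sig = (s, s)
    gen = sample_participant(config.archetype, rng, problem=shuffled,
                             sigma_override=sig)
    runs = [
        run_closed_loop(
            gen, shuffled, algorithm,
            n_trials=n_trials or config.n_trials,
            blocksize=blocksize or config.blocksize,
            rng=rng, outcome_mode=config.outcome_mode,
        )
        for _ in range(config.ensemble)
    ]
    voted = majority_vote(runs) if len(runs) > 1 else runs[0].chosen_site
    # for the degenerate (all-equal) problem optimal_site is site 0 by the
    # argmin convention, so accuracy measures pure chance agreement
    correct = voted == shuffled.optimal_site
    return correct, voted, runs


def _cells(config: ExperimentConfig):
    if config.sweep == "none":
        return [None]
    return list(config.values)


def run_sweep(config: ExperimentConfig) -> AccuracyReport:
    """Run the configured sweep and aggregate accuracy per cell.

    Per-replicate failures are logged and excluded, with the failure count
    reported in the ``failures`` column.
    """
    import logging

    log = logging.getLogger(__name__)
    rows = []
    for ai, algorithm in enumerate(config.algorithms):
        for ci, cell in enumerate(_cells(config)):
            n_trials = config.n_trials
            blocksize = config.blocksize
            problem = SURFACES[config.problem]
            sigma_override = None
            if config.sweep == "blocksize":
                blocksize = int(cell)
            elif config.sweep == "budget":
                n_trials = int(cell)
            elif config.sweep in ("sites", "discriminability"):
                problem = SURFACES[cell]
            elif config.sweep == "snr":
                sigma_override = float(cell)

            correct = 0
            failures = 0
            for rep in range(config.replicates):
                rng = _cell_rng(config.base_seed, ai, ci, rep)
                try:
                    ok, _, _ = run_replicate(config, algorithm, problem, rng,
                                             n_trials=n_trials, blocksize=blocksize,
                                             sigma_override=sigma_override)
                except Exception as exc:   # noqa: BLE001 — per-replicate isolation
                    log.warning("replicate %d (%s, %s) failed: %s", rep, algorithm, cell, exc)
                    failures += 1
                    continue
                correct += int(ok)
            n_ok = config.replicates - failures
            p = correct / n_ok if n_ok else float("nan")
            se = math.sqrt(p * (1 - p) / n_ok) if n_ok else float("nan")
            rows.append({
                "algorithm": algorithm,
                "sweep": config.sweep,
                "value": cell,
                "n_trials": n_trials,
                "blocksize": blocksize,
                "problem": problem.label,
                "ensemble": config.ensemble,
                "replicates": n_ok,
                "failures": failures,
                "accuracy": p,
                "se": se,
            })
    return AccuracyReport(pd.DataFrame(rows))


def run_ensemble(config: ExperimentConfig, n_votes: int) -> AccuracyReport:
    """Majority-vote ensemble accuracy: per replicate, one fixed participant
    and ``n_votes`` independent closed-loop runs with fresh sensors."""
    if n_votes < 1:
        raise ValueError("n_votes must be >= 1")
    cfg = replace(config, ensemble=n_votes)
    return run_sweep(cfg)
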
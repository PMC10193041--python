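"""Pools of synthetic participants and session simulation.

Stands in for a pool of state-space models fitted to real task data: each
participant is an independent draw of offset-gamma observation parameters and
state-noise levels from an archetype of plausible ranges, producing MSIT-like
behavior — mean RTs in roughly the 0.3-1.5 s band, an approximately 200 ms
conflict cost, and slow AR(1) drift of the baseline state.

Also provides the stimulation response surfaces (per-site steady-state
effects on ``x_base``, with a 10-fold smaller effect on ``x_conflict``) used
by the optimizer experiments, and the gamma-consistency (KS) validation of
simulated RT output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import GeneratorParams, LatentState, TrialRecord, mean_rt, sample_rt, step_states
from .inference import scale_to_sigma

__all__ = [
    "ParticipantArchetype",
    "StimProblem",
    "SURFACES",
    "sample_participant",
    "simulate_session",
    "ks_gamma_fraction",
    "write_pool",
    "read_pool",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ParticipantArchetype:
    """Ranges from which synthetic participants are drawn.

    Noise is drawn on the logarithmic scale grid (``sigma = (1/sqrt 2)**scale``)
    with the operational ranges [7, 16] for the baseline state and [13, 27]
    for the conflict state; AR coefficients are fixed close to 1.  The
    conflict state is initialized so that high-conflict trials start roughly
    ``conflict_cost_s`` slower than non-conflict trials.
    """

    alpha_range: tuple[float, float] = (0.1, 0.3)
    v_range: tuple[float, float] = (10.0, 40.0)
    b0_range: tuple[float, float] = (math.log(0.4), math.log(0.8))
    sigma1_scale_range: tuple[float, float] = (7.0, 16.0)
    sigma2_scale_range: tuple[float, float] = (13.0, 27.0)
    a1: float = 0.9999
    a2: float = 0.9999
    conflict_cost_s: float = 0.2
    stim_rho: float = 0.7

    def __post_init__(self) -> None:
        for lo, hi in (self.sigma1_scale_range, self.sigma2_scale_range):
            if lo < 1 or hi > 40 or lo > hi:
                raise ValueError("scale ranges must lie within [1, 40]")


@dataclass
class StimProblem:
    """A response surface: per-site steady-state effects on ``x_base``.

    The optimal site is the one with the most negative effect (largest RT
    reduction).  ``b_diff`` is the gap between the best and second-best site.
    """

    effects: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.size < 1:
            raise ValueError("a problem needs at least one site")

    @property
    def n_sites(self) -> int:
        return int(self.effects.size)

    @property
    def optimal_site(self) -> int:
        return int(np.argmin(self.effects))

    @property
    def degenerate(self) -> bool:
        return bool(np.all(self.effects == self.effects[0])) and self.n_sites > 1

    @property
    def b_diff(self) -> float:
        s = np.sort(self.effects)
        return float(s[1] - s[0])

    def shuffled(self, rng: np.random.Generator) -> "StimProblem":
        """Return a copy with the site order randomly permuted."""
        return StimProblem(self.effects[rng.permutation(self.n_sites)], self.label)


#: Response surfaces used across experiments: the multi-site problems, the
#: two-site discriminability ladder b1-b7 (b7 degenerate), and the large
#: "bss" contrast used only for settling-time demonstrations.
SURFACES: dict[str, StimProblem] = {
    "8-site": StimProblem([0, -0.005, -0.01, -0.02, -0.03, -0.031, -0.04, -0.07], "8-site"),
    "6-site": StimProblem([0, -0.005, -0.01, -0.02, -0.04, -0.07], "6-site"),
    "4-site": StimProblem([0, -0.005, -0.01, -0.04], "4-site"),
    "2-site": StimProblem([-0.01, -0.04], "2-site"),
    "b1": StimProblem([0.05, -0.05], "b1"),
    "b2": StimProblem([0.0, -0.10], "b2"),
    "b3": StimProblem([0.0, -0.05], "b3"),
    "b4": StimProblem([0.0, -0.03], "b4"),
    "b5": StimProblem([0.0, -0.02], "b5"),
    "b6": StimProblem([0.0, -0.01], "b6"),
    "b7": StimProblem([0.0, 0.0], "b7"),
    "bss": StimProblem([0.25, -0.25], "bss"),
}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sample_participant(archetype: ParticipantArchetype, rng: np.random.Generator,
                       problem: Optional[StimProblem] = None,
                       sigma_override: Optional[tuple[float, float]] = None) -> GeneratorParams:
    """Draw one synthetic participant.

    Observation parameters are uniform over the archetype ranges; state-noise
    sigmas come from uniformly drawn logarithmic scales (or are overridden
    directly); the simulated state starts at zero baseline with
    ``x0_conflict`` set so the initial conflict cost is about
    ``archetype.conflict_cost_s`` seconds.  If a ``problem`` is given its
    effects become the per-site stimulation inputs.
    """
    alpha = rng.uniform(*archetype.alpha_range)
    v = rng.uniform(*archetype.v_range)
    b0 = rng.uniform(*archetype.b0_range)
    if sigma_override is not None:
        sigma1, sigma2 = (max(float(s), 0.0) for s in sigma_override)
    else:
        sigma1 = scale_to_sigma(rng.uniform(*archetype.sigma1_scale_range))
        sigma2 = scale_to_sigma(rng.uniform(*archetype.sigma2_scale_range))
    # The simulated state starts at zero baseline: a fitted generator's level
    # is absorbed into b0 (only b0 + x_base is observable), so the state
    # itself carries no arbitrary constant.  N(0,1) initial conditions belong
    # to model *fitting* (em_fit / fit_sensor), not to the simulated start.
    x0_base = 0.0
    base_mu = math.exp(b0 + x0_base)
    x0_conflict = math.log1p(archetype.conflict_cost_s / base_mu)

    params = GeneratorParams(
        alpha_offset=alpha, v=v, b0=b0, sigma1=sigma1, sigma2=sigma2,
        a1=archetype.a1, a2=archetype.a2, stim_rho=archetype.stim_rho,
        x0_base=x0_base, x0_conflict=x0_conflict,
    )
    if problem is not None:
        params = params.with_effects(problem.effects)
    return params


def simulate_session(gen: GeneratorParams,
                     schedule: Sequence[Optional[int]],
                     rng: np.random.Generator,
                     conflict: Optional[Sequence[int]] = None,
                     noise: bool = True,
                     state: Optional["LatentState"] = None) -> list[TrialRecord]:
    """Simulate a full session under a per-trial stimulation schedule.

    ``schedule`` gives the active site per trial (None = no stimulation).
    Conflict indicators are Bernoulli(0.5) unless a fixed sequence is given.
    Ground-truth latent states are recorded on every trial.  Pass
    ``noise=False`` for a deterministic state rollout (RTs are still gamma
    draws unless the caller also fixes them).
    """
    n_trials = len(schedule)
    if conflict is not None and len(conflict) != n_trials:
        raise ValueError("conflict sequence length must match schedule")
    if state is None:
        state = gen.initial_state()
    coeffs = (gen.b0, gen.b1, gen.b2)
    out: list[TrialRecord] = []
    for k in range(n_trials):
        state = step_states(state, gen, schedule[k], rng if noise else None)
        I = int(conflict[k]) if conflict is not None else int(rng.random() < 0.5)
        mu = mean_rt(state, I, coeffs)
        rt = sample_rt(mu, gen.v, gen.alpha_offset, rng)
        out.append(TrialRecord(k=k, I_conflict=I, site=schedule[k], rt=rt, truth=state))
    return out


def ks_gamma_fraction(archetype: ParticipantArchetype, n_runs: int, n_trials: int,
                      rng: np.random.Generator,
                      rts_fn=None) -> float:
    """Fraction of simulated runs whose RTs are gamma-consistent.

    Per run: simulate ``n_trials`` trials with random conflict indicators and
    no stimulation, fit a shifted gamma by maximum likelihood, and run a
    one-sample KS test of the RTs against the fitted distribution; a run
    passes when p > 0.05.  ``rts_fn(run_index, rng) -> array`` can replace
    the simulation (e.g. to check the test's power on non-gamma input).
    """
    if n_runs <= 0:
        raise ValueError("n_runs must be >= 1")
    if n_trials < 100:
        raise ValueError("n_trials must be >= 100")
    passes = 0
    for i in range(n_runs):
        if rts_fn is not None:
            rts = np.asarray(rts_fn(i, rng), dtype=float)
        else:
            gen = sample_participant(archetype, rng)
            trials = simulate_session(gen, [None] * n_trials, rng)
            rts = np.array([t.rt for t in trials])
        if np.ptp(rts) == 0:
            raise ValueError("degenerate constant RT input")
        shape, loc, scale = stats.gamma.fit(rts)
        p = stats.kstest(rts, "gamma", args=(shape, loc, scale)).pvalue
        if p > 0.05:
            passes += 1
    return passes / n_runs


# ---------------------------------------------------------------------------
# Pool serialization (JSON lines)
# ---------------------------------------------------------------------------

def write_pool(path, pool: Sequence[GeneratorParams], seed: Optional[int] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pool:
            rec = {
                "alpha_offset": p.alpha_offset, "v": p.v, "b0": p.b0,
                "b1": p.b1, "b2": p.b2, "a1": p.a1, "a2": p.a2,
                "sigma1": p.sigma1, "sigma2": p.sigma2,
                "b_in_base": p.b_in_base.tolist(),
                "b_in_conflict": p.b_in_conflict.tolist(),
                "stim_rho": p.stim_rho,
                "x0_base": p.x0_base, "x0_conflict": p.x0_conflict,
            }
            if seed is not None:
                rec["seed"] = seed
            fh.write(json.dumps(rec) + "\n")


def read_pool(path) -> list[GeneratorParams]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            rec.pop("seed", None)
            out.append(GeneratorParams(**rec))
    return out
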
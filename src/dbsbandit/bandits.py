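"""Site-selection algorithms and block-wise closed-loop execution.

Selecting the best stimulation contact during a monopolar survey is treated
as a multi-armed bandit over discrete sites, in minimization convention
(lower RT = better).  Implemented policies:

``brute_force``
    Round-robin equal allocation across sites (the clinical-survey baseline).
``greedy`` / ``eps_greedy``
    Exploit the site with the lowest mean outcome; epsilon-greedy explores a
    random site with probability ``eps`` (default 0.1).
``ucb1``
    ``Q(u) = mean(u) - sqrt(2 ln T / N(u))``; pick argmin.
``bayes_ucb``
    Gamma(alpha, beta) hyperparameters; ``mu = alpha/beta``,
    ``sigma = alpha/beta**2``; score ``mu - c * sigma / sqrt(N(u))`` with
    ``c = 1.96`` (95% confidence); pick argmin.
``ts_bernoulli`` / ``ts_poisson`` / ``ts_normal`` / ``c_ts``
    Thompson sampling: one posterior draw per site, best draw wins.

Block outcomes are mapped to a success/failure reward by the threshold rule:
the observed outcome is compared against ``RT_val``, which is the previous
block's outcome when the site just changed, and otherwise the minimum mean
outcome among the *other* sites.  ``outcome < RT_val`` counts as success.

All Bayesian policies start from weakly-informative hyperparameters made
proper by a forced-exploration phase in which every site is selected once
(in seeded random order) before the policy takes control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import GeneratorParams, TrialRecord, mean_rt, sample_rt, step_states
from .pool import StimProblem
from .sensor import SensorState, fit_sensor, sensor_step

__all__ = [
    "ALGORITHMS",
    "BanditState",
    "BlockOutcome",
    "RunResult",
    "select_site",
    "update_state",
    "forced_exploration",
    "run_closed_loop",
    "majority_vote",
]

ALGORITHMS = (
    "brute_force", "greedy", "eps_greedy", "ucb1", "bayes_ucb",
    "ts_bernoulli", "ts_poisson", "ts_normal", "c_ts",
)


@dataclass
class BlockOutcome:
    """Outcome of one block: the mean tracked expected-RT over its trials."""

    block: int
    site: int
    value: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("block outcome must be > 0")


@dataclass
class BanditState:
    """Per-site statistics and conjugate hyperparameters for any policy."""

    n_sites: int
    rng: np.random.Generator
    eps: float = 0.1
    c: float = 1.96
    counts: np.ndarray = field(init=False)
    sums: np.ndarray = field(init=False)
    # conjugate hyperparameters (policy-specific interpretation)
    gam_a: np.ndarray = field(init=False)   # gamma shape   (bayes_ucb, ts_poisson, ts_normal)
    gam_b: np.ndarray = field(init=False)   # gamma rate
    beta_a: np.ndarray = field(init=False)  # beta successes (ts_bernoulli)
    beta_b: np.ndarray = field(init=False)  # beta failures
    mu_z: np.ndarray = field(init=False)    # normal mean    (c_ts)
    k_z: np.ndarray = field(init=False)     # normal pseudo-count
    T: int = 0
    last_site: Optional[int] = None
    last_outcome: Optional[float] = None
    forced_order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        m = self.n_sites
        self.counts = np.zeros(m, dtype=int)
        self.sums = np.zeros(m)
        self.gam_a = np.full(m, 0.5)
        self.gam_b = np.full(m, 0.5)
        self.beta_a = np.ones(m)
        self.beta_b = np.ones(m)
        self.mu_z = np.full(m, np.nan)   # set to first observation per site
        self.k_z = np.zeros(m)
        self.forced_order = self.rng.permutation(m)

    @property
    def means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.counts > 0, self.sums / np.maximum(self.counts, 1), np.inf)

    @property
    def exploration_done(self) -> bool:
        return bool(np.all(self.counts >= 1))


def forced_exploration(state: BanditState) -> np.ndarray:
    """The seeded random order in which each site is selected exactly once
    before algorithmic control begins."""
    return state.forced_order.copy()


def select_site(state: BanditState, algorithm: str) -> int:
    """Select the next site under the given policy (minimization convention).

    During the forced-exploration phase (some site still unselected) every
    policy except brute force emits the next site of the forced order.
    Ties break toward the lowest site index (argmin convention).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    m = state.n_sites
    rng = state.rng

    if algorithm == "brute_force":
        return int(state.forced_order[state.T % m])

    if not state.exploration_done:
        return int(state.forced_order[state.T])

    means = state.means
    if algorithm == "greedy":
        return int(np.argmin(means))
    if algorithm == "eps_greedy":
        if rng.random() < state.eps:
            return int(rng.integers(m))
        return int(np.argmin(means))
    if algorithm == "ucb1":
        bonus = np.sqrt(2.0 * math.log(max(state.T, 2)) / state.counts)
        return int(np.argmin(means - bonus))
    if algorithm == "bayes_ucb":
        mu = state.gam_a / state.gam_b
        sigma = state.gam_a / state.gam_b ** 2
        score = mu - state.c * sigma / np.sqrt(state.counts)
        return int(np.argmin(score))
    if algorithm == "ts_bernoulli":
        draws = rng.beta(state.beta_a, state.beta_b)
        return int(np.argmax(draws))     # draw = success probability; higher is better
    if algorithm == "ts_poisson":
        draws = rng.gamma(state.gam_a, 1.0 / state.gam_b)
        return int(np.argmin(draws))
    if algorithm == "ts_normal":
        tau = rng.gamma(state.gam_a, 1.0 / state.gam_b)
        draws = rng.normal(means, 1.0 / np.sqrt(np.maximum(tau, 1e-12)))
        return int(np.argmin(draws))
    if algorithm == "c_ts":
        mu = np.where(np.isnan(state.mu_z), means, state.mu_z)
        draws = rng.normal(mu, 1.0 / np.sqrt(1.0 + state.k_z))
        return int(np.argmin(draws))
    raise AssertionError("unreachable")


def _rt_val(state: BanditState, site: int) -> float:
    """Threshold against which the new outcome is judged a success."""
    if state.last_site is None:
        return math.inf
    if site != state.last_site:
        return float(state.last_outcome)
    others = [u for u in range(state.n_sites) if u != site and state.counts[u] > 0]
    if not others:
        return float(state.last_outcome)
    means = state.means
    return float(min(means[u] for u in others))


def update_state(state: BanditState, site: int, outcome: BlockOutcome,
                 algorithm: str) -> BanditState:
    """Fold one block outcome into the bandit statistics.

    Computes the threshold ``RT_val``, maps the outcome to a success
    (``outcome < RT_val``) or failure, and applies the policy's conjugate
    update; running counts/means are maintained for every policy.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if outcome.site != site:
        raise ValueError("outcome does not belong to the selected site")
    rt = float(outcome.value)
    rt_val = _rt_val(state, site)
    success = rt < rt_val
    r = 1.0 if success else 0.0

    if algorithm in ("bayes_ucb", "ts_normal"):
        mu_site = state.means[site] if state.counts[site] > 0 else rt
        if not success:                         # RT >= threshold
            state.gam_a[site] += outcome.n_trials / 2.0
        else:                                   # RT < threshold
            state.gam_b[site] += (rt - mu_site) ** 2 / 2.0
    elif algorithm == "ts_bernoulli":
        state.beta_a[site] += r
        state.beta_b[site] += 1.0 - r
    elif algorithm == "ts_poisson":
        if not success:
            state.gam_a[site] += rt
        else:
            state.gam_b[site] += 1.0 - r
    elif algorithm == "c_ts":
        if np.isnan(state.mu_z[site]):
            state.mu_z[site] = rt
            state.k_z[site] = 1.0
        else:
            state.mu_z[site] = (state.mu_z[site] * state.k_z[site] + rt) / (state.k_z[site] + 1.0)
            state.k_z[site] += 1.0

    state.counts[site] += 1
    state.sums[site] += rt
    state.T += 1
    state.last_site = site
    state.last_outcome = rt
    return state


# ---------------------------------------------------------------------------
# Closed loop
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of one closed-loop optimization run."""

    chosen_site: int
    correct: bool
    outcomes: list[BlockOutcome]
    site_means: np.ndarray
    algorithm: str
    optimal_site: int
    estimate_trace: Optional[np.ndarray] = None   # per-trial sensor baseline-RT
    truth_trace: Optional[np.ndarray] = None      # per-trial true x_base
    bandit: Optional[BanditState] = None          # terminal bandit statistics

    def votes(self) -> int:
        return self.chosen_site


def run_closed_loop(gen: GeneratorParams,
                    problem: StimProblem,
                    algorithm: str,
                    n_trials: int,
                    blocksize: int,
                    rng: np.random.Generator,
                    outcome_mode: str = "sensor",
                    sensor_fit_trials: int = 64,
                    sensor: Optional[SensorState] = None,
                    keep_traces: bool = False) -> RunResult:
    """Run one full closed-loop optimization against a simulated participant.

    A sensor is first fitted to ``sensor_fit_trials`` stimulation-free trials
    from the generator (unless one is supplied).  Then, per block: the policy
    selects a site, the generator simulates ``blocksize`` trials under that
    site, each RT passes through the sensor, the block outcome is the mean of
    the sensor's baseline expected-RT over the block (``outcome_mode="raw"``
    uses the mean raw RT instead), and the bandit is updated.  After the trial
    budget the declared winner is the site with the lowest mean outcome.
    """
    m = problem.n_sites
    if gen.n_sites != m:
        gen = gen.with_effects(problem.effects)
    n_blocks = n_trials // blocksize
    if n_blocks < m:
        raise ValueError("trial budget too small for forced exploration")
    if outcome_mode not in ("sensor", "raw"):
        raise ValueError("outcome_mode must be 'sensor' or 'raw'")

    state = gen.initial_state()
    if sensor is None:
        warmup: list[TrialRecord] = []
        coeffs = (gen.b0, gen.b1, gen.b2)
        for k in range(sensor_fit_trials):
            state = step_states(state, gen, None, rng)
            I = int(rng.random() < 0.5)
            rt = sample_rt(mean_rt(state, I, coeffs), gen.v, gen.alpha_offset, rng)
            warmup.append(TrialRecord(k, I, None, rt))
        sensor = fit_sensor(warmup, rng)

    bandit = BanditState(n_sites=m, rng=rng)
    coeffs = (gen.b0, gen.b1, gen.b2)
    outcomes: list[BlockOutcome] = []
    est_trace = [] if keep_traces else None
    truth_trace = [] if keep_traces else None

    for blk in range(n_blocks):
        site = select_site(bandit, algorithm)
        vals = np.empty(blocksize)
        for j in range(blocksize):
            state = step_states(state, gen, site, rng)
            I = int(rng.random() < 0.5)
            rt = sample_rt(mean_rt(state, I, coeffs), gen.v, gen.alpha_offset, rng)
            sensor, est = sensor_step(sensor, rt, I)
            vals[j] = est.baseline_rt if outcome_mode == "sensor" else rt
            if keep_traces:
                est_trace.append(est.baseline_rt)
                truth_trace.append(state.x_base)
        outcome = BlockOutcome(block=blk, site=site, value=float(vals.mean()),
                               n_trials=blocksize)
        update_state(bandit, site, outcome, algorithm)
        outcomes.append(outcome)

    site_means = bandit.means
    chosen = int(np.argmin(site_means))
    return RunResult(
        chosen_site=chosen,
        correct=(chosen == problem.optimal_site),
        outcomes=outcomes,
        site_means=np.asarray(site_means),
        algorithm=algorithm,
        optimal_site=problem.optimal_site,
        estimate_trace=np.array(est_trace) if keep_traces else None,
        truth_trace=np.array(truth_trace) if keep_traces else None,
        bandit=bandit,
    )


def majority_vote(results: Sequence[RunResult]) -> int:
    """Hard majority vote over the declared sites of repeated runs.

    Ties break toward the site with the lower pooled mean outcome across all
    runs' blocks.
    """
    if len(results) == 0:
        raise ValueError("need at least one run result")
    n_sites = results[0].site_means.size
    counts = np.zeros(n_sites, dtype=int)
    pooled_sum = np.zeros(n_sites)
    pooled_n = np.zeros(n_sites, dtype=int)
    for r in results:
        counts[r.chosen_site] += 1
        for o in r.outcomes:
            pooled_sum[o.site] += o.value
            pooled_n[o.site] += 1
    top = np.flatnonzero(counts == counts.max())
    if top.size == 1:
        return int(top[0])
    with np.errstate(invalid="ignore"):
        pooled_mean = np.where(pooled_n > 0, pooled_sum / np.maximum(pooled_n, 1), np.inf)
    return int(top[np.argmin(pooled_mean[top])])
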
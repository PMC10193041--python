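"""Online stimulation-blind tracker of the latent cognitive state.

The sensor plays the role of the real-time estimator that would run on a
patient's RT stream: it is fitted by EM to an initial block of data (with no
knowledge of stimulation), then filtered trial-by-trial to produce the
smoothed expected-RT / baseline-state estimate consumed by the optimizers.

Two deliberate asymmetries versus the generator: the RT offset (the model's
lower bound on RT) is held at 0.1 s rather than estimated — free estimation
of a shifted-gamma threshold on one task block is degenerate (it creeps to
the block minimum, and later RTs fall below it), while 0.1 s is a floor no
plausible human RT undercuts — and the assumed state-noise sigmas are
inflated by 0.0625 (the sigma at logarithmic scale 8) so that the
stimulation-blind filter adapts faster when stimulation forces the state
away from its default AR(1) drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import GeneratorParams, TrialRecord
from .inference import FitSpec, GammaStateFilter, em_fit, scale_to_sigma

__all__ = ["SensorState", "SensorEstimate", "fit_sensor", "sensor_step", "nrmse",
           "SENSOR_SIGMA_INFLATION"]

#: Added to both drawn state-noise sigmas (the sigma at scale 8).
SENSOR_SIGMA_INFLATION = 0.0625

#: Scale ranges from which the sensor's assumed state noise is drawn
#: (narrower for the baseline state than the generator's range).
SENSOR_SIGMA1_SCALES = (7.0, 12.0)
SENSOR_SIGMA2_SCALES = (13.0, 27.0)


@dataclass
class SensorEstimate:
    """Per-trial sensor output."""

    expected_rt: float       # E[rt] for the trial as presented (with conflict)
    baseline_rt: float       # E[rt] at I_conflict = 0 — the optimizer signal
    x_base: float
    x_conflict: float


@dataclass
class SensorState:
    """Fitted observation parameters plus the running filtered belief."""

    params: GeneratorParams
    sigma_drawn: tuple[float, float]
    m: np.ndarray                 # filtered mean (2,)
    P: np.ndarray                 # filtered covariance entries (p11, p12, p22)
    k: int = 0                    # trials consumed
    converged: bool = True

    def __post_init__(self) -> None:
        self._filter = GammaStateFilter.from_params(self.params)

    @property
    def x_base(self) -> float:
        return float(self.m[0])

    def snapshot(self) -> dict:
        """JSON-serializable snapshot for run resumption."""
        p = self.params
        return {
            "alpha_offset": p.alpha_offset, "v": p.v, "b0": p.b0,
            "sigma1": p.sigma1, "sigma2": p.sigma2,
            "sigma_drawn": list(self.sigma_drawn),
            "m": self.m.tolist(), "P": self.P.tolist(), "k": self.k,
        }


def fit_sensor(initial_trials: Sequence[TrialRecord], rng: np.random.Generator,
               em_tol: float = 0.001, max_iter: int = 50) -> SensorState:
    """Fit a sensor to an initial block of trials.

    Runs the reduced EM with the sensor constraints: the RT offset held at
    0.1 s, state-noise sigmas drawn from the sensor scale ranges and inflated
    by 0.0625, initial state drawn from N(0, 1).
    """
    if len(initial_trials) == 0:
        raise ValueError("initial_trials must be nonempty")
    s1 = scale_to_sigma(rng.uniform(*SENSOR_SIGMA1_SCALES))
    s2 = scale_to_sigma(rng.uniform(*SENSOR_SIGMA2_SCALES))
    spec = FitSpec(
        sigma1=s1 + SENSOR_SIGMA_INFLATION,
        sigma2=s2 + SENSOR_SIGMA_INFLATION,
        alpha_lo=0.1, alpha_fixed=0.1, em_tol=em_tol, max_iter=max_iter,
    )
    res = em_fit(initial_trials, spec, rng=rng)
    traj = res.trajectory
    m = traj.filtered_mean[-1].copy()
    # carry the full filtered covariance forward
    filt = GammaStateFilter.from_params(res.params)
    s = (res.params.x0_base, res.params.x0_conflict, spec.x0_var, 0.0, spec.x0_var)
    for tr in initial_trials:
        s = filt.predict(s)
        s, _ = filt.update(s, tr.rt, tr.I_conflict, on_invalid="clip")
    P = np.array([s[2], s[3], s[4]])
    m = np.array([s[0], s[1]])
    return SensorState(params=res.params, sigma_drawn=(s1, s2), m=m, P=P,
                       k=len(initial_trials), converged=res.converged)


def sensor_step(sensor: SensorState, rt: float, I_conflict: int) -> tuple[SensorState, SensorEstimate]:
    """One predict+update step of the stimulation-blind filter.

    Returns the updated sensor (mutated in place) and the trial estimate.
    RTs at or below the fitted offset are handled by clipping the update
    innovation (logged), not by crashing.
    """
    filt = sensor._filter
    s = (sensor.m[0], sensor.m[1], sensor.P[0], sensor.P[1], sensor.P[2])
    s = filt.predict(s)
    s, _ = filt.update(s, rt, I_conflict, on_invalid="clip")
    sensor.m[0], sensor.m[1] = s[0], s[1]
    sensor.P[0], sensor.P[1], sensor.P[2] = s[2], s[3], s[4]
    sensor.k += 1
    est = SensorEstimate(
        expected_rt=filt.expected_rt(s, I_conflict),
        baseline_rt=filt.expected_rt(s, 0),
        x_base=s[0],
        x_conflict=s[1],
    )
    return sensor, est


def nrmse(truth: Sequence[float], estimate: Sequence[float]) -> float:
    """Gain-invariant tracking error.

    Each series is rescaled multiplicatively to [-1, 1] by dividing by its
    own maximum absolute value, then the RMSE of the difference is taken.  A
    pure gain error therefore scores 0.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape or t.size < 2:
        raise ValueError("series must have equal length >= 2")
    tmax = np.abs(t).max()
    emax = np.abs(e).max()
    if tmax == 0 or emax == 0:
        raise ValueError("all-zero series: rescale undefined")
    d = t / tmax - e / emax
    return float(np.sqrt(np.mean(d ** 2)))
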
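"""Synthetic single-cell ERK-activity trace ensembles.

Emulates the three ligand response classes seen in KTR reporter experiments:

* class 1 — transient pulse: ``f1(s) = (s/tau_r) * exp(1 - s/tau_r)``
  (unit peak at ``s = tau_r``),
* class 2 — prolonged but waning: ``f2(s) = exp(-s/tau_decay) * (1 - exp(-s/tau_r))``,
* class 3 — sustained plateau: ``f3(s) = 1 - exp(-s/tau_r)``,
* class 0 — non-inducer: no response.

Each cell responds with probability ``p(dose) = pmax / (1 + (ec50/dose)**hill)``
(logistic in log-dose).  A responder's noiseless activity is
``baseline + A * f_class(t - treatment_time)`` with a per-cell amplitude
``A`` drawn from a gamma distribution with mean ``amplitude_mean`` and
coefficient of variation ``amplitude_cv``.  After MEK-inhibitor addition all
activity relaxes exponentially (tau = 12 min) to ``meki_floor``.  Measurement
noise is additive Gaussian per frame (optionally AR(1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ..schedule import AcquisitionSchedule
from ..traces import TraceSet

__all__ = ["SimParams", "TraceGroundTruth", "simulate_trace_ensemble",
           "class_shape", "MEKI_TAU"]

#: relaxation time constant (min) of ERK activity after MEK inhibition
MEKI_TAU = 12.0

# per-class default rise/decay constants (min); invented, illustrative only
_CLASS_TAUS = {1: (18.0, None), 2: (12.0, 240.0), 3: (30.0, None)}


@dataclass
class SimParams:
    """Parameters of a simulated trace ensemble for one condition."""

    response_class: Literal[0, 1, 2, 3] = 3
    baseline_level: float = 1.0
    amplitude_mean: float = 1.5
    amplitude_cv: float = 0.2
    tau_rise: float | None = None      # min; class default if None
    tau_decay: float | None = None     # min; class default if None
    responder_pmax: float = 0.8
    responder_ec50: float = 10.0       # ng/mL
    responder_hill: float = 1.0
    noise_sigma: float = 0.1
    noise_ar1: float = 0.0             # AR(1) coefficient; 0 = iid
    meki_floor: float = 0.2
    n_cells: int = 500
    dose: float = 100.0                # ng/mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_class not in (0, 1, 2, 3):
            raise ValueError("response_class must be 0, 1, 2 or 3")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 <= self.responder_pmax <= 1:
            raise ValueError("responder_pmax must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.baseline_level <= 0 or self.meki_floor <= 0:
            raise ValueError("baseline_level and meki_floor must be positive")
        if self.meki_floor >= self.baseline_level:
            raise ValueError("meki_floor must be below baseline_level")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.response_class in _CLASS_TAUS:
            tr, td = _CLASS_TAUS[self.response_class]
            if self.tau_rise is None:
                self.tau_rise = tr
            if self.tau_decay is None:
                self.tau_decay = td
        if self.tau_rise is not None and self.tau_rise <= 0:
            raise ValueError("tau_rise must be positive")

    @property
    def responder_probability(self) -> float:
        """p(dose) under the logistic dose–response model; 0 for class 0."""
        if self.response_class == 0 or self.responder_pmax == 0:
            return 0.0
        return self.responder_pmax / (
            1.0 + (self.responder_ec50 / self.dose) ** self.responder_hill)


@dataclass
class TraceGroundTruth:
    """Truth paired with a simulated ensemble."""

    responder: np.ndarray          # (n_cells,) bool
    amplitude: np.ndarray          # (n_cells,) true A (0 for non-responders)
    noiseless: np.ndarray          # (n_cells, n_frames) noise-free activity
    responder_probability: float


def class_shape(s: np.ndarray, response_class: int, tau_rise: float,
                tau_decay: float | None = None) -> np.ndarray:
    """Unit response shape ``f_class`` evaluated at ``s`` minutes post-ligand.

    Zero for ``s < 0`` and for class 0.
    """
    s = np.asarray(s, dtype=float)
    f = np.zeros_like(s)
    pos = s > 0
    sp = s[pos]
    if response_class == 1:
        f[pos] = (sp / tau_rise) * np.exp(1.0 - sp / tau_rise)
    elif response_class == 2:
        if tau_decay is None:
            raise ValueError("class 2 requires tau_decay")
        f[pos] = np.exp(-sp / tau_decay) * (1.0 - np.exp(-sp / tau_rise))
    elif response_class == 3:
        f[pos] = 1.0 - np.exp(-sp / tau_rise)
    elif response_class != 0:
        raise ValueError(f"unknown response class {response_class}")
    return f


def _apply_meki(activity: np.ndarray, schedule: AcquisitionSchedule,
                floor: float) -> np.ndarray:
    """Relax all activity exponentially to the floor after MEKi addition."""
    t = schedule.times
    after = t >= schedule.meki_time
    if not after.any():
        return activity
    i0 = int(np.argmax(after))
    elapsed = t[after] - schedule.meki_time
    decay = np.exp(-elapsed / MEKI_TAU)
    a0 = activity[:, i0][:, None]  # value at the moment of MEKi addition
    activity[:, after] = floor + (a0 - floor) * decay[None, :]
    return activity


def simulate_trace_ensemble(
        params: SimParams,
        schedule: AcquisitionSchedule | None = None,
        condition: str = "sim",
) -> tuple[TraceSet, TraceGroundTruth]:
    """Simulate an ensemble of single-cell ERK-activity traces.

    Returns the traces on the schedule's frame grid together with the
    ground truth (responder flags, true amplitudes, noiseless traces).
    """
    if schedule is None:
        schedule = AcquisitionSchedule()
    rng = np.random.default_rng(params.seed)
    t = schedule.times
    n, m = params.n_cells, len(t)

    p = params.responder_probability
    responder = rng.random(n) < p
    amplitude = np.zeros(n)
    n_resp = int(responder.sum())
    if n_resp and params.amplitude_cv > 0:
        k = 1.0 / params.amplitude_cv ** 2
        amplitude[responder] = rng.gamma(
            k, params.amplitude_mean / k, size=n_resp)
    elif n_resp:
        amplitude[responder] = params.amplitude_mean

    noiseless = np.full((n, m), params.baseline_level)
    if n_resp:
        f = class_shape(t - schedule.treatment_time, params.response_class,
                        params.tau_rise, params.tau_decay)
        noiseless[responder] += amplitude[responder][:, None] * f[None, :]
    noiseless = _apply_meki(noiseless, schedule, params.meki_floor)

    if params.noise_sigma > 0:
        eps = rng.normal(0.0, params.noise_sigma, size=(n, m))
        if params.noise_ar1 > 0:
            rho = params.noise_ar1
            # stationary AR(1) with marginal sd = noise_sigma
            innov = eps * np.sqrt(1.0 - rho ** 2)
            innov[:, 0] = eps[:, 0]
            for j in range(1, m):
                innov[:, j] += rho * innov[:, j - 1]
            eps = innov
        activity = noiseless + eps
    else:
        activity = noiseless.copy()

    traces = TraceSet.from_matrix(activity, schedule, condition=condition,
                                  dose_ng_ml=params.dose)
    truth = TraceGroundTruth(responder=responder, amplitude=amplitude,
                             noiseless=noiseless, responder_probability=p)
    return traces, truth
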
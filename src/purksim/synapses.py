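"""Climbing-fiber and parallel-fiber event trains and dual-exponential
conductance synapses.

CF input makes 17 synchronous contacts of 1 uS on the most proximal smooth
compartments at 1 Hz; PF input makes one asynchronous (Poisson) contact of
0.0005 uS on every spiny compartment around a mean rate of 100 Hz.  Both
use the same dual-exponential waveform (tau1 = 0.5 ms rise, tau2 = 1.2 ms
decay, reversal 0 mV), peak-normalised so that a single event reaches the
stated conductance (the NEURON Exp2Syn convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, SynapseConfig


@dataclass(frozen=True)
class SynapseSpec:
    target_compartment: int
    g_syn: float                  # uS
    e_rev: float = 0.0            # mV
    tau1: float = 0.5             # ms
    tau2: float = 1.2             # ms

    def __post_init__(self) -> None:
        if not (self.tau2 > self.tau1 > 0):
            raise ConfigurationError("require tau2 > tau1 > 0")
        if self.g_syn <= 0:
            raise ConfigurationError("g_syn must be positive")

    @property
    def peak_time(self) -> float:
        """Time to peak of a single event, ms (closed form)."""
        t1, t2 = self.tau1, self.tau2
        return t1 * t2 / (t2 - t1) * math.log(t2 / t1)

    @property
    def norm(self) -> float:
        """Peak normalisation so one event tops out at g_syn."""
        tp = self.peak_time
        return 1.0 / (math.exp(-tp / self.tau2) - math.exp(-tp / self.tau1))


@dataclass
class EventTrain:
    synapse: SynapseSpec
    event_times: np.ndarray       # ms, strictly increasing
    source: str = "CF"            # "CF" | "PF"
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
            raise ConfigurationError("event times must be strictly increasing")
        self.event_times = t


def make_cf_trains(freq: float, t_start: float, t_end: float,
                   smooth_ids: list[int], n_contacts: int = 17,
                   cfg: SynapseConfig | None = None) -> list[EventTrain]:
    """Synchronous periodic CF trains on the n most proximal smooth
    compartments."""
    cfg = cfg or SynapseConfig()
    if freq <= 0:
        raise ConfigurationError("CF frequency must be positive")
    if len(smooth_ids) < n_contacts:
        raise ConfigurationError(
            f"need {n_contacts} smooth compartments, have {len(smooth_ids)}")
    period = 1000.0 / freq
    times = np.arange(t_start, t_end, period)
    return [
        EventTrain(SynapseSpec(cid, cfg.cf_g, cfg.e_rev, cfg.tau1, cfg.tau2),
                   times.copy(), source="CF")
        for cid in sorted(smooth_ids)[:n_contacts]
    ]


def make_pf_trains(rate: float, t_end: float, seed: int,
                   spiny_ids: list[int],
                   cfg: SynapseConfig | None = None) -> list[EventTrain]:
    """Independent homogeneous-Poisson PF trains, one per spiny
    compartment, reproducible from a master seed."""
    cfg = cfg or SynapseConfig()
    if rate < 0:
        raise ConfigurationError("PF rate must be non-negative")
    master = np.random.SeedSequence(seed)
    trains = []
    for cid, child in zip(sorted(spiny_ids), master.spawn(len(spiny_ids))):
        rng = np.random.default_rng(child)
        if rate == 0:
            times = np.empty(0)
        else:
            n_expect = int(rate * t_end / 1000.0 * 3 + 50)
            gaps = rng.exponential(1000.0 / rate, size=n_expect)
            times = np.cumsum(gaps)
            while times[-1] < t_end:   # pragma: no cover - rare refill
                extra = np.cumsum(rng.exponential(1000.0 / rate, size=n_expect))
                times = np.concatenate([times, times[-1] + extra])
            times = times[times < t_end]
        trains.append(EventTrain(
            SynapseSpec(cid, cfg.pf_g, cfg.e_rev, cfg.tau1, cfg.tau2),
            times, source="PF", seed=seed))
    return trains


def synaptic_conductance(spec: SynapseSpec, events: EventTrain,
                         t: float) -> float:
    """Summed dual-exponential conductance at time t, uS."""
    past = events.event_times[events.event_times <= t]
    if len(past) == 0:
        return 0.0
    dt = t - past
    g = np.exp(-dt / spec.tau2) - np.exp(-dt / spec.tau1)
    return float(spec.g_syn * spec.norm * np.sum(g))


def synaptic_current(spec: SynapseSpec, events: EventTrain, t: float,
                     v: float) -> tuple[float, float]:
    """(current nA, conductance uS) at time t and voltage v.

    i = g * (v - e_rev); uS * mV = nA.  Returned alongside g so the CF
    r-trigger can read the synaptic current magnitude.
    """
    g = synaptic_conductance(spec, events, t)
    return g * (v - spec.e_rev), g


def export_trains(trains: list[EventTrain], path) -> None:
    """Two-column text export (synapse id, time ms) for replay."""
    with open(path, "w") as fh:
        for i, tr in enumerate(trains):
            for t in tr.event_times:
                fh.write(f"{i}\t{t:.6f}\n")
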
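"""Somatic Na+/K+ pump electrogenesis and lagged Na+ accumulation.

The pump current is a sigmoid of intracellular Na+ with midpoint 40 mM and
unit slope; its density (0.04 mA/cm^2) caps the net outward charge.  The
3:2 stoichiometry makes the Na+ branch 3*i_pump and the K+ branch
-2*i_pump.  Intracellular Na+ integrates the *lagged* difference between
resurgent-channel influx and pump efflux: the net current entering the
accumulation equation at time t is the one recorded tau = 5 s earlier,
a phenomenological stand-in for slow diffusion from channel mouths to the
pump's fuzzy space.  [Na+]i is floored at 10 mM and E_Na at +70 mV.

Sign convention: membrane currents are outward-positive, so channel influx
(i_na_r < 0) raises [Na+]i and pump efflux (+3*i_pump) lowers it:
d[Na]/dt = -(i_na_r + i_pump_na) * 4e4 / (d * F) mM/ms, d in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import ConfigurationError, PumpConfig
from .constants import FARADAY

#: mA/cm^2 -> mM/ms for a cylinder of diameter d um (volume/area = d/4).
NA_ACCUM_FACTOR = 4e4


@njit(cache=True)
def pump_current_kernel(na_i, density, na_half, na_slope):
    return density / (1.0 + np.exp((na_half - na_i) / na_slope))


def pump_current(na_i: float, density: float = 0.04, na_half: float = 40.0,
                 na_slope: float = 1.0) -> float:
    """Net pump current, mA/cm^2 (outward positive, hyperpolarising)."""
    if na_i <= 0:
        raise ValueError("na_i must be positive")
    return float(pump_current_kernel(na_i, density, na_half, na_slope))


@njit(cache=True)
def na_accumulation_rate(i_na_r, i_pump_na, d_soma, scale):
    """d[Na+]i/dt in mM/ms from the two somatic Na+ currents (mA/cm^2)."""
    return -(i_na_r + i_pump_na) * NA_ACCUM_FACTOR * scale / (d_soma * FARADAY)


@dataclass
class PumpSodiumState:
    """Pump currents, lagged-influx FIFO and the Na+ concentration."""

    cfg: PumpConfig = field(default_factory=PumpConfig)
    dt: float = 0.025
    na_i: float = 10.0
    e_na: float = 70.0
    i_pump: float = 0.0
    i_pump_na: float = 0.0
    i_pump_k: float = 0.0
    delay_buffer: np.ndarray | None = None
    _head: int = 0

    def __post_init__(self) -> None:
        self.na_i = self.cfg.na_init
        n = int(round(self.cfg.tau_lag / self.dt))
        if n <= 0:
            raise ConfigurationError("tau_lag must exceed dt")
        if self.delay_buffer is None:
            self.delay_buffer = np.empty(n)
            self._primed = False
        elif len(self.delay_buffer) != n:
            raise ConfigurationError(
                f"delay buffer length {len(self.delay_buffer)} != tau/dt = {n}")
        else:
            self._primed = True
        self._update_pump()

    def _update_pump(self) -> None:
        self.i_pump = pump_current(self.na_i, self.cfg.density,
                                   self.cfg.na_half, self.cfg.na_slope)
        self.i_pump_na = 3.0 * self.i_pump
        self.i_pump_k = -2.0 * self.i_pump

    def prime(self, i_na_r: float) -> None:
        """Warm-start the FIFO with the current net Na current, avoiding a
        spurious tau-long transient from a zero-filled buffer."""
        self.delay_buffer[:] = i_na_r + self.i_pump_na
        self._primed = True


def step_na_i(state: PumpSodiumState, i_na_r_now: float, dt: float,
              d_soma: float) -> PumpSodiumState:
    """Push the instantaneous net Na current, pop the tau-old one, advance
    [Na+]i, refresh pump currents and apply the floors."""
    if abs(dt - state.dt) > 1e-12:
        raise ConfigurationError("dt changed after delay-buffer allocation")
    if not state._primed:
        state.prime(i_na_r_now)
    buf = state.delay_buffer
    lagged = buf[state._head]
    buf[state._head] = i_na_r_now + state.i_pump_na
    state._head = (state._head + 1) % len(buf)

    state.na_i += dt * na_accumulation_rate(
        lagged, 0.0, d_soma, state.cfg.na_accum_scale)
    if state.na_i < state.cfg.na_floor:
        state.na_i = state.cfg.na_floor
    if state.e_na < state.cfg.e_na_floor:
        state.e_na = state.cfg.e_na_floor
    state._update_pump()
    return state
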
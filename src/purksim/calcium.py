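"""Intracellular Ca2+ systems and the CF-triggered SK control switches.

Three shell systems coexist:

* soma: single shell, linear decay (beta = 1/ms) toward zero with a 100 nM
  floor, fed by the P-type GHK current;
* spiny dendrites: shell with saturable extrusion kt*ca/(ca+kd) and first
  order relaxation toward a *fixed* set point y = 4e-5 mM;
* smooth dendrites: the same structure but with a *floating* set point y
  that itself accumulates Ca influx slowly and relaxes toward a fixed
  anchor z = 2.4e-4 mM.  The accumulation rate of y is divided by a gain
  g, and its relaxation time is tau_m; both switch between a default pair
  (1e5, 100 ms) and a CF pair (1e4, 1000 ms) under control of the trigger
  variable w.  A second trigger variable r enables the smooth-dendrite SK
  conductance (from its 1e-7 S/cm^2 resting value to the protocol's g_sk)
  after a climbing-fiber synaptic event.

Inward membrane currents are negative; Ca influx therefore corresponds to
ica < 0 and the clamped "chan" term zeroes any outward contribution.
All concentrations are mM, currents mA/cm^2, times ms, depths/diameters um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from numba import njit

from .config import CalciumConfig
from .constants import FARADAY

#: mA/cm^2 / (F * um) -> mM/ms for a shell of given depth (divalent ion).
SHELL_FACTOR = 1e4

#: Unit factor of the floating-set-point influx term
#: dy/dt = |ica| * Y_UNIT_FACTOR / (4 * g * d * F), d in um.  The printed
#: grouping of this term does not determine its units; this value is the
#: package's calibrated reading (see methods note), overridable through
#: CalciumConfig.y_influx_scale.
Y_UNIT_FACTOR = 1e5


@njit(cache=True)
def chan_influx(ica, depth):
    """Clamped shell influx, mM/ms: -(1e4)*ica/(2*F*depth), floored at 0."""
    chan = -(SHELL_FACTOR * ica) / (2.0 * FARADAY * depth)
    if chan < 0.0:
        chan = 0.0
    return chan


@njit(cache=True)
def soma_ca_step(ca, ica, dt, beta, depth, floor):
    """Explicit soma-shell update with decay beta and concentration floor."""
    dca = -(SHELL_FACTOR * ica) / (2.0 * FARADAY * depth) - beta * ca
    ca = ca + dt * dca
    if ca < floor:
        ca = floor
    return ca


@njit(cache=True)
def pool_ca_step(ca, ica, y, dt, kt, kd, tau_r, depth):
    """Explicit dendritic-shell update (spiny, and smooth inner pool)."""
    dca = chan_influx(ica, depth) - kt * ca / (ca + kd) + (y - ca) / tau_r
    ca = ca + dt * dca
    if ca < 1e-12:
        ca = 1e-12
    return ca


@njit(cache=True)
def y_step(y, ica, dt, g, tau_m, z, diameter, y_unit):
    """Floating set point update: influx term (sign-handled so Ca entry,
    ica < 0, raises y) plus first-order relaxation toward z."""
    influx = abs(min(ica, 0.0)) * y_unit / (4.0 * g * diameter * FARADAY)
    return y + dt * (influx + (z - y) / tau_m)


@njit(cache=True)
def switch_step(val, triggered, dt, decay_tau):
    """One w/r switch update: reset to 1 on trigger, else exponential decay."""
    if triggered:
        return 1.0
    return val * math.exp(-dt / decay_tau)


@dataclass
class SomaCaShell:
    """Somatic sub-membrane Ca2+ shell."""

    ca: float = 1e-4
    beta: float = 1.0
    depth: float = 0.1
    floor: float = 1e-4


def step_soma_ca(state: SomaCaShell, i_ca: float, dt: float) -> SomaCaShell:
    state.ca = soma_ca_step(state.ca, i_ca, dt, state.beta, state.depth,
                            state.floor)
    return state


@dataclass
class SpinyCaState:
    """Spiny-dendrite Ca2+ shell with a fixed set point."""

    ca: float = 4e-5
    kt: float = 4e-5
    kd: float = 4e-5
    tau_r: float = 2.0
    y: float = 4e-5
    depth: float = 0.1


def step_spiny_ca(state: SpinyCaState, i_ca: float, dt: float) -> SpinyCaState:
    state.ca = pool_ca_step(state.ca, i_ca, state.y, dt, state.kt,
                            state.kd, state.tau_r, state.depth)
    return state


@dataclass
class SmoothCaState:
    """Smooth-dendrite layered Ca2+ system with floating set point and
    the w (set-point kinetics) and r (SK enable) CF switches."""

    ca: float = 4e-5
    y: float = 2.4e-4
    w: float = 0.0
    r: float = 0.0
    depth: float = 0.1
    cfg: CalciumConfig = field(default_factory=CalciumConfig)
    gsk_protocol: float = 0.72       # S/cm^2 applied while r > threshold

    @property
    def g(self) -> float:
        return self.cfg.g_cf if self.w > self.cfg.switch_on \
            else self.cfg.g_default

    @property
    def tau_m_y(self) -> float:
        return self.cfg.tau_m_cf if self.w > self.cfg.switch_on \
            else self.cfg.tau_m_default

    @property
    def gsk_live(self) -> float:
        return self.gsk_protocol if self.r > self.cfg.switch_on \
            else self.cfg.gsk_off


def step_smooth_ca(state: SmoothCaState, i_ca: float, d: float,
                   dt: float) -> SmoothCaState:
    """Advance the inner pool and the floating set point over one step.

    ``i_ca`` is the summed CaT + CaE + CaP current of the compartment and
    ``d`` its diameter (um).  The live (g, tau_m) pair is read from the
    current w switch state.
    """
    c = state.cfg
    state.ca = pool_ca_step(state.ca, i_ca, state.y, dt, c.smooth_kt,
                            c.smooth_kd, c.tau_r, state.depth)
    state.y = y_step(state.y, i_ca, dt, state.g, state.tau_m_y, c.z, d,
                     Y_UNIT_FACTOR)
    return state


def update_w(state: SmoothCaState, i_ca: float, dt: float) -> SmoothCaState:
    """w trigger: a large *inward* Ca current (|i_ca| above threshold with
    i_ca < 0) resets w to 1, prolonging the CF (g, tau_m) pair."""
    trig = (i_ca < 0.0) and (abs(i_ca) > state.cfg.w_threshold)
    state.w = switch_step(state.w, trig, dt, state.cfg.f)
    return state


def update_r(state: SmoothCaState, i_syn_cf: float, dt: float) -> SmoothCaState:
    """r trigger: CF synaptic current magnitude above 3 nA resets r to 1,
    enabling the protocol SK conductance."""
    trig = abs(i_syn_cf) > state.cfg.r_threshold_nA
    state.r = switch_step(state.r, trig, dt, state.cfg.s)
    return state
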
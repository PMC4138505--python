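"""Hodgkin-Huxley-style currents of soma and dendrite.

Two channel families coexist:

* Somatic channels (fast/mid/slow TEA-class K+, BK, P-type Ca GHK, I_h,
  leak) carry their voltage dependence as (m_inf, tau) pairs whose printed
  time constants are in seconds; they are converted to milliseconds here.
  Printed steady states of the form ``1/exp(x)`` are read as the Boltzmann
  sigmoid ``1/(1+exp(x))``, the only reading that keeps gates in [0, 1].
* Dendritic channels (CaT/CaE/CaP, I_h, A/M/D/DR K+, BK, K2, SK) carry
  (alpha, beta) rate pairs in 1/ms, combined through
  m_inf = a/(a+b), tau = 1/((a+b)*mt) with the temperature factor
  mt = 3^((T-37)/10) where the printed update includes it.

Several dendritic gates advance with an extra dimensionless factor inside
the update exponent (printed channel-specific constants: CaE m x4, CaE h
x10, D-type m x10, D-type h x k with k = 0.1 by default).  That factor is
the ``rate_scale`` argument of :func:`gate_update`; it is equivalent to
dividing the time constant.

All gate functions are numba-compiled scalars so the same code serves unit
tests and the simulation kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from numba import njit

from .constants import CONSTANTS, FARADAY, GAS_CONSTANT, GHK_TEMP_K

MT = CONSTANTS.mt      # 3^((36-37)/10)
FT = CONSTANTS.ft      # 2.3^((36-36)/10) = 1
RT_SK = GAS_CONSTANT * (CONSTANTS.temp_c + 273.15)   # R*(T+273.15), T in C

# Fixed concentrations seen by the somatic GHK flux (mol/cm^3).
GHK_CA_I = 1e-10       # 100 nM
GHK_CA_O = 2e-6        # 2 mM
GHK_P_CA = 5e-5        # cm/s

# --------------------------------------------------------------------------
# gate identifiers (indices into the kernel's gate state matrix)
# --------------------------------------------------------------------------
(G_KF_M, G_KF_H, G_KMID_M, G_KSLOW_M, G_CAPS_M, G_IHS_M,
 G_BKS_M, G_BKS_H, G_BKS_Z,
 G_CAT_M, G_CAT_H, G_CAE_M, G_CAE_H, G_CAPD_M, G_IHD_M,
 G_KA_M, G_KA_H, G_KM_M, G_KD_M, G_KD_H, G_DR_M,
 G_BKD_M, G_BKD_Z, G_K2_M, G_K2_Z, G_SK_M) = range(26)

N_GATES = 26


@njit(cache=True)
def _sexp(x):
    """Overflow-protected exponential."""
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return math.exp(x)


@njit(cache=True)
def gate_inf_tau(gate_id, v, ca):
    """Steady state and time constant (ms) of one gate law.

    ``ca`` (mM) is read only by the Ca-dependent gates (BK z, K2 z, SK m).
    Somatic time constants are converted from their native seconds.
    Temperature factors are folded into tau; the printed channel-specific
    rate factors are *not* (they travel as ``rate_scale``).
    """
    if gate_id == G_KF_M:
        inf = 1.0 / (1.0 + _sexp(-(v + 24.0) / 15.4))
        if v < -35.0:
            tau = 0.000103 + 0.0149 * _sexp(0.035 * v)
        else:
            tau = 0.000129 + 1.0 / (_sexp((v + 100.7) / 12.9)
                                    + _sexp(-(v - 56.0) / 23.1))
        return inf, tau * 1000.0
    elif gate_id == G_KF_H:
        inf = 0.31 + 0.69 / (1.0 + _sexp((v + 5.8) / 11.2))
        if v <= 0.0:
            a = (v + 56.3) / 49.6
            tau = 1.22e-5 + 0.012 * _sexp(-a * a)
        else:
            tau = 0.0012 + 0.0023 * _sexp(-0.141 * v)
        return inf, tau * 1000.0
    elif gate_id == G_KMID_M:
        inf = 1.0 / (1.0 + _sexp(-(v + 24.0) / 20.4))
        if v < -20.0:
            tau = 0.000688 + 1.0 / (_sexp((v + 64.2) / 6.5)
                                    + _sexp(-(v - 141.5) / 34.8))
        else:
            tau = 0.00016 + 0.0008 * _sexp(-0.0267 * v)
        return inf, tau * 1000.0
    elif gate_id == G_KSLOW_M:
        inf = 1.0 / (1.0 + _sexp(-(v + 16.5) / 18.4))
        tau = 0.000796 + 1.0 / (_sexp((v + 73.2) / 11.7)
                                + _sexp(-(v - 306.7) / 74.2))
        return inf, tau * 1000.0
    elif gate_id == G_CAPS_M:
        inf = 1.0 / (1.0 + _sexp(-(v + 19.0) / 5.5))
        if v <= -50.0:
            tau = 0.000264 + 0.128 * _sexp(0.103 * v)
        else:
            a = (v + 11.9) / 27.8
            tau = 0.000191 + 0.00376 * _sexp(-a * a)
        return inf, tau * 1000.0
    elif gate_id == G_IHS_M:
        inf = 1.0 / (1.0 + _sexp((v + 90.1) / 9.9))
        a = (v + 81.5) / 11.9
        tau = 0.19 + 0.72 * _sexp(-a * a)
        return inf, tau * 1000.0
    elif gate_id == G_BKS_M:
        inf = 1.0 / (1.0 + _sexp(-(v + 28.9) / 6.2))
        tau = 0.000505 + 1.0 / (_sexp((v + 86.4) / 10.1)
                                + _sexp(-(v - 33.3) / 10.0))
        return inf, tau * 1000.0
    elif gate_id == G_BKS_H:
        inf = 0.085 + 0.915 / (1.0 + _sexp((v + 32.0) / 5.8))
        tau = 0.0019 + 1.0 / (_sexp((v + 48.5) / 5.2)
                              + _sexp(-(v - 54.2) / 12.9))
        return inf, tau * 1000.0
    elif gate_id == G_BKS_Z:
        # z_inf = 1/(1 + 0.001/[Ca]) with [Ca] in mM; tau_z = 1 ms
        inf = 1.0 / (1.0 + 0.001 / ca)
        return inf, 1.0
    elif gate_id == G_CAT_M:
        a = 2.6 / (1.0 + _sexp(-(v + 21.0) / 8.0))
        b = 0.18 / (1.0 + _sexp((v + 40.0) / 4.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_CAT_H:
        a = 0.0025 / (1.0 + _sexp((v + 40.0) / 8.0))
        b = 0.19 / (1.0 + _sexp(-(v + 50.0) / 10.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_CAE_M:
        a = 2.6 / (1.0 + _sexp(-(v + 7.0) / 8.0))
        b = 0.18 / (1.0 + _sexp((v + 26.0) / 4.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_CAE_H:
        a = 0.0025 / (1.0 + _sexp((v + 32.0) / 8.0))
        b = 0.19 / (1.0 + _sexp(-(v + 42.0) / 10.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_CAPD_M:
        a = 8.5 / (1.0 + _sexp(-(v - 8.0) / 12.5))
        b = 35.0 / (1.0 + _sexp((v + 74.0) / 14.5))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_IHD_M:
        inf = 1.0 / (1.0 + _sexp((v + 84.1) / 10.2))
        tau = 1.0 / (_sexp(-17.9 - 0.116 * v)
                     + _sexp(-1.84 + 0.09 * v)) + 100.0
        return inf, tau
    elif gate_id == G_KA_M:
        a = 1.4 / (1.0 + _sexp(-(v + 27.0) / 12.0))
        b = 0.49 / (1.0 + _sexp((v + 30.0) / 4.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_KA_H:
        a = 0.00175 / (1.0 + _sexp((v + 50.0) / 8.0))
        b = 0.49 / (1.0 + _sexp(-(v + 13.0) / 10.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_KM_M:
        inf = 1.0 / (1.0 + _sexp(-(v + 35.0) / 10.0))
        tau = (1000.0 / FT) / (3.3 * (_sexp((v + 35.0) / 40.0)
                                      + _sexp(-(v + 35.0) / 20.0)))
        return inf, tau
    elif gate_id == G_KD_M:
        a = 8.5 / (1.0 + _sexp(-(v + 17.0) / 12.5))
        b = 35.0 / (1.0 + _sexp((v + 99.0) / 14.5))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_KD_H:
        a = 0.0015 / (1.0 + _sexp((v + 89.0) / 8.0))
        b = 0.0055 / (1.0 + _sexp(-(v + 83.0) / 8.0))
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_DR_M:
        x = -(v + 55.0) / 10.0
        if abs(x) < 1e-6:
            vtrap = 10.0 * (1.0 - x / 2.0)
        else:
            vtrap = -(v + 55.0) / (_sexp(x) - 1.0)
        a = 0.1 * vtrap
        b = 0.125 * _sexp(-(v + 65.0) / 80.0)
        return a / (a + b), 1.0 / ((a + b) * MT)
    elif gate_id == G_BKD_M:
        a = 7.5
        b = 0.11 * _sexp(-(v - 35.0) / 14.9)
        return a / (a + b), 1.0 / (a + b)          # no temperature factor
    elif gate_id == G_BKD_Z:
        # beta_z = 400/(1000*[Ca]) -> z_inf = 1/(1 + 0.4/[Ca]); tau = 10 ms
        inf = 1.0 / (1.0 + 0.4 / ca)
        return inf, 10.0
    elif gate_id == G_K2_M:
        a = 25.0
        b = 0.075 * _sexp(-(v + 5.0) / 10.0)
        return a / (a + b), 1.0 / (a + b)
    elif gate_id == G_K2_Z:
        # beta_z = 20/(1000*[Ca]) -> z_inf = 1/(1 + 0.02/[Ca]); tau = 10 ms
        inf = 1.0 / (1.0 + 0.02 / ca)
        return inf, 10.0
    else:  # G_SK_M  (Moczydlowski-Latorre, Ca- and V-dependent)
        e1 = _sexp(-2.0 * 0.84 * FARADAY * (v * 1e-3) / RT_SK)
        a = 0.48 / (1.0 + 0.18 * e1 / ca)
        e2 = _sexp(-2.0 * 1.0 * FARADAY * (v * 1e-3) / RT_SK)
        b = 0.28 / (1.0 + ca / (0.011 * e2))
        return a / (a + b), 1.0 / (a + b)


@njit(cache=True)
def gate_update(state, inf, tau, dt, rate_scale=1.0):
    """Exponential-Euler gate advance over one step.

    new = state + (inf - state) * (1 - exp(-dt*rate_scale/tau)); clipped to
    [0, 1] against round-off.
    """
    out = state + (inf - state) * (-math.expm1(-dt * rate_scale / tau))
    if out < 0.0:
        out = 0.0
    elif out > 1.0:
        out = 1.0
    return out


@njit(cache=True)
def ghk_flux(v):
    """Somatic GHK Ca2+ flux, mA/cm^2, at fixed concentrations and 295 K.

    De-singularised at v = 0 by the analytic limit 2*P*F*(ca_i - ca_o).
    """
    u = -2.0 * FARADAY * (v * 1e-3) / (GAS_CONSTANT * GHK_TEMP_K)
    if abs(u) < 1e-12:
        return 2.0 * GHK_P_CA * FARADAY * (GHK_CA_I - GHK_CA_O) * 1e3
    em1 = math.expm1(u)
    num = GHK_CA_I - GHK_CA_O * (1.0 + em1)
    front = 4.0 * GHK_P_CA * (v * 1e-3) * FARADAY * FARADAY \
        / (GAS_CONSTANT * GHK_TEMP_K)
    return front * num / (-em1) * 1e3


# --------------------------------------------------------------------------
# data-driven channel catalog
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GateLaw:
    """One gate of one current: law id, power in the product, update factor."""

    name: str
    gate_id: int
    exponent: int
    rate_scale: float = 1.0
    ca_dependent: bool = False


@dataclass(frozen=True)
class ChannelSpec:
    """One current: zone, reversal handling, and its gate product."""

    name: str
    zone: str                      # "soma" | "dendrite" | "smooth"
    reversal: str                  # "ek" | "eca" | "eh" | "el" | "ena" | "ghk"
    gates: tuple[GateLaw, ...] = field(default_factory=tuple)


def _g(name, gid, exp, scale=1.0, ca=False):
    return GateLaw(name, gid, exp, scale, ca)


#: Every HH-style current of the model.  (The Markov resurgent Na+ current
#: and the leak currents are not gate products and live elsewhere.)
CHANNEL_CATALOG: tuple[ChannelSpec, ...] = (
    ChannelSpec("k_fast", "soma", "ek",
                (_g("m", G_KF_M, 3), _g("h", G_KF_H, 1))),
    ChannelSpec("k_mid", "soma", "ek", (_g("m", G_KMID_M, 4),)),
    ChannelSpec("k_slow", "soma", "ek", (_g("m", G_KSLOW_M, 4),)),
    ChannelSpec("bk", "soma", "ek",
                (_g("m", G_BKS_M, 3), _g("z", G_BKS_Z, 2, ca=True),
                 _g("h", G_BKS_H, 1))),
    ChannelSpec("ca_p", "soma", "ghk", (_g("m", G_CAPS_M, 1),)),
    ChannelSpec("ih", "soma", "eh", (_g("m", G_IHS_M, 1),)),
    ChannelSpec("ca_t", "dendrite", "eca",
                (_g("m", G_CAT_M, 1), _g("h", G_CAT_H, 1))),
    ChannelSpec("ca_e", "dendrite", "eca",
                (_g("m", G_CAE_M, 1, scale=4.0),
                 _g("h", G_CAE_H, 1, scale=10.0))),
    ChannelSpec("ca_p", "dendrite", "eca", (_g("m", G_CAPD_M, 1),)),
    ChannelSpec("ih", "dendrite", "eh", (_g("m", G_IHD_M, 1),)),
    ChannelSpec("k_a", "dendrite", "ek",
                (_g("m", G_KA_M, 4), _g("h", G_KA_H, 1))),
    ChannelSpec("k_m", "dendrite", "ek", (_g("m", G_KM_M, 1),)),
    ChannelSpec("k_d", "dendrite", "ek",
                (_g("m", G_KD_M, 1, scale=10.0),
                 _g("h", G_KD_H, 1, scale=0.1))),   # h scale = k, config
    ChannelSpec("k_dr", "dendrite", "ek", (_g("m", G_DR_M, 4),)),
    ChannelSpec("bk", "dendrite", "ek",
                (_g("m", G_BKD_M, 1), _g("z", G_BKD_Z, 2, ca=True))),
    ChannelSpec("k2", "dendrite", "ek",
                (_g("m", G_K2_M, 1), _g("z", G_K2_Z, 2, ca=True))),
    ChannelSpec("sk", "smooth", "ek", (_g("m", G_SK_M, 1, ca=True),)),
)


def channel_current(spec: ChannelSpec, gate_values, v: float,
                    reversal: float, gmax: float) -> float:
    """Ohmic/GHK current of one channel, mA/cm^2.

    ``gate_values`` maps gate name -> probability.  For the GHK branch the
    reversal argument is ignored and ``gmax`` scales the fixed-concentration
    flux; for ohmic branches gmax is in mS/cm^2.
    """
    prod = 1.0
    for g in spec.gates:
        prod *= gate_values[g.name] ** g.exponent
    if spec.reversal == "ghk":
        return gmax * prod * ghk_flux(v)
    return gmax * prod * (v - reversal) * 1e-3


def steady_state(gate_id: int, v: float, ca: float = 1e-4) -> float:
    inf, _ = gate_inf_tau(gate_id, v, ca)
    return inf


def time_constant(gate_id: int, v: float, ca: float = 1e-4) -> float:
    _, tau = gate_inf_tau(gate_id, v, ca)
    return tau
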
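"""Simulation driver: couples morphology, channels, Ca2+/Na+ systems and
synapses into the per-step loop and returns recorded traces.

The integration scheme, per 25 us step: (1) synaptic conductances advance
by exact exponential decay with grid-snapped event impulses; (2) HH gates
advance by exponential Euler at the frozen voltage; (3) the Markov
occupancies advance by an implicit linear solve; (4) the cable voltages
advance by a backward-Euler tridiagonal solve with ohmic currents at the
new gate values (GHK and pump currents enter explicitly); (5) the Ca2+
shells, floating set points, w/r switches and lagged pump/Na+ state update
from the new currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernel, morphology
from .config import CHANNEL_NAMES, ConfigurationError, ModelConfig
from .morphology import axial_resistance, build_default_topology


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class ProtocolSpec:
    """One named experiment: duration, synaptic drive and overrides."""

    name: str = "trimodal"
    duration: float = 25000.0            # ms
    cf_on: bool = False
    cf_freq: float = 1.0                 # Hz
    pf_on: bool = False
    pf_rate: float = 100.0               # Hz
    pf_seed: int = 0
    g_sk: float = 0.72                   # S/cm^2 while the r switch is high
    k: float | None = None               # I_D inactivation factor override
    g_ih_soma: float | None = None       # mS/cm^2 override
    pump_density: float | None = None    # mA/cm^2 override
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class Trace:
    """Uniformly sampled recordings plus full-rate spike times."""

    t: np.ndarray                        # ms, protocol-relative
    v: np.ndarray                        # (n_samples, n_comp)
    ca: np.ndarray                       # (n_samples, n_comp)
    y: np.ndarray                        # (n_samples, n_smooth)
    w: np.ndarray
    r: np.ndarray
    na_i: np.ndarray                     # (n_samples,)
    i_pump: np.ndarray
    gsk_live: np.ndarray
    soma_spikes: np.ndarray              # ms
    dend_spikes: np.ndarray              # ms
    meta: dict[str, Any] = field(default_factory=dict)

    def to_frame(self):
        """Wide DataFrame of the sampled channels (voltage per compartment)."""
        import pandas as pd
        data = {"t_ms": self.t, "na_i": self.na_i, "i_pump": self.i_pump,
                "gsk_live": self.gsk_live}
        for i in range(self.v.shape[1]):
            data[f"v{i}"] = self.v[:, i]
        return pd.DataFrame(data)


class Simulation:
    """Mutable simulation holding the full coupled state."""

    def __init__(self, config: ModelConfig | None = None,
                 protocol: ProtocolSpec | None = None):
        self.config = config or ModelConfig()
        self.protocol = protocol or ProtocolSpec()
        self.topology = build_default_topology(self.config)
        if not self.topology.is_chain():
            raise ConfigurationError("the compiled engine requires a path")
        self._build_arrays()
        self._init_state()
        self._build_synapses()

    # ------------------------------------------------------------------
    def _path_order(self) -> list[int]:
        '''Compartment ids ordered along the cable path (soma interior for
        the split topology, first for the chain).'''
        n = len(self.topology.compartments)
        adj = {i: self.topology.neighbors(i) for i in range(n)}
        ends = [i for i in range(n) if len(adj[i]) == 1]
        start = min(ends)
        order = [start]
        prev = -1
        while len(order) < n:
            nxt = [j for j in adj[order[-1]] if j != prev]
            prev = order[-1]
            order.append(nxt[0])
        return order

    def _build_arrays(self) -> None:
        cfg = self.config
        comps_by_id = self.topology.compartments
        self.path = self._path_order()
        self.id2path = {cid: k for k, cid in enumerate(self.path)}
        comps = [comps_by_id[cid] for cid in self.path]
        n = len(comps)
        self.n = n
        zone_code = {"soma": 0, "smooth": 1, "spiny": 2}
        self.zone = np.array([zone_code[c.zone] for c in comps],
                             dtype=np.int64)
        self.cm = np.array([c.cm for c in comps])
        self.area = np.array([c.membrane_area for c in comps])
        self.diam = np.array([c.diameter for c in comps])
        self.soma_idx = self.id2path[0]
        # smooth slot: smooth compartment id m (1..n_smooth) -> slot m-1
        self.smooth_slot = np.full(n, -1, dtype=np.int64)
        for k, c in enumerate(comps):
            if c.zone == "smooth":
                self.smooth_slot[k] = c.id - 1

        # axial coupling conductance densities along the path, mS/cm^2
        self.c_lo = np.zeros(n)
        self.c_hi = np.zeros(n)
        for k in range(n - 1):
            a, b = comps[k], comps[k + 1]
            rr = axial_resistance(a, b, self.topology.ra)
            self.c_hi[k] = 1e-3 / (rr * self.area[k])
            self.c_lo[k + 1] = 1e-3 / (rr * self.area[k + 1])

        self.gdens = np.zeros((len(CHANNEL_NAMES), n))
        for k, c in enumerate(comps):
            for j, name in enumerate(CHANNEL_NAMES):
                self.gdens[j, k] = c.channel_densities.get(name, 0.0)
        if self.protocol.g_ih_soma is not None:
            self.gdens[CHANNEL_NAMES.index("ih"),
                       self.soma_idx] = self.protocol.g_ih_soma

        rev = cfg.reversals
        self.ek = np.where(self.zone == 0, rev.ek_soma, rev.ek_dend)
        self.eh = np.where(self.zone == 0, rev.eh_soma, rev.eh_dend)
        self.el = np.where(self.zone == 0, rev.el_soma, rev.el_dend)

        self.k_d_h = self.protocol.k if self.protocol.k is not None \
            else cfg.k_d_inactivation
        self.pump_density = self.protocol.pump_density \
            if self.protocol.pump_density is not None else cfg.pump.density

    def _init_state(self) -> None:
        cfg = self.config
        n = self.n
        self.v = np.full(n, -65.0)
        self.ca = np.where(self.zone == 0, cfg.calcium.ca_init_soma,
                           cfg.calcium.ca_init_dend).astype(float)
        self.gates = _kernel.init_gates(self.v, self.ca, self.zone,
                                        self.k_d_h)
        from .resurgent_na import initial_occupancy, step_occupancy_kernel
        p = initial_occupancy()
        # settle the Markov chain at the initial voltage (implicit steps
        # with growing dt converge on the fixed-voltage equilibrium)
        settle = cfg.integration.markov_settle_ms
        for _ in range(10):
            p = step_occupancy_kernel(p, self.v[self.soma_idx], settle / 10.0)
        self.markov_p = p

        self.n_smooth = int(np.sum(self.zone == 1))
        self.y = np.full(self.n_smooth, cfg.calcium.z)
        self.w = np.zeros(self.n_smooth)
        self.r = np.zeros(self.n_smooth)

        dt = cfg.integration.dt
        n_lag = int(round(cfg.pump.tau_lag / dt))
        self.na_buf = np.zeros(n_lag)
        self.na_i_arr = np.array([cfg.pump.na_init])
        self.na_head = np.array([0], dtype=np.int64)
        # prime the lag buffer with the resting net Na current
        from .resurgent_na import resurgent_current
        i_na0 = resurgent_current(self.markov_p, self.v[self.soma_idx],
                                  cfg.reversals.e_na,
                                  self.gdens[0, self.soma_idx])
        from .pump_sodium import pump_current
        ip0 = pump_current(self.na_i_arr[0], self.pump_density,
                           cfg.pump.na_half, cfg.pump.na_slope)
        self.na_buf[:] = i_na0 + 3.0 * ip0

        self.step0 = 0
        self.soma_spike_times: list[np.ndarray] = []
        self.dend_spike_times: list[np.ndarray] = []

    def _build_synapses(self) -> None:
        from .synapses import make_cf_trains, make_pf_trains
        cfg = self.config
        proto = self.protocol
        dt = cfg.integration.dt
        settle_steps = int(round(cfg.integration.settle_ms / dt))
        comps = self.topology.compartments
        smooth_ids = [c.id for c in comps if c.zone == "smooth"]
        spiny_ids = [c.id for c in comps if c.zone == "spiny"]

        trains = []
        if proto.cf_on:
            trains += make_cf_trains(proto.cf_freq, 0.0, proto.duration,
                                     smooth_ids, cfg.synapse.n_cf_contacts,
                                     cfg.synapse)
        if proto.pf_on:
            trains += make_pf_trains(proto.pf_rate, proto.duration,
                                     proto.pf_seed, spiny_ids, cfg.synapse)
        self.event_trains = trains

        n_syn = len(trains)
        self.syn_target = np.zeros(n_syn, dtype=np.int64)
        self.syn_weight = np.zeros(n_syn)
        self.syn_is_cf = np.zeros(n_syn, dtype=np.bool_)
        ev_steps: list[np.ndarray] = []
        for i, tr in enumerate(trains):
            self.syn_target[i] = self.id2path[tr.synapse.target_compartment]
            self.syn_weight[i] = tr.synapse.g_syn * tr.synapse.norm
            self.syn_is_cf[i] = tr.source == "CF"
            # events snap to the integration grid, offset by the settle phase
            ev_steps.append(np.round(tr.event_times / dt).astype(np.int64)
                            + settle_steps)
        self.syn_ev_off = np.zeros(n_syn + 1, dtype=np.int64)
        for i, e in enumerate(ev_steps):
            self.syn_ev_off[i + 1] = self.syn_ev_off[i] + len(e)
        self.syn_ev_steps = (np.concatenate(ev_steps)
                             if ev_steps else np.zeros(0, dtype=np.int64))
        self.syn_a = np.zeros(n_syn)
        self.syn_b = np.zeros(n_syn)
        self.syn_ptr = self.syn_ev_off[:-1].copy()
        tau1, tau2 = cfg.synapse.tau1, cfg.synapse.tau2
        self.dec1 = float(np.exp(-dt / tau1))
        self.dec2 = float(np.exp(-dt / tau2))

    # ------------------------------------------------------------------
    def advance(self, duration_ms: float, t0: float = 0.0,
                record: bool = True) -> dict[str, np.ndarray] | None:
        """Advance the coupled state by ``duration_ms``; optionally record."""
        cfg = self.config
        cal = cfg.calcium
        dt = cfg.integration.dt
        n_steps = int(round(duration_ms / dt))
        stride = max(1, int(round(cfg.integration.sample_ms / dt)))
        n_samp = (n_steps + stride - 1) // stride if record else 1

        v_out = np.zeros((n_samp, self.n))
        ca_out = np.zeros((n_samp, self.n))
        y_out = np.zeros((n_samp, self.n_smooth))
        w_out = np.zeros((n_samp, self.n_smooth))
        r_out = np.zeros((n_samp, self.n_smooth))
        na_out = np.zeros(n_samp)
        ipump_out = np.zeros(n_samp)
        gsk_out = np.zeros(n_samp)
        max_spk = max(16, int(duration_ms))
        soma_spk = np.zeros(max_spk)
        dend_spk = np.zeros(max_spk)
        counts = np.zeros(2, dtype=np.int64)
        # Ca spikes detected on the mid-chain smooth compartment
        dend_comp = self.id2path[1 + self.n_smooth // 2]

        # offset event-step comparisons to the absolute step counter
        ev_steps = self.syn_ev_steps - self.step0

        got = _kernel.run_sim(
            n_steps, dt, t0, self.soma_idx, self.smooth_slot,
            self.v, self.gates, self.markov_p, self.ca, self.y, self.w,
            self.r, self.na_i_arr, self.na_buf, self.na_head,
            self.syn_a, self.syn_b, self.syn_ptr,
            self.zone, self.cm, self.area, self.diam, self.c_lo, self.c_hi,
            self.gdens, self.ek, self.eh, self.el,
            cfg.reversals.eca_dend, cfg.reversals.e_na, self.k_d_h,
            cal.depth, cal.soma_beta, cal.soma_floor,
            cal.smooth_kt, cal.smooth_kd, cal.spiny_kt, cal.spiny_kd,
            cal.tau_r, cal.z,
            cal.g_default, cal.g_cf, cal.tau_m_default, cal.tau_m_cf,
            cal.w_threshold, cal.f, cal.s, cal.switch_on,
            cal.gsk_off, self.protocol.g_sk, self._y_unit(), cal.spiny_y,
            self.pump_density, cfg.pump.na_half, cfg.pump.na_slope,
            cfg.pump.na_floor, cfg.pump.na_accum_scale,
            cfg.geometry.soma_diameter,
            self.syn_target, self.syn_weight, self.syn_is_cf,
            ev_steps, self.syn_ev_off, self.dec1, self.dec2,
            stride if record else n_steps + 1,
            v_out, ca_out, y_out, na_out, w_out, r_out, gsk_out, ipump_out,
            soma_spk, dend_spk, counts,
            -20.0, 2.0, -30.0, dend_comp)

        self.step0 += n_steps
        if not np.isfinite(self.v).all():
            bad = int(np.argmax(~np.isfinite(self.v)))
            raise IntegrationError(
                f"non-finite voltage in compartment {self.path[bad]} "
                f"(zone {self.zone[bad]}) at t = {t0 + duration_ms:.3f} ms")
        self.soma_spike_times.append(soma_spk[:counts[0]].copy())
        self.dend_spike_times.append(dend_spk[:counts[1]].copy())
        if not record:
            return None
        # reorder sampled per-compartment channels back to compartment ids
        inv = np.array([self.id2path[cid] for cid in range(self.n)])
        v_out = v_out[:, inv]
        ca_out = ca_out[:, inv]
        return {"t": t0 + np.arange(got) * stride * dt,
                "v": v_out[:got], "ca": ca_out[:got], "y": y_out[:got],
                "w": w_out[:got], "r": r_out[:got], "na_i": na_out[:got],
                "i_pump": ipump_out[:got], "gsk_live": gsk_out[:got]}

    def _y_unit(self) -> float:
        return self.config.calcium.y_influx_scale

    def run(self) -> Trace:
        """Settle, then run the protocol window and return its Trace."""
        cfg = self.config
        settle = cfg.integration.settle_ms
        if settle > 0:
            self.advance(settle, t0=-settle, record=False)
        self.soma_spike_times.clear()
        self.dend_spike_times.clear()
        rec = self.advance(self.protocol.duration, t0=0.0, record=True)
        if rec is None:                      # zero-length protocol window
            rec = {"t": np.zeros(0), "v": np.zeros((0, self.n)),
                   "ca": np.zeros((0, self.n)),
                   "y": np.zeros((0, self.n_smooth)),
                   "w": np.zeros((0, self.n_smooth)),
                   "r": np.zeros((0, self.n_smooth)),
                   "na_i": np.zeros(0), "i_pump": np.zeros(0),
                   "gsk_live": np.zeros(0)}
        soma_spk = (np.concatenate(self.soma_spike_times)
                    if self.soma_spike_times else np.zeros(0))
        dend_spk = (np.concatenate(self.dend_spike_times)
                    if self.dend_spike_times else np.zeros(0))
        return Trace(
            t=rec["t"], v=rec["v"], ca=rec["ca"], y=rec["y"], w=rec["w"],
            r=rec["r"], na_i=rec["na_i"], i_pump=rec["i_pump"],
            gsk_live=rec["gsk_live"], soma_spikes=soma_spk,
            dend_spikes=dend_spk,
            meta={"protocol": self.protocol.name,
                  "duration_ms": self.protocol.duration,
                  "settle_ms": settle,
                  "dt": cfg.integration.dt,
                  "na_i_final": float(self.na_i_arr[0])})


def simulate(config: ModelConfig | None = None,
             protocol: ProtocolSpec | None = None) -> Trace:
    """Build a simulation, settle, run the protocol, return its Trace."""
    return Simulation(config, protocol).run()
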
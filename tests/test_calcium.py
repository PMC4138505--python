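"""Ca2+ shell systems, the floating set point and the w/r switches."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from purksim import calcium as cal
from purksim.config import CalciumConfig
from purksim.constants import FARADAY

DT = 0.025


class TestSomaShell:
    def test_floor_holds_without_influx(self):
        s = cal.SomaCaShell(ca=1e-4)
        for _ in range(1000):
            cal.step_soma_ca(s, 0.0, DT)
        assert s.ca == pytest.approx(1e-4)

    def test_exponential_decay_toward_floor(self):
        s = cal.SomaCaShell(ca=1e-2)
        cal.step_soma_ca(s, 0.0, DT)
        # one explicit Euler step of dca/dt = -beta*ca
        assert s.ca == pytest.approx(1e-2 * (1 - DT))

    def test_influx_decay_balance(self):
        """Sustained inward current reaches the algebraic steady state
        influx = beta * ca."""
        ica = -0.01                       # mA/cm^2, inward
        s = cal.SomaCaShell(ca=1e-4)
        for _ in range(20000):
            cal.step_soma_ca(s, ica, DT)
        expect = (1e4 * 0.01) / (2 * FARADAY * 0.1) / 1.0
        assert s.ca == pytest.approx(expect, rel=1e-3)


class TestSpinyPool:
    def test_outward_current_is_clamped(self):
        s1 = cal.SpinyCaState(ca=1e-3)
        s2 = cal.SpinyCaState(ca=1e-3)
        cal.step_spiny_ca(s1, +0.5, DT)    # outward
        cal.step_spiny_ca(s2, 0.0, DT)
        assert s1.ca == s2.ca

    def test_chan_free_steady_state_root_oracle(self):
        """ca* solves (y - ca)/tau_r = kt*ca/(ca + kd)."""
        s = cal.SpinyCaState(ca=1e-3)
        for _ in range(40000):
            cal.step_spiny_ca(s, 0.0, DT)
        f = lambda ca: (s.y - ca) / s.tau_r - s.kt * ca / (ca + s.kd)
        root = brentq(f, 1e-12, 1e-2)
        assert s.ca == pytest.approx(root, rel=1e-4)

    def test_doubling_depth_halves_influx(self):
        assert cal.chan_influx(-0.1, 0.2) == pytest.approx(
            cal.chan_influx(-0.1, 0.1) / 2)


class TestSmoothSystem:
    def test_relaxes_to_anchor_without_influx(self):
        s = cal.SmoothCaState(ca=1e-3, y=1e-3)
        for _ in range(80000):             # 2 s
            cal.step_smooth_ca(s, 0.0, 0.4, DT)
        assert s.y == pytest.approx(s.cfg.z, rel=1e-3)

    def test_reduces_to_spiny_form_when_y_fixed(self):
        """With matching constants and y pinned, the smooth pool update is
        the spiny update."""
        cfg = CalciumConfig(smooth_kt=4e-5, smooth_kd=4e-5)
        sm = cal.SmoothCaState(ca=2e-3, y=4e-5, cfg=cfg)
        sp = cal.SpinyCaState(ca=2e-3)
        for _ in range(200):
            sm.ca = cal.pool_ca_step(sm.ca, -0.02, sm.y, DT, cfg.smooth_kt,
                                     cfg.smooth_kd, cfg.tau_r, sm.depth)
            cal.step_spiny_ca(sp, -0.02, DT)
        assert sm.ca == pytest.approx(sp.ca, rel=1e-12)

    def test_g_pair_scales_set_point_rise_tenfold(self):
        """(g, tau_m) = (1e4, 1000) accumulates 10x faster per step than
        (1e5, 100) under a fixed influx (first-term scaling)."""
        cfg = CalciumConfig()
        rise_cf = cal.y_step(1e-4, -0.1, DT, cfg.g_cf, 1e12, cfg.z, 0.4,
                             cfg.y_influx_scale) - 1e-4
        rise_def = cal.y_step(1e-4, -0.1, DT, cfg.g_default, 1e12, cfg.z,
                              0.4, cfg.y_influx_scale) - 1e-4
        assert rise_cf == pytest.approx(10 * rise_def, rel=1e-9)

    def test_outward_current_never_raises_y(self):
        y0 = 5e-4
        y1 = cal.y_step(y0, +0.5, DT, 1e5, 1e12, 2.4e-4, 0.4, 1e5)
        assert y1 <= y0


class TestSwitches:
    def test_w_lifespan_closed_form(self):
        """Time from w = 1 to w = 0.1 is f*ln(10) ~ 230.26 ms."""
        s = cal.SmoothCaState(w=1.0)
        t = 0.0
        while s.w > 0.1:
            cal.update_w(s, 0.0, DT)
            t += DT
        assert t == pytest.approx(100.0 * math.log(10), abs=0.1)

    def test_w_retrigger_restarts_lifespan(self):
        s = cal.SmoothCaState(w=1.0)
        for _ in range(12000):             # 300 ms > f ln10
            cal.update_w(s, 0.0, DT)
        assert s.w < 0.1
        cal.update_w(s, -0.07, DT)        # inward above 0.06 mA/cm^2
        assert s.w == 1.0

    def test_w_trigger_requires_inward_current(self):
        s = cal.SmoothCaState(w=0.0)
        cal.update_w(s, +0.5, DT)          # outward: no trigger
        assert s.w < 0.1
        assert (s.g, s.tau_m_y) == (s.cfg.g_default, s.cfg.tau_m_default)

    def test_r_lifespan_and_sk_gating(self):
        s = cal.SmoothCaState(r=0.0, gsk_protocol=0.72)
        assert s.gsk_live == pytest.approx(1e-7)
        cal.update_r(s, 65.0, DT)          # CF current >> 3 nA
        assert s.r == 1.0
        assert s.gsk_live == 0.72
        t = 0.0
        while s.r > 0.1:
            cal.update_r(s, 0.0, DT)
            t += DT
        assert t == pytest.approx(1000.0 * math.log(10), abs=0.5)
        assert s.gsk_live == pytest.approx(1e-7)

    def test_one_hz_cf_keeps_sk_enabled_but_fifth_hz_does_not(self):
        """r decays below 0.1 only if the inter-event interval exceeds
        s*ln(10) ~ 2.3 s."""
        for period, stays_on in ((1000.0, True), (5000.0, False)):
            s = cal.SmoothCaState(r=1.0)
            dropped = False
            steps = int(period / DT)
            for _ in range(3):
                for _ in range(steps):
                    cal.update_r(s, 0.0, DT)
                    if s.r < 0.1:
                        dropped = True
                cal.update_r(s, 65.0, DT)
            assert dropped != stays_on
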
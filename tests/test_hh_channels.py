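"""Gate laws: steady states, time constants, updates and current forms."""

import math

import numpy as np
import pytest

from purksim import hh_channels as hh
from purksim.constants import CONSTANTS, FARADAY, GAS_CONSTANT

ALL_GATES = list(range(hh.N_GATES))
CA_GRID = [1e-5, 1e-4, 1e-3, 1e-2, 0.1, 1.0]

#: Relative discontinuity of the printed piecewise time constants at their
#: voltage seams.  These jumps are properties of the published expressions
#: themselves; the values below document the measured magnitude per channel.
SEAM_TOLERANCE = {
    (hh.G_KF_M, -35.0): 0.08,
    (hh.G_KF_H, 0.0): 0.06,
    (hh.G_KMID_M, -20.0): 0.11,
    (hh.G_CAPS_M, -50.0): 0.25,
}


@pytest.mark.parametrize("gate_id", ALL_GATES)
def test_gate_law_sweep_bounded(gate_id):
    """inf in [0,1] and tau > 0 for all V in [-120, 60] mV and [Ca] > 0."""
    for v in np.arange(-120.0, 60.01, 0.5):
        for ca in CA_GRID:
            inf, tau = hh.gate_inf_tau(gate_id, float(v), ca)
            assert 0.0 <= inf <= 1.0, (gate_id, v, ca, inf)
            assert tau > 0.0, (gate_id, v, ca, tau)
            assert np.isfinite(inf) and np.isfinite(tau)


def test_printed_anchor_values():
    # fast-K m sits at its Boltzmann midpoint at -24 mV
    inf, _ = hh.gate_inf_tau(hh.G_KF_M, -24.0, 1e-4)
    assert inf == pytest.approx(0.5)
    # somatic I_h tau peaks at 0.19 + 0.72 = 0.91 (native seconds -> ms)
    _, tau = hh.gate_inf_tau(hh.G_IHS_M, -81.5, 1e-4)
    assert tau == pytest.approx(910.0)
    # somatic BK z midpoint at [Ca] = 0.001 mM
    inf, tau = hh.gate_inf_tau(hh.G_BKS_Z, -60.0, 0.001)
    assert inf == pytest.approx(0.5)
    assert tau == 1.0
    # dendritic I_h tau reading: 1/(sum of exponentials) + 100 ms
    v = -70.0
    expect = 1.0 / (math.exp(-17.9 - 0.116 * v)
                    + math.exp(-1.84 + 0.09 * v)) + 100.0
    _, tau = hh.gate_inf_tau(hh.G_IHD_M, v, 1e-4)
    assert tau == pytest.approx(expect)


def test_dr_vtrap_series_limit():
    """The delayed-rectifier alpha at V = -55 uses the x/(e^x - 1) limit;
    compare against a high-precision series evaluation."""
    inf0, tau0 = hh.gate_inf_tau(hh.G_DR_M, -55.0, 1e-4)
    # independent oracle: alpha = 0.1 * 10*x/(e^x - 1) with x -> 0 => 1.0
    x = 1e-9
    alpha_series = 0.1 * 10.0 * (1.0 - x / 2.0 + x * x / 12.0)
    beta = 0.125 * math.exp(-(-55.0 + 65.0) / 80.0)
    assert inf0 == pytest.approx(alpha_series / (alpha_series + beta),
                                 rel=1e-6)
    assert tau0 == pytest.approx(
        1.0 / ((alpha_series + beta) * CONSTANTS.mt), rel=1e-6)
    # continuity across the branch switch
    inf1, tau1 = hh.gate_inf_tau(hh.G_DR_M, -55.0 + 1e-5, 1e-4)
    assert inf1 == pytest.approx(inf0, rel=1e-4)
    assert tau1 == pytest.approx(tau0, rel=1e-4)


def test_sk_matches_independent_rate_recomputation():
    """SK m_inf/tau equal alpha/(alpha+beta), 1/(alpha+beta) recomputed
    from scratch."""
    rt = GAS_CONSTANT * (CONSTANTS.temp_c + 273.15)
    for v in (-80.0, -60.0, -30.0, 0.0):
        for ca in (1e-4, 1e-3, 1e-2, 0.5):
            a = 0.48 / (1.0 + 0.18
                        * math.exp(-2 * 0.84 * FARADAY * v * 1e-3 / rt) / ca)
            b = 0.28 / (1.0 + ca
                        / (0.011 * math.exp(-2 * FARADAY * v * 1e-3 / rt)))
            inf, tau = hh.gate_inf_tau(hh.G_SK_M, v, ca)
            assert inf == pytest.approx(a / (a + b), rel=1e-12)
            assert tau == pytest.approx(1.0 / (a + b), rel=1e-12)


@pytest.mark.parametrize("gate_id,seam", sorted(SEAM_TOLERANCE))
def test_piecewise_tau_seam_jumps_documented(gate_id, seam):
    lo = hh.gate_inf_tau(gate_id, seam - 1e-9, 1e-4)[1]
    hi = hh.gate_inf_tau(gate_id, seam + 1e-9, 1e-4)[1]
    assert abs(hi - lo) / lo < SEAM_TOLERANCE[(gate_id, seam)]


class TestGateUpdate:
    def test_fixed_point(self):
        assert hh.gate_update(0.3, 0.3, 5.0, 0.025) == pytest.approx(0.3)

    def test_saturation(self):
        assert hh.gate_update(0.1, 0.9, 5.0, 1e9) == pytest.approx(0.9)

    def test_contraction_and_monotonicity(self):
        old = 0.2
        new = hh.gate_update(old, 0.8, 3.0, 0.025)
        assert old < new < 0.8
        assert abs(new - 0.8) < abs(old - 0.8)

    def test_iterated_convergence(self):
        x = 0.0
        for _ in range(4000):
            x = hh.gate_update(x, 0.7, 2.0, 0.025)
        assert abs(x - 0.7) < 1e-9

    def test_rate_scale_slows_by_factor_ten(self):
        """The D-type h factor k = 0.1 gives a 10x longer time-to-half."""
        def time_to_half(scale):
            x, t = 0.0, 0.0
            while x < 0.5:
                x = hh.gate_update(x, 1.0, 10.0, 0.025, scale)
                t += 0.025
            return t
        assert time_to_half(0.1) == pytest.approx(10 * time_to_half(1.0),
                                                  rel=0.01)

    def test_clipping(self):
        assert 0.0 <= hh.gate_update(1.0, 1.0, 1e-6, 1e3) <= 1.0


class TestCurrents:
    def test_ohmic_zero_at_reversal(self):
        for spec in hh.CHANNEL_CATALOG:
            if spec.reversal == "ghk":
                continue
            gates = {g.name: 0.5 for g in spec.gates}
            assert hh.channel_current(spec, gates, -77.0, -77.0, 10.0) == 0.0

    def test_ghk_limit_at_zero_voltage(self):
        """The de-singularised v = 0 value matches the numeric limit."""
        numeric = 0.5 * (hh.ghk_flux(1e-7) + hh.ghk_flux(-1e-7))
        assert hh.ghk_flux(0.0) == pytest.approx(numeric, rel=1e-5)

    def test_ghk_is_inward_at_physiological_voltages(self):
        for v in (-80.0, -40.0, 0.0, 30.0):
            assert hh.ghk_flux(v) < 0.0     # Ca_o >> Ca_i drives influx

    def test_dendritic_cat_fixed_reversal(self):
        spec = next(s for s in hh.CHANNEL_CATALOG
                    if s.name == "ca_t" and s.zone == "dendrite")
        i = hh.channel_current(spec, {"m": 1.0, "h": 1.0}, -40.0, 135.0,
                               2.28)
        assert i == pytest.approx(2.28 * (-40.0 - 135.0) * 1e-3)

    def test_catalog_exponents_match_printed_products(self):
        by_name = {(s.zone, s.name): s for s in hh.CHANNEL_CATALOG}
        assert [g.exponent for g in by_name[("soma", "k_fast")].gates] \
            == [3, 1]
        assert [g.exponent for g in by_name[("soma", "k_mid")].gates] == [4]
        assert [g.exponent for g in by_name[("soma", "bk")].gates] \
            == [3, 2, 1]
        assert [g.exponent for g in by_name[("dendrite", "k_a")].gates] \
            == [4, 1]
        assert [g.exponent for g in by_name[("dendrite", "bk")].gates] \
            == [1, 2]
        assert [g.exponent for g in by_name[("dendrite", "k_dr")].gates] \
            == [4]
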
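"""Model configuration: geometry, channel densities, constants, integration.

Every tunable quantity of the model lives here with its shipped default, so
that experiments (and any re-calibration) go through configuration rather
than code edits.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# Maximal conductance table, mS/cm^2, keyed by current name, per zone.
# Dendrite values already include the C_d = 3.80 surface-correction factor
# (every dendritic entry is an exact multiple of 3.8).
SOMA_DENSITIES: dict[str, float] = {
    "na_r": 156.0,       # resurgent Na+ (Markov)
    "ca_p": 0.52,        # P-type Ca2+ (GHK, dimensionless scale on flux)
    "ca_t": 0.0,
    "ca_e": 0.0,
    "k_a": 0.0,
    "k_d": 0.0,
    "k_m": 0.0,
    "k_dr": 0.0,
    "bk": 72.8,
    "k2": 0.0,
    "k_fast": 41.6,      # highly TEA-sensitive K+
    "k_mid": 20.8,       # moderately TEA-sensitive K+
    "k_slow": 41.6,      # TEA-insensitive K+
    "ih": 1.04,
    "leak": 0.1,
}

DENDRITE_DENSITIES: dict[str, float] = {
    "na_r": 0.0,
    "ca_p": 6.1,
    "ca_t": 2.28,
    "ca_e": 12.16,
    "k_a": 121.6,
    "k_d": 136.8,
    "k_m": 0.0152,
    "k_dr": 0.912,
    "bk": 228.0,
    "k2": 0.608,
    "k_fast": 0.0,
    "k_mid": 0.0,
    "k_slow": 0.0,
    "ih": 1.4,
    "leak": 0.38,
}

CHANNEL_NAMES = tuple(SOMA_DENSITIES)


@dataclass
class Geometry:
    """Compartment dimensions, micrometres.

    The dendritic dimensions are a shipped calibration default: the reduced
    cable inherits only compartment counts and capacitance scaling from its
    published description, not explicit segment dimensions.
    """

    topology: str = "split"       # "split": smooth and spiny chains on
                                  # opposite sides of the soma; "chain":
                                  # soma -> smooth x20 -> spiny x20
    soma_length: float = 22.0
    soma_diameter: float = 22.0
    n_smooth: int = 20
    n_spiny: int = 20
    smooth_length: float = 12.0
    smooth_diameter: float = 0.32
    spiny_length: float = 6.0
    spiny_diameter: float = 1.78


@dataclass
class Passive:
    ra: float = 35.4              # specific axial resistivity, ohm cm
    cd: float = 3.80              # dendrite surface-correction factor
    cm_soma: float = 0.8          # uF/cm^2
    cm_smooth_base: float = 0.8   # multiplied by cd
    cm_spiny_base: float = 1.5    # multiplied by cd


@dataclass
class Reversals:
    """Reversal potentials, mV."""

    ek_soma: float = -88.0
    ek_dend: float = -77.0
    e_na: float = 70.0            # floored at +70 (Eq-54-style clamp)
    eca_dend: float = 135.0       # fixed for dendritic CaT/CaE/CaP
    el_soma: float = -70.0
    el_dend: float = -80.0
    eh_soma: float = -30.0
    eh_dend: float = -32.9


@dataclass
class CalciumConfig:
    """Intracellular Ca2+ shell systems."""

    depth: float = 0.1            # shell depth, um (all zones)
    soma_beta: float = 1.0        # soma shell decay, 1/ms
    soma_floor: float = 1e-4      # 100 nM floor, mM
    spiny_kt: float = 4e-5        # mM/ms
    spiny_kd: float = 4e-5        # mM
    spiny_y: float = 4e-5         # fixed set point, mM
    smooth_kt: float = 1e-4
    smooth_kd: float = 1e-4
    tau_r: float = 2.0            # ms (smooth and spiny)
    z: float = 2.4e-4             # fixed set point for the floating y, mM
    tau_m_default: float = 100.0  # ms, y relaxation (w low)
    tau_m_cf: float = 1000.0      # ms, y relaxation (w high)
    g_default: float = 1e5        # divisive scale on y accumulation (w low)
    g_cf: float = 1e4             # (w high)
    w_threshold: float = 0.06     # mA/cm^2, |Ca current| trigger for w
    f: float = 100.0              # ms, w decay constant
    r_threshold_nA: float = 3.0   # nA, CF synaptic current trigger for r
    s: float = 1000.0             # ms, r decay constant
    switch_on: float = 0.1        # w/r level above which CF values apply
    gsk_off: float = 1e-7         # S/cm^2, SK conductance with r low
    y_influx_scale: float = 1e5   # unit factor of the y-influx term
    ca_init_soma: float = 1e-4    # mM
    ca_init_dend: float = 4e-5    # mM


@dataclass
class PumpConfig:
    """Somatic Na+/K+ pump and lagged Na+ accumulation."""

    density: float = 0.04         # mA/cm^2
    na_half: float = 40.0         # mM, sigmoid midpoint
    na_slope: float = 1.0         # mM
    tau_lag: float = 5000.0       # ms, Na influx lag
    na_floor: float = 10.0        # mM
    e_na_floor: float = 70.0      # mV
    na_init: float = 10.0         # mM
    na_accum_scale: float = 1.0   # calibration multiplier on d[Na]/dt
    diffusion: bool = False       # longitudinal Na diffusion term
    diff_coeff: float = 0.6       # um^2/ms


@dataclass
class SynapseConfig:
    cf_g: float = 1.0             # uS per CF contact
    pf_g: float = 0.0005          # uS per PF contact
    e_rev: float = 0.0            # mV
    tau1: float = 0.5             # ms
    tau2: float = 1.2             # ms
    n_cf_contacts: int = 17


@dataclass
class Integration:
    dt: float = 0.025             # ms
    settle_ms: float = 2000.0     # pre-protocol settle
    markov_settle_ms: float = 500.0
    sample_ms: float = 1.0        # trace sampling interval


@dataclass
class ModelConfig:
    geometry: Geometry = field(default_factory=Geometry)
    passive: Passive = field(default_factory=Passive)
    reversals: Reversals = field(default_factory=Reversals)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    pump: PumpConfig = field(default_factory=PumpConfig)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    integration: Integration = field(default_factory=Integration)
    densities_soma: dict[str, float] = field(
        default_factory=lambda: dict(SOMA_DENSITIES))
    densities_dend: dict[str, float] = field(
        default_factory=lambda: dict(DENDRITE_DENSITIES))
    k_d_inactivation: float = 0.1   # the k factor slowing I_D inactivation

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        kwargs: dict[str, Any] = {}
        for f_ in dataclasses.fields(cls):
            if f_.name not in d:
                continue
            val = d[f_.name]
            typ = {
                "geometry": Geometry, "passive": Passive,
                "reversals": Reversals, "calcium": CalciumConfig,
                "pump": PumpConfig, "synapse": SynapseConfig,
                "integration": Integration,
            }.get(f_.name)
            kwargs[f_.name] = typ(**val) if typ is not None else val
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class ConfigurationError(ValueError):
    """Invalid model configuration (geometry, densities, buffers)."""
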
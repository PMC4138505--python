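"""The 41-compartment cable: soma, 20 smooth and 20 spiny dendrite segments.

The default topology is an unbranched path with the soma interior: the 20
smooth compartments form an equivalent cable on one side of the soma and
the 20 spiny compartments an equivalent cable on the other ("split").  The
two equivalent dendrites then couple to the soma with independent
electrotonic distances, which is what the surviving behaviours require
(see the methods note); the classic single chain soma -> smooth -> spiny
is available as ``topology = "chain"``.  Compartments carry open-cylinder
lateral areas (end caps are ignored, the NEURON convention) and per-zone
channel-density tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import (CHANNEL_NAMES, ConfigurationError, ModelConfig)

ZONE_SOMA = "soma"
ZONE_SMOOTH = "smooth"
ZONE_SPINY = "spiny"


@dataclass
class Compartment:
    """One cable node: geometry, passive properties, channel densities."""

    id: int
    zone: str
    length: float                 # um
    diameter: float               # um
    cm: float                     # uF/cm^2, after C_d scaling
    channel_densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ConfigurationError(
                f"compartment {self.id}: non-positive dimensions "
                f"(L={self.length}, d={self.diameter})")
        if self.cm <= 0:
            raise ConfigurationError(f"compartment {self.id}: cm <= 0")

    @property
    def membrane_area(self) -> float:
        """Lateral cylinder area, cm^2."""
        return math.pi * self.diameter * self.length * 1e-8


@dataclass
class CableTopology:
    """Connected acyclic cable of compartments with axial resistivity."""

    compartments: list[Compartment]
    edges: list[tuple[int, int]]
    ra: float = 35.4              # ohm cm

    def __post_init__(self) -> None:
        n = len(self.compartments)
        if len(self.edges) != n - 1:
            raise ConfigurationError(
                f"{n} compartments need {n - 1} edges for a tree, "
                f"got {len(self.edges)}")
        # union-find connectivity/acyclicity check
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in self.edges:
            ra_, rb_ = find(a), find(b)
            if ra_ == rb_:
                raise ConfigurationError("cable topology contains a cycle")
            parent[ra_] = rb_
        if len({find(i) for i in range(n)}) != 1:
            raise ConfigurationError("cable topology is not connected")

    def zone_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.compartments:
            out[c.zone] = out.get(c.zone, 0) + 1
        return out

    def neighbors(self, i: int) -> list[int]:
        return [b for a, b in self.edges if a == i] + \
               [a for a, b in self.edges if b == i]

    def is_chain(self) -> bool:
        degree = [len(self.neighbors(i)) for i in range(len(self.compartments))]
        return max(degree) <= 2


def axial_resistance(a: Compartment, b: Compartment, ra: float) -> float:
    """Axial resistance between the centres of two adjacent cylinders, MOhm.

    R = ra*(L_a/2)/(pi r_a^2) + ra*(L_b/2)/(pi r_b^2), with ra in ohm cm and
    dimensions in um.
    """
    if a.diameter <= 0 or b.diameter <= 0:
        raise ConfigurationError("axial resistance of zero-radius cylinder")

    def half(c: Compartment) -> float:
        # ohm cm * um / um^2 = ohm cm / um = ohm * 1e4 -> MOhm factor 1e-2
        r_um = c.diameter / 2.0
        return ra * (c.length / 2.0) / (math.pi * r_um * r_um) * 1e-2

    return half(a) + half(b)


def transfer_current(v_a: float, v_b: float, r_ab: float,
                     area_a: float) -> float:
    """Axial current density entering compartment a, mA/cm^2.

    (v_b - v_a)/r_ab is in nA (mV/MOhm); dividing by the membrane area of a
    (cm^2) and converting nA -> mA gives mA/cm^2.  Antisymmetric with the
    current entering b up to the area normalisation.
    """
    return (v_b - v_a) / r_ab / area_a * 1e-6


def build_default_topology(config: ModelConfig | None = None) -> CableTopology:
    """Build the reduced cable: 1 soma + n_smooth + n_spiny chain."""
    config = config or ModelConfig()
    geo, pas = config.geometry, config.passive
    comps: list[Compartment] = []

    def densities(zone: str) -> dict[str, float]:
        src = config.densities_soma if zone == ZONE_SOMA \
            else config.densities_dend
        return {k: float(src.get(k, 0.0)) for k in CHANNEL_NAMES}

    comps.append(Compartment(0, ZONE_SOMA, geo.soma_length,
                             geo.soma_diameter, pas.cm_soma,
                             densities(ZONE_SOMA)))
    idx = 1
    for _ in range(geo.n_smooth):
        comps.append(Compartment(idx, ZONE_SMOOTH, geo.smooth_length,
                                 geo.smooth_diameter,
                                 pas.cm_smooth_base * pas.cd,
                                 densities(ZONE_SMOOTH)))
        idx += 1
    for _ in range(geo.n_spiny):
        comps.append(Compartment(idx, ZONE_SPINY, geo.spiny_length,
                                 geo.spiny_diameter,
                                 pas.cm_spiny_base * pas.cd,
                                 densities(ZONE_SPINY)))
        idx += 1
    if geo.topology == "chain":
        edges = [(i, i + 1) for i in range(len(comps) - 1)]
    elif geo.topology == "split":
        edges = []
        smooth_ids = [c.id for c in comps if c.zone == ZONE_SMOOTH]
        spiny_ids = [c.id for c in comps if c.zone == ZONE_SPINY]
        prev = 0
        for cid in smooth_ids:
            edges.append((prev, cid))
            prev = cid
        prev = 0
        for cid in spiny_ids:
            edges.append((prev, cid))
            prev = cid
    else:
        raise ConfigurationError(f"unknown topology {geo.topology!r}")
    return CableTopology(comps, edges, ra=pas.ra)
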
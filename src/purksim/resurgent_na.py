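"""13-state Markov model of the somatic resurgent Na+ current.

State layout: C1-C5 (sequential closed), O (open), OB (open-channel
blocked), I1-I6 (inactivated).  The activation chain C1->...->C5->O carries
forward rates {4a, 3a, 2a, a, gamma} and backward {b, 2b, 3b, 4b, delta};
the inactivated chain mirrors it scaled by the allosteric factors
a = (Oon/Con)^(1/4) forward and b = (Ooff/Coff)^(1/4) backward; vertical
rungs Ci<->Ii run at Con*a^(i-1) / Coff*b^(i-1); O<->I6 at Oon/Ooff and
O<->OB at eps/zeta.  Occupancies advance by a backward-Euler linear solve,
which is unconditionally stable at the model's 25 us step despite rates of
order 150/ms.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# state indices
C1, C2, C3, C4, C5, O, OB, I1, I2, I3, I4, I5, I6 = range(13)
N_STATES = 13

STATE_NAMES = ("C1", "C2", "C3", "C4", "C5", "O", "OB",
               "I1", "I2", "I3", "I4", "I5", "I6")

# fixed rate constants (1/ms)
GAMMA = 150.0
DELTA = 40.0
CON = 0.005
COFF = 0.5
OON = 0.75
OOFF = 0.005
EPS = 1.75
A_FACT = (OON / CON) ** 0.25
B_FACT = (OOFF / COFF) ** 0.25


@njit(cache=True)
def _alpha(v):
    return 150.0 * math.exp(v / 20.0)


@njit(cache=True)
def _beta(v):
    # 3*exp(-V/20): deactivation accelerates with hyperpolarisation,
    # closing the channel at rest (beta(0) = 3)
    return 3.0 * math.exp(-v / 20.0)


@njit(cache=True)
def _zeta(v):
    # 0.03*exp(-V/25): open-channel block releases on repolarisation,
    # the source of the resurgent component (zeta(0) = 0.03)
    return 0.03 * math.exp(-v / 25.0)


def voltage_rates(v: float) -> dict[str, float]:
    """All scheme rates at one voltage, 1/ms."""
    return {"alpha": _alpha(v), "beta": _beta(v), "gamma": GAMMA,
            "delta": DELTA, "Con": CON, "Coff": COFF, "Oon": OON,
            "Ooff": OOFF, "a": A_FACT, "b": B_FACT, "eps": EPS,
            "zeta": _zeta(v)}


def scheme_edges(v: float = 0.0) -> list[tuple[int, int, float]]:
    """The scheme as an auditable (from, to, rate) edge list at voltage v."""
    al, be, ze = _alpha(v), _beta(v), _zeta(v)
    edges: list[tuple[int, int, float]] = []
    closed = [C1, C2, C3, C4, C5]
    inact = [I1, I2, I3, I4, I5]
    # activation chain C1..C5 -> O
    fwd = [4 * al, 3 * al, 2 * al, al, GAMMA]
    bwd = [be, 2 * be, 3 * be, 4 * be, DELTA]
    chain = closed + [O]
    for i in range(5):
        edges.append((chain[i], chain[i + 1], fwd[i]))
        edges.append((chain[i + 1], chain[i], bwd[i]))
    # inactivated chain I1..I5 -> I6, scaled by a (fwd) and b (bwd)
    ifwd = [4 * al * A_FACT, 3 * al * A_FACT, 2 * al * A_FACT,
            al * A_FACT, GAMMA]
    ibwd = [be * B_FACT, 2 * be * B_FACT, 3 * be * B_FACT,
            4 * be * B_FACT, DELTA]
    ichain = inact + [I6]
    for i in range(5):
        edges.append((ichain[i], ichain[i + 1], ifwd[i]))
        edges.append((ichain[i + 1], ichain[i], ibwd[i]))
    # vertical rungs Ci <-> Ii
    for i in range(5):
        edges.append((closed[i], inact[i], CON * A_FACT ** i))
        edges.append((inact[i], closed[i], COFF * B_FACT ** i))
    # O <-> I6 and O <-> OB
    edges.append((O, I6, OON))
    edges.append((I6, O, OOFF))
    edges.append((O, OB, EPS))
    edges.append((OB, O, ze))
    return edges


@njit(cache=True)
def build_transition_matrix(v):
    """Generator matrix Q (13x13), Q[i, j] = rate i -> j, diagonal = -rowsum."""
    q = np.zeros((13, 13))
    al = _alpha(v)
    be = _beta(v)
    ze = _zeta(v)
    fwd = np.array([4.0 * al, 3.0 * al, 2.0 * al, al, GAMMA])
    bwd = np.array([be, 2.0 * be, 3.0 * be, 4.0 * be, DELTA])
    # C chain: states 0..4 then O=5
    for i in range(5):
        j = i + 1 if i < 4 else 5
        q[i, j] = fwd[i]
        q[j, i] = bwd[i]
    # I chain: states 7..11 then I6=12; the voltage-dependent steps carry
    # the allosteric factors, the final gamma/delta pair does not
    for i in range(5):
        s = 7 + i
        j = s + 1
        q[s, j] = fwd[i] * A_FACT if i < 4 else fwd[i]
        q[j, s] = bwd[i] * B_FACT if i < 4 else bwd[i]
    # rungs
    for i in range(5):
        q[i, 7 + i] = CON * A_FACT ** i
        q[7 + i, i] = COFF * B_FACT ** i
    q[5, 12] = OON
    q[12, 5] = OOFF
    q[5, 6] = EPS
    q[6, 5] = ze
    for i in range(13):
        q[i, i] = -(q[i, :].sum() - q[i, i])
    return q


@njit(cache=True)
def _expm(a):
    """Matrix exponential by scaling-and-squaring with a diagonal Pade
    approximant; accurate to ~1e-12 for the generator norms seen here."""
    n = a.shape[0]
    norm = 0.0
    for i in range(n):
        row = 0.0
        for j in range(n):
            row += abs(a[i, j])
        if row > norm:
            norm = row
    s = 0
    while norm > 0.5:
        norm *= 0.5
        s += 1
    a = a / (2.0 ** s)
    # Pade(6,6)
    c = np.array([1.0, 0.5, 3.0 / 26.0, 5.0 / 312.0, 5.0 / 3432.0,
                  1.0 / 11440.0, 1.0 / 308880.0])
    a2 = a @ a
    a4 = a2 @ a2
    a6 = a4 @ a2
    ident = np.eye(n)
    u = a @ (c[1] * ident + c[3] * a2 + c[5] * a4)
    v_ = c[0] * ident + c[2] * a2 + c[4] * a4 + c[6] * a6
    r = np.linalg.solve(v_ - u, v_ + u)
    for _ in range(s):
        r = r @ r
    return r


@njit(cache=True)
def step_occupancy_kernel(occ, v, dt):
    """Exact propagation at frozen voltage: p_new = expm(dt*Q^T) p_old.

    The exponential propagator is unconditionally stable (like the
    backward-Euler solve it replaces) and in addition exact for the frozen
    generator, which matters because the scheme's fastest rates reach
    ~150/ms and make any first-order step visibly lossy at 25 us.
    """
    q = build_transition_matrix(v)
    out = _expm(q.T * dt) @ occ
    # renormalise against round-off
    s = 0.0
    for i in range(13):
        if out[i] < 0.0:
            out[i] = 0.0
        s += out[i]
    return out / s


def step_occupancy(occ: np.ndarray, v: float, dt: float) -> np.ndarray:
    """Advance a 13-vector of occupancies over dt (ms) at fixed voltage."""
    occ = np.asarray(occ, dtype=float)
    if occ.shape != (13,):
        raise ValueError("occupancy must be a 13-vector")
    if dt == 0.0:
        return occ.copy()
    return step_occupancy_kernel(occ, v, dt)


def equilibrium_occupancy(v: float) -> np.ndarray:
    """Null-space equilibrium of the generator at fixed voltage."""
    q = build_transition_matrix(v)
    w, vec = np.linalg.eig(q.T)
    i = int(np.argmin(np.abs(w)))
    p = np.real(vec[:, i])
    p = np.abs(p)
    return p / p.sum()


def initial_occupancy() -> np.ndarray:
    """All mass in C1 (rest); callers settle before protocols."""
    p = np.zeros(13)
    p[C1] = 1.0
    return p


def resurgent_current(occ: np.ndarray, v: float, e_na: float,
                      gmax: float) -> float:
    """I_NaR = gmax * O * (v - E_Na), mA/cm^2 (gmax in mS/cm^2)."""
    return gmax * occ[O] * (v - e_na) * 1e-3


def export_edge_table(path, v: float = 0.0) -> None:
    """Write the scheme's (from, to, rate) edge list as TSV for audit."""
    with open(path, "w") as fh:
        fh.write("from\tto\trate_per_ms\n")
        for frm, to, rate in scheme_edges(v):
            fh.write(f"{STATE_NAMES[frm]}\t{STATE_NAMES[to]}\t{rate:.6g}\n")
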
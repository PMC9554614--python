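"""Nine-state AMPA receptor kinetic scheme and helpers.

The receptor is a ligand-gated channel with two glutamate binding sites:
three closed states (C0, C1, C2 carrying 0/1/2 bound molecules), one open
state (O2) and five desensitized states (D1 with one bound molecule,
D2a-D2d with two).  Transitions form a continuous-time Markov chain; binding
transitions carry bimolecular rates (M^-1 s^-1) which the particle engine
converts to per-step capture probabilities through the equivalent
concentration of a single molecule inside the binding half-sphere.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "STATES",
    "GLU_COUNT",
    "DESENSITIZED_STATES",
    "OPEN_STATE",
    "Transition",
    "KineticScheme",
    "default_scheme",
    "equivalent_concentration",
]

STATES: tuple[str, ...] = ("C0", "C1", "C2", "O2", "D1", "D2a", "D2b", "D2c", "D2d")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: number of bound glutamate molecules encoded by each state label
GLU_COUNT = {"C0": 0, "C1": 1, "C2": 2, "O2": 2, "D1": 1,
             "D2a": 2, "D2b": 2, "D2c": 2, "D2d": 2}

DESENSITIZED_STATES = ("D1", "D2a", "D2b", "D2c", "D2d")
OPEN_STATE = "O2"


class Transition(NamedTuple):
    frm: str
    to: str
    rate: float        # M^-1 s^-1 for kind == "binding", s^-1 otherwise
    kind: str          # "binding" | "unbinding" | "conformational"
    name: str = ""


# Rate constants of the scheme (binding rates in M^-1 s^-1, others s^-1).
RATES = {
    "K1": 1.8412e7, "K-1": 4.323e3,
    "K2": 4.000e6, "K-2": 1.7201e4,
    "K3": 1.9863e7, "K-3": 1.168e3,
    "beta": 5.1690e4, "alpha": 1.0082e4,
    "K4": 885.990, "K-4": 280.350,
    "K5": 449.033, "K-5": 1.944,
    "K6": 2.797, "K-6": 3.9497e-2,
    "K7": 1.380e3, "K-7": 421.849,
    "K8": 848.141, "K-8": 538.920,
    "K9": 51.700, "K-9": 29.164,
    "K10": 939.000, "K-10": 24.463,
}


def _edges(affinity_scale: float) -> list[Transition]:
    r = RATES
    return [
        Transition("C0", "C1", r["K1"] * affinity_scale, "binding", "K1"),
        Transition("C1", "C0", r["K-1"], "unbinding", "K-1"),
        Transition("C1", "C2", r["K2"] * affinity_scale, "binding", "K2"),
        Transition("C2", "C1", r["K-2"], "unbinding", "K-2"),
        Transition("C2", "O2", r["beta"], "conformational", "beta"),
        Transition("O2", "C2", r["alpha"], "conformational", "alpha"),
        Transition("C1", "D1", r["K4"], "conformational", "K4"),
        Transition("D1", "C1", r["K-4"], "conformational", "K-4"),
        Transition("D1", "D2a", r["K3"], "binding", "K3"),
        Transition("D2a", "D1", r["K-3"], "unbinding", "K-3"),
        Transition("C2", "D2a", r["K5"], "conformational", "K5"),
        Transition("D2a", "C2", r["K-5"], "conformational", "K-5"),
        Transition("D2a", "D2b", r["K6"], "conformational", "K6"),
        Transition("D2b", "D2a", r["K-6"], "conformational", "K-6"),
        Transition("C2", "D2b", r["K7"], "conformational", "K7"),
        Transition("D2b", "C2", r["K-7"], "conformational", "K-7"),
        Transition("C2", "D2c", r["K9"], "conformational", "K9"),
        Transition("D2c", "C2", r["K-9"], "conformational", "K-9"),
        Transition("D2c", "D2d", r["K8"], "conformational", "K8"),
        Transition("D2d", "D2c", r["K-8"], "conformational", "K-8"),
        Transition("O2", "D2d", r["K10"], "conformational", "K10"),
        Transition("D2d", "O2", r["K-10"], "conformational", "K-10"),
    ]


@dataclass
class KineticScheme:
    """A receptor state-transition scheme with per-step probability tables."""

    transitions: list[Transition] = field(default_factory=lambda: _edges(1.0))

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        binding = [t for t in self.transitions if t.kind == "binding"]
        if len(binding) != 3:
            raise ValueError(f"expected exactly 3 binding transitions, got {len(binding)}")
        for t in self.transitions:
            if t.rate < 0:
                raise ValueError(f"negative rate on edge {t}")
            if t.frm not in STATE_INDEX or t.to not in STATE_INDEX:
                raise ValueError(f"unknown state on edge {t}")
            dg = GLU_COUNT[t.to] - GLU_COUNT[t.frm]
            expected = {"binding": 1, "unbinding": -1, "conformational": 0}[t.kind]
            if dg != expected:
                raise ValueError(f"edge {t} changes glutamate count by {dg}, "
                                 f"inconsistent with kind {t.kind!r}")
        # C0 must be the unique absorbing state of the chain restricted to
        # non-binding edges: every state reaches C0 and C0 has no way out.
        adj: dict[str, set[str]] = {s: set() for s in STATES}
        for t in self.transitions:
            if t.kind != "binding":
                adj[t.frm].add(t.to)
        if adj["C0"]:
            raise ValueError("C0 must have no outgoing non-binding edges")
        for s in STATES:
            seen, stack = {s}, [s]
            while stack:
                for nxt in adj[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            if "C0" not in seen:
                raise ValueError(f"state {s} cannot reach C0 without ligand")

    def check_dt(self, dt_s: float, limit: float = 0.1) -> None:
        """Linearised per-step probabilities must stay small (rate*dt < limit)."""
        worst = max(t.rate * dt_s for t in self.transitions if t.kind != "binding")
        if worst >= limit:
            raise ValueError(f"rate*dt = {worst:.3g} >= {limit}; reduce the time step")

    # -- lookups -----------------------------------------------------------

    def binding_rate_by_state(self) -> np.ndarray:
        """k_on (M^-1 s^-1) of the outgoing binding edge per state (0 if none)."""
        out = np.zeros(len(STATES))
        for t in self.transitions:
            if t.kind == "binding":
                out[STATE_INDEX[t.frm]] = t.rate
        return out

    def binding_target_by_state(self) -> np.ndarray:
        out = np.arange(len(STATES), dtype=np.int8)
        for t in self.transitions:
            if t.kind == "binding":
                out[STATE_INDEX[t.frm]] = STATE_INDEX[t.to]
        return out

    def step_tables(self, dt_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-state categorical tables for the non-binding transitions.

        Returns ``(cum, target, unbind)`` where ``cum[s]`` holds the cumulative
        per-step firing thresholds of state s's outgoing non-binding edges
        (padded with 2.0), ``target[s, j]`` the destination state of edge j
        (padded with s itself) and ``unbind[s, j]`` whether edge j releases a
        bound molecule.  A receptor in state s with uniform draw u takes edge
        j iff cum[s, j-1] <= u < cum[s, j]; u >= the last threshold means stay.
        """
        per_state: list[list[Transition]] = [[] for _ in STATES]
        for t in self.transitions:
            if t.kind != "binding":
                per_state[STATE_INDEX[t.frm]].append(t)
        emax = max(1, max(len(e) for e in per_state))
        cum = np.full((len(STATES), emax), 2.0)
        # one trailing "stay" column: a draw above every threshold keeps the state
        target = np.tile(np.arange(len(STATES), dtype=np.int8)[:, None], (1, emax + 1))
        unbind = np.zeros((len(STATES), emax + 1), dtype=bool)
        for s, edges in enumerate(per_state):
            total = 0.0
            for j, t in enumerate(edges):
                p = t.rate * dt_s
                total += p
                cum[s, j] = total
                target[s, j] = STATE_INDEX[t.to]
                unbind[s, j] = t.kind == "unbinding"
            if total >= 1.0:
                raise ValueError(f"total outgoing probability {total:.3g} >= 1 from "
                                 f"state {STATES[s]}; reduce the time step")
        return cum, target, unbind

    def generator_matrix(self, concentration_M: float = 0.0) -> np.ndarray:
        """Continuous-time generator Q (s^-1) under a fixed free-ligand concentration.

        Binding edges contribute k_on * C; used as the matrix-exponential
        oracle for the sampled dynamics.
        """
        n = len(STATES)
        Q = np.zeros((n, n))
        for t in self.transitions:
            rate = t.rate * concentration_M if t.kind == "binding" else t.rate
            i, j = STATE_INDEX[t.frm], STATE_INDEX[t.to]
            Q[i, j] += rate
            Q[i, i] -= rate
        return Q

    # -- serialisation -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["from", "to", "rate", "kind", "name"])
            for t in self.transitions:
                w.writerow([t.frm, t.to, repr(t.rate), t.kind, t.name])

    @classmethod
    def from_csv(cls, path: str | Path) -> "KineticScheme":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        ts = [Transition(r["from"], r["to"], float(r["rate"]), r["kind"], r.get("name", ""))
              for r in rows]
        return cls(ts)


def default_scheme(affinity_scale: float = 1.0) -> KineticScheme:
    """The reference scheme; ``affinity_scale`` multiplies K1 and K2 only."""
    if affinity_scale <= 0:
        raise ValueError("affinity_scale must be positive")
    return KineticScheme(_edges(affinity_scale))


def attempt_binding(ens, rec_x: np.ndarray, rec_y: np.ndarray, rec_state: np.ndarray,
                    scheme: KineticScheme, params, numerics,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Reference (single-repetition) capture step.

    A free molecule is eligible for a receptor when it sits inside the
    receptor's protrusion volume: lateral (xy) distance <= b_rad and within
    b_rad of the postsynaptic membrane.  Each eligible pair binds with
    probability k_on * C_eq * dt; eligible molecules are visited in random
    order and at most one binding happens per molecule and per receptor per
    step.  Updates the ensemble and ``rec_state`` in place, returns the
    applied (molecule, receptor) pairs.
    """
    from .molecules import BOUND, FREE

    c_eq = equivalent_concentration(numerics.b_rad)
    p_state = scheme.binding_rate_by_state() * c_eq * numerics.dt_s
    if np.any(p_state >= 1.0):
        raise ValueError("binding probability k_on * C_eq * dt >= 1; reduce the time step")
    b_target = scheme.binding_target_by_state()
    cand = np.flatnonzero((ens.status == FREE) & (ens.z >= params.H_c - numerics.b_rad))
    taken = np.zeros(len(rec_x), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for mi in rng.permutation(cand):
        d2 = (ens.x[mi] - rec_x) ** 2 + (ens.y[mi] - rec_y) ** 2
        for ri in np.flatnonzero(d2 <= numerics.b_rad**2):
            if taken[ri] or p_state[rec_state[ri]] <= 0.0:
                continue
            if rng.random() < p_state[rec_state[ri]]:
                rec_state[ri] = b_target[rec_state[ri]]
                ens.status[mi] = BOUND
                ens.bound_to[mi] = ri
                ens.capture_count[mi] += 1
                taken[ri] = True
                pairs.append((int(mi), int(ri)))
                break
    return pairs


def step_markov(rec_state: np.ndarray, scheme: KineticScheme, dt_s: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Reference non-binding transition step for an array of receptor states.

    Each receptor takes at most one transition, chosen by a single
    categorical draw over its outgoing non-binding edges (stay probability
    1 - sum rate*dt).  Returns ``(new_states, released)`` where ``released``
    flags receptors whose fired edge was an unbinding edge.
    """
    cum, target, unbind = scheme.step_tables(dt_s)
    u = rng.random(len(rec_state))
    k = (u[:, None] >= cum[rec_state]).sum(axis=1)
    new = target[rec_state, k]
    released = unbind[rec_state, k]
    return new, released


def lateral_move_probability(D_r_um2_s: float, dt_ns: float, h_nm: float) -> float:
    """Per-step probability that a receptor attempts a lattice move: 4 D dt / h^2."""
    d_nm2_per_ns = D_r_um2_s * 1e-3
    return 4.0 * d_nm2_per_ns * dt_ns / h_nm**2


def equivalent_concentration(b_rad_nm: float) -> float:
    """Molar concentration equivalent of one molecule inside the binding half-sphere.

    C = 1 / (N_A * V) with V = (2/3) pi b_rad^3 (1 nm^3 = 1e-24 L).  For the
    5 nm binding radius this is ~6.34 mM.
    """
    if b_rad_nm <= 0:
        raise ValueError("binding radius must be positive")
    vol_L = (2.0 / 3.0) * math.pi * b_rad_nm**3 * 1e-24
    from .params import N_AVOGADRO
    return 1.0 / (N_AVOGADRO * vol_L)
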
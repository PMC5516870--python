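"""Synchronous Boolean network dynamics and attractor detection.

Two general-purpose logic rules for genes receiving multiple inputs:

* ``threshold`` — summed weights of ON activators (A) vs ON inhibitors (I)
  are compared and the stronger side wins; a tie (including the no-ON-input
  case A = I = 0) holds the gene in its current state.
* ``inhibitor_dominant`` — one ON inhibitor suffices to switch the gene off
  regardless of activators; otherwise any ON activator switches it on, and a
  gene with no ON input holds its state.

All updates are synchronous and deterministic, so every trajectory ends in a
fixed point or a state cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .priors import ACTIVATION, INHIBITION, SignedEdge

__all__ = [
    "BooleanNetwork",
    "Attractor",
    "update",
    "find_attractor",
    "enumerate_attractors",
    "RULES",
]

RULES = ("threshold", "inhibitor_dominant")


class BooleanDynamicsError(ValueError):
    pass


@dataclass
class BooleanNetwork:
    """Signed weighted digraph with a fixed node order and an update rule."""

    nodes: list[str]
    edges: list[SignedEdge]
    rule: str = "threshold"
    _w_act: np.ndarray = field(init=False, repr=False)
    _w_inh: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise BooleanDynamicsError(f"unknown rule {self.rule!r}")
        idx = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        self._w_act = np.zeros((n, n))
        self._w_inh = np.zeros((n, n))
        for e in self.edges:
            if e.source not in idx or e.target not in idx:
                raise BooleanDynamicsError(f"edge {e.pair} references unknown node")
            if e.sign == ACTIVATION:
                self._w_act[idx[e.target], idx[e.source]] += e.weight
            elif e.sign == INHIBITION:
                self._w_inh[idx[e.target], idx[e.source]] += e.weight
            else:
                raise BooleanDynamicsError(f"edge {e.pair} has unassigned sign at simulation time")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def state_vector(self, state: Mapping[str, int] | Iterable[int]) -> np.ndarray:
        if isinstance(state, Mapping):
            return np.array([state[g] for g in self.nodes], dtype=np.uint8)
        v = np.asarray(list(state), dtype=np.uint8)
        if v.shape != (self.n,):
            raise BooleanDynamicsError("state length does not match node count")
        return v

    def state_dict(self, vector: np.ndarray) -> dict[str, int]:
        return {g: int(v) for g, v in zip(self.nodes, vector)}


def _step(net: BooleanNetwork, s: np.ndarray) -> np.ndarray:
    a = net._w_act @ s
    i = net._w_inh @ s
    if net.rule == "threshold":
        return np.where(a > i, 1, np.where(i > a, 0, s)).astype(np.uint8)
    return np.where(i > 0, 0, np.where(a > 0, 1, s)).astype(np.uint8)


def update(net: BooleanNetwork, state) -> dict[str, int]:
    """One synchronous update of all genes."""
    return net.state_dict(_step(net, net.state_vector(state)))


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length-1) or state cycle, canonically rotated."""

    kind: str  # "fixed_point" | "cycle"
    states: tuple[tuple[int, ...], ...]
    basin_entry: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def key(self) -> tuple:
        """Identity of the attractor irrespective of where it was entered."""
        return self.states

    def min_hamming(self, target: np.ndarray) -> int:
        t = np.asarray(target, dtype=np.uint8)
        return min(int(np.sum(np.asarray(s, dtype=np.uint8) != t)) for s in self.states)


def _canonical_cycle(states: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    k = min(range(len(states)), key=lambda i: states[i])
    return tuple(states[k:] + states[:k])


def find_attractor(net: BooleanNetwork, start, max_steps: int | None = None) -> Attractor:
    """Iterate synchronous updates from ``start`` until a state repeats."""
    s = net.state_vector(start)
    if max_steps is None:
        max_steps = 2 ** min(net.n, 24) + 2
    seen: dict[tuple[int, ...], int] = {}
    trajectory: list[tuple[int, ...]] = []
    cur = tuple(int(v) for v in s)
    entry = cur
    for _ in range(max_steps + 1):
        if cur in seen:
            cycle = trajectory[seen[cur] :]
            return Attractor(
                kind="fixed_point" if len(cycle) == 1 else "cycle",
                states=_canonical_cycle(cycle),
                basin_entry=entry,
            )
        seen[cur] = len(trajectory)
        trajectory.append(cur)
        s = _step(net, s)
        cur = tuple(int(v) for v in s)
    raise BooleanDynamicsError(f"no attractor within {max_steps} steps")


def enumerate_attractors(
    net: BooleanNetwork,
    exhaustive_max_n: int = 20,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[Attractor]:
    """All attractors of the synchronous transition graph.

    Exhaustive over all 2^n states for n <= ``exhaustive_max_n``; otherwise
    attractors reached from ``n_samples`` seeded random start states.
    """
    n = net.n
    found: dict[tuple, Attractor] = {}
    if n <= exhaustive_max_n:
        starts: Iterable[np.ndarray] = (
            np.array([(code >> b) & 1 for b in range(n)], dtype=np.uint8) for code in range(2**n)
        )
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        starts = (rng.integers(0, 2, size=n).astype(np.uint8) for _ in range(n_samples))
    for start in starts:
        att = find_attractor(net, start)
        found.setdefault(att.key, att)
    return sorted(found.values(), key=lambda a: a.states)
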
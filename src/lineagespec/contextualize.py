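"""Genetic-algorithm contextualization of a raw TRN to a Boolean profile.

A raw TRN aggregates evidence that is partly generic (literature, motif
presence), so its synchronous Boolean attractor generally disagrees with the
subpopulation's Booleanized expression state.  Contextualization searches for
a subnetwork (edges only removed, never added) and a sign assignment for
unassigned edges whose attractor — reached from the Booleanized profile as
the start state — matches the profile.

Candidates are bit strings (one keep/remove bit per edge, one
activation/inhibition bit per unassigned edge).  Fitness is the Hamming
mismatch between the reached attractor and the profile (minimum over cycle
states).  Selection is elitist, so the best fitness is non-increasing; sign
bits of fitter candidates propagate, biasing sign assignment toward better
solutions over generations.  Among zero-mismatch solutions the search prefers
keeping more edges (minimal pruning keeps maximal literature support), which
a deterministic greedy restore pass enforces at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .assembly import RawTRN
from .boolnet import Attractor, BooleanNetwork, find_attractor
from .expression import BooleanProfile
from .priors import ACTIVATION, INHIBITION, UNASSIGNED, SignedEdge

__all__ = ["GAParams", "ContextualizedTRN", "fitness", "contextualize", "restrict_to_scc"]


class ContextualizationError(ValueError):
    pass


@dataclass
class GAParams:
    """Hyperparameters of the pruning GA (all configurable; none is data-dependent)."""

    population_size: int = 100
    elite_fraction: float = 0.1
    mutation_rate: float | None = None  # default 1 / total bit count
    max_generations: int = 500
    init_keep_prob: float = 0.8
    tournament_size: int = 2


@dataclass
class ContextualizedTRN:
    """Pruned, fully signed network plus the attractor it settles into."""

    subpopulation_id: str
    nodes: list[str]
    edges: list[SignedEdge]
    achieved_fitness: int
    attractor: Attractor
    rule: str
    converged: bool
    fitness_history: list[int] = field(default_factory=list)

    def network(self) -> BooleanNetwork:
        return BooleanNetwork(nodes=list(self.nodes), edges=list(self.edges), rule=self.rule)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}


def fitness(net: BooleanNetwork, profile: BooleanProfile) -> int:
    """Mismatch between the attractor reached from the profile and the profile."""
    target = profile.as_vector(net.nodes)
    att = find_attractor(net, target)
    return att.min_hamming(target)


def restrict_to_scc(raw: RawTRN) -> RawTRN:
    """Induce the raw TRN on its largest strongly connected component.

    Used when the full network is too large for the GA to converge; the
    stability-core analysis only ever looks inside SCCs anyway.
    """
    g = nx.DiGraph()
    g.add_nodes_from(raw.nodes)
    g.add_edges_from(e.pair for e in raw.edges)
    sccs = [c for c in nx.strongly_connected_components(g) if len(c) >= 2]
    if not sccs:
        raise ContextualizationError(
            "no strongly connected component of size >= 2; contextualize the full network directly"
        )
    core = max(sccs, key=lambda c: (len(c), tuple(sorted(c))))
    nodes = [n for n in raw.nodes if n in core]
    edges = [e for e in raw.edges if e.source in core and e.target in core]
    return RawTRN(subpopulation_id=raw.subpopulation_id, nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# GA machinery


class _Problem:
    """Precomputed edge indexing for fast candidate evaluation."""

    def __init__(self, raw: RawTRN, profile: BooleanProfile, rule: str):
        missing = [n for n in raw.nodes if n not in profile.states]
        if missing:
            raise ContextualizationError(f"profile does not cover nodes: {missing}")
        if not raw.edges:
            raise ContextualizationError("raw TRN has no edges")
        self.raw = raw
        self.rule = rule
        self.nodes = list(raw.nodes)
        self.idx = {g: i for i, g in enumerate(self.nodes)}
        self.edges = list(raw.edges)
        self.src = np.array([self.idx[e.source] for e in self.edges])
        self.tgt = np.array([self.idx[e.target] for e in self.edges])
        self.weight = np.array([e.weight for e in self.edges])
        self.fixed_sign = np.array(
            [1 if e.sign == ACTIVATION else (-1 if e.sign == INHIBITION else 0) for e in self.edges]
        )
        self.unassigned = np.nonzero(self.fixed_sign == 0)[0]
        self.n_edges = len(self.edges)
        self.n_signs = len(self.unassigned)
        self.n_bits = self.n_edges + self.n_signs
        self.target = profile.as_vector(self.nodes)

    def signs(self, genome: np.ndarray) -> np.ndarray:
        """Per-edge sign in {-1, +1} after applying the candidate's sign bits."""
        signs = self.fixed_sign.copy()
        if self.n_signs:
            bits = genome[self.n_edges :]
            signs[self.unassigned] = np.where(bits, 1, -1)
        return signs

    def evaluate(self, genome: np.ndarray) -> tuple[int, Attractor]:
        mask = genome[: self.n_edges].astype(bool)
        signs = self.signs(genome)
        n = len(self.nodes)
        w_act = np.zeros((n, n))
        w_inh = np.zeros((n, n))
        keep_act = mask & (signs > 0)
        keep_inh = mask & (signs < 0)
        np.add.at(w_act, (self.tgt[keep_act], self.src[keep_act]), self.weight[keep_act])
        np.add.at(w_inh, (self.tgt[keep_inh], self.src[keep_inh]), self.weight[keep_inh])
        att = _find_attractor_matrices(w_act, w_inh, self.rule, self.target)
        return att.min_hamming(self.target), att, self._held(w_act, w_inh, att)

    def _held(self, w_act: np.ndarray, w_inh: np.ndarray, att: Attractor) -> int:
        """Genes sustained only by the hold-on-tie rule in the attractor state.

        A phenotype state actively maintained by regulatory input is preferred
        over one frozen by the tie rule (keeping a gene active requires
        constant input in the underlying stability model), so among otherwise
        equal candidates the GA minimizes this count — which in particular
        resolves sign assignments that the mismatch objective leaves free.
        """
        s = np.asarray(att.states[0], dtype=np.uint8)
        a = w_act @ s
        i = w_inh @ s
        if self.rule == "threshold":
            return int(np.sum(a == i))
        return int(np.sum((i == 0) & (a == 0)))

    def materialize(self, genome: np.ndarray) -> list[SignedEdge]:
        mask = genome[: self.n_edges].astype(bool)
        signs = self.signs(genome)
        out = []
        for k in np.nonzero(mask)[0]:
            e = self.edges[k]
            out.append(
                SignedEdge(
                    source=e.source,
                    target=e.target,
                    sign=ACTIVATION if signs[k] > 0 else INHIBITION,
                    provenance=e.provenance,
                    weight=e.weight,
                )
            )
        return out


def _find_attractor_matrices(w_act: np.ndarray, w_inh: np.ndarray, rule: str, start: np.ndarray) -> Attractor:
    seen: dict[tuple[int, ...], int] = {}
    traj: list[tuple[int, ...]] = []
    s = start.astype(np.uint8)
    cur = tuple(int(v) for v in s)
    entry = cur
    while cur not in seen:
        seen[cur] = len(traj)
        traj.append(cur)
        a = w_act @ s
        i = w_inh @ s
        if rule == "threshold":
            s = np.where(a > i, 1, np.where(i > a, 0, s)).astype(np.uint8)
        else:
            s = np.where(i > 0, 0, np.where(a > 0, 1, s)).astype(np.uint8)
        cur = tuple(int(v) for v in s)
    cycle = traj[seen[cur] :]
    k = min(range(len(cycle)), key=lambda t: cycle[t])
    return Attractor(
        kind="fixed_point" if len(cycle) == 1 else "cycle",
        states=tuple(cycle[k:] + cycle[:k]),
        basin_entry=entry,
    )


def _greedy_restore(problem: _Problem, genome: np.ndarray) -> np.ndarray:
    """Re-add removed edges (trying both signs when unassigned) while fitness allows.

    Deterministic edge order makes the minimal-pruning secondary objective
    reproducible.
    """
    genome = genome.copy()

    def key(g: np.ndarray) -> tuple[int, int, int]:
        fit, att, held = problem.evaluate(g)
        return (fit, 0 if att.kind == "fixed_point" else 1, held)

    best = key(genome)
    sign_bit_of = {int(e): b for b, e in enumerate(problem.unassigned)}
    # pass 1: re-add removed edges whenever mismatch and stability allow
    # (minimal pruning outranks the held-gene count); choose the better sign
    for k in range(problem.n_edges):
        if genome[k]:
            continue
        genome[k] = 1
        options = [None] if k not in sign_bit_of else [1, 0]
        cands = []
        for opt in options:
            if opt is not None:
                genome[problem.n_edges + sign_bit_of[k]] = opt
            cands.append((key(genome), opt))
        cand_key, cand_opt = min(cands)
        if cand_key[:2] <= best[:2]:
            best = cand_key
            if cand_opt is not None:
                genome[problem.n_edges + sign_bit_of[k]] = cand_opt
        else:
            genome[k] = 0
    # pass 2: flip free signs of kept edges where that lowers the key
    for k, bit in sign_bit_of.items():
        if not genome[k]:
            continue
        pos = problem.n_edges + bit
        genome[pos] ^= 1
        flipped = key(genome)
        if flipped < best:
            best = flipped
        else:
            genome[pos] ^= 1
    return genome


def contextualize(
    raw: RawTRN,
    profile: BooleanProfile,
    params: GAParams | None = None,
    seed: int | np.random.Generator = 0,
    rule: str = "threshold",
) -> ContextualizedTRN:
    """Evolve edge masks and sign assignments until the attractor matches the profile.

    Returns the best candidate found (fitness 0 when the search converged;
    otherwise the best-so-far network with ``converged=False``).
    """
    params = params or GAParams()
    problem = _Problem(raw, profile, rule)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop_size = params.population_size
    n_bits = problem.n_bits
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / n_bits
    n_elite = max(1, int(round(params.elite_fraction * pop_size)))

    pop = np.empty((pop_size, n_bits), dtype=np.uint8)
    pop[:, : problem.n_edges] = rng.random((pop_size, problem.n_edges)) < params.init_keep_prob
    if problem.n_signs:
        pop[:, problem.n_edges :] = rng.integers(0, 2, size=(pop_size, problem.n_signs))
    pop[0, : problem.n_edges] = 1  # seed the all-kept candidate

    def score(genome: np.ndarray) -> tuple[int, int, int, int]:
        # a stable steady state is the model's notion of a phenotype, so a
        # fixed point beats a cycle at equal mismatch; then minimal pruning;
        # then prefer attractor states actively sustained by regulation
        fit, att, held = problem.evaluate(genome)
        return fit, 0 if att.kind == "fixed_point" else 1, -int(genome[: problem.n_edges].sum()), held

    history: list[int] = []
    best_genome: np.ndarray | None = None
    best_key: tuple[int, int] | None = None
    for _gen in range(params.max_generations):
        keys = [score(g) for g in pop]
        order = sorted(range(pop_size), key=lambda i: keys[i])
        gen_best = keys[order[0]]
        if best_key is None or gen_best < best_key:
            best_key = gen_best
            best_genome = pop[order[0]].copy()
        history.append(best_key[0])
        if best_key[0] == 0:
            break
        elites = pop[order[:n_elite]]
        children = [e.copy() for e in elites]
        while len(children) < pop_size:
            contenders = rng.integers(0, pop_size, size=params.tournament_size)
            p1 = pop[min(contenders, key=lambda i: keys[i])]
            contenders = rng.integers(0, pop_size, size=params.tournament_size)
            p2 = pop[min(contenders, key=lambda i: keys[i])]
            take = rng.random(n_bits) < 0.5
            child = np.where(take, p1, p2)
            flip = rng.random(n_bits) < mut
            child = child ^ flip.astype(np.uint8)
            children.append(child)
        pop = np.array(children, dtype=np.uint8)

    assert best_genome is not None and best_key is not None
    best_genome = _greedy_restore(problem, best_genome)
    final_fit, att, _held = problem.evaluate(best_genome)
    return ContextualizedTRN(
        subpopulation_id=raw.subpopulation_id,
        nodes=list(problem.nodes),
        edges=problem.materialize(best_genome),
        achieved_fitness=final_fit,
        attractor=att,
        rule=rule,
        converged=final_fit == 0,
        fitness_history=history,
    )
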
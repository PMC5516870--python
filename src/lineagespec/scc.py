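"""Stability-core analysis: sub-SCCs from elementary circuits, filtered and ranked.

A strongly connected component (SCC) is a cluster of feedback circuits and can
autonomously hold a gene expression state, which makes SCCs the candidate
stability cores of a cell subpopulation.  Large SCCs are decomposed into
smaller candidate cores: for every node, the k shortest simple self-paths
(Yen's algorithm on a split-node construction) give elementary circuits, and
each circuit's gene set induces a sub-SCC from the contextualized network.

A sub-SCC survives only if its own dynamics, started from the Booleanized
profile, settle exactly onto both the whole-network attractor and the profile
(restricted to its members).  Survivors are ranked by regulatory influence:
outgoing minus incoming interface edges, counted over Boolean-active members
only — inactive genes exert only basal influence on the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .boolnet import Attractor, BooleanNetwork, find_attractor
from .contextualize import ContextualizedTRN
from .expression import BooleanProfile
from .priors import SignedEdge

__all__ = [
    "SubSCC",
    "strongly_connected_components",
    "elementary_circuits",
    "build_subsccs",
    "consistency_filter",
    "influence_rank",
    "default_top_k",
    "TOP_K_SMALL",
    "TOP_K_LARGE",
    "TOP_K_NODE_THRESHOLD",
]

#: Number of most influential sub-SCCs retained: 5 for compact networks
#: (tens of TFs, typical of RT-PCR panels), 10 above the node threshold
#: (hundreds of TFs, typical of RNA-seq).
TOP_K_SMALL = 5
TOP_K_LARGE = 10
TOP_K_NODE_THRESHOLD = 100


def default_top_k(n_nodes: int) -> int:
    return TOP_K_SMALL if n_nodes <= TOP_K_NODE_THRESHOLD else TOP_K_LARGE


@dataclass
class SubSCC:
    """Candidate stability core: a circuit's gene set with its induced edges."""

    members: frozenset
    edges: list[SignedEdge]
    influence: int | None = None
    attractor: Attractor | None = None
    scc_id: str = ""

    def member_list(self) -> list[str]:
        return sorted(self.members)


def _digraph(nodes, edges) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from((e.source, e.target) for e in edges)
    return g


def strongly_connected_components(nodes, edges) -> list[frozenset]:
    """Maximal SCCs partitioning the nodes, largest (then lexicographic) first."""
    g = _digraph(nodes, edges)
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), tuple(sorted(c))))


def elementary_circuits(nodes, edges, k_paths: int = 1) -> list[tuple[str, ...]]:
    """k shortest elementary circuits through every node, deduplicated.

    For each node v the graph is split (edges into v redirected to a twin
    sink) and Yen's loopless k-shortest-paths enumerates simple v -> v
    cycles in edge-count order.  Circuits identical up to rotation collapse
    to a canonical form with the smallest node first.
    """
    if k_paths < 1:
        raise ValueError("k_paths must be >= 1")
    g = _digraph(nodes, edges)
    circuits: dict[tuple[str, ...], None] = {}
    for v in g.nodes:
        sink = ("__sink__", v)
        h = nx.DiGraph()
        h.add_nodes_from(g.nodes)
        h.add_node(sink)
        for u, w in g.edges:
            h.add_edge(u, sink if w == v else w)
        try:
            paths = nx.shortest_simple_paths(h, v, sink)
            for path in itertools.islice(paths, k_paths):
                cyc = tuple(path[:-1])  # drop the twin sink; cycle closes back to v
                k = min(range(len(cyc)), key=lambda i: cyc[i])
                circuits.setdefault(cyc[k:] + cyc[:k], None)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            continue
    return sorted(circuits, key=lambda c: (len(c), c))


def build_subsccs(ctrn: ContextualizedTRN, circuits: list[tuple[str, ...]]) -> list[SubSCC]:
    """Induce the contextualized network on each circuit's gene set; merge duplicates."""
    seen: dict[frozenset, SubSCC] = {}
    for circ in circuits:
        members = frozenset(circ)
        if members in seen:
            continue
        induced = [e for e in ctrn.edges if e.source in members and e.target in members]
        seen[members] = SubSCC(members=members, edges=induced)
    return sorted(seen.values(), key=lambda s: (len(s.members), tuple(sorted(s.members))))


def consistency_filter(
    subsccs: list[SubSCC],
    whole_attractor: Attractor,
    profile: BooleanProfile,
    whole_nodes: list[str] | None = None,
    rule: str = "threshold",
    any_cycle_state: bool = False,
) -> list[SubSCC]:
    """Keep sub-SCCs whose autonomous dynamics reproduce the global state.

    The induced subnetwork is simulated from the profile restricted to its
    members; it must reach a fixed point identical to both the profile and
    the whole-network attractor on those members.  ``whole_nodes`` gives the
    node order of the whole-network attractor states (defaults to the
    profile's gene order).  When the whole-network attractor is a cycle,
    strict comparison fails unless ``any_cycle_state`` allows a match
    against any one cycle state.
    """
    if whole_nodes is None:
        whole_nodes = profile.genes
    pos = {g: i for i, g in enumerate(whole_nodes)}
    kept = []
    for sub in subsccs:
        members = sub.member_list()
        net = BooleanNetwork(nodes=members, edges=sub.edges, rule=rule)
        start = profile.as_vector(members)
        att = find_attractor(net, start)
        sub.attractor = att
        if att.kind != "fixed_point":
            continue
        reached = np.asarray(att.states[0], dtype=np.uint8)
        if not np.array_equal(reached, start):
            continue
        if whole_attractor.kind == "cycle" and not any_cycle_state:
            continue
        restrictions = [
            np.asarray([state[pos[m]] for m in members], dtype=np.uint8) for state in whole_attractor.states
        ]
        if any(np.array_equal(reached, r) for r in restrictions):
            kept.append(sub)
    return kept


def influence_rank(
    subsccs: list[SubSCC],
    ctrn: ContextualizedTRN,
    profile: BooleanProfile,
    top_k: int | None = None,
) -> list[SubSCC]:
    """Rank sub-SCCs by out-minus-in interface degree over active members.

    Interface edges are counted on the contextualized network; edges whose
    member endpoint is Boolean-inactive are ignored.  Ties break by larger
    member count, then lexicographically smallest member id.
    """
    if top_k is None:
        top_k = default_top_k(len(ctrn.nodes))
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    active = profile.active_genes()
    for sub in subsccs:
        out_deg = sum(
            1 for e in ctrn.edges if e.source in sub.members and e.source in active and e.target not in sub.members
        )
        in_deg = sum(
            1 for e in ctrn.edges if e.target in sub.members and e.target in active and e.source not in sub.members
        )
        sub.influence = out_deg - in_deg
    ranked = sorted(subsccs, key=lambda s: (-s.influence, -len(s.members), tuple(sorted(s.members))))
    top = ranked[: min(top_k, len(ranked))]
    for rank, sub in enumerate(top, 1):
        sub.scc_id = f"{ctrn.subpopulation_id}:scc{rank}" if ctrn.subpopulation_id else f"scc{rank}"
    return top


def subsccs_to_tsv(subsccs: list[SubSCC], kept_ids: set[frozenset], path) -> None:
    rows = [
        {
            "members": ",".join(s.member_list()),
            "influence": s.influence if s.influence is not None else "",
            "kept": int(s.members in kept_ids),
        }
        for s in subsccs
    ]
    pd.DataFrame(rows, columns=["members", "influence", "kept"]).to_csv(path, sep="\t", index=False)
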
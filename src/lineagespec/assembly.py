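"""Combine the three evidence channels into one raw TRN per subpopulation.

The combination rule is a union of intersections: an edge enters the raw TRN
when it is (literature AND coexpression-kept) OR (binding AND
coexpression-kept).  Coexpression pairs are undirected, so a kept pair
validates either directed edge over it; direction and sign come from the
literature/binding channels (a curated literature sign wins over the
unassigned binding sign on merge).  Genes accumulating more than ``max_in``
incoming edges get a seeded random reduction to ``keep`` to bound the
contextualization search space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpr import MINetwork
from .priors import SignedEdge, UNASSIGNED

__all__ = ["RawTRN", "combine_sources", "cap_indegree", "DEFAULT_MAX_IN", "DEFAULT_KEEP_IN"]

DEFAULT_MAX_IN = 30
DEFAULT_KEEP_IN = 29


@dataclass
class RawTRN:
    """Directed signed network for one subpopulation, pre-contextualization."""

    subpopulation_id: str
    nodes: list[str]
    edges: list[SignedEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [e.pair for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (source, target) edges in TRN")

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}

    def to_tsv(self, path) -> None:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "provenance": ",".join(sorted(e.provenance)),
            }
            for e in sorted(self.edges, key=lambda e: e.pair)
        ]
        pd.DataFrame(rows, columns=["source", "target", "sign", "provenance"]).to_csv(path, sep="\t", index=False)

    def to_sif(self, path) -> None:
        rel = {"activation": "activates", "inhibition": "inhibits", UNASSIGNED: "unknown"}
        with open(path, "w") as fh:
            for e in sorted(self.edges, key=lambda e: e.pair):
                fh.write(f"{e.source}\t{rel[e.sign]}\t{e.target}\n")

    @classmethod
    def from_tsv(cls, path, subpopulation_id: str, nodes: list[str] | None = None) -> "RawTRN":
        df = pd.read_csv(path, sep="\t", dtype=str)
        edges = [
            SignedEdge(
                source=r.source,
                target=r.target,
                sign=r.sign,
                provenance=frozenset(str(r.provenance).split(",")),
            )
            for r in df.itertuples()
        ]
        if nodes is None:
            nodes = sorted({e.source for e in edges} | {e.target for e in edges})
        return cls(subpopulation_id=subpopulation_id, nodes=nodes, edges=edges)


def combine_sources(
    lit: list[SignedEdge],
    bind: list[SignedEdge],
    coex: MINetwork,
    subpopulation_id: str = "",
    nodes: list[str] | None = None,
) -> RawTRN:
    """(lit ∩ coex_kept) ∪ (bind ∩ coex_kept), with literature sign on merge."""
    kept = coex.kept_pairs()
    merged: dict[tuple[str, str], SignedEdge] = {}
    for e in lit:
        if frozenset(e.pair) in kept:
            merged[e.pair] = SignedEdge(
                source=e.source,
                target=e.target,
                sign=e.sign,
                provenance=frozenset(e.provenance | {"coexpression"}),
                weight=e.weight,
            )
    for e in bind:
        if frozenset(e.pair) in kept:
            prev = merged.get(e.pair)
            if prev is not None:
                merged[e.pair] = SignedEdge(
                    source=prev.source,
                    target=prev.target,
                    sign=prev.sign,  # curated mode-of-action beats motif presence
                    provenance=frozenset(prev.provenance | e.provenance | {"coexpression"}),
                    weight=prev.weight,
                )
            else:
                merged[e.pair] = SignedEdge(
                    source=e.source,
                    target=e.target,
                    sign=e.sign,
                    provenance=frozenset(e.provenance | {"coexpression"}),
                    weight=e.weight,
                )
    if nodes is None:
        nodes = list(coex.genes)
    return RawTRN(subpopulation_id=subpopulation_id, nodes=nodes, edges=list(merged.values()))


def cap_indegree(
    trn: RawTRN,
    max_in: int = DEFAULT_MAX_IN,
    keep: int = DEFAULT_KEEP_IN,
    seed: int | np.random.Generator = 0,
) -> RawTRN:
    """Randomly thin incoming edges of nodes with in-degree > max_in down to ``keep``."""
    if keep >= max_in:
        raise ValueError("keep must be < max_in")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_target: dict[str, list[SignedEdge]] = {}
    for e in trn.edges:
        by_target.setdefault(e.target, []).append(e)
    out: list[SignedEdge] = []
    for target in sorted(by_target):
        incoming = sorted(by_target[target], key=lambda e: e.pair)
        if len(incoming) > max_in:
            idx = rng.choice(len(incoming), size=keep, replace=False)
            incoming = [incoming[i] for i in sorted(idx)]
        out.extend(incoming)
    return RawTRN(subpopulation_id=trn.subpopulation_id, nodes=list(trn.nodes), edges=out)
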
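"""Coexpression channel: MRNET mutual-information inference with a permutation null.

Mutual information makes no distributional assumption, which suits single-cell
expression data.  MRNET scores each candidate regulator of a target by maximum
relevance minus mean redundancy with already-selected regulators (greedy
forward selection per target); the pairwise interaction strength is the larger
of the two directional selection scores, floored at zero.

Significance is assessed against a null built by shuffling each cell's values
across genes (destroying gene-gene coupling while preserving each cell's value
multiset) and re-running the same inference.  Pairs ranking in the top half of
null-calibrated p-values among nonzero-strength pairs are kept as putative
interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MINetwork",
    "mutual_information",
    "mrnet",
    "permutation_null",
    "filter_top_half",
    "default_bins",
    "DEFAULT_N_PERM",
]

#: Default number of expression-shuffling replicates for the null distribution.
DEFAULT_N_PERM = 10_000


class CoexpressionError(ValueError):
    pass


def default_bins(n_samples: int) -> int:
    """Equal-frequency bin count: ceil(sqrt(n))."""
    return max(2, math.ceil(math.sqrt(n_samples)))


@dataclass
class MINetwork:
    """Undirected MRNET result for one subpopulation.

    ``strengths`` is a symmetric non-negative gene x gene matrix with zero
    diagonal; ``pvalues`` is NaN until :func:`permutation_null` fills it;
    ``kept`` holds the unordered gene pairs surviving the top-half filter.
    """

    genes: list[str]
    strengths: np.ndarray
    pvalues: np.ndarray | None = None
    kept: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        g = len(self.genes)
        if self.strengths.shape != (g, g):
            raise CoexpressionError("strength matrix shape does not match gene list")
        if not np.allclose(self.strengths, self.strengths.T):
            raise CoexpressionError("strength matrix must be symmetric")
        if (self.strengths < 0).any() or np.diag(self.strengths).any():
            raise CoexpressionError("strengths must be non-negative with zero diagonal")

    def pair_index(self) -> list[tuple[int, int]]:
        g = len(self.genes)
        return [(i, j) for i in range(g) for j in range(i + 1, g)]

    def kept_pairs(self) -> set[frozenset]:
        return {frozenset(p) for p in self.kept}

    def to_tsv(self, path) -> None:
        rows = []
        for i, j in self.pair_index():
            a, b = sorted((self.genes[i], self.genes[j]))
            rows.append(
                {
                    "geneA": a,
                    "geneB": b,
                    "strength": self.strengths[i, j],
                    "pvalue": float("nan") if self.pvalues is None else self.pvalues[i, j],
                    "kept": int((a, b) in {tuple(sorted(p)) for p in self.kept}),
                }
            )
        pd.DataFrame(rows).sort_values(["geneA", "geneB"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutual information


def _discretize_rows(data: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency discretization of each row; ties split by stable order."""
    g, n = data.shape
    out = np.empty((g, n), dtype=np.int64)
    edges = (np.arange(n, dtype=np.int64) * bins) // n
    for r in range(g):
        order = np.argsort(data[r], kind="stable")
        out[r, order] = edges
    return out


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, bins: int) -> float:
    joint = np.bincount(cx * bins + cy, minlength=bins * bins).astype(float)
    n = joint.sum()
    p = joint / n
    px = p.reshape(bins, bins).sum(axis=1)
    py = p.reshape(bins, bins).sum(axis=0)
    outer = np.outer(px, py).ravel()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in empirical MI (nats) after equal-frequency discretization.

    Constant vectors return 0 by convention.  MI(x, x) equals the entropy of
    the discretized x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise CoexpressionError("vectors must have equal length")
    if len(x) < 4:
        raise CoexpressionError("need at least 4 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    if bins is None:
        bins = default_bins(len(x))
    if bins < 2:
        raise CoexpressionError("bins must be >= 2")
    codes = _discretize_rows(np.vstack([x, y]), bins)
    return max(0.0, _mi_from_codes(codes[0], codes[1], bins))


def _mi_matrix(data: np.ndarray, bins: int) -> np.ndarray:
    g = data.shape[0]
    constant = np.array([np.all(row == row[0]) for row in data])
    codes = _discretize_rows(data, bins)
    M = np.zeros((g, g))
    for i in range(g):
        if constant[i]:
            continue
        for j in range(i + 1, g):
            if constant[j]:
                continue
            M[i, j] = M[j, i] = max(0.0, _mi_from_codes(codes[i], codes[j], bins))
    return M


def _mrnet_strengths(M: np.ndarray) -> np.ndarray:
    """Greedy MRMR selection per target; pairwise strength = max directional score."""
    g = M.shape[0]
    sel_score = np.full((g, g), -np.inf)  # sel_score[j, t]: score of regulator j for target t
    for t in range(g):
        candidates = [j for j in range(g) if j != t]
        selected: list[int] = []
        while candidates:
            if selected:
                redundancy = M[np.ix_(candidates, selected)].mean(axis=1)
            else:
                redundancy = np.zeros(len(candidates))
            scores = M[candidates, t] - redundancy
            best = int(np.argmax(scores))  # argmax takes the first = lowest index on ties
            j = candidates.pop(best)
            sel_score[j, t] = scores[best]
            selected.append(j)
    strengths = np.maximum(sel_score, sel_score.T)
    strengths = np.maximum(strengths, 0.0)
    np.fill_diagonal(strengths, 0.0)
    return strengths


def mrnet(data, genes: list[str] | None = None, bins: int | None = None) -> MINetwork:
    """MRNET inference on a genes x cells matrix of one subpopulation."""
    if isinstance(data, pd.DataFrame):
        genes = list(data.index) if genes is None else genes
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 4:
        raise CoexpressionError("need at least 4 cells for inference")
    if genes is None:
        genes = [f"g{i}" for i in range(data.shape[0])]
    if bins is None:
        bins = default_bins(data.shape[1])
    M = _mi_matrix(data, bins)
    return MINetwork(genes=genes, strengths=_mrnet_strengths(M))


def permutation_null(
    data,
    net: MINetwork | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    bins: int | None = None,
) -> MINetwork:
    """Attach permutation p-values to an MRNET result.

    Each replicate independently shuffles every cell's values across genes and
    re-runs the inference; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise CoexpressionError("n_perm must be >= 1")
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if bins is None:
        bins = default_bins(data.shape[1])
    if net is None:
        net = mrnet(data, bins=bins)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = net.strengths
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        shuffled = rng.permuted(data, axis=0)  # per column: values move across genes
        null = _mrnet_strengths(_mi_matrix(shuffled, bins))
        exceed += null >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    return MINetwork(genes=net.genes, strengths=observed, pvalues=pvals, kept=set(net.kept))


def filter_top_half(net: MINetwork) -> MINetwork:
    """Keep the best-ranked half (by p-value) of the nonzero-strength pairs.

    Ties broken by higher observed strength, then lexicographic pair id.
    """
    if net.pvalues is None:
        raise CoexpressionError("p-values not computed; run permutation_null first")
    nonzero = [(i, j) for i, j in net.pair_index() if net.strengths[i, j] > 0]
    k = math.ceil(len(nonzero) / 2)
    ranked = sorted(
        nonzero,
        key=lambda ij: (
            net.pvalues[ij[0], ij[1]],
            -net.strengths[ij[0], ij[1]],
            tuple(sorted((net.genes[ij[0]], net.genes[ij[1]]))),
        ),
    )
    kept = {tuple(sorted((net.genes[i], net.genes[j]))) for i, j in ranked[:k]}
    return MINetwork(genes=net.genes, strengths=net.strengths, pvalues=net.pvalues, kept=kept)
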
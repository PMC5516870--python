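"""Single-cell expression input, linear-scale transforms and Booleanization.

Expression matrices are genes x cells in linear scale. Each subpopulation's
gene activity is binarized against the pooled expression of all subpopulations
that co-exist at the same developmental stage (the subpopulation's own cells
included in that background), using a one-sided Mann-Whitney-Wilcoxon test:
a gene is "differentially active" (state 1) when p <= p_cutoff.

The lenient default cutoff of 0.4 is deliberate: Booleanization feeds a
network-pruning step that tolerates false positives far better than false
negatives (a gene wrongly set to 0 can never anchor a stability core).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "StageDesign",
    "BooleanProfile",
    "read_expression",
    "impute_missing",
    "subset_tfs",
    "booleanize",
    "rank_sum_p_greater",
    "DEFAULT_P_CUTOFF",
    "DEFAULT_MISSING_TOKENS",
    "CT_EXPONENT_OFFSET",
    "EXACT_TEST_MAX_N",
]

#: p-value cutoff below which a gene counts as differentially active.
DEFAULT_P_CUTOFF = 0.4

#: Tokens treated as missing entries in expression tables.
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", "NULL")

#: K in the C_T transform value = 2**(K - C_T).  Any K gives the same ranks
#: and fold-change ratios; 0 keeps values in (0, 1] for typical C_T ranges.
CT_EXPONENT_OFFSET = 0.0

#: Largest pooled sample size for which the rank-sum p-value is computed by
#: exact enumeration of all group assignments (handles ties by midranks).
EXACT_TEST_MAX_N = 12


class ExpressionError(ValueError):
    """Raised for malformed expression inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x cells linear-scale expression with a cell -> subpopulation map.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are cell ids, non-negative.
    cell_labels
        Mapping from cell id to subpopulation id; every cell must be labeled.
    """

    values: pd.DataFrame
    cell_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ExpressionError(f"duplicate cell ids: {dupes}")
        unlabeled = [c for c in self.values.columns if c not in self.cell_labels]
        if unlabeled:
            raise ExpressionError(f"cells without subpopulation labels: {unlabeled}")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative expression values after transformation")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subpopulations(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.values.columns:
            seen.setdefault(self.cell_labels[c], None)
        return list(seen)

    def cells_of(self, subpop: str) -> list[str]:
        return [c for c in self.values.columns if self.cell_labels[c] == subpop]

    def submatrix(self, subpops: set[str] | list[str]) -> pd.DataFrame:
        wanted = set(subpops)
        cols = [c for c in self.values.columns if self.cell_labels[c] in wanted]
        return self.values[cols]


@dataclass
class StageDesign:
    """Which subpopulations co-exist at each stage, plus lineage triples.

    ``stages`` maps stage id to the set of co-existing subpopulation ids; a
    subpopulation's Booleanization background is the union of cells of its
    stage.  ``lineage_triples`` lists binary-fate events as
    (parent, daughterA, daughterB).
    """

    stages: list[tuple[str, frozenset[str]]]
    lineage_triples: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = set().union(*(s for _, s in self.stages)) if self.stages else set()
        for parent, a, b in self.lineage_triples:
            if a == b:
                raise ExpressionError(f"lineage triple with identical daughters: {a}")
            for sp in (parent, a, b):
                if sp not in members:
                    raise ExpressionError(f"subpopulation {sp!r} of a lineage triple appears in no stage")

    def stage_of(self, subpop: str) -> tuple[str, frozenset[str]]:
        hits = [(sid, s) for sid, s in self.stages if subpop in s]
        if not hits:
            raise ExpressionError(f"subpopulation {subpop!r} appears in no stage")
        if len(hits) > 1:
            raise ExpressionError(f"subpopulation {subpop!r} appears in multiple stages")
        return hits[0]

    @classmethod
    def from_yaml(cls, path) -> "StageDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        stages = [(str(sid), frozenset(map(str, subs))) for sid, subs in doc["stages"].items()]
        triples = [tuple(map(str, t)) for t in doc.get("lineage_triples", [])]
        return cls(stages=stages, lineage_triples=triples)

    def to_yaml(self, path) -> None:
        doc = {
            "stages": {sid: sorted(s) for sid, s in self.stages},
            "lineage_triples": [list(t) for t in self.lineage_triples],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class BooleanProfile:
    """Per-subpopulation differential-activity vector (the attractor target)."""

    subpopulation_id: str
    states: dict[str, int]
    pvalues: dict[str, float]

    def __post_init__(self) -> None:
        for g, s in self.states.items():
            if s not in (0, 1):
                raise ExpressionError(f"non-Boolean state for {g}: {s}")

    @property
    def genes(self) -> list[str]:
        return list(self.states)

    def active_genes(self) -> set[str]:
        return {g for g, s in self.states.items() if s == 1}

    def as_vector(self, genes: list[str]) -> np.ndarray:
        return np.array([self.states[g] for g in genes], dtype=np.uint8)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "gene": list(self.states),
                "state": [self.states[g] for g in self.states],
                "pvalue": [self.pvalues.get(g, float("nan")) for g in self.states],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subpopulation_id: str) -> "BooleanProfile":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(
            subpopulation_id=subpopulation_id,
            states={g: int(s) for g, s in zip(df["gene"], df["state"])},
            pvalues={g: float(p) for g, p in zip(df["gene"], df["pvalue"])},
        )


# ---------------------------------------------------------------------------
# Reading and transforming


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_expression(
    path,
    label_path,
    assay: str,
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    ct_offset: float = CT_EXPONENT_OFFSET,
) -> ExpressionMatrix:
    """Read a genes x cells table and return linear-scale expression.

    ``assay='ct'`` applies value = 2**(ct_offset - C_T), the monotone-
    decreasing exponential transform of normalized RT-PCR cycle thresholds;
    ``assay='fpkm'`` passes values through.  Missing entries (either the
    declared tokens or empty fields) are imputed with the lowest observed
    value on the linear scale.
    """
    if assay not in ("ct", "fpkm"):
        raise ExpressionError(f"unknown assay {assay!r}; expected 'ct' or 'fpkm'")
    raw = _read_table(path)
    mask = raw.isna()
    for tok in missing_tokens:
        mask |= raw == tok
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        vals = raw[col].where(~mask[col])
        try:
            numeric[col] = pd.to_numeric(vals)
        except (ValueError, TypeError) as exc:
            raise ExpressionError(f"non-numeric entry in column {col!r}: {exc}") from exc

    arr = numeric.to_numpy(dtype=float)
    if assay == "ct":
        with np.errstate(over="ignore"):
            arr = np.power(2.0, ct_offset - arr)
    arr = impute_missing(arr)
    values = pd.DataFrame(arr, index=raw.index, columns=raw.columns)

    labels_df = pd.read_csv(label_path, sep=None, engine="python", header=None, dtype=str, comment="#")
    if labels_df.shape[1] < 2:
        raise ExpressionError("label table must have two columns: cell_id, subpopulation_id")
    # tolerate a header row
    if labels_df.iloc[0, 0] in ("cell", "cell_id") or labels_df.iloc[0, 1] in ("subpopulation", "subpopulation_id", "label"):
        labels_df = labels_df.iloc[1:]
    labels = dict(zip(labels_df.iloc[:, 0], labels_df.iloc[:, 1]))
    return ExpressionMatrix(values=values, cell_labels=labels)


def impute_missing(values: np.ndarray) -> np.ndarray:
    """Replace NaN entries by the minimum over all non-missing entries."""
    arr = np.asarray(values, dtype=float)
    missing = np.isnan(arr)
    if not missing.any():
        return arr.copy()
    if missing.all():
        raise ExpressionError("all entries missing; nothing to impute from")
    out = arr.copy()
    out[missing] = np.nanmin(arr)
    return out


def subset_tfs(m: ExpressionMatrix, tf_list: set[str] | list[str]) -> ExpressionMatrix:
    """Restrict rows to annotated transcription factors, keeping gene order."""
    wanted = set(tf_list)
    if not wanted:
        raise ExpressionError("empty TF list")
    keep = [g for g in m.values.index if g in wanted]
    if not keep:
        raise ExpressionError("no genes of the matrix are in the TF list")
    return ExpressionMatrix(values=m.values.loc[keep], cell_labels=dict(m.cell_labels))


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon, one-sided "greater"


def _exact_p_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact conditional permutation p-value for the one-sided rank-sum test.

    Enumerates all C(n, n_x) assignments of the pooled values to the first
    group; ties are handled by midranks, so this is the exact conditional
    null of the tie-corrected statistic.
    """
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n1].sum()
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            count += 1
    return count / total


def rank_sum_p_greater(x, y, exact_max_n: int = EXACT_TEST_MAX_N) -> float:
    """One-sided MWW p-value for H1: x stochastically greater than y.

    Exact enumeration for pooled n <= ``exact_max_n``; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) <= exact_max_n:
        return _exact_p_greater(x, y)
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def booleanize(
    m: ExpressionMatrix,
    design: StageDesign,
    subpop: str,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> BooleanProfile:
    """Binarize one subpopulation's gene activity against its stage background.

    The background for each gene is the union of the expression values of all
    cells belonging to subpopulations co-existing with ``subpop`` at its
    stage, the subpopulation's own cells included.  A gene is set to 1 when
    its one-sided (greater) rank-sum p-value against that background is at
    most ``p_cutoff``.
    """
    if subpop not in m.subpopulations:
        raise ExpressionError(f"unknown subpopulation {subpop!r}")
    own_cells = m.cells_of(subpop)
    if len(own_cells) < 2:
        raise ExpressionError(f"subpopulation {subpop!r} has <2 cells")
    _, coexisting = design.stage_of(subpop)
    background = m.submatrix(coexisting)
    if background.shape[1] == 0:
        raise ExpressionError(f"empty background for {subpop!r}")
    own = m.values[own_cells]

    states: dict[str, int] = {}
    pvalues: dict[str, float] = {}
    for gene in m.gene_ids:
        p = rank_sum_p_greater(own.loc[gene].to_numpy(), background.loc[gene].to_numpy())
        pvalues[gene] = p
        states[gene] = 1 if p <= p_cutoff else 0
    return BooleanProfile(subpopulation_id=subpop, states=states, pvalues=pvalues)
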
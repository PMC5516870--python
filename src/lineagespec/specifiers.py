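"""Lineage-specifier calling for a binary-fate differentiation event.

A candidate lineage specifier for daughter A must pass four gates:
Boolean-active (1) in A and inactive (0) in the sibling daughter B; more than
2-fold higher mean linear-scale expression in A than in B; membership in a
most-influential sub-SCC of the parental subpopulation; and membership in a
most-influential sub-SCC of daughter A.  The dual-core requirement encodes
the model that a specifier must destabilize the parent's stability core and
stabilize the daughter's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .expression import BooleanProfile, ExpressionMatrix
from .scc import SubSCC

__all__ = ["SpecifierCall", "differential_tfs", "predict_specifiers", "DEFAULT_FC_CUTOFF"]

DEFAULT_FC_CUTOFF = 2.0


@dataclass(frozen=True)
class SpecifierCall:
    tf: str
    lineage: str
    fold_change: float
    parent_scc_ids: tuple[str, ...] = ()
    daughter_scc_ids: tuple[str, ...] = ()


def differential_tfs(
    profile_a: BooleanProfile,
    profile_b: BooleanProfile,
    m: ExpressionMatrix,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    use_median: bool = False,
) -> list[tuple[str, str, float]]:
    """TFs Boolean-active in exactly one daughter with > fc_cutoff expression ratio.

    Fold change is the ratio of mean (or median) linear-scale expression
    between the daughters' cells; genes whose denominator is zero are
    excluded with a warning.
    """
    genes_a, genes_b = set(profile_a.states), set(profile_b.states)
    if genes_a != genes_b:
        raise ValueError("daughter profiles cover different gene sets")
    sub_a = m.submatrix({profile_a.subpopulation_id})
    sub_b = m.submatrix({profile_b.subpopulation_id})
    if sub_a.shape[1] == 0 or sub_b.shape[1] == 0:
        raise ValueError("both daughters must have cells in the expression matrix")
    stat = (lambda df: df.median(axis=1)) if use_median else (lambda df: df.mean(axis=1))
    mean_a, mean_b = stat(sub_a), stat(sub_b)

    out: list[tuple[str, str, float]] = []
    for gene in profile_a.states:
        if gene not in mean_a.index:
            raise ValueError(f"gene {gene!r} absent from the expression matrix")
        sa, sb = profile_a.states[gene], profile_b.states[gene]
        if sa == sb:
            continue
        hi, lo = (mean_a[gene], mean_b[gene]) if sa == 1 else (mean_b[gene], mean_a[gene])
        lineage = profile_a.subpopulation_id if sa == 1 else profile_b.subpopulation_id
        if lo == 0:
            if hi > 0:
                warnings.warn(f"gene {gene}: zero mean in the inactive daughter; excluded from fold-change gate")
            continue
        fc = hi / lo
        if fc > fc_cutoff:
            out.append((gene, lineage, float(fc)))
    return out


def predict_specifiers(
    candidates: list[tuple[str, str, float]],
    parent_top: list[SubSCC],
    daughter_a_top: list[SubSCC],
    daughter_b_top: list[SubSCC],
    daughter_a_id: str | None = None,
    daughter_b_id: str | None = None,
) -> list[SpecifierCall]:
    """Gate differential TFs on membership in parent and own-daughter top cores.

    ``candidates`` are (tf, lineage, fold_change) from :func:`differential_tfs`.
    Daughter ids default to the lineage labels seen among the candidates, in
    which case the first distinct label maps to ``daughter_a_top``.
    """
    if daughter_a_id is None or daughter_b_id is None:
        seen = []
        for _, lineage, _ in candidates:
            if lineage not in seen:
                seen.append(lineage)
        if daughter_a_id is None:
            daughter_a_id = seen[0] if seen else ""
        if daughter_b_id is None:
            daughter_b_id = next((l for l in seen if l != daughter_a_id), "")

    def membership(top: list[SubSCC], tf: str) -> tuple[str, ...]:
        return tuple(s.scc_id or ",".join(s.member_list()) for s in top if tf in s.members)

    calls = []
    for tf, lineage, fc in candidates:
        daughter_top = daughter_a_top if lineage == daughter_a_id else daughter_b_top
        parent_ids = membership(parent_top, tf)
        daughter_ids = membership(daughter_top, tf)
        if parent_ids and daughter_ids:
            calls.append(
                SpecifierCall(
                    tf=tf,
                    lineage=lineage,
                    fold_change=fc,
                    parent_scc_ids=parent_ids,
                    daughter_scc_ids=daughter_ids,
                )
            )
    calls.sort(key=lambda c: (c.lineage, -c.fold_change, c.tf))
    return calls


def calls_to_tsv(calls: list[SpecifierCall], path) -> None:
    rows = [
        {
            "tf": c.tf,
            "lineage": c.lineage,
            "fold_change": f"{c.fold_change:.6g}",
            "parent_sccs": ";".join(c.parent_scc_ids),
            "daughter_sccs": ";".join(c.daughter_scc_ids),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["tf", "lineage", "fold_change", "parent_sccs", "daughter_sccs"]).to_csv(
        path, sep="\t", index=False
    )
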
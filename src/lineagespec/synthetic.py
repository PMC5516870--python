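"""Ground-truth tri-population systems with planted stability cores and specifiers.

The generator emulates the study design the pipeline targets: a bipotent
parent subpopulation P with two daughter fates A and B, profiled by
single-cell expression alongside the subpopulations they co-exist with.
Four gene classes are planted (``n_per_class`` of each):

* ``a*`` — specifiers of daughter A: active in P and A, silent in B;
* ``b*`` — specifiers of daughter B: active in P and B, silent in A;
* ``c*`` — A-specific downstream genes: active in A (and in the outgroup O);
* ``d*`` — B-specific downstream genes: active in B (and in O).

P's stability cores are mutual-activation pairs (a_i, b_i) — the two opposing
specifier sets co-expressed in the parent, locked pairwise in the classic
bistable feedback motif; daughter cores pair each specifier with one of its
lineage's downstream genes ((a_i, c_i) in A, (b_i, d_i) in B).  Every planted
profile is a verified fixed point of its network under the threshold rule,
and every specifier passes the 1/0, >2-fold and dual-core-membership gates by
construction.

The outgroup O co-exists with P at the early stage (the way trophoectoderm
co-exists with the inner cell mass) and the daughters co-exist with each
other at the late stage, so every gene is differentially active in at least
one member of each stage — Booleanization against the stage background then
has a clear decision at every gene.

Expression is bimodal log-normal: the two genes of a core pair share a
per-cell latent factor (so regulator and target are strongly co-expressed,
which is what mutual-information inference keys on, with no correlation
leaking to other pairs); silent genes are independent.  Bernoulli dropout zeroes entries at
random.  The literature channel is the union of the planted networks with a
fraction of signs erased and random decoy edges added; the binding channel
embeds each regulator's consensus motif in its targets' promoters inside a
synthetic genome.

What this does not emulate: amplification noise, batch effects, doublets,
continuous intermediate states, or realistic genome sequence composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .boolnet import BooleanNetwork, find_attractor
from .expression import BooleanProfile, ExpressionMatrix, StageDesign
from .priors import (
    ACTIVATION,
    INHIBITION,
    UNASSIGNED,
    PWM,
    SignedEdge,
    write_pwms_jaspar,
    write_signed_edgelist,
)

__all__ = ["GenerationParams", "PlantedSystem", "generate_system", "write_system"]

_BASES = "ACGT"


class GenerationError(ValueError):
    pass


@dataclass
class GenerationParams:
    """Study conditions of the synthetic system.

    ``mu_on - mu_off`` is the log-scale separation between the active and
    silent expression modes (ln 4 by default, i.e. a 4-fold mean ratio, which
    clears the 2-fold specifier gate with margin); ``sigma`` is the log-normal
    dispersion within a mode; ``pair_corr`` is the latent correlation between
    the two genes of a core pair.
    """

    n_per_class: int = 2
    cells_per_subpop: int = 30
    mu_on: float = math.log(4.0)
    mu_off: float = 0.0
    sigma: float = 0.35
    dropout: float = 0.02
    pair_corr: float = 0.9
    decoy_fraction: float = 0.5
    sign_erasure: float = 0.3
    binding_fraction: float = 0.7
    n_binding_decoys: int = 2
    promoter_up: int = 2000
    promoter_down: int = 1000
    motif_length: int = 12
    parent_id: str = "P"
    daughter_a_id: str = "A"
    daughter_b_id: str = "B"
    outgroup_id: str = "O"

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise GenerationError("need at least 2 genes per class (>= 8 genes total)")
        if self.cells_per_subpop < 8:
            raise GenerationError("need at least 8 cells per subpopulation")
        if self.mu_on - self.mu_off < math.log(4.0) - 1e-9:
            raise GenerationError("active/silent log-mean separation must be >= ln 4")


@dataclass
class PlantedSystem:
    """Everything the pipeline consumes plus the ground truth to score against."""

    params: GenerationParams
    seed: int
    gene_ids: list[str]
    true_networks: dict[str, list[SignedEdge]]
    true_cores: dict[str, frozenset]
    true_profiles: dict[str, BooleanProfile]
    planted_specifiers: dict[str, frozenset]
    expression: ExpressionMatrix
    design: StageDesign
    literature_edges: list[SignedEdge]
    pwms: list[PWM]
    genome: dict[str, str]
    tss_table: list[tuple[str, str, str, int]]
    binding_truth: list[tuple[str, str]] = field(default_factory=list)


def _pair_edges(pairs: list[tuple[str, str]]) -> list[SignedEdge]:
    out = []
    for x, y in pairs:
        out.append(SignedEdge(source=x, target=y, sign=ACTIVATION))
        out.append(SignedEdge(source=y, target=x, sign=ACTIVATION))
    return out


def generate_system(params: GenerationParams | None = None, seed: int = 0) -> PlantedSystem:
    """Build a tri-population system with planted cores and specifiers."""
    p = params or GenerationParams()
    rng = np.random.default_rng(seed)
    k = p.n_per_class
    a_genes = [f"a{i+1}" for i in range(k)]
    b_genes = [f"b{i+1}" for i in range(k)]
    c_genes = [f"c{i+1}" for i in range(k)]
    d_genes = [f"d{i+1}" for i in range(k)]
    genes = a_genes + b_genes + c_genes + d_genes
    P, A, B, O = p.parent_id, p.daughter_a_id, p.daughter_b_id, p.outgroup_id

    active = {
        P: a_genes + b_genes,
        A: a_genes + c_genes,
        B: b_genes + d_genes,
        O: c_genes + d_genes,
    }
    core_pairs = {
        P: list(zip(a_genes, b_genes)),
        A: list(zip(a_genes, c_genes)),
        B: list(zip(b_genes, d_genes)),
    }
    # cross-lineage repressions: each fate's lead specifier silences the
    # opposite lineage's downstream program where that program is off
    extra = {
        P: [SignedEdge(a_genes[0], d_genes[0], INHIBITION), SignedEdge(b_genes[0], c_genes[0], INHIBITION)],
        A: [SignedEdge(a_genes[0], b_genes[0], INHIBITION)],
        B: [SignedEdge(b_genes[0], a_genes[0], INHIBITION)],
    }
    true_networks = {sp: _pair_edges(core_pairs[sp]) + extra[sp] for sp in (P, A, B)}
    true_cores = {sp: frozenset(g for pair in core_pairs[sp] for g in pair) for sp in (P, A, B)}

    true_profiles = {}
    for sp in (P, A, B):
        states = {g: int(g in active[sp]) for g in genes}
        true_profiles[sp] = BooleanProfile(
            subpopulation_id=sp,
            states=states,
            pvalues={g: 0.0 if states[g] else 1.0 for g in genes},
        )

    # self-consistency: each planted profile must be a fixed point of its network
    for sp in (P, A, B):
        net = BooleanNetwork(nodes=genes, edges=true_networks[sp], rule="threshold")
        att = find_attractor(net, true_profiles[sp].states)
        if att.kind != "fixed_point" or att.states[0] != tuple(true_profiles[sp].as_vector(genes)):
            raise GenerationError(f"planted profile of {sp} is not a fixed point of its network")

    # ---- expression -------------------------------------------------------
    n_cells = p.cells_per_subpop
    gene_pos = {g: i for i, g in enumerate(genes)}
    blocks, cell_ids, labels = [], [], {}
    alpha = math.sqrt(p.pair_corr)
    beta = math.sqrt(1.0 - p.pair_corr)
    for sp in (P, O, A, B):
        z = rng.standard_normal((len(genes), n_cells))
        for x, y in core_pairs.get(sp, []):
            shared = rng.standard_normal(n_cells)
            z[gene_pos[x]] = alpha * shared + beta * rng.standard_normal(n_cells)
            z[gene_pos[y]] = alpha * shared + beta * rng.standard_normal(n_cells)
        mu = np.array([p.mu_on if g in active[sp] else p.mu_off for g in genes])[:, None]
        x = np.exp(mu + p.sigma * z)
        if p.dropout > 0:
            x = np.where(rng.random(x.shape) < p.dropout, 0.0, x)
        blocks.append(x)
        ids = [f"{sp}_{i+1:03d}" for i in range(n_cells)]
        cell_ids.extend(ids)
        labels.update({cid: sp for cid in ids})
    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cell_ids)
    expression = ExpressionMatrix(values=values, cell_labels=labels)

    design = StageDesign(
        stages=[("early", frozenset({P, O})), ("late", frozenset({A, B}))],
        lineage_triples=[(P, A, B)],
    )

    # fold-change gate must hold on the realized expression
    for sp, specs in ((A, a_genes), (B, b_genes)):
        other = B if sp == A else A
        for g in specs:
            hi = values.loc[g, expression.cells_of(sp)].mean()
            lo = values.loc[g, expression.cells_of(other)].mean()
            if lo <= 0 or hi / lo <= 2.0:
                raise GenerationError(
                    f"planted specifier {g} fails the 2-fold gate ({hi:.3g} vs {lo:.3g}); "
                    "increase separation or cells_per_subpop"
                )

    # ---- literature channel ----------------------------------------------
    seen: dict[tuple[str, str], SignedEdge] = {}
    for sp in (P, A, B):
        for e in true_networks[sp]:
            seen.setdefault(e.pair, e)
    true_pairs = set(seen)
    n_decoys = round(p.decoy_fraction * len(seen))
    all_pairs = [(s, t) for s in genes for t in genes if s != t and (s, t) not in true_pairs]
    decoy_idx = rng.choice(len(all_pairs), size=min(n_decoys, len(all_pairs)), replace=False)
    for i in decoy_idx:
        s, t = all_pairs[i]
        sign = ACTIVATION if rng.random() < 0.5 else INHIBITION
        seen[(s, t)] = SignedEdge(source=s, target=t, sign=sign)
    literature = []
    for e in seen.values():
        sign = UNASSIGNED if rng.random() < p.sign_erasure else e.sign
        literature.append(SignedEdge(source=e.source, target=e.target, sign=sign))

    # ---- binding channel --------------------------------------------------
    motifs = {}
    pwms = []
    for g in genes:
        consensus = "".join(_BASES[i] for i in rng.integers(0, 4, size=p.motif_length))
        motifs[g] = consensus
        mat = np.zeros((p.motif_length, 4))
        for i, base in enumerate(consensus):
            mat[i, _BASES.index(base)] = 12.0
        pwms.append(PWM(tf_id=g, matrix=mat))

    contig_len = p.promoter_up + p.promoter_down + 100
    tss = p.promoter_up + 1  # 1-based; the [TSS-up, TSS+down) window sits inside the contig
    genome = {}
    seqs = {}
    for g in genes:
        seqs[g] = list("".join(_BASES[i] for i in rng.integers(0, 4, size=contig_len)))
    binding_truth = []
    candidates = [e.pair for sp in (P, A, B) for e in true_networks[sp]]
    candidates = sorted(set(candidates))
    chosen = [pair for pair in candidates if rng.random() < p.binding_fraction]
    non_edges = [(s, t) for s in genes for t in genes if s != t and (s, t) not in true_pairs]
    decoys = [non_edges[i] for i in rng.choice(len(non_edges), size=min(p.n_binding_decoys, len(non_edges)), replace=False)]
    for src, tgt in chosen + decoys:
        window_lo, window_hi = tss - 1 - p.promoter_up, tss - 1 + p.promoter_down
        off = int(rng.integers(window_lo, window_hi - p.motif_length))
        seqs[tgt][off : off + p.motif_length] = list(motifs[src])
        binding_truth.append((src, tgt))
    genome = {f"chr_{g}": "".join(seqs[g]) for g in genes}
    tss_table = [(g, f"chr_{g}", "+", tss) for g in genes]

    return PlantedSystem(
        params=p,
        seed=seed,
        gene_ids=genes,
        true_networks=true_networks,
        true_cores=true_cores,
        true_profiles=true_profiles,
        planted_specifiers={A: frozenset(a_genes), B: frozenset(b_genes)},
        expression=expression,
        design=design,
        literature_edges=literature,
        pwms=pwms,
        genome=genome,
        tss_table=tss_table,
        binding_truth=binding_truth,
    )


def write_system(system: PlantedSystem, outdir) -> dict[str, Path]:
    """Emit the file formats the pipeline consumes, plus a ground-truth YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "design": out / "design.yaml",
        "literature": out / "literature.tsv",
        "genome": out / "genome.fa",
        "tss": out / "tss.tsv",
        "pwms": out / "pwms.jaspar",
        "truth": out / "truth.yaml",
    }
    system.expression.values.to_csv(paths["expression"], sep="\t")
    with open(paths["labels"], "w") as fh:
        for cid in system.expression.cell_ids:
            fh.write(f"{cid}\t{system.expression.cell_labels[cid]}\n")
    system.design.to_yaml(paths["design"])
    write_signed_edgelist(system.literature_edges, paths["literature"])
    with open(paths["genome"], "w") as fh:
        for chrom, seq in system.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["tss"], "w") as fh:
        fh.write("gene\tchrom\tstrand\ttss\n")
        for row in system.tss_table:
            fh.write("\t".join(map(str, row)) + "\n")
    write_pwms_jaspar(system.pwms, paths["pwms"])
    truth = {
        "seed": system.seed,
        "planted_specifiers": {sp: sorted(g) for sp, g in system.planted_specifiers.items()},
        "true_cores": {sp: sorted(c) for sp, c in system.true_cores.items()},
        "true_profiles": {sp: prof.states for sp, prof in system.true_profiles.items()},
        "true_edges": {
            sp: [[e.source, e.target, e.sign] for e in edges] for sp, edges in system.true_networks.items()
        },
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths
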
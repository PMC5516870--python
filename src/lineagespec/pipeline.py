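"""End-to-end orchestration: Booleanize -> infer -> assemble -> contextualize -> cores -> specifiers.

Per subpopulation named in a lineage triple the pipeline (i) Booleanizes
expression against the stage background, (ii) runs MRNET + permutation-null
coexpression inference on that subpopulation's cells, (iii) intersects the
literature and binding channels with the kept coexpression pairs, (iv)
GA-contextualizes the raw TRN to the Boolean profile, and (v) extracts,
filters and ranks sub-SCC stability cores.  Per lineage triple it then calls
specifiers from differential activity, fold change and dual core membership.

All randomness flows from ``RunConfig.seed``; result tables contain no
timestamps, so identical configs reproduce outputs byte for byte (run logs
carry the wall-clock data instead).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import assembly, coexpr, expression as expr, priors, scc, specifiers as spec_mod
from .contextualize import ContextualizedTRN, GAParams, contextualize as contextualize_trn, restrict_to_scc
from .expression import BooleanProfile, ExpressionMatrix, StageDesign
from .scc import SubSCC

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """All inputs and tunables of one pipeline run."""

    expression_path: str
    labels_path: str
    design_path: str
    literature_path: str
    assay: str = "fpkm"
    genome_path: str | None = None
    tss_path: str | None = None
    pwm_path: str | None = None
    pwm_format: str = "jaspar"
    tf_list_path: str | None = None
    out_dir: str = "lineagespec_out"
    p_cutoff: float = expr.DEFAULT_P_CUTOFF
    n_perm: int = coexpr.DEFAULT_N_PERM
    bins: int | None = None
    matrix_threshold: float = priors.DEFAULT_MATRIX_THRESHOLD
    core_threshold: float = priors.DEFAULT_CORE_THRESHOLD
    promoter_up: int = 2000
    promoter_down: int = 1000
    max_in: int = assembly.DEFAULT_MAX_IN
    keep_in: int = assembly.DEFAULT_KEEP_IN
    ga: GAParams = field(default_factory=GAParams)
    rule: str = "threshold"
    top_k: int | None = None
    k_paths: int = 1
    fc_cutoff: float = spec_mod.DEFAULT_FC_CUTOFF
    restrict_to_scc: bool = False
    any_cycle_state: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ga = GAParams(**doc.pop("ga", {}))
        return cls(ga=ga, **doc)


@dataclass
class PipelineResult:
    profiles: dict[str, BooleanProfile]
    raw_trns: dict[str, assembly.RawTRN]
    contextualized: dict[str, ContextualizedTRN]
    top_sccs: dict[str, list[SubSCC]]
    calls: list[spec_mod.SpecifierCall]
    out_dir: Path
    log: dict


def _stage(log: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            log.setdefault("timing_s", {})[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc

    return _Timer()


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "rule": config.rule}
    master = np.random.default_rng(config.seed)
    # one independent child stream per randomized stage, in a fixed order
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("permutation", "cap", "ga"), master.integers(0, 2**31 - 1, size=3)
    )}

    for path_attr in ("expression_path", "labels_path", "design_path", "literature_path"):
        path = getattr(config, path_attr)
        if not Path(path).exists():
            raise FileNotFoundError(f"{path_attr.replace('_path', '')} input not found: {path}")

    with _stage(log, "read"):
        matrix = expr.read_expression(config.expression_path, config.labels_path, assay=config.assay)
        if config.tf_list_path:
            tf_list = {line.strip() for line in open(config.tf_list_path) if line.strip()}
            matrix = expr.subset_tfs(matrix, tf_list)
        design = StageDesign.from_yaml(config.design_path)
        literature = priors.read_signed_edgelist(config.literature_path)
        genes = set(matrix.gene_ids)
        literature = [e for e in literature if e.source in genes and e.target in genes]

    with _stage(log, "binding"):
        binding: list[priors.SignedEdge] = []
        if config.genome_path and config.tss_path and config.pwm_path:
            promoters = priors.extract_promoters(
                config.tss_path, config.genome_path, up=config.promoter_up, down=config.promoter_down
            )
            promoters = [r for r in promoters if r.gene_id in genes]
            pwms = [p for p in priors.read_pwms(config.pwm_path, config.pwm_format) if p.tf_id in genes]
            binding = priors.predict_binding_network(
                pwms, promoters, config.matrix_threshold, config.core_threshold
            )

    subpops: list[str] = []
    for parent, a, b in design.lineage_triples:
        for sp in (parent, a, b):
            if sp not in subpops:
                subpops.append(sp)

    profiles: dict[str, BooleanProfile] = {}
    raw_trns: dict[str, assembly.RawTRN] = {}
    contextualized: dict[str, ContextualizedTRN] = {}
    top_sccs: dict[str, list[SubSCC]] = {}

    for sp in subpops:
        with _stage(log, f"booleanize:{sp}"):
            profile = expr.booleanize(matrix, design, sp, p_cutoff=config.p_cutoff)
            profile.to_tsv(out / f"profile_{sp}.tsv")
            profiles[sp] = profile

        with _stage(log, f"infer:{sp}"):
            sub = matrix.values[matrix.cells_of(sp)]
            net = coexpr.mrnet(sub, bins=config.bins)
            net = coexpr.permutation_null(
                sub, net, n_perm=config.n_perm, seed=streams["permutation"], bins=config.bins
            )
            net = coexpr.filter_top_half(net)
            net.to_tsv(out / f"coexpression_{sp}.tsv")

        with _stage(log, f"assemble:{sp}"):
            raw = assembly.combine_sources(literature, binding, net, subpopulation_id=sp)
            raw = assembly.cap_indegree(raw, config.max_in, config.keep_in, seed=streams["cap"])
            if config.restrict_to_scc:
                raw = restrict_to_scc(raw)
            raw.to_tsv(out / f"raw_trn_{sp}.tsv")
            raw.to_sif(out / f"raw_trn_{sp}.sif")
            raw_trns[sp] = raw

        with _stage(log, f"contextualize:{sp}"):
            restricted_profile = BooleanProfile(
                subpopulation_id=sp,
                states={g: profiles[sp].states[g] for g in raw.nodes},
                pvalues={g: profiles[sp].pvalues[g] for g in raw.nodes},
            )
            trn = contextualize_trn(raw, restricted_profile, config.ga, seed=streams["ga"], rule=config.rule)
            log.setdefault("ga_fitness", {})[sp] = trn.achieved_fitness
            log.setdefault("ga_converged", {})[sp] = trn.converged
            contextualized[sp] = trn
            assembly.RawTRN(subpopulation_id=sp, nodes=trn.nodes, edges=trn.edges).to_tsv(
                out / f"contextualized_trn_{sp}.tsv"
            )

        with _stage(log, f"scc:{sp}"):
            circuits = scc.elementary_circuits(trn.nodes, trn.edges, k_paths=config.k_paths)
            subs = scc.build_subsccs(trn, circuits)
            kept = scc.consistency_filter(
                subs,
                trn.attractor,
                restricted_profile,
                whole_nodes=trn.nodes,
                rule=config.rule,
                any_cycle_state=config.any_cycle_state,
            )
            top = scc.influence_rank(kept, trn, restricted_profile, top_k=config.top_k)
            scc.subsccs_to_tsv(subs, {s.members for s in top}, out / f"subsccs_{sp}.tsv")
            for rank, sub_scc in enumerate(top, 1):
                assembly.RawTRN(
                    subpopulation_id=sp, nodes=sub_scc.member_list(), edges=sub_scc.edges
                ).to_sif(out / f"top_scc_{sp}_{rank}.sif")
            top_sccs[sp] = top

    calls: list[spec_mod.SpecifierCall] = []
    for parent, a, b in design.lineage_triples:
        with _stage(log, f"predict:{parent}->{a}|{b}"):
            candidates = spec_mod.differential_tfs(
                profiles[a], profiles[b], matrix, fc_cutoff=config.fc_cutoff
            )
            calls.extend(
                spec_mod.predict_specifiers(
                    candidates,
                    top_sccs[parent],
                    top_sccs[a],
                    top_sccs[b],
                    daughter_a_id=a,
                    daughter_b_id=b,
                )
            )

    spec_mod.calls_to_tsv(calls, out / "specifiers.tsv")
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return PipelineResult(
        profiles=profiles,
        raw_trns=raw_trns,
        contextualized=contextualized,
        top_sccs=top_sccs,
        calls=calls,
        out_dir=out,
        log=log,
    )
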
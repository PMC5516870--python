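# Methods

This note documents the modelling assumptions, numerical choices, and the
design decisions taken where the method leaves room, in the order the
pipeline runs. The README describes the overall model; here we record the
details a user needs to interpret or change the defaults.

## Expression input and Booleanization

Single-cell RT-PCR input is given as normalized cycle-threshold values and
transformed to linear scale as `2^(K − C_T)` with `K = 0`
(`CT_EXPONENT_OFFSET`). Any choice of K rescales all values by a constant
factor, which leaves both the rank-based Booleanization and the fold-change
ratios invariant, so K is exposed only for presentation purposes. RNA-seq
input (FPKM) passes through unchanged. Missing entries (empty fields, `NA`
and friends; token list configurable) are imputed with the global minimum
observed value — the conventional stand-in for "below detection".

Booleanization asks, per gene and subpopulation, whether the gene is
expressed above the background formed by the union of all cells of the
subpopulations co-existing at the same developmental stage. The
subpopulation's own cells are part of that union: the background represents
the stage, not the complement. The test is the one-sided (greater)
Mann–Whitney–Wilcoxon test; `P ≤ 0.4` ⇒ state 1. The lenient cutoff is
intentional: downstream contextualization tolerates false 1s (edges into
them can be pruned) far better than false 0s, which can never anchor a
stability core. Because genes with no expression difference have P
fluctuating around 0.5, users should expect ~40% of genuinely null genes to
be called active at this cutoff; the attractor-consistency and
influence-ranking stages are the corrective filters.

P-values are computed by exact enumeration of all group assignments (with
midranks, so ties are handled exactly) whenever the pooled sample size is at
most 12, and by the tie-corrected, continuity-corrected normal approximation
above that. The exact branch exists because at RT-PCR panel sizes the
asymptotic approximation is visibly off near the 0.4 cutoff.

## Prior-knowledge channels

The literature channel is a signed directed edge list (TSV or SIF).
Duplicate (source, target) rows collapse; conflicting signs collapse to
*unassigned*, to be resolved during contextualization. Self-loops are legal
(autoregulation is a feedback circuit) but can be dropped by flag.

The binding channel scans promoter windows spanning 2,000 bp upstream to
1,000 bp downstream of the TSS (0-based half-open internally, 1-based TSS in
input tables; minus-strand windows mirrored and reverse-complemented;
clipped at contig edges). Scoring is min–max normalized log-odds against a
uniform background with pseudocount 0.01: `score = (S − S_min)/(S_max −
S_min)` where S sums the per-position log-odds of the window and S_min/S_max
are the per-position column extremes. A hit requires both the full-matrix
score and the core score — the 5 consecutive positions of highest
information content — to clear their thresholds (defaults 0.85 / 0.90,
configurable; the method's original cut-off profile is not published).
Ambiguous bases score at the column minimum, so N-runs never create hits.
Binding edges enter with sign *unassigned*: motif presence does not reveal
activation vs repression.

## Coexpression inference

Mutual information uses equal-frequency discretization (ties split by
stable sample order) and the plug-in estimator in nats. The library default
of `⌈√n⌉` bins follows common MRNET practice, but note the estimator's
finite-sample behaviour: with 30 cells and 6 bins the 36-cell joint table is
bias- and variance-dominated and genuinely coupled pairs become hard to
distinguish from null pairs. For subpopulations of a few dozen cells we use
and recommend 3–4 levels (`bins` in the run config; the worked example and
the acceptance study use 4). The permutation null — each cell's values
shuffled across genes, inference re-run, p = (1 + #{null ≥ observed}) /
(n_perm + 1) — is computed with the same bin count and therefore calibrates
away the estimator's bias wherever exchangeability holds.

MRNET records, per target, each regulator's greedy MRMR selection score;
the undirected strength is the larger of the two directional scores floored
at zero. Zero-strength pairs are "no interaction inferred": they are never
kept, and their p-value is 1 by the add-one convention. The top-half filter
keeps the `⌈T/2⌉` best pairs by p-value among the T nonzero-strength pairs,
breaking ties by higher strength and then lexicographic pair id (the method
description leaves the tie order open; this makes it deterministic).

The default of 10,000 permutations is the published setting; tests and the
acceptance study use 150–500, which is sufficient because only the
*ranking* of p-values enters the top-half filter.

## Network assembly

Raw TRN = (literature ∩ coexpression-kept) ∪ (binding ∩ coexpression-kept).
Coexpression pairs are undirected and validate both possible directed edges
over them; direction and sign always come from literature/binding. Where
literature and binding support the same edge, the curated literature sign
wins and provenance is merged. A consequence of requiring coexpression
support is that self-loops never survive assembly (a pair needs two distinct
genes); self-loops supplied directly to the dynamics or circuit analysis are
still honored. Nodes with in-degree above 30 are thinned to 29 by seeded
uniform removal, bounding the GA search space.

## Boolean dynamics

Synchronous updates under two logic rules. Threshold rule: with A and I the
summed weights of ON activators and ON inhibitors, the next state is 1 if
A > I, 0 if I > A, and the current state if A = I — including A = I = 0, so
an input-free gene holds its state. Inhibitor-dominant rule: any ON
inhibitor forces 0; otherwise any ON activator forces 1; otherwise hold.
The hold-on-tie convention is applied uniformly; note it deliberately
diverges from the narrative "activity decays without input" motivation of
the stability model — the simulation rule, not the narrative, defines the
dynamics, and the no-input case is documented here as its only point of
divergence. Attractors are detected by iterating until a state repeats;
cycles are canonicalized by rotating the lexicographically smallest state
first. Exhaustive attractor enumeration is available up to 20 nodes, seeded
random starts beyond.

## GA contextualization

Candidates are bit strings: one keep/remove bit per raw edge and one
activation/inhibition bit per unassigned edge. Fitness is the Hamming
mismatch between the profile and the attractor reached from the profile
(minimum over cycle states). Defaults: population 100, elite fraction 0.1,
tournament selection (size 2), uniform crossover, per-bit mutation rate
1/(number of bits), at most 500 generations, initial keep probability 0.8
plus one all-edges-kept seed candidate, early stop at zero mismatch.
Candidate ranking is lexicographic:

1. mismatch count;
2. fixed-point attractors before cycles (a phenotype is a stable steady
   state; a cycle grazing the profile is a weaker solution);
3. more edges kept (minimal pruning preserves maximal curated support);
4. fewer genes sustained only by the tie-hold rule in the attractor state.

The last key deserves a note: the mismatch objective alone leaves many sign
assignments free — an erased-sign edge between two active genes can be
"inhibition" without cost, because the tie rule holds the target. Such
assignments are dynamically inert and produce cores that fail the later
consistency filter when isolated. Preferring actively sustained states
(every active gene driven by surplus activation rather than frozen by a
tie) resolves these signs deterministically and matches the model's premise
that active states require constant input. A deterministic post-pass
greedily restores removed edges whenever mismatch and fixed-point-ness
allow (choosing the better sign for unassigned edges) and then flips any
free sign that lowers the held-gene count, making "minimal pruning" exact
rather than best-effort. Edge weights are fixed at 1 throughout and are not
evolved.

Non-convergence within the generation budget returns the best candidate
found, flagged `converged=False`; for large networks the raw TRN can first
be restricted to its largest SCC (`restrict_to_scc`), which is where all
downstream core analysis happens anyway.

## Stability cores and specifier calling

Elementary circuits are the k shortest simple self-paths per node (edge
count metric, k defaults to 1 — the literal shortest; configurable up, at
which point the circuit set converges to the full elementary-cycle set).
Duplicates are merged by canonical rotation; self-loops are length-1
circuits and legal single-gene cores. Each circuit induces a sub-SCC from
the contextualized network. The consistency filter simulates the induced
subnetwork alone from the profile restricted to its members and keeps it
only if it reaches a fixed point equal to both the profile and the
whole-network attractor on those members. When the whole-network attractor
is cyclic, strict comparison discards everything; an `any_cycle_state` flag
relaxes the comparison to any one cycle state (off by default).

Influence = outgoing minus incoming interface edges of the sub-SCC, counted
on the contextualized network and only over edges whose member endpoint is
Boolean-active — inactive genes exert only basal influence. Ties break by
larger member count, then smallest member id. The top 5 cores are retained
for networks of up to 100 nodes, top 10 above (RT-PCR panels vs
transcriptome-wide TF sets).

Specifier gates for daughter A: Boolean 1 in A and 0 in B; mean linear
expression in A more than 2-fold that of B (medians behind a flag; genes
with a zero denominator are excluded with a warning); membership in the
union of the parent's and of A's top cores. Only single-TF calls are made —
combinatorial specifier sets are out of scope.

## Synthetic benchmark systems

The generator plants a parent P with daughters A and B plus an outgroup O
that co-exists with P at the early stage (as trophoectoderm co-exists with
the inner cell mass), while A and B co-exist at the late stage. Gene classes
(`n_per_class` each, default 2): A-specifiers (active in P and A),
B-specifiers (P and B), A-downstream (O and A), B-downstream (O and B).
Every gene therefore differs between the members of each stage, so each
Booleanization decision has a real effect to detect — a gene constant across
a stage would sit at P ≈ 0.5, a coin flip at the 0.4 cutoff. Stability cores
are mutual-activation pairs (specifier_i ↔ partner_i), the classic bistable
motif; the planted profiles are verified fixed points at generation time,
and cross-lineage repressions (lead specifier ⊣ opposite downstream gene)
add signed interface edges.

Expression: log-normal with log-means 0 (silent) and ln 4 (active),
dispersion σ = 0.35, 30 cells per subpopulation; the two genes of a core
pair share a per-cell latent factor with correlation 0.9, and uniform
Bernoulli dropout (default 0.02) zeroes entries. These are the study
conditions, chosen so that the planted signal is detectable at the stated
sample size: the ln 4 separation gives Booleanization margins of ≥ 3 normal
standard errors per bit at 30-vs-60 cells, the 4-fold mean ratio clears the
2-fold gate with room for sampling noise, and the pair coupling keeps
regulator–target mutual information well above the plug-in estimator's null
at 3–4 bins. Dropout is deliberately small: with 30 cells, a binomial
fluctuation of ≥ 5 zeros on one core gene (likely at a 5% rate across a
whole system) destroys that pair's rank coupling and no estimator could
recover the edge; at 2% the expected zeros per gene stay below one.

The evidence channels add realistic contamination: the literature list is
the union of all three planted networks plus 50% random decoy edges, with
30% of signs erased; the binding channel embeds each regulator's 12-bp
consensus motif in its targets' synthetic promoters (70% of true edges,
plus two decoy placements) inside random-sequence contigs.

What the generator does not emulate — and hence what passing tests do not
establish about real data: amplification and batch noise, doublets,
continuous differentiation intermediates, expression-dependent dropout,
realistic promoter composition, and literature bias toward well-studied
genes. The benchmark shows the machinery is correct and the pipeline
recovers a recoverable signal; it does not certify performance on any real
dataset.

## Problem sizes and determinism

Default study sizes: 8 genes × 4 subpopulations × 30 cells, 150–500
permutations in tests (10,000 remains the library default), GA populations
of 50–100 for networks of ≤ 30 edges. The acceptance script runs five
systems at 300 permutations. Every stochastic component (permutation null,
in-degree cap, GA) draws from a stream derived from the single run seed, in
a fixed order; result tables contain no timestamps, so identical
config + seed reproduces outputs byte for byte (wall-clock data lives in the
run log only).
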
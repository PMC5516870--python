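"""Non-expression evidence channels: literature edge lists and TF-DNA binding.

The literature channel is a signed directed edge list (SIF or 3-4 column TSV)
of curated TF-TF interactions.  The binding channel scans gene promoters
(2,000 bp upstream to 1,000 bp downstream of the TSS) with position weight
matrices and emits a TF -> gene edge whenever the TF's matrix hits the gene's
promoter.  Binding says nothing about mode of action, so binding-only edges
carry an unassigned sign to be resolved during contextualization.

PWM scoring is min-max normalized log-odds against a uniform background
(the scheme popularized by MATCH): a window is a hit when both the full
matrix score and the core score (the 5 consecutive most informative
positions) clear their thresholds, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs
from Bio.Seq import Seq

__all__ = [
    "SignedEdge",
    "PWM",
    "PromoterRegion",
    "PwmHit",
    "read_signed_edgelist",
    "write_signed_edgelist",
    "read_pwms",
    "extract_promoters",
    "scan_pwm",
    "predict_binding_network",
    "ACTIVATION",
    "INHIBITION",
    "UNASSIGNED",
    "DEFAULT_MATRIX_THRESHOLD",
    "DEFAULT_CORE_THRESHOLD",
    "PWM_PSEUDOCOUNT",
    "CORE_LENGTH",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNASSIGNED = "unassigned"

DEFAULT_MATRIX_THRESHOLD = 0.85
DEFAULT_CORE_THRESHOLD = 0.90
PWM_PSEUDOCOUNT = 0.01
CORE_LENGTH = 5

_BASES = "ACGT"
_SIGN_TOKENS = {
    "+": ACTIVATION,
    "activation": ACTIVATION,
    "activates": ACTIVATION,
    "act": ACTIVATION,
    "1": ACTIVATION,
    "-": INHIBITION,
    "−": INHIBITION,
    "inhibition": INHIBITION,
    "inhibits": INHIBITION,
    "inh": INHIBITION,
    "-1": INHIBITION,
    "?": UNASSIGNED,
    "unknown": UNASSIGNED,
    "unassigned": UNASSIGNED,
    "unspecified": UNASSIGNED,
    "0": UNASSIGNED,
}


class PriorInputError(ValueError):
    """Raised for malformed prior-knowledge inputs."""


@dataclass(frozen=True)
class SignedEdge:
    """Directed regulatory edge with sign and evidence provenance."""

    source: str
    target: str
    sign: str = UNASSIGNED
    provenance: frozenset = frozenset({"literature"})
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION, UNASSIGNED):
            raise PriorInputError(f"bad sign {self.sign!r}")
        if self.weight <= 0:
            raise PriorInputError("edge weight must be positive")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


def read_signed_edgelist(path, allow_self_loops: bool = True) -> list[SignedEdge]:
    """Parse a SIF ("source relation target") or TSV (source target sign [type]) file.

    Duplicate (source, target) pairs collapse to one edge; conflicting signs
    collapse to unassigned.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise PriorInputError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            # SIF puts the relation token in the middle column
            if parts[1].lower() in ("activates", "inhibits", "unknown"):
                src, tok, tgt = parts[0], parts[1].lower(), parts[2]
            else:
                src, tgt, tok = parts[0], parts[1], parts[2].lower()
            if tok not in _SIGN_TOKENS:
                raise PriorInputError(f"{path}:{lineno}: malformed sign token {tok!r}")
            if src == tgt and not allow_self_loops:
                continue
            rows.append((src, tgt, _SIGN_TOKENS[tok]))

    collapsed: dict[tuple[str, str], str] = {}
    for src, tgt, sign in rows:
        key = (src, tgt)
        if key in collapsed and collapsed[key] != sign:
            collapsed[key] = UNASSIGNED
        else:
            collapsed.setdefault(key, sign)
    return [
        SignedEdge(source=s, target=t, sign=sign, provenance=frozenset({"literature"}))
        for (s, t), sign in collapsed.items()
    ]


def write_signed_edgelist(edges, path) -> None:
    """Write edges as 3-column TSV with sign tokens {+, -, ?}."""
    rev = {ACTIVATION: "+", INHIBITION: "-", UNASSIGNED: "?"}
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{rev[e.sign]}\n")


# ---------------------------------------------------------------------------
# Position weight matrices


@dataclass
class PWM:
    """Position count/weight matrix for one TF, with MATCH-style scoring tables."""

    tf_id: str
    matrix: np.ndarray  # positions x ACGT, non-negative counts or frequencies
    core_range: tuple[int, int] = field(init=False)
    _logodds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise PriorInputError(f"PWM {self.tf_id}: matrix must be positions x 4")
        if len(self.matrix) < 4:
            raise PriorInputError(f"PWM {self.tf_id}: length must be >= 4")
        if (self.matrix < 0).any():
            raise PriorInputError(f"PWM {self.tf_id}: negative counts")
        freqs = self.matrix + PWM_PSEUDOCOUNT
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
        self._logodds = np.log(freqs / 0.25)
        info = (freqs * np.log2(freqs * 4.0)).sum(axis=1)
        w = min(CORE_LENGTH, len(info))
        sums = np.convolve(info, np.ones(w), mode="valid")
        start = int(np.argmax(sums))
        self.core_range = (start, start + w)

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self._logodds.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(tf_id=self.tf_id, matrix=self.matrix[::-1, ::-1])


def read_pwms(path, fmt: str = "jaspar") -> list[PWM]:
    """Read PWMs from a JASPAR pfm or TRANSFAC text file via Bio.motifs."""
    if fmt not in ("jaspar", "transfac"):
        raise PriorInputError(f"unknown PWM format {fmt!r}")
    with open(path) as fh:
        parsed = motifs.parse(fh, fmt)
    out = []
    for mot in parsed:
        name = mot.name or getattr(mot, "matrix_id", None) or getattr(mot, "base_id", None)
        if name is None and hasattr(mot, "get"):
            name = mot.get("ID") or mot.get("AC")
        mat = np.array([[mot.counts[b][i] for b in _BASES] for i in range(mot.length)])
        out.append(PWM(tf_id=str(name), matrix=mat))
    return out


def write_pwms_jaspar(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_id} {pwm.tf_id}\n")
            for bi, base in enumerate(_BASES):
                counts = " ".join(f"{pwm.matrix[i, bi]:.0f}" for i in range(len(pwm)))
                fh.write(f"{base}  [ {counts} ]\n")


# ---------------------------------------------------------------------------
# Promoters


@dataclass
class PromoterRegion:
    """Strand-aware promoter window around a TSS, 5' -> 3' of the gene."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open on the forward genome strand
    end: int
    sequence: str


def extract_promoters(tss_table, genome_fasta, up: int = 2000, down: int = 1000) -> list[PromoterRegion]:
    """Cut [TSS-up, TSS+down) promoter windows from a genome.

    ``tss_table`` rows are (gene, chrom, strand, TSS) with a 1-based TSS.
    Minus-strand windows are mirrored and reverse-complemented so the
    returned sequence always reads upstream -> downstream of the gene.
    Windows are clipped at contig boundaries.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    regions = []
    with open(tss_table) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] in ("gene", "gene_id") and lineno == 1:
                continue
            gene, chrom, strand, tss_s = parts[:4]
            if chrom not in contigs:
                raise PriorInputError(f"{tss_table}:{lineno}: unknown chromosome {chrom!r}")
            seq = contigs[chrom]
            tss = int(tss_s)
            if not (1 <= tss <= len(seq)):
                raise PriorInputError(f"{tss_table}:{lineno}: TSS {tss} outside contig {chrom}")
            if strand == "+":
                start, end = tss - 1 - up, tss - 1 + down
            elif strand == "-":
                start, end = tss - down, tss + up
            else:
                raise PriorInputError(f"{tss_table}:{lineno}: bad strand {strand!r}")
            start_c, end_c = max(0, start), min(len(seq), end)
            window = seq[start_c:end_c]
            if strand == "-":
                window = str(Seq(window).reverse_complement())
            regions.append(
                PromoterRegion(gene_id=gene, chrom=chrom, strand=strand, start=start_c, end=end_c, sequence=window)
            )
    return regions


# ---------------------------------------------------------------------------
# Scanning


@dataclass(frozen=True)
class PwmHit:
    position: int  # offset of the window start on the region's forward sequence
    strand: str  # '+' = as given, '-' = reverse complement
    score: float
    core_score: float


def _encode(seq: str) -> np.ndarray:
    """Map bases to column indices; ambiguous bases get -1 (scored at column min)."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(logodds: np.ndarray, codes: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Min-max normalized log-odds sums for columns [lo, hi) over all windows."""
    L = len(logodds)
    n_win = len(codes) - L + 1
    sub = logodds[lo:hi]
    col_min, col_max = sub.min(axis=1), sub.max(axis=1)
    s_min, s_max = col_min.sum(), col_max.sum()
    scores = np.zeros(n_win)
    for k in range(lo, hi):
        c = codes[k : k + n_win]
        row = logodds[k]
        contrib = np.where(c >= 0, row[np.clip(c, 0, 3)], row.min())
        scores += contrib
    denom = s_max - s_min
    if denom <= 0:
        return np.ones(n_win)
    return (scores - s_min) / denom


def scan_pwm(
    pwm: PWM,
    region: PromoterRegion,
    matrix_threshold: float = DEFAULT_MATRIX_THRESHOLD,
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
) -> list[PwmHit]:
    """Scan both strands of a promoter; a hit needs core and full scores above threshold."""
    if not (0 <= matrix_threshold <= 1 and 0 <= core_threshold <= 1):
        raise PriorInputError("thresholds must lie in [0, 1]")
    L = len(pwm)
    seq = region.sequence
    if len(seq) < L:
        return []
    hits: list[PwmHit] = []
    lo, hi = pwm.core_range
    for strand, scan_seq in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        codes = _encode(scan_seq)
        full = _window_scores(pwm._logodds, codes, 0, L)
        # _window_scores indexes columns relative to the window start, so the
        # core scores are already aligned with the full-window offsets
        core_at_start = _window_scores(pwm._logodds, codes, lo, hi)
        for off in np.nonzero((full >= matrix_threshold) & (core_at_start >= core_threshold))[0]:
            pos = int(off) if strand == "+" else len(seq) - int(off) - L
            hits.append(PwmHit(position=pos, strand=strand, score=float(full[off]), core_score=float(core_at_start[off])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def predict_binding_network(
    pwms: list[PWM],
    promoters: list[PromoterRegion],
    matrix_threshold: float = DEFAULT_MATRIX_THRESHOLD,
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
) -> list[SignedEdge]:
    """TF -> gene edges (sign unassigned) wherever a TF's PWM hits a promoter."""
    edges = []
    for pwm in pwms:
        for region in promoters:
            if scan_pwm(pwm, region, matrix_threshold, core_threshold):
                edges.append(
                    SignedEdge(
                        source=pwm.tf_id,
                        target=region.gene_id,
                        sign=UNASSIGNED,
                        provenance=frozenset({"binding"}),
                    )
                )
    return edges
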
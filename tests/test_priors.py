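"""Literature edge lists, promoter extraction and PWM scanning."""

import numpy as np
import pytest
from Bio.Seq import Seq

from lineagespec.priors import (
    ACTIVATION,
    INHIBITION,
    UNASSIGNED,
    PWM,
    PriorInputError,
    PromoterRegion,
    SignedEdge,
    extract_promoters,
    predict_binding_network,
    read_pwms,
    read_signed_edgelist,
    scan_pwm,
    write_pwms_jaspar,
)

_BASES = "ACGT"


class TestEdgeList:
    def test_tsv_tokens(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t+\nB\tC\t-\nC\tD\t?\n")
        edges = {e.pair: e.sign for e in read_signed_edgelist(path)}
        assert edges == {("A", "B"): ACTIVATION, ("B", "C"): INHIBITION, ("C", "D"): UNASSIGNED}

    def test_sif_dialect(self, tmp_path):
        path = tmp_path / "edges.sif"
        path.write_text("A\tactivates\tB\nB\tinhibits\tC\n")
        edges = {e.pair: e.sign for e in read_signed_edgelist(path)}
        assert edges == {("A", "B"): ACTIVATION, ("B", "C"): INHIBITION}

    def test_conflicting_duplicates_collapse_to_unassigned(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t+\nA\tB\t-\nC\tD\t+\nC\tD\t+\n")
        edges = {e.pair: e.sign for e in read_signed_edgelist(path)}
        assert edges == {("A", "B"): UNASSIGNED, ("C", "D"): ACTIVATION}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("")
        assert read_signed_edgelist(path) == []

    def test_malformed_sign_rejected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\tmaybe\n")
        with pytest.raises(PriorInputError, match="sign token"):
            read_signed_edgelist(path)

    def test_self_loops_allowed_by_default_and_excludable(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tA\t+\n")
        assert len(read_signed_edgelist(path)) == 1
        assert read_signed_edgelist(path, allow_self_loops=False) == []


class TestExtractPromoters:
    def _genome(self, tmp_path, seq, chrom="chr1"):
        path = tmp_path / "genome.fa"
        path.write_text(f">{chrom}\n{seq}\n")
        return path

    def _tss(self, tmp_path, rows):
        path = tmp_path / "tss.tsv"
        path.write_text("".join(f"{g}\t{c}\t{s}\t{t}\n" for g, c, s, t in rows))
        return path

    def test_full_window_length(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=6000))
        regions = extract_promoters(
            self._tss(tmp_path, [("g1", "chr1", "+", 5000)]), self._genome(tmp_path, seq)
        )
        assert len(regions[0].sequence) == 3000
        # 0-based half-open [TSS-1-up, TSS-1+down)
        assert regions[0].sequence == seq[2999:5999]

    def test_clipping_at_contig_start(self, tmp_path):
        seq = "A" * 2000
        regions = extract_promoters(
            self._tss(tmp_path, [("g1", "chr1", "+", 100)]), self._genome(tmp_path, seq)
        )
        # window [-1901, 1099) clips to [0, 1099): 99 upstream + 1000 downstream
        assert len(regions[0].sequence) == 1099

    def test_minus_strand_is_reverse_complement_of_mirrored_window(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=7000))
        regions = extract_promoters(
            self._tss(tmp_path, [("g1", "chr1", "-", 3000)]), self._genome(tmp_path, seq)
        )
        expected = str(Seq(seq[2000:5000]).reverse_complement())
        assert regions[0].sequence == expected

    def test_unknown_chromosome_rejected(self, tmp_path):
        with pytest.raises(PriorInputError, match="chromosome"):
            extract_promoters(
                self._tss(tmp_path, [("g1", "chrX", "+", 10)]), self._genome(tmp_path, "ACGT")
            )

    def test_tss_outside_contig_rejected(self, tmp_path):
        with pytest.raises(PriorInputError, match="outside"):
            extract_promoters(
                self._tss(tmp_path, [("g1", "chr1", "+", 10)]), self._genome(tmp_path, "ACGT")
            )


def _pwm_from_consensus(consensus, tf_id="tf", strong=12.0):
    mat = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus):
        mat[i, _BASES.index(base)] = strong
    return PWM(tf_id=tf_id, matrix=mat)


def _region(seq, gene="g"):
    return PromoterRegion(gene_id=gene, chrom="chr", strand="+", start=0, end=len(seq), sequence=seq)


class TestScanPwm:
    def test_consensus_scores_one(self):
        pwm = _pwm_from_consensus("ACGTAC")
        hits = scan_pwm(pwm, _region("ACGTAC"), matrix_threshold=0.99, core_threshold=0.99)
        assert any(h.strand == "+" and h.score == pytest.approx(1.0) for h in hits)

    def test_anti_consensus_scores_zero(self):
        # per-position worst base everywhere gives the minimum score
        pwm = _pwm_from_consensus("AAAAAA")
        hits = scan_pwm(pwm, _region("GGGGGG"), matrix_threshold=0.0, core_threshold=0.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd and fwd[0].score == pytest.approx(0.0)

    def test_all_window_scores_match_brute_force(self):
        rng = np.random.default_rng(3)
        pwm = PWM(tf_id="t", matrix=rng.integers(0, 10, size=(4, 4)).astype(float))
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=12))
        hits = scan_pwm(pwm, _region(seq), matrix_threshold=0.0, core_threshold=0.0)
        assert len(hits) == 2 * 9

        logodds = pwm._logodds
        s_min = logodds.min(axis=1).sum()
        s_max = logodds.max(axis=1).sum()

        def brute_score(window):
            s = sum(logodds[i, _BASES.index(b)] for i, b in enumerate(window))
            return (s - s_min) / (s_max - s_min)

        rc = str(Seq(seq).reverse_complement())
        for hit in hits:
            window = seq[hit.position : hit.position + 4]
            if hit.strand == "-":
                window = str(Seq(window).reverse_complement())
            assert hit.score == pytest.approx(brute_score(window), abs=1e-12)

    def test_scores_lie_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pwm = PWM(tf_id="t", matrix=rng.integers(0, 20, size=(5, 4)).astype(float))
            seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=40))
            for h in scan_pwm(pwm, _region(seq), matrix_threshold=0.0, core_threshold=0.0):
                assert 0.0 <= h.score <= 1.0 + 1e-12

    def test_strand_symmetry(self):
        """Reverse-complementing both PWM and region leaves the hit count invariant."""
        rng = np.random.default_rng(5)
        pwm = PWM(tf_id="t", matrix=rng.integers(0, 10, size=(6, 4)).astype(float))
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=30))
        hits1 = scan_pwm(pwm, _region(seq), 0.7, 0.7)
        hits2 = scan_pwm(
            pwm.reverse_complement(), _region(str(Seq(seq).reverse_complement())), 0.7, 0.7
        )
        assert sorted(round(h.score, 9) for h in hits1) == sorted(round(h.score, 9) for h in hits2)

    def test_region_shorter_than_pwm_is_empty(self):
        pwm = _pwm_from_consensus("ACGTACGT")
        assert scan_pwm(pwm, _region("ACG"), 0.5, 0.5) == []


class TestPredictBindingNetwork:
    def test_consensus_in_promoter_gives_edge(self):
        pwm = _pwm_from_consensus("ACGTACGTACGT", tf_id="tf1")
        region = _region("TTTT" + "ACGTACGTACGT" + "TTTT", gene="g1")
        edges = predict_binding_network([pwm], [region])
        assert [(e.source, e.target, e.sign) for e in edges] == [("tf1", "g1", UNASSIGNED)]

    def test_no_consensus_no_edge_at_strict_thresholds(self):
        pwm = _pwm_from_consensus("AAAAAAAA", tf_id="tf1")
        region = _region("CGCGCGCGCGCGCGCG", gene="g1")
        assert predict_binding_network([pwm], [region], 1.0, 1.0) == []

    def test_matches_exhaustive_pairwise_scan(self):
        rng = np.random.default_rng(6)
        pwms = [_pwm_from_consensus("".join(_BASES[i] for i in rng.integers(0, 4, 8)), f"tf{k}") for k in range(3)]
        regions = [
            _region("".join(_BASES[i] for i in rng.integers(0, 4, 50)), f"g{k}") for k in range(4)
        ]
        # plant one consensus
        planted = regions[2].sequence[:10] + pwms[1].consensus + regions[2].sequence[18:]
        regions[2] = _region(planted, "g2")
        edges = {(e.source, e.target) for e in predict_binding_network(pwms, regions, 0.9, 0.9)}
        expected = {
            (p.tf_id, r.gene_id) for p in pwms for r in regions if scan_pwm(p, r, 0.9, 0.9)
        }
        assert edges == expected
        assert ("tf1", "g2") in edges


class TestPwmIO:
    def test_jaspar_round_trip(self, tmp_path):
        pwms = [_pwm_from_consensus("ACGTACGT", "tfA"), _pwm_from_consensus("GGGGCCCC", "tfB")]
        path = tmp_path / "pwms.jaspar"
        write_pwms_jaspar(pwms, path)
        loaded = read_pwms(path, "jaspar")
        assert [p.tf_id for p in loaded] == ["tfA", "tfB"]
        np.testing.assert_allclose(loaded[0].matrix, pwms[0].matrix)

    def test_core_range_is_most_informative_window(self):
        # informative consensus block in the middle of a flat matrix
        mat = np.full((10, 4), 3.0)
        mat[3:8] = 0.0
        mat[3:8, 0] = 12.0
        pwm = PWM(tf_id="t", matrix=mat)
        assert pwm.core_range == (3, 8)

    def test_short_matrix_rejected(self):
        with pytest.raises(PriorInputError, match="length"):
            PWM(tf_id="t", matrix=np.ones((3, 4)))
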
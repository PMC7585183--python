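"""PWM construction and scanning, allele windows, and motif gain/loss calls."""

import math

import numpy as np
import pytest
from Bio import motifs as bio_motifs

from sweepscan.errors import ConfigError, DataError, ParseError
from sweepscan.synthetic_data import SimulationConfig, simulate_tfbs_fixture, write_jaspar
from sweepscan.tfbs_delta import (
    PFM,
    allele_window_sequences,
    load_pfms,
    pfm_to_pwm,
    scan_pwm,
    tfbs_change,
)

JASPAR_TEXT = """>MA0001.1 toyTF
A  [ 8 0 2 2 0 4 ]
C  [ 0 8 2 2 0 0 ]
G  [ 0 0 2 2 8 0 ]
T  [ 0 0 2 2 0 4 ]
"""


@pytest.fixture
def toy_pfm(tmp_path):
    path = tmp_path / "m.jaspar"
    path.write_text(JASPAR_TEXT)
    (pfm,) = load_pfms(path)
    return pfm


class TestLoadPfms:
    def test_single_matrix_dimensions(self, toy_pfm):
        assert toy_pfm.matrix_id == "MA0001.1"
        assert toy_pfm.tf_name == "toyTF"
        assert toy_pfm.length == 6

    def test_unequal_row_lengths_rejected(self, tmp_path):
        bad = tmp_path / "bad.jaspar"
        bad.write_text(">M1 x\nA [ 1 2 ]\nC [ 1 2 3 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
        with pytest.raises(ParseError):
            load_pfms(bad)

    def test_matrix_count_equals_header_count(self, tmp_path):
        fx = simulate_tfbs_fixture(SimulationConfig(seed=3))
        path = tmp_path / "multi.jaspar"
        write_jaspar(fx.pfms * 3, path)
        headers = sum(1 for line in path.read_text().splitlines() if line.startswith(">"))
        assert len(load_pfms(path)) == headers == 3


class TestPfmToPwm:
    def test_uniform_column_is_uninformative(self):
        counts = np.full((4, 4), 25.0)
        pwm = pfm_to_pwm(PFM("U", "u", counts))
        assert np.allclose(pwm.matrix, pwm.matrix[0, 0])
        assert abs(pwm.matrix[0, 0]) < 0.02  # -> 0 as counts grow

    def test_consensus_attains_max_score(self, toy_pfm):
        pwm = pfm_to_pwm(toy_pfm)
        (hit,) = [h for h in scan_pwm(pwm.consensus, pwm, 0.999) if h.strand == "+"]
        assert hit.rel_score == pytest.approx(1.0)

    def test_two_column_score_verified_by_exhaustive_enumeration(self):
        counts = np.array([[8.0, 0.0], [0.0, 8.0], [0.0, 0.0], [0.0, 0.0]])
        pwm = pfm_to_pwm(PFM("D", "d", counts), pseudocount=0.8)
        # independent arithmetic for every dimer score
        match = math.log2(((8 + 0.8 * 0.25) / 8.8) / 0.25)
        miss = math.log2(((0 + 0.8 * 0.25) / 8.8) / 0.25)
        expected = {}
        for b1 in "ACGT":
            for b2 in "ACGT":
                s = (match if b1 == "A" else miss) + (match if b2 == "C" else miss)
                expected[b1 + b2] = s
        assert pwm.max_score == pytest.approx(max(expected.values()))
        assert pwm.min_score == pytest.approx(min(expected.values()))
        span = pwm.max_score - pwm.min_score
        for dimer, score in expected.items():
            hits = scan_pwm(dimer, pwm, min_rel_score=1e-9)
            fwd = [h for h in hits if h.strand == "+"]
            if (score - pwm.min_score) / span >= 1e-9:
                assert fwd[0].score == pytest.approx(score)
            else:  # the anti-consensus dimer sits exactly at min_score
                assert fwd == [] and score == pytest.approx(pwm.min_score)

    def test_zero_background_rejected(self, toy_pfm):
        with pytest.raises(ConfigError):
            pfm_to_pwm(toy_pfm, background=(0.5, 0.5, 0.0, 0.0))

    def test_relative_scores_invariant_under_affine_pwm_rescaling(self, toy_pfm):
        from sweepscan.tfbs_delta import PWM

        pwm1 = pfm_to_pwm(toy_pfm)
        matrix2 = 2.5 * pwm1.matrix + 0.3
        pwm2 = PWM("S", "s", matrix2,
                   max_score=float(matrix2.max(axis=0).sum()),
                   min_score=float(matrix2.min(axis=0).sum()))
        seq = "AACCGGTTAACC"
        h1 = {(h.strand, h.offset): h.rel_score for h in scan_pwm(seq, pwm1, 0.01)}
        h2 = {(h.strand, h.offset): h.rel_score for h in scan_pwm(seq, pwm2, 0.01)}
        assert h1.keys() == h2.keys()
        for key in h1:
            assert h1[key] == pytest.approx(h2[key])


class TestAlleleWindows:
    GENOME = {"c": "ACGT" * 40}

    def test_snp_windows_differ_at_one_position(self):
        win = allele_window_sequences(("c", 80, "T", "A"), self.GENOME)
        assert len(win.ref) == len(win.alt) == 60
        diffs = [i for i, (a, b) in enumerate(zip(win.ref, win.alt)) if a != b]
        assert diffs == [30]
        assert win.ref == self.GENOME["c"][49:109]

    def test_insertion_window_length_arithmetic(self):
        ins = "G" * 44
        win = allele_window_sequences(("c", 80, "T", "T" + ins), self.GENOME)
        assert len(win.ref) == 60 and len(win.alt) == 104

    def test_contig_edge_truncates_and_flags(self):
        win = allele_window_sequences(("c", 5, "A", "T"), self.GENOME)
        assert win.truncated and len(win.ref) < 60

    def test_reference_mismatch_is_an_error(self):
        with pytest.raises(DataError):
            allele_window_sequences(("c", 80, "G", "A"), self.GENOME)


class TestScanPwm:
    def test_consensus_and_its_reverse_complement_are_found(self, toy_pfm):
        pwm = pfm_to_pwm(toy_pfm)
        cons = pwm.consensus
        rc = cons.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd_hits = scan_pwm("TT" + cons + "TT", pwm, 0.95)
        rev_hits = scan_pwm("TT" + rc + "TT", pwm, 0.95)
        assert any(h.strand == "+" and h.offset == 2 for h in fwd_hits)
        assert any(h.strand == "-" and h.offset == 2 for h in rev_hits)

    def test_strand_completeness_mirrors_offsets(self, toy_pfm):
        pwm = pfm_to_pwm(toy_pfm)
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = {(h.offset, h.score) for h in scan_pwm(seq, pwm, 0.5) if h.strand == "+"}
        n = len(seq) - pwm.length
        mirrored = {
            (n - h.offset, h.score) for h in scan_pwm(rc, pwm, 0.5) if h.strand == "-"
        }
        assert {(o, round(s, 9)) for o, s in fwd} == {(o, round(s, 9)) for o, s in mirrored}

    def test_hits_match_biopython_pssm_oracle(self, toy_pfm):
        """Dual route: our scanner vs Bio.motifs PSSM on a random 60-mer."""
        pwm = pfm_to_pwm(toy_pfm, pseudocount=0.8)
        motif = bio_motifs.Motif(
            alphabet="ACGT",
            counts={b: list(toy_pfm.counts["ACGT".index(b)]) for b in "ACGT"},
        )
        motif.pseudocounts = {b: 0.8 * 0.25 for b in "ACGT"}
        motif.background = {b: 0.25 for b in "ACGT"}
        pssm = motif.pssm
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        oracle = pssm.calculate(seq)
        ours = [h for h in scan_pwm(seq, pwm, min_rel_score=1e-9) if h.strand == "+"]
        ours_by_offset = {h.offset: h.score for h in ours}
        span = pwm.max_score - pwm.min_score
        for off, score in enumerate(oracle):
            if off in ours_by_offset:
                assert ours_by_offset[off] == pytest.approx(float(score), abs=2e-3)
            else:  # below the tiny threshold: the oracle must agree it is minimal
                assert (float(score) - pwm.min_score) / span < 1e-9

    def test_window_shorter_than_motif_yields_no_hits(self, toy_pfm):
        pwm = pfm_to_pwm(toy_pfm)
        assert scan_pwm("ACG", pwm, 0.5) == []

    def test_ambiguity_bases_score_as_background(self, toy_pfm):
        pwm = pfm_to_pwm(toy_pfm)
        cons = pwm.consensus
        with_n = scan_pwm("NN" + cons + "NN", pwm, 0.9)
        assert any(h.offset == 2 and h.strand == "+" for h in with_n)


class TestTfbsChange:
    def test_identical_alleles_change_nothing(self):
        fx = simulate_tfbs_fixture(SimulationConfig(seed=1))
        chrom, pos, ref, _ = fx.variants[0]
        delta = tfbs_change((chrom, pos, ref, ref), fx.pfms, fx.genome,
                            min_rel_score=fx.min_rel_score)
        assert delta.lost == set() and delta.gained == set()

    def test_antisymmetry_of_lost_and_gained(self):
        fx = simulate_tfbs_fixture(SimulationConfig(seed=1))
        for chrom, pos, ref, alt in fx.variants:
            fwd = tfbs_change((chrom, pos, ref, alt), fx.pfms, fx.genome,
                              min_rel_score=fx.min_rel_score)
            swapped_genome = dict(fx.genome)
            seq = swapped_genome[chrom]
            swapped_genome[chrom] = seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]
            rev = tfbs_change((chrom, pos, alt, ref), fx.pfms, swapped_genome,
                              min_rel_score=fx.min_rel_score)
            assert fwd.lost == rev.gained and fwd.gained == rev.lost

    def test_lost_and_gained_are_disjoint(self):
        fx = simulate_tfbs_fixture(SimulationConfig(seed=2))
        for v in fx.variants:
            delta = tfbs_change(v, fx.pfms, fx.genome, min_rel_score=fx.min_rel_score)
            assert delta.lost.isdisjoint(delta.gained)
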
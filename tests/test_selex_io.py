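import numpy as np
import pytest

from coopselex.motif_core import PWM, consensus_to_pwm
from coopselex.selex_io import (
    RegionSet,
    SelexCycleSet,
    extract_region_sequences,
    read_cycle_reads,
    read_homer_motif,
    read_jaspar_pfm,
    subsample_reads,
    write_homer_motif,
    write_jaspar_pfm,
)

from .conftest import random_reads


class TestReadCycleReads:
    def test_fasta_read_back(self, tmp_path):
        p = tmp_path / "pool.fasta"
        p.write_text(">r1\nTAATGGGGGGGTAATCCCCC\n>r2\nACGTACGTACGTACGTACGT\n")
        reads = read_cycle_reads(p, "fasta")
        assert reads == ["TAATGGGGGGGTAATCCCCC", "ACGTACGTACGTACGTACGT"]

    def test_fastq_drops_qualities(self, tmp_path):
        p = tmp_path / "pool.fastq"
        p.write_text("@r1\nTAATGGGGGGGTAAT\n+\nIIIIIIIIIIIIIII\n")
        assert read_cycle_reads(p, "fastq") == ["TAATGGGGGGGTAAT"]

    def test_invalid_alphabet_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">r1\nTAAXGG\n")
        with pytest.raises(ValueError, match="record 0"):
            read_cycle_reads(p, "fasta")

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_cycle_reads(p, "fasta")


class TestSubsample:
    def test_n_exceeding_pool_returns_all(self):
        reads = random_reads(5, 10, seed=0)
        assert subsample_reads(reads, 10, seed=1) == reads

    def test_deterministic_under_fixed_seed(self):
        reads = random_reads(100, 10, seed=0)
        a = subsample_reads(reads, 50, seed=7)
        b = subsample_reads(reads, 50, seed=7)
        assert a == b

    def test_different_seeds_differ(self):
        reads = random_reads(100, 20, seed=0)
        a = subsample_reads(reads, 50, seed=1)
        b = subsample_reads(reads, 50, seed=2)
        assert a != b

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            subsample_reads(["AAAA"], 0, seed=1)

    def test_uniformity(self):
        """Each of 4 reads drawn ~uniformly over 10,000 single-read draws."""
        reads = ["AAAA", "CCCC", "GGGG", "TTTT"]
        counts = {r: 0 for r in reads}
        for seed in range(10_000):
            counts[subsample_reads(reads, 1, seed=seed)[0]] += 1
        se = np.sqrt(0.25 * 0.75 / 10_000)
        for r in reads:
            assert abs(counts[r] / 10_000 - 0.25) < 3 * se


class TestHomerMotifIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        pwm = PWM(rng.dirichlet(np.ones(4), size=16), name="m1", score_threshold=6.5)
        path = tmp_path / "m.motif"
        write_homer_motif(pwm, path)
        back = read_homer_motif(path)
        assert len(back) == 1
        assert back[0].length == 16
        assert back[0].score_threshold == pytest.approx(6.5)
        assert np.allclose(back[0].probs, pwm.probs, atol=1e-6)

    def test_rows_renormalized(self, tmp_path):
        path = tmp_path / "m.motif"
        path.write_text(">TAAT\tm\t5.0\n" + "0.96\t0.02\t0.02\t0.02\n" * 4)
        pwm = read_homer_motif(path)[0]
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_bad_row_width_rejected(self, tmp_path):
        path = tmp_path / "m.motif"
        path.write_text(">TAAT\tm\t5.0\n0.97 0.01 0.01\n")
        with pytest.raises(ValueError, match="4 probabilities"):
            read_homer_motif(path)

    def test_bad_row_sum_rejected(self, tmp_path):
        path = tmp_path / "m.motif"
        path.write_text(">TAAT\tm\t5.0\n0.5 0.1 0.1 0.1\n")
        with pytest.raises(ValueError, match="outside"):
            read_homer_motif(path)


class TestJasparPfm:
    def test_uniform_counts(self, tmp_path):
        pwm = PWM(np.full((4, 4), 0.25), name="uni")
        path = tmp_path / "u.pfm"
        write_jaspar_pfm(pwm, 100, path)
        text = path.read_text()
        assert text.count("25") == 16

    def test_consensus_pattern(self, tmp_path):
        pwm = consensus_to_pwm("TAAT", eps=0.0)
        path = tmp_path / "t.pfm"
        write_jaspar_pfm(pwm, 100, path)
        lines = path.read_text().splitlines()
        a_row = [int(v) for v in lines[1].split("[")[1].rstrip(" ]").split()]
        t_row = [int(v) for v in lines[4].split("[")[1].rstrip(" ]").split()]
        assert a_row == [0, 100, 100, 0]
        assert t_row == [100, 0, 0, 100]

    def test_round_trip_through_jaspar_reader(self, tmp_path):
        rng = np.random.default_rng(11)
        pwm = PWM(rng.dirichlet(np.ones(4), size=8), name="rt")
        path = tmp_path / "rt.pfm"
        write_jaspar_pfm(pwm, 10_000, path)
        back = read_jaspar_pfm(path)[0]
        assert np.allclose(back.probs, pwm.probs, atol=1e-4)


class TestRegions:
    def _genome(self, tmp_path):
        fa = tmp_path / "g.fasta"
        fa.write_text(">chr1\nTAATCC\n>chr2\nGGGGGGGGGG\n")
        return fa

    def test_basic_extraction(self, tmp_path):
        fa = self._genome(tmp_path)
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t4\n")
        rs = extract_region_sequences(bed, fa)
        assert rs.sequences == ["TAAT"]

    def test_length_conservation(self, tmp_path):
        fa = self._genome(tmp_path)
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t1\t5\nchr2\t2\t9\n")
        rs = extract_region_sequences(bed, fa)
        for (c, s, e), seq in zip(rs.intervals, rs.sequences):
            assert len(seq) == e - s

    def test_empty_interval_rejected(self, tmp_path):
        fa = self._genome(tmp_path)
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t2\t2\n")
        with pytest.raises(ValueError, match="empty interval"):
            extract_region_sequences(bed, fa)

    def test_out_of_bounds_rejected(self, tmp_path):
        fa = self._genome(tmp_path)
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t100\n")
        with pytest.raises(ValueError, match="beyond contig end"):
            extract_region_sequences(bed, fa)

    def test_missing_chromosome_named(self, tmp_path):
        fa = self._genome(tmp_path)
        bed = tmp_path / "r.bed"
        bed.write_text("chrX\t0\t4\n")
        with pytest.raises(ValueError, match="chrX"):
            extract_region_sequences(bed, fa)

    def test_region_set_validates_lengths(self):
        with pytest.raises(ValueError):
            RegionSet(intervals=[("chr1", 0, 4)], sequences=["TA"])


class TestSelexCycleSet:
    def test_requires_cycle0(self):
        cs = SelexCycleSet(cycles={1: ["AAAA"], 4: ["CCCC"]})
        with pytest.raises(ValueError, match="initial library"):
            cs.require_initial_library()

    def test_requires_two_cycles(self):
        cs = SelexCycleSet(cycles={0: ["AAAA"]})
        with pytest.raises(ValueError, match="2 cycles"):
            cs.require_initial_library()
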
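import numpy as np
import pytest
from scipy import stats

from coopselex._seq import reverse_complement
from coopselex.selex_io import RegionSet
from coopselex.spacing import (
    call_spacer_specificity,
    chi_square_independence,
    count_spacers,
    count_spacers_in_regions,
    grubbs_max_test,
)

from .conftest import random_reads


def brute_force_spacer_counts(reads, c1, c2, spacer_range, orientation):
    """Nested string-scan oracle: per-spacer read counts, either strand."""
    rc = reverse_complement
    patterns = {
        "FF": [(c1, c2), (rc(c2), rc(c1))],
        "FR": [(c1, rc(c2)), (c2, rc(c1))],
        "RF": [(rc(c1), c2), (rc(c2), c1)],
    }[orientation]
    lo, hi = spacer_range
    counts = np.zeros(hi - lo + 1, dtype=int)
    for read in reads:
        for si, s in enumerate(range(lo, hi + 1)):
            gap = 4 + s
            found = False
            for a, b in patterns:
                for p in range(len(read) - gap - 3):
                    if read[p : p + 4] == a and read[p + gap : p + gap + 4] == b:
                        found = True
            counts[si] += found
    return counts


class TestCountSpacers:
    def test_single_ff_placement(self):
        sc = count_spacers("TAAT", "TAAT", ["TAATGGGGGGGTAAT"], (0, 10))
        ff = sc.counts[:, sc.orientations.index("FF")]
        assert ff[7] == 1
        assert ff.sum() == 1

    def test_palindromic_head_to_head(self):
        sc = count_spacers("TAAT", "TAAT", ["TAATGGGATTA"], (0, 10))
        fr = sc.counts[:, sc.orientations.index("FR")]
        assert fr[3] == 1

    def test_unobservable_spacers_flagged(self):
        sc = count_spacers("TAAT", "TAAT", ["A" * 20], (0, 20))
        assert sc.observable.tolist() == [(s + 8) <= 20 for s in range(21)]

    def test_strand_symmetry(self):
        """Reverse-complementing every read leaves FF counts unchanged."""
        reads = random_reads(2000, 30, seed=31)
        rc_reads = [reverse_complement(r) for r in reads]
        a = count_spacers("TAAT", "TAAT", reads, (0, 12))
        b = count_spacers("TAAT", "TAAT", rc_reads, (0, 12))
        assert np.array_equal(
            a.counts[:, a.orientations.index("FF")],
            b.counts[:, b.orientations.index("FF")],
        )

    @pytest.mark.parametrize("orientation", ["FF", "FR", "RF"])
    def test_matches_brute_force_nested_scan(self, orientation):
        reads = random_reads(3000, 30, seed=37)
        sc = count_spacers("TAAT", "GGCA", reads, (0, 8))
        oracle = brute_force_spacer_counts(reads, "TAAT", "GGCA", (0, 8), orientation)
        got = sc.counts[:, sc.orientations.index(orientation)]
        assert np.array_equal(got, oracle)


class TestGrubbs:
    def test_constant_vector_no_outlier(self):
        g, p = grubbs_max_test([5, 5, 5, 5, 5])
        assert (g, p) == (0.0, 1.0)

    def test_clear_outlier_detected(self):
        g, p = grubbs_max_test([5, 5, 5, 5, 5, 5, 5, 500])
        # published one-sided critical value for n=8, alpha=0.05 is ~2.03
        # (two-sided table value ~2.13); G here is far beyond both
        assert g > 2.13
        assert p < 0.05

    def test_needs_three_cells(self):
        with pytest.raises(ValueError):
            grubbs_max_test([1, 2])

    def test_agrees_with_beta_form_reference(self):
        """t-form implementation vs the Beta(1/2,(n-2)/2) form of the same law."""
        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.poisson(50, size=n).astype(float)
            x[rng.integers(0, n)] += rng.integers(0, 200)
            g, p = grubbs_max_test(x)
            if x.std(ddof=1) == 0:
                continue
            b = n * g * g / (n - 1) ** 2
            p_ref = min(1.0, n * 0.5 * stats.beta.sf(b, 0.5, (n - 2) / 2))
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_type_i_error_near_alpha(self):
        """~5% rejection under the test's own (Gaussian) null, 10,000 draws.

        Skewed count nulls (e.g. iid Poisson with low mean) inflate the
        max-outlier rejection rate above alpha — a property of Grubbs, not of
        this implementation — so calibration is checked under normality.
        """
        rng = np.random.default_rng(43)
        rejections = 0
        for x in rng.normal(50, 7, size=(10_000, 21)):
            _, p = grubbs_max_test(x)
            rejections += p < 0.05
        rate = rejections / 10_000
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) < 3 * se


class TestChiSquare:
    def test_identical_proportions_give_p_one(self):
        chi2, p = chi_square_independence([10, 20, 30], [20, 40, 60])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_concentrated_shift_detected(self):
        c0 = [100] * 8
        c4 = [100] * 7 + [800]
        chi2, p = chi_square_independence(c0, c4)
        ref = stats.chi2_contingency([c0, c4], correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)
        assert p < 0.05

    def test_all_zero_cycle_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([0, 0, 0], [1, 2, 3])

    def test_agrees_with_scipy_on_random_vectors(self):
        rng = np.random.default_rng(47)
        checked = 0
        for _ in range(100):
            k = int(rng.integers(3, 15))
            c0 = rng.poisson(80, size=k) + 5  # keep expected counts >= 1
            c4 = rng.poisson(80, size=k) + 5
            chi2, p = chi_square_independence(c0, c4)
            ref = stats.chi2_contingency(np.vstack([c0, c4]), correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)
            checked += 1
        assert checked == 100

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(53)
        rejections = 0
        n_rep = 10_000
        probs = np.full(8, 1 / 8)
        c0s = rng.multinomial(800, probs, size=n_rep)
        c4s = rng.multinomial(800, probs, size=n_rep)
        for c0, c4 in zip(c0s, c4s):
            _, p = chi_square_independence(c0, c4)
            rejections += p < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestCallSpacerSpecificity:
    def _counts(self, reads, spacer_range=(0, 12)):
        return count_spacers("TAAT", "TAAT", reads, spacer_range)

    def test_planted_spacer_called(self):
        rng = np.random.default_rng(59)
        c0_reads = random_reads(3000, 25, seed=61)
        c4_reads = random_reads(3000, 25, seed=67)
        for i in range(900):
            spacer = "".join(rng.choice(list("ACGT"), 7))
            c4_reads[i] = "TAAT" + spacer + "TAAT" + c4_reads[i][15:]
        profile = call_spacer_specificity(
            self._counts(c0_reads), self._counts(c4_reads)
        )
        assert profile.called_spacer == 7
        assert profile.best_orientation == "FF"

    def test_no_selection_gives_no_call(self):
        c0 = self._counts(random_reads(3000, 25, seed=71))
        c4 = self._counts(random_reads(3000, 25, seed=73))
        profile = call_spacer_specificity(c0, c4)
        assert profile.called_spacer is None

    def test_uniform_enrichment_fails_grubbs(self):
        """Enrichment at ALL spacers equally: chi2 may fire, Grubbs must not."""
        rng = np.random.default_rng(79)
        c0_reads = random_reads(4000, 25, seed=83)
        c4_reads = random_reads(1000, 25, seed=89)
        for i in range(900):
            s = int(rng.integers(0, 9))
            spacer = "".join(rng.choice(list("ACGT"), s))
            tail = c4_reads[i][8 + s :]
            c4_reads[i] = ("TAAT" + spacer + "TAAT" + tail)[:25].ljust(25, "G")
        profile = call_spacer_specificity(
            self._counts(c0_reads), self._counts(c4_reads)
        )
        assert profile.grubbs_p > 0.05 or profile.called_spacer is None


class TestRegions:
    def test_peak_counting_matches_read_counting(self):
        regions = RegionSet(
            intervals=[("chr1", 0, 15)], sequences=["TAATGGGGGGGTAAT"]
        )
        sc = count_spacers_in_regions("TAAT", "TAAT", regions, (0, 7))
        assert sc.counts[7, sc.orientations.index("FF")] == 1

    def test_gc_peaks_all_zero(self):
        regions = RegionSet(
            intervals=[("chr1", 0, 30)], sequences=["GC" * 15]
        )
        sc = count_spacers_in_regions("AATT", "AATT", regions, (0, 10))
        assert sc.counts.sum() == 0

    def test_planted_spacer2_outlier_in_peaks(self):
        """PHOX2B-like: AATT pairs 2 bp apart enriched in synthetic peaks."""
        rng = np.random.default_rng(97)
        seqs = []
        for i in range(500):
            seq = "".join(rng.choice(list("ACGT"), 60))
            if i < 150:
                pos = int(rng.integers(0, 50))
                seq = seq[:pos] + "AATTGCAATT" + seq[pos + 10 :]
            seqs.append(seq[:60])
        regions = RegionSet(
            intervals=[("chr1", i * 60, (i + 1) * 60) for i in range(500)],
            sequences=seqs,
        )
        sc = count_spacers_in_regions("AATT", "AATT", regions, (0, 12))
        ff = sc.counts[:, sc.orientations.index("FF")]
        g, p = grubbs_max_test(ff)
        assert int(np.argmax(ff)) == 2
        assert p < 0.05
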
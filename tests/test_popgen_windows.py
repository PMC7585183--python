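"""Windowing, diversity, F_ST and ROD statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.errors import ConfigError, DataError
from sweepscan.genotype_io import GeneRegion
from sweepscan.popgen_windows import (
    Window,
    hudson_fst,
    make_windows,
    rod,
    site_pi,
    stats_to_frame,
    wc_fst,
    window_pi,
    window_stats_table,
)
from tests.conftest import make_matrix


def region_of_length(n, chrom="chr1"):
    return GeneRegion("g", chrom, "+", 1, n, 1, n)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (1200, [(0, 1000), (100, 1100), (200, 1200)]),
            (1000, [(0, 1000)]),
            (1050, [(0, 1000), (100, 1050)]),
            (400, [(0, 400)]),
        ],
    )
    def test_window_tiling(self, length, expected):
        windows = make_windows(region_of_length(length))
        assert [(w.start, w.end) for w in windows] == expected

    def test_step_must_not_exceed_window(self):
        with pytest.raises(ConfigError):
            make_windows(region_of_length(5000), window_bp=100, step_bp=200)

    def test_windows_respect_region_offset(self):
        region = GeneRegion("g", "chr1", "+", 501, 1700, 501, 1700)
        windows = make_windows(region)
        assert windows[0].start == 500 and windows[-1].end == 1700


class TestSitePi:
    def test_monomorphic_and_fixed_sites_have_zero_diversity(self):
        assert site_pi(0, 10) == 0.0
        assert site_pi(10, 10) == 0.0

    def test_matches_mean_pairwise_difference(self):
        # brute force over the 6 allele-copy pairs of {1,1,0,0}
        alleles = [1, 1, 0, 0]
        pairs = list(itertools.combinations(alleles, 2))
        brute = sum(a != b for a, b in pairs) / len(pairs)
        assert site_pi(2, 4) == pytest.approx(brute) == pytest.approx(2 / 3)

    def test_undefined_below_two_alleles(self):
        assert np.isnan(site_pi(1, 1))


def brute_force_window_pi(genotypes, window_length):
    """Mean pairwise difference among called allele copies, summed over sites,
    divided by window length.  Independent of the analytic site formula."""
    total = 0.0
    for site in genotypes:
        copies = [a for pair in site for a in pair if a >= 0]
        if len(copies) < 2:
            continue
        pairs = list(itertools.combinations(copies, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / window_length


class TestWindowPi:
    def test_two_sites_in_kilobase_window(self, two_pop_manifest):
        sites = [
            ("chr1", 100, "A", "T",
             [[0, 1], [0, 1], [-1, -1], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0]]),
            ("chr1", 200, "C", "G",
             [[1, 1], [0, 0], [-1, -1], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0]]),
        ]
        vm = make_matrix(sites, ["W1", "W2", "W3", "L1", "L2", "L3", "I1", "I2"])
        w = Window("g", "chr1", 0, 1000)
        # each site: alt 2 of 4 wild alleles -> site_pi = 2/3; total 4/3 per kb
        assert window_pi(vm, two_pop_manifest, "wild", w) == pytest.approx(4 / 3 / 1000)

    def test_no_variants_gives_zero(self, two_pop_manifest):
        vm = make_matrix([], ["W1", "W2", "W3", "L1", "L2", "L3", "I1", "I2"])
        assert window_pi(vm, two_pop_manifest, "wild", Window("g", "chr1", 0, 1000)) == 0.0

    def test_doubling_length_halves_pi(self, two_pop_manifest):
        sites = [("chr1", 100, "A", "T",
                  [[0, 1], [0, 1], [1, 1], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0]])]
        vm = make_matrix(sites, ["W1", "W2", "W3", "L1", "L2", "L3", "I1", "I2"])
        pi_1k = window_pi(vm, two_pop_manifest, "wild", Window("g", "chr1", 0, 1000))
        pi_2k = window_pi(vm, two_pop_manifest, "wild", Window("g", "chr1", 0, 2000))
        assert pi_1k == pytest.approx(2 * pi_2k)

    def test_equals_brute_force_oracle_on_random_configurations(self, two_pop_manifest):
        rng = np.random.default_rng(7)
        samples = ["W1", "W2", "W3", "L1", "L2", "L3", "I1", "I2"]
        wild_cols = [0, 1, 2]
        for _ in range(30):
            n_sites = int(rng.integers(1, 11))
            sites = []
            for k in range(n_sites):
                rows = rng.choice([-1, 0, 1], size=(8, 2), p=[0.15, 0.45, 0.4])
                sites.append(("chr1", 10 * (k + 1), "A", "T", rows.tolist()))
            vm = make_matrix(sites, samples)
            w = Window("g", "chr1", 0, 1000)
            brute = brute_force_window_pi(vm.genotypes[:, wild_cols, :], 1000)
            assert window_pi(vm, two_pop_manifest, "wild", w) == pytest.approx(
                brute, abs=1e-12
            )


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        assert hudson_fst(20, 20, 0, 20) == pytest.approx(1.0)

    def test_identical_frequencies_are_nonpositive(self):
        assert hudson_fst(5, 10, 5, 10) <= 0.0

    def test_hand_evaluated_example(self):
        # p_A = 0.6, p_B = 0.1, n = 10 alleles each:
        # N = 0.25 - 0.24/9 - 0.09/9, D = 0.54 + 0.04
        expected = (0.25 - 0.24 / 9 - 0.09 / 9) / 0.58
        assert hudson_fst(6, 10, 1, 10) == pytest.approx(expected)
        assert expected == pytest.approx(0.3678, abs=2e-4)

    def test_window_value_is_ratio_of_sums(self):
        alt_a = np.array([6, 0]); n_a = np.array([10, 10])
        alt_b = np.array([1, 10]); n_b = np.array([10, 10])
        num = sum(
            (pa - pb) ** 2 - pa * (1 - pa) / 9 - pb * (1 - pb) / 9
            for pa, pb in [(0.6, 0.1), (0.0, 1.0)]
        )
        den = sum(pa * (1 - pb) + pb * (1 - pa) for pa, pb in [(0.6, 0.1), (0.0, 1.0)])
        assert hudson_fst(alt_a, n_a, alt_b, n_b) == pytest.approx(num / den)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        na=st.integers(2, 12), nb=st.integers(2, 12),
    )
    @settings(derandomize=True, max_examples=60)
    def test_symmetry_under_label_and_population_swap(self, a, b, na, nb):
        a, b = min(a, na), min(b, nb)
        fst = hudson_fst(a, na, b, nb)
        swapped_alleles = hudson_fst(na - a, na, nb - b, nb)
        swapped_pops = hudson_fst(b, nb, a, na)
        if np.isnan(fst):
            assert np.isnan(swapped_alleles) and np.isnan(swapped_pops)
        else:
            assert fst == pytest.approx(swapped_alleles)
            assert fst == pytest.approx(swapped_pops)

    def test_undefined_when_a_population_has_below_two_alleles(self):
        assert np.isnan(hudson_fst(1, 1, 5, 10))

    def test_wc_alternative_agrees_on_fixed_difference(self):
        assert wc_fst(20, 20, 0, 20) == pytest.approx(1.0)


class TestRod:
    def test_identity_and_complete_sweep(self):
        assert rod(0.05, 0.05) == 0.0
        assert rod(0.05, 0.0) == 1.0
        assert rod(0.05, 0.01) == pytest.approx(0.8)

    def test_undefined_for_zero_ancestral_diversity(self):
        assert np.isnan(rod(0.0, 0.01))

    def test_negative_inputs_rejected(self):
        with pytest.raises(DataError):
            rod(-0.1, 0.05)

    @given(
        anc=st.floats(1e-6, 0.1), d1=st.floats(0, 0.1), d2=st.floats(0, 0.1)
    )
    @settings(derandomize=True, max_examples=60)
    def test_antitone_in_derived_diversity(self, anc, d1, d2):
        lo, hi = sorted((d1, d2))
        assert rod(anc, lo) >= rod(anc, hi)


class TestWindowStatsTable:
    def test_planted_sweep_shows_expected_structure(self, default_panel):
        cfg, vm, manifest, regions, truth = default_panel
        stats = window_stats_table(vm, manifest, regions)
        df = stats_to_frame(stats)
        swept = df[df.gene_id.isin(truth)]
        neutral = df[~df.gene_id.isin(truth)]
        assert swept.pi_local.min() < 0.1 * neutral.pi_local.mean()
        assert swept.rod_domesticated.max() > 0.9
        # planted genes rank top-2 by mean window ROD
        by_gene = df.groupby("gene_id").rod_domesticated.mean().sort_values()
        assert set(by_gene.index[-2:]) == set(truth)

    def test_permuting_samples_leaves_statistics_unchanged(self, default_panel):
        cfg, vm, manifest, regions, _ = default_panel
        rng = np.random.default_rng(3)
        perm = rng.permutation(vm.n_samples)
        shuffled = type(vm)(
            chrom=vm.chrom, pos=vm.pos, ref=vm.ref, alt=vm.alt, vclass=vm.vclass,
            genotypes=vm.genotypes[:, perm, :],
            sample_ids=[vm.sample_ids[i] for i in perm],
        )
        a = stats_to_frame(window_stats_table(vm, manifest, regions[:3]))
        b = stats_to_frame(window_stats_table(shuffled, manifest, regions[:3]))
        for col in ("pi_wild", "pi_local", "fst_wild_local", "rod_domesticated"):
            np.testing.assert_allclose(a[col], b[col], equal_nan=True)

    def test_translation_invariance_of_window_statistics(self, two_pop_manifest):
        samples = ["W1", "W2", "W3", "L1", "L2", "L3", "I1", "I2"]
        rng = np.random.default_rng(11)
        sites, shifted = [], []
        for k in range(12):
            pos = int(rng.integers(1, 2001))
            rows = rng.choice([0, 1], size=(8, 2)).tolist()
            sites.append(("chr1", pos, "A", "T", rows))
            shifted.append(("chr1", pos + 700, "A", "T", rows))
        region = GeneRegion("g", "chr1", "+", 1, 2000, 1, 2000)
        region_shift = GeneRegion("g", "chr1", "+", 701, 2700, 701, 2700)
        a = stats_to_frame(
            window_stats_table(make_matrix(sites, samples), two_pop_manifest, [region])
        )
        b = stats_to_frame(
            window_stats_table(
                make_matrix(shifted, samples), two_pop_manifest, [region_shift]
            )
        )
        for col in ("n_sites", "pi_wild", "fst_wild_local", "rod_domesticated"):
            np.testing.assert_allclose(a[col], b[col], equal_nan=True)

    def test_region_without_variants_yields_flagged_windows(self, two_pop_manifest):
        vm = make_matrix(
            [("chr9", 5, "A", "T", [[0, 1]] * 8)],
            ["W1", "W2", "W3", "L1", "L2", "L3", "I1", "I2"],
        )
        region = GeneRegion("empty", "chr1", "+", 1, 1500, 1, 1500)
        stats = window_stats_table(vm, two_pop_manifest, [region])
        assert all(s.n_sites == 0 for s in stats)
        assert all(s.pi["wild"] == 0 for s in stats)
        assert all(np.isnan(s.fst["wild_local"]) for s in stats)
        assert all(np.isnan(s.rod_domesticated) for s in stats)
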
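"""Population-genetic statistics against independent oracles."""

import numpy as np
import pytest

from altadapt.popgen import (HaplotypeSet, delta_af, ehh, integrated_ehh,
                             ihs_unstandardized, ld_r2, mean_pairwise_diff,
                             standardize_scores, weir_cockerham_fst,
                             xpehh_unstandardized)


def wc_fst_oracle(counts1, counts2):
    """Line-by-line Weir & Cockerham (1984) a/b/c for two populations.

    Written independently of the vectorized implementation: scalar
    arithmetic straight from the published variance components.
    """
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (2 * counts1[2] + counts1[1]) / (2 * n1)
    p2 = (2 * counts2[2] + counts2[1]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        # all pop1 homozygous alt, all pop2 homozygous ref, any sample size
        for n1, n2 in [(5, 5), (10, 3), (38, 39)]:
            theta = weir_cockerham_fst([[0, 0, n1]], [[n2, 0, 0]])
            assert theta[0] == pytest.approx(1.0)

    def test_monomorphic_in_both_is_missing(self):
        theta = weir_cockerham_fst([[10, 0, 0]], [[7, 0, 0]])
        assert np.isnan(theta[0])

    def test_against_hand_oracle_hw_counts(self):
        # n1=n2=10, p=0.8 vs 0.2, Hardy-Weinberg-ish integer genotype counts
        c1, c2 = (1, 2, 7), (7, 2, 1)
        assert weir_cockerham_fst([c1], [c2])[0] == pytest.approx(
            wc_fst_oracle(c1, c2), abs=1e-12)

    def test_against_hand_oracle_random_fixtures(self, rng):
        for _ in range(100):
            c1 = tuple(rng.integers(0, 20, size=3) + np.array([1, 1, 1]))
            c2 = tuple(rng.integers(0, 20, size=3) + np.array([1, 1, 1]))
            got = weir_cockerham_fst([c1], [c2])[0]
            want = wc_fst_oracle(c1, c2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_allele_label_swap_invariance(self, rng):
        for _ in range(20):
            c1 = rng.integers(1, 15, size=3)
            c2 = rng.integers(1, 15, size=3)
            assert weir_cockerham_fst([c1], [c2])[0] == pytest.approx(
                weir_cockerham_fst([c1[::-1]], [c2[::-1]])[0], abs=1e-12)


class TestDeltaAF:
    def test_published_example(self):
        # highland 0.76 vs lowland 0.03
        assert delta_af(0.76, 0.03) == pytest.approx(0.73)

    def test_identical_and_fixed(self):
        assert delta_af(0.4, 0.4) == 0
        assert delta_af(1.0, 0.0) == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            delta_af(1.2, 0.0)


def _hapset(alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(alleles.shape[1]) * 100
    return HaplotypeSet(alleles=alleles, positions=np.asarray(positions),
                        chromosome="1",
                        populations=np.array(["P"] * alleles.shape[0]))


def ehh_bruteforce(alleles, core, allele, marker):
    """All-pairs scan: fraction of carrier pairs identical core..marker."""
    carriers = [h for h in alleles if h[core] == allele]
    lo, hi = (core + 1, marker + 1) if marker > core else (marker, core)
    n = len(carriers)
    if n < 2:
        return float("nan")
    ident = 0
    for i in range(n):
        for j in range(i + 1, n):
            seg_i = carriers[i][lo:hi]
            seg_j = carriers[j][lo:hi]
            if all(a == b and a != -1 for a, b in zip(seg_i, seg_j)):
                ident += 1
    return ident / (n * (n - 1) / 2)


class TestEHH:
    def test_identical_carriers_stay_at_one(self):
        hs = _hapset([[1, 1, 0, 1]] * 5 + [[0, 0, 0, 0]] * 3)
        e = ehh(hs, 0, 1)
        assert np.allclose(e, 1.0)

    def test_two_identical_pairs_drop_to_third(self):
        # 4 carriers: two identical pairs differing at the first flanking
        # marker -> 2 identical pairs of 6 total
        hs = _hapset([[1, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 0],
                      [0, 0, 0], [0, 1, 0]])
        e = ehh(hs, 0, 1)
        assert e[0] == 1.0
        assert e[1] == pytest.approx(2 / 6)

    def test_fewer_than_two_carriers_missing(self):
        hs = _hapset([[1, 0], [0, 0], [0, 1]])
        assert np.all(np.isnan(ehh(hs, 0, 1)))

    def test_matches_bruteforce_on_random_fixture(self, rng):
        alleles = rng.integers(0, 2, size=(20, 9)).astype(np.int8)
        alleles[rng.random(alleles.shape) < 0.05] = -1
        alleles[:, 4] = rng.integers(0, 2, size=20)  # polymorphic core
        if (alleles[:, 4] == 1).sum() < 2:
            alleles[:3, 4] = 1
        hs = _hapset(alleles)
        e = ehh(hs, 4, 1)
        for m in range(9):
            if m == 4:
                continue
            assert e[m] == pytest.approx(
                ehh_bruteforce(alleles.tolist(), 4, 1, m), abs=1e-12), m

    def test_monotone_non_increasing_outward(self, rng):
        alleles = rng.integers(0, 2, size=(30, 15)).astype(np.int8)
        alleles[:, 7] = [1] * 15 + [0] * 15
        e = ehh(_hapset(alleles), 7, 1)
        right = e[7:]
        left = e[7::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)


class TestIHS:
    def test_symmetric_structure_gives_zero(self):
        # ancestral and derived carrier sets with identical haplotype layout
        block = [[0, 1, 0, 1, 0], [0, 1, 1, 1, 0], [1, 0, 0, 0, 1], [1, 0, 1, 0, 1]]
        alleles = [[r[0], r[1], 1, r[3], r[4]] for r in block] + \
                  [[r[0], r[1], 0, r[3], r[4]] for r in block]
        score, _ = ihs_unstandardized(_hapset(alleles), 2)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_hand_integrated_three_marker_toy(self):
        # positions 0/100/200, core in the middle; ancestral carriers all
        # identical (EHH=1 both sides, area 2*100); derived carriers split
        # into two identical pairs at both flanks (EHH=1/3, trapezoid
        # area 2 * (1+1/3)/2 * 100)
        alleles = [[0, 1, 0], [0, 1, 0], [1, 1, 1], [1, 1, 1],
                   [0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]
        hs = _hapset(alleles, positions=[0, 100, 200])
        ihh_anc, _ = integrated_ehh(hs, 1, 0)
        ihh_der, _ = integrated_ehh(hs, 1, 1)
        assert ihh_anc == pytest.approx(2 * 100.0)
        assert ihh_der == pytest.approx(2 * (1 + 1 / 3) / 2 * 100)
        score, _ = ihs_unstandardized(hs, 1)
        assert score == pytest.approx(np.log(200.0 / (400 / 3)), abs=1e-12)

    def test_standardized_bins_have_zero_mean_unit_sd(self, rng):
        scores = rng.normal(0, 2, size=500)
        freqs = rng.uniform(0.05, 0.95, size=500)
        std = standardize_scores(scores, freqs)
        # recompute bin membership from the standardized output: moments
        # within each 2% frequency bin (merged where sparse) must be 0/1
        from altadapt.popgen import _frequency_bins
        bins = _frequency_bins(freqs)
        for b in np.unique(bins):
            sel = bins == b
            assert std[sel].mean() == pytest.approx(0.0, abs=1e-9)
            assert std[sel].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_position_translation_invariance(self, rng):
        alleles = rng.integers(0, 2, size=(16, 11)).astype(np.int8)
        alleles[:, 5] = [1] * 8 + [0] * 8
        pos = np.sort(rng.choice(10_000, size=11, replace=False))
        a, _ = ihs_unstandardized(_hapset(alleles, pos), 5)
        b, _ = ihs_unstandardized(_hapset(alleles, pos + 50_000), 5)
        assert a == pytest.approx(b, abs=1e-12)


class TestXPEHH:
    def test_identical_populations_give_zero(self, rng):
        alleles = rng.integers(0, 2, size=(10, 9)).astype(np.int8)
        h1 = _hapset(alleles)
        h2 = _hapset(alleles)
        score, _ = xpehh_unstandardized(h1, h2, 4)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_swept_pop1_strongly_positive(self, rng):
        uniform = np.tile(rng.integers(0, 2, size=9), (12, 1)).astype(np.int8)
        diverse = rng.integers(0, 2, size=(12, 9)).astype(np.int8)
        score, _ = xpehh_unstandardized(_hapset(uniform), _hapset(diverse), 4)
        assert score > 0.5

    def test_matches_bruteforce_integral(self, rng):
        def pooled_ihh_bruteforce(alleles, positions, core):
            n = len(alleles)
            total = n * (n - 1) / 2

            def h(m):
                lo, hi = (core + 1, m + 1) if m > core else (m, core)
                ident = sum(
                    1
                    for i in range(n)
                    for j in range(i + 1, n)
                    if all(a == b and a != -1
                           for a, b in zip(alleles[i][lo:hi], alleles[j][lo:hi]))
                )
                return ident / total

            area = 0.0
            right = list(range(core + 1, len(positions)))
            left = list(range(core - 1, -1, -1))
            for side in (right, left):
                prev_e, prev_m = 1.0, core
                for m in side:
                    e = h(m)
                    area += 0.5 * (prev_e + e) * abs(positions[m] - positions[prev_m])
                    prev_e, prev_m = e, m
                    if e < 0.05:
                        break
            return area

        alleles = rng.integers(0, 2, size=(14, 9)).astype(np.int8)
        h1 = _hapset(alleles)
        from altadapt.popgen import _pooled_ihh
        got, _ = _pooled_ihh(h1, 4, 0.05)
        want = pooled_ihh_bruteforce(alleles.tolist(), list(range(0, 900, 100)), 4)
        assert got == pytest.approx(want, abs=1e-9)


class TestLD:
    def test_self_and_anticorrelated(self):
        m = np.array([[0, 1], [0, 1], [1, 0], [1, 0], [0, 1]], dtype=np.int8)
        assert ld_r2(m, 0, 0) == pytest.approx(1.0)
        assert ld_r2(m, 0, 1) == pytest.approx(1.0)  # r^2 symmetric in sign

    def test_monomorphic_missing(self):
        m = np.array([[0, 1], [0, 0], [0, 1]], dtype=np.int8)
        assert np.isnan(ld_r2(m, 0, 1))

    def test_matches_direct_pearson(self, rng):
        m = rng.integers(0, 2, size=(10, 4)).astype(np.int8)
        m[:, 0] = [0, 1] * 5
        m[:, 1] = rng.integers(0, 2, size=10)
        if m[:, 1].std() == 0:
            m[0, 1] = 1 - m[0, 1]
        want = np.corrcoef(m[:, 0], m[:, 1])[0, 1] ** 2
        assert ld_r2(m, 0, 1) == pytest.approx(want, abs=1e-12)


class TestPiBar:
    def test_two_haplotypes_three_diffs(self):
        hs = _hapset([[0, 0, 0, 0], [1, 1, 1, 0]])
        assert mean_pairwise_diff(hs) == pytest.approx(3.0)

    def test_identical_haplotypes_zero(self):
        hs = _hapset([[1, 0, 1]] * 4)
        assert mean_pairwise_diff(hs) == 0.0

    def test_requires_two_haplotypes(self):
        with pytest.raises(ValueError):
            mean_pairwise_diff(_hapset([[0, 1]]))

    def test_matches_pair_enumeration(self, rng):
        alleles = rng.integers(0, 2, size=(5, 20)).astype(np.int8)
        hs = _hapset(alleles)
        n = 5
        total = sum(
            (alleles[i] != alleles[j]).sum()
            for i in range(n) for j in range(i + 1, n)
        )
        assert mean_pairwise_diff(hs) == pytest.approx(2 * total / (n * (n - 1)))

    def test_heterozygosity_identity_complete_data(self, rng):
        # pi-bar equals sum over sites of 2p(1-p) n/(n-1) without missingness
        alleles = rng.integers(0, 2, size=(12, 30)).astype(np.int8)
        hs = _hapset(alleles)
        p = alleles.mean(axis=0)
        n = 12
        want = (2 * p * (1 - p) * n / (n - 1)).sum()
        assert mean_pairwise_diff(hs) == pytest.approx(want, abs=1e-9)
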
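import itertools
import math

import numpy as np
import pytest

from palmscan import io_core, popgen_stats as ps
from palmscan.io_core import ConfigurationError, GenotypeMatrix, make_windows

from conftest import make_two_pop_matrix


def pi_pairs_oracle(alt_count, n_alleles):
    """Site pi by direct enumeration of allele pairs."""
    if n_alleles < 2:
        return float("nan")
    alleles = [1] * alt_count + [0] * (n_alleles - alt_count)
    diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
    return diffs / math.comb(n_alleles, 2)


def wc_anova(genos1, genos2):
    """Weir-Cockerham a, b, c for one site via ANOVA mean squares.

    genos1/genos2: dosage lists for the two populations (no missing).
    Independent of the package formulation: builds sums of squares for
    populations, individuals-within-populations, and gametes-within-
    individuals, then converts mean squares to variance components.
    """
    pops = [list(genos1), list(genos2)]
    n_i = [len(g) for g in pops]
    n_tot = sum(n_i)
    r = 2
    p_i = [sum(g) / (2 * n) for g, n in zip(pops, n_i)]
    p_bar = sum(sum(g) for g in pops) / (2 * n_tot)
    ssp = sum(2 * n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i))
    ssi = sum(
        2 * (g / 2 - p) ** 2 for gs, p in zip(pops, p_i) for g in gs
    )
    ssg = sum(g * (2 - g) / 2 for gs in pops for g in gs)
    msp = ssp / (r - 1)
    msi = ssi / (n_tot - r)
    msg = ssg / n_tot
    n_c = (n_tot - sum(n * n for n in n_i) / n_tot) / (r - 1)
    a = (msp - msi) / (2 * n_c)
    b = (msi - msg) / 2
    c = msg
    return a, b, c


class TestFilterVariants:
    def test_missingness_strictly_above_threshold_removed(self):
        # 72 alleles per site; one site with 21 missing alleles, one with 20.
        n = 36
        # a missing sample contributes 2 missing alleles
        site_20 = [io_core.MISSING] * 10 + [1] * 26  # 20/72 missing
        site_22 = [io_core.MISSING] * 11 + [1] * 25  # 22/72 missing
        gt = np.array([site_20, site_22], dtype=np.int8)
        m = GenotypeMatrix(
            [f"s{i}" for i in range(n)],
            ["A"] * 18 + ["B"] * 18,
            ["chr1", "chr1"],
            [10, 20],
            ["A", "A"],
            ["T", "T"],
            gt,
        )
        kept = ps.filter_variants(m, max_missing_fraction=20 / 72)
        assert kept.n_sites == 1
        assert kept.pos.tolist() == [10]

    def test_defaults_keep_everything(self, toy_matrix):
        assert ps.filter_variants(toy_matrix) == toy_matrix

    def test_min_maf_hand_count(self):
        # 4 samples, alt counts 1/8, 2/8, 4/8 -> MAF .125, .25, .5
        m = make_two_pop_matrix(
            [[0, 1], [1, 1], [2, 2]], [[0, 0], [0, 0], [0, 0]], pos=[10, 20, 30]
        )
        kept = ps.filter_variants(m, min_maf=0.2)
        assert kept.pos.tolist() == [20, 30]


class TestSitePi:
    def test_worked_example(self):
        # 3 alt alleles among 30: pi = 3*27 / C(30,2) = 81/435
        assert ps.site_pi(np.array([3]), np.array([30]))[0] == pytest.approx(
            81 / 435
        )

    def test_matches_allele_pair_enumeration(self):
        for n in range(2, 13):
            for c in range(n + 1):
                got = ps.site_pi(np.array([c]), np.array([n]))[0]
                assert got == pytest.approx(pi_pairs_oracle(c, n), abs=1e-12)

    def test_fewer_than_two_alleles_is_nan(self):
        out = ps.site_pi(np.array([0, 1]), np.array([0, 1]))
        assert np.isnan(out).all()


class TestWindowDiversity:
    def test_monomorphic_window_has_zero_s_and_undefined_d(self):
        m = make_two_pop_matrix([[0, 0], [0, 0]], [[0, 0], [0, 0]], pos=[10, 20])
        (d,) = ps.window_diversity(m, [io_core.GenomicWindow("chr1", 0, 100)])
        assert d.S == 0 and d.pi == 0 and d.theta_w == 0
        assert math.isnan(d.tajima_d)

    def test_d_undefined_iff_no_segregating_sites(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            gt = rng.integers(0, 3, size=(5, 6)).astype(np.int8)
            m = make_two_pop_matrix(gt[:, :3].tolist(), gt[:, 3:].tolist())
            (d,) = ps.window_diversity(m, [io_core.GenomicWindow("chr1", 0, 100)])
            assert math.isnan(d.tajima_d) == (d.S == 0)

    def test_tajima_d_hand_computed_single_site(self):
        # n=4 alleles, one site with 1 alt: pi = 3/6 = 0.5, S = 1
        m = make_two_pop_matrix([[0]], [[1]])
        (d,) = ps.window_diversity(m, [io_core.GenomicWindow("chr1", 0, 10)])
        n = 4
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1 * a1 + a2)
        want = (0.5 - 1 / a1) / math.sqrt(e1 + e2 * 0)
        assert d.tajima_d == pytest.approx(want, abs=1e-12)

    def test_watterson_theta_counts_sites_per_bp(self):
        m = make_two_pop_matrix(
            [[0, 1], [1, 0]], [[0, 0], [0, 0]], pos=[10, 20]
        )
        (d,) = ps.window_diversity(m, [io_core.GenomicWindow("chr1", 0, 100)])
        a1 = sum(1 / i for i in range(1, 8))
        assert d.theta_w == pytest.approx(2 / a1 / 100)


class TestWindowFst:
    def test_single_site_worked_example_matches_oracle(self):
        g1 = [2, 2, 2, 1, 1, 0]  # 8/12 alt, 2 hets
        g2 = [1, 1, 0, 0, 0, 0]  # 2/12 alt, 2 hets
        m = make_two_pop_matrix([g1], [g2])
        (f,) = ps.window_fst(m, [io_core.GenomicWindow("chr1", 0, 10)], "A", "B")
        a, b, c = wc_anova(g1, g2)
        assert f.fst == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_exhaustive_small_configs_match_anova_oracle(self):
        # every genotype configuration with 2+2 samples
        for g1 in itertools.product(range(3), repeat=2):
            for g2 in itertools.product(range(3), repeat=2):
                p_bar = (sum(g1) + sum(g2)) / 8
                m = make_two_pop_matrix([list(g1)], [list(g2)])
                out = ps.window_fst(
                    m, [io_core.GenomicWindow("chr1", 0, 10)], "A", "B"
                )
                if p_bar in (0.0, 1.0):
                    assert math.isnan(out[0].fst)
                    continue
                a, b, c = wc_anova(g1, g2)
                want = a / (a + b + c) if (a + b + c) != 0 else float("nan")
                if math.isnan(want):
                    assert math.isnan(out[0].fst)
                else:
                    assert out[0].fst == pytest.approx(want, abs=1e-12)

    def test_multi_site_ratio_of_sums(self):
        rng = np.random.default_rng(1)
        g1 = rng.integers(0, 3, size=(8, 4)).tolist()
        g2 = rng.integers(0, 3, size=(8, 4)).tolist()
        m = make_two_pop_matrix(g1, g2)
        (f,) = ps.window_fst(m, [io_core.GenomicWindow("chr1", 0, 100)], "A", "B")
        num = den = 0.0
        for s1, s2 in zip(g1, g2):
            p_bar = (sum(s1) + sum(s2)) / 16
            if p_bar in (0.0, 1.0):
                continue
            a, b, c = wc_anova(s1, s2)
            num += a
            den += a + b + c
        assert f.fst == pytest.approx(num / den, abs=1e-12)
        assert ps.genome_fst(m, "A", "B") == pytest.approx(num / den, abs=1e-12)

    def test_identical_populations_give_near_zero_fst(self):
        g = [[0, 1, 2, 1], [1, 1, 0, 2], [2, 0, 1, 1]]
        m = make_two_pop_matrix(g, g, pos=[10, 20, 30])
        f = ps.genome_fst(m, "A", "B")
        assert f < 0.05  # finite-sample estimate scatters around 0


class TestPiRatio:
    def test_equal_diversity_gives_ratio_one(self):
        m = make_two_pop_matrix([[0, 1, 1]], [[1, 1, 0]])
        w = [io_core.GenomicWindow("chr1", 0, 10)]
        da = ps.window_diversity(m, w, "A")
        db = ps.window_diversity(m, w, "B")
        t = ps.window_pi_ratio(da, db)
        assert t["pi_ratio"].iloc[0] == pytest.approx(1.0)
        assert t["log2_pi_ratio"].iloc[0] == pytest.approx(0.0)

    def test_worked_ratio(self):
        w = [io_core.GenomicWindow("chr1", 0, 10)]
        da = [ps.DiversityWindowStats(w[0], 1, 0.0011, 0.001, 0.0, 10)]
        db = [ps.DiversityWindowStats(w[0], 1, 0.0008, 0.001, 0.0, 10)]
        t = ps.window_pi_ratio(da, db)
        assert t["pi_ratio"].iloc[0] == pytest.approx(1.375)

    def test_zero_denominator_is_nan(self):
        w = [io_core.GenomicWindow("chr1", 0, 10)]
        da = [ps.DiversityWindowStats(w[0], 1, 0.001, 0.001, 0.0, 10)]
        db = [ps.DiversityWindowStats(w[0], 0, 0.0, 0.0, float("nan"), 10)]
        t = ps.window_pi_ratio(da, db)
        assert math.isnan(t["pi_ratio"].iloc[0])

    def test_mismatched_window_grids_rejected(self):
        w1 = [io_core.GenomicWindow("chr1", 0, 10)]
        w2 = [io_core.GenomicWindow("chr1", 5, 15)]
        da = [ps.DiversityWindowStats(w1[0], 1, 0.001, 0.001, 0.0, 10)]
        db = [ps.DiversityWindowStats(w2[0], 1, 0.001, 0.001, 0.0, 10)]
        with pytest.raises(ConfigurationError):
            ps.window_pi_ratio(da, db)


class TestLDDecay:
    def test_duplicated_site_has_r2_one(self):
        g = [[0, 1, 2, 1, 0, 2, 1, 1]]
        m = make_two_pop_matrix(
            [g[0][:4]] * 2, [g[0][4:]] * 2, pos=[100, 600]
        )
        decay = ps.ld_decay(m, "A", max_dist=1000, bin_width=1000, min_maf=0.0)
        (b,) = [b for b in decay.bins if b.n_pairs > 0]
        assert b.mean_r2 == pytest.approx(1.0)

    def test_r2_matches_hand_pearson(self):
        x = [0, 1, 2, 1, 0, 2]
        y = [0, 1, 1, 2, 0, 2]
        m = make_two_pop_matrix([x, y], [[0, 0], [0, 0]], pos=[100, 600])
        decay = ps.ld_decay(m, "A", max_dist=1000, bin_width=1000, min_maf=0.0)
        r = np.corrcoef(x, y)[0, 1]
        (b,) = [b for b in decay.bins if b.n_pairs > 0]
        assert b.mean_r2 == pytest.approx(r * r, abs=1e-12)

    def test_half_decay_increases_with_block_size(self):
        from palmscan import synthetic_data as sim

        halves = []
        for block in (5_000, 20_000):
            cfg = sim.PopSimConfig(
                theta=0.002,
                chrom_lengths={"chr1": 400_000},
                ld_block_bp=block,
                seed=4,
            )
            m = sim.simulate_two_pop_genotypes(cfg)
            d = ps.ld_decay(m, "ancestral", max_dist=60_000, bin_width=1_000)
            halves.append(d.half_decay_distance)
        assert halves[0] < halves[1]
        assert halves[0] <= 10_000
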
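import numpy as np
import pytest

from rearrkit.io_formats import AllSitesVariantTable
from rearrkit.popgen import (chromosome_compare, dxy_windows, pi_windows,
                             site_cross_counts, site_pair_counts)
from rearrkit.synthetic import simulate_haplotypes

from tests.test_synthetic import brute_pairwise


def _table(alleles, contig="c"):
    alleles = np.asarray(alleles, dtype=np.int8)
    samples = {f"s{i}": [i] for i in range(alleles.shape[1])}
    return AllSitesVariantTable(contig, np.arange(1, alleles.shape[0] + 1),
                                alleles, samples)


# ------------------------------------------------------------ hand examples

def test_two_haplotypes_one_difference_in_ten_sites():
    alleles = np.zeros((10, 2), dtype=np.int8)
    alleles[3, 1] = 1
    (w,) = pi_windows(_table(alleles), ["s0", "s1"], window=10)
    assert w.value == pytest.approx(0.1)
    assert (w.n_diffs, w.n_comparisons) == (1, 10)  # one pair per site


def test_four_haplotypes_2_2_site_among_100():
    alleles = np.zeros((100, 4), dtype=np.int8)
    alleles[50, 2:] = 1            # allele counts 2/2 -> 4 differing pairs
    (w,) = pi_windows(_table(alleles), [f"s{i}" for i in range(4)], window=100)
    assert w.value == pytest.approx(4 / 600)


def test_fixed_difference_dxy():
    alleles = np.zeros((10, 4), dtype=np.int8)
    alleles[0, 2:] = 1             # one fixed difference among 10 sites
    (w,) = dxy_windows(_table(alleles), ["s0", "s1"], ["s2", "s3"], window=10)
    assert w.value == pytest.approx(0.1)


def test_identical_populations_give_zero():
    alleles = np.zeros((50, 4), dtype=np.int8)
    (pi,) = pi_windows(_table(alleles), [f"s{i}" for i in range(4)], window=50)
    (dxy,) = dxy_windows(_table(alleles), ["s0", "s1"], ["s2", "s3"], window=50)
    assert pi.value == 0.0 and dxy.value == 0.0


def test_multiallelic_sites_count_all_differing_pairs():
    alleles = np.array([[0, 1, 2]], dtype=np.int8)
    d, c = site_pair_counts(alleles)
    assert (d[0], c[0]) == (3, 3)


# ------------------------------------------------------------ missing data

def test_missing_alleles_shrink_comparisons_not_value():
    full = np.zeros((10, 4), dtype=np.int8)
    full[0, 0] = 1
    masked = full.copy()
    masked[5:, :] = -1             # half the sites fully missing
    (w_full,) = pi_windows(_table(full), [f"s{i}" for i in range(4)], window=10)
    (w_mask,) = pi_windows(_table(masked), [f"s{i}" for i in range(4)], window=10)
    # site 0 has allele counts 3/1 -> 3 differing pairs of the 6
    assert w_mask.n_comparisons == w_full.n_comparisons / 2
    assert w_full.value == pytest.approx(3 / 60)
    assert w_mask.value == pytest.approx(3 / 30)


def test_all_missing_window_flagged_not_zero():
    alleles = np.full((10, 2), -1, dtype=np.int8)
    (w,) = pi_windows(_table(alleles), ["s0", "s1"], window=10)
    assert w.value is None and w.n_comparisons == 0


def test_all_sites_vs_variants_only_differ():
    """Dropping invariant sites inflates the per-site estimate."""
    alleles = np.zeros((100, 2), dtype=np.int8)
    alleles[7, 0] = 1
    all_sites = _table(alleles)
    variants_only = _table(alleles[[7]])
    (w_all,) = pi_windows(all_sites, ["s0", "s1"], window=100)
    (w_var,) = pi_windows(variants_only, ["s0", "s1"], window=100)
    assert w_all.value == pytest.approx(0.01)
    assert w_var.value == pytest.approx(1.0)
    assert w_var.value > w_all.value


# ------------------------------------------------------------ vectorized vs brute

def test_pair_counts_match_plain_loop_oracle():
    rng = np.random.default_rng(1)
    alleles = rng.choice([-1, 0, 0, 0, 1, 2], size=(300, 6)).astype(np.int8)
    d, c = site_pair_counts(alleles)
    bd, bc = brute_pairwise(alleles, list(range(6)))
    assert (d.sum(), c.sum()) == (bd, bc)
    dx, cx = site_cross_counts(alleles[:, :3], alleles[:, 3:])
    bdx, bcx = brute_pairwise(alleles, [0, 1, 2], [3, 4, 5])
    assert (dx.sum(), cx.sum()) == (bdx, bcx)


# ------------------------------------------------------------ windows

def test_window_partition_conserves_difference_counts():
    table, _ = simulate_haplotypes(47_000, 6, theta=0.01, seed=2, n_pops=1)
    samples = [f"pop0_{i}" for i in range(6)]
    windows = pi_windows(table, samples, window=20_000, contig_length=47_000)
    assert [(w.start, w.end) for w in windows] == \
        [(0, 20_000), (20_000, 40_000), (40_000, 47_000)]
    assert windows[-1].short
    d, c = site_pair_counts(table.alleles)
    assert sum(w.n_diffs for w in windows) == d.sum()
    assert sum(w.n_comparisons for w in windows) == c.sum()


def test_estimator_recovery_from_simulated_haplotypes():
    table, _ = simulate_haplotypes(100_000, 8, theta=0.01, d_b=0.0, seed=5)
    pops = [f"pop0_{i}" for i in range(8)]
    windows = pi_windows(table, pops, window=20_000, contig_length=100_000)
    mean_pi = np.mean([w.value for w in windows])
    assert abs(mean_pi - 0.01) < 3 * np.sqrt(0.01 / 100_000)

    table2, _ = simulate_haplotypes(100_000, 8, theta=0.0, d_b=0.05, seed=6)
    b = [f"pop1_{i}" for i in range(8)]
    dxy = dxy_windows(table2, pops, b, window=20_000, contig_length=100_000)
    mean_dxy = np.mean([w.value for w in dxy])
    assert abs(mean_dxy - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 100_000)


def test_population_size_validation():
    alleles = np.zeros((10, 2), dtype=np.int8)
    with pytest.raises(ValueError):
        pi_windows(_table(alleles), ["s0"], window=10)
    with pytest.raises(ValueError):
        dxy_windows(_table(alleles), [], ["s0"], window=10)


# ------------------------------------------------------------ rank-sum

def test_rank_sum_direction_on_shifted_groups():
    rng = np.random.default_rng(7)
    a = rng.normal(0.02, 0.002, 40)
    b = rng.normal(0.01, 0.002, 40)
    res = chromosome_compare(a, b)
    assert res.p_value < 1e-6 and res.direction == "A > B"


def test_rank_sum_null_is_calibrated():
    rng = np.random.default_rng(8)
    ps = []
    for _ in range(200):
        a, b = rng.normal(size=15), rng.normal(size=15)
        ps.append(chromosome_compare(a, b).p_value)
    from scipy import stats
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_all_tied_values_flagged():
    res = chromosome_compare([0.5, 0.5], [0.5])
    assert res.p_value == 1.0 and res.flagged


def test_exact_method_for_tiny_groups():
    res = chromosome_compare([1.0, 2.0, 3.0], [4.0, 5.0])
    assert 0 < res.p_value <= 1 and res.direction == "A < B"
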
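from collections import Counter

import numpy as np
import pytest

from rearrkit.io_formats import SequenceRecord
from rearrkit.synthetic import (GenomeBlueprint, InversionSpec,
                                RepeatInsertSpec, build_genome, derive_genome,
                                revcomp, simulate_haplotypes,
                                simulate_sex_reads)


def _blueprint(seed=0, repeats=()):
    return GenomeBlueprint(contigs=[("c1", 30_000, "autosome")],
                           repeats=list(repeats), seed=seed)


def test_build_genome_is_deterministic_and_plain_without_features():
    recs1, hits1, _ = build_genome(_blueprint(seed=5))
    recs2, hits2, _ = build_genome(_blueprint(seed=5))
    assert recs1 == recs2 and hits1 == hits2 == []
    assert len(recs1) == 1 and len(recs1[0]) == 30_000
    recs3, _, _ = build_genome(_blueprint(seed=6))
    assert recs3 != recs1


def test_zero_divergence_copies_are_exact_consensus(random_seq):
    cons = random_seq(400, 1)
    spec = RepeatInsertSpec("fam", cons, "interspersed", n_loci=5, divergence=0.0)
    recs, hits, truth = build_genome(_blueprint(seed=2, repeats=[spec]))
    assert len(hits) == 5
    for h in hits:
        assert recs[0].sequence[h.start:h.end] == cons
        assert h.pct_divergence == 0.0


def test_realized_divergence_tracks_target_binomially(random_seq):
    # 50 copies of a 1 kb consensus at 10%: mean within ~3 binomial s.e.
    cons = random_seq(1000, 3)
    spec = RepeatInsertSpec("fam", cons, "interspersed", n_loci=50,
                            divergence=10.0)
    bp = GenomeBlueprint(contigs=[("c1", 400_000, "autosome")],
                         repeats=[spec], seed=3)
    _recs, hits, _ = build_genome(bp)
    mean = np.mean([h.pct_divergence for h in hits])
    se = 100 * np.sqrt(0.1 * 0.9 / 1000 / 50)
    assert abs(mean - 10.0) < max(3 * se, 1.5)


def test_tandem_arrays_are_head_to_tail_monomers(random_seq):
    cons = random_seq(150, 4)
    spec = RepeatInsertSpec("itr", cons, "tandem_array", n_loci=3,
                            divergence=0.0, array_length_range=(500, 2000))
    recs, hits, _ = build_genome(_blueprint(seed=7, repeats=[spec]))
    for h in hits:
        copy = recs[0].sequence[h.start:h.end]
        assert 500 <= len(copy) <= 2000
        assert copy == (cons * (len(copy) // 150 + 1))[:len(copy)]


# ---------------------------------------------------------------- inversions

def test_derive_identity_involution_and_conservation():
    recs, _, _ = build_genome(_blueprint(seed=9))
    same, truth = derive_genome(recs, [])
    assert same == recs and truth.breakpoints == []

    plan = [InversionSpec("c1", 5_000, 9_000)]
    once, t1 = derive_genome(recs, plan)
    assert t1.breakpoints == [("c1", 5_000), ("c1", 9_000)]
    assert once[0].sequence[5_000:9_000] == revcomp(recs[0].sequence[5_000:9_000])
    assert len(once[0]) == len(recs[0])
    # reverse complement swaps A<->T and C<->G, so AT and GC content conserve
    before, after = Counter(recs[0].sequence), Counter(once[0].sequence)
    assert before["A"] + before["T"] == after["A"] + after["T"]
    assert before["C"] + before["G"] == after["C"] + after["G"]
    twice, _ = derive_genome(once, plan)
    assert twice == recs


def test_derive_rejects_overlapping_blocks():
    recs, _, _ = build_genome(_blueprint())
    with pytest.raises(ValueError):
        derive_genome(recs, [InversionSpec("c1", 1_000, 5_000),
                             InversionSpec("c1", 4_000, 8_000)])


def test_inversions_below_detectability_floor_rejected():
    with pytest.raises(ValueError):
        InversionSpec("c1", 0, 1_000)


# ---------------------------------------------------------------- reads

def _sex_genome(seed=0, L=20_000):
    bp = GenomeBlueprint(contigs=[("A", L, "autosome"), ("X", L, "X"),
                                  ("Y", L, "Y")], seed=seed)
    recs, _, _ = build_genome(bp)
    return recs, bp.sex_labels


def test_female_library_contains_no_y_reads():
    recs, labels = _sex_genome()
    _male, female = simulate_sex_reads(recs, labels, seed=1)
    assert female and not any(rid.split("_")[1] == "Y" for rid, _s, _q in female)


def test_copy_number_scaling_of_read_counts():
    recs, labels = _sex_genome(seed=3)
    male, female = simulate_sex_reads(recs, labels, depth_per_copy=15.0, seed=2)

    def count(lib, contig):
        return sum(1 for rid, _s, _q in lib if rid.split("_")[1] == contig)

    # female/male expectations: autosome 1, X 2, Y 0
    assert abs(count(female, "A") / count(male, "A") - 1) < 0.1
    assert abs(count(female, "X") / count(male, "X") - 2) < 0.25
    assert count(male, "Y") > 0 and count(female, "Y") == 0


def test_coverage_linearity_in_requested_depth():
    recs, labels = _sex_genome(seed=4)
    m1, _ = simulate_sex_reads(recs, labels, depth_per_copy=10.0, seed=5)
    m2, _ = simulate_sex_reads(recs, labels, depth_per_copy=20.0, seed=5)
    assert abs(len(m2) / len(m1) - 2.0) < 0.1


def test_read_simulation_deterministic_under_seed():
    recs, labels = _sex_genome(seed=6)
    assert simulate_sex_reads(recs, labels, seed=8) == \
        simulate_sex_reads(recs, labels, seed=8)


# ---------------------------------------------------------------- haplotypes

def brute_pairwise(alleles, cols_a, cols_b=None):
    """Plain-loop pairwise difference counter (independent oracle)."""
    diffs = comps = 0
    for row in alleles:
        if cols_b is None:
            vals = [row[c] for c in cols_a if row[c] >= 0]
            for i in range(len(vals)):
                for j in range(i + 1, len(vals)):
                    comps += 1
                    diffs += vals[i] != vals[j]
        else:
            va = [row[c] for c in cols_a if row[c] >= 0]
            vb = [row[c] for c in cols_b if row[c] >= 0]
            for x in va:
                for y in vb:
                    comps += 1
                    diffs += x != y
    return diffs, comps


def test_theta_zero_means_identical_haplotypes():
    table, _ = simulate_haplotypes(5_000, 6, theta=0.0, d_b=0.0, seed=1)
    assert not table.alleles.any()


def test_realized_diversity_matches_planted_theta():
    theta, L, n = 0.01, 100_000, 8
    table, truth = simulate_haplotypes(L, n, theta=theta, d_b=0.0, seed=11)
    d, c = brute_pairwise(table.alleles, list(range(n)))
    pi = d / c
    se = np.sqrt(theta / L)  # generous: iid-site binomial scale
    assert abs(pi - theta) < 3 * max(se, 0.0008)
    assert truth.theta == theta


def test_fixed_differences_give_dxy_equal_to_their_fraction():
    L, n = 50_000, 4
    table, _ = simulate_haplotypes(L, n, theta=0.0, d_b=0.05, seed=12)
    fixed = int(np.sum(table.alleles[:, n:].all(axis=1)
                       & ~table.alleles[:, :n].any(axis=1)))
    d, c = brute_pairwise(table.alleles, list(range(n)),
                          list(range(n, 2 * n)))
    assert d / c == pytest.approx(fixed / L)


def test_haplotype_parameter_validation():
    with pytest.raises(ValueError):
        simulate_haplotypes(100, 4, theta=0.6)
    with pytest.raises(ValueError):
        simulate_haplotypes(100, 4, theta=0.0, n_pops=3)
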
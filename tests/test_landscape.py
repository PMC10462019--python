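import numpy as np
import pytest

from rearrkit.io_formats import RepeatHit
from rearrkit.landscape import (abundance_decomposition, array_summary,
                                call_arrays, genome_proportions, landscape,
                                window_density)
from rearrkit.synthetic import GenomeBlueprint, RepeatInsertSpec, build_genome


def H(start, end, family="fam", subclass="LINE", div=5.0, contig="c1"):
    return RepeatHit(contig, start, end, "+", family, subclass, div)


# ------------------------------------------------------------ proportions

def test_proportion_arithmetic_and_merging():
    assert genome_proportions([], 1_000_000) == {}
    assert genome_proportions([H(0, 10_000, subclass="LTR")],
                              1_000_000) == {"LTR": 1.0}
    merged = genome_proportions([H(0, 100), H(50, 150)], 1_000)
    assert merged == {"LINE": 15.0}  # 150 bp counted once


# ------------------------------------------------------------ landscape

def test_landscape_bins_by_floor_divergence():
    lf = landscape([H(0, 1_000, div=0.4)], 100_000)
    row = lf[(lf.subclass == "LINE") & (lf.bin_lo == 0)]
    assert row.proportion_pct.iloc[0] == 1.0
    assert lf[lf.bin_lo == 1].proportion_pct.iloc[0] == 0.0


def test_landscape_modal_bin_tracks_planted_divergence(random_seq):
    spec = RepeatInsertSpec("fam", random_seq(800, 1), "interspersed",
                            n_loci=40, divergence=10.0, subclass="LINE")
    bp = GenomeBlueprint(contigs=[("c1", 300_000, "autosome")],
                         repeats=[spec], seed=1)
    _recs, hits, _ = build_genome(bp)
    lf = landscape(hits, 300_000)
    modal = lf.loc[lf.proportion_pct.idxmax()]
    assert 8 <= modal.bin_lo < 12


def test_two_planted_families_give_distinct_modes(random_seq):
    # DINE-TR-like at 9% and ITR-like at 16% divergence
    specs = [RepeatInsertSpec("DINE-TR1", random_seq(400, 2), "interspersed",
                              n_loci=30, divergence=9.0),
             RepeatInsertSpec("172TR", random_seq(300, 3), "tandem_array",
                              n_loci=12, divergence=16.0,
                              array_length_range=(500, 3_000))]
    bp = GenomeBlueprint(contigs=[("c1", 400_000, "autosome")],
                         repeats=specs, seed=2)
    _recs, hits, _ = build_genome(bp)
    lf = landscape(hits, 400_000)
    dine = lf[lf.subclass == "Helitron_DINE_TR"]
    itr = lf[lf.subclass == "ITR"]
    dine_mode = dine.loc[dine.proportion_pct.idxmax(), "bin_lo"]
    itr_mode = itr.loc[itr.proportion_pct.idxmax(), "bin_lo"]
    assert 7 <= dine_mode <= 11 and 14 <= itr_mode <= 18
    assert itr_mode > dine_mode


def test_landscape_bins_sum_to_subclass_proportion():
    rng = np.random.default_rng(3)
    hits, cursor = [], 0
    for _ in range(50):  # non-overlapping by construction
        ln = int(rng.integers(100, 2_000))
        hits.append(H(cursor, cursor + ln,
                      subclass=str(rng.choice(["LINE", "LTR", "ITR"])),
                      div=float(rng.uniform(0, 49.9))))
        cursor += ln + int(rng.integers(1, 500))
    lf = landscape(hits, cursor)
    props = genome_proportions(hits, cursor)
    for sc, total in props.items():
        assert lf[lf.subclass == sc].proportion_pct.sum() == pytest.approx(total)


def test_out_of_range_divergence_clamped_with_warning():
    with pytest.warns(UserWarning):
        lf = landscape([H(0, 100, div=55.0)], 10_000)
    assert lf.proportion_pct.sum() == pytest.approx(1.0)


# ------------------------------------------------------------ windows

def test_window_apportionment_and_conservation():
    lengths = {"c1": 250_000}
    hits = [H(0, 100_000),                       # fills window 0
            H(160_000, 240_000)]                 # straddles windows 1/2: 40k/40k
    wd = window_density(hits, lengths, window=100_000)
    line = wd["LINE"].tolist()
    assert line == [100_000, 40_000, 40_000]
    assert wd["short"].tolist() == [False, False, True]
    merged_bp = sum(len(h) for h in hits)
    assert wd["LINE"].sum() == merged_bp


def test_window_density_gradient_recovered():
    lengths = {"c1": 300_000}
    hits = [H(s, s + w) for s, w in
            ((10_000, 2_000), (110_000, 10_000), (210_000, 40_000))]
    wd = window_density(hits, lengths, window=100_000)
    assert wd["LINE"].is_monotonic_increasing


# ------------------------------------------------------------ arrays

def test_array_merge_rule_and_boundary():
    hits = [H(100, 600, family="itr", subclass="ITR"),
            H(700, 1_200, family="itr", subclass="ITR")]
    (arr,) = call_arrays(hits, merge_gap=500)
    assert (arr.start, arr.end, arr.length, arr.n_hits) == (100, 1_200, 1_100, 2)
    two = call_arrays([hits[0], H(1_101, 1_200, family="itr", subclass="ITR")],
                      merge_gap=500)
    assert len(two) == 2  # gap 501 exceeds the merge gap


def test_isolated_hit_is_its_own_array():
    (arr,) = call_arrays([H(10, 500, family="itr")])
    assert (arr.start, arr.end, arr.n_hits) == (10, 500, 1)


def test_array_lengths_sum_to_family_bp_and_recovery(random_seq):
    spec = RepeatInsertSpec("172TR", random_seq(200, 4), "tandem_array",
                            n_loci=15, divergence=5.0,
                            array_length_range=(500, 8_000))
    bp = GenomeBlueprint(contigs=[("c1", 500_000, "autosome")],
                         repeats=[spec], seed=5)
    _recs, hits, truth = build_genome(bp)
    arrays = call_arrays(hits, merge_gap=500)
    assert len(arrays) == 15  # planted gaps exceed the merge gap
    assert sum(a.length for a in arrays) == sum(len(h) for h in hits)
    planted = sorted((r["start"], r["end"]) for r in truth.repeats)
    assert sorted((a.start, a.end) for a in arrays) == planted


# ------------------------------------------------------------ decomposition

def _summary(n, mean):
    import pandas as pd
    return pd.DataFrame([{"family": "itr", "n_loci": n, "total_bp": n * mean,
                          "mean_length": mean}])


def test_decomposition_directions():
    res = abundance_decomposition(_summary(100, 2_000), _summary(100, 5_000), "itr")
    assert res["dominant"] == "length-dominated"
    assert res["total_fold"] == pytest.approx(2.5)
    res = abundance_decomposition(_summary(100, 2_000), _summary(300, 2_000), "itr")
    assert res["dominant"] == "count-dominated"
    res = abundance_decomposition(_summary(100, 2_000), _summary(100, 2_000), "itr")
    assert res["count_fold"] == res["length_fold"] == 1.0


def test_decomposition_zero_loci_flagged():
    import pandas as pd
    empty = pd.DataFrame(columns=["family", "n_loci", "total_bp", "mean_length"])
    assert abundance_decomposition(empty, _summary(10, 100), "itr")["flagged"]


def test_array_summary_totals():
    arrays = call_arrays([H(0, 500, family="a"), H(2_000, 2_400, family="a"),
                          H(0, 300, family="b", contig="c2")])
    summ = array_summary(arrays).set_index("family")
    assert summ.loc["a", "n_loci"] == 2 and summ.loc["a", "total_bp"] == 900
    assert summ.loc["b", "mean_length"] == 300
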
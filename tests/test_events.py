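import numpy as np
import pytest

from rearrkit.events import (NoveltyCriteria, call_polymorphic_insertions,
                             cluster_families, eligible_insertion_loci,
                             local_hits, novelty_filter, pairwise_identity,
                             probe_matches)
from rearrkit.io_formats import RepeatHit, SequenceRecord
from rearrkit.landscape import call_arrays
from rearrkit.synthetic import revcomp


# ------------------------------------------------------------ identity

def test_pairwise_identity_of_constructed_pair(random_seq, mutate):
    a = random_seq(1_000, 1)
    b = mutate(a, 150, 2)  # exactly 15% substitutions
    assert pairwise_identity(a, b) == pytest.approx(85.0, abs=0.5)
    assert pairwise_identity(a, revcomp(b)) == pytest.approx(85.0, abs=0.5)
    assert pairwise_identity(a, a) == 100.0


# ------------------------------------------------------------ clustering

def _libs(random_seq, mutate):
    a = random_seq(1_000, 3)
    return [("g1", SequenceRecord("famA", a)),
            ("g2", SequenceRecord("famA_variant", mutate(a, 150, 4))),
            ("g1", SequenceRecord("lone", random_seq(2_000, 5)))]


def test_identical_consensus_cluster_across_genomes(random_seq):
    seq = random_seq(800, 6)
    libs = [("g1", SequenceRecord("f1", seq)), ("g2", SequenceRecord("f2", seq))]
    clusters, singletons = cluster_families(libs)
    assert len(clusters) == 1 and singletons == []


def test_threshold_splits_85pct_pair(random_seq, mutate):
    libs = _libs(random_seq, mutate)
    _cl80, sing80 = cluster_families(libs, NoveltyCriteria(cluster_identity=80))
    assert [r.id for _g, r in sing80] == ["lone"]
    _cl90, sing90 = cluster_families(libs, NoveltyCriteria(cluster_identity=90))
    assert {r.id for _g, r in sing90} == {"famA", "famA_variant", "lone"}


def test_clustering_visits_longest_first_deterministically(random_seq):
    seq = random_seq(500, 7)
    libs = [("g1", SequenceRecord("short", seq[:400])),
            ("g2", SequenceRecord("long", seq))]
    clusters, _ = cluster_families(libs)
    assert clusters[0].representative[1].id == "long"


def test_short_consensus_rejected(random_seq):
    with pytest.raises(ValueError):
        cluster_families([("g1", SequenceRecord("tiny", "ACGT" * 10))])


# ------------------------------------------------------------ local search

def test_local_hits_finds_planted_diverged_piece(random_seq, mutate):
    cons = random_seq(600, 8)
    bg = random_seq(30_000, 9)
    piece = mutate(cons[100:250], 22, 10)     # 150 bp at ~15% divergence
    target = SequenceRecord("t", bg[:10_000] + piece + bg[10_000:])
    hits = local_hits(cons, [target], min_len=100, max_divergence=20.0)
    assert hits and any(abs(h.start - 10_000) < 200 for h in hits)
    assert not local_hits(cons, [SequenceRecord("t", bg)],
                          min_len=100, max_divergence=20.0)


def test_local_hits_sees_reverse_strand(random_seq):
    cons = random_seq(400, 11)
    bg = random_seq(20_000, 12)
    target = SequenceRecord("t", bg[:5_000] + revcomp(cons) + bg[5_000:])
    hits = local_hits(cons, [target], min_len=100, max_divergence=20.0)
    assert any(h.strand == "-" for h in hits)


# ------------------------------------------------------------ novelty gates

def _own_hits(total_bp, div, family="nov"):
    n = max(1, total_bp // 3_000)
    size = total_bp // n
    return [RepeatHit("c", i * 10_000, i * 10_000 + size, "+", family,
                      "Unknown", div) for i in range(n)]


def test_novelty_gate_order_and_reasons(random_seq, mutate):
    cons = SequenceRecord("nov", random_seq(600, 13))
    clean_bg = [SequenceRecord("t", random_seq(30_000, 14))]

    piece = mutate(cons.sequence[:150], 22, 15)
    with_homolog = [SequenceRecord("t", clean_bg[0].sequence[:8_000] + piece
                                   + clean_bg[0].sequence[8_000:])]
    v = novelty_filter(cons, {"g2": with_homolog}, _own_hits(6_000, 4.0))
    assert (v.novel, v.reason) == (False, "homolog_found")

    v = novelty_filter(cons, {"g2": clean_bg}, _own_hits(3_000, 4.0))
    assert (v.novel, v.reason) == (False, "low_abundance")

    v = novelty_filter(cons, {"g2": clean_bg}, _own_hits(6_000, 12.0))
    assert (v.novel, v.reason) == (False, "old_copies")

    v = novelty_filter(cons, {"g2": clean_bg}, _own_hits(6_000, 8.0))
    assert (v.novel, v.reason) == (True, "novel")
    assert v.genomic_bp >= 5_000


def test_novelty_monotone_in_thresholds(random_seq):
    cons = SequenceRecord("nov", random_seq(600, 16))
    bg = [SequenceRecord("t", random_seq(20_000, 17))]
    hits = _own_hits(6_000, 8.0)
    strict = novelty_filter(cons, {"g2": bg}, hits,
                            NoveltyCriteria(min_genomic_bp=5_000))
    loose = novelty_filter(cons, {"g2": bg}, hits,
                           NoveltyCriteria(min_genomic_bp=1_000,
                                           max_mean_divergence=20.0))
    assert strict.novel
    assert loose.novel  # loosening never removes a novel verdict


# ------------------------------------------------------------ insertions

@pytest.fixture
def trio(random_seq):
    """Donor carries a private 1.5 kb tandem insertion; others are intact."""
    monomer = random_seq(180, 20)
    array = (monomer * 9)[:1_500]
    bg = random_seq(40_000, 21)
    p = 17_000
    donor = [SequenceRecord("chr5", bg[:p] + array + bg[p:])]
    hits = [RepeatHit("chr5", p, p + 1_500, "+", "172TR", "ITR", 0.0)]
    others = {"ML": [SequenceRecord("chr5", bg)],
              "SB": [SequenceRecord("chr5", bg)]}
    return donor, hits, others, array, bg, p


def test_eligibility_flank_rules():
    lengths = {"c": 50_000}
    clean = call_arrays([RepeatHit("c", 20_000, 21_000, "+", "itr", "ITR", 0.0)])
    assert len(eligible_insertion_loci(clean, [], lengths)) == 1

    flanked_hits = [RepeatHit("c", 20_000, 21_000, "+", "itr", "ITR", 0.0),
                    RepeatHit("c", 19_000, 19_200, "+", "line", "LINE", 0.0)]
    arrays = call_arrays(flanked_hits, families=["itr"])
    assert eligible_insertion_loci(arrays, flanked_hits, lengths) == []

    near_end = call_arrays([RepeatHit("c", 49_400, 49_700, "+", "itr", "ITR", 0.0)])
    assert eligible_insertion_loci(near_end, [], lengths) == []


def test_private_insertion_called_with_full_evidence(trio):
    donor, hits, others, _array, _bg, p = trio
    loci = eligible_insertion_loci(call_arrays(hits), hits,
                                   {"chr5": len(donor[0])})
    (call,) = call_polymorphic_insertions(loci, "G96", donor, others)
    assert (call.contig, call.start, call.end, call.length) == \
        ("chr5", p, p + 1_500, 1_500)
    assert all(n == 1 and ident >= 90 for ident, n in call.evidence.values())


def test_shared_insertion_not_called(trio):
    donor, hits, _others, array, bg, p = trio
    shared = {"ML": [SequenceRecord("chr5", bg[:p] + array + bg[p:])],
              "SB": [SequenceRecord("chr5", bg[:p] + array + bg[p:])]}
    loci = eligible_insertion_loci(call_arrays(hits), hits,
                                   {"chr5": len(donor[0])})
    assert call_polymorphic_insertions(loci, "G96", donor, shared) == []


def test_duplicated_intact_site_is_ambiguous(trio):
    donor, hits, others, _array, bg, p = trio
    dup = dict(others)
    dup["ML"] = [SequenceRecord("chr5", bg + bg[p - 300:p + 300])]
    loci = eligible_insertion_loci(call_arrays(hits), hits,
                                   {"chr5": len(donor[0])})
    assert call_polymorphic_insertions(loci, "G96", donor, dup) == []


def test_probe_matches_identity_floor(random_seq, mutate):
    probe = random_seq(200, 22)
    bg = random_seq(10_000, 23)
    good = SequenceRecord("t", bg[:4_000] + mutate(probe, 10, 24) + bg[4_000:])
    bad = SequenceRecord("t", bg[:4_000] + mutate(probe, 40, 25) + bg[4_000:])
    assert len(probe_matches(probe, [good], min_identity=90.0)) == 1
    assert probe_matches(probe, [bad], min_identity=90.0) == []
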
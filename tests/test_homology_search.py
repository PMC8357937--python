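import numpy as np
import pytest

import oracles
from marinerscan import ContigSet, revcomp
from marinerscan.homology_search import (
    HomologyHit,
    SearchParams,
    filter_hits,
    iterative_search,
    screen_other_families,
    seed_and_extend,
)
from marinerscan.io_formats import PanelRecord


def _dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate(rng, seq, frac):
    out = list(seq)
    pos = rng.choice(len(seq), size=int(frac * len(seq)), replace=False)
    for p in pos:
        out[p] = "ACGT"[(("ACGT".index(out[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    query = _dna(rng, 300)
    contig = _dna(rng, 1500) + query + _dna(rng, 1500)
    return query, contig, (1500, 1800)


def test_exact_substring_hit(planted):
    query, contig, span = planted
    genome = ContigSet("g", {"c1": contig})
    hits = seed_and_extend(genome, [("q", query)])
    top = max(hits, key=lambda h: h.score)
    assert (top.identity, top.coverage, top.strand) == (1.0, 1.0, "+")
    assert top.contig_span == span


def test_reverse_complement_hit(planted):
    query, contig, span = planted
    genome = ContigSet("g", {"c1": contig})
    hits = seed_and_extend(genome, [("q", revcomp(query))])
    top = max(hits, key=lambda h: h.score)
    assert (top.identity, top.strand) == (1.0, "-")
    assert top.contig_span == span


def test_divergent_copy_identity_matches_sw_oracle():
    rng = np.random.default_rng(3)
    query = _dna(rng, 200)
    copy = _mutate(rng, query, 0.10)
    contig = _dna(rng, 600) + copy + _dna(rng, 600)
    genome = ContigSet("g", {"c1": contig})
    top = max(seed_and_extend(genome, [("q", query)]), key=lambda h: h.score)
    score, matches, cols = oracles.sw_align_stats(query, copy)
    assert abs(top.identity - matches / cols) <= 0.03


def test_scores_equal_full_sw_on_small_contigs():
    """On desk-size instances the seeded search is exactly Smith-Waterman."""
    rng = np.random.default_rng(11)
    for trial in range(5):
        query = _dna(rng, 150 + 10 * trial)
        copy = _mutate(rng, query, 0.05 + 0.03 * trial)
        contig = _dna(rng, 700) + copy + _dna(rng, 2000 - 700 - len(copy))
        genome = ContigSet("g", {"c1": contig})
        hits = seed_and_extend(genome, [("q", query)])
        assert hits, "planted copy not found"
        assert max(h.score for h in hits) == oracles.sw_score(query, contig)


def _hit(identity, coverage, span=(0, 100)):
    return HomologyHit(query_id="q", contig_id="c", strand="+",
                       query_span=(0, 100), contig_span=span,
                       identity=identity, coverage=coverage, score=50)


def test_filter_is_strictly_greater():
    kept = filter_hits([_hit(0.61, 0.61), _hit(0.60, 0.90), _hit(0.90, 0.60)])
    assert [h.identity for h in kept] == [0.61]


def test_filter_equals_brute_force_predicate(rng):
    hits = [_hit(float(i), float(c))
            for i, c in rng.random((100, 2))]
    params = SearchParams()
    expected = [h for h in hits
                if h.identity > params.min_identity
                and h.coverage > params.min_coverage]
    assert filter_hits(hits, params) == expected


def test_monotonicity_of_thresholds(rng):
    hits = [_hit(float(i), float(c)) for i, c in rng.random((60, 2))]
    base = set(id(h) for h in filter_hits(hits, SearchParams()))
    for mi, mc in [(0.7, 0.6), (0.6, 0.7), (0.8, 0.8)]:
        tighter = filter_hits(hits, SearchParams(min_identity=mi, min_coverage=mc))
        assert set(id(h) for h in tighter) <= base


@pytest.fixture(scope="module")
def two_tier_genome():
    """Copy A detectable from the panel; copy B only via A (iterative mining)."""
    rng = np.random.default_rng(5)
    q = _dna(rng, 600)
    a = _mutate(rng, q, 0.30)  # ~0.7 alignment identity to the panel query
    b = _mutate(rng, a, 0.32)  # <0.6 to the query, ~0.7 to A
    contig = _dna(rng, 700) + a + _dna(rng, 1200) + b + _dna(rng, 700)
    genome = ContigSet("g", {"c1": contig})
    return genome, q, (700, 1300), (2500, 3100)


def test_iterative_search_recovers_second_tier(two_tier_genome):
    genome, q, span_a, span_b = two_tier_genome
    params = SearchParams()
    round1 = iterative_search(genome, [("q", q)], params, max_rounds=1)
    assert any(_overlap_frac(h.contig_span, span_a) > 0.8 for h in round1)
    assert not any(_overlap_frac(h.contig_span, span_b) > 0.5 for h in round1)
    round2 = iterative_search(genome, [("q", q)], params, max_rounds=3)
    assert any(_overlap_frac(h.contig_span, span_b) > 0.8 for h in round2)


def test_iterative_single_round_equals_plain_search(planted):
    query, contig, _ = planted
    genome = ContigSet("g", {"c1": contig})
    params = SearchParams()
    one = iterative_search(genome, [("q", query)], params, max_rounds=1)
    plain = filter_hits(seed_and_extend(genome, [("q", query)], params), params)
    assert one == plain


def test_iterative_fixpoint_on_single_copy(planted):
    query, contig, _ = planted
    genome = ContigSet("g", {"c1": contig})
    params = SearchParams()
    assert iterative_search(genome, [("q", query)], params, max_rounds=1) == \
        iterative_search(genome, [("q", query)], params, max_rounds=4)


def _overlap_frac(a, b):
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return ov / min(a[1] - a[0], b[1] - b[0])


def test_strand_symmetry():
    rng = np.random.default_rng(9)
    query = _dna(rng, 250)
    contig = _dna(rng, 800) + query + _dna(rng, 500)
    genome_fwd = ContigSet("g", {"c1": contig})
    genome_rev = ContigSet("g", {"c1": revcomp(contig)})
    fwd = seed_and_extend(genome_fwd, [("q", query)])
    rev = seed_and_extend(genome_rev, [("q", query)])
    n = len(contig)
    mirrored = sorted(
        ((n - e, n - s), {"+": "-", "-": "+"}[h.strand], h.score)
        for h in rev for s, e in [h.contig_span]
    )
    assert sorted((h.contig_span, h.strand, h.score) for h in fwd) == mirrored


def test_determinism():
    rng = np.random.default_rng(13)
    query = _dna(rng, 200)
    contig = _dna(rng, 900) + query + _dna(rng, 900)
    genome = ContigSet("g", {"c1": contig})
    assert seed_and_extend(genome, [("q", query)]) == \
        seed_and_extend(genome, [("q", query)])


def test_family_screen_detects_planted_and_ignores_background():
    rng = np.random.default_rng(21)
    tc1 = _dna(rng, 1000)
    contig = _dna(rng, 4000) + tc1 + _dna(rng, 4000)
    genome = ContigSet("g", {"c1": contig})
    panels = [
        PanelRecord(seq_id="Tc1_c", sequence=tc1, family="Tc1"),
        PanelRecord(seq_id="maT_c", sequence=_dna(rng, 1000), family="maT"),
    ]
    flags = screen_other_families(genome, panels)
    assert flags == {"Tc1": True, "maT": False}
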
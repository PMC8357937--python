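import numpy as np
import pytest

import oracles
from marinerscan import revcomp
from marinerscan.element_structure import (
    StructureParams,
    check_tsd,
    classify_completeness,
    find_tir_pair,
    refine_element_span,
    tir_consensus,
)
from marinerscan.io_formats import MarinerScanError


def _dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_constructed_inverted_repeat_found_exactly(rng):
    tir = _dna(rng, 28)
    while "TA" in tir:
        tir = _dna(rng, 28)
    core = _dna(rng, 900)
    pair = find_tir_pair(tir + core + revcomp(tir))
    assert pair is not None
    assert (pair.length, pair.mismatches) == (28, 0)
    assert pair.left_span == (0, 28)
    assert pair.verify()


def test_12bp_repeat_below_floor_is_rejected(rng):
    tir = _dna(rng, 12)
    seq = tir + _dna(rng, 400) + revcomp(tir)
    pair = find_tir_pair(seq)
    # either nothing, or a chance repeat unrelated to the planted 12-mer
    assert pair is None or pair.length >= 13


def test_short_sequence_rejected():
    with pytest.raises(MarinerScanError):
        find_tir_pair("ACGT" * 10)


@pytest.mark.parametrize("trial", range(25))
def test_detection_equals_exhaustive_enumeration(trial):
    """Planted TIRs of random length and mutation load: the detected pair
    must equal the optimum of a brute-force enumeration."""
    rng = np.random.default_rng(100 + trial)
    length = int(rng.integers(13, 33))
    tir = _dna(rng, length)
    right = list(revcomp(tir))
    for p in rng.choice(length, size=int(rng.integers(0, 3)), replace=False):
        right[p] = "ACGT"[(("ACGT".index(right[p])) + 1) % 4]
    seq = tir + _dna(rng, 600) + "".join(right)
    got = find_tir_pair(seq)
    expected = oracles.best_tir_pair(seq)
    if expected is None:
        assert got is None
        return
    i, L, mm, right_end = expected
    assert got is not None
    assert (got.left_span[0], got.length, got.mismatches, got.right_span[1]) \
        == (i, L, mm, right_end)


def test_check_tsd_flanks():
    contig = "GG" + "TA" + "C" * 50 + "TA" + "GG"
    span = (4, 54)
    assert check_tsd(contig, span) == (True, True)
    assert check_tsd("C" * 60, (0, 50)) == (False, False)


def test_check_tsd_missing_flank_at_contig_edge():
    contig = "C" * 50 + "TA" + "GG"
    assert check_tsd(contig, (0, 50)) == (False, True)


def _element(rng, tir_len=28):
    tir = _dna(rng, tir_len)
    while "TA" in tir:
        tir = _dna(rng, tir_len)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    core = list(_dna(rng, 1100))
    # break chance base-pairing just inside the TIRs so the planted repeat
    # cannot extend inward (mirrors how real TIR boundaries are defined by
    # the transposase-bound motif, not by incidental flanking complementarity)
    for k in range(10):
        if core[-1 - k] == comp[core[k]]:
            core[-1 - k] = "ACGT"[("ACGT".index(core[-1 - k]) + 1) % 4]
    return tir + "".join(core) + revcomp(tir)


def test_classify_complete(rng):
    elem = _element(rng)
    contig = _dna(rng, 200) + "TA" + elem + "TA" + _dna(rng, 200)
    span = (202, 202 + len(elem))
    tir = find_tir_pair(elem)
    cand = classify_completeness("c", contig, span, "+", tir)
    assert cand.completeness == "complete"
    assert (cand.tsd_left, cand.tsd_right) == (True, True)


def test_classify_flush_truncated_5p_at_contig_end(rng):
    elem = _element(rng)
    ref_tir = elem[:28]
    clipped = elem[40:]  # 5' TIR gone
    contig = clipped + "TA" + _dna(rng, 300)
    cand = classify_completeness("c", contig, (0, len(clipped)), "+", None,
                                 ref_tir=ref_tir)
    assert cand.completeness == "truncated_5p"
    assert cand.at_contig_end
    assert cand.tsd_right


def test_short_candidate_discarded(rng):
    contig = _dna(rng, 2000)
    assert classify_completeness("c", contig, (100, 1000), "+", None) is None


def test_refine_recovers_exact_boundaries(rng):
    elem = _element(rng)
    contig = _dna(rng, 300) + "CCTA" + elem + "TACC" + _dna(rng, 300)
    true_span = (304, 304 + len(elem))
    sloppy = (true_span[0] + 9, true_span[1] - 7)  # a trimmed local hit
    span, pair = refine_element_span(contig, sloppy)
    assert span == true_span
    assert pair is not None and pair.length == 28 and pair.mismatches == 0


def test_reverse_complement_invariance(rng):
    elem = _element(rng)
    contig = _dna(rng, 250) + "CCTA" + elem + "TACC" + _dna(rng, 350)
    n = len(contig)
    true_span = (254, 254 + len(elem))
    span_f, pair_f = refine_element_span(contig, true_span)
    rc_span = (n - true_span[1], n - true_span[0])
    span_r, pair_r = refine_element_span(revcomp(contig), rc_span)
    assert span_r == (n - span_f[1], n - span_f[0])
    assert pair_r is not None and pair_r.length == pair_f.length


def test_tir_consensus_identical_members():
    groups = {"Mauritiana": [("e1", "ACGTACGTACGTA"), ("e2", "ACGTACGTACGTA"),
                             ("e3", "ACGTACGTACGTA")]}
    res = tir_consensus(groups)["Mauritiana"]
    assert res.consensus == "ACGTACGTACGTA"
    assert res.flagged == []


def test_tir_consensus_single_mismatch_majority(rng):
    base = _dna(rng, 28)
    variant = "G" + base[1:] if base[0] != "G" else "A" + base[1:]
    groups = {"x": [("e1", base), ("e2", base), ("e3", variant)]}
    res = tir_consensus(groups)["x"]
    assert res.consensus == base
    assert abs(res.identities["e3"] - 27 / 28) < 1e-9
    assert res.flagged == []


def test_tir_consensus_flags_outlier(rng):
    base = _dna(rng, 28)
    outlier = list(base)
    for p in rng.choice(28, size=9, replace=False):  # ~68% identity
        outlier[p] = "ACGT"[(("ACGT".index(outlier[p])) + 2) % 4]
    groups = {"x": [("e1", base), ("e2", base), ("e3", base),
                    ("bad", "".join(outlier))]}
    res = tir_consensus(groups)["x"]
    assert res.flagged == ["bad"]
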
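import numpy as np
import pytest

import oracles
from marinerscan import revcomp
from marinerscan.element_structure import ElementCandidate
from marinerscan.synthetic_data import AA_TO_CODONS
from marinerscan.transposase_analysis import (
    ActivityParams,
    classify_activity,
    classify_triad,
    detect_catalytic_triad,
    find_best_orf,
    frameshift_suspected,
    fuzzy_motif_scan,
    hth_scan,
    nls_heuristic,
    scan_motifs,
)

_BG = "ACFGHILMNPQSTVY"  # no D/E/K/R/W: keeps planted motifs unique


def _protein(rng, n=335):
    return "M" + "".join(_BG[i] for i in rng.integers(0, len(_BG), n - 1))


def _encode(protein, rng, stop="TAA"):
    return "".join(
        AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in protein
    ) + stop


def _element(rng, protein):
    return ( "".join("ACGT"[i] for i in rng.integers(0, 4, 60)) + "TAA"
             + _encode(protein, rng)
             + "".join("ACGT"[i] for i in rng.integers(0, 4, 80)) )


def test_orf_finder_recovers_planted_orf(rng):
    protein = _protein(rng)
    elem = _element(rng, protein)
    orf = find_best_orf(elem)
    assert orf.aa_seq == protein
    assert not orf.has_internal_stop and orf.n_premature_stops == 0
    s, e = orf.nt_span
    assert e - s == 3 * len(protein)


def test_single_stop_codon_is_counted(rng):
    protein = _protein(rng)
    elem = _element(rng, protein)
    orf0 = find_best_orf(elem)
    s, _ = orf0.nt_span
    mut = elem[:s + 3 * 150] + "TAA" + elem[s + 3 * 151:]
    orf = find_best_orf(mut)
    assert orf.has_internal_stop
    assert orf.n_premature_stops == 1


def test_orf_strand_symmetry(rng):
    protein = _protein(rng)
    elem = _element(rng, protein)
    fwd = find_best_orf(elem)
    rev = find_best_orf(revcomp(elem))
    assert fwd.aa_seq == rev.aa_seq
    assert fwd.strand == "+" and rev.strand == "-"
    n = len(elem)
    assert rev.nt_span == (n - fwd.nt_span[1], n - fwd.nt_span[0])


def test_triad_constructed_spacing(rng):
    aa = list(_protein(rng, 300))
    aa[50], aa[120], aa[154] = "D", "D", "D"
    hit = detect_catalytic_triad("".join(aa))
    assert hit.triad_class == "DD34D"
    assert hit.positions == (50, 120, 154)


def test_triad_terminal_glutamate_is_tc1_not_mariner(rng):
    aa = list(_protein(rng, 300))
    aa[50], aa[120], aa[154] = "D", "D", "E"
    s = "".join(aa)
    assert detect_catalytic_triad(s).positions is None
    assert classify_triad(s).triad_class == "DD34E"


@pytest.mark.parametrize("trial", range(30))
def test_triad_scan_equals_bruteforce(trial):
    rng = np.random.default_rng(500 + trial)
    aa = list(_protein(rng, 250))
    spots = sorted(rng.choice(np.arange(5, 210), size=3, replace=False).tolist())
    aa[spots[0]], aa[spots[1]] = "D", "D"
    aa[min(spots[1] + 34, 249)] = "D"
    s = "".join(aa)
    got = detect_catalytic_triad(s)
    expected = oracles.triad_positions(s)
    assert got.positions == expected


def test_fuzzy_motif_exact_and_substituted(rng):
    base = _protein(rng, 200)
    prot = base[:90] + "WVPHEL" + base[96:]
    assert fuzzy_motif_scan(prot, "WVPHEL") == ((90, 96), 0)
    prot2 = base[:90] + "WVPYDL" + base[96:]
    span, subs = fuzzy_motif_scan(prot2, "WVPHEL")
    assert span == (90, 96) and subs == 2
    prot3 = base[:90] + "WVAYDL" + base[96:]  # three substitutions
    assert fuzzy_motif_scan(prot3, "WVPHEL") is None


@pytest.mark.parametrize("trial", range(20))
def test_fuzzy_motif_equals_bruteforce(trial):
    rng = np.random.default_rng(900 + trial)
    base = _protein(rng, 150)
    pos = int(rng.integers(10, 140))
    motif = "YSPDL"
    noisy = list(motif)
    if trial % 3:
        noisy[int(rng.integers(5))] = "G"
    prot = base[:pos] + "".join(noisy) + base[pos + 5:]
    got = fuzzy_motif_scan(prot, motif, max_subs=2)
    start, dist = oracles.best_motif_window(prot, motif)
    if dist > 2:
        assert got is None
    else:
        assert got == ((start, start + 5), dist)


def test_nls_basic_window(rng):
    prot = _protein(rng, 150) + "KRKRKR" + _protein(rng, 30)[1:]
    span, count = nls_heuristic(prot)
    assert count >= 6
    assert nls_heuristic("A" * 100) is None


def test_hth_heuristic_planted(rng):
    aa = list(_protein(rng, 200))
    for h in (18, 31):
        for off in (0, 3, 4, 7):
            aa[h + off] = "L"
    aa[28:31] = list("GQS")
    assert hth_scan("".join(aa))


def _cand(completeness="complete"):
    return ElementCandidate(contig_id="c", span=(0, 1300), strand="+",
                            tir=None, tsd_left=True, tsd_right=True,
                            completeness=completeness, at_contig_end=False)


def test_activity_classification_rules(rng):
    protein = _protein(rng)
    aa = list(protein)
    aa[100], aa[180], aa[214] = "D", "D", "D"
    protein = "".join(aa)
    elem = _element(rng, protein)
    orf = find_best_orf(elem)
    motifs = scan_motifs(orf.aa_seq)
    assert classify_activity(_cand("complete"), orf, motifs) == "potentially_active"
    assert classify_activity(_cand("truncated_5p"), orf, motifs) == \
        "intact_orf_truncated"
    s, _ = orf.nt_span
    broken = find_best_orf(elem[:s + 300] + "TAA" + elem[s + 303:])
    motifs_b = scan_motifs(broken.aa_seq)
    assert classify_activity(_cand("complete"), broken, motifs_b) == "inactive"


def test_triad_gate_blocks_dd34e(rng):
    protein = _protein(rng)
    aa = list(protein)
    aa[100], aa[180], aa[214] = "D", "D", "E"  # Tc1-style triad
    elem = _element(rng, "".join(aa))
    orf = find_best_orf(elem)
    motifs = scan_motifs(orf.aa_seq)
    assert motifs.triad.triad_class != "DD34D"
    assert classify_activity(_cand("complete"), orf, motifs) == "inactive"


def test_frameshift_surrogate(rng):
    protein = _protein(rng)
    elem = _element(rng, protein)
    assert not frameshift_suspected(elem, protein)
    orf = find_best_orf(elem)
    s, _ = orf.nt_span
    mid = s + 3 * 160
    shifted = elem[:mid] + elem[mid + 1:]  # single-base deletion
    assert frameshift_suspected(shifted, protein)
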
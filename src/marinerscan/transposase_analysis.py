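"""Transposase ORF and motif analysis.

Mariner transposases are 282--350 aa proteins carrying, from N- to
C-terminus: a helix-turn-helix (HTH) DNA-binding region, the WVPHEL
peptide, the DD34D catalytic triad (two aspartates, then a third exactly
34 residues after the second -- DD34E marks Tc1, DD37D/DD39D/DD41D the
maT/GT/VS families), the YSPDL peptide near the triad, and often a basic
nuclear localization signal (NLS). A copy is potentially active only when
it is complete (both TIRs) and its ORF is intact: no premature stop, no
frameshift, 310--345 aa, with the DD34D triad in place. HTH and NLS are
annotation-only heuristics and never gate the activity call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ._align import local_align, revcomp
from .io_formats import MarinerScanError

ACTIVITY_CLASSES = ("potentially_active", "intact_orf_truncated", "inactive")


@dataclass
class ActivityParams:
    """ORF-intactness gates: 310--345 aa bounds the active call; 282--350 is
    the family-wide range recorded as a soft annotation flag only."""

    orf_min_aa: int = 310
    orf_max_aa: int = 345
    family_aa_range: tuple[int, int] = (282, 350)

    def __post_init__(self):
        if self.orf_min_aa > self.orf_max_aa:
            raise MarinerScanError("orf_min_aa must be <= orf_max_aa")


@dataclass
class MotifParams:
    triad_signature: tuple[str, str, int, str] = ("D", "D", 34, "D")
    alt_signatures: dict = field(default_factory=lambda: {
        "DD34E": ("D", "D", 34, "E"),
        "DD37D": ("D", "D", 37, "D"),
        "DD39D": ("D", "D", 39, "D"),
        "DD41D": ("D", "D", 41, "D"),
    })
    wvphel: str = "WVPHEL"
    yspdl: str = "YSPDL"
    motif_max_subs: int = 2
    nls_window: int = 16
    nls_min_basic: int = 6
    hth_region_aa: int = 120


@dataclass
class ORFRecord:
    """The best transposase ORF of one element.

    ``nt_span`` is on the element sequence as given (forward coordinates
    even for a minus-frame ORF). When no ATG-initiated, stop-terminated ORF
    reaches ``orf_min_aa``, the record describes the longest open stretch in
    the frame with the longest stop-free run, and ``n_premature_stops``
    counts in-frame stops between the first ATG and the expected ORF extent.
    """

    strand: str
    frame: int
    aa_seq: str
    nt_span: tuple[int, int]
    has_internal_stop: bool
    n_premature_stops: int
    frameshift_suspected: bool = False
    aa_len_in_family_range: bool = False


@dataclass
class TriadHit:
    positions: tuple[int, int, int] | None
    triad_class: str  # e.g. DD34D, DD34E, degenerate, none


@dataclass
class MotifHits:
    triad: TriadHit
    wvphel: tuple[tuple[int, int], int] | None  # (span, substitutions)
    yspdl: tuple[tuple[int, int], int] | None
    hth_spans: list[tuple[tuple[int, int], tuple[int, int]]]
    nls: tuple[tuple[int, int], int] | None  # (span, basic-residue count)


def _frame_orfs(aa: str):
    """(start_codon_idx, end_codon_idx) of ATG-initiated, stop-terminated
    ORFs in one translated frame (aa includes '*' for stops)."""
    orfs = []
    start = None
    for i, c in enumerate(aa):
        if c == "M" and start is None:
            start = i
        elif c == "*":
            if start is not None:
                orfs.append((start, i))
            start = None
    return orfs


def find_best_orf(element_seq: str, params: ActivityParams | None = None) -> ORFRecord:
    """Scan all six frames for the longest ATG-initiated, stop-terminated ORF.

    If no ORF reaches ``orf_min_aa``, the frame with the longest stop-free
    run is reported instead, with its longest open stretch and the count of
    premature stops after the first ATG (excluding the expected terminator,
    looked for within ``orf_max_aa`` codons of that ATG).
    """
    params = params or ActivityParams()
    if len(element_seq) < 3:
        raise MarinerScanError("element shorter than one codon")
    n = len(element_seq)
    frames = []  # (strand, frame, aa_string)
    for strand, seq in (("+", element_seq), ("-", revcomp(element_seq))):
        for f in range(3):
            sub = seq[f:f + 3 * ((n - f) // 3)]
            aa = str(Seq(sub).translate())
            frames.append((strand, f, aa))

    def nt_span(strand: str, frame: int, c0: int, c1: int) -> tuple[int, int]:
        # codon range [c0, c1) of a frame -> forward element coordinates
        if strand == "+":
            return (frame + 3 * c0, frame + 3 * c1)
        start_rev = frame + 3 * c0
        end_rev = frame + 3 * c1
        return (n - end_rev, n - start_rev)

    best = None  # (aa_len, strand_pref, frame, start) for determinism
    for strand, f, aa in frames:
        for c0, c1 in _frame_orfs(aa):
            length = c1 - c0
            key = (-length, strand != "+", f, c0)
            if best is None or key < best[0]:
                best = (key, strand, f, aa, c0, c1)
    if best is not None and (best[5] - best[4]) >= params.orf_min_aa:
        _, strand, f, aa, c0, c1 = best
        length = c1 - c0
        return ORFRecord(
            strand=strand, frame=f, aa_seq=aa[c0:c1],
            nt_span=nt_span(strand, f, c0, c1),
            has_internal_stop=False, n_premature_stops=0,
            aa_len_in_family_range=(
                params.family_aa_range[0] <= length <= params.family_aa_range[1]
            ),
        )

    # degraded copy: the transposase frame is the one with the fewest
    # in-frame stops (a decayed coding frame carries a handful; the other
    # five frames of a ~1.3 kb element carry dozens), ties broken by the
    # longest stop-free run
    def longest_run(aa: str) -> int:
        run = best_run = 0
        for c in aa:
            run = 0 if c == "*" else run + 1
            best_run = max(best_run, run)
        return best_run

    strand, f, aa = min(
        frames,
        key=lambda t: (t[2].count("*"), -longest_run(t[2]), t[0] != "+", t[1]),
    )
    m = aa.find("M")
    if m < 0:
        m = 0
    # premature stops: in-frame stops after the first ATG and before the
    # expected terminator (the first stop that would close an ORF of at
    # least orf_min_aa); if no stop reaches that length, every stop within
    # the orf_max_aa window is premature
    window_end = min(len(aa), m + params.orf_max_aa + 1)
    stops = [i for i in range(m + 1, len(aa)) if aa[i] == "*"]
    terminator = next((s for s in stops if s - m >= params.orf_min_aa), None)
    if terminator is not None:
        n_premature = sum(1 for s in stops if s < terminator)
    else:
        n_premature = sum(1 for s in stops if s < window_end)
    # longest open (stop-free) stretch starting at or after the first ATG
    seg_start, seg = m, ""
    cur = []
    start_i = m
    for i in range(m, len(aa)):
        if aa[i] == "*":
            if len(cur) > len(seg):
                seg, seg_start = "".join(cur), start_i
            cur = []
            start_i = i + 1
        else:
            cur.append(aa[i])
    if len(cur) > len(seg):
        seg, seg_start = "".join(cur), start_i
    length = len(seg)
    return ORFRecord(
        strand=strand, frame=f, aa_seq=seg,
        nt_span=nt_span(strand, f, seg_start, seg_start + length),
        has_internal_stop=n_premature > 0,
        n_premature_stops=n_premature,
        aa_len_in_family_range=(
            params.family_aa_range[0] <= length <= params.family_aa_range[1]
        ),
    )


def detect_catalytic_triad(aa_seq: str,
                           signature: tuple[str, str, int, str] = ("D", "D", 34, "D"),
                           ) -> TriadHit:
    """Find positions i<j<k matching the DDE/D signature with exact spacing.

    The spacing constraint binds the 2nd and 3rd residues (k - j equals the
    signature spacing, 34 for Mariner); the first residue may sit anywhere
    upstream. The leftmost qualifying (j, k) pair is reported with the
    leftmost upstream first residue. When only the spaced (j, k) pair is
    found without an upstream first residue, the hit is 'degenerate'.
    """
    if not aa_seq:
        raise MarinerScanError("empty protein")
    r1, r2, spacing, r3 = signature
    label = f"{r1}{r2}{spacing}{r3}"
    first_pair = None
    for j, c in enumerate(aa_seq):
        if c == r2:
            k = j + spacing
            if k < len(aa_seq) and aa_seq[k] == r3:
                if first_pair is None:
                    first_pair = (j, k)
                for i in range(j):
                    if aa_seq[i] == r1:
                        return TriadHit(positions=(i, j, k), triad_class=label)
    if first_pair is None:
        return TriadHit(positions=None, triad_class="none")
    return TriadHit(positions=None, triad_class="degenerate")


def classify_triad(aa_seq: str, params: MotifParams | None = None) -> TriadHit:
    """Classify against DD34D first, then the alternative family signatures."""
    params = params or MotifParams()
    hit = detect_catalytic_triad(aa_seq, params.triad_signature)
    if hit.positions is not None:
        return hit
    for sig in params.alt_signatures.values():
        alt = detect_catalytic_triad(aa_seq, sig)
        if alt.positions is not None:
            return alt
    return hit  # none or degenerate under the Mariner signature


def fuzzy_motif_scan(aa_seq: str, motif: str, max_subs: int = 2
                     ) -> tuple[tuple[int, int], int] | None:
    """Best Hamming-distance window for a short peptide motif (no indels).

    Returns (span, substitution count) of the lowest-distance (leftmost on
    ties) window with at most ``max_subs`` substitutions, else None.
    """
    if len(motif) < 4:
        raise MarinerScanError("motif too short")
    L = len(motif)
    if len(aa_seq) < L:
        return None
    arr = np.frombuffer(aa_seq.encode("ascii"), dtype=np.uint8)
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    wins = np.lib.stride_tricks.sliding_window_view(arr, L)
    dist = L - (wins == m).sum(axis=1)
    best = int(dist.argmin())
    if dist[best] > max_subs:
        return None
    return (best, best + L), int(dist[best])


def nls_heuristic(aa_seq: str, params: MotifParams | None = None
                  ) -> tuple[tuple[int, int], int] | None:
    """Basic-residue-rich window standing in for an NLS predictor.

    The highest-count window of ``nls_window`` residues scored by K/R
    content; reported when the count reaches ``nls_min_basic``.
    """
    params = params or MotifParams()
    if not aa_seq:
        raise MarinerScanError("empty protein")
    w = params.nls_window
    if len(aa_seq) < w:
        return None
    arr = np.frombuffer(aa_seq.encode("ascii"), dtype=np.uint8)
    basic = ((arr == ord("K")) | (arr == ord("R"))).astype(np.int32)
    counts = np.convolve(basic, np.ones(w, np.int32), mode="valid")
    best = int(counts.argmax())
    if counts[best] < params.nls_min_basic:
        return None
    return (best, best + w), int(counts[best])


_HYDROPHOBIC = frozenset("AVLIMFWY")


def hth_scan(aa_seq: str, params: MotifParams | None = None
             ) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Positional helix-turn-helix heuristic in the N-terminal region.

    A 'helix' is a 10-aa window with hydrophobic residues at the helical-wheel
    positions 0, 3, 4 and 7; an HTH is two such windows separated by a 3--5 aa
    turn containing G or P, within the first ``hth_region_aa`` residues.
    Annotation-only; never gates the activity call.
    """
    params = params or MotifParams()
    region = aa_seq[:params.hth_region_aa]
    helix_starts = [
        i for i in range(len(region) - 9)
        if all(region[i + o] in _HYDROPHOBIC for o in (0, 3, 4, 7))
    ]
    out = []
    for h1 in helix_starts:
        for h2 in helix_starts:
            gap = h2 - (h1 + 10)
            if 3 <= gap <= 5 and any(c in "GP" for c in region[h1 + 10:h2]):
                out.append(((h1, h1 + 10), (h2, h2 + 10)))
    return out


def scan_motifs(aa_seq: str, params: MotifParams | None = None) -> MotifHits:
    params = params or MotifParams()
    return MotifHits(
        triad=classify_triad(aa_seq, params),
        wvphel=fuzzy_motif_scan(aa_seq, params.wvphel, params.motif_max_subs),
        yspdl=fuzzy_motif_scan(aa_seq, params.yspdl, params.motif_max_subs),
        hth_spans=hth_scan(aa_seq, params),
        nls=nls_heuristic(aa_seq, params),
    )


def frameshift_suspected(element_seq: str, ref_protein: str,
                         min_combined_coverage: float = 0.8,
                         min_part: float = 0.15) -> bool:
    """Frameshift surrogate: the element's conceptual translation only covers
    the reference transposase when two different reading frames are combined.

    Each forward frame's translation is locally aligned to the reference; a
    frameshift is suspected when no single frame covers >= 80% of the
    reference but two frames' aligned reference intervals jointly do, each
    contributing a non-trivial part.
    """
    n = len(element_seq)
    spans = []
    for f in range(3):
        sub = element_seq[f:f + 3 * ((n - f) // 3)]
        if len(sub) < 3:
            spans.append((0, 0))
            continue
        aa = str(Seq(sub).translate())
        aln = local_align(aa, ref_protein, protein=True)
        spans.append((aln.b_start, aln.b_end))
    ref_len = len(ref_protein)
    cov = [(e - s) / ref_len for s, e in spans]
    if max(cov) >= min_combined_coverage:
        return False
    for a in range(3):
        for b in range(a + 1, 3):
            lo = min(spans[a][0], spans[b][0])
            hi = max(spans[a][1], spans[b][1])
            union = (spans[a][1] - spans[a][0]) + (spans[b][1] - spans[b][0])
            union -= max(0, min(spans[a][1], spans[b][1]) - max(spans[a][0], spans[b][0]))
            if (
                union / ref_len >= min_combined_coverage
                and cov[a] >= min_part
                and cov[b] >= min_part
                and (hi - lo) / ref_len >= min_combined_coverage
            ):
                return True
    return False


def classify_activity(candidate, orf: ORFRecord, motifs: MotifHits,
                      params: ActivityParams | None = None) -> str:
    """Activity class of one element.

    potentially_active: complete (both TIRs) AND intact ORF (no premature
    stop, no suspected frameshift, 310--345 aa) AND DD34D triad.
    intact_orf_truncated: intact ORF but the element is truncated.
    inactive: everything else.
    """
    params = params or ActivityParams()
    length = len(orf.aa_seq)
    orf_intact = (
        not orf.has_internal_stop
        and not orf.frameshift_suspected
        and params.orf_min_aa <= length <= params.orf_max_aa
    )
    if orf_intact and candidate.completeness == "complete":
        if motifs.triad.triad_class == "DD34D":
            return "potentially_active"
        return "inactive"
    if orf_intact:
        return "intact_orf_truncated"
    return "inactive"
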
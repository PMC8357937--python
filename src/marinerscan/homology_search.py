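"""Homology mining of genome contigs against an MLE query panel.

The search is a k-mer-seeded, DP-extended local aligner: exact k-mer
matches between query and contig are clustered on diagonals, each cluster
defines a candidate window, and the window is aligned with the package's
Smith--Waterman kernel. Small contigs (where seeding buys nothing) are
aligned in full, so on desk-size instances the reported scores are exactly
the full-DP optima. Hits are then filtered with the mining thresholds the
method prescribes: identity > 0.60 and query coverage > 0.60, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _align
from .io_formats import ContigSet, MarinerScanError, ReferencePanel

Queries = "ReferencePanel | list[tuple[str, str]]"


@dataclass
class SearchParams:
    """Tunable knobs of the homology search.

    ``min_identity``/``min_coverage`` are the mining thresholds (fractions,
    strict ``>``); ``reject_identity``/``reject_coverage`` are the much looser
    floors used when screening for the non-Mariner DD-family panels
    (coverage >= 0.15 and identity >= 0.30 flags a family as present).
    ``min_score`` is an absolute alignment-score cutoff standing in for a
    raw E-value threshold, which cannot be calibrated without a database
    model; the identity/coverage post-filter does the real selection.
    """

    k: int = 12
    min_identity: float = 0.60
    min_coverage: float = 0.60
    match: int = _align.MATCH
    mismatch: int = _align.MISMATCH
    gap_open: int = -_align.GAP_OPEN
    gap_extend: int = -_align.GAP_EXTEND
    min_score: int = 40
    reject_identity: float = 0.30
    reject_coverage: float = 0.15
    min_seed_count: int = 2
    diag_band: int = 16
    max_seed_gap: int = 400
    window_margin: int = 80
    full_dp_max_contig: int = 4000
    requery_min_coverage: float = 0.90

    def __post_init__(self):
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise MarinerScanError("identity/coverage thresholds must be in (0,1]")
        if self.k < 8:
            raise MarinerScanError("seed word length k must be >= 8")


@dataclass(frozen=True)
class HomologyHit:
    """A scored local alignment of a query to a genome contig interval.

    Spans are 0-based half-open; ``query_span`` is always on the forward
    query, ``contig_span`` on the forward contig, with ``strand`` recording
    the orientation of the match.
    """

    query_id: str
    contig_id: str
    strand: str
    query_span: tuple[int, int]
    contig_span: tuple[int, int]
    identity: float
    coverage: float
    score: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise MarinerScanError(f"bad strand {self.strand!r}")
        if not (0 <= self.identity <= 1 and 0 <= self.coverage <= 1):
            raise MarinerScanError("identity/coverage out of [0,1]")

    @property
    def length(self) -> int:
        return self.contig_span[1] - self.contig_span[0]


def _as_query_list(queries) -> list[tuple[str, str]]:
    if isinstance(queries, ReferencePanel):
        qs = [(r.seq_id, r.sequence) for r in queries.by_role("query")]
        if not qs:  # a panel of references with no explicit query role
            qs = [(r.seq_id, r.sequence) for r in queries.records]
        return qs
    return list(queries)


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, positions) of all N-free k-mers of an encoded sequence."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    codes = np.zeros(n, np.int64)
    ok = np.ones(n, bool)
    e = enc.astype(np.int64)
    for i in range(k):
        win = e[i:i + n]
        codes = (codes << 2) | (win & 3)
        ok &= win < 4
    pos = np.nonzero(ok)[0]
    return codes[pos], pos


class _ContigIndex:
    """Sorted k-mer index of one contig for seed lookup."""

    def __init__(self, seq: str, k: int):
        self.k = k
        codes, pos = _kmer_codes(_align.encode_dna(seq), k)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def seed_positions(self, qcodes: np.ndarray, qpos: np.ndarray):
        """(contig_pos, query_pos) of every exact k-mer match."""
        lo = np.searchsorted(self.codes, qcodes, "left")
        hi = np.searchsorted(self.codes, qcodes, "right")
        counts = hi - lo
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        cpos = np.concatenate([self.pos[lo[i]:hi[i]] for i in nz])
        qp = np.repeat(qpos[nz], counts[nz])
        return cpos, qp


def _seed_windows(index: _ContigIndex, qseq: str, qlen: int, contig_len: int,
                  params: SearchParams) -> list[tuple[int, int]]:
    qcodes, qpos = _kmer_codes(_align.encode_dna(qseq), params.k)
    cpos, qp = index.seed_positions(qcodes, qpos)
    if cpos.size < params.min_seed_count:
        return []
    diag = cpos - qp
    order = np.lexsort((cpos, diag))
    diag, cpos, qp = diag[order], cpos[order], qp[order]
    windows = []
    start = 0
    n = diag.size
    for i in range(1, n + 1):
        if (
            i == n
            or diag[i] - diag[i - 1] > params.diag_band
            or cpos[i] - cpos[i - 1] > params.max_seed_gap
        ):
            if i - start >= params.min_seed_count:
                c0, c1 = int(cpos[start:i].min()), int(cpos[start:i].max())
                q0, q1 = int(qp[start:i].min()), int(qp[start:i].max())
                w0 = max(0, c0 - q0 - params.window_margin)
                w1 = min(contig_len, c1 + params.k + (qlen - q1) + params.window_margin)
                windows.append((w0, w1))
            start = i
    return _merge_intervals(windows)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = _overlap(a, b)
    if ov == 0:
        return 0.0
    return ov / min(a[1] - a[0], b[1] - b[0])


def _align_window(qseq: str, qid: str, qlen: int, strand: str, contig_id: str,
                  contig_seq: str, window: tuple[int, int],
                  params: SearchParams) -> list[HomologyHit]:
    w0, w1 = window
    hits = []
    for aln in _align.local_align_multi(qseq, contig_seq[w0:w1], params.min_score):
        cspan = (w0 + aln.b_start, w0 + aln.b_end)
        if strand == "+":
            qspan = (aln.a_start, aln.a_end)
        else:
            qspan = (qlen - aln.a_end, qlen - aln.a_start)
        hits.append(
            HomologyHit(
                query_id=qid,
                contig_id=contig_id,
                strand=strand,
                query_span=qspan,
                contig_span=cspan,
                identity=aln.identity,
                coverage=(aln.a_end - aln.a_start) / qlen,
                score=aln.score,
            )
        )
    return hits


def _merge_same_query(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Merge overlapping hits of the same query/strand, keeping the best score.

    Two hits overlapping by >= 50% of the shorter one are considered the same
    local alignment reported twice (e.g. from adjacent windows).
    """
    kept: list[HomologyHit] = []
    for hit in sorted(hits, key=lambda h: -h.score):
        dup = any(
            k.query_id == hit.query_id
            and k.contig_id == hit.contig_id
            and k.strand == hit.strand
            and reciprocal_overlap(k.contig_span, hit.contig_span) >= 0.5
            for k in kept
        )
        if not dup:
            kept.append(hit)
    return _sorted_hits(kept)


def _sorted_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    return sorted(
        hits,
        key=lambda h: (h.contig_id, h.contig_span, -h.score, h.query_id, h.strand),
    )


def seed_and_extend(genome: ContigSet, queries, params: SearchParams | None = None,
                    skip_intervals: dict[str, list[tuple[int, int]]] | None = None,
                    ) -> list[HomologyHit]:
    """Local alignments of every query against both strands of every contig.

    ``queries`` is a :class:`ReferencePanel` (role ``query``) or a list of
    ``(id, sequence)`` pairs. ``skip_intervals`` (per contig) suppresses
    alignment of candidate windows already covered by accepted hits; it is
    used by :func:`iterative_search` re-query rounds.
    """
    params = params or SearchParams()
    qlist = _as_query_list(queries)
    if not qlist:
        raise MarinerScanError("query panel is empty")
    hits: list[HomologyHit] = []
    for contig_id, cseq in genome.items():
        clen = len(cseq)
        known = (skip_intervals or {}).get(contig_id, [])
        index = None
        small_kmers = None
        for qid, qseq in qlist:
            qlen = len(qseq)
            for strand, q in (("+", qseq), ("-", _align.revcomp(qseq))):
                if clen <= params.full_dp_max_contig:
                    # small contig: full DP, gated on at least one shared
                    # k-mer so featureless contigs are not aligned at all
                    if small_kmers is None:
                        small_kmers = np.unique(
                            _kmer_codes(_align.encode_dna(cseq), params.k)[0]
                        )
                    qcodes = _kmer_codes(_align.encode_dna(q), params.k)[0]
                    idx = np.searchsorted(small_kmers, qcodes)
                    valid = idx < small_kmers.size
                    shared = bool(
                        np.any(small_kmers[idx[valid]] == qcodes[valid])
                    ) if valid.any() else False
                    windows = [(0, clen)] if shared else []
                    seeded = False
                else:
                    if index is None:
                        index = _ContigIndex(cseq, params.k)
                    windows = _seed_windows(index, q, qlen, clen, params)
                    seeded = True
                for win in windows:
                    # a seed window whose signal is an already-accepted
                    # interval would only rediscover it; skip the alignment
                    # (whole-contig windows may still hold novel copies)
                    if seeded and known and any(
                        _overlap(win, iv) >= 0.9 * (iv[1] - iv[0]) for iv in known
                    ):
                        continue
                    hits.extend(
                        _align_window(q, qid, qlen, strand, contig_id, cseq, win, params)
                    )
    return _merge_same_query(hits)


def filter_hits(hits: list[HomologyHit], params: SearchParams | None = None
                ) -> list[HomologyHit]:
    """Retain hits with identity and query coverage strictly above threshold."""
    params = params or SearchParams()
    return [
        h for h in hits
        if h.identity > params.min_identity and h.coverage > params.min_coverage
    ]


def iterative_search(genome: ContigSet, initial_panel, params: SearchParams | None = None,
                     max_rounds: int = 3) -> list[HomologyHit]:
    """Iterative homology mining: re-query with extracted near-complete copies.

    Round 1 is ``filter_hits(seed_and_extend(...))`` with the initial panel.
    Each later round extracts the genomic sequence of hits covering >= 90% of
    their query and uses them as additional queries, so copies too diverged
    from the panel but close to an extracted copy are recovered. Stops at a
    fixpoint (no new genomic interval) or ``max_rounds``. Hits rediscovered in
    a later round at an interval already known are dropped.
    """
    if max_rounds < 1:
        raise MarinerScanError("max_rounds must be >= 1")
    params = params or SearchParams()
    accepted = filter_hits(seed_and_extend(genome, initial_panel, params), params)
    known: dict[str, list[tuple[int, int]]] = {}
    for h in accepted:
        known.setdefault(h.contig_id, []).append(h.contig_span)
    frontier = _extract_requery(genome, accepted, params)
    seen_queries = set()
    for _ in range(1, max_rounds):
        frontier = [(n, s) for n, s in frontier if n not in seen_queries]
        if not frontier:
            break
        seen_queries.update(n for n, _ in frontier)
        new_hits = filter_hits(
            seed_and_extend(genome, frontier, params, skip_intervals=known), params
        )
        novel = []
        for h in new_hits:
            if any(
                reciprocal_overlap(h.contig_span, iv) >= 0.5
                for iv in known.get(h.contig_id, [])
            ):
                continue
            novel.append(h)
            known.setdefault(h.contig_id, []).append(h.contig_span)
        if not novel:
            break
        accepted.extend(novel)
        frontier = _extract_requery(genome, novel, params)
    return _sorted_hits(accepted)


def _extract_requery(genome: ContigSet, hits: list[HomologyHit],
                     params: SearchParams) -> list[tuple[str, str]]:
    out = []
    for h in hits:
        if h.coverage >= params.requery_min_coverage:
            s, e = h.contig_span
            seq = genome.contigs[h.contig_id][s:e]
            out.append((f"{h.contig_id}:{s}-{e}", seq))
    return out


def cluster_hits_by_interval(hits: list[HomologyHit]) -> list[list[HomologyHit]]:
    """Group hits whose contig intervals overlap >= 50% of the shorter.

    Each cluster corresponds to one putative genomic element hit by one or
    more queries; within a cluster hits are ordered best score first.
    """
    clusters: list[list[HomologyHit]] = []
    spans: list[tuple[str, tuple[int, int]]] = []
    for h in _sorted_hits(hits):
        placed = False
        for i, (cid, span) in enumerate(spans):
            if cid == h.contig_id and reciprocal_overlap(span, h.contig_span) >= 0.5:
                clusters[i].append(h)
                lo = min(span[0], h.contig_span[0])
                hi = max(span[1], h.contig_span[1])
                spans[i] = (cid, (lo, hi))
                placed = True
                break
        if not placed:
            clusters.append([h])
            spans.append((h.contig_id, h.contig_span))
    for cl in clusters:
        cl.sort(key=lambda h: (-h.score, h.query_id))
    return clusters


def screen_other_families(genome: ContigSet, family_panels, params: SearchParams | None = None
                          ) -> dict[str, bool]:
    """Presence/absence screen for the non-Mariner DD-families.

    ``family_panels`` is a list of :class:`PanelRecord`-like objects (or a
    ReferencePanel) labeled by ``family``. A family is flagged present only if
    some hit reaches both reject floors (identity >= 0.30 and query coverage
    >= 0.15); anything weaker counts as "no good hit".
    """
    params = params or SearchParams()
    if isinstance(family_panels, ReferencePanel):
        records = family_panels.records
    else:
        records = list(family_panels)
    by_family: dict[str, list[tuple[str, str]]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append((r.seq_id, r.sequence))
    out = {}
    for family, qs in sorted(by_family.items()):
        hits = seed_and_extend(genome, qs, params)
        out[family] = any(
            h.identity >= params.reject_identity and h.coverage >= params.reject_coverage
            for h in hits
        )
    return out
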
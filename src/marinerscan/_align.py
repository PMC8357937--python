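"""Pairwise DP alignment kernels used across the package.

Three alignment flavours are provided, all with affine gaps:

* local (Smith--Waterman) -- used by the homology search to extend seed
  clusters into scored hits;
* semiglobal (free terminal gaps, path trimmed at the matrix edges);
* global (terminal gaps penalized) -- used for whole-element identity and
  the center-star MSA, where full-length paths are required.

Scoring scheme (fixed package-wide): match +1, mismatch -1, a gap of
length L costs ``gap_open + (L-1)*gap_extend`` with defaults 2 and 1.
``N`` bases (and the ``*`` stop character in protein mode) never match
anything, so assembly gaps act as mismatch barriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP_OPEN = 2  # cost of the first gapped column
GAP_EXTEND = 1  # cost of each additional gapped column

_NEG = np.int32(-(10 ** 8))

_DNA_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _DNA_LUT[ord(_c)] = _i
    _DNA_LUT[ord(_c.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes A=0 C=1 G=2 T=3, anything else 4 (never matches)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _DNA_LUT[raw]


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string as int8 ordinals; '*' becomes a never-match code."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int8)
    raw = raw.copy()
    raw[raw == ord("*")] = -2
    return raw


@dataclass(frozen=True)
class Alignment:
    """One pairwise alignment path.

    Spans are 0-based half-open on the *input* sequences; ``n_cols`` counts
    the columns on the path including gaps (local and semiglobal paths never
    contain terminal gaps; global paths do).
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_match: int
    n_cols: int
    ops: np.ndarray  # 0 = diagonal, 1 = gap in a (consumes b), 2 = gap in b

    @property
    def identity(self) -> float:
        return self.n_match / self.n_cols if self.n_cols else 0.0


@njit(cache=True)
def _fill_local(a, b, match, mismatch, gopen, gext, nm):
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    ph = np.zeros((n + 1, m + 1), np.int8)  # 0 stop, 1 diag, 2 from E, 3 from F
    pe = np.zeros((n + 1, m + 1), np.int8)  # 0 open, 1 extend
    pf = np.zeros((n + 1, m + 1), np.int8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] - gopen
            ee = E[i, j - 1] - gext
            if ee > eo:
                E[i, j] = ee
                pe[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] - gopen
            fe = F[i - 1, j] - gext
            if fe > fo:
                F[i, j] = fe
                pf[i, j] = 1
            else:
                F[i, j] = fo
            bj_ = b[j - 1]
            if ai == bj_ and 0 <= ai < nm:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ph, pe, pf


@njit(cache=True)
def _trace(a, b, nm, bi, bj, ph, pe, pf, mode):
    # state 0 = H, 1 = E (gap in a), 2 = F (gap in b)
    # mode: 0 local, 1 semiglobal (stop at an edge), 2 global (run to origin)
    ops = np.empty(a.size + b.size, np.int8)
    k = ops.size
    i, j = bi, bj
    nmatch = 0
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if mode == 2 and (i == 0 or j == 0):
                while j > 0:
                    k -= 1
                    ops[k] = 1
                    j -= 1
                while i > 0:
                    k -= 1
                    ops[k] = 2
                    i -= 1
                break
            p = ph[i, j]
            if mode == 0 and p == 0:
                break
            if mode == 1 and (i == 0 or j == 0):
                break
            if p == 1:
                k -= 1
                ops[k] = 0
                if a[i - 1] == b[j - 1] and 0 <= a[i - 1] < nm:
                    nmatch += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 3
        elif state == 1:
            k -= 1
            ops[k] = 1
            if pe[i, j] == 0:
                state = 0
            j -= 1
        else:
            k -= 1
            ops[k] = 2
            if pf[i, j] == 0:
                state = 0
            i -= 1
    return ops[k:], i, j, nmatch


@njit(cache=True)
def _fill_semiglobal(a, b, match, mismatch, gopen, gext, nm):
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), np.int32)  # free end gaps: first row/col 0
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    ph = np.zeros((n + 1, m + 1), np.int8)
    pe = np.zeros((n + 1, m + 1), np.int8)
    pf = np.zeros((n + 1, m + 1), np.int8)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] - gopen
            ee = E[i, j - 1] - gext
            if ee > eo:
                E[i, j] = ee
                pe[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] - gopen
            fe = F[i - 1, j] - gext
            if fe > fo:
                F[i, j] = fe
                pf[i, j] = 1
            else:
                F[i, j] = fo
            if ai == b[j - 1] and 0 <= ai < nm:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ph[i, j] = p
    # best over last row and last column (terminal gaps free)
    best = _NEG
    bi = n
    bj = m
    for j in range(0, m + 1):
        if H[n, j] > best:
            best = H[n, j]
            bi = n
            bj = j
    for i in range(0, n + 1):
        if H[i, m] > best:
            best = H[i, m]
            bi = i
            bj = m
    return best, bi, bj, ph, pe, pf


@njit(cache=True)
def _fill_globalnw(a, b, match, mismatch, gopen, gext, nm):
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    ph = np.zeros((n + 1, m + 1), np.int8)
    pe = np.zeros((n + 1, m + 1), np.int8)
    pf = np.zeros((n + 1, m + 1), np.int8)
    for j in range(1, m + 1):
        H[0, j] = -(gopen + (j - 1) * gext)
        E[0, j] = H[0, j]
    for i in range(1, n + 1):
        H[i, 0] = -(gopen + (i - 1) * gext)
        F[i, 0] = H[i, 0]
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] - gopen
            ee = E[i, j - 1] - gext
            if ee > eo:
                E[i, j] = ee
                pe[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] - gopen
            fe = F[i - 1, j] - gext
            if fe > fo:
                F[i, j] = fe
                pf[i, j] = 1
            else:
                F[i, j] = fo
            if ai == b[j - 1] and 0 <= ai < nm:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ph[i, j] = p
    return H[n, m], n, m, ph, pe, pf


_FILLS = {"local": _fill_local, "semiglobal": _fill_semiglobal,
          "global": _fill_globalnw}
_MODE_CODE = {"local": 0, "semiglobal": 1, "global": 2}


def _run(a_enc, b_enc, nm, mode):
    fill = _FILLS[mode]
    score, bi, bj, ph, pe, pf = fill(
        a_enc, b_enc, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND, nm
    )
    ops, i0, j0, nmatch = _trace(a_enc, b_enc, nm, bi, bj, ph, pe, pf,
                                 _MODE_CODE[mode])
    return Alignment(
        score=int(score),
        a_start=int(i0),
        a_end=int(bi),
        b_start=int(j0),
        b_end=int(bj),
        n_match=int(nmatch),
        n_cols=int(ops.size),
        ops=ops,
    )


def local_align(a: str, b: str, protein: bool = False) -> Alignment:
    """Best local alignment of ``a`` against ``b``."""
    enc = encode_protein if protein else encode_dna
    nm = 127 if protein else 4
    return _run(enc(a), enc(b), nm, "local")


def local_align_multi(a: str, b: str, min_score: int, max_hits: int = 64) -> list[Alignment]:
    """All non-overlapping local alignments of ``a`` in ``b`` scoring >= min_score.

    Greedy best-first with masking of the matched target interval, the
    standard way one local aligner reports multiple copies of a query.
    """
    a_enc = encode_dna(a)
    b_enc = encode_dna(b).copy()
    hits: list[Alignment] = []
    for _ in range(max_hits):
        aln = _run(a_enc, b_enc, 4, "local")
        if aln.score < min_score or aln.n_cols == 0:
            break
        hits.append(aln)
        b_enc[aln.b_start:aln.b_end] = -3  # never matches again
    return hits


def semiglobal_align(a: str, b: str, protein: bool = False) -> Alignment:
    """Global alignment with free terminal gaps in either sequence."""
    enc = encode_protein if protein else encode_dna
    nm = 127 if protein else 4
    return _run(enc(a), enc(b), nm, "semiglobal")


def semiglobal_identity(a: str, b: str) -> float:
    """Identity over aligned columns, terminal gaps excluded."""
    return semiglobal_align(a, b).identity


def global_align(a: str, b: str, protein: bool = False) -> Alignment:
    """True global alignment (terminal gaps penalized like any other)."""
    enc = encode_protein if protein else encode_dna
    nm = 127 if protein else 4
    return _run(enc(a), enc(b), nm, "global")


def global_identity(a: str, b: str) -> float:
    """End-gap-free identity on the global alignment path.

    The path is the penalized global optimum (so unrelated sequences cannot
    collapse onto a tiny high-identity overlap); terminal gap runs are then
    excluded from the column count, which matches how whole-element percent
    identity is quoted for truncated copies.
    """
    aln = _run(encode_dna(a), encode_dna(b), 4, "global")
    ops = aln.ops
    lead = 0
    while lead < ops.size and ops[lead] != 0:
        lead += 1
    trail = 0
    while trail < ops.size - lead and ops[ops.size - 1 - trail] != 0:
        trail += 1
    core = ops.size - lead - trail
    return aln.n_match / core if core else 0.0
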
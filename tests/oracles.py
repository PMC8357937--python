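"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (pure-Python dynamic programming and
exhaustive enumeration) and shares no code with the package's optimized
paths. The scoring scheme mirrors the package contract: match +1,
mismatch -1, a gap of length L costs 2 + (L - 1).
"""

from __future__ import annotations

import itertools

NEG = -(10 ** 9)
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def _pairs_score(x: str, y: str) -> int:
    return 1 if (x == y and x != "N" and y != "N") else -1


def sw_score(a: str, b: str) -> int:
    """Best local alignment score, affine gaps, triple-matrix DP."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - 2, E[i][j - 1] - 1)
            F[i][j] = max(H[i - 1][j] - 2, F[i - 1][j] - 1)
            h = max(0, H[i - 1][j - 1] + _pairs_score(a[i - 1], b[j - 1]),
                    E[i][j], F[i][j])
            H[i][j] = h
            best = max(best, h)
    return best


def sw_align_stats(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, aligned columns) of the best local alignment."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - 2, E[i][j - 1] - 1)
            F[i][j] = max(H[i - 1][j] - 2, F[i - 1][j] - 1)
            h = max(0, H[i - 1][j - 1] + _pairs_score(a[i - 1], b[j - 1]),
                    E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback (recompute choices greedily in the same precedence order
    # as the forward pass: diagonal, then E, then F)
    i, j = bi, bj
    matches = cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            if H[i][j] == H[i - 1][j - 1] + _pairs_score(a[i - 1], b[j - 1]):
                if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                    matches += 1
                cols += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            state = "H" if E[i][j] == H[i][j - 1] - 2 else "E"
            j -= 1
        else:
            cols += 1
            state = "H" if F[i][j] == H[i - 1][j] - 2 else "F"
            i -= 1
    return best, matches, cols


def global_identity(a: str, b: str) -> float:
    """Identity on the penalized global alignment path, with terminal gap
    columns excluded from the count (end-gap-free identity)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        H[0][j] = -(2 + (j - 1))
        E[0][j] = H[0][j]
    for i in range(1, n + 1):
        H[i][0] = -(2 + (i - 1))
        F[i][0] = H[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - 2, E[i][j - 1] - 1)
            F[i][j] = max(H[i - 1][j] - 2, F[i - 1][j] - 1)
            H[i][j] = max(H[i - 1][j - 1] + _pairs_score(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
    # traceback collecting the op string (0 diag, 1 gap-in-a, 2 gap-in-b)
    i, j = n, m
    ops = []
    state = "H"
    while i > 0 or j > 0:
        if i == 0:
            ops.append(1)
            j -= 1
            continue
        if j == 0:
            ops.append(2)
            i -= 1
            continue
        if state == "H":
            if H[i][j] == H[i - 1][j - 1] + _pairs_score(a[i - 1], b[j - 1]):
                ops.append(0 if a[i - 1] == b[j - 1] and a[i - 1] != "N" else 3)
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append(1)
            state = "H" if E[i][j] == H[i][j - 1] - 2 else "E"
            j -= 1
        else:
            ops.append(2)
            state = "H" if F[i][j] == H[i - 1][j] - 2 else "F"
            i -= 1
    ops.reverse()
    lead = 0
    while lead < len(ops) and ops[lead] in (1, 2):
        lead += 1
    trail = 0
    while trail < len(ops) - lead and ops[len(ops) - 1 - trail] in (1, 2):
        trail += 1
    core = ops[lead:len(ops) - trail]
    matches = sum(1 for o in core if o == 0)
    return matches / len(core) if core else 0.0


def best_tir_pair(seq: str, tir_min=13, tir_max=32, frac=0.15, window=60):
    """Exhaustive TIR-pair enumeration under the package objective:
    maximize matches-mismatches, then fewest mismatches, then longest,
    then leftmost (then the pair closest to the 3' end)."""
    n = len(seq)
    w = min(window, n // 2)
    best = None
    for length in range(tir_min, min(tir_max, w) + 1):
        budget = int(frac * length)
        for i in range(0, w - length + 1):
            left = seq[i:i + length]
            for q in range(0, w - length + 1):
                right_end = n - q
                if i + length > right_end - length:
                    continue
                right = seq[right_end - length:right_end]
                rc = revcomp(right)
                mm = sum(1 for x, y in zip(left, rc)
                         if x != y or x == "N" or y == "N")
                if mm > budget:
                    continue
                key = (-(length - 2 * mm), mm, -length, i, -right_end)
                if best is None or key < best[0]:
                    best = (key, (i, length, mm, right_end))
    return None if best is None else best[1]


def triad_positions(aa: str, r1="D", r2="D", spacing=34, r3="D"):
    """First (j,k) pair with exact spacing plus the leftmost upstream r1."""
    for j, c in enumerate(aa):
        if c == r2 and j + spacing < len(aa) and aa[j + spacing] == r3:
            for i in range(j):
                if aa[i] == r1:
                    return (i, j, j + spacing)
    return None


def count_triads(aa: str, spacing=34):
    """All (j,k) aspartate pairs at the exact spacing with an upstream D."""
    out = []
    for j, k in itertools.combinations(range(len(aa)), 2):
        if k - j == spacing and aa[j] == "D" and aa[k] == "D":
            if any(aa[i] == "D" for i in range(j)):
                out.append((j, k))
    return out


def best_motif_window(aa: str, motif: str):
    """(start, substitutions) of the minimum-Hamming window, leftmost ties."""
    L = len(motif)
    best = None
    for i in range(len(aa) - L + 1):
        d = sum(1 for x, y in zip(aa[i:i + L], motif) if x != y)
        if best is None or d < best[1]:
            best = (i, d)
    return best
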
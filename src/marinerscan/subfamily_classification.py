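"""Subfamily assignment of Mariner-like elements.

Two complementary rules are computed for every element and their agreement
recorded:

* identity rule -- an element inherits the subfamily of its best-matching
  labeled reference when whole-sequence identity >= 0.80, with a TIR
  fallback (TIR identity >= 0.80 to a subfamily's TIR consensus) for
  decayed copies;
* clade rule -- membership of the smallest label-homogeneous clade
  containing a labeled reference, in a neighbor-joining tree built from a
  center-star multiple alignment of whole nucleotide sequences, rooted on
  a Tc1 outgroup, with column-resampling bootstrap support.

NJ on K2P distances stands in for a full maximum-likelihood search: the
tree is consumed only for clade grouping, which NJ preserves, and NJ is
exact on additive distance matrices (a property the tests exploit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from skbio import TreeNode

from ._align import global_align, global_identity
from .io_formats import MarinerScanError, PanelRecord

DISTANCE_MODELS = ("p-distance", "JC69", "K2P")
_DMAX = 5.0  # saturation cap for undefined model distances


@dataclass
class ClassifyParams:
    similarity_threshold: float = 0.80
    n_bootstrap: int = 1000
    distance_model: str = "K2P"
    outgroup_id: str | None = None
    use_tir_fallback: bool = True

    def __post_init__(self):
        if not (0 < self.similarity_threshold < 1):
            raise MarinerScanError("similarity_threshold must be in (0,1)")
        if self.n_bootstrap < 0:
            raise MarinerScanError("n_bootstrap must be >= 0")
        if self.distance_model not in DISTANCE_MODELS:
            raise MarinerScanError(f"unknown distance model {self.distance_model!r}")


@dataclass
class SubfamilyAssignment:
    element_id: str
    subfamily: str | None  # None = unassigned
    method: str  # identity_rule | clade_rule | both | unassigned
    support: float | None = None  # bootstrap fraction of the defining clade
    identity_label: str | None = None
    clade_label: str | None = None
    conflict: bool = False


def pairwise_identity(a: str, b: str) -> float:
    """Whole-sequence identity: matches / aligned columns of the global DP
    alignment, with terminal gap runs excluded from the count (end-gap-free
    identity). The path itself is the penalized global optimum, so unrelated
    sequences cannot collapse onto a short high-identity overlap."""
    if not a or not b:
        raise MarinerScanError("empty sequence")
    return global_identity(a, b)


def identity_cluster(elements: list[tuple[str, str]],
                     references: list[PanelRecord],
                     params: ClassifyParams | None = None,
                     element_tirs: dict[str, str] | None = None,
                     tir_consensi: dict[str, str] | None = None,
                     ) -> dict[str, SubfamilyAssignment]:
    """Assign subfamilies by the >= 80% similarity rule.

    Full-sequence identity to the best-matching labeled reference decides
    first; elements below threshold fall back to TIR identity against each
    subfamily's TIR consensus (the "complete sequence or TIRs" disjunction);
    anything still below threshold is left unassigned for the clade rule.
    """
    params = params or ClassifyParams()
    refs = [r for r in references if r.subfamily]
    if not refs:
        raise MarinerScanError("no subfamily-labeled references")
    out = {}
    for eid, seq in elements:
        best_label, best_ident = None, -1.0
        for ref in refs:
            ident = pairwise_identity(seq, ref.sequence)
            if ident > best_ident:
                best_label, best_ident = ref.subfamily, ident
        if best_ident >= params.similarity_threshold:
            out[eid] = SubfamilyAssignment(
                element_id=eid, subfamily=best_label, method="identity_rule",
                identity_label=best_label,
            )
            continue
        label = None
        if params.use_tir_fallback and element_tirs and tir_consensi:
            tir = element_tirs.get(eid)
            if tir:
                scored = [
                    (pairwise_identity(tir, cons), sub)
                    for sub, cons in sorted(tir_consensi.items())
                ]
                ident, sub = max(scored)
                if ident >= params.similarity_threshold:
                    label = sub
        out[eid] = SubfamilyAssignment(
            element_id=eid, subfamily=label,
            method="identity_rule" if label else "unassigned",
            identity_label=label,
        )
    return out


# ---------------------------------------------------------------------------
# Center-star multiple alignment


def center_star_msa(seqs: list[str]) -> list[str]:
    """Multiple alignment by aligning everything to the center sequence.

    The center minimizes summed pairwise distance (edit distance, computed
    with edlib for speed); each sequence is globally aligned to it with the
    package aligner (terminal gaps penalized, so even distant sequences are
    forced onto full-length paths) and the alignments are merged column-wise
    ("once a gap, always a gap").
    """
    n = len(seqs)
    if n < 2:
        raise MarinerScanError("need at least two sequences")
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], task="distance")["editDistance"]
            total[i] += d
            total[j] += d
    center = int(total.argmin())
    c = seqs[center]
    lc = len(c)
    rows = []  # per seq: (ins, cells); ins[k] = inserted string before center col k
    for idx, s in enumerate(seqs):
        if idx == center:
            rows.append(None)
            continue
        aln = global_align(s, c)
        ins = [""] * (lc + 1)
        cells = ["-"] * lc
        ai, bi = aln.a_start, aln.b_start
        if bi == 0:
            ins[0] = s[:ai]
        for op in aln.ops.tolist():
            if op == 0:  # diagonal
                cells[bi] = s[ai]
                ai += 1
                bi += 1
            elif op == 2:  # consumes s only -> insertion before center col bi
                ins[bi] += s[ai]
                ai += 1
            else:  # consumes center only
                bi += 1
        if bi == lc:
            ins[lc] += s[ai:]
        rows.append((ins, cells))
    max_ins = [0] * (lc + 1)
    for row in rows:
        if row is None:
            continue
        for k, chunk in enumerate(row[0]):
            max_ins[k] = max(max_ins[k], len(chunk))
    out = []
    for idx in range(n):
        parts = []
        if idx == center:
            for k in range(lc):
                parts.append("-" * max_ins[k])
                parts.append(c[k])
            parts.append("-" * max_ins[lc])
        else:
            ins, cells = rows[idx]
            for k in range(lc):
                parts.append(ins[k].ljust(max_ins[k], "-"))
                parts.append(cells[k])
            parts.append(ins[lc].ljust(max_ins[lc], "-"))
        out.append("".join(parts))
    return out


# ---------------------------------------------------------------------------
# Distances

_MSA_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _MSA_LUT[ord(_c)] = _i


def encode_msa(msa: list[str]) -> np.ndarray:
    """(n, L) int8 matrix; gaps and ambiguous bases code 4 (ignored in pairs)."""
    return np.stack([
        _MSA_LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)] for row in msa
    ])


def _pair_counts(enc: np.ndarray, weights: np.ndarray | None = None):
    """Weighted per-pair counts of valid columns, matches and transitions."""
    w = np.ones(enc.shape[1]) if weights is None else weights.astype(float)
    A = [(enc == s).astype(np.float64) for s in range(4)]
    V = (enc < 4).astype(np.float64)
    valid = (V * w) @ V.T
    match = sum((a * w) @ a.T for a in A)
    # transitions: A<->G (codes 0,2) and C<->T (codes 1,3)
    ts = (A[0] * w) @ A[2].T + (A[2] * w) @ A[0].T \
        + (A[1] * w) @ A[3].T + (A[3] * w) @ A[1].T
    return valid, match, ts


def distance_matrix(enc: np.ndarray, model: str = "K2P",
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Pairwise distances from an encoded MSA under p, JC69 or K2P models.

    Saturated or undefined distances are capped at a large constant rather
    than infinity so NJ stays finite (affects only the deep outgroup edge).
    """
    if model not in DISTANCE_MODELS:
        raise MarinerScanError(f"unknown distance model {model!r}")
    valid, match, ts = _pair_counts(enc, weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        vsafe = np.where(valid > 0, valid, 1.0)
        p = 1.0 - match / vsafe
        if model == "p-distance":
            d = p
        elif model == "JC69":
            arg = 1.0 - 4.0 * p / 3.0
            d = np.where(arg > 1e-9,
                         -0.75 * np.log(np.clip(arg, 1e-9, None)),
                         _DMAX + p)
        else:  # K2P
            P = ts / vsafe
            Q = p - P
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            ok = (a1 > 1e-9) & (a2 > 1e-9)
            d = np.where(
                ok,
                -0.5 * np.log(np.clip(a1, 1e-9, None))
                - 0.25 * np.log(np.clip(a2, 1e-9, None)),
                _DMAX + p,  # saturated: stay monotone in observed divergence
            )
        d = np.where(valid > 0, d, _DMAX + 1.0)
    d = np.minimum(d, _DMAX + 2.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(D: np.ndarray, names: list[str]) -> TreeNode:
    """Canonical NJ; exact on additive matrices. Returns an unrooted tree
    (trifurcating root) of scikit-bio TreeNodes with branch lengths."""
    n = len(names)
    if D.shape != (n, n):
        raise MarinerScanError("distance matrix shape mismatch")
    if n < 2:
        raise MarinerScanError("need at least two taxa")
    nodes = [TreeNode(name=nm) for nm in names]
    Dm = D.astype(float).copy()
    if n == 2:
        for node in nodes:
            node.length = max(0.0, Dm[0, 1] / 2.0)
        return TreeNode(children=nodes)
    while len(nodes) > 3:
        m = len(nodes)
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(Q.argmin()), m)  # row-major argmin: deterministic ties
        if i > j:
            i, j = j, i
        dij = Dm[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (Dm[i, :] + Dm[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        Dm = np.vstack([
            np.hstack([Dm[np.ix_(keep, keep)], dnew[keep, None]]),
            np.hstack([dnew[keep], [0.0]]),
        ])
        nodes = [nodes[k] for k in keep] + [new]
    d01, d02, d12 = Dm[0, 1], Dm[0, 2], Dm[1, 2]
    lens = [(d01 + d02 - d12) / 2.0, (d01 + d12 - d02) / 2.0, (d02 + d12 - d01) / 2.0]
    for node, ln in zip(nodes, lens):
        node.length = max(0.0, ln)
    return TreeNode(children=nodes)


def root_on_outgroup(tree: TreeNode, outgroup_id: str) -> TreeNode:
    """Root an unrooted NJ tree on the edge leading to the outgroup leaf,
    splitting that branch at its midpoint."""
    t = tree.copy()
    try:
        leaf = t.find(outgroup_id)
    except Exception as exc:  # skbio MissingNodeError
        raise MarinerScanError(f"outgroup {outgroup_id!r} not in tree") from exc
    if not leaf.is_tip():
        raise MarinerScanError("outgroup id names an internal node")
    return t.root_at(leaf, above=True, branch_attrs=[])


def clade_sets(tree: TreeNode) -> dict[int, frozenset]:
    """Leaf-name set under every internal, non-root node (id(node) keyed)."""
    out = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        out[id(node)] = frozenset(t.name for t in node.tips())
    return out


def _normalized_bipartitions(tree: TreeNode, ref_taxon: str) -> set[frozenset]:
    taxa = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref_taxon in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


@dataclass
class DistanceTreeResult:
    tree: TreeNode  # rooted on the outgroup edge; internal names = support %
    supports: dict[frozenset, float]
    msa: list[str] = field(repr=False, default_factory=list)
    ids: list[str] = field(default_factory=list)


def build_distance_tree(entries: list[tuple[str, str]],
                        params: ClassifyParams | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> DistanceTreeResult:
    """Center-star MSA + NJ + outgroup rooting + column-resampling bootstrap.

    ``entries`` are (id, sequence) pairs including labeled references and
    exactly one record whose id equals ``params.outgroup_id``.
    """
    params = params or ClassifyParams()
    rng = rng or np.random.default_rng(0)
    if len(entries) < 4:
        raise MarinerScanError("need at least four sequences for a tree")
    ids = [e[0] for e in entries]
    if len(set(ids)) != len(ids):
        raise MarinerScanError("duplicate sequence ids")
    if params.outgroup_id is None or params.outgroup_id not in ids:
        raise MarinerScanError("outgroup_id must name one of the sequences")
    msa = center_star_msa([e[1] for e in entries])
    enc = encode_msa(msa)
    D = distance_matrix(enc, params.distance_model)
    main = neighbor_joining(D, ids)
    rooted = root_on_outgroup(main, params.outgroup_id)
    main_parts = _normalized_bipartitions(main, params.outgroup_id)
    counts = {part: 0 for part in main_parts}
    L = enc.shape[1]
    for _ in range(params.n_bootstrap):
        idx = rng.integers(0, L, L)
        w = np.bincount(idx, minlength=L).astype(float)
        Db = distance_matrix(enc, params.distance_model, weights=w)
        rep = neighbor_joining(Db, ids)
        rep_parts = _normalized_bipartitions(rep, params.outgroup_id)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    nb = max(1, params.n_bootstrap)
    supports = {part: c / nb for part, c in counts.items()}
    taxa = frozenset(ids)
    if params.n_bootstrap > 0:
        for node in rooted.postorder(include_self=False):
            if node.is_tip():
                continue
            side = frozenset(t.name for t in node.tips())
            if params.outgroup_id in side:
                side = taxa - side
            if side in supports:
                node.name = str(int(round(100 * supports[side])))
    return DistanceTreeResult(tree=rooted, supports=supports, msa=msa, ids=ids)


def clade_assign(result: DistanceTreeResult,
                 reference_labels: dict[str, str],
                 assignments: dict[str, SubfamilyAssignment],
                 ) -> dict[str, SubfamilyAssignment]:
    """Final labels: smallest reference-containing clade, homogeneity required.

    Every element gets a clade label (agreement with the identity rule is
    recorded); elements the identity rule left unassigned take the clade
    label, and a clade mixing reference labels yields unassigned + conflict.
    """
    tree = result.tree
    for eid, assignment in assignments.items():
        try:
            leaf = tree.find(eid)
        except Exception:
            continue
        clade_label = None
        conflict = False
        support = None
        node = leaf.parent
        taxa = frozenset(t.name for t in tree.tips())
        while node is not None:
            leaves = frozenset(t.name for t in node.tips())
            ref_labels = {
                reference_labels[x] for x in leaves if x in reference_labels
            }
            if ref_labels:
                if len(ref_labels) == 1:
                    clade_label = next(iter(ref_labels))
                    side = leaves
                    og = [x for x in taxa if x not in leaves]
                    if any(x in result.supports for x in (side, frozenset(og))):
                        support = result.supports.get(
                            side, result.supports.get(frozenset(og))
                        )
                else:
                    conflict = True
                break
            node = node.parent
        assignment.clade_label = clade_label
        assignment.conflict = conflict
        if assignment.identity_label is not None:
            if clade_label == assignment.identity_label:
                assignment.method = "both"
                assignment.support = support
        elif clade_label is not None:
            assignment.subfamily = clade_label
            assignment.method = "clade_rule"
            assignment.support = support
        else:
            assignment.method = "unassigned"
    return assignments
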
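"""Synthetic genomes with planted Mariner-like elements of known truth.

The generator builds, per subfamily, a consensus element with the full MLE
anatomy -- TIR pair, 5' UTR, an ATG-initiated transposase ORF (310--345 aa)
carrying HTH, WVPHEL, DD34D, YSPDL and NLS motifs, 3' UTR, reverse-
complement TIR -- and plants mutated copies of it in random-background
contigs (GC about 34%, matching the assemblies the method targets), with
TA target-site duplications, optional truncation (usually flush with a
contig end, the dominant cause of truncation in short-read assemblies) and
an explicit mutation ledger. The default configuration reproduces the
published per-species count structure of the seven Rhus-gall-aphid
genomes: 121 elements, four subfamilies, five potentially active copies,
two intact-ORF truncated copies, 106 complete / 15 truncated.

Constructional choices that make ground truth exact (documented in the
methods note): consensus proteins draw their background from an amino-acid
alphabet without D/E/K/R/W so the planted triad and NLS are unique;
substitutions on intact copies are synonymous-only; decayed copies get
stop-free substitutions plus explicitly planted TAA stops; TIRs and a
short run of anti-extension guard bases just inside each TIR are never
mutated, so the planted TIR length is exactly recoverable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._align import revcomp
from .io_formats import ContigSet, MarinerScanError, PanelRecord, ReferencePanel

SUBFAMILIES = ("Mauritiana", "Drosophila", "Vertumana", "Irritans")

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = tuple(standard_dna_table.stop_codons)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

# background amino-acid alphabet: no D/E (triad control), no K/R (NLS
# control), no W (WVPHEL control)
_BACKGROUND_AA = "ACFGHILMNPQSTVY"
_HYDROPHOBIC_AA = "AVLIMF"

# per-subfamily anatomy: (tir_len, aa_len, utr5_len, element_len)
_SUBFAMILY_ANATOMY = {
    "Mauritiana": (28, 338, 45, 1380),
    "Drosophila": (30, 335, 50, 1340),
    "Vertumana": (27, 330, 40, 1270),
    "Irritans": (22, 318, 38, 1210),
}

# screening families: triad signature spacing/terminal residue
_OTHER_FAMILIES = {
    "Tc1": (34, "E", 30, 340, 46, 1360),
    "maT": (37, "D", 26, 330, 42, 1300),
    "GT": (39, "D", 24, 325, 40, 1280),
    "VS": (41, "D", 25, 320, 40, 1260),
}

_GC = 0.34
_BASE_P = np.array([(1 - _GC) / 2, _GC / 2, _GC / 2, (1 - _GC) / 2])


@dataclass(frozen=True)
class Consensus:
    """One subfamily (or screening-family) consensus element."""

    name: str
    element: str
    tir: str
    utr5_len: int
    orf_span: tuple[int, int]  # includes the terminator codon
    protein: str  # without the stop
    triad: tuple[int, int, int]
    motif_positions: dict[str, int]
    protected: frozenset  # element positions never mutated

    @property
    def tir_len(self) -> int:
        return len(self.tir)


@dataclass
class CopyPlan:
    """Plan for one planted copy."""

    subfamily: str
    completeness: str = "complete"  # complete|truncated_5p|truncated_3p|truncated_both
    activity: str = "intact"  # intact | decayed
    n_premature_stops: int = 0
    triad_mutation: bool = False
    frameshift: bool = False
    nls_ablated: bool = False
    tsd: str = "both"  # both | 3p_only
    at_contig_end: bool = False
    divergence: float = 0.08
    strand: str | None = None  # None: random for mid-contig copies

    def truth_activity(self) -> str:
        if self.activity == "intact":
            return (
                "potentially_active" if self.completeness == "complete"
                else "intact_orf_truncated"
            )
        return "inactive"


@dataclass
class GenomePlan:
    species: str
    prefix: str
    copies: list[CopyPlan]
    n_large_contigs: int = 2
    large_contig_len: int = 650_000
    n_small_contigs: int = 150
    small_contig_len_range: tuple[int, int] = (120, 900)
    end_contig_len_range: tuple[int, int] = (9_000, 15_000)


@dataclass
class PlantConfig:
    genomes: list[GenomePlan]
    seed: int = 0
    n_refs_per_subfamily: int = 2
    ref_divergence: float = 0.05

    def __post_init__(self):
        for g in self.genomes:
            for c in g.copies:
                if not (0 <= c.divergence <= 1):
                    raise MarinerScanError("divergence must be in [0,1]")
                if c.subfamily not in _SUBFAMILY_ANATOMY:
                    raise MarinerScanError(f"unknown subfamily {c.subfamily!r}")


@dataclass(frozen=True)
class TruthRecord:
    element_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    subfamily: str
    completeness: str
    activity: str
    tir_len: int
    tsd_left: bool
    tsd_right: bool
    at_contig_end: bool
    mutations: tuple = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TruthTable:
    records: list[TruthRecord]

    def __post_init__(self):
        by_contig: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for r in self.records:
            spans = by_contig.setdefault((r.genome_id, r.contig_id), [])
            for s, e in spans:
                if max(s, r.start) < min(e, r.end):
                    raise MarinerScanError("planted spans overlap")
            spans.append((r.start, r.end))

    def __len__(self):
        return len(self.records)

    def for_genome(self, genome_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.genome_id == genome_id]

    def write_tsv(self, path) -> None:
        cols = ["element_id", "genome_id", "contig_id", "start", "end", "strand",
                "subfamily", "completeness", "activity", "tir_len",
                "tsd_left", "tsd_right", "at_contig_end"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                d = dict(zip(header, line.rstrip("\n").split("\t")))
                records.append(TruthRecord(
                    element_id=d["element_id"], genome_id=d["genome_id"],
                    contig_id=d["contig_id"], start=int(d["start"]),
                    end=int(d["end"]), strand=d["strand"],
                    subfamily=d["subfamily"], completeness=d["completeness"],
                    activity=d["activity"], tir_len=int(d["tir_len"]),
                    tsd_left=d["tsd_left"] == "True",
                    tsd_right=d["tsd_right"] == "True",
                    at_contig_end=d["at_contig_end"] == "True",
                ))
        return cls(records)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=_BASE_P)])


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in protein
    )


def _design_protein(rng: np.random.Generator, aa_len: int,
                    spacing: int, last_residue: str) -> tuple[str, tuple, dict]:
    """Protein with planted HTH, WVPHEL, triad, YSPDL and NLS on a
    controlled background (exactly one triad, one basic window)."""
    aa = ["M"] + [
        _BACKGROUND_AA[rng.integers(len(_BACKGROUND_AA))] for _ in range(aa_len - 1)
    ]

    def put(pos: int, s: str):
        aa[pos:pos + len(s)] = list(s)

    # HTH: two helical-wheel windows separated by a 3-aa G turn
    for h in (18, 31):
        for off in (0, 3, 4, 7):
            aa[h + off] = _HYDROPHOBIC_AA[rng.integers(len(_HYDROPHOBIC_AA))]
    put(28, "GQS")
    put(110, "WVPHEL")
    d1, d2 = 150, 230
    d3 = d2 + spacing
    aa[d1] = "D"
    aa[d2] = "D"
    aa[d3] = last_residue
    yspdl_pos = d3 + 24
    put(yspdl_pos, "YSPDL")
    nls = "KRPKSKRARKIPKR"
    nls_pos = min(yspdl_pos + 12, aa_len - len(nls) - 1)
    if nls_pos < yspdl_pos + 5:
        raise MarinerScanError("protein too short for the planted anatomy")
    put(nls_pos, nls)
    motifs = {"wvphel": 110, "yspdl": yspdl_pos, "nls": nls_pos, "hth1": 18, "hth2": 31}
    return "".join(aa), (d1, d2, d3), motifs


def make_subfamily_consensus(name: str, rng: np.random.Generator,
                             tir_len: int, aa_len: int, utr5_len: int,
                             element_len: int, spacing: int = 34,
                             last_residue: str = "D") -> Consensus:
    """Build one consensus element (see module docstring for the anatomy)."""
    protein, triad, motifs = _design_protein(rng, aa_len, spacing, last_residue)
    orf_nt = _reverse_translate(protein, rng) + "TAA"
    # a TIR containing the TA dinucleotide would let an inward-shifted
    # sub-pair of itself mimic a TA-flanked boundary; draw until TA-free
    tir = _random_dna(rng, tir_len)
    while "TA" in tir:
        tir = _random_dna(rng, tir_len)
    utr5 = list(_random_dna(rng, utr5_len))
    # in-frame stop at the end of the 5' UTR: upstream ATGs cannot extend
    # the planted ORF
    utr5[-3:] = list("TAA")
    utr3_len = element_len - 2 * tir_len - utr5_len - len(orf_nt)
    if utr3_len < 10:
        raise MarinerScanError("element_len too small for the anatomy")
    utr3 = list(_random_dna(rng, utr3_len))
    orf_start = tir_len + utr5_len
    # no in-frame ATG upstream of the real start codon: the first ATG of the
    # coding frame must be the transposase start
    frame = orf_start % 3
    prefix = list(tir) + utr5
    changed = True
    while changed:
        changed = False
        for p in range(frame, orf_start - 2, 3):
            if "".join(prefix[p:p + 3]) == "ATG":
                if p + 1 >= tir_len:  # middle base in the UTR: flip it
                    prefix[p + 1] = "C"
                else:  # inside the TIR: redraw the TIR
                    tir = _random_dna(rng, tir_len)
                    while "TA" in tir:
                        tir = _random_dna(rng, tir_len)
                    prefix[:tir_len] = list(tir)
                changed = True
    tir = "".join(prefix[:tir_len])
    utr5 = prefix[tir_len:]
    # anti-extension guards: the first bases of the 5' UTR must not base-pair
    # with the last bases of the 3' UTR at any offset the 32 bp cap allows,
    # so every inward extension of the true TIR pair costs a mismatch
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n_guard = min(10, utr5_len, utr3_len)
    for k in range(n_guard):
        if utr3[-1 - k] == comp[utr5[k]]:
            allowed = [b for b in "ACGT" if b != comp[utr5[k]]]
            utr3[-1 - k] = allowed[rng.integers(3)]
    element = tir + "".join(utr5) + orf_nt + "".join(utr3) + revcomp(tir)
    orf_end = orf_start + len(orf_nt)
    protected = set(range(tir_len)) | set(range(len(element) - tir_len, len(element)))
    protected |= set(range(tir_len, tir_len + n_guard))  # 5' guards
    protected |= set(
        range(len(element) - tir_len - n_guard, len(element) - tir_len)
    )  # 3' guards
    protected |= set(range(orf_start - 3, orf_start + 3))  # UTR stop + start codon
    protected |= set(range(orf_end - 3, orf_end))  # terminator
    return Consensus(
        name=name, element=element, tir=tir, utr5_len=utr5_len,
        orf_span=(orf_start, orf_end), protein=protein, triad=triad,
        motif_positions=motifs, protected=frozenset(protected),
    )


def build_consensi(config: PlantConfig) -> dict[str, Consensus]:
    """The four Mariner subfamily consensi (deterministic in config.seed)."""
    out = {}
    for i, sub in enumerate(SUBFAMILIES):
        tir_len, aa_len, utr5_len, element_len = _SUBFAMILY_ANATOMY[sub]
        rng = np.random.default_rng([config.seed, 101, i])
        out[sub] = make_subfamily_consensus(
            sub, rng, tir_len, aa_len, utr5_len, element_len
        )
    return out


def build_other_family_consensi(config: PlantConfig) -> dict[str, Consensus]:
    """Consensi of the non-Mariner DD-families used for the absence screen."""
    out = {}
    for i, (fam, (spacing, last, tir_len, aa_len, utr5_len, element_len)
            ) in enumerate(sorted(_OTHER_FAMILIES.items())):
        rng = np.random.default_rng([config.seed, 202, i])
        out[fam] = make_subfamily_consensus(
            fam, rng, tir_len, aa_len, utr5_len, element_len,
            spacing=spacing, last_residue=last,
        )
    return out


def _mutate_copy(cons: Consensus, plan: CopyPlan, rng: np.random.Generator
                 ) -> tuple[str, tuple]:
    """Apply the plan's mutations to a consensus copy; returns (seq, ledger)."""
    seq = list(cons.element)
    orf_start, orf_end = cons.orf_span
    ledger = []
    candidates = [i for i in range(len(seq)) if i not in cons.protected]
    n_sub = int(round(plan.divergence * len(seq)))
    n_sub = min(n_sub, len(candidates))
    chosen = sorted(rng.choice(len(candidates), size=n_sub, replace=False).tolist())
    for idx in chosen:
        p = candidates[idx]
        if orf_start <= p < orf_end - 3:
            ci = orf_start + 3 * ((p - orf_start) // 3)
            codon = seq[ci:ci + 3]
            off = p - ci
            alts = []
            for b in "ACGT":
                if b == seq[p]:
                    continue
                cand = codon.copy()
                cand[off] = b
                cc = "".join(cand)
                if cc in STOP_CODONS:
                    continue
                if plan.activity == "intact" and CODON_TO_AA.get(cc) != \
                        CODON_TO_AA.get("".join(codon)):
                    continue
                alts.append(b)
            if not alts:
                continue
            b = alts[rng.integers(len(alts))]
        else:
            others = [x for x in "ACGT" if x != seq[p]]
            b = others[rng.integers(3)]
        ledger.append((p, seq[p], b))
        seq[p] = b
    aa_len = len(cons.protein)
    if plan.n_premature_stops:
        codon_idx = sorted(
            (15 + rng.choice(aa_len - 40, size=plan.n_premature_stops,
                             replace=False)).tolist()
        )
        for ci in codon_idx:
            p = orf_start + 3 * ci
            old = "".join(seq[p:p + 3])
            seq[p:p + 3] = list("TAA")
            ledger.append((p, old, "TAA"))
    if plan.triad_mutation:
        p = orf_start + 3 * cons.triad[2]
        old = "".join(seq[p:p + 3])
        seq[p:p + 3] = list("AAC")  # D -> N in the third catalytic position
        ledger.append((p, old, "AAC"))
    if plan.nls_ablated:
        p0 = cons.motif_positions["nls"]
        for ci in range(p0, p0 + 14):
            p = orf_start + 3 * ci
            old = "".join(seq[p:p + 3])
            seq[p:p + 3] = list("TCA")  # serine; removes the basic window
            ledger.append((p, old, "TCA"))
    if plan.frameshift:
        p = orf_start + 3 * (aa_len // 2)
        ledger.append((p, seq[p], "-"))
        del seq[p]
    out = "".join(seq)
    if plan.completeness == "truncated_5p":
        cut = cons.tir_len + int(rng.integers(5, 21))
        ledger.append((0, f"trunc5p:{cut}", ""))
        out = out[cut:]
    elif plan.completeness == "truncated_3p":
        cut = cons.tir_len + int(rng.integers(5, 21))
        ledger.append((len(out) - cut, f"trunc3p:{cut}", ""))
        out = out[:-cut]
    elif plan.completeness == "truncated_both":
        cut5 = cons.tir_len + int(rng.integers(5, 21))
        cut3 = cons.tir_len + int(rng.integers(5, 21))
        ledger.append((0, f"trunc_both:{cut5},{cut3}", ""))
        out = out[cut5:len(out) - cut3]
    return out, tuple(ledger)


def _insert_flanks(elem: str, plan: CopyPlan) -> tuple[str, int, bool, bool]:
    """Wrap a copy with TSD and anti-extension guard flanks.

    Returns (insert, element offset within insert, tsd_left, tsd_right) in
    element orientation before any strand flip.
    """
    comp = plan.completeness
    left_tsd = comp in ("complete",) and plan.tsd == "both"
    right_tsd = comp in ("complete", "truncated_5p")
    if comp == "truncated_3p":
        left_tsd = True
    left = "CC" + ("TA" if left_tsd else "CC")
    right = ("TA" if right_tsd else "CC") + "CC"
    return left + elem + right, len(left), left_tsd, right_tsd


def plant_copies(config: PlantConfig, seed: int | None = None
                 ) -> tuple[list[ContigSet], TruthTable]:
    """Generate the genomes and the ground-truth ledger.

    Deterministic in (config, seed); ``seed`` defaults to ``config.seed``.
    """
    seed = config.seed if seed is None else seed
    consensi = build_consensi(config)
    genomes = []
    truth: list[TruthRecord] = []
    for gi, gplan in enumerate(config.genomes):
        rng = np.random.default_rng([seed, 1, gi])
        contigs: dict[str, str] = {}
        prepared = []
        for ci, plan in enumerate(gplan.copies):
            cons = consensi[plan.subfamily]
            elem, ledger = _mutate_copy(cons, plan, rng)
            strand = plan.strand
            if strand is None:
                strand = "-" if (not plan.at_contig_end and rng.random() < 0.4) else "+"
            eid = f"{gplan.prefix}mar{ci + 1}"
            prepared.append((plan, cons, elem, ledger, strand, eid))
        at_end = [p for p in prepared if p[0].at_contig_end]
        mid = [p for p in prepared if not p[0].at_contig_end]
        # dedicated contigs with the truncated element flush at one edge
        for k, (plan, cons, elem, ledger, strand, eid) in enumerate(at_end):
            bg_len = int(rng.integers(*gplan.end_contig_len_range))
            bg = _random_dna(rng, bg_len)
            cid = f"{gplan.prefix}_endctg{k + 1}"
            flush_5p = plan.completeness in ("truncated_5p", "truncated_both")
            # element 5' flush -> element at contig start on '+'
            if flush_5p:
                right_tsd = plan.completeness == "truncated_5p"
                tail = ("TA" if right_tsd else "CC") + "CC"
                contigs[cid] = elem + tail + bg
                span = (0, len(elem))
                tsd = (False, right_tsd)
            else:  # 3' end missing, element flush at contig end
                left_tsd = plan.completeness == "truncated_3p"
                head = "CC" + ("TA" if left_tsd else "CC")
                contigs[cid] = bg + head + elem
                span = (len(bg) + len(head), len(bg) + len(head) + len(elem))
                tsd = (left_tsd, False)
            truth.append(TruthRecord(
                element_id=eid, genome_id=gplan.species, contig_id=cid,
                start=span[0], end=span[1], strand="+",
                subfamily=plan.subfamily, completeness=plan.completeness,
                activity=plan.truth_activity(), tir_len=cons.tir_len,
                tsd_left=tsd[0], tsd_right=tsd[1], at_contig_end=True,
                mutations=ledger,
            ))
        # large contigs host the remaining copies
        per_contig: list[list] = [[] for _ in range(gplan.n_large_contigs)]
        for k, item in enumerate(mid):
            per_contig[k % gplan.n_large_contigs].append(item)
        for li in range(gplan.n_large_contigs):
            cid = f"{gplan.prefix}_ctg{li + 1}"
            bg = _random_dna(rng, gplan.large_contig_len)
            items = per_contig[li]
            grid = np.arange(3000, gplan.large_contig_len - 3000, 4000)
            positions = np.sort(rng.choice(grid, size=len(items), replace=False))
            pieces = []
            cursor = 0
            offset = 0
            for (plan, cons, elem, ledger, strand, eid), pos in zip(items, positions):
                insert, eoff, tsd_l, tsd_r = _insert_flanks(elem, plan)
                if strand == "-":
                    insert = revcomp(insert)
                    eoff = len(insert) - eoff - len(elem)
                    tsd_l, tsd_r = tsd_l, tsd_r  # flags stay element-oriented
                pieces.append(bg[cursor:pos])
                offset += pos - cursor
                start = offset + eoff
                pieces.append(insert)
                offset += len(insert)
                cursor = pos
                truth.append(TruthRecord(
                    element_id=eid, genome_id=gplan.species, contig_id=cid,
                    start=start, end=start + len(elem), strand=strand,
                    subfamily=plan.subfamily, completeness=plan.completeness,
                    activity=plan.truth_activity(), tir_len=cons.tir_len,
                    tsd_left=tsd_l, tsd_right=tsd_r, at_contig_end=False,
                    mutations=ledger,
                ))
            pieces.append(bg[cursor:])
            contigs[cid] = "".join(pieces)
        for si in range(gplan.n_small_contigs):
            cid = f"{gplan.prefix}_sm{si + 1}"
            contigs[cid] = _random_dna(
                rng, int(rng.integers(*gplan.small_contig_len_range))
            )
        genomes.append(ContigSet(genome_id=gplan.species, contigs=contigs))
    return genomes, TruthTable(truth)


def build_panel(config: PlantConfig) -> ReferencePanel:
    """Query + labeled-reference + outgroup panel matching the consensi."""
    consensi = build_consensi(config)
    records = []
    for sub, cons in consensi.items():
        records.append(PanelRecord(
            seq_id=f"{sub}_query", sequence=cons.element, family="Mariner",
            subfamily=sub, role="query",
        ))
        for r in range(config.n_refs_per_subfamily):
            rng = np.random.default_rng([config.seed, 303, list(consensi).index(sub), r])
            plan = CopyPlan(subfamily=sub, activity="decayed",
                            divergence=config.ref_divergence)
            seq, _ = _mutate_copy(cons, plan, rng)
            records.append(PanelRecord(
                seq_id=f"{sub}_ref{r + 1}", sequence=seq, family="Mariner",
                subfamily=sub, role="phylo_reference",
            ))
    tc1 = build_other_family_consensi(config)["Tc1"]
    records.append(PanelRecord(
        seq_id="Tc1_outgroup", sequence=tc1.element, family="Tc1",
        subfamily=None, role="outgroup",
    ))
    return ReferencePanel(records)


def build_screen_panel(config: PlantConfig) -> list[PanelRecord]:
    """Consensus queries of the Tc1/maT/GT/VS families for the absence screen."""
    return [
        PanelRecord(seq_id=f"{fam}_consensus", sequence=cons.element,
                    family=fam, subfamily=None, role="query")
        for fam, cons in sorted(build_other_family_consensi(config).items())
    ]


# ---------------------------------------------------------------------------
# Default configuration: the published per-species count structure


def _species_plans(subfam_counts: dict[str, int], truncated: list[CopyPlan],
                   actives: list[tuple[str, int]], tsd_3p_only: int = 0,
                   frameshift_one: bool = False) -> list[CopyPlan]:
    """Expand a species row into copy plans.

    ``truncated`` plans are taken as-is; the remaining count per subfamily
    becomes complete copies: the requested actives first, the rest decayed
    with a deterministic premature-stop pattern (1,2,1,3,...) and every
    third one also triad-mutated.
    """
    plans = list(truncated)
    remaining = dict(subfam_counts)
    for p in truncated:
        remaining[p.subfamily] -= 1
    active_budget = dict()
    for sub, n in actives:
        active_budget[sub] = active_budget.get(sub, 0) + n
    stop_cycle = itertools.cycle([1, 2, 1, 3])
    decay_i = 0
    for sub in SUBFAMILIES:
        for _ in range(remaining.get(sub, 0)):
            if active_budget.get(sub, 0) > 0:
                active_budget[sub] -= 1
                plans.append(CopyPlan(subfamily=sub, activity="intact",
                                      divergence=0.02))
                continue
            decay_i += 1
            plans.append(CopyPlan(
                subfamily=sub, activity="decayed",
                n_premature_stops=next(stop_cycle),
                triad_mutation=(decay_i % 3 == 0),
            ))
    if frameshift_one:
        for p in plans:
            if p.activity == "decayed" and p.completeness == "complete":
                p.frameshift = True
                p.n_premature_stops = 0
                p.triad_mutation = False
                break
    done = 0
    for p in plans:
        if (p.completeness == "complete" and p.activity == "decayed"
                and done < tsd_3p_only):
            p.tsd = "3p_only"
            done += 1
    return plans


def _trunc(sub: str, comp: str, at_end: bool = True, intact: bool = False,
           stops: int = 1) -> CopyPlan:
    return CopyPlan(
        subfamily=sub, completeness=comp, at_contig_end=at_end,
        activity="intact" if intact else "decayed",
        n_premature_stops=0 if intact else stops,
        divergence=0.02 if intact else 0.08,
    )


def default_paper_config(seed: int = 0) -> PlantConfig:
    """Seven genomes reproducing the published survey count structure.

    Totals 33/26/16/10/10/10/16 (121), subfamily splits per species, five
    potentially active complete copies (three in the K. rhusicola analogue,
    one each in the M. flavogallis and F. choui analogues), the two
    intact-ORF 5'-truncated copies in the S. chinensis analogue, the two
    complete copies with TA only at the 3' end in the K. rhusicola
    analogue, and 106 complete / 15 truncated copies overall.
    """
    genomes = [
        GenomePlan(
            species="S_chinensis", prefix="Sc",
            copies=_species_plans(
                {"Mauritiana": 4, "Drosophila": 9, "Vertumana": 8, "Irritans": 12},
                truncated=[
                    _trunc("Drosophila", "truncated_5p", intact=True),
                    _trunc("Drosophila", "truncated_5p", intact=True),
                    _trunc("Vertumana", "truncated_5p", stops=2),
                    _trunc("Irritans", "truncated_3p", stops=1),
                    _trunc("Irritans", "truncated_both", at_end=False, stops=1),
                ],
                actives=[], frameshift_one=True,
            ),
        ),
        GenomePlan(
            species="S_peitan", prefix="Sp",
            copies=_species_plans(
                {"Mauritiana": 2, "Drosophila": 2, "Vertumana": 6, "Irritans": 16},
                truncated=[
                    _trunc("Irritans", "truncated_5p"),
                    _trunc("Irritans", "truncated_3p"),
                    _trunc("Vertumana", "truncated_3p"),
                ],
                actives=[],
            ),
        ),
        GenomePlan(
            species="N_ibofushi", prefix="Ni",
            copies=_species_plans(
                {"Mauritiana": 3, "Drosophila": 5, "Vertumana": 4, "Irritans": 4},
                truncated=[_trunc("Irritans", "truncated_5p")],
                actives=[],
            ),
        ),
        GenomePlan(
            species="M_flavogallis", prefix="Mf",
            copies=_species_plans(
                {"Mauritiana": 4, "Drosophila": 3, "Vertumana": 2, "Irritans": 1},
                truncated=[
                    _trunc("Mauritiana", "truncated_5p"),
                    _trunc("Irritans", "truncated_3p"),
                ],
                actives=[("Drosophila", 1)],
            ),
        ),
        GenomePlan(
            species="F_choui", prefix="Fc",
            copies=_species_plans(
                {"Mauritiana": 3, "Drosophila": 4, "Vertumana": 3, "Irritans": 0},
                truncated=[
                    _trunc("Mauritiana", "truncated_5p"),
                    _trunc("Vertumana", "truncated_3p"),
                ],
                actives=[("Drosophila", 1)],
            ),
        ),
        GenomePlan(
            species="K_rhusicola", prefix="Kr",
            copies=_species_plans(
                {"Mauritiana": 4, "Drosophila": 2, "Vertumana": 4, "Irritans": 0},
                truncated=[
                    _trunc("Vertumana", "truncated_5p"),
                    _trunc("Vertumana", "truncated_3p"),
                ],
                actives=[("Drosophila", 1), ("Mauritiana", 2)],
                tsd_3p_only=2,
            ),
        ),
        GenomePlan(
            species="M_rhois", prefix="Mr",
            copies=_species_plans(
                {"Mauritiana": 9, "Drosophila": 1, "Vertumana": 6, "Irritans": 0},
                truncated=[],
                actives=[],
            ),
        ),
    ]
    return PlantConfig(genomes=genomes, seed=seed)


def simulate(config: PlantConfig | None = None, seed: int | None = None):
    """One-stop generation: (genomes, truth, panel, screen_panel)."""
    config = config or default_paper_config()
    if seed is not None:
        config = replace(config, seed=seed)
    genomes, truth = plant_copies(config)
    return genomes, truth, build_panel(config), build_screen_panel(config)
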
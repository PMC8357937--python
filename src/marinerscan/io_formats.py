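"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere in the package;
everything serialized (GFF3) is 1-based inclusive, per the format norm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

FAMILIES = ("Mariner", "Tc1", "maT", "GT", "VS")
SUBFAMILY_ORDER = ("Mauritiana", "Drosophila", "Vertumana", "Irritans")


class MarinerScanError(Exception):
    """Base class for package errors."""


class FastaError(MarinerScanError):
    pass


class EmptyFastaError(FastaError):
    pass


class DuplicateIdError(FastaError):
    pass


class AlphabetError(FastaError):
    pass


class CoordinateError(MarinerScanError):
    pass


class TreeError(MarinerScanError):
    pass


_DNA_OK = set("ACGTN")


@dataclass
class ContigSet:
    """A genome assembly: ordered contigs of one genome.

    Contig ids are unique, sequences upper-case over {A,C,G,T,N}.
    """

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for cid, seq in self.contigs.items():
            if not seq:
                raise AlphabetError(f"empty sequence for contig {cid!r}")

    def __len__(self):
        return len(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def items(self):
        return self.contigs.items()


@dataclass(frozen=True)
class PanelRecord:
    seq_id: str
    sequence: str
    family: str = "Mariner"
    subfamily: str | None = None
    role: str = "query"  # query | phylo_reference | outgroup


@dataclass
class ReferencePanel:
    """Labeled MLE query/reference sequences (plus one Tc1 outgroup for trees)."""

    records: list[PanelRecord]

    def __post_init__(self):
        for r in self.records:
            if r.family not in FAMILIES:
                raise MarinerScanError(f"unknown family {r.family!r}")
            if r.role == "phylo_reference" and not r.subfamily:
                raise MarinerScanError(
                    f"phylo_reference {r.seq_id!r} must carry a subfamily label"
                )
        n_out = sum(1 for r in self.records if r.role == "outgroup")
        if n_out > 1:
            raise MarinerScanError("at most one outgroup record allowed")

    def by_role(self, role: str) -> list[PanelRecord]:
        return [r for r in self.records if r.role == role]

    @property
    def outgroup(self) -> PanelRecord | None:
        out = self.by_role("outgroup")
        return out[0] if out else None


def _normalize(seq: str, where: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA_OK
    if bad:
        raise AlphabetError(
            f"{where}: characters {sorted(bad)} outside A/C/G/T/N"
        )
    return s


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a DNA multi-FASTA into (id, sequence) pairs.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased with U normalized to T. Empty files, duplicate ids and
    non-IUPAC characters beyond A/C/G/T/N are rejected.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, _normalize(str(rec.seq), rec.id)))
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return records


def read_contigs(path, genome_id: str | None = None) -> ContigSet:
    recs = read_fasta(path)
    gid = genome_id or Path(path).stem
    return ContigSet(genome_id=gid, contigs=dict(recs))


def read_panel(path) -> ReferencePanel:
    """Read a reference panel FASTA; ``key=value`` header tokens carry metadata.

    Recognized keys: ``family=`` (default Mariner), ``subfamily=``, ``role=``
    (default query), e.g. ``>Mau_ref1 family=Mariner subfamily=Mauritiana
    role=phylo_reference``.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        meta = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        records.append(
            PanelRecord(
                seq_id=rec.id,
                sequence=_normalize(str(rec.seq), rec.id),
                family=meta.get("family", "Mariner"),
                subfamily=meta.get("subfamily") or None,
                role=meta.get("role", "query"),
            )
        )
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return ReferencePanel(records)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_panel(panel: ReferencePanel, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in panel.records:
            header = f">{r.seq_id} family={r.family} role={r.role}"
            if r.subfamily:
                header += f" subfamily={r.subfamily}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(records: Sequence, path, contig_lengths: dict[str, int]) -> None:
    """Write annotated elements as GFF3.

    One ``transposable_element`` parent per element, with
    ``terminal_inverted_repeat`` children for each detected TIR and a ``CDS``
    child for the transposase ORF. Internal 0-based half-open spans become
    1-based inclusive columns. Records are duck-typed (see
    :class:`marinerscan.pipeline.MLERecord`).
    """
    lines = ["##gff-version 3"]
    for rec in records:
        start, end = rec.span
        clen = contig_lengths.get(rec.contig_id)
        if clen is None:
            raise CoordinateError(f"unknown contig {rec.contig_id!r}")
        if not (0 <= start < end <= clen):
            raise CoordinateError(
                f"{rec.element_id}: span {rec.span} outside contig "
                f"{rec.contig_id} (length {clen})"
            )
        attrs = (
            f"ID={rec.element_id};completeness={rec.completeness};"
            f"activity={rec.activity};subfamily={rec.subfamily or 'unassigned'};"
            f"tsd_left={str(rec.tsd_left).lower()};"
            f"tsd_right={str(rec.tsd_right).lower()}"
        )
        lines.append(
            "\t".join(
                [
                    rec.contig_id,
                    "marinerscan",
                    "transposable_element",
                    str(start + 1),
                    str(end),
                    "." if rec.score is None else str(rec.score),
                    rec.strand,
                    ".",
                    attrs,
                ]
            )
        )
        children = []
        if rec.tir is not None:
            children.append(("terminal_inverted_repeat", rec.tir_left_contig_span))
            children.append(("terminal_inverted_repeat", rec.tir_right_contig_span))
        if rec.orf_contig_span is not None:
            children.append(("CDS", rec.orf_contig_span))
        for idx, (ftype, (cs, ce)) in enumerate(children, 1):
            if not (0 <= cs < ce <= clen):
                raise CoordinateError(
                    f"{rec.element_id}: child span ({cs},{ce}) outside contig"
                )
            lines.append(
                "\t".join(
                    [
                        rec.contig_id,
                        "marinerscan",
                        ftype,
                        str(cs + 1),
                        str(ce),
                        ".",
                        rec.strand,
                        "0" if ftype == "CDS" else ".",
                        f"ID={rec.element_id}.{ftype}.{idx};Parent={rec.element_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Summary TSV (survey-table shaped)

SUMMARY_COLUMNS = [
    "species",
    "n_MLEs",
    "Mauritiana",
    "Drosophila",
    "Vertumana",
    "Irritans",
    "length_kb",
    "active",
    "inactive",
    "TIR_bp",
    "complete",
    "truncated",
]


def write_summary_tsv(report, path) -> None:
    """Write the per-genome summary with the survey-table column set.

    ``report`` is duck-typed (see :class:`marinerscan.pipeline.SummaryReport`):
    it exposes ``rows``, each with the fields named in ``SUMMARY_COLUMNS``.
    """
    buf = io.StringIO()
    buf.write("\t".join(SUMMARY_COLUMNS) + "\n")
    for row in report.rows:
        buf.write(
            "\t".join(
                str(getattr(row, c)) for c in SUMMARY_COLUMNS
            )
            + "\n"
        )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path, require_rooted: bool = True) -> None:
    """Serialize a scikit-bio ``TreeNode`` (branch lengths, support labels).

    Internal node names are used for bootstrap support by convention. When
    ``require_rooted`` the root must be bifurcating (rooted on the outgroup
    edge); an unrooted (trifurcating) tree is rejected.
    """
    if require_rooted and len(tree.children) != 2:
        raise TreeError(
            f"tree root has {len(tree.children)} children; expected a rooted "
            "(bifurcating) tree"
        )
    tree.write(str(path), format="newick")


def read_newick(path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
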
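"""Core data model and readers/writers for FASTA, MAF, GFF3, BED and newick.

All internal coordinates are 0-based half-open on the forward strand.  GFF3
is converted on read/write; MAF minus-strand rows keep their native fields
for re-emission but expose a normalized forward-strand interval.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: minimum run of N treated as an assembly gap
DEFAULT_MIN_N_RUN = 10


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    sequence_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.sequence_name}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.sequence_name == other.sequence_name
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.sequence_name == other.sequence_name
            and self.start <= other.start
            and other.end <= self.end
        )


def find_n_runs(seq: str, min_n_run: int = DEFAULT_MIN_N_RUN) -> list[tuple[int, int]]:
    """Maximal runs of N of length >= min_n_run, as (start, end) pairs."""
    runs = []
    for m in re.finditer(r"N+", seq):
        if m.end() - m.start() >= min_n_run:
            runs.append((m.start(), m.end()))
    return runs


class GenomeSet:
    """Sequences of one species, with assembly-gap (N-run) annotations."""

    def __init__(self, species_id: str, sequences: dict[str, str],
                 min_n_run: int = DEFAULT_MIN_N_RUN):
        self.species_id = species_id
        self.min_n_run = min_n_run
        self.sequences: dict[str, str] = {}
        self.mask: dict[str, list[tuple[int, int]]] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate sequence name {name!r}")
            if not seq:
                raise ValueError(f"empty sequence {name!r}")
            self.mask[name] = [
                (m.start(), m.end()) for m in re.finditer(r"[a-z]+", seq)
            ]
            up = seq.upper()
            if re.search(r"[^ACGTN]", up):
                logger.warning(
                    "sequence %s contains non-ACGTN codes; converted to N", name
                )
                up = re.sub(r"[^ACGTN]", "N", up)
            self.sequences[name] = up
        self.n_gaps: dict[str, list[tuple[int, int]]] = {
            name: find_n_runs(seq, min_n_run)
            for name, seq in self.sequences.items()
        }

    def __eq__(self, other):
        return (
            isinstance(other, GenomeSet)
            and self.species_id == other.species_id
            and self.sequences == other.sequences
        )

    def fetch(self, iv: Interval) -> str:
        seq = self.sequences[iv.sequence_name][iv.start:iv.end]
        return revcomp(seq) if iv.strand == "-" else seq

    def overlaps_n_gap(self, iv: Interval) -> bool:
        return any(
            s < iv.end and iv.start < e
            for s, e in self.n_gaps.get(iv.sequence_name, [])
        )


@dataclass
class AnnotationRecord:
    """One GFF3 feature, coordinates already 0-based half-open."""

    kind: str  # gene, mRNA, CDS, exon
    interval: Interval
    record_id: str | None = None
    parent: str | None = None
    gene_id: str | None = None
    phase: int | None = None

    def tss(self) -> int:
        """Transcription start: leftmost base on '+', rightmost on '-'."""
        if self.kind != "gene":
            raise ValueError("TSS is defined for gene records")
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1


@dataclass
class MafRow:
    species_id: str
    sequence_name: str
    start: int  # native MAF start (strand-relative)
    ungapped_size: int
    strand: str
    source_length: int
    text: str

    @property
    def src(self) -> str:
        return f"{self.species_id}.{self.sequence_name}"

    def forward_interval(self) -> Interval:
        """Forward-strand interval on the source sequence (MAF convention)."""
        if self.strand == "+":
            return Interval(self.sequence_name, self.start,
                            self.start + self.ungapped_size, "+")
        start = self.source_length - self.start - self.ungapped_size
        return Interval(self.sequence_name, start,
                        start + self.ungapped_size, "-")


class AlignmentBlock:
    """One MAF block; first row is the reference."""

    def __init__(self, rows: list[MafRow], score: float = 0.0):
        if not rows:
            raise ValueError("alignment block needs at least one row")
        width = len(rows[0].text)
        for i, row in enumerate(rows):
            if len(row.text) != width:
                raise ValueError(
                    f"row {i} ({row.src}) length {len(row.text)} != {width}"
                )
            ungapped = sum(1 for c in row.text if c != "-")
            if ungapped != row.ungapped_size:
                raise ValueError(
                    f"row {row.src}: declared size {row.ungapped_size} "
                    f"!= non-gap count {ungapped}"
                )
        self.rows = rows
        self.score = score

    @property
    def reference(self) -> MafRow:
        return self.rows[0]

    @property
    def width(self) -> int:
        return len(self.rows[0].text)

    def species(self) -> list[str]:
        return [r.species_id for r in self.rows]

    def row_for(self, species_id: str) -> MafRow | None:
        for row in self.rows:
            if row.species_id == species_id:
                return row
        return None

    def ref_positions(self) -> list[int]:
        """Reference source offset per column; -1 where the reference is gapped."""
        pos = []
        p = self.reference.start
        for c in self.reference.text:
            if c == "-":
                pos.append(-1)
            else:
                pos.append(p)
                p += 1
        return pos

    def column(self, i: int) -> str:
        return "".join(row.text[i] for row in self.rows)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, species_id: str | None = None,
               min_n_run: int = DEFAULT_MIN_N_RUN) -> GenomeSet:
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in sequences:
                    raise ValueError(f"duplicate sequence name {name!r}")
                sequences[name] = []
            else:
                if name is None:
                    raise ValueError("sequence data before first header")
                sequences[name].append(line)
    if species_id is None:
        species_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    joined = {n: "".join(parts) for n, parts in sequences.items()}
    for n, s in joined.items():
        if not s:
            raise ValueError(f"empty sequence {n!r}")
    return GenomeSet(species_id, joined, min_n_run=min_n_run)


def write_fasta(genome: GenomeSet, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.sequences):
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# MAF


def read_maf(path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    rows: list[MafRow] = []
    score = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("a"):
                if rows:
                    blocks.append(_make_block(rows, score, len(blocks)))
                    rows = []
                score = 0.0
                m = re.search(r"score=([-\d.eE+]+)", line)
                if m:
                    score = float(m.group(1))
            elif line.startswith("s "):
                fields = line.split()
                if len(fields) != 7:
                    raise ValueError(f"malformed s line: {line!r}")
                src = fields[1]
                if "." in src:
                    species, seqname = src.split(".", 1)
                else:
                    species, seqname = src, src
                rows.append(MafRow(
                    species_id=species, sequence_name=seqname,
                    start=int(fields[2]), ungapped_size=int(fields[3]),
                    strand=fields[4], source_length=int(fields[5]),
                    text=fields[6].upper(),
                ))
    if rows:
        blocks.append(_make_block(rows, score, len(blocks)))
    return blocks


def _make_block(rows, score, index):
    try:
        return AlignmentBlock(rows, score=score)
    except ValueError as exc:
        raise ValueError(f"block {index}: {exc}") from exc


def write_maf(blocks: list[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write(f"a score={block.score:.6g}\n")
            for row in block.rows:
                fh.write(
                    f"s {row.src} {row.start} {row.ungapped_size} "
                    f"{row.strand} {row.source_length} {row.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[AnnotationRecord]:
    records: list[AnnotationRecord] = []
    seen_ids: set[str] = set()
    for line in open(path):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqname, _source, kind, start1, end1, _score, strand, phase, attrs = f
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        rec = AnnotationRecord(
            kind=kind,
            interval=Interval(seqname, int(start1) - 1, int(end1), strand),
            record_id=attr.get("ID"),
            parent=attr.get("Parent"),
            gene_id=attr.get("gene_id"),
            phase=None if phase == "." else int(phase),
        )
        if rec.kind == "CDS" and rec.parent is None:
            raise ValueError(f"CDS without Parent: {line!r}")
        records.append(rec)
        if rec.record_id:
            seen_ids.add(rec.record_id)
    for rec in records:
        if rec.parent is not None and rec.parent not in seen_ids:
            raise ValueError(f"record parent {rec.parent!r} not defined")
    _propagate_gene_ids(records)
    return records


def _propagate_gene_ids(records):
    by_id = {r.record_id: r for r in records if r.record_id}
    for rec in records:
        if rec.gene_id is not None:
            continue
        node = rec
        while node is not None and node.kind != "gene":
            node = by_id.get(node.parent)
        if node is not None:
            rec.gene_id = node.gene_id or node.record_id


def write_gff3(records: list[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = []
            if rec.record_id:
                attrs.append(f"ID={rec.record_id}")
            if rec.parent:
                attrs.append(f"Parent={rec.parent}")
            if rec.gene_id and rec.kind == "gene":
                attrs.append(f"gene_id={rec.gene_id}")
            fh.write("\t".join([
                rec.interval.sequence_name, "cneloss", rec.kind,
                str(rec.interval.start + 1), str(rec.interval.end), ".",
                rec.interval.strand,
                "." if rec.phase is None else str(rec.phase),
                ";".join(attrs) or ".",
            ]) + "\n")


def cds_of_gene(records: list[AnnotationRecord], gene_id: str) -> list[AnnotationRecord]:
    """CDS records of one gene in transcription order, validated."""
    gene = next(
        r for r in records if r.kind == "gene"
        and (r.gene_id == gene_id or r.record_id == gene_id)
    )
    cds = [r for r in records if r.kind == "CDS" and r.gene_id == gene.gene_id]
    cds.sort(key=lambda r: r.interval.start)
    for a, b in zip(cds, cds[1:]):
        if a.interval.end > b.interval.start:
            raise ValueError(f"overlapping CDS in gene {gene_id}")
    total = sum(r.interval.length for r in cds)
    if total % 3 != 0:
        raise ValueError(f"CDS length of gene {gene_id} not divisible by 3")
    if gene.interval.strand == "-":
        cds = cds[::-1]
    return cds


# ---------------------------------------------------------------------------
# BED


@dataclass
class BedRecord:
    interval: Interval
    name: str = "."
    score: float = 0.0


def read_bed(path) -> list[BedRecord]:
    out = []
    for line in open(path):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        iv = Interval(f[0], int(f[1]), int(f[2]))
        name = f[3] if len(f) > 3 else "."
        score = float(f[4]) if len(f) > 4 else 0.0
        out.append(BedRecord(iv, name, score))
    return out


def write_bed(records: list[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.interval.sequence_name}\t{rec.interval.start}\t"
                f"{rec.interval.end}\t{rec.name}\t{rec.score:.6g}\n"
            )


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) pairs as a sorted list of disjoint pairs."""
    merged: list[list[int]] = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage_fraction(a: Interval, hits: list[Interval]) -> float:
    """Fraction of `a` covered by the union of `hits` (same sequence)."""
    pairs = [
        (max(h.start, a.start), min(h.end, a.end))
        for h in hits
        if h.sequence_name == a.sequence_name and h.start < a.end and a.start < h.end
    ]
    covered = sum(e - s for s, e in merge_intervals(pairs))
    return covered / a.length
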
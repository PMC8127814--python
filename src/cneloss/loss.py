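"""Per-species element presence classification, gap-free syntenic
intervals, unique-loss calling, and ghost-locus gene-loss scanning.

Presence follows a two-stage rule: alignment coverage of at least 30%
makes an element present; otherwise a whole-genome homology rescue search
may find it (rearranged or partitioned loci); otherwise it is missing —
unless its projected target locus overlaps an assembly N-gap, which makes
the call gap-uncertain rather than missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .formats import AlignmentBlock, GenomeSet, Interval
from .search import Chain, SequenceIndex, build_genome_index, rescue_search

logger = logging.getLogger(__name__)

PRESENT_BY_ALIGNMENT = "present_by_alignment"
PRESENT_BY_RESCUE = "present_by_rescue"
MISSING = "missing"
GAP_UNCERTAIN = "gap_uncertain"

PRESENT_STATES = (PRESENT_BY_ALIGNMENT, PRESENT_BY_RESCUE)


@dataclass
class PresenceCell:
    state: str
    coverage: float


class PresenceMatrix:
    """Rows = elements, columns = non-reference species."""

    def __init__(self, element_intervals: dict[str, Interval],
                 species: list[str]):
        self.element_intervals = element_intervals
        self.species = list(species)
        self.cells: dict[tuple[str, str], PresenceCell] = {}

    def set(self, element: str, species: str, state: str, coverage: float):
        self.cells[(element, species)] = PresenceCell(state, coverage)

    def get(self, element: str, species: str) -> PresenceCell:
        return self.cells[(element, species)]

    def states_of(self, element: str) -> dict[str, str]:
        return {sp: self.cells[(element, sp)].state for sp in self.species}

    def present_anywhere(self, element: str) -> bool:
        return any(s in PRESENT_STATES
                   for s in self.states_of(element).values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("element\tchrom\tstart\tend\tspecies\tstate\tcoverage\n")
            for name in sorted(self.element_intervals):
                iv = self.element_intervals[name]
                for sp in self.species:
                    cell = self.cells[(name, sp)]
                    fh.write(f"{name}\t{iv.sequence_name}\t{iv.start}\t"
                             f"{iv.end}\t{sp}\t{cell.state}\t"
                             f"{cell.coverage:.6g}\n")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        intervals: dict[str, Interval] = {}
        rows = []
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("element\t")
            for line in fh:
                name, chrom, start, end, sp, state, cov = \
                    line.rstrip("\n").split("\t")
                intervals[name] = Interval(chrom, int(start), int(end))
                rows.append((name, sp, state, float(cov)))
        species = sorted({sp for _, sp, _, _ in rows})
        mat = cls(intervals, species)
        for name, sp, state, cov in rows:
            mat.set(name, sp, state, cov)
        return mat


# ---------------------------------------------------------------------------
# alignment coverage


class _BlockView:
    """Per-species numpy views of one block keyed by reference position."""

    def __init__(self, block: AlignmentBlock):
        self.block = block
        ref = block.reference
        self.chrom = ref.sequence_name
        self.ref_pos = np.array(block.ref_positions())
        self._cols: dict[str, np.ndarray] = {}
        self._tpos: dict[str, np.ndarray] = {}

    def chars(self, species: str) -> np.ndarray | None:
        if species not in self._cols:
            row = self.block.row_for(species)
            if row is None:
                self._cols[species] = None
            else:
                self._cols[species] = np.frombuffer(
                    row.text.encode(), dtype=np.uint8)
        return self._cols[species]

    def target_positions(self, species: str) -> np.ndarray | None:
        """Forward-strand target offset per column; -1 where target gapped."""
        if species not in self._tpos:
            row = self.block.row_for(species)
            chars = self.chars(species)
            if row is None:
                self._tpos[species] = None
            else:
                aligned = chars != ord("-")
                rel = np.cumsum(aligned) - 1
                if row.strand == "+":
                    pos = row.start + rel
                else:
                    pos = row.source_length - 1 - (row.start + rel)
                self._tpos[species] = np.where(aligned, pos, -1)
        return self._tpos[species]


_ACGT = frozenset(b"ACGT")


def _aligned_base_mask(chars: np.ndarray) -> np.ndarray:
    """Columns carrying a real target base (not '-', not N)."""
    mask = np.zeros(len(chars), dtype=bool)
    for b in b"ACGT":
        mask |= chars == b
    return mask


def alignment_presence(cne: Interval, blocks: list[AlignmentBlock],
                       species: str, threshold: float = 0.30,
                       views: list[_BlockView] | None = None
                       ) -> tuple[float, bool]:
    """Fraction of element reference bases aligned to real bases of
    `species`, and whether it meets the presence threshold (inclusive)."""
    if views is None:
        views = [_BlockView(b) for b in blocks]
    covered = 0
    for view in views:
        if view.chrom != cne.sequence_name:
            continue
        chars = view.chars(species)
        if chars is None:
            continue
        in_cne = (view.ref_pos >= cne.start) & (view.ref_pos < cne.end)
        if not in_cne.any():
            continue
        covered += int((_aligned_base_mask(chars) & in_cne).sum())
    coverage = covered / cne.length
    return coverage, coverage >= threshold


def _projected_locus(cne: Interval, views: list[_BlockView], species: str
                     ) -> Interval | None:
    """Target span between the element's nearest flanking aligned anchors."""
    lo = hi = None
    tname = None
    for view in views:
        if view.chrom != cne.sequence_name:
            continue
        tpos = view.target_positions(species)
        if tpos is None:
            continue
        row = view.block.row_for(species)
        # anchors: aligned target positions at or just outside the element
        in_span = (view.ref_pos >= cne.start) & (view.ref_pos < cne.end)
        aligned = tpos >= 0
        inside = tpos[in_span & aligned]
        if inside.size:
            a, b = int(inside.min()), int(inside.max()) + 1
        else:
            left = tpos[(view.ref_pos >= 0) & (view.ref_pos < cne.start)
                        & aligned]
            right = tpos[(view.ref_pos >= cne.end) & aligned]
            if left.size == 0 or right.size == 0:
                continue
            a = int(min(left.max(), right.min()))
            b = int(max(left.max(), right.min())) + 1
        if lo is None or a < lo:
            lo = a
        if hi is None or b > hi:
            hi = b
        tname = row.sequence_name
    if lo is None:
        return None
    return Interval(tname, lo, max(hi, lo + 1))


def classify_presence(cnes: dict[str, Interval],
                      blocks: list[AlignmentBlock],
                      genomes: dict[str, GenomeSet],
                      ref_species: str,
                      coverage_threshold: float = 0.30,
                      rescue: bool = True,
                      rescue_thresholds: dict | None = None
                      ) -> PresenceMatrix:
    """Two-stage presence classification of every element in every
    non-reference species, with gap-uncertain override."""
    species = [sp for sp in sorted(genomes) if sp != ref_species]
    matrix = PresenceMatrix(cnes, species)
    views = [_BlockView(b) for b in blocks]
    ref_genome = genomes[ref_species]
    thresholds = rescue_thresholds or {}
    indices: dict[str, dict[str, SequenceIndex]] = {}
    for name in sorted(cnes):
        iv = cnes[name]
        seq = ref_genome.fetch(iv)
        for sp in species:
            coverage, present = alignment_presence(
                iv, blocks, sp, coverage_threshold, views)
            if present:
                matrix.set(name, sp, PRESENT_BY_ALIGNMENT, coverage)
                continue
            if rescue:
                if sp not in indices:
                    indices[sp] = build_genome_index(genomes[sp].sequences)
                res = rescue_search(seq, indices[sp], **thresholds)
                if res.found:
                    matrix.set(name, sp, PRESENT_BY_RESCUE, coverage)
                    continue
            locus = _projected_locus(iv, views, sp)
            if locus is None or genomes[sp].overlaps_n_gap(locus):
                matrix.set(name, sp, GAP_UNCERTAIN, coverage)
            else:
                matrix.set(name, sp, MISSING, coverage)
    return matrix


# ---------------------------------------------------------------------------
# gap-free syntenic intervals


@dataclass
class SyntenicInterval:
    species: str
    ref: Interval
    target: Interval
    gap_free: bool


def _block_segments(view: _BlockView, species: str, min_n_run: int):
    """Split one block into clean segments at aligned target N-runs of
    length >= min_n_run; yields (ref_span, target_span) pairs plus the
    full span with a cleanliness flag."""
    chars = view.chars(species)
    if chars is None:
        return [], None
    is_n = chars == ord("N")
    # N-runs long enough to count as assembly gaps
    breaks = np.zeros(len(chars), dtype=bool)
    i = 0
    while i < len(chars):
        if is_n[i]:
            j = i
            while j < len(chars) and is_n[j]:
                j += 1
            if j - i >= min_n_run:
                breaks[i:j] = True
            i = j
        else:
            i += 1
    tpos = view.target_positions(species)
    aligned = tpos >= 0
    segments = []
    start = None
    for i in range(len(chars) + 1):
        at_break = i == len(chars) or breaks[i]
        if not at_break and start is None:
            start = i
        elif at_break and start is not None:
            seg = _span_of(view, species, start, i, aligned, tpos)
            if seg is not None:
                segments.append(seg)
            start = None
    full = _span_of(view, species, 0, len(chars), aligned, tpos)
    return segments, (full, not breaks.any())


def _span_of(view, species, c0, c1, aligned, tpos):
    rp = view.ref_pos[c0:c1]
    rp = rp[rp >= 0]
    tp = tpos[c0:c1]
    tp = tp[aligned[c0:c1]]
    if rp.size == 0 or tp.size == 0:
        return None
    row = view.block.row_for(species)
    return (Interval(view.chrom, int(rp.min()), int(rp.max()) + 1),
            Interval(row.sequence_name, int(tp.min()), int(tp.max()) + 1))


def gap_free_syntenic_intervals(blocks: list[AlignmentBlock],
                                genomes: dict[str, GenomeSet],
                                species: str,
                                max_anchor_gap: int = 100_000
                                ) -> list[SyntenicInterval]:
    """Collinear aligned spans whose target side is free of assembly gaps.

    Clean segments (no aligned N-runs, no target N-gap between anchors) are
    merged into maximal gap-free intervals; spans that include an N-gap are
    additionally reported with gap_free=False.
    """
    genome = genomes[species]
    min_n_run = genome.min_n_run
    views = [_BlockView(b) for b in blocks]
    clean: list[tuple[Interval, Interval]] = []
    dirty_spans: list[tuple[Interval, Interval]] = []
    for view in views:
        segments, full = _block_segments(view, species, min_n_run)
        clean.extend(segments)
        if full is not None and full[0] is not None and not full[1]:
            dirty_spans.append(full[0])
    clean.sort(key=lambda seg: (seg[0].sequence_name, seg[0].start))

    def joinable(a, b):
        return (a[0].sequence_name == b[0].sequence_name
                and a[1].sequence_name == b[1].sequence_name
                and 0 <= b[0].start - a[0].end <= max_anchor_gap
                and 0 <= b[1].start - a[1].end <= max_anchor_gap
                and not genome.overlaps_n_gap(
                    Interval(a[1].sequence_name, a[1].end,
                             max(b[1].start, a[1].end + 1))))

    out: list[SyntenicInterval] = []
    current: tuple[Interval, Interval] | None = None
    for seg in clean:
        if current is None:
            current = seg
        elif joinable(current, seg):
            current = (Interval(current[0].sequence_name, current[0].start,
                                seg[0].end),
                       Interval(current[1].sequence_name, current[1].start,
                                seg[1].end))
        else:
            out.append(SyntenicInterval(species, current[0], current[1], True))
            current = seg
    if current is not None:
        out.append(SyntenicInterval(species, current[0], current[1], True))
    for ref_iv, target_iv in dirty_spans:
        out.append(SyntenicInterval(species, ref_iv, target_iv, False))
    return out


def write_syntenic_tsv(intervals: list[SyntenicInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tref_chrom\tref_start\tref_end\t"
                 "target_seq\ttarget_start\ttarget_end\tgap_free\n")
        for si in intervals:
            fh.write(f"{si.species}\t{si.ref.sequence_name}\t{si.ref.start}"
                     f"\t{si.ref.end}\t{si.target.sequence_name}\t"
                     f"{si.target.start}\t{si.target.end}\t"
                     f"{int(si.gap_free)}\n")


def read_syntenic_tsv(path) -> list[SyntenicInterval]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            sp, rc, rs, re_, tc, ts, te, gf = line.rstrip("\n").split("\t")
            out.append(SyntenicInterval(
                sp, Interval(rc, int(rs), int(re_)),
                Interval(tc, int(ts), int(te)), bool(int(gf))))
    return out


# ---------------------------------------------------------------------------
# unique-loss calling


CANDIDATE, HIGH_CONFIDENCE = "candidate", "high_confidence"


@dataclass
class LossCall:
    element: str
    interval: Interval
    lost_in: str
    tier: str


def call_unique_losses(matrix: PresenceMatrix,
                       intervals: list[SyntenicInterval],
                       min_witnesses: int = 1) -> list[LossCall]:
    """Elements missing in exactly one non-reference species, attested in at
    least `min_witnesses` others; high-confidence when inside a gap-free
    syntenic interval of the losing species."""
    gap_free_by_sp: dict[str, list[SyntenicInterval]] = {}
    for si in intervals:
        if si.gap_free:
            gap_free_by_sp.setdefault(si.species, []).append(si)
    calls: list[LossCall] = []
    for name in sorted(matrix.element_intervals):
        states = matrix.states_of(name)
        missing = [sp for sp, s in states.items() if s == MISSING]
        witnesses = sum(1 for s in states.values() if s in PRESENT_STATES)
        if len(missing) != 1 or witnesses < min_witnesses:
            continue
        sp = missing[0]
        iv = matrix.element_intervals[name]
        inside = any(si.ref.contains(iv) for si in gap_free_by_sp.get(sp, []))
        calls.append(LossCall(name, iv, sp,
                              HIGH_CONFIDENCE if inside else CANDIDATE))
    return calls


# ---------------------------------------------------------------------------
# ghost-locus scanning


@dataclass
class GhostLocusReport:
    status: str  # absent | present | present_elsewhere | locus_broken | anchors_missing
    interval: Interval | None
    n_gap_bases: int
    probe_hits_inside: dict[str, bool]
    probe_hits_genome: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "interval": None if self.interval is None else {
                "sequence": self.interval.sequence_name,
                "start": self.interval.start,
                "end": self.interval.end,
            },
            "n_gap_bases": self.n_gap_bases,
            "probe_hits_inside": self.probe_hits_inside,
            "probe_hits_genome": self.probe_hits_genome,
        }


def ghost_locus_scan(anchor_a: str, anchor_b: str,
                     genome: GenomeSet,
                     probes: dict[str, str],
                     anchor_proteins: dict[str, str],
                     rescue_thresholds: dict | None = None
                     ) -> GhostLocusReport:
    """Scan the interval between two anchor genes for any trace of a gene.

    Anchors are located by translated mapping of their proteins; probes
    (CDS fragments or locus elements) are searched both inside the
    inter-anchor interval and genome-wide.  Verdict "absent" requires no
    probe hit anywhere.
    """
    from .search import mine_candidate_loci

    loci = {
        name: mine_candidate_loci({name: anchor_proteins[name]},
                                  genome.sequences)
        for name in (anchor_a, anchor_b)
    }
    if not loci[anchor_a] or not loci[anchor_b]:
        return GhostLocusReport("anchors_missing", None, 0, {}, {})
    la = max(loci[anchor_a], key=lambda c: c.score)
    lb = max(loci[anchor_b], key=lambda c: c.score)
    if la.interval.sequence_name != lb.interval.sequence_name:
        return GhostLocusReport("locus_broken", None, 0, {}, {})
    seq_name = la.interval.sequence_name
    left, right = sorted([la.interval, lb.interval], key=lambda iv: iv.start)
    if left.end >= right.start:
        interval = Interval(seq_name, left.start, right.end)
    else:
        interval = Interval(seq_name, left.end, right.start)
    inner = genome.sequences[seq_name][interval.start:interval.end]
    n_gap_bases = inner.count("N")

    thresholds = rescue_thresholds or {}
    inner_index = ({seq_name: SequenceIndex(inner)} if len(inner) >= 11
                   else {})
    genome_index = build_genome_index(genome.sequences)
    hits_inside: dict[str, bool] = {}
    hits_genome: dict[str, bool] = {}
    for pname, pseq in probes.items():
        hits_inside[pname] = (bool(inner_index)
                              and rescue_search(pseq, inner_index,
                                                **thresholds).found)
        hits_genome[pname] = rescue_search(pseq, genome_index,
                                           **thresholds).found
    if any(hits_inside.values()):
        status = "present"
    elif any(hits_genome.values()):
        status = "present_elsewhere"
    else:
        status = "absent"
    return GhostLocusReport(status, interval, n_gap_bases,
                            hits_inside, hits_genome)


def write_loss_bed(calls: list[LossCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.interval.sequence_name}\t{c.interval.start}\t"
                     f"{c.interval.end}\t{c.element}\t0\t+\t{c.lost_in}\t"
                     f"{c.tier}\n")
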
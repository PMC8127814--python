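"""Seed-and-extend ungapped local search (nucleotide and translated) with
collinear HSP chaining.

Extensions are ungapped with an x-drop rule; gaps are handled at the
chaining level.  E-values use Karlin-Altschul statistics with constants
fixed for the default +1/-1 scoring; they are a gating/ranking device, not
calibrated p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .formats import Interval, revcomp

logger = logging.getLogger(__name__)

# Karlin-Altschul constants for +1/-1 scoring on ~uniform DNA:
# lambda solves 0.25*e^l + 0.75*e^-l = 1 -> l = ln 3.
KA_LAMBDA = math.log(3.0)
KA_K = 0.34

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(seq: str) -> str:
    return "".join(
        GENETIC_CODE.get(seq[i:i + 3], "X")
        for i in range(0, len(seq) - 2, 3)
    )


@dataclass
class Hsp:
    """Ungapped high-scoring segment pair (query and target same length)."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    score: float
    identity: float
    e_value: float = math.inf

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start

    @property
    def per_base_score(self) -> float:
        return self.score / max(self.query_length, 1)


@dataclass
class Chain:
    """Collinear non-crossing HSPs with overlap-trimmed total score."""

    hsps: list[Hsp] = field(default_factory=list)
    score: float = 0.0
    strand: str = "+"

    def query_coverage(self, query_length: int) -> float:
        if not self.hsps:
            return 0.0
        covered = 0
        prev_end = -1
        for h in sorted(self.hsps, key=lambda h: h.query_start):
            s = max(h.query_start, prev_end)
            covered += max(0, h.query_end - s)
            prev_end = max(prev_end, h.query_end)
        return covered / query_length

    @property
    def identity(self) -> float:
        if not self.hsps:
            return 0.0
        total = sum(h.query_length for h in self.hsps)
        return sum(h.identity * h.query_length for h in self.hsps) / total

    @property
    def e_value(self) -> float:
        return min((h.e_value for h in self.hsps), default=math.inf)

    def target_span(self) -> tuple[int, int]:
        return (min(h.target_start for h in self.hsps),
                max(h.target_end for h in self.hsps))


def e_value(score: float, m: int, n: int,
            lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    return k * m * n * math.exp(-lam * score)


class SequenceIndex:
    """Exact-word index of a target sequence for seeding."""

    def __init__(self, sequence: str, word_size: int = 11,
                 wildcard: str = "N"):
        self.sequence = sequence.upper()
        self.word_size = word_size
        self.wildcard = wildcard
        self.words: dict[str, list[int]] = {}
        for i in range(len(self.sequence) - word_size + 1):
            w = self.sequence[i:i + word_size]
            if wildcard not in w:
                self.words.setdefault(w, []).append(i)


def _extend(query: str, target: str, qpos: int, tpos: int, word_size: int,
            match: float, mismatch: float, xdrop: float, wildcard: str = "N"):
    """Ungapped x-drop extension of an exact seed; returns trimmed HSP span."""
    def is_match(a, b):
        return a == b and a != wildcard

    # left extension
    best = 0.0
    run = 0.0
    left = 0
    i = 1
    while qpos - i >= 0 and tpos - i >= 0:
        run += match if is_match(query[qpos - i], target[tpos - i]) else mismatch
        if run > best:
            best, left = run, i
        if best - run > xdrop:
            break
        i += 1
    left_score = best
    # right extension
    best = 0.0
    run = 0.0
    right = 0
    j = 0
    while qpos + word_size + j < len(query) and tpos + word_size + j < len(target):
        run += (match if is_match(query[qpos + word_size + j],
                                  target[tpos + word_size + j])
                else mismatch)
        if run > best:
            best, right = run, j + 1
        if best - run > xdrop:
            break
        j += 1
    right_score = best
    qs, qe = qpos - left, qpos + word_size + right
    matches = sum(1 for a, b in zip(query[qs:qe], target[tpos - left:
                                                         tpos + word_size + right])
                  if is_match(a, b))
    score = word_size * match + left_score + right_score
    return qs, qe, tpos - left, tpos + word_size + right, score, matches


def seed_and_extend(query_seq: str, target_seq: str | SequenceIndex,
                    word_size: int = 11, match: float = 1.0,
                    mismatch: float = -1.0, xdrop: float = 10.0,
                    min_score: float = 0.0, both_strands: bool = True,
                    wildcard: str = "N") -> list[Hsp]:
    """All maximal ungapped HSPs between query and target.

    Both strands of the query are searched (hits on "-" carry query
    coordinates on the forward query via the reverse-complement mapping).
    """
    query_seq = query_seq.upper()
    if isinstance(target_seq, SequenceIndex):
        index = target_seq
    else:
        index = SequenceIndex(target_seq, word_size)
    if len(query_seq) < word_size:
        logger.warning("query shorter than word size; no search performed")
        return []
    m, n = len(query_seq), len(index.sequence)
    strands = [("+", query_seq)]
    if both_strands:
        strands.append(("-", revcomp(query_seq)))
    hsps: list[Hsp] = []
    for strand, q in strands:
        seen: set[tuple[int, int]] = set()  # (diagonal, query_end) dedup
        for qpos in range(len(q) - word_size + 1):
            w = q[qpos:qpos + word_size]
            for tpos in index.words.get(w, ()):
                diag = tpos - qpos
                qs, qe, ts, te, score, matches = _extend(
                    q, index.sequence, qpos, tpos, word_size, match,
                    mismatch, xdrop, wildcard)
                key = (diag, qe)
                if key in seen or score < min_score:
                    continue
                seen.add(key)
                if strand == "-":
                    fqs, fqe = m - qe, m - qs
                else:
                    fqs, fqe = qs, qe
                hsps.append(Hsp(
                    query_start=fqs, query_end=fqe,
                    target_start=ts, target_end=te, strand=strand,
                    score=score, identity=matches / (qe - qs),
                    e_value=e_value(score, m, n),
                ))
    # drop HSPs fully contained in a higher-scoring one on the same strand
    hsps.sort(key=lambda h: -h.score)
    kept: list[Hsp] = []
    for h in hsps:
        if any(k.strand == h.strand and k.query_start <= h.query_start
               and h.query_end <= k.query_end
               and k.target_start <= h.target_start
               and h.target_end <= k.target_end for k in kept):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Chaining


def chain_score(hsps_in_order: list[Hsp]) -> float:
    """Score of an ordered collinear chain; overlaps are trimmed from the
    lower per-base-scoring member."""
    total = 0.0
    prev: Hsp | None = None
    for h in hsps_in_order:
        total += h.score
        if prev is not None:
            overlap = max(0, prev.query_end - h.query_start) + \
                max(0, prev.target_end - h.target_start)
            if overlap:
                total -= overlap * min(prev.per_base_score, h.per_base_score)
        prev = h
    return total


def chain_hsps(hsps: list[Hsp], max_gap: int = 5000) -> Chain:
    """Maximum-score collinear chain by sparse dynamic programming.

    HSPs must come from one query/target/strand triple.  Successive chain
    members must strictly increase in both query and target start; gaps
    larger than max_gap (in either coordinate) break the chain.
    """
    if not hsps:
        return Chain()
    strand = hsps[0].strand
    order = sorted(range(len(hsps)),
                   key=lambda i: (hsps[i].query_start, hsps[i].target_start))
    dp = [hsps[i].score for i in order]
    backptr = [-1] * len(order)
    for a in range(len(order)):
        ha = hsps[order[a]]
        for b in range(a):
            hb = hsps[order[b]]
            if not (hb.query_start < ha.query_start
                    and hb.target_start < ha.target_start):
                continue
            if (ha.query_start - hb.query_end > max_gap
                    or ha.target_start - hb.target_end > max_gap):
                continue
            overlap = max(0, hb.query_end - ha.query_start) + \
                max(0, hb.target_end - ha.target_start)
            cand = dp[b] + ha.score - overlap * min(hb.per_base_score,
                                                    ha.per_base_score)
            if cand > dp[a]:
                dp[a] = cand
                backptr[a] = b
    best = max(range(len(order)), key=lambda a: dp[a])
    members = []
    a = best
    while a != -1:
        members.append(hsps[order[a]])
        a = backptr[a]
    members.reverse()
    return Chain(hsps=members, score=dp[best], strand=strand)


# ---------------------------------------------------------------------------
# CNE rescue


@dataclass
class RescueResult:
    found: bool
    chain: Chain
    target_name: str | None = None


def rescue_search(cne_seq: str,
                  target_indices: dict[str, SequenceIndex],
                  e_threshold: float = 1e-10,
                  identity_threshold: float = 0.80,
                  coverage_threshold: float = 0.30,
                  word_size: int = 11) -> RescueResult:
    """Whether a reference element has a significant match anywhere in the
    target genome: some chain with E < e_threshold, identity >= 0.80 and
    query coverage >= 0.30."""
    best: Chain | None = None
    best_name = None
    qlen = len(cne_seq)
    for name, index in target_indices.items():
        hsps = seed_and_extend(cne_seq, index, word_size=word_size)
        for strand in ("+", "-"):
            sub = [h for h in hsps if h.strand == strand]
            if not sub:
                continue
            chain = chain_hsps(sub)
            if best is None or chain.score > best.score:
                best, best_name = chain, name
            if (chain.e_value < e_threshold
                    and chain.identity >= identity_threshold
                    and chain.query_coverage(qlen) >= coverage_threshold):
                return RescueResult(True, chain, name)
    return RescueResult(False, best or Chain(), best_name)


def build_genome_index(sequences: dict[str, str], word_size: int = 11
                       ) -> dict[str, SequenceIndex]:
    return {name: SequenceIndex(seq, word_size)
            for name, seq in sequences.items()}


# ---------------------------------------------------------------------------
# Translated search / candidate gene loci


@dataclass
class CandidateLocus:
    interval: Interval
    best_query: str
    score: float
    identity: float
    alignment_rate: float


def _frame_hsps(protein: str, frame_seq: str, frame_offset: int, strand: str,
                target_len: int, word_size: int, xdrop: float,
                match: float, mismatch: float) -> list[Hsp]:
    """HSPs of a protein query against one translated frame; extensions do
    not cross stop codons."""
    hsps = []
    for segment, seg_off in _split_at_stops(frame_seq):
        if len(segment) < word_size:
            continue
        idx = SequenceIndex(segment, word_size, wildcard="X")
        # protein alphabet: reuse nucleotide machinery (exact-word seeding
        # and +1/-1 extension are alphabet-agnostic)
        for h in seed_and_extend(protein, idx, word_size=word_size,
                                 match=match, mismatch=mismatch, xdrop=xdrop,
                                 both_strands=False, wildcard="X"):
            ts_aa = h.target_start + seg_off
            te_aa = h.target_end + seg_off
            if strand == "+":
                ts = frame_offset + 3 * ts_aa
                te = frame_offset + 3 * te_aa
            else:
                te = target_len - (frame_offset + 3 * ts_aa)
                ts = target_len - (frame_offset + 3 * te_aa)
            hsps.append(Hsp(
                query_start=h.query_start, query_end=h.query_end,
                target_start=ts, target_end=te, strand=strand,
                score=h.score, identity=h.identity, e_value=h.e_value,
            ))
    return hsps


def _split_at_stops(protein: str):
    start = 0
    for i, aa in enumerate(protein):
        if aa == "*":
            if i > start:
                yield protein[start:i], start
            start = i + 1
    if len(protein) > start:
        yield protein[start:], start


def mine_candidate_loci(protein_queries: dict[str, str],
                        genome: dict[str, str],
                        map_e: float = 1e-10, map_rate: float = 0.5,
                        keep_rate: float = 0.70, keep_identity: float = 0.40,
                        flank: int = 280, word_size: int = 4,
                        xdrop: float = 12.0) -> list[CandidateLocus]:
    """Translated mapping of protein queries to a genome, with two-gate
    filtering and flank extension.

    Chains must first pass the mapping gates (E <= map_e, alignment rate >=
    map_rate), then the retention gates (rate > keep_rate, identity >
    keep_identity).  Chain target spans extended by `flank` bp on both sides
    define candidate loci; overlapping loci are merged keeping the
    best-scoring query.
    """
    raw: list[CandidateLocus] = []
    for seq_name, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        frames: list[tuple[str, int, str]] = []
        for off in range(3):
            frames.append((translate(seq[off:]), off, "+"))
        rc = revcomp(seq)
        for off in range(3):
            frames.append((translate(rc[off:]), off, "-"))
        for qname, protein in protein_queries.items():
            qlen = len(protein)
            for frame_seq, off, strand in frames:
                hsps = _frame_hsps(protein, frame_seq, off, strand, n,
                                   word_size, xdrop, 1.0, -1.0)
                for h in hsps:
                    h.e_value = e_value(h.score, qlen, n // 3)
                if not hsps:
                    continue
                chain = chain_hsps(hsps)
                rate = chain.query_coverage(qlen)
                if chain.e_value > map_e or rate < map_rate:
                    continue
                if rate <= keep_rate or chain.identity <= keep_identity:
                    continue
                ts, te = chain.target_span()
                raw.append(CandidateLocus(
                    interval=Interval(seq_name, max(0, ts - flank),
                                      min(n, te + flank)),
                    best_query=qname, score=chain.score,
                    identity=chain.identity, alignment_rate=rate,
                ))
    # merge overlapping loci, keep best query
    raw.sort(key=lambda c: (c.interval.sequence_name, c.interval.start))
    merged: list[CandidateLocus] = []
    for loc in raw:
        if merged and merged[-1].interval.overlaps(loc.interval):
            prev = merged[-1]
            best = loc if loc.score > prev.score else prev
            merged[-1] = CandidateLocus(
                interval=Interval(
                    prev.interval.sequence_name,
                    min(prev.interval.start, loc.interval.start),
                    max(prev.interval.end, loc.interval.end)),
                best_query=best.best_query, score=best.score,
                identity=best.identity, alignment_rate=best.alignment_rate,
            )
        else:
            merged.append(loc)
    return merged
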
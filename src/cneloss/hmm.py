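"""Two-state phylo-HMM segmentation of reference-anchored alignments into
conserved elements, with rho estimation for the conserved state.

State 0 is "conserved" (neutral tree with every branch scaled by rho < 1),
state 1 is "neutral".  Transitions are parameterized by the target coverage
gamma and the expected element length omega: mu = 1/omega is the
conserved->neutral rate and nu = mu*gamma/(1-gamma) the reverse, which makes
gamma the exact stationary occupancy of the conserved state and omega its
mean run length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .formats import (AlignmentBlock, AnnotationRecord, BedRecord, Interval,
                      coverage_fraction)
from .phylo import (MISSING_CODE, PhyloTree, SiteColumnSet, SubstitutionModel,
                    column_log_likelihoods)

logger = logging.getLogger(__name__)

CONSERVED, NEUTRAL = 0, 1


@dataclass(frozen=True)
class HmmParams:
    """Transition priors of the two-state HMM."""

    target_coverage: float = 0.3
    expected_length: float = 45.0

    def __post_init__(self):
        if not 0 < self.target_coverage < 1:
            raise ValueError("target_coverage must be in (0,1)")
        if self.expected_length <= 1:
            raise ValueError("expected_length must be > 1")

    @property
    def mu(self) -> float:
        return 1.0 / self.expected_length

    @property
    def nu(self) -> float:
        g = self.target_coverage
        return self.mu * g / (1.0 - g)

    def transition_matrix(self) -> np.ndarray:
        return np.array([
            [1.0 - self.mu, self.mu],
            [self.nu, 1.0 - self.nu],
        ])

    def initial_distribution(self) -> np.ndarray:
        return np.array([self.target_coverage, 1.0 - self.target_coverage])


def scale_tree(tree: PhyloTree, rho: float) -> PhyloTree:
    """Copy of `tree` with every branch multiplied by rho (> 0)."""
    return tree.scaled(rho)


# ---------------------------------------------------------------------------
# HMM recursions (log space, 2 states)


def _check_emissions(log_emissions: np.ndarray) -> np.ndarray:
    e = np.asarray(log_emissions, dtype=float)
    if e.ndim != 2 or e.shape[1] != 2 or e.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (L, 2) array")
    return e


def forward_backward(log_emissions: np.ndarray, params: HmmParams
                     ) -> tuple[np.ndarray, float]:
    """Posterior P(conserved | columns) per column and total log-likelihood.

    `log_emissions[:, 0]` is the conserved-state column log-likelihood,
    `[:, 1]` the neutral one.
    """
    e = _check_emissions(log_emissions)
    L = e.shape[0]
    logT = np.log(params.transition_matrix())
    logpi = np.log(params.initial_distribution())

    fwd = np.empty((L, 2))
    fwd[0] = logpi + e[0]
    for i in range(1, L):
        fwd[i] = e[i] + _logsumexp2(fwd[i - 1][:, None] + logT)
    total = _logsumexp(fwd[-1])

    bwd = np.empty((L, 2))
    bwd[-1] = 0.0
    for i in range(L - 2, -1, -1):
        bwd[i] = _logsumexp2(logT + (e[i + 1] + bwd[i + 1])[None, :], axis=1)
    post = np.exp(fwd + bwd - total)
    post = post / post.sum(axis=1, keepdims=True)
    return post[:, CONSERVED], float(total)


def _logsumexp(v):
    m = np.max(v)
    return m + np.log(np.sum(np.exp(v - m)))


def _logsumexp2(mat, axis=0):
    m = np.max(mat, axis=axis)
    return m + np.log(np.sum(np.exp(mat - np.expand_dims(m, axis)), axis=axis))


def hmm_log_likelihood(log_emissions: np.ndarray, params: HmmParams) -> float:
    """Total forward log-likelihood (scalar inner loop for speed)."""
    from math import exp, log

    e = _check_emissions(log_emissions)
    t00, t01 = 1.0 - params.mu, params.mu
    t10, t11 = params.nu, 1.0 - params.nu
    l00, l01, l10, l11 = log(t00), log(t01), log(t10), log(t11)
    f0 = log(params.target_coverage) + e[0, 0]
    f1 = log(1.0 - params.target_coverage) + e[0, 1]
    e_list = log_emissions.tolist()
    for e0, e1 in e_list[1:]:
        a, b = f0 + l00, f1 + l10
        m = a if a > b else b
        g0 = e0 + m + log(exp(a - m) + exp(b - m))
        a, b = f0 + l01, f1 + l11
        m = a if a > b else b
        g1 = e1 + m + log(exp(a - m) + exp(b - m))
        f0, f1 = g0, g1
    m = f0 if f0 > f1 else f1
    return float(m + log(exp(f0 - m) + exp(f1 - m)))


def viterbi_path(log_emissions: np.ndarray, params: HmmParams
                 ) -> tuple[np.ndarray, float]:
    """Most probable state path; ties broken toward the neutral state."""
    from math import log

    e = _check_emissions(log_emissions)
    L = e.shape[0]
    l00, l01 = log(1.0 - params.mu), log(params.mu)
    l10, l11 = log(params.nu), log(1.0 - params.nu)
    d0 = log(params.target_coverage) + e[0, 0]
    d1 = log(1.0 - params.target_coverage) + e[0, 1]
    back = np.zeros((L, 2), dtype=np.int8)
    e_list = e.tolist()
    for i in range(1, L):
        e0, e1 = e_list[i]
        a, b = d0 + l00, d1 + l10
        # ties broken toward the neutral predecessor (state 1)
        if b >= a:
            n0, b0 = e0 + b, 1
        else:
            n0, b0 = e0 + a, 0
        a, b = d0 + l01, d1 + l11
        if b >= a:
            n1, b1 = e1 + b, 1
        else:
            n1, b1 = e1 + a, 0
        back[i, 0], back[i, 1] = b0, b1
        d0, d1 = n0, n1
    last = 1 if d1 >= d0 else 0
    score = float(d1 if last else d0)
    path = np.empty(L, dtype=np.int8)
    path[-1] = last
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path, score


def viterbi_segments(log_emissions: np.ndarray, params: HmmParams
                     ) -> list[tuple[int, int]]:
    """Maximal runs of the conserved state, as half-open column ranges."""
    path, _ = viterbi_path(log_emissions, params)
    segments = []
    start = None
    for i, s in enumerate(path):
        if s == CONSERVED and start is None:
            start = i
        elif s != CONSERVED and start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, len(path)))
    return segments


# ---------------------------------------------------------------------------
# Emissions from alignments


def block_columns(block: AlignmentBlock, species_order: list[str]
                  ) -> SiteColumnSet:
    """Columns of one block over a fixed species order (missing row -> N)."""
    texts = []
    for sp in species_order:
        row = block.row_for(sp)
        texts.append(row.text if row is not None else "N" * block.width)
    codes = np.full((block.width, len(species_order)), MISSING_CODE,
                    dtype=np.int8)
    for j, text in enumerate(texts):
        arr = np.frombuffer(text.encode(), dtype=np.uint8)
        for b, code in zip(b"ACGT", range(4)):
            codes[arr == b, j] = code
    return SiteColumnSet(species_order, codes)


def block_emissions(block: AlignmentBlock, neutral_model: SubstitutionModel,
                    neutral_tree: PhyloTree, rho: float,
                    species_order: list[str] | None = None) -> np.ndarray:
    """(L, 2) log-emissions: conserved (rho-scaled tree) and neutral."""
    if species_order is None:
        species_order = neutral_tree.leaf_names()
    cols = block_columns(block, species_order)
    # collapse patterns once, evaluate both models on the unique set
    uniq, inverse = np.unique(cols.codes, axis=0, return_inverse=True)
    ucols = SiteColumnSet(species_order, uniq)
    cons = column_log_likelihoods(neutral_tree.scaled(rho), neutral_model, ucols)
    neut = column_log_likelihoods(neutral_tree, neutral_model, ucols)
    return np.stack([cons[inverse], neut[inverse]], axis=1)


# ---------------------------------------------------------------------------
# rho estimation


@dataclass
class RhoEstimate:
    rho: float
    per_chromosome: dict[str, float]
    at_boundary: bool


def estimate_rho(blocks: list[AlignmentBlock],
                 neutral_model: SubstitutionModel, neutral_tree: PhyloTree,
                 params: HmmParams | None = None,
                 bounds: tuple[float, float] = (0.01, 1.0)) -> RhoEstimate:
    """Per-reference-chromosome ML estimate of rho, and the unweighted mean.

    rho maximizes the total HMM log-likelihood of each chromosome's columns
    with the conserved state's tree scaled by rho; chromosomes are the
    reference sequence names of the blocks.
    """
    if params is None:
        params = HmmParams()
    species = neutral_tree.leaf_names()
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.reference.sequence_name, []).append(b)

    per_chrom: dict[str, float] = {}
    boundary = False
    for chrom, chrom_blocks in sorted(by_chrom.items()):
        total_cols = sum(b.width for b in chrom_blocks)
        if total_cols < 500:
            logger.warning("chromosome %s has only %d columns; rho estimate "
                           "may be unstable", chrom, total_cols)
        neut = [
            column_log_likelihoods(
                neutral_tree, neutral_model,
                block_columns(b, species))
            for b in chrom_blocks
        ]
        uniq_sets = []
        for b in chrom_blocks:
            cols = block_columns(b, species)
            uniq, inverse = np.unique(cols.codes, axis=0, return_inverse=True)
            uniq_sets.append((SiteColumnSet(species, uniq), inverse))

        def neg(rho):
            scaled = neutral_tree.scaled(rho)
            ll = 0.0
            for (ucols, inverse), n in zip(uniq_sets, neut):
                cons = column_log_likelihoods(scaled, neutral_model, ucols)
                e = np.stack([cons[inverse], n], axis=1)
                ll += hmm_log_likelihood(e, params)
            return -ll

        res = optimize.minimize_scalar(neg, bounds=bounds, method="bounded",
                                       options={"xatol": 1e-3})
        rho = float(res.x)
        per_chrom[chrom] = rho
        if rho <= bounds[0] + 0.02 or rho >= bounds[1] - 0.02:
            boundary = True
            logger.warning("rho estimate for %s at boundary: %.3f", chrom, rho)
    mean_rho = float(np.mean(list(per_chrom.values())))
    return RhoEstimate(mean_rho, per_chrom, boundary)


# ---------------------------------------------------------------------------
# Element calling


@dataclass
class ConservedElement:
    interval: Interval
    score: float  # summed log-odds conserved vs neutral
    mean_posterior: float
    name: str = ""


def call_elements(blocks: list[AlignmentBlock],
                  neutral_model: SubstitutionModel, neutral_tree: PhyloTree,
                  rho: float, params: HmmParams | None = None,
                  min_length: int = 15, bridge_gap: int = 10
                  ) -> list[ConservedElement]:
    """Segment alignments into conserved elements in reference coordinates.

    Viterbi runs of the conserved state are mapped to reference positions;
    runs interrupted by reference-gap columns are bridged when the gap is at
    most `bridge_gap` columns, otherwise split.  Elements shorter than
    `min_length` reference bp are dropped.
    """
    if params is None:
        params = HmmParams()
    species = neutral_tree.leaf_names()
    elements: list[ConservedElement] = []
    for bi, block in enumerate(blocks):
        ref = block.reference
        if ref.species_id not in species:
            logger.warning("block %d reference %s not in tree; skipped",
                           bi, ref.species_id)
            continue
        emissions = block_emissions(block, neutral_model, neutral_tree, rho,
                                    species)
        post, _ = forward_backward(emissions, params)
        segs = viterbi_segments(emissions, params)
        ref_pos = block.ref_positions()
        log_odds = emissions[:, CONSERVED] - emissions[:, NEUTRAL]
        for c0, c1 in segs:
            for s, e in _split_on_ref_gaps(ref_pos, c0, c1, bridge_gap):
                positions = [ref_pos[i] for i in range(s, e) if ref_pos[i] >= 0]
                if not positions or positions[-1] - positions[0] + 1 < min_length:
                    continue
                elements.append(ConservedElement(
                    interval=Interval(ref.sequence_name, positions[0],
                                      positions[-1] + 1),
                    score=float(log_odds[s:e].sum()),
                    mean_posterior=float(post[s:e].mean()),
                ))
    elements.sort(key=lambda el: (el.interval.sequence_name, el.interval.start))
    for i, el in enumerate(elements):
        el.name = f"ce{i + 1}"
    return elements


def _split_on_ref_gaps(ref_pos, c0, c1, bridge_gap):
    """Split [c0,c1) at runs of >bridge_gap reference-gap columns."""
    pieces = []
    start = None
    gap_run = 0
    for i in range(c0, c1):
        if ref_pos[i] >= 0:
            if start is None:
                start = i
            gap_run = 0
        else:
            gap_run += 1
            if start is not None and gap_run > bridge_gap:
                pieces.append((start, i - gap_run + 1))
                start = None
    if start is not None:
        pieces.append((start, c1))
    return pieces


def elements_to_bed(elements: list[ConservedElement]) -> list[BedRecord]:
    return [BedRecord(el.interval, el.name, el.score) for el in elements]


# ---------------------------------------------------------------------------
# Sensitivity and CNE definition


def exon_sensitivity(elements: list[ConservedElement],
                     annotations: list[AnnotationRecord],
                     min_cov: float = 0.10) -> float:
    """Fraction of coding exons covered at >= min_cov by conserved elements."""
    exons = [r.interval for r in annotations if r.kind in ("CDS", "exon")]
    if not exons:
        raise ValueError("no exon annotations")
    ivs = [el.interval for el in elements]
    covered = sum(1 for ex in exons if coverage_fraction(ex, ivs) >= min_cov)
    return covered / len(exons)


def define_cnes(elements: list[ConservedElement],
                annotations: list[AnnotationRecord],
                presence: dict[str, dict[str, bool]] | None = None
                ) -> list[ConservedElement]:
    """Noncoding elements attested outside the reference.

    Keeps elements with zero overlap to annotated CDS/exon intervals and,
    when a presence map (element name -> species -> present) is given,
    present in at least one non-reference species.
    """
    coding = [r.interval for r in annotations if r.kind in ("CDS", "exon")]
    out = []
    for el in elements:
        if any(el.interval.overlaps(iv) for iv in coding):
            continue
        if presence is not None:
            states = presence.get(el.name, {})
            if not any(states.values()):
                continue
        out.append(el)
    return out
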
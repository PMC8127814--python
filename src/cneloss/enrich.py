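"""Region-to-gene assignment by nearest TSS and hypergeometric term
enrichment with Benjamini-Hochberg FDR control."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats import AnnotationRecord, Interval

MAX_TSS_DISTANCE = 1_000_000


@dataclass
class RegionGeneAssignment:
    region: str
    gene: str | None
    distance: int | None  # signed, TSS - region midpoint
    assigned: bool
    ties: tuple[str, ...] = ()


def tss_table(annotations: list[AnnotationRecord]) -> dict[str, tuple[str, int]]:
    """gene id -> (sequence name, TSS position)."""
    out = {}
    for rec in annotations:
        if rec.kind == "gene":
            out[rec.gene_id or rec.record_id] = (
                rec.interval.sequence_name, rec.tss())
    return out


def assign_to_nearest_tss(regions: dict[str, Interval],
                          tss: dict[str, tuple[str, int]],
                          max_dist: int = MAX_TSS_DISTANCE
                          ) -> list[RegionGeneAssignment]:
    """Assign each region (by its midpoint) to the nearest TSS on the same
    sequence within max_dist; exact ties break to the smaller coordinate
    and are recorded."""
    by_seq: dict[str, list[tuple[int, str]]] = {}
    for gene, (seq, pos) in tss.items():
        by_seq.setdefault(seq, []).append((pos, gene))
    for seq in by_seq:
        by_seq[seq].sort()
    out = []
    for name in sorted(regions):
        iv = regions[name]
        mid = (iv.start + iv.end) // 2
        candidates = by_seq.get(iv.sequence_name, [])
        best: tuple[int, int, str] | None = None  # (|d|, pos, gene)
        ties: list[str] = []
        for pos, gene in candidates:
            d = abs(pos - mid)
            if d > max_dist:
                continue
            key = (d, pos, gene)
            if best is None or key < best:
                best = key
                ties = [g for p, g in candidates if abs(p - mid) == d]
        if best is None:
            out.append(RegionGeneAssignment(name, None, None, False))
        else:
            _, pos, gene = best
            out.append(RegionGeneAssignment(
                name, gene, pos - mid, True,
                tuple(sorted(ties)) if len(ties) > 1 else ()))
    return out


@dataclass
class EnrichmentResult:
    term: str
    k: int  # sample genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # sample size
    N: int  # universe size
    p_value: float
    q_value: float = 1.0


def hypergeometric_enrichment(sample_genes: set[str],
                              term_map: dict[str, set[str]],
                              universe: set[str],
                              alpha: float = 0.05
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term with BH q-values.

    term_map maps term id -> set of genes.  Results sorted by q then p.
    """
    if not sample_genes:
        raise ValueError("empty sample")
    if not sample_genes <= universe:
        raise ValueError("sample must be a subset of the universe")
    N = len(universe)
    n = len(sample_genes)
    results = []
    for term in sorted(term_map):
        genes = term_map[term] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & sample_genes)
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, K, n, N, p))
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH step-up q-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = running
    return q.tolist()


def randomized_null_pvalue(k: int, N: int, K: int, n: int, rng) -> float:
    """Randomized (exactly uniform under the null) hypergeometric p-value:
    P(X > k) + U * P(X = k).  Used for calibration checks, not for calling."""
    return float(stats.hypergeom.sf(k, N, K, n)
                 + rng.random() * stats.hypergeom.pmf(k, N, K, n))


def gene_loss_counts(assignments: list[RegionGeneAssignment]
                     ) -> list[tuple[str, int]]:
    """Genes ranked by number of assigned (lost) regions, descending."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.assigned:
            counts[a.gene] = counts.get(a.gene, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> term -> genes."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(term, set()).add(gene)
    return out


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tK\tn\tN\tp_value\tq_value\n")
        for r in results:
            fh.write(f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p_value:.6g}\t{r.q_value:.6g}\n")
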
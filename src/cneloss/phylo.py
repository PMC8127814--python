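"""Phylogenetic machinery: trees, reversible substitution models, pruning
likelihoods, 4D-site extraction, neutral-model fitting and lineage rate tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

from .formats import AlignmentBlock, AnnotationRecord, cds_of_gene

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING_CODE = 4  # N or gap

# codon prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}

# exchangeability order: (A,C) (A,G) (A,T) (C,G) (C,T) (G,T)
EXCH_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


# ---------------------------------------------------------------------------
# Trees


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with branch lengths in expected substitutions/site."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")
        for node in self.postorder():
            if node.length < 0:
                raise ValueError("branch lengths must be >= 0")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode):
            node = TreeNode(
                name=dnode.taxon.label.replace(" ", "_") if dnode.taxon
                else dnode.label,
                length=dnode.edge.length or 0.0,
            )
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dt.seed_node))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        return cls.from_newick(open(path).read())

    def to_newick(self) -> str:
        def fmt(node):
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    core += node.name
            if node.parent is not None:
                core += f":{node.length:.6g}"
            return core

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        out = []

        def walk(node):
            for child in node.children:
                walk(child)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes (each owns the branch to its parent)."""
        return [n for n in self.postorder() if n.parent is not None]

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    def scaled(self, rho: float) -> "PhyloTree":
        """A copy with every branch length multiplied by rho."""
        if rho <= 0:
            raise ValueError("rho must be > 0")
        tree = self.copy()
        for node in tree.branches():
            node.length *= rho
        return tree

    # -- distances ---------------------------------------------------------

    def _path_to_root(self, name: str) -> list[TreeNode]:
        leaf = next((n for n in self.leaves() if n.name == name), None)
        if leaf is None:
            raise KeyError(f"unknown leaf {name!r}")
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    def leaf_distance(self, a: str, b: str) -> float:
        pa = self._path_to_root(a)
        pb = self._path_to_root(b)
        sb = set(id(n) for n in pb)
        lca = next(n for n in pa if id(n) in sb)
        dist = 0.0
        for node in pa:
            if node is lca:
                break
            dist += node.length
        for node in pb:
            if node is lca:
                break
            dist += node.length
        return dist

    def cophenetic_matrix(self) -> tuple[list[str], np.ndarray]:
        names = self.leaf_names()
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = self.leaf_distance(names[i], names[j])
                mat[i, j] = mat[j, i] = d
        return names, mat


def distance_to_outgroup(tree: PhyloTree, outgroup: str) -> dict[str, float]:
    """Path-length distance from every other leaf to the outgroup leaf."""
    return {
        name: tree.leaf_distance(name, outgroup)
        for name in tree.leaf_names()
        if name != outgroup
    }


# ---------------------------------------------------------------------------
# GTR substitution model


class SubstitutionModel:
    """General time-reversible model, rate-normalized to one expected
    substitution per unit branch length."""

    def __init__(self, pi, exchangeabilities):
        pi = np.asarray(pi, dtype=float)
        exch = np.asarray(exchangeabilities, dtype=float)
        if pi.shape != (4,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi must be a 4-vector summing to 1")
        if exch.shape != (6,) or np.any(exch <= 0) or np.any(pi <= 0):
            raise ValueError("exchangeabilities and pi must be positive")
        self.pi = pi / pi.sum()
        self.exchangeabilities = exch
        Q = np.zeros((4, 4))
        for (i, j), s in zip(EXCH_PAIRS, exch):
            Q[i, j] = s * self.pi[j]
            Q[j, i] = s * self.pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(self.pi, np.diag(Q))
        self.Q = Q / rate
        # symmetrizable: B = D^{1/2} Q D^{-1/2} is symmetric
        d = np.sqrt(self.pi)
        B = self.Q * d[:, None] / d[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._left = U.T * d[None, :]       # U^T D^{1/2}
        self._right = U / d[:, None]        # D^{-1/2} U

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        return cls(np.full(4, 0.25), np.ones(6))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1 for t >= 0."""
        if t < 0:
            raise ValueError("t must be >= 0")
        P = self._right @ (np.exp(self._eigvals * t)[:, None] * self._left)
        return np.clip(P, 0.0, None)

    def to_dict(self) -> dict:
        return {
            "pi": [round(x, 10) for x in self.pi],
            "exchangeabilities": [round(x, 10) for x in self.exchangeabilities],
        }

    @classmethod
    def from_dict(cls, d) -> "SubstitutionModel":
        return cls(d["pi"], d["exchangeabilities"])


def save_model(model: SubstitutionModel, tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        json.dump({"model": model.to_dict(), "tree": tree.to_newick()},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> tuple[SubstitutionModel, PhyloTree]:
    d = json.load(open(path))
    return SubstitutionModel.from_dict(d["model"]), PhyloTree.from_newick(d["tree"])


# ---------------------------------------------------------------------------
# Aligned columns


class SiteColumnSet:
    """Aligned columns over a fixed leaf order, encoded A=0..T=3, missing=4.

    Repeated column patterns are collapsed and carried as weights.
    """

    def __init__(self, leaf_names: list[str], codes: np.ndarray,
                 weights: np.ndarray | None = None):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[1] != len(leaf_names):
            raise ValueError("codes must be (n_columns, n_leaves)")
        self.leaf_names = list(leaf_names)
        self.codes = codes
        if weights is None:
            weights = np.ones(len(codes))
        self.weights = np.asarray(weights, dtype=float)
        if np.any(self.weights < 1) and len(self.weights):
            raise ValueError("weights must be >= 1")

    @classmethod
    def from_strings(cls, leaf_names, columns: list[str]) -> "SiteColumnSet":
        table = {b: i for i, b in enumerate(BASES)}
        codes = np.array(
            [[table.get(c, MISSING_CODE) for c in col] for col in columns],
            dtype=np.int8,
        ).reshape(len(columns), len(leaf_names))
        return cls(leaf_names, codes)

    def __len__(self):
        return len(self.codes)

    @property
    def n_sites(self) -> float:
        return float(self.weights.sum())

    def collapsed(self) -> "SiteColumnSet":
        """Collapse identical patterns, summing weights."""
        if len(self.codes) == 0:
            return self
        uniq, inverse = np.unique(self.codes, axis=0, return_inverse=True)
        weights = np.bincount(inverse, weights=self.weights,
                              minlength=len(uniq))
        return SiteColumnSet(self.leaf_names, uniq, weights)

    def base_frequencies(self) -> np.ndarray:
        counts = np.zeros(4)
        for b in range(4):
            counts[b] = self.weights @ (self.codes == b).sum(axis=1)
        if counts.sum() == 0:
            raise ValueError("no informative bases in column set")
        return counts / counts.sum()

    def drop_uninformative(self) -> "SiteColumnSet":
        keep = (self.codes != MISSING_CODE).any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d all-missing columns", n_dropped)
        return SiteColumnSet(self.leaf_names, self.codes[keep],
                             self.weights[keep])


# ---------------------------------------------------------------------------
# Pruning likelihood


def _leaf_partials(codes_col: np.ndarray) -> np.ndarray:
    """(n_columns, 4) partials for one leaf; missing data -> all ones."""
    out = np.zeros((len(codes_col), 4))
    missing = codes_col == MISSING_CODE
    out[np.arange(len(codes_col)), np.where(missing, 0, codes_col)] = 1.0
    out[missing] = 1.0
    return out


def column_log_likelihoods(tree: PhyloTree, model: SubstitutionModel,
                           columns: SiteColumnSet) -> np.ndarray:
    """Felsenstein-pruning log-likelihood of every column (vectorized).

    Leaf states N and '-' contribute flat partials (missing data).  Raises
    if a column-set leaf is absent from the tree.
    """
    order = tree.postorder()
    leaf_idx = {}
    for name in columns.leaf_names:
        if name not in tree.leaf_names():
            raise KeyError(f"leaf {name!r} not in tree")
        leaf_idx[name] = columns.leaf_names.index(name)

    ncols = len(columns.codes)
    partials: dict[int, np.ndarray] = {}
    scale = np.zeros(ncols)
    for node in order:
        if node.is_leaf:
            if node.name not in leaf_idx:
                raise KeyError(f"tree leaf {node.name!r} missing from columns")
            p = _leaf_partials(columns.codes[:, leaf_idx[node.name]])
        else:
            p = np.ones((ncols, 4))
            for child in node.children:
                P = model.transition_matrix(child.length)
                p = p * (partials.pop(id(child)) @ P.T)
            # rescale to avoid underflow on deep trees
            m = p.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            p = p / m[:, None]
            scale += np.log(m)
        partials[id(node)] = p
    root_p = partials[id(tree.root)]
    like = root_p @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(like) + scale


def column_log_likelihood(tree: PhyloTree, model: SubstitutionModel,
                          column: str, leaf_names: list[str] | None = None) -> float:
    """Log-likelihood of a single column given as a string of leaf states."""
    if leaf_names is None:
        leaf_names = tree.leaf_names()
    cols = SiteColumnSet.from_strings(leaf_names, [column])
    return float(column_log_likelihoods(tree, model, cols)[0])


def total_log_likelihood(tree: PhyloTree, model: SubstitutionModel,
                         columns: SiteColumnSet) -> float:
    return float(columns.weights @ column_log_likelihoods(tree, model, columns))


# ---------------------------------------------------------------------------
# 4D site extraction


def _ref_position_index(blocks: list[AlignmentBlock], ref_species: str):
    """Map reference source offsets to (block, column) for every block."""
    index: dict[str, dict[int, tuple[int, int]]] = {}
    for bi, block in enumerate(blocks):
        ref = block.reference
        if ref.species_id != ref_species:
            continue
        seq_index = index.setdefault(ref.sequence_name, {})
        for ci, pos in enumerate(block.ref_positions()):
            if pos >= 0:
                seq_index[pos] = (bi, ci)
    return index


def extract_4d_columns(blocks: list[AlignmentBlock],
                       annotations: list[AnnotationRecord],
                       species_order: list[str],
                       ref_species: str) -> SiteColumnSet:
    """Third-position columns of fourfold-degenerate reference codons.

    The codon identity is read from the reference rows of the alignment
    (strand-aware); the emitted column is the alignment column at the third
    codon position, in `species_order`.  Codons that span block boundaries
    or fall outside the alignment are skipped and counted.
    """
    index = _ref_position_index(blocks, ref_species)
    gene_ids = sorted({
        r.gene_id or r.record_id for r in annotations if r.kind == "gene"
    })
    columns: list[str] = []
    skipped = 0
    for gid in gene_ids:
        cds = cds_of_gene(annotations, gid)
        if not cds:
            continue
        strand = cds[0].interval.strand
        coding_positions: list[int] = []
        for rec in cds:
            span = range(rec.interval.start, rec.interval.end)
            coding_positions.extend(reversed(span) if strand == "-" else span)
        for k in range(0, len(coding_positions) - 2, 3):
            codon_pos = coding_positions[k:k + 3]
            seq_index = index.get(cds[0].interval.sequence_name, {})
            located = [seq_index.get(p) for p in codon_pos]
            if any(loc is None for loc in located) or len(
                    {loc[0] for loc in located}) != 1:
                skipped += 1
                continue
            bi = located[0][0]
            block = blocks[bi]
            ref_text = block.reference.text
            codon = "".join(ref_text[ci] for _, ci in located)
            if strand == "-":
                codon = "".join(_COMPLEMENT[c] for c in codon)
            if codon[:2] not in FOURFOLD_PREFIXES:
                continue
            col_idx = located[2][1]
            col = []
            for sp in species_order:
                row = block.row_for(sp)
                col.append(row.text[col_idx] if row is not None else "N")
            columns.append("".join(col))
    if skipped:
        logger.info("extract_4d_columns: skipped %d codons at block "
                    "boundaries or unaligned positions", skipped)
    return SiteColumnSet.from_strings(species_order, columns)


# ---------------------------------------------------------------------------
# Neutral-model fitting


@dataclass
class FitResult:
    model: SubstitutionModel
    tree: PhyloTree
    log_likelihood: float
    n_iterations: int
    converged: bool


def fit_neutral_model(columns: SiteColumnSet, topology: PhyloTree,
                      max_sweeps: int = 20, tol: float = 1e-6,
                      branch_bounds: tuple[float, float] = (1e-6, 10.0),
                      ) -> FitResult:
    """ML fit of a GTR model and branch lengths on a fixed topology.

    Equilibrium frequencies are set to the empirical base frequencies;
    exchangeabilities (last one fixed to 1 for identifiability) and branch
    lengths are optimized by coordinate ascent until the total weighted
    log-likelihood improves by less than `tol`.
    """
    columns = columns.drop_uninformative().collapsed()
    if len(columns) == 0:
        raise ValueError("no usable columns")
    variable = np.any(
        (columns.codes != columns.codes[:, :1]) & (columns.codes != MISSING_CODE)
        & (columns.codes[:, :1] != MISSING_CODE), axis=1)
    pi = columns.base_frequencies()
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()

    tree = topology.copy()
    if not variable.any():
        for node in tree.branches():
            node.length = branch_bounds[0]
        model = SubstitutionModel(pi, np.ones(6))
        ll = total_log_likelihood(tree, model, columns)
        return FitResult(model, tree, ll, 0, True)

    exch = np.ones(6)
    for node in tree.branches():
        node.length = max(node.length, 0.05)

    def loglik(model):
        return total_log_likelihood(tree, model, columns)

    model = SubstitutionModel(pi, exch)
    ll = loglik(model)
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        prev = ll
        # branch lengths, one at a time (Brent within bounds)
        for node in tree.branches():
            def neg(t, node=node):
                node.length = t
                return -loglik(model)

            res = optimize.minimize_scalar(
                neg, bounds=branch_bounds, method="bounded",
                options={"xatol": 1e-7})
            node.length = float(res.x)
        # exchangeabilities in log space, last fixed at 1
        def neg_exch(logx):
            e = np.append(np.exp(logx), 1.0)
            return -loglik(SubstitutionModel(pi, e))

        res = optimize.minimize(
            neg_exch, np.log(model.exchangeabilities[:5]
                             / model.exchangeabilities[5]),
            method="L-BFGS-B", bounds=[(-8, 8)] * 5)
        exch = np.append(np.exp(res.x), 1.0)
        model = SubstitutionModel(pi, exch)
        ll = loglik(model)
        if ll - prev < tol:
            converged = True
            break
    return FitResult(model, tree, ll, sweep, converged)


# ---------------------------------------------------------------------------
# Relative rate test


@dataclass
class RateTestResult:
    m1: int
    m2: int
    chi2: float
    p_value: float
    n_excluded: int = 0


def relative_rate_test(seq_a: str, seq_b: str, seq_outgroup: str) -> RateTestResult:
    """Tajima-style relative rate test on three aligned sequences.

    m1 counts sites where a differs from the outgroup while b agrees with
    it; m2 is the mirror.  Under equal rates m1 and m2 are exchangeable and
    (m1-m2)^2/(m1+m2) is asymptotically chi-square with df=1.
    """
    if not (len(seq_a) == len(seq_b) == len(seq_outgroup)):
        raise ValueError("sequences must have equal length")
    m1 = m2 = excluded = 0
    for a, b, o in zip(seq_a.upper(), seq_b.upper(), seq_outgroup.upper()):
        if any(c not in BASE_INDEX for c in (a, b, o)):
            excluded += 1
            continue
        if a != o and b == o:
            m1 += 1
        elif b != o and a == o:
            m2 += 1
    if m1 + m2 > 0:
        chi2 = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    return RateTestResult(m1, m2, chi2, p, excluded)
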
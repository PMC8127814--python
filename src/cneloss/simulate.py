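"""Synthetic genomes, true alignments, annotations and truth tables.

Sequences evolve site-independently along a fixed tree under a reversible
substitution model; planted elements use the same model with branch lengths
scaled by rho < 1.  Lineage-specific deletions and assembly gaps (N-runs)
are planted structurally after evolution, so the true alignment and the
per-element truth table stay exact.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .formats import (AlignmentBlock, AnnotationRecord, BedRecord, GenomeSet,
                      Interval, MafRow, write_bed, write_fasta, write_gff3,
                      write_maf)
from .phylo import BASES, FOURFOLD_PREFIXES, PhyloTree, SubstitutionModel

# site evolution classes
INVARIANT, NEUTRAL_SITE, CONSERVED_SITE = 0, 1, 2

PRESENT, DELETED, GAP_OBSCURED = "present", "deleted", "gap_obscured"

MIN_FEATURE_SPACING = 20

DEFAULT_TREE = ("(Zv9:0.35,(hipCom0:0.22,((fr3:0.09,gasAcu1:0.08):0.05,"
                "(oryLat2:0.1,oreNil2:0.09):0.04):0.06):0.12);")


def default_tree() -> PhyloTree:
    try:
        text = (importlib.resources.files("cneloss") / "data" /
                "default_tree.nwk").read_text()
    except FileNotFoundError:
        text = DEFAULT_TREE
    return PhyloTree.from_newick(text)


@dataclass
class SimulationConfig:
    tree_newick: str = DEFAULT_TREE
    pi: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    exchangeabilities: tuple[float, ...] = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)
    rho_conserved: float = 0.3
    n_elements: int = 500
    element_length_mean: float = 168.0
    element_length_min: int = 30
    element_length_max: int = 500
    background_length: int = 200_000
    n_chromosomes: int = 1
    loss_plan: dict[str, int] = field(default_factory=dict)
    gap_plan: dict[str, int] = field(default_factory=dict)
    n_genes: int = 10
    gene_codons: int = 100  # internal codons per single-exon gene
    reference: str | None = None
    min_n_run: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rho_conserved <= 1:
            raise ValueError("rho_conserved must be in (0, 1]")
        if any(v < 0 for v in list(self.loss_plan.values())
               + list(self.gap_plan.values())):
            raise ValueError("plan counts must be >= 0")
        planned = sum(self.loss_plan.values()) + sum(self.gap_plan.values())
        if planned > self.n_elements:
            raise ValueError("loss+gap plans exceed element count")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pi", "exchangeabilities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["pi"] = list(self.pi)
        d["exchangeabilities"] = list(self.exchangeabilities)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def tree(self) -> PhyloTree:
        return PhyloTree.from_newick(self.tree_newick)

    def model(self) -> SubstitutionModel:
        return SubstitutionModel(self.pi, self.exchangeabilities)

    def reference_species(self) -> str:
        return self.reference or self.tree().leaf_names()[0]


@dataclass
class ElementTruth:
    name: str
    interval: Interval
    rho: float
    status: dict[str, str]  # non-reference species -> state


@dataclass
class TruthTable:
    elements: list[ElementTruth]

    def by_name(self) -> dict[str, ElementTruth]:
        return {e.name: e for e in self.elements}


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict[str, GenomeSet]
    blocks: list[AlignmentBlock]
    truth: TruthTable
    annotations: list[AnnotationRecord]


# ---------------------------------------------------------------------------
# feature placement


@dataclass
class _Slot:
    chrom: str
    start: int
    length: int
    kind: str  # element | gene
    strand: str = "+"


def _truncated_geometric_lengths(rng, n, mean, lo, hi):
    p = 1.0 / max(mean - lo + 1, 1.0)
    lengths = lo + rng.geometric(p, size=n) - 1
    return np.clip(lengths, lo, hi)


def place_features(config: SimulationConfig, rng) -> list[_Slot]:
    """Random non-overlapping placement of elements and genes over the
    chromosomes, with a minimum spacing between features."""
    elem_lengths = _truncated_geometric_lengths(
        rng, config.n_elements, config.element_length_mean,
        config.element_length_min, config.element_length_max)
    gene_length = 3 * config.gene_codons + 6
    kinds = (["element"] * config.n_elements + ["gene"] * config.n_genes)
    lengths = list(map(int, elem_lengths)) + [gene_length] * config.n_genes
    order = rng.permutation(len(kinds))
    # round-robin assignment of features to chromosomes
    per_chrom: dict[str, list[tuple[str, int]]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    chrom_names = sorted(per_chrom)
    for i, fi in enumerate(order):
        per_chrom[chrom_names[i % len(chrom_names)]].append(
            (kinds[fi], lengths[fi]))
    slots: list[_Slot] = []
    gene_count = 0
    for chrom in chrom_names:
        feats = per_chrom[chrom]
        total = sum(ln for _, ln in feats)
        free = config.background_length - total - \
            MIN_FEATURE_SPACING * (len(feats) + 1)
        if free < 0:
            raise ValueError(
                f"features exceed background length on {chrom}: "
                f"{total} bp of features in {config.background_length} bp")
        extra = rng.multinomial(free, np.full(len(feats) + 1,
                                              1.0 / (len(feats) + 1)))
        pos = 0
        for (kind, ln), pad in zip(feats, extra[:-1]):
            pos += MIN_FEATURE_SPACING + int(pad)
            strand = "+"
            if kind == "gene":
                strand = "+" if gene_count % 2 == 0 else "-"
                gene_count += 1
            slots.append(_Slot(chrom, pos, ln, kind, strand))
            pos += ln
    return slots


# ---------------------------------------------------------------------------
# gene planting


_FOURFOLD_PREFIX_LIST = sorted(FOURFOLD_PREFIXES)


def _build_orf(rng, n_codons: int) -> str:
    """Random ORF: ATG + fourfold-family codons + TAA.  No codon in the
    fourfold families is a stop, so the ORF is valid for any third base."""
    codons = ["ATG"]
    prefixes = rng.choice(len(_FOURFOLD_PREFIX_LIST), size=n_codons)
    thirds = rng.choice(4, size=n_codons)
    for pi, ti in zip(prefixes, thirds):
        codons.append(_FOURFOLD_PREFIX_LIST[pi] + BASES[ti])
    codons.append("TAA")
    return "".join(codons)


def plant_genes(config: SimulationConfig, rng=None,
                slots: list[_Slot] | None = None
                ) -> tuple[list[AnnotationRecord], dict[str, str],
                           dict[str, set[int]]]:
    """Design gene structures: annotation records, root-strand gene
    sequences per gene id, and per-chromosome genome positions of neutral
    (fourfold third) coding sites."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if slots is None:
        slots = place_features(config, rng)
    records: list[AnnotationRecord] = []
    gene_seqs: dict[str, str] = {}
    neutral_positions: dict[str, set[int]] = {}
    gi = 0
    for slot in slots:
        if slot.kind != "gene":
            continue
        gi += 1
        gid = f"gene{gi}"
        orf = _build_orf(rng, (slot.length - 6) // 3)
        gene_seqs[gid] = orf
        iv = Interval(slot.chrom, slot.start, slot.start + len(orf),
                      slot.strand)
        records.append(AnnotationRecord("gene", iv, record_id=gid,
                                        gene_id=gid))
        records.append(AnnotationRecord("mRNA", iv, record_id=f"{gid}.t1",
                                        parent=gid, gene_id=gid))
        records.append(AnnotationRecord("CDS", iv, record_id=f"{gid}.cds",
                                        parent=f"{gid}.t1", gene_id=gid,
                                        phase=0))
        # genome-forward coordinates of third positions of internal codons
        pos = neutral_positions.setdefault(slot.chrom, set())
        n_codons = (slot.length - 6) // 3
        for k in range(n_codons):
            coding_offset = 3 + 3 * k + 2  # third base of internal codon k
            if slot.strand == "+":
                pos.add(slot.start + coding_offset)
            else:
                pos.add(slot.start + len(orf) - 1 - coding_offset)
    return records, gene_seqs, neutral_positions


# ---------------------------------------------------------------------------
# sequence evolution


def _sample_markov(parent_states: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(len(parent_states))
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)


def _evolve_down(node, parent_seq, classes, model, rho, rng, leaves_out):
    for child in node.children:
        seq = parent_seq.copy()
        for cls, scale in ((NEUTRAL_SITE, 1.0), (CONSERVED_SITE, rho)):
            idx = np.nonzero(classes == cls)[0]
            if len(idx) == 0:
                continue
            P = model.transition_matrix(child.length * scale)
            seq[idx] = _sample_markov(seq[idx], P, rng)
        if child.is_leaf:
            leaves_out[child.name] = seq
        else:
            _evolve_down(child, seq, classes, model, rho, rng, leaves_out)


def evolve_alignment(config: SimulationConfig) -> SimulationResult:
    """Simulate genomes, the true alignment, annotations and the truth table."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree()
    model = config.model()
    ref = config.reference_species()
    if ref not in tree.leaf_names():
        raise ValueError(f"reference {ref!r} not a tree leaf")
    for sp in list(config.loss_plan) + list(config.gap_plan):
        if sp not in tree.leaf_names() or sp == ref:
            raise ValueError(f"plan species {sp!r} invalid")

    slots = place_features(config, rng)
    records, gene_seqs, neutral_cds_pos = plant_genes(config, rng, slots)
    base_index = {b: i for i, b in enumerate(BASES)}

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]

    leaf_order = tree.leaf_names()
    species_order = [ref] + [s for s in leaf_order if s != ref]

    all_elements: list[ElementTruth] = []
    rows_per_chrom: dict[str, dict[str, np.ndarray]] = {}

    gene_iter = iter(sorted(gene_seqs))
    gene_of_slot = {}
    for slot in slots:
        if slot.kind == "gene":
            gene_of_slot[id(slot)] = next(gene_iter)

    ei = 0
    for chrom in chrom_names:
        L = config.background_length
        root = rng.choice(4, size=L, p=np.asarray(config.pi)
                          / np.sum(config.pi)).astype(np.int8)
        classes = np.full(L, NEUTRAL_SITE, dtype=np.int8)
        for slot in [s for s in slots if s.chrom == chrom]:
            if slot.kind == "element":
                ei += 1
                classes[slot.start:slot.start + slot.length] = CONSERVED_SITE
                all_elements.append(ElementTruth(
                    name=f"elem{ei}",
                    interval=Interval(chrom, slot.start,
                                      slot.start + slot.length),
                    rho=config.rho_conserved,
                    status={sp: PRESENT for sp in species_order if sp != ref},
                ))
            else:
                gid = gene_of_slot[id(slot)]
                orf = gene_seqs[gid]
                forward = orf if slot.strand == "+" else _revcomp_str(orf)
                root[slot.start:slot.start + len(orf)] = [
                    base_index[b] for b in forward]
                classes[slot.start:slot.start + len(orf)] = INVARIANT
                for p in neutral_cds_pos.get(chrom, ()):
                    if slot.start <= p < slot.start + len(orf):
                        classes[p] = NEUTRAL_SITE
        leaves: dict[str, np.ndarray] = {}
        _evolve_down(tree.root, root, classes, model, config.rho_conserved,
                     rng, leaves)
        if tree.root.is_leaf:
            leaves[tree.root.name] = root
        rows_per_chrom[chrom] = {
            sp: leaves[sp].copy() for sp in species_order}

    # plan deletions and gaps over disjoint element subsets
    perm = rng.permutation(len(all_elements))
    cursor = 0
    plans: list[tuple[str, str, int]] = []  # (kind, species, element index)
    for sp in sorted(config.loss_plan):
        for _ in range(config.loss_plan[sp]):
            plans.append(("loss", sp, int(perm[cursor])))
            cursor += 1
    for sp in sorted(config.gap_plan):
        for _ in range(config.gap_plan[sp]):
            plans.append(("gap", sp, int(perm[cursor])))
            cursor += 1

    GAP_CODE, N_CODE = -1, 4
    for kind, sp, idx in plans:
        el = all_elements[idx]
        arr = rows_per_chrom[el.interval.sequence_name][sp]
        if kind == "loss":
            arr[el.interval.start:el.interval.end] = GAP_CODE
            el.status[sp] = DELETED
        else:
            arr[el.interval.start:el.interval.end] = N_CODE
            el.status[sp] = GAP_OBSCURED

    # materialize genomes and MAF blocks
    alphabet = np.array(list(BASES + "N-"))
    genomes: dict[str, GenomeSet] = {}
    seqs_per_species: dict[str, dict[str, str]] = {sp: {}
                                                   for sp in species_order}
    blocks: list[AlignmentBlock] = []
    for chrom in chrom_names:
        texts = {}
        for sp in species_order:
            arr = rows_per_chrom[chrom][sp]
            codes = np.where(arr == GAP_CODE, 5, arr)
            text = "".join(alphabet[codes])
            texts[sp] = text
            seqs_per_species[sp][chrom] = text.replace("-", "")
        rows = []
        for sp in species_order:
            ungapped = seqs_per_species[sp][chrom]
            rows.append(MafRow(
                species_id=sp, sequence_name=chrom, start=0,
                ungapped_size=len(ungapped), strand="+",
                source_length=len(ungapped), text=texts[sp]))
        blocks.append(AlignmentBlock(rows))
    for sp in species_order:
        genomes[sp] = GenomeSet(sp, seqs_per_species[sp],
                                min_n_run=config.min_n_run)

    all_elements.sort(key=lambda e: (e.interval.sequence_name,
                                     e.interval.start))
    for i, el in enumerate(all_elements):
        el.name = f"elem{i + 1}"
    return SimulationResult(config, genomes, blocks,
                            TruthTable(all_elements), records)


def _revcomp_str(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# fixture emission


def emit_fixtures(result: SimulationResult, directory) -> dict[str, str]:
    """Write FASTA per species, MAF, GFF3, truth BED/TSV and the tree;
    returns the manifest of written paths (all seed-deterministic)."""
    import os

    os.makedirs(directory, exist_ok=True)
    manifest: dict[str, str] = {}

    def path(name):
        p = os.path.join(directory, name)
        manifest[name] = p
        return p

    for sp, genome in sorted(result.genomes.items()):
        write_fasta(genome, path(f"{sp}.fa"))
    write_maf(result.blocks, path("alignment.maf"))
    write_gff3(result.annotations, path("genes.gff3"))
    write_bed(
        [BedRecord(el.interval, el.name, 0.0)
         for el in result.truth.elements],
        path("truth_elements.bed"))
    with open(path("truth_status.tsv"), "w") as fh:
        fh.write("element\tspecies\tstatus\n")
        for el in result.truth.elements:
            for sp in sorted(el.status):
                fh.write(f"{el.name}\t{sp}\t{el.status[sp]}\n")
    result.config.tree().write(path("tree.nwk"))
    result.config.to_yaml(path("config.yaml"))
    return manifest
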
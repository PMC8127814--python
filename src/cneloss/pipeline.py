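"""End-to-end orchestration: simulate -> fit neutral model -> estimate rho
-> call elements -> define CNEs -> classify presence -> call losses ->
enrichment, with a checksummed run manifest and resume support."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

from . import __version__
from .enrich import (assign_to_nearest_tss, gene_loss_counts,
                     hypergeometric_enrichment, read_term_map, tss_table,
                     write_enrichment_tsv)
from .formats import read_bed, read_gff3, read_maf, write_bed
from .hmm import (HmmParams, call_elements, define_cnes, elements_to_bed,
                  estimate_rho)
from .loss import (PRESENT_STATES, PresenceMatrix, call_unique_losses,
                   classify_presence, gap_free_syntenic_intervals,
                   write_loss_bed, write_syntenic_tsv)
from .phylo import extract_4d_columns, fit_neutral_model, load_model, save_model
from .simulate import SimulationConfig, emit_fixtures, evolve_alignment

logger = logging.getLogger(__name__)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    def __init__(self, path: str):
        self.path = path
        self.data = {"version": __version__, "stages": {}}
        if os.path.exists(path):
            try:
                self.data = json.load(open(path))
            except json.JSONDecodeError:
                logger.warning("unreadable manifest; starting fresh")

    def stage_done(self, name: str, outputs: list[str]) -> bool:
        info = self.data["stages"].get(name)
        if not info:
            return False
        for out in outputs:
            if not os.path.exists(out):
                return False
            if info["outputs"].get(out) != _sha256(out):
                return False
        return True

    def record(self, name: str, outputs: list[str], seconds: float) -> None:
        self.data["stages"][name] = {
            "outputs": {out: _sha256(out) for out in outputs},
            "seconds": round(seconds, 3),
        }
        self.save()

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: SimulationConfig, outdir: str,
                 gamma: float = 0.3, omega: float = 45.0,
                 terms_path: str | None = None,
                 resume: bool = False) -> RunManifest:
    """Run every stage, writing outputs and a manifest under `outdir`."""
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(os.path.join(outdir, "manifest.json"))
    manifest.data["seed"] = config.seed
    manifest.data["config"] = {
        k: getattr(config, k) for k in config.__dataclass_fields__}
    for key in ("pi", "exchangeabilities"):
        manifest.data["config"][key] = list(manifest.data["config"][key])
    params = HmmParams(target_coverage=gamma, expected_length=omega)

    def path(name):
        return os.path.join(outdir, name)

    def stage(name, outputs, fn):
        paths = [path(o) for o in outputs]
        if resume and manifest.stage_done(name, paths):
            logger.info("[%s] up to date; skipped", name)
            return
        t0 = time.time()
        logger.info("[%s] running", name)
        fn()
        for p in paths:
            if not os.path.exists(p):
                raise RuntimeError(f"stage {name} did not produce {p}")
        manifest.record(name, paths, time.time() - t0)

    species = config.tree().leaf_names()
    ref = config.reference_species()
    fixture_files = sorted(
        [f"{sp}.fa" for sp in species]
        + ["alignment.maf", "genes.gff3", "truth_elements.bed",
           "truth_status.tsv", "tree.nwk", "config.yaml"])

    state: dict = {}

    def load_inputs():
        from .formats import read_fasta
        state["blocks"] = read_maf(path("alignment.maf"))
        state["annotations"] = read_gff3(path("genes.gff3"))
        state["genomes"] = {
            sp: read_fasta(path(f"{sp}.fa"), species_id=sp,
                           min_n_run=config.min_n_run)
            for sp in species
        }

    stage("simulate", fixture_files,
          lambda: emit_fixtures(evolve_alignment(config), outdir))
    load_inputs()

    def fit():
        columns = extract_4d_columns(state["blocks"], state["annotations"],
                                     species, ref)
        result = fit_neutral_model(columns, config.tree())
        save_model(result.model, result.tree, path("model.json"))

    stage("fit_neutral", ["model.json"], fit)
    model, tree = load_model(path("model.json"))

    def rho_stage():
        est = estimate_rho(state["blocks"], model, tree, params)
        with open(path("rho.json"), "w") as fh:
            json.dump({"rho": est.rho, "per_chromosome": est.per_chromosome,
                       "at_boundary": est.at_boundary}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")

    stage("estimate_rho", ["rho.json"], rho_stage)
    rho = json.load(open(path("rho.json")))["rho"]

    def elements_stage():
        elements = call_elements(state["blocks"], model, tree, rho, params)
        write_bed(elements_to_bed(elements), path("elements.bed"))

    stage("call_elements", ["elements.bed"], elements_stage)

    def cnes_stage():
        from .formats import Interval
        elements = read_bed(path("elements.bed"))
        intervals = {r.name: r.interval for r in elements}
        matrix = classify_presence(intervals, state["blocks"],
                                   state["genomes"], ref, rescue=False)
        presence = {
            name: {sp: matrix.get(name, sp).state in PRESENT_STATES
                   for sp in matrix.species}
            for name in intervals
        }
        from .hmm import ConservedElement
        objs = [ConservedElement(r.interval, r.score, 0.0, r.name)
                for r in elements]
        cnes = define_cnes(objs, state["annotations"], presence)
        write_bed(elements_to_bed(cnes), path("cnes.bed"))

    stage("define_cnes", ["cnes.bed"], cnes_stage)

    def classify_stage():
        cnes = {r.name: r.interval for r in read_bed(path("cnes.bed"))}
        matrix = classify_presence(cnes, state["blocks"], state["genomes"],
                                   ref)
        matrix.to_tsv(path("matrix.tsv"))

    stage("classify", ["matrix.tsv"], classify_stage)

    def synteny_stage():
        intervals = []
        for sp in species:
            if sp == ref:
                continue
            intervals.extend(gap_free_syntenic_intervals(
                state["blocks"], state["genomes"], sp))
        write_syntenic_tsv(intervals, path("synteny.tsv"))

    stage("synteny", ["synteny.tsv"], synteny_stage)

    def losses_stage():
        from .loss import read_syntenic_tsv
        matrix = PresenceMatrix.from_tsv(path("matrix.tsv"))
        intervals = read_syntenic_tsv(path("synteny.tsv"))
        calls = call_unique_losses(matrix, intervals)
        write_loss_bed(calls, path("losses.bed"))

    stage("call_losses", ["losses.bed"], losses_stage)

    def enrich_stage():
        from .formats import Interval
        losses = {}
        for line in open(path("losses.bed")):
            f = line.rstrip("\n").split("\t")
            losses[f[3]] = Interval(f[0], int(f[1]), int(f[2]))
        tss = tss_table(state["annotations"])
        assignments = assign_to_nearest_tss(losses, tss)
        with open(path("gene_loss_counts.tsv"), "w") as fh:
            fh.write("gene\tn_lost\n")
            for gene, count in gene_loss_counts(assignments):
                fh.write(f"{gene}\t{count}\n")
        if terms_path is not None:
            term_map = read_term_map(terms_path)
        else:
            # fallback term map: split genes into two synthetic categories
            genes = sorted(tss)
            term_map = {
                "CAT:even": {g for i, g in enumerate(genes) if i % 2 == 0},
                "CAT:odd": {g for i, g in enumerate(genes) if i % 2 == 1},
            }
            logger.info("no term map supplied; using synthetic categories")
        universe = set(tss)
        sample = {a.gene for a in assignments if a.assigned}
        if sample:
            results = hypergeometric_enrichment(sample, term_map, universe)
        else:
            results = []
            logger.warning("no losses assigned to genes; empty enrichment")
        write_enrichment_tsv(results, path("enrichment.tsv"))

    stage("enrich", ["enrichment.tsv", "gene_loss_counts.tsv"], enrich_stage)
    manifest.save()
    return manifest
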
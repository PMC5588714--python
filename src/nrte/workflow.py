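"""End-to-end pipeline orchestration over the stage modules.

One `RunConfig` (YAML-loadable) drives simulate -> build-edges -> scan ->
landscape -> popgen -> gwas and aggregates a summary report. Every output
directory carries a provenance file (tool version, config hash, master
seed); a stage is re-used on rerun only when the recorded config hash
matches, so a fixed config is idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc, io, landscape, popgen, scan as scan_mod
from .edges import build_edge_db, write_edge_db
from .simulate import (SimConfig, TEMPERATE, TROPICAL, simulate_expression,
                       simulate_panel, simulate_phenotypes, simulate_reference)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "nrte_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)     # SimConfig overrides
    cluster_tolerance_bp: int = 10
    min_support: int = 1
    window_size: int = 1_000_000
    fst_B: int = 1000
    fst_L: int = 1000
    maf_min: float = 0.15
    gwas_alpha: float = 1.0
    n_pcs: int = 3
    ld_max_distance: int = 500_000
    ld_min_geno: float = 0.5
    ld_ci_reps: int = 100
    write_fastq: bool = False
    stages: tuple = ("simulate", "edges", "scan", "landscape", "popgen", "gwas")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kw = dict(self.sim)
        kw.setdefault("seed", self.seed)
        for key in ("n_lines_per_pop", "te_length_range"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return SimConfig(**kw)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location is not scientific config
        payload["stages"] = list(payload["stages"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the
    summary report (also written to <outdir>/report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"tool": "nrte", "version": __version__,
                  "config_hash": config.digest(), "seed": config.seed}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    report = {"provenance": provenance}
    sim_cfg = config.sim_config()

    # --- simulate -----------------------------------------------------
    reference = simulate_reference(sim_cfg)
    truth, reads_iter = simulate_panel(sim_cfg, reference)
    if "simulate" in config.stages:
        io.write_reference(reference, out / "reference")
        io.write_truth(truth, out / "truth")
        if config.write_fastq:
            (out / "reads").mkdir(exist_ok=True)
            for block in reads_iter():
                io.write_fastq(block, out / "reads" / f"{block.line_id}.fastq")
    phenotypes = simulate_phenotypes(truth, sim_cfg)
    expression = simulate_expression(truth, sim_cfg,
                                     list(reference.genes["gene_id"]))

    # --- edges --------------------------------------------------------
    te_classes = dict(zip(reference.te_meta["te_id"], reference.te_meta["te_class"]))
    edge_db = build_edge_db(reference.te_library, te_classes)
    if "edges" in config.stages:
        write_edge_db(edge_db, out / "te_edges.fa", out / "te_edges.tsv")
    report["n_edges"] = len(edge_db)

    # --- scan ---------------------------------------------------------
    scanner = scan_mod.JunctionScanner(edge_db, reference.chromosomes)
    hits = []
    for block in reads_iter():
        line_hits = scanner.scan_block(block)
        logger.info("scanned %s: %d reads, %d junction hits",
                    block.line_id, block.n_reads, len(line_hits))
        hits.extend(line_hits)
    loci, genotypes = scan_mod.cluster_hits(
        scan_mod.hits_to_frame(hits), lines=sim_cfg.line_ids,
        tolerance_bp=config.cluster_tolerance_bp,
        min_support=config.min_support)
    io.write_locus_report(loci, genotypes, out / "nrte_loci.tsv")
    n1, n2, n3 = scan_mod.sharing_spectrum(genotypes)
    freqs = scan_mod.population_frequencies(genotypes, truth.panel)
    report["scan"] = {
        "n_loci": int(len(loci)),
        "by_class": loci["te_class"].value_counts().to_dict(),
        "sharing": {"single_line": n1, "two_lines": n2, "three_plus": n3},
    }

    # --- landscape ----------------------------------------------------
    chrom_lengths = {c: len(s) for c, s in reference.chromosomes.items()}
    windows = landscape.make_windows(chrom_lengths, config.window_size)
    third = sim_cfg.chrom_length / 3
    peri = pd.DataFrame([(c, int(third), int(2 * third))
                         for c in chrom_lengths], columns=["chrom", "start", "end"])
    region = landscape.label_regions(windows, peri)
    nrte_track = landscape.window_density(
        loci.rename(columns={"position": "position"}), windows, chrom_lengths,
        name="nrte_per_mb", region=region)
    gene_pos = reference.genes.assign(
        position=(reference.genes["start"] + reference.genes["end"]) // 2)
    gene_track = landscape.window_density(gene_pos, windows, chrom_lengths,
                                          name="genes_per_mb", region=region)
    rate_track = landscape.gr_rate(reference.genetic_map, windows, region=region)
    corr_rows = []
    for other, label in ((gene_track, "gene_density"), (rate_track, "cm_per_mb")):
        for reg in ("all", "arms"):
            c = landscape.correlate_tracks(nrte_track, other, region=reg)
            corr_rows.append((label, reg, c.r, c.p_value, c.n))
    corr = pd.DataFrame(corr_rows, columns=["feature", "region", "r", "p", "n"])
    corr.to_csv(out / "landscape_correlations.tsv", sep="\t", index=False)
    contexts = landscape.classify_context(loci, reference.genes,
                                          reference.gene_features)
    report["landscape"] = {
        "correlations": corr.to_dict("records"),
        "context_counts": contexts.value_counts().to_dict(),
    }

    # --- popgen -------------------------------------------------------
    panel = truth.panel
    n_tem = int((panel == TEMPERATE).sum())
    n_tro = int((panel == TROPICAL).sum())
    genome_size = reference.genome_size
    spectra = {pop: popgen.spectrum(freqs[pop], genome_size, pop)
               for pop in (TEMPERATE, TROPICAL)}
    fst = popgen.resample_fst(freqs[TEMPERATE], n_tem, freqs[TROPICAL], n_tro,
                              B=config.fst_B, L=config.fst_L,
                              seed=_stage_seed(config.seed, "fst"))
    qst_res = popgen.qst(phenotypes, panel)
    call = popgen.qst_fst_call(qst_res.qst, fst)
    report["popgen"] = {
        "spectra": {p: asdict(s) for p, s in spectra.items()},
        "fst_mean": fst.mean, "fst_ci99": list(fst.ci99),
        "qst": qst_res.qst, "selection_regime": call.regime,
    }
    if "popgen" in config.stages:
        per_chrom_blocks = 0
        for chrom in chrom_lengths:
            on_chrom = loci[loci["chrom"] == chrom]
            if len(on_chrom) < 2:
                continue
            pos = on_chrom.set_index("locus_id")["position"]
            bset = popgen.ld_blocks(
                genotypes[on_chrom["locus_id"]], pos, chrom=chrom,
                max_distance=config.ld_max_distance,
                min_geno=config.ld_min_geno, ci_reps=config.ld_ci_reps,
                seed=_stage_seed(config.seed, f"ld:{chrom}"))
            per_chrom_blocks += len(bset.blocks)
        report["popgen"]["n_ld_blocks"] = per_chrom_blocks

    # --- gwas ---------------------------------------------------------
    trait = phenotypes.groupby("line")["trait"].mean()
    pca = assoc.pca_covariates(genotypes, k=config.n_pcs,
                               seed=_stage_seed(config.seed, "pca"))
    scan_table = assoc.gwas_scan(trait, genotypes, pca.scores,
                                 alpha=config.gwas_alpha,
                                 maf_min=config.maf_min, positions=loci)
    scan_table.to_csv(out / "gwas.tsv", sep="\t", index=False)
    report["gwas"] = {
        "n_markers_tested": int(len(scan_table)),
        "threshold": scan_table.attrs.get("threshold"),
        "n_significant": int(scan_table["significant"].sum()),
    }
    if len(truth.expression_effects):
        (gid, lid), _ = next(iter(truth.expression_effects.items()))
        expr_table = assoc.expression_assoc(expression, genotypes[lid]
                                            if lid in genotypes else truth.genotypes[lid])
        report["gwas"]["expression_example"] = {
            "locus": lid, "gene": gid,
            "p": float(expr_table.set_index("gene_id").loc[gid, "p"]),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
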
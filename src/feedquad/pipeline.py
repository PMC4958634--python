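"""End-to-end orchestration of the divergent-selection expression/CNV analysis.

Stages run in order: synth (optional) -> phenotypes -> diffexpr -> qpcr -> cnvcall ->
cnvr -> exprcall -> enrich. Every stage reads and writes plain-text intermediates in
the run directory, so any stage can be re-run in isolation, and the run report
records the count at every funnel stage (animals selected, DEGs, CNV calls, CNVRs,
CNV genes, expressed CNV genes, enriched categories).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnvcall, cnvr, diffexpr, enrich, exprcall, io, phenotypes, qpcr
from .synthdata import SimConfig, simulate_expression, simulate_gene_annotation, \
    simulate_phenotypes, simulate_qpcr, simulate_read_depth

log = logging.getLogger(__name__)

N_QPCR_GENES = 13


@dataclass
class PipelineConfig:
    """All stage parameters plus the simulation settings for the synth stage."""

    outdir: str = "feedquad_run"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    k_per_quadrant: int = 4
    max_per_breed: int = 2
    alpha: float = 0.05
    fdr_m: int | None = None          # platform size; None = number of genes tested
    overlap_t: float = 0.5
    min_windows: int = 3
    upc_threshold: float = 0.3
    genome_length: int | None = None  # default: sim genome length

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _simulate_category_map(genes: list[str], rng: np.random.Generator,
                           n_categories: int = 20) -> pd.DataFrame:
    """Random gene -> category annotation over the reference gene set."""
    cats = [f"BP{c + 1:02d}" for c in range(n_categories)]
    rows = []
    for g in genes:
        for c in rng.choice(n_categories, size=rng.integers(0, 4), replace=False):
            rows.append({"gene": g, "category": cats[int(c)]})
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to report.json).

    On a stage failure a ``FAILED_<stage>`` marker file is left next to the partial
    outputs and the exception is re-raised.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    stage = "setup"
    try:
        if config.simulate:
            stage = "synth"
            t0 = time.perf_counter()
            cfg = config.sim
            pheno = simulate_phenotypes(cfg)
            io.write_phenotypes(pheno, out / "phenotypes.tsv")
            expr, truth_de = simulate_expression(cfg)
            io.write_matrix(expr, out / "expression.tsv", "gene")
            pd.Series(expr.attrs["quadrants"]).rename("quadrant").to_csv(
                out / "sample_map.tsv", sep="\t", index_label="sample"
            )
            de_truth = pd.DataFrame(
                [
                    {"gene": g, "eff_HH": e[0], "eff_HL": e[1], "eff_LL": e[2], "eff_LH": e[3]}
                    for g, e in sorted(truth_de.de_effects.items())
                ]
            )
            io.write_tsv(de_truth, out / "truth_de_genes.tsv")
            windows, counts, truth_cnv = simulate_read_depth(cfg)
            depth = windows.join(counts)
            io.write_tsv(depth, out / "read_depth.tsv")
            if not truth_cnv.implanted_cnvs.empty:
                io.write_bed3(truth_cnv.implanted_cnvs, out / "truth_cnvs.bed", ["sample", "cn"])
            genes_ann = simulate_gene_annotation(cfg)
            io.write_gff3(genes_ann, out / "genes.gff3")
            qpcr_genes = list(expr.index[: N_QPCR_GENES])
            io.write_tsv(simulate_qpcr(expr, qpcr_genes, cfg), out / "qpcr_cq.tsv")
            catmap = _simulate_category_map(list(expr.index), cfg.rng("genes"))
            io.write_tsv(catmap, out / "category_map.tsv")
            log.info("synth stage done in %.1fs", time.perf_counter() - t0)

        stage = "phenotypes"
        t0 = time.perf_counter()
        pheno = io.read_phenotypes(out / "phenotypes.tsv")
        pheno["gain_total"] = [
            phenotypes.fit_gain(w, a).gain_total
            for w, a in zip(pheno["weights"], pheno["animal_id"])
        ]
        pheno["dominant_breed"] = pheno["breed_fractions"].map(phenotypes.dominant_breed)
        ranked = phenotypes.rank_bivariate(pheno)
        selected = phenotypes.select_divergent(ranked, config.k_per_quadrant, config.max_per_breed)
        io.write_tsv(
            selected.drop(columns=["weights", "breed_fractions"]), out / "selection.tsv"
        )
        io.write_tsv(phenotypes.group_summary(selected), out / "group_summary.tsv")
        report["stages"]["animals_selected"] = int(len(selected))
        log.info("phenotypes stage done in %.1fs", time.perf_counter() - t0)

        stage = "diffexpr"
        t0 = time.perf_counter()
        expr = io.read_matrix(out / "expression.tsv")
        sample_map = pd.read_csv(out / "sample_map.tsv", sep="\t", index_col=0)["quadrant"]
        de = diffexpr.fit_quadrant_model(expr, sample_map)
        de["q"] = diffexpr.adjust_fdr(de["p_overall"].to_numpy(), m=config.fdr_m)
        io.write_matrix(de, out / "de_results.tsv", "gene")
        report["stages"]["de_genes"] = int((de["p_overall"] < config.alpha).sum())
        report["stages"]["de_genes_gain"] = int(
            ((de["p_overall"] < config.alpha) & (de["p_gain"] < config.alpha)).sum()
        )
        log.info("diffexpr stage done in %.1fs", time.perf_counter() - t0)

        stage = "qpcr"
        t0 = time.perf_counter()
        cq = io.read_tsv(out / "qpcr_cq.tsv")
        lfc = qpcr.livak(cq)
        quad_of = sample_map.to_dict()
        qpcr_means = lfc.T.groupby(lfc.columns.map(quad_of)).mean().T
        array_means = de[[f"lsmean_{q}" for q in phenotypes.QUADRANTS]].copy()
        array_means.columns = list(phenotypes.QUADRANTS)
        conc = qpcr.concordance(qpcr_means, array_means)
        io.write_matrix(conc, out / "qpcr_concordance.tsv", "gene")
        report["stages"]["qpcr_concordant"] = int(
            conc["concordance_class"].isin(["high", "moderate"]).sum()
        )
        log.info("qpcr stage done in %.1fs", time.perf_counter() - t0)

        stage = "cnvcall"
        t0 = time.perf_counter()
        depth = io.read_tsv(out / "read_depth.tsv")
        windows = depth[["chrom", "start", "end"]].copy()
        windows["chrom"] = windows["chrom"].astype(str)
        counts = depth.drop(columns=["chrom", "start", "end"])
        calls = cnvcall.call_cnvs(windows, counts, min_windows=config.min_windows)
        io.write_calls_bed(calls, out / "cnv_calls.bed")
        report["stages"]["cnv_calls"] = int(len(calls))
        log.info("cnvcall stage done in %.1fs", time.perf_counter() - t0)

        stage = "cnvr"
        t0 = time.perf_counter()
        regions = cnvr.build_cnvrs(calls, t=config.overlap_t)
        genome_length = config.genome_length or config.sim.genome_length
        if regions:
            summary = cnvr.summarize(regions, genome_length)
            io.write_tsv(pd.DataFrame([dataclasses.asdict(summary)]), out / "cnvr_summary.tsv")
        regions_df = pd.DataFrame(
            [
                {"chrom": r.chrom, "start": r.start, "end": r.end,
                 "n_samples": r.n_samples, "type": r.type}
                for r in regions
            ]
        )
        if len(regions_df):
            io.write_bed3(regions_df, out / "cnvrs.bed", ["n_samples", "type"])
        annotation = io.read_gene_annotation(out / "genes.gff3")
        cnv_genes = cnvr.overlap_genes(regions, annotation)
        io.write_gene_list(cnv_genes, out / "cnv_genes.txt")
        report["stages"]["cnvrs"] = int(len(regions))
        report["stages"]["cnv_genes"] = int(len(cnv_genes))
        log.info("cnvr stage done in %.1fs", time.perf_counter() - t0)

        stage = "exprcall"
        t0 = time.perf_counter()
        scores = exprcall.activity_scores(expr)
        io.write_matrix(scores, out / "activity_scores.tsv", "gene")
        expressed = exprcall.expressed_genes(scores, config.upc_threshold)
        io.write_gene_list(expressed, out / "expressed_genes.txt")
        expressed_cnv = exprcall.expressed_cnv_genes(expressed, cnv_genes)
        io.write_gene_list(expressed_cnv, out / "expressed_cnv_genes.txt")
        report["stages"]["expressed_cnv_genes"] = int(len(expressed_cnv))
        log.info("exprcall stage done in %.1fs", time.perf_counter() - t0)

        stage = "enrich"
        t0 = time.perf_counter()
        catmap = io.read_tsv(out / "category_map.tsv")
        target = expressed_cnv if expressed_cnv else expressed
        rows = enrich.overrepresentation(target, catmap, reference_size=len(expr))
        if len(rows):
            io.write_tsv(rows, out / "enrichment.tsv")
            report["stages"]["enriched_categories"] = int(rows["significant"].sum())
        else:
            report["stages"]["enriched_categories"] = 0
        log.info("enrich stage done in %.1fs", time.perf_counter() - t0)

    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise

    io.write_json(report, out / "report.json")
    lines = ["feedquad run report", "==================="] + [
        f"{k:>22s}: {v}" for k, v in report["stages"].items()
    ]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
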
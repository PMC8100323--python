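"""End-to-end orchestration of the synthetic analysis pipeline.

Stages run in dependency order: simulate -> edscan -> annotate ->
diff_expr -> integrate -> qpcr -> physiology.  Every stage is a pure
function of (inputs, parameters, seed), so re-running with the same
config reproduces byte-identical primary outputs; a JSON manifest
records per-stage outputs with SHA-256 checksums and record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_expr, integrate, physiology, pool_ed, synthetic_data, validation
from . import variant_annot
from .synthetic_data import SimulationConfig

__all__ = ["RunConfig", "StageError", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "edscan",
    "annotate",
    "diff_expr",
    "integrate",
    "qpcr",
    "physiology",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``.stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: str
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_depth: int = 10
    ed_min: float = 0.3
    top_q: float = 0.05
    upstream_window: int = 3000
    downstream_window: int = 3000
    alpha: float = 0.05
    lfc_min: float = 1.0
    calibrator_mode: str = "control_within_timepoint"
    survival_day: int = 120
    n_heat_responsive: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.top_q < 1:
            raise ValueError("top_q must be in (0, 1)")
        if self.ed_min < 0 or self.min_depth < 0:
            raise ValueError("ed_min and min_depth must be non-negative")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_kwargs = raw.pop("sim", {}) or {}
        return cls(sim=SimulationConfig(**sim_kwargs), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "sim"
        },
        "sim": dataclasses.asdict(config.sim),
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "status": "complete",
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            "record_counts": counts,
        }

    cfg = config.sim

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        genome, genes = synthetic_data.gen_genome_and_genes(cfg)
        variants, snp_truth = synthetic_data.gen_pool_variants(cfg, genes, genome=genome)
        counts, groups, de_truth = synthetic_data.gen_expression(
            cfg, gene_ids=[g.gene_id for g in genes]
        )
        qpcr = synthetic_data.gen_qpcr(
            cfg, genotype_effects={"CC": -1.5, "CT": -0.5, "TT": 0.0}
        )
        traces = synthetic_data.gen_respirometry_cohort(cfg)
        survival = synthetic_data.gen_survival(cfg)
        reads = synthetic_data.gen_reads(cfg)
        # heat-responsive reference list: a deterministic slice of the gene
        # universe enriched for true DE genes (stands in for the published
        # list, which is a user input in real runs)
        rng = np.random.default_rng([cfg.seed, 99])
        de_ids = sorted(de_truth.de_gene_ids)
        others = sorted(set(g.gene_id for g in genes) - set(de_ids))
        n_de_part = min(len(de_ids), config.n_heat_responsive // 2)
        heat_list = sorted(
            list(rng.choice(de_ids, size=n_de_part, replace=False))
            + list(rng.choice(others, size=config.n_heat_responsive - n_de_part,
                              replace=False))
        )
        p = {name: out / name for name in (
            "genome.fa", "genes.gff3", "variants.vcf", "truth_snps.tsv",
            "counts.tsv", "groups.tsv", "truth_de.tsv", "qpcr.tsv",
            "respirometry.tsv", "survival.tsv", "reads.fastq", "heat_list.txt",
        )}
        synthetic_data.write_fasta(genome, p["genome.fa"])
        synthetic_data.write_gff3(genes, p["genes.gff3"])
        synthetic_data.write_vcf(
            variants, p["variants.vcf"],
            contig_lengths={c: len(s) for c, s in genome.items()},
        )
        _write_tsv(snp_truth.selected_frame(), p["truth_snps.tsv"])
        _write_tsv(counts, p["counts.tsv"], index=True)
        _write_tsv(groups.rename_axis("sample").reset_index(), p["groups.tsv"])
        _write_tsv(de_truth.de_frame(), p["truth_de.tsv"])
        _write_tsv(qpcr, p["qpcr.tsv"])
        _write_tsv(traces, p["respirometry.tsv"])
        _write_tsv(survival, p["survival.tsv"])
        synthetic_data.write_fastq(reads, p["reads.fastq"])
        p["heat_list.txt"].write_text("".join(g + "\n" for g in heat_list))
        record(stage, p, {"genes": len(genes), "snps": len(variants),
                          "expr_genes": len(counts), "reads": len(reads)})
    except Exception as e:  # noqa: BLE001 - halt with the failing stage named
        raise StageError(stage, e) from e

    # -- edscan ------------------------------------------------------------
    stage = "edscan"
    try:
        vcf_variants = pool_ed.read_pooled_vcf(str(out / "variants.vcf"))
        table = pool_ed.ed_table(
            vcf_variants, min_depth=config.min_depth, ed_min=config.ed_min,
            top_q=config.top_q,
        )
        pool_ed.write_ed_table(table, str(out / "ed_scan.tsv"))
        retained = pool_ed.ed_scan(
            vcf_variants, min_depth=config.min_depth, ed_min=config.ed_min
        )
        outliers = pool_ed.top_percentile(retained, q=config.top_q)
        hist = pool_ed.ed_class_histogram(retained) if retained else {}
        (out / "ed_histogram.json").write_text(json.dumps(hist, indent=2, sort_keys=True))
        record(stage, {"ed_scan.tsv": out / "ed_scan.tsv",
                       "ed_histogram.json": out / "ed_histogram.json"},
               {"sites": len(vcf_variants), "retained": len(retained),
                "outliers": len(outliers)})
    except Exception as e:
        raise StageError(stage, e) from e

    # -- annotate ----------------------------------------------------------
    stage = "annotate"
    try:
        genome = variant_annot.load_genome(str(out / "genome.fa"))
        gene_models = variant_annot.load_gene_models(str(out / "genes.gff3"))
        index = variant_annot.build_interval_index(gene_models)
        by_id = {v.variant_id: v for v in vcf_variants}
        annotated = [
            variant_annot.classify_variant(
                by_id[r.variant_id], index, genome,
                upstream_window=config.upstream_window,
                downstream_window=config.downstream_window, ed=r.ed,
            )
            for r in outliers
        ]
        ann_df = pd.DataFrame(
            [(a.variant_id, a.chrom, a.pos, a.ref, a.alt, a.ed,
              a.functional_class, a.gene_id or "", a.distance)
             for a in annotated],
            columns=["snp_id", "chrom", "pos", "ref", "alt", "ed",
                     "class", "gene_id", "distance"],
        )
        _write_tsv(ann_df, out / "annotated_outliers.tsv")
        record(stage, {"annotated_outliers.tsv": out / "annotated_outliers.tsv"},
               {"outliers_annotated": len(annotated)})
    except Exception as e:
        raise StageError(stage, e) from e

    # -- diff_expr ---------------------------------------------------------
    stage = "diff_expr"
    try:
        tally = diff_expr.filter_fastq(
            str(out / "reads.fastq"), str(out / "reads.clean.fastq"),
            adaptor=cfg.adaptor,
        )
        counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="gene_id")
        groups = pd.read_csv(out / "groups.tsv", sep="\t", index_col="sample")["group"]
        de = diff_expr.de_test(
            counts, groups, alpha=config.alpha, lfc_min=config.lfc_min
        )
        _write_tsv(de.rename_axis("gene_id").reset_index(), out / "de_results.tsv")
        n_up, n_down = diff_expr.up_down_counts(de)
        record(stage, {"de_results.tsv": out / "de_results.tsv",
                       "reads.clean.fastq": out / "reads.clean.fastq"},
               {"reads_kept": tally.kept, "reads_removed": tally.removed,
                "degs_up": n_up, "degs_down": n_down})
    except Exception as e:
        raise StageError(stage, e) from e

    # -- integrate ---------------------------------------------------------
    stage = "integrate"
    try:
        outlier_genes = integrate.genes_with_outlier_snps(annotated)
        degs = integrate.deg_gene_set(de, universe=[g.gene_id for g in gene_models])
        candidates = integrate.intersect_sets(outlier_genes, degs, name="candidates")
        heat = integrate.heat_responsive_overlap(
            degs, (out / "heat_list.txt").read_text().split()
        )
        summary = {
            "ed_outlier_genes": outlier_genes.cardinality,
            "degs": degs.cardinality,
            "candidates": candidates.cardinality,
            "heat_responsive_degs": heat.cardinality,
        }
        candidates.write(str(out / "candidate_genes.txt"))
        (out / "integration_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        record(stage, {"candidate_genes.txt": out / "candidate_genes.txt",
                       "integration_summary.json": out / "integration_summary.json"},
               summary)
    except Exception as e:
        raise StageError(stage, e) from e

    # -- qpcr --------------------------------------------------------------
    stage = "qpcr"
    try:
        ct = pd.read_csv(out / "qpcr.tsv", sep="\t")
        rq = validation.rq_table(ct, calibrator_mode=config.calibrator_mode)
        _write_tsv(rq, out / "qpcr_rq.tsv")
        basal = validation.basal_expression_compare(rq)
        _write_tsv(basal, out / "qpcr_basal.tsv")
        geno = {
            gene: validation.genotype_expression_test(sub[sub["timepoint"] == 0])
            for gene, sub in rq.groupby("gene")
        }
        (out / "qpcr_genotype.json").write_text(
            json.dumps(geno, indent=2, sort_keys=True)
        )
        record(stage, {"qpcr_rq.tsv": out / "qpcr_rq.tsv",
                       "qpcr_basal.tsv": out / "qpcr_basal.tsv",
                       "qpcr_genotype.json": out / "qpcr_genotype.json"},
               {"measurements": len(rq)})
    except Exception as e:
        raise StageError(stage, e) from e

    # -- physiology --------------------------------------------------------
    stage = "physiology"
    try:
        traces = pd.read_csv(out / "respirometry.tsv", sep="\t")
        rates = physiology.rates_by_subject(traces)
        _write_tsv(rates, out / "respiration_rates.tsv")
        comparison = physiology.compare_rates(rates)
        survival = pd.read_csv(out / "survival.tsv", sep="\t")
        surv = physiology.survival_summary(survival, day=config.survival_day)
        (out / "physiology_summary.json").write_text(
            json.dumps({"respiration": comparison, "survival": surv},
                       indent=2, sort_keys=True)
        )
        record(stage, {"respiration_rates.tsv": out / "respiration_rates.tsv",
                       "physiology_summary.json": out / "physiology_summary.json"},
               {"subjects": len(rates)})
    except Exception as e:
        raise StageError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
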
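"""Generator contracts: determinism, conservation, distributional sanity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermosel import pool_ed
from thermosel.synthetic_data import (
    SimulationConfig,
    gen_expression,
    gen_genome_and_genes,
    gen_pool_variants,
    gen_qpcr,
    gen_reads,
    gen_respirometry,
    gen_survival,
    write_fasta,
    write_fastq,
    write_gff3,
    write_vcf,
)


class TestGenomeAndGenes:
    def test_zero_genes_gives_genome_only(self):
        genome, genes = gen_genome_and_genes(SimulationConfig(seed=1, n_genes=0))
        assert genes == [] and len(genome) == 2

    def test_gene_count_and_no_overlap(self, small_genome):
        genome, genes = small_genome
        assert len(genes) == 12
        assert {g.strand for g in genes} == {"+", "-"}
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] < b[0] for a, b in zip(ivs, ivs[1:]))

    def test_cds_length_divisible_by_three(self, small_genome):
        _, genes = small_genome
        for g in genes:
            assert g.exons
            assert sum(e - s + 1 for s, e in g.cds) % 3 == 0

    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            cfg = SimulationConfig(seed=42, n_genes=6, chrom_length=60_000)
            genome, genes = gen_genome_and_genes(cfg)
            write_fasta(genome, tmp_path / f"{sub}.fa")
            write_gff3(genes, tmp_path / f"{sub}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_genome_too_small_is_an_error(self):
        with pytest.raises(ValueError, match="too small"):
            gen_genome_and_genes(
                SimulationConfig(seed=1, n_chromosomes=1, chrom_length=20_000,
                                 n_genes=10)
            )


class TestPoolVariants:
    def test_no_selection_means_empty_truth(self):
        cfg = SimulationConfig(seed=2, n_snps=200, frac_selected=0.0)
        _, truth = gen_pool_variants(cfg)
        assert truth.selected_snp_ids == frozenset()

    def test_exact_selected_count(self):
        cfg = SimulationConfig(seed=2, n_snps=1000, frac_selected=0.05)
        variants, truth = gen_pool_variants(cfg)
        assert len(variants) == 1000
        assert len(truth.selected_snp_ids) == 50
        assert truth.selected_snp_ids <= {v.variant_id for v in variants}

    def test_ed_at_selected_loci_approaches_closed_form_at_high_depth(self):
        """At depth 1e6 sampling noise vanishes: ED at selected loci is
        ~ sqrt(2) * delta_f = 0.7071 (away from frequency clamping)."""
        cfg = SimulationConfig(seed=8, n_snps=600, frac_selected=0.5,
                               delta_f=0.5, mean_depth=1e6)
        variants, truth = gen_pool_variants(cfg)
        eds = []
        for v in variants:
            if v.variant_id not in truth.selected_snp_ids:
                continue
            f1, f2 = pool_ed.allele_frequencies(v, min_depth=1)
            shared = f2[1]
            if not 0.05 <= shared <= 0.45 and not 0.55 <= shared <= 0.95:
                continue  # clamped shifts distort |delta f|
            if abs(f1[1] - f2[1]) < 0.49:  # keep unclamped shifts only
                continue
            eds.append(pool_ed.compute_ed(f1, f2))
        assert len(eds) > 50
        assert np.mean(eds) == pytest.approx(math.sqrt(2) * 0.5, abs=1e-3)

    def test_vcf_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_snps=50)
        variants, _ = gen_pool_variants(cfg)
        path = tmp_path / "v.vcf"
        write_vcf(variants, path)
        back = pool_ed.read_pooled_vcf(str(path))
        assert [(v.chrom, v.pos, v.ref, v.alts, v.depths_pool1, v.depths_pool2)
                for v in sorted(variants, key=lambda x: (x.chrom, x.pos))] == [
            (v.chrom, v.pos, v.ref, v.alts, v.depths_pool1, v.depths_pool2)
            for v in back
        ]

    def test_neutral_ed_matches_neutral_sampling_distribution(self):
        """With no selection, observed EDs are indistinguishable (KS) from
        a direct re-simulation of the neutral binomial sampling process."""
        cfg = SimulationConfig(seed=17, n_snps=5000, frac_selected=0.0, mean_depth=82)
        variants, _ = gen_pool_variants(cfg)
        eds = []
        for v in variants:
            f1, f2 = pool_ed.allele_frequencies(v, min_depth=1)
            eds.append(pool_ed.compute_ed(f1, f2))
        rng = np.random.default_rng(4)  # independent oracle simulation
        p = rng.uniform(0.05, 0.95, size=5000)
        d1 = np.maximum(rng.poisson(82, 5000), 1)
        d2 = np.maximum(rng.poisson(82, 5000), 1)
        f1 = rng.binomial(d1, p) / d1
        f2 = rng.binomial(d2, p) / d2
        ref_eds = math.sqrt(2) * np.abs(f1 - f2)
        assert stats.ks_2samp(eds, ref_eds).pvalue > 0.01


class TestExpression:
    def test_no_de_means_empty_truth(self):
        _, _, truth = gen_expression(SimulationConfig(seed=4, frac_de=0.0))
        assert truth.de_gene_ids == {}

    def test_three_vs_three_layout(self):
        counts, groups, _ = gen_expression(SimulationConfig(seed=4))
        assert counts.shape[1] == 6
        assert (groups == "selected").sum() == 3 and (groups == "control").sum() == 3

    def test_truth_split_up_down(self):
        cfg = SimulationConfig(seed=4, n_genes=100, frac_de=0.2, lfc_effect=2.0)
        _, _, truth = gen_expression(cfg)
        lfcs = list(truth.de_gene_ids.values())
        assert len(lfcs) == 20
        assert sorted(set(lfcs)) == [-2.0, 2.0]


class TestQpcr:
    def test_three_timepoints_per_sample(self):
        df = gen_qpcr(SimulationConfig(seed=5), genotype_effects={"CC": 0.0})
        per_sample = df.groupby("sample")["timepoint"].agg(lambda t: sorted(set(t)))
        assert all(tp == [0, 12, 24] for tp in per_sample)

    def test_unknown_genotype_label_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype"):
            gen_qpcr(SimulationConfig(seed=5), genotype_effects={"CC": 0.0},
                     genotypes=["CC", "XX"])

    def test_null_effects_give_mean_rq_one(self):
        """All effects zero: RQ fluctuates around 1 within Monte-Carlo error."""
        from thermosel.validation import rq_table

        cfg = SimulationConfig(seed=6, qpcr_noise_sd=0.2)
        df = gen_qpcr(
            cfg, genotype_effects={"NN": 0.0}, n_per_group=40,
            group_basal={"selected": 0.0, "control": 0.0},
            induction={g: {0: 0.0, 12: 0.0, 24: 0.0} for g in ("selected", "control")},
        )
        rq = rq_table(df)
        mean_log2 = np.log2(rq["rq"]).mean()
        assert abs(mean_log2) < 0.1

    def test_one_cycle_effect_doubles_rq(self):
        """Lowering target ΔCt by one cycle doubles relative expression."""
        from thermosel.validation import rq_table

        cfg = SimulationConfig(seed=7, qpcr_noise_sd=0.05)
        df = gen_qpcr(
            cfg, genotype_effects={"NN": 0.0}, n_per_group=60,
            group_basal={"selected": -1.0, "control": 0.0},
            induction={g: {0: 0.0, 12: 0.0, 24: 0.0} for g in ("selected", "control")},
        )
        rq = rq_table(df)
        sel = rq[(rq["group"] == "selected") & (rq["timepoint"] == 0)]
        assert 2.0 ** np.log2(sel["rq"]).mean() == pytest.approx(2.0, rel=0.05)


class TestRespirometry:
    def test_cadence_and_length(self):
        trace = gen_respirometry(SimulationConfig(seed=8))
        assert len(trace) == 1801
        assert np.all(np.diff(trace["time_s"]) == 3)

    def test_noiseless_trace_is_exactly_linear(self):
        cfg = SimulationConfig(seed=8, trace_noise_sd=0.0, respiration_rate_true=0.0012)
        trace = gen_respirometry(cfg, group="selected")
        slopes = np.diff(trace["o2_mg_per_ml"]) / np.diff(trace["time_s"] / 3600.0)
        assert np.allclose(slopes, -0.0012, atol=1e-15)

    def test_zero_rate_constant_trace(self):
        cfg = SimulationConfig(seed=8, trace_noise_sd=0.0)
        trace = gen_respirometry(cfg, rate=0.0)
        assert trace["o2_mg_per_ml"].nunique() == 1


class TestSurvival:
    def test_full_survival(self):
        cfg = SimulationConfig(seed=9, survival_p_selected=1.0, survival_p_control=1.0)
        df = gen_survival(cfg)
        assert (df["n_alive"] == 100).all()

    def test_monotone_non_increasing_within_cage(self):
        df = gen_survival(SimulationConfig(seed=9))
        for _, sub in df.groupby("cage"):
            alive = sub.sort_values("day")["n_alive"].to_numpy()
            assert np.all(np.diff(alive) <= 0)

    def test_group_means_recover_truth_within_binomial_error(self):
        df = gen_survival(SimulationConfig(seed=10))
        final = df[df["day"] == 120].groupby("group")["n_alive"].mean() / 100.0
        # 3 cages x 100: se of the mean ~ sqrt(p(1-p)/300) ~ 0.026; allow 3 se
        assert abs(final["selected"] - 0.73) < 0.08
        assert abs(final["control"] - 0.62) < 0.08


class TestReads:
    def test_all_clean_when_no_bad_fractions(self):
        reads = gen_reads(SimulationConfig(seed=11), n_reads=50,
                          frac_adaptor=0, frac_high_n=0, frac_lowq=0)
        assert all(r.id.endswith(":keep") for r in reads)

    def test_tagged_fates_counted(self):
        reads = gen_reads(SimulationConfig(seed=11), n_reads=200,
                          frac_adaptor=0.1, frac_high_n=0.1, frac_lowq=0.1)
        fates = pd.Series([r.id.split(":")[1] for r in reads]).value_counts()
        assert fates["adaptor"] == fates["highN"] == fates["lowq"] == 20

    def test_same_seed_byte_identical_fastq(self, tmp_path):
        for sub in ("a", "b"):
            reads = gen_reads(SimulationConfig(seed=12), n_reads=100)
            write_fastq(reads, tmp_path / f"{sub}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            gen_reads(SimulationConfig(seed=11), frac_adaptor=0.5, frac_high_n=0.4,
                      frac_lowq=0.2)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_selected=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(mean_depth=0)
    with pytest.raises(ValueError):
        SimulationConfig(trace_noise_sd=-1)
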
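"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study conditions of a two-population
selection experiment on Pacific oyster: a thermotolerance-selected pool
and a control pool sequenced at ~82x each, larval RNA-seq with three
replicates per group, adult qPCR around a heat-shock time course,
closed-chamber respirometry traces sampled every 3 s for 1.5 h, and a
summer field survival trial with 3 cages of 100 animals per group.

Every generator is a pure function of (config, seed): the same
configuration produces byte-identical output files.  Each dataset is
accompanied by a machine-readable truth table so recovery tests can
score the pipeline against the generating parameters.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pool_ed import PooledVariant
from .variant_annot import GeneModel

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "gen_genome_and_genes",
    "gen_pool_variants",
    "gen_expression",
    "gen_qpcr",
    "gen_respirometry",
    "gen_respirometry_cohort",
    "gen_survival",
    "gen_reads",
    "write_fasta",
    "write_gff3",
    "write_vcf",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))

# Distinct RNG streams per generator so adding SNPs never perturbs counts etc.
_STREAMS = {
    "genome": 1,
    "variants": 2,
    "expression": 3,
    "qpcr": 4,
    "respirometry": 5,
    "survival": 6,
    "reads": 7,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the experiment's defaults.

    Defaults mirror the real design: pooled depth 82x per pool, 3 RNA-seq
    replicates per group, O2 sampled every 3 s for 1.5 h, respiration
    rates 0.0012 (selected) vs 0.0006 (control) mg/mL/h at 20 degC, and
    summer survival probabilities 0.73 vs 0.62 over 3 cages x 100
    animals.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 40
    n_snps: int = 2_000
    frac_selected: float = 0.05
    delta_f: float = 0.5
    mean_depth: float = 82.0
    n_reps_per_group: int = 3
    frac_de: float = 0.10
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.05
    respiration_rate_true: float = 0.0012  # mg/mL/h, selected group at 20 degC
    respiration_rate_control: float = 0.0006  # mg/mL/h
    trace_noise_sd: float = 1e-4  # mg/mL
    o2_initial: float = 0.008  # mg/mL (~8 mg/L seawater)
    survival_p_selected: float = 0.73
    survival_p_control: float = 0.62
    n_cages: int = 3
    n_per_cage: int = 100
    survival_days: int = 120
    adaptor: str = "AGATCGGAAGAGC"
    qpcr_noise_sd: float = 0.3  # cycles

    def __post_init__(self) -> None:
        for name in ("frac_selected", "delta_f", "frac_de",
                     "survival_p_selected", "survival_p_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_reps_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.trace_noise_sd < 0:
            raise ValueError("trace_noise_sd must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.respiration_rate_true < 0 or self.respiration_rate_control < 0:
            raise ValueError("respiration rates must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one data stream."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a generated dataset, for recovery tests."""

    selected_snp_ids: frozenset[str] = frozenset()
    de_gene_ids: Mapping[str, float] = field(default_factory=dict)  # id -> true log2FC
    params: Mapping[str, float] = field(default_factory=dict)

    def selected_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": sorted(self.selected_snp_ids), "selected": True}
        )

    def de_frame(self) -> pd.DataFrame:
        ids = sorted(self.de_gene_ids)
        return pd.DataFrame(
            {
                "gene_id": ids,
                "true_log2fc": [self.de_gene_ids[g] for g in ids],
                "direction": ["up" if self.de_gene_ids[g] > 0 else "down" for g in ids],
            }
        )


# ---------------------------------------------------------------------------
# genome and gene models


def gen_genome_and_genes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping multi-exon gene models.

    Genes are placed with generous intergenic gaps so that upstream,
    downstream and intergenic zones all exist; each gene has 1-4 exons,
    mixed strands, and a CDS whose length is divisible by 3.

    Raises ``ValueError`` when ``n_genes`` genes cannot be placed on the
    configured chromosomes without overlap.
    """
    rng = config.rng("genome")
    genome = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=config.chrom_length))
        for i in range(config.n_chromosomes)
    }
    gap = 7_000  # keeps flank windows of neighbouring genes disjoint at 3 kb
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genome, genes
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    gene_no = 0
    for ci, idxs in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = gap
        for _ in idxs:
            length = int(rng.integers(1_200, 3_600))
            if cursor + length + gap > config.chrom_length:
                raise ValueError(
                    "genome too small: cannot place "
                    f"{config.n_genes} genes of ~2.4 kb with {gap} bp gaps "
                    f"on {config.n_chromosomes} x {config.chrom_length} bp"
                )
            start = cursor + int(rng.integers(0, gap // 2))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _split_exons(rng, start, end)
            cds = _carve_cds(exons)
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gene_no:05d}", chrom=chrom, strand=strand,
                    start=start, end=end, exons=exons, cds=cds,
                )
            )
            cursor = end + gap
    return genome, genes


def _split_exons(
    rng: np.random.Generator, start: int, end: int
) -> tuple[tuple[int, int], ...]:
    """1-4 exons spanning the gene ends, separated by >=80 bp introns."""
    n_exons = int(rng.integers(1, 5))
    length = end - start + 1
    if n_exons == 1 or length < n_exons * 150 + (n_exons - 1) * 80:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(150, length - 150), size=2 * (n_exons - 1),
                              replace=False))
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    exons = []
    for i in range(n_exons):
        s, e = bounds[2 * i], bounds[2 * i + 1]
        if i > 0:
            s += 1
        if e - s < 30:  # degenerate split; fall back to a single exon
            return ((start, end),)
        exons.append((s, e))
    return tuple(exons)


def _carve_cds(exons: tuple[tuple[int, int], ...]) -> tuple[tuple[int, int], ...]:
    """CDS = exons trimmed at the 3' end so total length is divisible by 3."""
    total = sum(e - s + 1 for s, e in exons)
    trim = total % 3
    cds = [list(iv) for iv in exons]
    cds[-1][1] -= trim
    return tuple((s, e) for s, e in cds if e >= s)


# ---------------------------------------------------------------------------
# pooled variants


def gen_pool_variants(
    config: SimulationConfig, gene_models: Sequence[GeneModel] | None = None,
    genome: Mapping[str, str] | None = None,
) -> tuple[list[PooledVariant], TruthTable]:
    """Biallelic SNPs with per-pool allele depths and a selection truth set.

    Neutral sites draw a shared allele frequency Uniform(0.05, 0.95) for
    both pools; a fraction ``frac_selected`` of sites are under divergent
    selection and shift the selected pool's frequency by ``delta_f``
    (clamped to [0, 1]).  Per-pool site depth is Poisson(``mean_depth``)
    with a floor of 1 read; alternate-allele depths are binomial draws.

    When a genome is supplied, reference alleles match it; otherwise they
    are drawn at random.
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = config.rng("variants")
    chroms = (
        sorted(genome) if genome is not None
        else [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    )
    chrom_len = (
        {c: len(genome[c]) for c in chroms} if genome is not None
        else {c: config.chrom_length for c in chroms}
    )
    # distinct positions per chromosome
    per_chrom = np.array_split(np.arange(config.n_snps), len(chroms))
    sites: list[tuple[str, int]] = []
    for c, idxs in zip(chroms, per_chrom):
        pos = rng.choice(np.arange(1, chrom_len[c] + 1), size=len(idxs), replace=False)
        sites.extend((c, int(p)) for p in np.sort(pos))

    n_sel = round(config.frac_selected * config.n_snps)
    sel_idx = set(rng.choice(config.n_snps, size=n_sel, replace=False).tolist())

    variants: list[PooledVariant] = []
    selected_ids: set[str] = set()
    for i, (chrom, pos) in enumerate(sites):
        if genome is not None:
            ref = genome[chrom][pos - 1].upper()
        else:
            ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        p_shared = rng.uniform(0.05, 0.95)
        if i in sel_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            p1 = float(np.clip(p_shared + sign * config.delta_f, 0.0, 1.0))
        else:
            p1 = p_shared
        p2 = p_shared
        d1 = max(1, int(rng.poisson(config.mean_depth)))
        d2 = max(1, int(rng.poisson(config.mean_depth)))
        a1 = int(rng.binomial(d1, p1))
        a2 = int(rng.binomial(d2, p2))
        v = PooledVariant(
            chrom=chrom, pos=pos, ref=ref, alts=(alt,),
            depths_pool1=(d1 - a1, a1), depths_pool2=(d2 - a2, a2),
        )
        variants.append(v)
        if i in sel_idx:
            selected_ids.add(v.variant_id)
    truth = TruthTable(
        selected_snp_ids=frozenset(selected_ids),
        params={"delta_f": config.delta_f, "frac_selected": config.frac_selected,
                "mean_depth": config.mean_depth},
    )
    return variants, truth


# ---------------------------------------------------------------------------
# expression counts


def gen_expression(
    config: SimulationConfig, gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, TruthTable]:
    """Negative-binomial count matrix for selected vs control replicates.

    Returns ``(counts, groups, truth)`` where ``counts`` is genes x
    samples, ``groups`` maps sample id to group label, and the truth
    table records the true differentially expressed genes with their
    log2 fold changes (half up, half down, magnitude ``lfc_effect``).
    Per-sample library-size factors are drawn lognormally, so raw
    columns are not directly comparable without normalisation.
    """
    rng = config.rng("expression")
    if gene_ids is None:
        gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    n_genes = len(gene_ids)
    n = config.n_reps_per_group
    samples = [f"sel_{i + 1}" for i in range(n)] + [f"ctl_{i + 1}" for i in range(n)]
    groups = pd.Series(
        ["selected"] * n + ["control"] * n, index=samples, name="group"
    )

    base_mu = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_genes)
    lib = rng.lognormal(mean=0.0, sigma=0.15, size=2 * n)

    n_de = round(config.frac_de * n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    half = n_de // 2
    lfc[de_idx[:half]] = config.lfc_effect
    lfc[de_idx[half:]] = -config.lfc_effect

    # selected group gets the multiplicative effect 2^lfc
    mu = np.empty((n_genes, 2 * n))
    mu[:, :n] = (base_mu * 2.0 ** lfc)[:, None] * lib[:n]
    mu[:, n:] = base_mu[:, None] * lib[n:]

    size = 1.0 / config.nb_dispersion  # var = mu + dispersion * mu^2
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    truth = TruthTable(
        de_gene_ids={gene_ids[i]: float(lfc[i]) for i in de_idx},
        params={"frac_de": config.frac_de, "lfc_effect": config.lfc_effect,
                "nb_dispersion": config.nb_dispersion},
    )
    return df, groups, truth


# ---------------------------------------------------------------------------
# qPCR

_TIMEPOINTS = (0, 12, 24)

# Per-group Ct shifts over the heat-shock time course (cycles; lower Ct =
# higher expression). The control group is strongly induced and relaxes,
# the selected group barely moves: low plasticity under selection.
_DEFAULT_INDUCTION = {
    "selected": {0: 0.0, 12: -0.5, 24: -0.3},
    "control": {0: 0.0, 12: -2.0, 24: -1.0},
}
# Basal ΔCt offset of the selected group relative to control (cycles);
# -1 means twice the basal expression.
_DEFAULT_GROUP_BASAL = {"selected": -1.0, "control": 0.0}


def gen_qpcr(
    config: SimulationConfig,
    genotype_effects: Mapping[str, float] | None = None,
    genes: Sequence[str] = ("HSP_A",),
    n_per_group: int = 10,
    genotypes: Sequence[str] | None = None,
    group_basal: Mapping[str, float] | None = None,
    induction: Mapping[str, Mapping[int, float]] | None = None,
) -> pd.DataFrame:
    """Ct table for a heat-shock time course with group/genotype effects.

    ``genotype_effects`` maps each genotype label to an additive shift of
    the target ΔCt (cycles; negative = higher expression).  Each sample
    is assigned one genotype and measured at 0, 12 and 24 h; the
    reference gene's Ct is stable around 20 cycles.

    Raises ``ValueError`` when a requested genotype label has no effect
    entry.
    """
    rng = config.rng("qpcr")
    genotype_effects = dict(genotype_effects or {"NN": 0.0})
    group_basal = dict(group_basal or _DEFAULT_GROUP_BASAL)
    induction = {g: dict(v) for g, v in (induction or _DEFAULT_INDUCTION).items()}
    labels = list(genotypes) if genotypes is not None else list(genotype_effects)
    unknown = [g for g in labels if g not in genotype_effects]
    if unknown:
        raise ValueError(f"unknown genotype label(s): {unknown}")

    rows = []
    for group in ("selected", "control"):
        for i in range(n_per_group):
            sample = f"{group[:3]}_{i + 1}"
            genotype = labels[int(rng.integers(len(labels)))]
            for gene in genes:
                base_dct = 4.0  # target ~4 cycles later than reference
                for tp in _TIMEPOINTS:
                    ct_ref = rng.normal(20.0, 0.15)
                    dct = (
                        base_dct
                        + group_basal[group]
                        + induction[group][tp]
                        + genotype_effects[genotype]
                        + rng.normal(0.0, config.qpcr_noise_sd)
                    )
                    rows.append(
                        (sample, group, tp, gene, ct_ref + dct, ct_ref, genotype)
                    )
    return pd.DataFrame(
        rows,
        columns=["sample", "group", "timepoint", "gene",
                 "ct_target", "ct_reference", "genotype"],
    )


# ---------------------------------------------------------------------------
# respirometry

TRACE_INTERVAL_S = 3
TRACE_DURATION_S = 5400  # 1.5 h


def gen_respirometry(
    config: SimulationConfig,
    subject: str = "S1",
    group: str = "selected",
    rate: float | None = None,
    temperature: float = 20.0,
) -> pd.DataFrame:
    """One closed-chamber O2 trace: 3-s cadence over 1.5 h (1801 points).

    O2(t) = O2(0) - rate * t + Gaussian noise, floored at zero.  ``rate``
    defaults to the config's group-specific true respiration rate in
    mg/mL/h.
    """
    if config.trace_noise_sd < 0:
        raise ValueError("trace_noise_sd must be non-negative")
    if rate is None:
        rate = (config.respiration_rate_true if group == "selected"
                else config.respiration_rate_control)
    if rate < 0:
        raise ValueError("respiration rate must be non-negative")
    rng = config.rng("respirometry")
    t = np.arange(0, TRACE_DURATION_S + 1, TRACE_INTERVAL_S, dtype=float)
    o2 = config.o2_initial - rate * (t / 3600.0)
    if config.trace_noise_sd > 0:
        o2 = o2 + rng.normal(0.0, config.trace_noise_sd, size=t.size)
    o2 = np.maximum(o2, 0.0)
    return pd.DataFrame(
        {"subject": subject, "group": group, "temperature": temperature,
         "time_s": t, "o2_mg_per_ml": o2}
    )


def gen_respirometry_cohort(
    config: SimulationConfig,
    n_per_group: int = 10,
    between_subject_sd: float = 2e-4,
    temperature: float = 20.0,
) -> pd.DataFrame:
    """Traces for a cohort: per-subject true rates vary around group means."""
    rng = config.rng("respirometry")
    frames = []
    for group, mean_rate in (
        ("selected", config.respiration_rate_true),
        ("control", config.respiration_rate_control),
    ):
        for i in range(n_per_group):
            subj_rate = max(0.0, rng.normal(mean_rate, between_subject_sd))
            sub = dataclasses.replace(config, seed=int(rng.integers(2**31)))
            frames.append(
                gen_respirometry(
                    sub, subject=f"{group[:3]}_{i + 1}", group=group,
                    rate=subj_rate, temperature=temperature,
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# survival


def gen_survival(config: SimulationConfig) -> pd.DataFrame:
    """Field-trial survival counts: per cage, daily, monotone non-increasing.

    Final survivors per cage are Binomial(``n_per_cage``, group survival
    probability); each death day is uniform over the trial, so daily
    counts decay monotonically to the binomial endpoint.
    """
    rng = config.rng("survival")
    rows = []
    for group, p in (
        ("selected", config.survival_p_selected),
        ("control", config.survival_p_control),
    ):
        for c in range(config.n_cages):
            cage = f"{group[:3]}_cage{c + 1}"
            survivors = int(rng.binomial(config.n_per_cage, p))
            n_deaths = config.n_per_cage - survivors
            death_days = rng.integers(1, config.survival_days + 1, size=n_deaths)
            for day in range(config.survival_days + 1):
                alive = config.n_per_cage - int(np.sum(death_days <= day))
                rows.append((cage, group, day, config.n_per_cage, alive))
    return pd.DataFrame(
        rows, columns=["cage", "group", "day", "n_initial", "n_alive"]
    )


# ---------------------------------------------------------------------------
# reads


def gen_reads(
    config: SimulationConfig,
    n_reads: int = 1000,
    read_length: int = 100,
    frac_adaptor: float = 0.05,
    frac_high_n: float = 0.05,
    frac_lowq: float = 0.05,
) -> list[SeqRecord]:
    """FASTQ reads with a known fraction failing each QC rule.

    Read names are tagged ``keep``, ``adaptor``, ``highN`` or ``lowq``
    with the intended QC fate, so downstream filter tests can assert
    exact removal sets.  ``highN`` reads carry N at just over 10% of
    bases; ``lowq`` reads have Phred <= 10 at just over half the bases.
    """
    if frac_adaptor + frac_high_n + frac_lowq > 1.0 + 1e-12:
        raise ValueError("bad-read fractions must sum to <= 1")
    rng = config.rng("reads")
    n_ad = round(frac_adaptor * n_reads)
    n_nn = round(frac_high_n * n_reads)
    n_lq = round(frac_lowq * n_reads)
    fates = (["adaptor"] * n_ad + ["highN"] * n_nn + ["lowq"] * n_lq
             + ["keep"] * (n_reads - n_ad - n_nn - n_lq))
    records = []
    for i, fate in enumerate(fates):
        seq = list(rng.choice(_BASES, size=read_length))
        qual = [int(q) for q in rng.integers(30, 41, size=read_length)]
        if fate == "adaptor":
            k = rng.integers(0, read_length - len(config.adaptor) + 1)
            seq[k : k + len(config.adaptor)] = list(config.adaptor)
        elif fate == "highN":
            n_n = int(np.floor(0.10 * read_length)) + 1  # just over 10%
            pos = rng.choice(read_length, size=n_n, replace=False)
            for p in pos:
                seq[p] = "N"
        elif fate == "lowq":
            n_l = int(np.floor(0.50 * read_length)) + 1  # just over 50%
            pos = rng.choice(read_length, size=n_l, replace=False)
            for p in pos:
                qual[p] = int(rng.integers(2, 11))
        rec = SeqRecord(
            Seq("".join(seq)), id=f"read{i + 1}:{fate}", description=""
        )
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# writers (plain-text, deterministic)


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon/CDS features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tthermosel\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tthermosel\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tthermosel\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{j};Parent={mrna}\n"
                )
            phase = 0
            cds_list = g.cds if g.strand == "+" else tuple(reversed(g.cds))
            for j, (s, e) in enumerate(cds_list, 1):
                fh.write(
                    f"{g.chrom}\tthermosel\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna}.cds{j};Parent={mrna}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def write_vcf(
    variants: Sequence[PooledVariant],
    path: str,
    contig_lengths: Mapping[str, int] | None = None,
    sample_names: tuple[str, str] = ("selected_pool", "control_pool"),
) -> None:
    """Two-sample VCF 4.2 with per-sample allele depths (AD)."""
    if contig_lengths is None:
        contig_lengths = {}
        for v in variants:
            contig_lengths[v.chrom] = max(contig_lengths.get(v.chrom, 0), v.pos)
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=thermosel-synthetic\n")
    for chrom in sorted(contig_lengths):
        buf.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths (ref first)">\n'
    )
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names) + "\n"
    )
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
        ad1 = ",".join(str(d) for d in v.depths_pool1)
        ad2 = ",".join(str(d) for d in v.depths_pool2)
        buf.write(
            f"{v.chrom}\t{v.pos}\t{v.chrom}:{v.pos}\t{v.ref}\t{','.join(v.alts)}"
            f"\t.\tPASS\t.\tGT:AD\t./.:{ad1}\t./.:{ad2}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_fastq(records: Sequence[SeqRecord], path: str) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
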
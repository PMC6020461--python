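"""Synthetic RNA/DNA bisulfite methylome generator.

Emulates the statistical structure the downstream analyses assume, so every
stage of the pipeline can be exercised and validated without any sequencing
data: binomial conversion counts over a background nonconversion floor p0,
region-specific methylation probabilities (5'UTR-enriched), clustered
methylation blocks with shared block-level methylation ratios,
mitochondrial enrichment, a Gaussian-copula-linked (anti)correlated DNA
methylome at CpG sites, and half-life / expression-change experiments with
recoverable effects.

The observation model at every cytosine is

    P(read unconverted) = true_m + (1 - true_m) * p0
    n_meth ~ Binomial(coverage, that probability)

with coverage drawn per site per replicate from a negative binomial.  All
randomness flows from one integer seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    CytosineSiteRecord,
    GenomicIntervalSet,
    TranscriptModel,
)

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_truth",
    "simulate_site_counts",
    "simulate_paired_dna",
    "simulate_structure_mask",
    "simulate_halflife",
    "simulate_fc_experiment",
    "simulate_dataset",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRUTH_COLUMNS = [
    "chrom", "pos", "strand", "true_m", "region_label", "gene_id", "block_id", "context",
]


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults set to the study conditions.

    ``p0`` defaults to 0.0275, the nonconversion floor of a typical
    poly(A)+ RNA BS-Seq library; region methylation probabilities encode the
    5'UTR enrichment (3x over CDS/3'UTR); the mitochondrial transcriptome is
    heavily methylated; coverage is overdispersed around 30x.
    """

    n_genes: int = 100
    seed: int = 0
    # region length ranges (nt), all >= 100 so metagene eligibility holds
    utr5_len: tuple[int, int] = (100, 300)
    cds_len: tuple[int, int] = (300, 1500)
    utr3_len: tuple[int, int] = (100, 600)
    n_exons: tuple[int, int] = (1, 3)
    intron_len: tuple[int, int] = (60, 200)
    intergenic_gap: int = 500
    n_chroms: int = 4
    noncoding_fraction: float = 0.1
    # observation model
    p0: float = 0.0275
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    n_replicates: int = 3
    # methylation placement
    region_meth_prob: dict[str, float] = field(
        default_factory=lambda: {"5UTR": 0.06, "CDS": 0.02, "3UTR": 0.02, "ncRNA": 0.02}
    )
    meth_ratio_beta: tuple[float, float] = (5.0, 2.0)
    context_bias: dict[str, float] | None = None
    # clustering block model (cluster_within_prob=None -> i.i.d. placement)
    cluster_block_len: int = 10
    cluster_within_prob: float | None = 0.8
    block_mratio_sd: float = 0.05
    # mitochondrial arm
    mito_fraction: float = 0.05
    mito_meth_prob: float = 0.4
    mito_chrom: str = "chrM"
    # DNA pairing (Gaussian copula at CG sites)
    rho_dna_rna: float = -0.5
    dna_meth_beta: tuple[float, float] = (2.0, 2.0)
    cg_mratio_beta: tuple[float, float] = (2.0, 2.0)
    # half-life experiment: log(halflife) = a + b*methylated + c*log2expr + noise
    hl_intercept: float = 0.5
    hl_meth_effect: float = 1.0
    hl_expr_effect: float = 0.2
    hl_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.p0 < 1):
            raise ValueError(f"p0 must lie in [0, 1), got {self.p0}")
        if abs(self.rho_dna_rna) > 1:
            raise ValueError(f"|rho_dna_rna| must be <= 1, got {self.rho_dna_rna}")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid length range {name}={getattr(self, name)}")
        for region, p in self.region_meth_prob.items():
            if not (0 <= p <= 1):
                raise ValueError(f"region_meth_prob[{region!r}] out of [0,1]: {p}")
        if not (0 <= self.mito_meth_prob <= 1) or not (0 <= self.mito_fraction <= 1):
            raise ValueError("mito probabilities must lie in [0,1]")
        if self.cluster_within_prob is not None and not (0 < self.cluster_within_prob <= 1):
            raise ValueError("cluster_within_prob must lie in (0,1] or be None")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# -- annotation -------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Lay out disjoint gene loci on synthetic chromosomes plus chrM.

    Returns the transcript models and per-chromosome uniform-composition
    sequences.  Every coding transcript has 5'UTR, CDS and 3'UTR each at
    least the configured minimum (>= 100 nt by default).
    """
    rng = np.random.default_rng(config.seed)
    n_mito = int(round(config.n_genes * config.mito_fraction))
    n_nuclear = config.n_genes - n_mito
    transcripts: list[TranscriptModel] = []
    cursors: dict[str, int] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]

    for gi in range(n_nuclear):
        chrom = chrom_names[gi % config.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        noncoding = rng.random() < config.noncoding_fraction
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        cds = int(rng.integers(config.cds_len[0], config.cds_len[1] + 1))
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        exonic_len = u5 + cds + u3
        n_ex = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
        # split exonic length into n_ex parts, each >= 50
        exon_sizes = _split_lengths(exonic_len, n_ex, 50, rng)
        introns = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(n_ex - 1)
        ]
        start = cursors.get(chrom, 0)
        exons = []
        pos = start
        for k, sz in enumerate(exon_sizes):
            exons.append((pos, pos + sz))
            pos += sz
            if k < len(introns):
                pos += introns[k]
        cursors[chrom] = pos + config.intergenic_gap
        gene_id = f"gene{gi:04d}"
        if noncoding:
            cds_start = cds_end = None
        else:
            # CDS occupies exonic offsets [left, left+cds) in genomic order
            left = u5 if strand == "+" else u3
            cds_start = _exonic_offset_to_genomic(exons, left)
            cds_end = _exonic_offset_to_genomic(exons, left + cds - 1) + 1
        transcripts.append(
            TranscriptModel(
                tx_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )

    for mi in range(n_mito):
        length = int(rng.integers(300, 1200))
        start = cursors.get(config.mito_chrom, 0)
        gene_id = f"mito{mi:03d}"
        transcripts.append(
            TranscriptModel(
                tx_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=config.mito_chrom,
                strand="+",
                exons=((start, start + length),),
            )
        )
        cursors[config.mito_chrom] = start + length + 100

    genome = {
        chrom: "".join(rng.choice(list("ACGT"), size=end + 10))
        for chrom, end in cursors.items()
    }
    return transcripts, genome


def _split_lengths(total: int, parts: int, minimum: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` into ``parts`` sizes, each >= ``minimum``."""
    if parts * minimum > total:
        parts = max(1, total // minimum)
    if parts == 1:
        return [total]
    extra = total - parts * minimum
    cuts = np.sort(rng.integers(0, extra + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [extra]]))
    return [minimum + int(s) for s in sizes]


def _exonic_offset_to_genomic(exons: Sequence[tuple[int, int]], off: int) -> int:
    for s, e in exons:
        if off < e - s:
            return s + off
        off -= e - s
    raise ValueError("offset beyond exonic length")


# -- truth ------------------------------------------------------------------


def simulate_truth(
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
    config: SimulationConfig,
    continuous_cg: bool = False,
) -> pd.DataFrame:
    """Assign a true methylation probability to every sense-strand cytosine.

    Placement follows the block model: the transcript is tiled into blocks of
    ``cluster_block_len`` nt; a block switches on with probability
    ``region_meth_prob / cluster_within_prob`` and sites inside an on-block
    are methylated with ``cluster_within_prob``, sharing the block's base
    methylation ratio up to ``block_mratio_sd`` jitter.  With
    ``cluster_within_prob=None`` placement is i.i.d. per site.  With
    ``continuous_cg`` every CG-context site instead receives a continuous
    Beta methylation ratio (the DNA-pairing experiment's marginal).
    """
    rng = np.random.default_rng(config.seed + 1)
    rows: list[tuple] = []
    a, b = config.meth_ratio_beta
    for t in transcripts:
        is_mito = t.chrom == config.mito_chrom
        seq = genome[t.chrom]
        sites = _sense_cytosines(t, seq)
        if not sites:
            continue
        n_blocks = max(1, math.ceil(t.exonic_length / config.cluster_block_len))
        if config.cluster_within_prob is not None:
            block_mr = rng.beta(a, b, size=n_blocks)
        block_on_cache: dict[tuple[int, str], bool] = {}
        for pos1, toff, context in sites:
            region = "mito" if is_mito else (t.region_of(pos1) or "ncRNA")
            p_site = (
                config.mito_meth_prob
                if is_mito
                else config.region_meth_prob.get(region, 0.0)
            )
            if config.context_bias:
                p_site = min(1.0, p_site * config.context_bias.get(context, 1.0))
            block_idx = toff // config.cluster_block_len
            block_id = ""
            if continuous_cg and context[2] == "G":
                ca, cb = config.cg_mratio_beta
                true_m = float(rng.beta(ca, cb))
            elif config.cluster_within_prob is None or is_mito:
                true_m = float(rng.beta(a, b)) if rng.random() < p_site else 0.0
            else:
                within = config.cluster_within_prob
                key = (block_idx, region)
                if key not in block_on_cache:
                    p_block = min(1.0, p_site / within)
                    block_on_cache[key] = bool(rng.random() < p_block)
                if block_on_cache[key] and rng.random() < within:
                    base = block_mr[block_idx]
                    true_m = float(
                        np.clip(base + rng.normal(0, config.block_mratio_sd), 0.02, 1.0)
                    )
                    block_id = f"{t.gene_id}_b{block_idx}"
                else:
                    true_m = 0.0
            rows.append((t.chrom, pos1, t.strand, true_m, region, t.gene_id, block_id, context))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _sense_cytosines(t: TranscriptModel, seq: str) -> list[tuple[int, int, str]]:
    """(1-based position, transcript offset, sense context) of every exonic C."""
    out = []
    want = "C" if t.strand == "+" else "G"
    for s, e in t.exons:
        for p0 in range(s, e):
            if p0 < 1 or p0 + 2 > len(seq):
                continue
            if seq[p0] != want:
                continue
            tri = seq[p0 - 1 : p0 + 2]
            context = tri if t.strand == "+" else _revcomp(tri)
            toff = t.genomic_to_transcript(p0 + 1)
            out.append((p0 + 1, toff, context))
    return out


# -- counts -----------------------------------------------------------------


def _draw_coverage(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    r = config.coverage_dispersion
    m = config.coverage_mean
    return rng.negative_binomial(r, r / (r + m), size=n)


def simulate_site_counts(
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "sim",
) -> dict[str, list[CytosineSiteRecord]]:
    """Emit per-replicate count records under the observation model.

    Zero-coverage draws emit no record for that site in that replicate.
    """
    if config.p0 >= 1:
        raise ValueError("p0 must be < 1")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    q = truth["true_m"].to_numpy() + (1 - truth["true_m"].to_numpy()) * config.p0
    out: dict[str, list[CytosineSiteRecord]] = {}
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep}"
        cov = _draw_coverage(rng, len(truth), config)
        n_meth = rng.binomial(cov, q)
        recs = [
            CytosineSiteRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                strand=row.strand,
                n_meth=int(m),
                n_unmeth=int(c - m),
                context=row.context,
                sample_id=sample_id,
                replicate_id=rep_id,
            )
            for row, c, m in zip(truth.itertuples(), cov, n_meth)
            if c > 0
        ]
        out[rep_id] = recs
    return out


# -- paired DNA methylome ---------------------------------------------------


def simulate_paired_dna(
    truth: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[dict[str, list[CytosineSiteRecord]], pd.DataFrame]:
    """DNA methylome over exonic cytosines, copula-linked to RNA at CG sites.

    At CG-context sites shared with the RNA truth, the DNA true methylation
    ratio is drawn through a Gaussian copula so that the rank correlation of
    (RNA true_m, DNA true_m) targets ``rho_dna_rna`` (Spearman); RNA ties are
    broken at random before computing normal scores, so the target is attained
    exactly only for continuous RNA marginals.  All non-CG DNA sites are
    unmethylated.  Counts come from the same observation model; DNA uses a
    single replicate.
    """
    rho_s = config.rho_dna_rna
    if abs(rho_s) > 1:
        raise ValueError("|rho_dna_rna| must be <= 1")
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    da, db = config.dna_meth_beta
    from scipy import stats as _st

    rna_cg = truth[truth["context"].str.endswith("G")]
    dna_rows: list[tuple] = []
    # copula at shared CG sites
    n_cg = len(rna_cg)
    if n_cg:
        # Pearson correlation on the normal scale attaining Spearman rho_s
        rho_n = 2 * math.sin(math.pi * rho_s / 6)
        vals = rna_cg["true_m"].to_numpy()
        jitter = rng.uniform(0, 1e-9, size=n_cg)
        ranks = _st.rankdata(vals + jitter * (1 + np.abs(vals)), method="ordinal")
        z1 = _st.norm.ppf(ranks / (n_cg + 1))
        eps = rng.standard_normal(n_cg)
        z2 = rho_n * z1 + math.sqrt(max(0.0, 1 - rho_n**2)) * eps
        if abs(rho_s) == 1:
            z2 = np.sign(rho_s) * z1
        dna_m = _st.beta.ppf(_st.norm.cdf(z2), da, db)
        for row, m in zip(rna_cg.itertuples(), dna_m):
            dna_rows.append(
                (row.chrom, row.pos, row.strand, float(m), row.region_label,
                 row.gene_id, "", row.context)
            )
    # remaining exonic Cs on both strands, unmethylated
    seen = {(r[0], r[1], r[2]) for r in dna_rows}
    for t in transcripts:
        seq = genome[t.chrom]
        for s, e in t.exons:
            for p0 in range(max(1, s), min(e, len(seq) - 2)):
                for strand, base in (("+", "C"), ("-", "G")):
                    if seq[p0] != base:
                        continue
                    key = (t.chrom, p0 + 1, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    tri = seq[p0 - 1 : p0 + 2]
                    context = tri if strand == "+" else _revcomp(tri)
                    dna_rows.append(
                        (t.chrom, p0 + 1, strand, 0.0, "DNA", t.gene_id, "", context)
                    )
    dna_truth = pd.DataFrame(dna_rows, columns=TRUTH_COLUMNS)
    dna_cfg = SimulationConfig(**{**config.to_dict(), "n_replicates": 1})
    counts = simulate_site_counts(
        dna_truth, dna_cfg, seed=int(rng.integers(2**31)), sample_id="sim_dna"
    )
    return counts, dna_truth


# -- structure masks --------------------------------------------------------


def simulate_structure_mask(
    transcripts: Sequence[TranscriptModel],
    config: SimulationConfig,
    mask_fraction: float = 0.05,
    seed: int | None = None,
) -> GenomicIntervalSet:
    """Random genomic intervals standing in for predicted paired regions.

    Roughly ``mask_fraction`` of each transcript's exonic span is covered by
    short (20-60 nt) intervals.
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    out = GenomicIntervalSet()
    for t in transcripts:
        span = t.exons[-1][1] - t.exons[0][0]
        n_iv = max(0, int(round(mask_fraction * span / 40)))
        for _ in range(n_iv):
            length = int(rng.integers(20, 61))
            start = int(rng.integers(t.exons[0][0], max(t.exons[0][0] + 1, t.exons[-1][1] - length)))
            out.add(t.chrom, start, start + length)
    return out


# -- half-life and fold-change experiments ----------------------------------


def simulate_halflife(
    n_genes: int,
    config: SimulationConfig,
    seed: int | None = None,
    meth_expr_effect: float = 0.5,
    meth_base_logit: float = -1.0,
) -> pd.DataFrame:
    """Gene table linking methylation status, expression and mRNA half-life.

    Methylation status depends on expression (the calling-depth confounder:
    better-expressed genes are easier to call), and log half-life follows
    ``hl_intercept + hl_meth_effect * methylated + hl_expr_effect * log2_expr
    + Normal(0, hl_noise_sd)``.  Setting ``hl_meth_effect=0`` gives the null.
    """
    rng = np.random.default_rng(config.seed + 5 if seed is None else seed)
    log2_expr = rng.normal(8.0, 1.5, size=n_genes)
    logit = meth_base_logit + meth_expr_effect * (log2_expr - 8.0)
    methylated = (rng.random(n_genes) < 1 / (1 + np.exp(-logit))).astype(int)
    log_hl = (
        config.hl_intercept
        + config.hl_meth_effect * methylated
        + config.hl_expr_effect * log2_expr
        + rng.normal(0, config.hl_noise_sd, size=n_genes)
    )
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "methylated": methylated,
            "log2_expr": log2_expr,
            "halflife": np.exp(log_hl),
        }
    )


def simulate_fc_experiment(
    n_genes: int = 1000,
    rho_fc: float = 0.3,
    seed: int = 0,
    n_replicates: int = 3,
    expr_mean_log2: float = 9.0,
    expr_sd_log2: float = 1.0,
    fc_sd: float = 1.0,
    meth_coverage: int = 500,
    base_mratio: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition experiment with correlated expression and methylation FC.

    Per gene, latent (log2 expression FC, log2 methylation odds FC) are
    bivariate normal with correlation ``rho_fc``.  Expression counts are
    Poisson per replicate; methylation counts are binomial at gene level
    with condition-2 odds scaled by the latent methylation FC.

    Returns (expression counts, methylation counts) long-format frames with
    columns gene_id, condition, replicate and the respective counts.
    """
    if abs(rho_fc) > 1:
        raise ValueError("|rho_fc| must be <= 1")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho_fc], [rho_fc, 1.0]]) * fc_sd**2
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    expr_fc, meth_fc = latent[:, 0], latent[:, 1]
    base_expr = 2 ** rng.normal(expr_mean_log2, expr_sd_log2, size=n_genes)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    expr_rows, meth_rows = [], []
    odds1 = base_mratio / (1 - base_mratio)
    for cond, scale_e, scale_m in (
        ("cond1", np.ones(n_genes), np.ones(n_genes)),
        ("cond2", 2.0**expr_fc, 2.0**meth_fc),
    ):
        m_cond = (odds1 * scale_m) / (1 + odds1 * scale_m)
        for rep in range(1, n_replicates + 1):
            counts = rng.poisson(base_expr * scale_e)
            n_meth = rng.binomial(meth_coverage, m_cond)
            for g, c, nm in zip(genes, counts, n_meth):
                expr_rows.append((g, cond, f"rep{rep}", int(c)))
            for g, nm in zip(genes, n_meth):
                meth_rows.append((g, cond, f"rep{rep}", int(nm), int(meth_coverage - nm)))
    expr = pd.DataFrame(expr_rows, columns=["gene_id", "condition", "replicate", "count"])
    meth = pd.DataFrame(
        meth_rows, columns=["gene_id", "condition", "replicate", "n_meth", "n_unmeth"]
    )
    return expr, meth


# -- bundle -----------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, continuous_cg: bool = False) -> dict:
    """One full synthetic study: annotation, truth, RNA counts, mask.

    Returns a dict with keys ``transcripts``, ``genome``, ``truth``,
    ``replicates`` (replicate id -> site records) and ``mask``.
    """
    transcripts, genome = simulate_annotation(config)
    truth = simulate_truth(transcripts, genome, config, continuous_cg=continuous_cg)
    replicates = simulate_site_counts(truth, config)
    mask = simulate_structure_mask(transcripts, config)
    return {
        "transcripts": transcripts,
        "genome": genome,
        "truth": truth,
        "replicates": replicates,
        "mask": mask,
    }
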
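# m5ctopo

Topological analysis of transcriptome 5-methylcytosine (m⁵C) from
single-base bisulfite sequencing.

RNA bisulfite sequencing reads out m⁵C at single-cytosine resolution:
unmethylated C converts to U (sequenced as T), methylated C resists
conversion. Turning per-cytosine conversion counts into biology requires a
chain of statistics that this package implements as a tested library with
a thin CLI, for computational epigenomics researchers analysing RNA (and
paired DNA) bisulfite methylomes:

* **site calling** — methylation ratio
  `mRatio = n_unconverted / (n_unconverted + n_converted)`, one-sided
  Fisher's exact test of each site against the pooled background
  nonconversion odds (noise floor p₀ ≈ 1–3%), Benjamini–Hochberg FDR, and
  all-replicate reproducibility rules;
* **filtering** — removal of false-positive-prone sites inside predicted
  RNA secondary structures (supplied as a BED mask; 2000/1000 nt window
  tiling helper for folding long sequences) and off annotated exons,
  keeping the mitochondrial chromosome;
* **topology** — enrichment odds ratios by mRNA region
  (`OR = (k_in/n_in)/(K_tot/N_tot)` over covered cytosines), chromosome
  and C-centred trinucleotide context; Guitar-style metagene density on a
  5'UTR/CDS/3'UTR axis with even isoform weighting; cross-sample
  conserved-locus association;
* **clustering** — proportion of called sites within 10 nt of another,
  against a per-gene conditional permutation null; m⁵C-p-m⁵C dimer
  fraction; distance-binned co-methylation correlation;
* **DNA–RNA comparison** — strand-aware pairing at matched coordinates
  and per-context correlation of methylation ratios (CpG strata are the
  informative ones);
* **differential methylation** — per-site odds ratio
  `(m₁/u₁)/(m₂/u₂)` with Haldane–Anscombe correction, Fisher's exact
  significance, hyper/hypo/mixed gene classification and region
  enrichment of hypermethylated sites;
* **association** — replicate-splitting correlation of expression vs
  methylation fold changes (no replicate on both sides of a split),
  binomial-family GLM of methylation status on mRNA half-life with
  expression as confounder, and loess-style local regression;
* **synthetic data** — a seeded generator producing annotation, truth
  tables and count reports with the structure above (region-enriched and
  block-clustered methylation, copula-linked DNA methylome, recoverable
  association effects), so every stage is verifiable without downloads.

## Worked example

Run the bundled synthetic demonstration (about 15 s):

```
$ m5ctopo run --config examples/demo.yaml --out runs/demo
{"seed": 7, "n_sites_called": 551}
```

`runs/demo/` now holds the annotation, per-replicate cytosine reports,
filtered calls and one TSV per analysis. The region enrichment table
(`region_enrichment.tsv`) reads:

```
stratum  k_in  n_in   k_total  n_total  odds_ratio  pvalue      rr_in_out
5UTR     124   2222   337      14907    2.469       1.1e-23     3.323
CDS      164   9289   337      14907    0.781       2.7e-07     0.573
3UTR     49    3396   337      14907    0.638       1.7e-04     0.716
```

The generator plants methylation at 3× the rate in 5'UTRs; the recovered
in/out rate ratio is 3.32 (95% CI 2.68–4.13), and the headline odds ratio
2.47 is the same signal measured against the transcriptome-wide rate.
`clustering.tsv` shows the block-clustered placement being detected
(observed within-10-nt proportion 0.82 vs null mean 0.35, permutation
p ≈ 0.005), and `dna_rna_correlation.tsv` recovers the simulated RNA–DNA
anticorrelation at CpG sites (ACG Spearman r = −0.44 under a copula
targeting −0.5; the gap is binomial noise at 30× coverage). The half-life
GLM (`halflife_glm.tsv`) estimates the simulated log-half-life effect 1.0
as 1.07 ± 0.06. The fold-change splits (`fc_split_correlation.tsv`) report
r ≈ 0.196 per split against a configured latent correlation of 0.3: this
particular seed realises a gene-level latent correlation of 0.198
(sampling sd ≈ 0.03 at 1000 genes), and the splits recover that realised
value almost exactly.

Each stage is equally usable as a library:

```python
from m5ctopo import SimulationConfig, call_sites, region_enrichment
from m5ctopo.synthetic_data import simulate_dataset

data = simulate_dataset(SimulationConfig(n_genes=60, seed=7))
calls = call_sites(data["replicates"]["rep1"])
for e in region_enrichment(calls, data["transcripts"]):
    print(e.stratum, round(e.odds_ratio, 2), e.pvalue)
```

Real data enters through `read_cytosine_report` (native and
Bismark-cytosine-report dialects, gzip-transparent), `read_bed12`
(transcript models) and `read_interval_bed` (structure masks); the `call`,
`simulate` and `plot-metagene` subcommands wrap the same functions.

## Documentation

`docs/methods.md` describes the statistical model, default parameters,
the generator's assumptions and limits, and the numerical choices.
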
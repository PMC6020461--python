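"""End-to-end orchestration of the synthetic demonstration pipeline.

Stages run in dependency order: simulate -> filter -> call -> topology /
clustering / DNA comparison / differential / association.  Filtering
(structure mask + exon/mito) precedes background estimation and calling.
Every output is a TSV (or BED/JSON) under one run directory; a manifest
records the sha256 of each file, the resolved config and its hash, and the
root seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import halflife_glm, run_fc_splits, local_regression
from .clustering import (
    DEFAULT_DISTANCE_BINS,
    dimer_fraction,
    distance_correlation,
    permutation_test,
    prop_within,
    group_positions,
)
from .differential import classify_genes, differential_sites, hyper_region_enrichment
from .dna_rna import CG_CONTEXTS, context_correlation, match_sites
from .formats_io import write_bed12, write_cytosine_report, write_interval_bed
from .region_filter import filter_nonexonic, filter_structured
from .site_calling import CallResult, call_sites, combine_replicates, estimate_background
from .synthetic_data import (
    SimulationConfig,
    simulate_dataset,
    simulate_fc_experiment,
    simulate_halflife,
    simulate_paired_dna,
    simulate_site_counts,
    simulate_truth,
)
from .topology import (
    chromosome_enrichment,
    context_table,
    metagene_profile,
    region_enrichment,
)

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "schema_version": 1,
    "seed": 7,
    "simulation": {"n_genes": 60},
    "calling": {"alpha": 0.05, "min_coverage": 10, "mode": "fisher"},
    "clustering": {"d": 10, "n_perm": 200},
    "differential": {"enabled": True, "utr5_scale": 3.0, "alpha": 0.05},
    "dna": {"enabled": True},
    "association": {"enabled": True, "n_genes": 1000, "rho_fc": 0.3},
}

_ALLOWED_KEYS = set(DEFAULT_CONFIG)


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Load and validate a pipeline config, merging over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = {**user, **overrides}
    unknown = set(user) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            bad = set(val) - set(cfg[key])
            sim_ok = key == "simulation"  # simulation accepts any generator field
            if bad and not sim_ok:
                raise ValueError(f"unknown config keys under {key!r}: {sorted(bad)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if "seed" not in user and path is not None:
        raise ValueError("config must set the field 'seed'")
    if not isinstance(cfg["seed"], int):
        raise ValueError("config field 'seed' must be an integer")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _calls_frame(calls: list[CallResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.site.chrom for c in calls],
            "pos": [c.site.pos for c in calls],
            "strand": [c.site.strand for c in calls],
            "context": [c.site.context for c in calls],
            "n_meth": [c.site.n_meth for c in calls],
            "n_unmeth": [c.site.n_unmeth for c in calls],
            "mratio": [c.mratio for c in calls],
            "pvalue": [c.pvalue for c in calls],
            "fdr": [c.fdr for c in calls],
            "called": [int(c.called) for c in calls],
        }
    )


def _filter_and_call(replicates, mask, transcripts, mito, calling) -> list[CallResult]:
    per_rep = []
    for rep_id in sorted(replicates):
        recs = replicates[rep_id]
        kept, _ = filter_structured(recs, mask)
        kept, _ = filter_nonexonic(kept, transcripts, mito_chrom=mito)
        per_rep.append(
            call_sites(
                kept,
                min_coverage=calling["min_coverage"],
                alpha=calling["alpha"],
                mode=calling["mode"],
            )
        )
    return combine_replicates(
        per_rep, alpha=calling["alpha"], min_coverage=calling["min_coverage"]
    )


def run_pipeline(config: str | Path | Mapping | None, out_dir: str | Path) -> dict:
    """Run every stage on the synthetic dataset; returns the manifest dict."""
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(None, overrides=dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    cfg_yaml = yaml.safe_dump(cfg, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    meta = f"# m5ctopo {__version__}; config_sha256={cfg_hash}; seed={seed}\n"
    (out / "config.resolved.yaml").write_text(cfg_yaml)

    # --- simulate ---------------------------------------------------------
    sim = SimulationConfig(**{**cfg["simulation"], "seed": seed})
    data = simulate_dataset(sim)
    transcripts, genome, truth = data["transcripts"], data["genome"], data["truth"]
    write_bed12(out / "annotation.bed12", transcripts)
    write_interval_bed(out / "structure_mask.bed", data["mask"])
    _write_tsv(truth, out / "truth.tsv", meta)
    for rep_id, recs in sorted(data["replicates"].items()):
        write_cytosine_report(out / f"report_{rep_id}.tsv", recs, header=True)

    # --- filter + call ----------------------------------------------------
    calling = cfg["calling"]
    combined = _filter_and_call(
        data["replicates"], data["mask"], transcripts, sim.mito_chrom, calling
    )
    _write_tsv(_calls_frame(combined), out / "calls.tsv", meta)
    n_called = sum(c.called for c in combined)

    # --- topology ---------------------------------------------------------
    reg = region_enrichment(combined, transcripts)
    _write_tsv(
        pd.DataFrame([vars(e) for e in reg]), out / "region_enrichment.tsv", meta
    )
    chrom = chromosome_enrichment(combined)
    _write_tsv(
        pd.DataFrame([vars(e) for e in chrom]), out / "chromosome_enrichment.tsv", meta
    )
    ctx = context_table(combined)
    _write_tsv(ctx, out / "context_table.tsv", meta)
    meta_profile = metagene_profile(combined, transcripts)
    _write_tsv(meta_profile, out / "metagene.tsv", meta)

    # --- clustering -------------------------------------------------------
    clu = cfg["clustering"]
    gene_of = {
        (r.chrom, int(r.pos), r.strand): r.gene_id for r in truth.itertuples()
    }
    called_by_gene: dict[str, list[int]] = {}
    cand_by_gene: dict[str, list[int]] = {}
    for c in combined:
        g = gene_of.get(c.key)
        if g is None:
            continue
        cand_by_gene.setdefault(g, []).append(c.site.pos)
        if c.called:
            called_by_gene.setdefault(g, []).append(c.site.pos)
    cand_by_gene = {g: v for g, v in cand_by_gene.items() if g in called_by_gene}
    perm = permutation_test(
        called_by_gene,
        cand_by_gene,
        d=clu["d"],
        n_perm=clu["n_perm"],
        seed=seed + 11,
    )
    dimer = dimer_fraction(called_by_gene, cand_by_gene)
    dist_r = distance_correlation(combined)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "observed_prop_within": perm.observed,
                    "null_mean": perm.null_mean,
                    "null_ci99_lo": perm.null_ci99[0],
                    "null_ci99_hi": perm.null_ci99[1],
                    "pvalue": perm.pvalue,
                    "n_perm": perm.n_perm,
                    "dimer_fraction": dimer,
                }
            ]
        ),
        out / "clustering.tsv",
        meta,
    )
    _write_tsv(
        pd.DataFrame(
            [
                {"bin_lo": lo, "bin_hi": hi, "pearson_r": r}
                for (lo, hi), r in dist_r.items()
            ]
        ),
        out / "distance_correlation.tsv",
        meta,
    )

    # --- DNA comparison ---------------------------------------------------
    if cfg["dna"]["enabled"]:
        truth_cg = simulate_truth(transcripts, genome, sim, continuous_cg=True)
        rna_counts = simulate_site_counts(truth_cg, sim, seed=seed + 21)
        rna_calls_dna_arm = _filter_and_call(
            rna_counts, data["mask"], transcripts, sim.mito_chrom, calling
        )
        dna_counts, _dna_truth = simulate_paired_dna(
            truth_cg, transcripts, genome, sim, seed=seed + 22
        )
        dna_calls = call_sites(
            dna_counts["rep1"],
            min_coverage=calling["min_coverage"],
            alpha=calling["alpha"],
            mode=calling["mode"],
        )
        pairs, match_log = match_sites(rna_calls_dna_arm, dna_calls)
        corr = context_correlation(pairs, contexts=list(CG_CONTEXTS))
        _write_tsv(corr, out / "dna_rna_correlation.tsv", meta)

    # --- differential -----------------------------------------------------
    if cfg["differential"]["enabled"]:
        scale = cfg["differential"]["utr5_scale"]
        sim2_probs = dict(sim.region_meth_prob)
        sim2_probs["5UTR"] = min(1.0, sim2_probs["5UTR"] * scale)
        sim2 = SimulationConfig(
            **{**sim.to_dict(), "region_meth_prob": sim2_probs, "seed": seed + 31}
        )
        truth2 = simulate_truth(transcripts, genome, sim2)
        reps2 = simulate_site_counts(truth2, sim2, seed=seed + 32)
        combined2 = _filter_and_call(
            reps2, data["mask"], transcripts, sim.mito_chrom, calling
        )
        cond1 = {c.key: (c.site.n_meth, c.site.n_unmeth) for c in combined2}
        cond2 = {c.key: (c.site.n_meth, c.site.n_unmeth) for c in combined}
        dms = differential_sites(
            cond1,
            cond2,
            min_coverage=calling["min_coverage"],
            alpha=cfg["differential"]["alpha"],
            gene_of=gene_of,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "chrom": d.chrom,
                        "pos": d.pos,
                        "strand": d.strand,
                        "odds_ratio": d.odds_ratio,
                        "pvalue": d.pvalue,
                        "fdr": d.fdr,
                        "direction": d.direction,
                        "gene_id": d.gene_id,
                    }
                    for d in dms
                ]
            ),
            out / "differential_sites.tsv",
            meta,
        )
        gene_dir = classify_genes(dms)
        _write_tsv(
            pd.DataFrame(
                sorted(gene_dir.items()), columns=["gene_id", "direction"]
            ),
            out / "gene_direction.tsv",
            meta,
        )
        hyper = hyper_region_enrichment(dms, transcripts)
        _write_tsv(
            pd.DataFrame([vars(e) for e in hyper]),
            out / "hyper_region_enrichment.tsv",
            meta,
        )

    # --- association ------------------------------------------------------
    if cfg["association"]["enabled"]:
        expr, meth = simulate_fc_experiment(
            n_genes=cfg["association"]["n_genes"],
            rho_fc=cfg["association"]["rho_fc"],
            seed=seed + 41,
        )
        splits = run_fc_splits(expr, meth)
        _write_tsv(splits, out / "fc_split_correlation.tsv", meta)
        hl = simulate_halflife(2000, sim, seed=seed + 42)
        fit = halflife_glm(
            hl["methylated"], np.log(hl["halflife"]), hl["log2_expr"]
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "term": t,
                        "coef": fit.coef[t],
                        "se": fit.se[t],
                        "wald_p": fit.wald_p[t],
                    }
                    for t in fit.coef
                ]
            ),
            out / "halflife_glm.tsv",
            meta,
        )
        window = hl[(hl.log2_expr >= 7) & (hl.log2_expr <= 11)]
        grid, curve_m = local_regression(
            window[window.methylated == 1].log2_expr,
            np.log(window[window.methylated == 1].halflife),
            grid=np.linspace(7, 11, 41),
        )
        _, curve_u = local_regression(
            window[window.methylated == 0].log2_expr,
            np.log(window[window.methylated == 0].halflife),
            grid=grid,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "log2_expr": grid,
                    "log_halflife_methylated": curve_m,
                    "log_halflife_unmethylated": curve_u,
                }
            ),
            out / "halflife_loess.tsv",
            meta,
        )

    # --- manifest ---------------------------------------------------------
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "tool": "m5ctopo",
        "version": __version__,
        "seed": seed,
        "config_sha256": cfg_hash,
        "n_sites_called": int(n_called),
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
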
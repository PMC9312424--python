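"""End-to-end pipeline: profile -> select -> compare -> enrich -> cluster.

A single YAML (or dict) config names the datasets and optional stages; the
pipeline writes per-dataset Gini profiles and selections, cross-dataset
statistics, enrichment tables with the compounded background, essentiality
comparisons, cross-species outputs, and a machine-readable ``summary.json``
stamped with the config hash and seed. Reruns with the same config and seed
are byte-identical. Stages are skipped when their config key is absent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cross_species as xs
from . import enrichment as enr
from . import essentiality as ess
from . import gini, stats
from .io import (
    GeneList,
    Unit,
    read_expression_matrix,
    read_gene_list,
    read_ortholog_map,
    write_gene_list,
)

logger = logging.getLogger("ginigenes")

__all__ = ["ConfigError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """A required config key is missing or malformed."""


def load_config(source) -> dict:
    """Load a pipeline config from a YAML path or pass a dict through."""
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _require(cfg: dict, key: str, context: str = "config"):
    if key not in cfg:
        raise ConfigError(f"missing key {key!r} in {context}")
    return cfg[key]


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in (sorted(x) if isinstance(x, (set, frozenset)) else x)]
    return x


def run_pipeline(config, outdir) -> Path:
    """Run every configured stage; returns the report directory.

    Config schema (keys marked * are required)::

        seed: 1
        datasets*:            # one entry per expression dataset
          - name*: hpa_like
            path*: matrix.tsv
            format: tsv       # tsv | mtx
            unit: RAW         # RAW | TPM | READS_PER_BASE
        selection*:
          method*: bottom_n | bottom_percentile
          threshold*: 3688 | 20
        benchmark: genes.txt  # optional benchmark gene list
        subsample: {dataset: hpa_like, sizes: [...], reps: 100}
        enrichment: {annotations: ann.tsv, format: tsv, aspect: BP,
                     fdr: 0.05, groups: {tissue: [a], cancer: [b]},
                     restrict_universe: true}
        essentiality: {dataset: hpa_like, table: ess.tsv,
                       groups: [[G1], [G2], [G1, G2]]}
        cross_species: {matrices: {org: path}, unit: RAW,
                        ortholog_map: orth.tsv, percentile: 20, k_extreme: 20}
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    summary: dict = {"config_hash": _config_hash(cfg), "seed": seed}

    datasets_cfg = _require(cfg, "datasets")
    if not datasets_cfg:
        raise ConfigError("datasets list is empty")
    sel_cfg = _require(cfg, "selection")
    method = _require(sel_cfg, "method", "selection")
    threshold = _require(sel_cfg, "threshold", "selection")

    # --- stage: Gini profiles and selections -------------------------------
    matrices, profiles, selections = {}, {}, {}
    for dcfg in datasets_cfg:
        name = _require(dcfg, "name", "dataset entry")
        path = _require(dcfg, "path", f"dataset {name!r}")
        m = read_expression_matrix(
            path, format=dcfg.get("format", "tsv"), unit=Unit(dcfg.get("unit", "RAW"))
        )
        matrices[name] = m
        prof = gini.gini_profile(m)
        profiles[name] = prof
        prof.to_csv(outdir / f"{name}.gini.tsv", sep="\t", float_format="%.10g")
        sel = gini.select_gini_genes(prof, method, threshold)
        selections[name] = sel
        write_gene_list(sel.selected.genes, outdir / f"{name}.selection.txt")
        summary.setdefault("datasets", {})[name] = {
            "n_genes": m.n_genes,
            "n_samples": m.n_samples,
            "n_selected": len(sel.selected),
            "cutoff_gc": float(sel.cutoff_gc),
        }
        logger.info("dataset %s: %d genes, %d selected", name, m.n_genes, len(sel.selected))

    # --- stage: benchmark coverage and percentile ratios -------------------
    benchmark = None
    if cfg.get("benchmark"):
        benchmark = read_gene_list(cfg["benchmark"], label="benchmark")
        cov, ratios = {}, {}
        for name, prof in profiles.items():
            universe = GeneList(frozenset(prof.index), label=name)
            if benchmark.genes & universe.genes:
                cov[name] = gini.benchmark_coverage(selections[name], benchmark, universe)
                ratios[name] = stats.benchmark_percentile_ratio(prof, benchmark)
        summary["benchmark_coverage"] = cov
        summary["benchmark_p90_ratio"] = ratios

    # --- stage: cross-dataset statistics ------------------------------------
    pair_rows = []
    for a, b in combinations(sorted(profiles), 2):
        rho, p, n = stats.cross_dataset_gc_correlation(profiles[a], profiles[b])
        p_ab = stats.cross_selection_gc_test(selections[a].selected, profiles[b])
        p_ba = stats.cross_selection_gc_test(selections[b].selected, profiles[a])
        pair_rows.append((a, b, n, rho, p, p_ab, p_ba))
    if pair_rows:
        pairs = pd.DataFrame(
            pair_rows,
            columns=["dataset_a", "dataset_b", "n_shared", "spearman_rho", "spearman_p",
                     "wilcoxon_p_a_in_b", "wilcoxon_p_b_in_a"],
        )
        pairs.to_csv(outdir / "cross_dataset_stats.tsv", sep="\t", index=False, float_format="%.10g")
        summary["cross_dataset_spearman"] = {
            f"{a}|{b}": float(r) for a, b, _, r, *_ in pair_rows
        }
    expr_corr = {}
    for name, prof in profiles.items():
        rho, p = stats.gc_expression_correlation(prof)
        expr_corr[name] = {"rho": float(rho), "p": float(p)}
    summary["gc_expression_spearman"] = expr_corr

    # --- stage: subsampling curve -------------------------------------------
    if cfg.get("subsample"):
        sub = cfg["subsample"]
        name = _require(sub, "dataset", "subsample")
        curve = stats.subsample_mean_gc(
            matrices[name], _require(sub, "sizes", "subsample"),
            reps=int(sub.get("reps", 100)), seed=seed,
        )
        curve.to_csv(outdir / f"{name}.subsample.tsv", sep="\t", float_format="%.10g")
        summary["subsample_mean_gc"] = {int(k): float(v) for k, v in curve.items()}

    # --- stage: GO enrichment with compounded background --------------------
    if cfg.get("enrichment"):
        ecfg = cfg["enrichment"]
        annotations = enr.read_annotations(
            _require(ecfg, "annotations", "enrichment"),
            format=ecfg.get("format", "auto"),
            aspect=ecfg.get("aspect", "BP"),
        )
        alpha = float(ecfg.get("fdr", 0.05))
        universes = {n: GeneList(frozenset(p.index), label=n) for n, p in profiles.items()}
        names = sorted(profiles)
        background = enr.build_background(
            annotations,
            [universes[n] for n in names],
            [selections[n].selected for n in names],
            alpha=alpha,
        )
        summary["n_background_terms"] = len(background.background_terms)
        tables, coverages = {}, {}
        for name in names:
            uni = universes[name]
            if ecfg.get("restrict_universe", True):
                uni = enr.background_universe(background, uni)
            query = GeneList(selections[name].selected.genes & uni.genes, label=name)
            table = enr.hypergeometric_enrichment(query, uni, background, direction="over", alpha=alpha)
            tables[name] = table
            coverages[name] = enr.term_coverage_profile(table)
            table.to_csv(outdir / f"{name}.enrichment.tsv", sep="\t", float_format="%.10g")
        cov_rhos = {}
        for a, b in combinations(names, 2):
            cov_rhos[f"{a}|{b}"] = float(enr.coverage_correlation(coverages[a], coverages[b]))
        summary["coverage_spearman"] = cov_rhos
        summary["n_enriched_terms"] = {n: int(t["enriched"].sum()) for n, t in tables.items()}
        if ecfg.get("groups"):
            common, exclusive = enr.compare_term_sets(tables, ecfg["groups"])
            summary["common_terms"] = sorted(common)
            summary["exclusive_terms"] = {g: sorted(t) for g, t in exclusive.items()}
            with open(outdir / "term_sets.json", "w") as fh:
                json.dump(_jsonable({"common": sorted(common),
                                     "exclusive": {g: sorted(t) for g, t in exclusive.items()}}),
                          fh, indent=2, sort_keys=True)
    else:
        logger.info("enrichment stage skipped (no 'enrichment' key)")

    # --- stage: essentiality -------------------------------------------------
    if cfg.get("essentiality"):
        kcfg = cfg["essentiality"]
        name = _require(kcfg, "dataset", "essentiality")
        table = ess.read_essentiality_table(_require(kcfg, "table", "essentiality"))
        groups = kcfg.get("groups") or [["G1"], ["G2"], ["G1", "G2"], ["G3"]]
        rows = []
        for group in groups:
            try:
                comp = ess.compare_gc_by_group(profiles[name], table, group)
            except ValueError as exc:
                logger.warning("essentiality group %s skipped: %s", group, exc)
                continue
            rows.append(comp)
        gtable = pd.DataFrame([vars(c) for c in rows])
        gtable.to_csv(outdir / f"{name}.essentiality.tsv", sep="\t", index=False, float_format="%.10g")
        summary["essentiality"] = {
            c.group_label: {"wilcoxon_p": c.wilcoxon_p, "ks_p": c.ks_p, "sign_test_p": c.sign_test_p,
                            "n_group": c.n_group, "n_gc_positive": c.n_group_gc_positive}
            for c in rows
        }
    else:
        logger.info("essentiality stage skipped (no 'essentiality' key)")

    # --- stage: cross-species ------------------------------------------------
    if cfg.get("cross_species"):
        xcfg = cfg["cross_species"]
        org_profiles = {}
        for org, path in _require(xcfg, "matrices", "cross_species").items():
            m = read_expression_matrix(path, format=xcfg.get("format", "tsv"),
                                       unit=Unit(xcfg.get("unit", "RAW")))
            org_profiles[org] = gini.gini_profile(m)
        omap = read_ortholog_map(_require(xcfg, "ortholog_map", "cross_species"))
        result = xs.analyze_cross_species(
            org_profiles, omap,
            percentile=float(xcfg.get("percentile", 20)),
            k_extreme=int(xcfg.get("k_extreme", 20)),
        )
        result.spearman.to_csv(outdir / "cross_species.spearman.tsv", sep="\t", float_format="%.10g")
        (outdir / "cross_species.newick").write_text(result.newick + "\n")
        result.pca.scores.to_csv(outdir / "cross_species.pca_scores.tsv", sep="\t", float_format="%.10g")
        result.pca.loadings.to_csv(outdir / "cross_species.pca_loadings.tsv", sep="\t", float_format="%.10g")
        pd.Series(result.pca.explained_var, name="explained_var").to_csv(
            outdir / "cross_species.explained_var.tsv", sep="\t", float_format="%.10g")
        summary["cross_species"] = {
            "n_orthologs": int(len(result.gc_matrix)),
            "n_gini_gene_union": int(len(result.gini_gene_matrix)),
            "gini_gene_counts": {k: int(v) for k, v in result.gini_gene_counts.items()},
            "explained_var": [float(v) for v in result.pca.explained_var],
            "newick": result.newick,
            "top_genes": result.top_genes,
            "middle_genes": result.middle_genes,
            "bottom_genes": result.bottom_genes,
        }
    else:
        logger.info("cross-species stage skipped (no 'cross_species' key)")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "config_hash": summary["config_hash"],
        "seed": seed,
        "inputs": sorted(str(d.get("path")) for d in datasets_cfg),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
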
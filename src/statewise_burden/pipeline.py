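"""End-to-end orchestration of the seven comparison groups.

Stages: sample filters -> kinship & relatedness pruning -> LD pruning &
genetic PCs -> sequencing-metadata PCs -> per-comparison GWAS,
annotation-state scan, repeat-class scan, and sliding-window scan, each in
the base and base+metaPCs covariate models where applicable -> a
Table-style lambda_GC matrix summarising calibration per comparison and
analysis family.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import sample_qc
from .burden_tests import build_covariates, run_category_scan, lambda_gc, gene_ptv_burden
from .io_formats import GenotypeMatrix, compute_maf_mac
from .metadata_pcs import compute_metadata_pcs, metric_matrix
from .single_variant import gwas_scan
from .synthetic_cohort import CohortConfig, CohortData, generate_cohort
from .weights_annotation import build_burden_matrix, select_analysis_variants
from .window_scan import enumerate_windows, window_burden_scan

log = logging.getLogger("statewise_burden")

__all__ = ["AnalysisOptions", "COMPARISONS", "run_comparisons", "run_full"]

#: the seven comparison groups: six case-control plus one control-control
COMPARISONS = {
    "ctrl_vs_ext": (("internal_control",), ("external_control",)),
    "bdsz_vs_all": (
        ("internal_case_BD", "internal_case_SZ"),
        ("internal_control", "external_control"),
    ),
    "bdsz_vs_int": (("internal_case_BD", "internal_case_SZ"), ("internal_control",)),
    "bd_vs_all": (("internal_case_BD",), ("internal_control", "external_control")),
    "bd_vs_int": (("internal_case_BD",), ("internal_control",)),
    "sz_vs_all": (("internal_case_SZ",), ("internal_control", "external_control")),
    "sz_vs_int": (("internal_case_SZ",), ("internal_control",)),
}


@dataclass
class AnalysisOptions:
    n_genetic_pcs: int = 10
    n_metadata_pcs: int = 4
    kinship_max_variants: int = 12000
    do_gwas: bool = True
    do_states: bool = True
    do_repeats: bool = True
    do_windows: bool = True
    do_genes: bool = False
    window_sizes_kb: tuple = (5, 10, 15, 20, 25, 50)
    comparisons: tuple = tuple(COMPARISONS)
    category_method: str = "wald"  # "score" for large scans
    seed: int = 0


def _comparison_is_internal(groups_a, groups_b) -> bool:
    return "external_control" not in groups_a + groups_b


def run_comparisons(cohort: CohortData, options: AnalysisOptions | None = None) -> dict:
    """Run the full analysis battery; returns the report bundle.

    The report holds per-comparison association results, a lambda_GC matrix
    over analysis families and models, sample/variant bookkeeping counts
    after each filter, and the shared QC artefacts (kinship pairs, PCs).
    """
    if options is None:
        options = AnalysisOptions()
    report: dict = {"counts": {}, "lambda": {}, "results": {}, "qc": {}}

    # ---- sample filters -------------------------------------------------
    kept_samples, excluded = sample_qc.filter_samples(cohort.samples)
    keep_idx = np.array(
        [i for i, s in enumerate(cohort.samples) if s.sample_id not in excluded]
    )
    log.info("sample filters: kept %d, excluded %d", len(kept_samples), len(excluded))
    report["counts"]["samples_input"] = len(cohort.samples)
    report["counts"]["samples_after_filters"] = len(kept_samples)
    report["qc"]["excluded"] = excluded

    gm = cohort.genotypes.subset_samples(keep_idx)
    maf_all, mac_all, _ = compute_maf_mac(gm.data)

    # ---- kinship + relatedness pruning ---------------------------------
    phi, flagged_pairs = sample_qc.estimate_kinship(
        gm, maf=maf_all, max_variants=options.kinship_max_variants, seed=options.seed
    )
    kept_rel, removed_rel = sample_qc.prune_related(phi, kept_samples, seed=options.seed)
    unrel_idx = np.asarray(kept_rel)
    samples_u = [kept_samples[i] for i in unrel_idx]
    gm_u = gm.subset_samples(unrel_idx)
    log.info("relatedness pruning: removed %d of %d", len(removed_rel), len(kept_samples))
    report["counts"]["related_removed"] = len(removed_rel)
    report["counts"]["samples_unrelated"] = len(samples_u)
    report["qc"]["kinship_pairs_flagged"] = len(flagged_pairs)

    maf_u, mac_u, _ = compute_maf_mac(gm_u.data)
    positions = np.array([v.pos for v in cohort.variants])
    chroms = np.array([v.chrom for v in cohort.variants], dtype=object)

    # ---- genetic PCs on the LD-pruned common variants -------------------
    pruned = sample_qc.ld_prune(gm_u, positions, chroms, maf=maf_u)
    report["counts"]["ld_pruned_variants"] = int(pruned.size)
    pcs, _ = sample_qc.compute_genetic_pcs(gm_u, pruned, k=options.n_genetic_pcs)

    # ---- sequencing metadata PCs ---------------------------------------
    meta_scores, meta_var = compute_metadata_pcs(
        metric_matrix(samples_u), k=options.n_metadata_pcs
    )
    report["qc"]["metadata_pc_variance"] = meta_var.tolist()

    sex_u = np.array([1.0 if s.sex == "XX" else 0.0 for s in samples_u])
    batch_u = np.array([s.batch for s in samples_u], dtype=object)
    cohort_u = np.array([s.cohort for s in samples_u], dtype=object)

    chrom_lengths = {}
    for chrom, length in cohort.truth.get("genome", []) or []:
        chrom_lengths[chrom] = length
    if not chrom_lengths:
        for chrom, s, e, _ in cohort.tracks["states"].intervals:
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), e)
    windows = enumerate_windows(chrom_lengths, options.window_sizes_kb)

    lam_rows = []
    for name in options.comparisons:
        groups_a, groups_b = COMPARISONS[name]
        in_a = np.isin(cohort_u, groups_a)
        in_b = np.isin(cohort_u, groups_b)
        sel = np.flatnonzero(in_a | in_b)
        if not in_a.any() or not in_b.any():
            log.info("skipping %s: one side empty", name)
            continue
        y = in_a[sel].astype(float)
        sub = gm_u.subset_samples(sel)
        maf_c, mac_c, _ = compute_maf_mac(sub.data)
        internal_only = _comparison_is_internal(groups_a, groups_b)
        batch_arg = batch_u[sel] if internal_only else None

        lam_row = {"comparison": name}
        res_c: dict = {}

        idx_rare = select_analysis_variants(cohort.variants, "state", maf=maf_c)
        log.info("%s: %d samples, %d rare analysis SNVs", name, sel.size, idx_rare.size)

        bm = None
        if options.do_states or options.do_repeats or options.do_windows:
            bm = build_burden_matrix(sub, cohort.variants, idx_rare, "state", maf=maf_c)
            total_burden = bm.totals
            cov_base = build_covariates(
                genetic_pcs=pcs[sel], sex=sex_u[sel], batch=batch_arg, total_burden=total_burden
            )
            cov_meta = build_covariates(
                genetic_pcs=pcs[sel],
                sex=sex_u[sel],
                batch=batch_arg,
                total_burden=total_burden,
                metadata_pcs=meta_scores[sel],
            )

        if options.do_states:
            r, lam, thr = run_category_scan(bm, y, cov_base, kind="state", model="base", method=options.category_method)
            res_c["state_base"] = r
            lam_row["state_base"] = lam
            r, lam, _ = run_category_scan(bm, y, cov_meta, kind="state", model="base+metaPCs", method=options.category_method)
            res_c["state_meta"] = r
            lam_row["state_meta"] = lam

        if options.do_repeats:
            bm_rep = build_burden_matrix(
                sub, cohort.variants, idx_rare, "repeat", maf=maf_c, overall_label="overall_repeat"
            )
            r, lam, thr = run_category_scan(bm_rep, y, cov_base, kind="repeat", model="base", method=options.category_method)
            res_c["repeat_base"] = r
            lam_row["repeat_base"] = lam
            r, lam, _ = run_category_scan(bm_rep, y, cov_meta, kind="repeat", model="base+metaPCs", method=options.category_method)
            res_c["repeat_meta"] = r
            lam_row["repeat_meta"] = lam

        if options.do_windows:
            wres, lam = window_burden_scan(
                sub, cohort.variants, idx_rare, windows, y, cov_base, model="base", maf=maf_c
            )
            res_c["window_base"] = wres
            lam_row["window_base"] = lam
            wres, lam = window_burden_scan(
                sub, cohort.variants, idx_rare, windows, y, cov_meta, model="base+metaPCs", maf=maf_c
            )
            res_c["window_meta"] = wres
            lam_row["window_meta"] = lam

        if options.do_gwas:
            cov_gwas = build_covariates(genetic_pcs=pcs[sel], sex=sex_u[sel], batch=batch_arg)
            tested, pvals, signs, lam = gwas_scan(sub, y, cov_gwas)
            res_c["gwas"] = {"idx": tested, "p": pvals, "sign": signs}
            lam_row["gwas"] = lam
            report["counts"][f"{name}_gwas_variants"] = int(tested.size)

        if options.do_genes and name == "bdsz_vs_all":
            idx_singleton = select_analysis_variants(
                cohort.variants, "singleton_ptv", maf=maf_c, mac_unrelated=mac_c
            )
            if idx_singleton.size:
                bm_gene = build_burden_matrix(
                    sub,
                    cohort.variants,
                    idx_singleton,
                    "gene",
                    weights=np.ones(idx_singleton.size),
                    maf=maf_c,
                )
                gres, skipped, thr = gene_ptv_burden(
                    bm_gene.burdens,
                    bm_gene.categories,
                    y,
                    covariates=build_covariates(genetic_pcs=pcs[sel], sex=sex_u[sel]),
                    total_singletons=bm_gene.totals,
                )
                res_c["gene_ptv"] = gres
                lam_row["gene_ptv"] = (
                    lambda_gc([g.p for g in gres]) if gres else float("nan")
                )
                report["counts"]["genes_tested"] = len(gres)
                report["counts"]["genes_skipped_le10_singletons"] = len(skipped)

        report["results"][name] = res_c
        lam_rows.append(lam_row)

    report["lambda"] = pd.DataFrame(lam_rows).set_index("comparison") if lam_rows else pd.DataFrame()
    report["qc"]["genetic_pcs"] = pcs
    report["qc"]["metadata_pcs"] = meta_scores
    report["qc"]["unrelated_sample_ids"] = [s.sample_id for s in samples_u]
    return report


def _config_hash(config: CohortConfig, options: AnalysisOptions) -> str:
    payload = json.dumps([asdict(config), asdict(options)], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full(config: CohortConfig, options: AnalysisOptions | None = None) -> dict:
    """Generate the synthetic cohort and run all comparisons.

    The report is tagged with a hash of (config, options) so downstream
    consumers can key caches on it; identical config + seed reproduce an
    identical report.
    """
    if options is None:
        options = AnalysisOptions(seed=config.seed)
    cohort = generate_cohort(config)
    cohort.truth["genome"] = list(config.genome)
    report = run_comparisons(cohort, options)
    report["config_hash"] = _config_hash(config, options)
    return report
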
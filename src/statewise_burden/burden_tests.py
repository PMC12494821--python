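"""Category-level logistic burden tests and genomic-control diagnostics.

Each category (annotation state, repeat class, gene, gene set) is tested by
logistic regression of case/control (or cohort) status on the per-sample
weighted burden, adjusting for genetic PCs, sex, sequencing batch
(internal-only comparisons), the per-sample total weighted burden, and —
in the ``base+metaPCs`` model — the first four sequencing-metadata PCs.

The genomic-control inflation factor over a family of tests is

    lambda_GC = median(qchisq_1(1 - p)) / 0.45494

i.e. the median inverse-chi-square(1 df) transform of the p-values divided
by the chi-square(1) median; values near 1 indicate a calibrated family,
values >> 1 systematic inflation (e.g. uncorrected batch effects).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._logistic import wald_logistic
from .io_formats import AssocResult
from .weights_annotation import CategoryBurdenMatrix

__all__ = [
    "burden_logistic_test",
    "run_category_scan",
    "lambda_gc",
    "gene_ptv_burden",
    "gene_set_burden",
    "build_covariates",
    "BONFERRONI_TABLE",
]

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45494...

#: the multiple-testing constants used across the analysis families
BONFERRONI_TABLE = {
    "states": 0.05 / 200,
    "states_all_comparisons": 0.05 / (200 * 7),
    "repeats": 0.05 / 22,
    "repeats_all_comparisons": 0.05 / (22 * 7),
    "genes_gt10_singletons": 0.05 / 1045,
    "genes_all": 0.05 / 22178,
    "gwas": 5e-9,
    "gwas_all_comparisons": 5e-9 / 7,
    "gene_sets": 0.05 / 3,
    "gene_sets_all_comparisons": 0.05 / (3 * 2),
}


def build_covariates(
    genetic_pcs: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    batch: np.ndarray | None = None,
    total_burden: np.ndarray | None = None,
    metadata_pcs: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the covariate matrix.

    Batch labels become indicator columns with the first level dropped;
    constant columns are removed so designs stay full rank.
    """
    cols = []
    if genetic_pcs is not None and genetic_pcs.size:
        cols.append(np.asarray(genetic_pcs, dtype=float))
    if sex is not None:
        cols.append(np.asarray(sex, dtype=float).reshape(-1, 1))
    if batch is not None:
        levels = sorted(set(batch))
        for lev in levels[1:]:
            cols.append((np.asarray(batch) == lev).astype(float).reshape(-1, 1))
    if total_burden is not None:
        cols.append(np.asarray(total_burden, dtype=float).reshape(-1, 1))
    if metadata_pcs is not None and metadata_pcs.size:
        cols.append(np.asarray(metadata_pcs, dtype=float))
    if not cols:
        return np.zeros((0, 0))
    X = np.column_stack(cols)
    keep = X.std(axis=0) > 0
    return X[:, keep]


def burden_logistic_test(
    burden: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    unit: str = "",
    kind: str = "category",
    model: str = "base",
    n_variants: int = 0,
) -> AssocResult:
    """Wald test of one burden vector; Firth fallback on separation.

    A constant burden is returned flagged ``degenerate`` with p = 1.
    """
    burden = np.asarray(burden, dtype=float)
    outcome = np.asarray(outcome)
    if np.unique(outcome).size < 2:
        raise ValueError("outcome must contain both classes")
    est, p, flag = wald_logistic(burden, outcome, covariates)
    return AssocResult(
        unit=unit, kind=kind, estimate=est, p=p, n_variants=n_variants, model=model, flag=flag
    )


def lambda_gc(pvalues) -> float:
    """Genomic-control lambda of a family of two-sided p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("lambda_gc needs at least one p-value")
    if np.any(p <= 0):
        tiny = np.finfo(float).tiny
        p = np.clip(p, tiny, None)
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def run_category_scan(
    burden_matrix: CategoryBurdenMatrix,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    kind: str = "state",
    model: str = "base",
    method: str = "wald",
):
    """One burden test per category plus family-level diagnostics.

    ``method='wald'`` fits each category's logistic model in full;
    ``method='score'`` tests every category against one shared
    covariate-only null fit (asymptotically equivalent, used for large
    scans where per-category ML fits dominate runtime; the reported
    estimate is then the one-step approximation U/V).  Returns
    ``(results, lam, thresholds)`` where ``thresholds`` holds the
    per-family Bonferroni cutoff 0.05/n_categories and the stricter
    0.05/(n_categories x 7 comparisons) cutoff.
    """
    n_cat = len(burden_matrix.categories)
    if n_cat < 2:
        raise ValueError("category scan needs >= 2 categories")
    results = []
    if method == "score":
        from ._logistic import fit_null, score_scan

        null = fit_null(np.asarray(outcome, dtype=float), covariates)
        B = burden_matrix.burdens
        ok = B.std(axis=0) > 0
        chi2 = np.zeros(n_cat)
        p = np.ones(n_cat)
        est = np.zeros(n_cat)
        if ok.any():
            U = B[:, ok].T @ null.resid
            c2, pv, _ = score_scan(null, B[:, ok])
            chi2[ok], p[ok] = c2, pv
            # one-step Newton coefficient from the null: beta ~ U/V = chi2/U
            with np.errstate(invalid="ignore", divide="ignore"):
                est[ok] = np.where(np.abs(U) > 1e-300, c2 / U, 0.0)
        for k, cat in enumerate(burden_matrix.categories):
            results.append(
                AssocResult(
                    unit=str(cat),
                    kind=kind,
                    estimate=float(est[k]),
                    p=float(p[k]),
                    n_variants=int(burden_matrix.category_sizes[k]),
                    model=model,
                    flag="" if ok[k] else "degenerate",
                )
            )
    elif method == "wald":
        for k, cat in enumerate(burden_matrix.categories):
            res = burden_logistic_test(
                burden_matrix.burdens[:, k],
                outcome,
                covariates,
                unit=str(cat),
                kind=kind,
                model=model,
                n_variants=int(burden_matrix.category_sizes[k]),
            )
            results.append(res)
    else:
        raise ValueError(f"unknown method {method!r}")
    usable = [r.p for r in results if r.flag != "degenerate"]
    lam = lambda_gc(usable) if usable else float("nan")
    thresholds = {"family": 0.05 / n_cat, "all_comparisons": 0.05 / (n_cat * 7)}
    return results, lam, thresholds


def gene_ptv_burden(
    gene_counts: np.ndarray,
    genes: list,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    total_singletons: np.ndarray | None = None,
    min_singletons: int = 10,
    model: str = "base",
):
    """Per-gene singleton-PTV burden tests.

    ``gene_counts``: samples x genes unweighted singleton PTV counts.  In
    strict mode only genes with more than ``min_singletons`` singletons are
    tested (the rest recorded as skipped); pass ``min_singletons=0`` for the
    1%-MAF sensitivity mode over all genes.  The per-sample total singleton
    count is appended to the covariates.  Returns
    ``(results, skipped, threshold)`` with threshold 0.05/n_tested.
    """
    gene_counts = np.asarray(gene_counts, dtype=float)
    if total_singletons is None:
        total_singletons = gene_counts.sum(axis=1)
    cov = build_covariates(
        genetic_pcs=covariates, total_burden=np.asarray(total_singletons, dtype=float)
    )
    totals_per_gene = gene_counts.sum(axis=0)
    results, skipped = [], []
    for k, gene in enumerate(genes):
        if totals_per_gene[k] <= min_singletons:
            skipped.append(gene)
            continue
        results.append(
            burden_logistic_test(
                gene_counts[:, k],
                outcome,
                cov,
                unit=str(gene),
                kind="gene",
                model=model,
                n_variants=int(totals_per_gene[k]),
            )
        )
    threshold = 0.05 / len(results) if results else float("nan")
    return results, skipped, threshold


def gene_set_burden(
    gene_sets: dict,
    gene_counts: np.ndarray,
    genes: list,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    total_singletons: np.ndarray | None = None,
    model: str = "base",
):
    """Summed-count burden test per gene set.

    For each set the per-sample PTV counts are summed over member genes and
    tested as a single burden.  Returns ``(results, thresholds)`` with the
    two-tier cutoffs 0.05/n_sets and 0.05/(n_sets x 2 comparisons).
    """
    gene_counts = np.asarray(gene_counts, dtype=float)
    gene_index = {g: k for k, g in enumerate(genes)}
    if total_singletons is None:
        total_singletons = gene_counts.sum(axis=1)
    cov = build_covariates(
        genetic_pcs=covariates, total_burden=np.asarray(total_singletons, dtype=float)
    )
    results = []
    for name, members in gene_sets.items():
        idx = [gene_index[g] for g in members if g in gene_index]
        if not idx:
            raise ValueError(f"gene set {name!r} has no annotated genes")
        burden = gene_counts[:, idx].sum(axis=1)
        results.append(
            burden_logistic_test(
                burden, outcome, cov, unit=name, kind="gene_set", model=model, n_variants=len(idx)
            )
        )
    n_sets = len(gene_sets)
    thresholds = {"family": 0.05 / n_sets, "all_comparisons": 0.05 / (n_sets * 2)}
    return results, thresholds
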
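"""Per-variant association tests and the exact-test machinery used when
allele counts are too small for asymptotic regression.

The genome-wide scan applies a MAC > 20 filter (logistic asymptotics are
unstable below that), fits the covariate-only null once, and score-tests
every variant column; individual variants can be refit with a full Wald
test.  The two-sided Fisher exact test follows the minimum-likelihood
convention: the p-value sums hypergeometric probabilities of all tables
with the observed margins whose point probability does not exceed the
observed one (within relative tolerance 1e-7).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._logistic import fit_null, score_scan, wald_logistic
from .burden_tests import lambda_gc
from .io_formats import AssocResult, GenotypeMatrix

__all__ = ["single_variant_test", "gwas_scan", "fisher_exact_2x2", "MAC_MIN"]

#: variants at or below this minor allele count are skipped (MAC > 20 rule)
MAC_MIN = 21


def single_variant_test(
    genotype: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    mac_min: int = MAC_MIN,
    unit: str = "",
    model: str = "base",
) -> AssocResult | None:
    """Covariate-adjusted logistic Wald test of one variant's dosage.

    The OR is reported per non-reference allele (reference-genome allele as
    the reference).  Missing genotypes are excluded.  Returns ``None`` when
    the variant's MAC in the tested individuals is below ``mac_min``.
    """
    g = np.asarray(genotype, dtype=float)
    called = g >= 0
    g = g[called]
    y = np.asarray(outcome)[called]
    cov = None if covariates is None else np.asarray(covariates)[called]
    alt = int(g.sum())
    mac = min(alt, 2 * g.size - alt)
    if mac < mac_min:
        return None
    est, p, flag = wald_logistic(g, y, cov)
    return AssocResult(unit=unit, kind="variant", estimate=est, p=p, n_variants=1, model=model, flag=flag)


def gwas_scan(
    genotypes: GenotypeMatrix,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    mac_min: int = MAC_MIN,
):
    """Score-test every variant with MAC > 20 against one shared null fit.

    Returns ``(variant_idx, pvalues, signs, lam)`` where ``lam`` is the
    genomic-control lambda over all tested variants.  The score statistic
    matches the Wald statistic asymptotically and allows the scan to run as
    a handful of matrix products.
    """
    from .io_formats import compute_maf_mac

    _, mac, _ = compute_maf_mac(genotypes.data)
    test_idx = np.flatnonzero(mac >= mac_min)
    null = fit_null(outcome, covariates)
    chunk = 4096
    pvals = np.empty(test_idx.size)
    signs = np.empty(test_idx.size, dtype=int)
    for k0 in range(0, test_idx.size, chunk):
        cols = test_idx[k0 : k0 + chunk]
        G = np.maximum(genotypes.data[:, cols], 0).astype(np.float64)
        _, p, s = score_scan(null, G)
        pvals[k0 : k0 + chunk] = p
        signs[k0 : k0 + chunk] = s
    lam = lambda_gc(pvals) if pvals.size else float("nan")
    return test_idx, pvals, signs, lam


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the allele-count table [[a, b], [c, d]].

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the probabilities of tables whose point
    probability is at most the observed one (relative tolerance 1e-7).
    An all-zero margin gives p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)
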
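"""Sample-level quality control: hard filters, kinship, relatedness
pruning, LD pruning, and genetic principal components.

Kinship uses the KING-robust within-pair estimator

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa,i + N_Aa,j)

computed over common variants, where N_Aa,Aa counts sites at which both
members are heterozygous, N_AA,aa counts opposite homozygotes, and the
denominator sums the two members' heterozygote counts.  Identical genomes
give phi = 0.5 exactly; parent-offspring ~0.25; third-degree relatives sit
near the 0.0409 pruning threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, SampleRecord

__all__ = [
    "FilterThresholds",
    "filter_samples",
    "estimate_kinship",
    "kinship_matrix",
    "prune_related",
    "ld_prune",
    "compute_genetic_pcs",
    "KINSHIP_THRESHOLD",
    "DUPLICATE_THRESHOLD",
]

#: third-degree-or-closer relatedness cutoff used for pruning
KINSHIP_THRESHOLD = 0.0409
#: monozygotic/duplicate cutoff (midpoint between 1st-degree and duplicate)
DUPLICATE_THRESHOLD = 0.354


@dataclass
class FilterThresholds:
    max_contamination: float = 0.05
    min_depth10_completeness: float = 0.98


def filter_samples(samples: list, thresholds: FilterThresholds | None = None):
    """Apply initial per-sample exclusions.

    Excludes samples with contamination > 5%, with < 98% of sites at depth
    >= 10, or whose reported sex disagrees with the genetic karyotype.
    Returns ``(kept, excluded)`` where ``excluded`` maps sample_id to a list
    of reason codes.  A missing required metric raises ``KeyError`` naming
    the sample and metric.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    kept, excluded = [], {}
    for s in samples:
        for metric in ("contamination", "depth10_completeness"):
            if metric not in s.metrics:
                raise KeyError(f"sample {s.sample_id}: missing metric {metric!r}")
        reasons = []
        if s.metrics["contamination"] > thresholds.max_contamination:
            reasons.append("contamination")
        if s.metrics["depth10_completeness"] < thresholds.min_depth10_completeness:
            reasons.append("coverage")
        if s.reported_sex != s.sex:
            reasons.append("sex_mismatch")
        if reasons:
            excluded[s.sample_id] = reasons
        else:
            kept.append(s)
    return kept, excluded


def kinship_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Full pairwise KING-robust kinship matrix.

    ``genotypes``: (n_samples, n_variants) 0/1/2 array restricted to common
    variants (missing treated as reference).  Computed with three indicator
    matrix products in float32; diagonal is set to 0.5.
    """
    g = np.asarray(genotypes)
    g = np.where(g < 0, 0, g)
    H = (g == 1).astype(np.float32)
    A = (g == 0).astype(np.float32)
    B = (g == 2).astype(np.float32)
    n_hh = H @ H.T
    M = A @ B.T
    n_opp = M + M.T
    het = H.sum(axis=1)
    denom = het[:, None] + het[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / np.maximum(denom, 1), np.nan)
    np.fill_diagonal(phi, 0.5)
    return phi


def estimate_kinship(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    maf: np.ndarray | None = None,
    max_variants: int | None = None,
    seed: int = 0,
):
    """KinshipTable over all sample pairs from common variants.

    Returns ``(phi_matrix, pairs)`` where ``pairs`` is a list of
    ``(id1, id2, phi)`` for pairs exceeding the third-degree threshold.
    Pairs in which neither member carries a heterozygote are reported with
    ``phi = nan`` (undefined).
    """
    if maf is None:
        from .io_formats import compute_maf_mac

        maf, _, _ = compute_maf_mac(genotypes.data)
    common = np.flatnonzero(np.asarray(maf) > maf_min)
    if common.size < 100:
        raise ValueError(f"need >=100 common variants for kinship, have {common.size}")
    if max_variants is not None and common.size > max_variants:
        rng = np.random.default_rng(seed)
        common = np.sort(rng.choice(common, size=max_variants, replace=False))
    phi = kinship_matrix(genotypes.data[:, common])
    ids = genotypes.sample_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    over = phi[iu, ju] > KINSHIP_THRESHOLD
    pairs = [(ids[i], ids[j], float(phi[i, j])) for i, j in zip(iu[over], ju[over])]
    return phi, pairs


def prune_related(
    phi: np.ndarray,
    samples: list,
    threshold: float = KINSHIP_THRESHOLD,
    seed: int = 0,
):
    """Select a maximal unrelated subset.

    Duplicate pairs (phi > 0.354) are resolved first with cohort priority:
    when an internal sample is duplicated with an external one, the internal
    sample is retained.  Remaining related groups are resolved by
    seeded-random greedy removal of the highest-degree sample until no pair
    above the threshold remains, which on chains A-B, B-C keeps A and C.
    Returns ``(kept_indices, removed_indices)``.
    """
    n = phi.shape[0]
    rng = np.random.default_rng(seed)
    removed: set[int] = set()
    internal = np.array([s.cohort != "external_control" for s in samples])

    adj_dup = np.triu(np.nan_to_num(phi, nan=0.0) > DUPLICATE_THRESHOLD, k=1)
    for i, j in zip(*np.nonzero(adj_dup)):
        if i in removed or j in removed:
            continue
        if internal[i] and not internal[j]:
            removed.add(int(j))
        elif internal[j] and not internal[i]:
            removed.add(int(i))
        else:
            removed.add(int(j) if rng.random() < 0.5 else int(i))

    adj = np.nan_to_num(phi, nan=0.0) > threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    for r in removed:
        alive[r] = False
    adj = adj & alive[:, None] & alive[None, :]
    degree = adj.sum(axis=1)
    while degree.max(initial=0) > 0:
        top = np.flatnonzero(degree == degree.max())
        pick = int(rng.choice(top))
        removed.add(pick)
        neighbours = np.flatnonzero(adj[pick])
        adj[pick, :] = False
        adj[:, pick] = False
        degree[pick] = 0
        degree[neighbours] -= 1
    kept = [i for i in range(n) if i not in removed]
    return kept, sorted(removed)


def ld_prune(
    genotypes: GenotypeMatrix,
    positions: np.ndarray,
    chroms: np.ndarray,
    window_bp: int = 500_000,
    step: int = 5,
    r2_max: float = 0.2,
    maf_min: float = 0.05,
    maf: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy left-to-right LD pruning within a sliding physical window.

    Considers only variants with MAF > ``maf_min``; walking variants in
    position order, a variant is dropped if its squared correlation with any
    retained variant within ``window_bp`` upstream exceeds ``r2_max``.
    ``step`` controls the evaluation batch size (the retained set is exact
    regardless).  Returns retained variant indices (into the full set).
    """
    if maf is None:
        from .io_formats import compute_maf_mac

        maf, _, _ = compute_maf_mac(genotypes.data)
    candidates = np.flatnonzero(np.asarray(maf) > maf_min)
    if candidates.size == 0:
        return candidates

    g = np.maximum(genotypes.data[:, candidates], 0).astype(np.float32)
    g = g - g.mean(axis=0)
    norms = np.sqrt((g**2).sum(axis=0))
    norms[norms == 0] = np.inf
    g = g / norms

    pos = np.asarray(positions)[candidates]
    chrom = np.asarray(chroms)[candidates]
    order = np.lexsort((pos, chrom))

    kept_local: list[int] = []
    kept_pos: list[int] = []
    kept_chrom: list = []
    win_start = 0  # first kept variant still inside the window
    for b0 in range(0, order.size, max(step, 1)):
        batch = order[b0 : b0 + max(step, 1)]
        for k in batch:
            c, p = chrom[k], pos[k]
            while win_start < len(kept_local) and (
                kept_chrom[win_start] != c or kept_pos[win_start] < p - window_bp
            ):
                win_start += 1
            active = kept_local[win_start:]
            if active:
                r = g[:, active].T @ g[:, k]
                if np.any(r * r > r2_max):
                    continue
            kept_local.append(k)
            kept_pos.append(p)
            kept_chrom.append(c)
    return np.sort(candidates[np.array(kept_local, dtype=int)])


def compute_genetic_pcs(genotypes: GenotypeMatrix, variant_idx: np.ndarray | None = None, k: int = 10):
    """PCs of the centred, variance-standardised genotype matrix.

    Uses a Lanczos eigendecomposition of the sample-sample covariance
    (exact to solver tolerance at this scale).  The sign of each component
    is fixed so that its largest-magnitude variant loading is positive.
    Returns ``(scores, explained_variance_ratio)``; if ``k`` exceeds the
    matrix rank, fewer components are returned with a warning.
    """
    import warnings

    data = genotypes.data
    if variant_idx is not None:
        data = data[:, np.asarray(variant_idx)]
    g = np.maximum(data, 0).astype(np.float32)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    keep = sd > 0
    g = g[:, keep] / sd[keep]
    n, m = g.shape
    rank_bound = min(n - 1, m)
    k_eff = min(k, rank_bound)
    if k_eff < k:
        warnings.warn(f"requested {k} PCs but rank bound is {rank_bound}; returning {k_eff}")
    if k_eff == 0:
        return np.zeros((n, 0)), np.zeros(0)

    from scipy.sparse.linalg import svds

    if k_eff >= rank_bound or min(n, m) < 3 * k_eff:
        U, s, Vt = np.linalg.svd(g, full_matrices=False)
        U, s, Vt = U[:, :k_eff], s[:k_eff], Vt[:k_eff]
    else:
        rng = np.random.default_rng(0)
        v0 = rng.standard_normal(min(n, m))
        U, s, Vt = svds(g, k=k_eff, v0=v0)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    # deterministic sign: largest-|loading| entry of each right singular
    # vector made positive
    for c in range(k_eff):
        jmax = np.argmax(np.abs(Vt[c]))
        if Vt[c, jmax] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    scores = U * s
    total_var = float((g**2).sum())
    evr = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    return scores, evr
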
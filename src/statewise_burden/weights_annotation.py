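"""Variant selection, MAF-based weighting, and per-sample category burdens.

Rarer variants are upweighted with the Beta(1, 25) density evaluated at the
minor allele frequency, w(MAF) = 25 (1 - MAF)^24, which is ~25 for
singletons and decays smoothly toward the 5% low-frequency boundary.  A
category burden for sample s and category c is

    B_sc = sum_{v in c} w(MAF_v) g_sv

with g_sv the non-reference allele count, plus a per-sample total over all
analysed variants used as a variant-density covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenotypeMatrix, IntervalTrack, VariantRecord

__all__ = [
    "beta_weight",
    "select_analysis_variants",
    "annotate_variants",
    "build_burden_matrix",
    "CategoryBurdenMatrix",
]


def beta_weight(maf):
    """Beta(1, 25) density at the minor allele frequency.

    Strictly decreasing on (0, 1); w -> 25 as maf -> 0.  Raises for
    maf <= 0 or >= 1.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0) or np.any(maf >= 1):
        raise ValueError("beta_weight requires 0 < maf < 1")
    w = stats.beta.pdf(maf, 1, 25)
    return float(w) if w.ndim == 0 else w


def annotate_variants(variants: list, tracks: dict) -> None:
    """Join interval-track annotations onto variant records in place.

    Each variant is assigned by 1-based point lookup of its position:
    the containing state (single-label partition), all overlapping repeat
    classes (multi-label), the containing gene, and the excluded-region
    flag.  Indels are assigned by their VCF position.
    """
    for v in variants:
        ann = dict(v.annotations)
        if "states" in tracks:
            label = tracks["states"].label_at(v.chrom, v.pos)
            if label is not None:
                ann["state"] = label
        if "repeats" in tracks:
            labels = tracks["repeats"].labels_at(v.chrom, v.pos)
            if labels:
                ann["repeat"] = labels[0] if len(labels) == 1 else labels
        if "genes" in tracks:
            label = tracks["genes"].label_at(v.chrom, v.pos)
            if label is not None:
                ann["gene"] = label
        if "excluded" in tracks:
            if tracks["excluded"].labels_at(v.chrom, v.pos):
                ann["excluded"] = True
        v.annotations = ann


def select_analysis_variants(
    variants: list,
    kind: str,
    maf: np.ndarray | None = None,
    mac_unrelated: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of variants entering an analysis.

    ``kind``:

    * ``state`` / ``repeat`` / ``window`` — SNVs only, MAF strictly < 0.05,
      not flagged as excluded-region.
    * ``singleton_ptv`` — PTV-flagged variants whose minor allele count in
      the unrelated sample set (``mac_unrelated``) is exactly 1.
    * ``ptv_1pct`` — PTV-flagged variants with MAF <= 0.01.
    """
    if maf is None:
        maf = np.array([v.maf for v in variants])
    maf = np.asarray(maf)
    if kind in ("state", "repeat", "window"):
        keep = []
        for j, v in enumerate(variants):
            if not v.is_snv:
                continue
            if v.annotations.get("excluded"):
                continue
            if maf[j] >= 0.05 or maf[j] <= 0:
                continue
            keep.append(j)
        return np.asarray(keep, dtype=int)
    if kind == "singleton_ptv":
        if mac_unrelated is None:
            raise ValueError("singleton selection requires MAC computed on the unrelated set")
        mac_unrelated = np.asarray(mac_unrelated)
        return np.asarray(
            [j for j, v in enumerate(variants) if v.annotations.get("ptv") and mac_unrelated[j] == 1],
            dtype=int,
        )
    if kind == "ptv_1pct":
        return np.asarray(
            [j for j, v in enumerate(variants) if v.annotations.get("ptv") and 0 < maf[j] <= 0.01],
            dtype=int,
        )
    raise ValueError(f"unknown selection kind {kind!r}")


@dataclass
class CategoryBurdenMatrix:
    """samples x categories weighted burdens plus per-sample totals."""

    burdens: np.ndarray  # (n_samples, n_categories)
    categories: list
    totals: np.ndarray  # (n_samples,)
    category_sizes: np.ndarray  # variants per category
    sample_ids: list

    def column(self, category) -> np.ndarray:
        return self.burdens[:, self.categories.index(category)]


def _category_labels(variants, idx, grouping, overall_label):
    labels_per_variant = []
    for j in idx:
        ann = variants[j].annotations.get(grouping)
        if ann is None:
            labels_per_variant.append([])
        elif isinstance(ann, (list, tuple)):
            labels_per_variant.append(list(ann))
        else:
            labels_per_variant.append([ann])
    if overall_label:
        for labels in labels_per_variant:
            if labels:
                labels.append(overall_label)
    return labels_per_variant


def build_burden_matrix(
    genotypes: GenotypeMatrix,
    variants: list,
    idx: np.ndarray,
    grouping: str,
    weights: np.ndarray | None = None,
    maf: np.ndarray | None = None,
    categories: list | None = None,
    overall_label: str | None = None,
) -> CategoryBurdenMatrix:
    """Weighted per-sample burden for each category of a grouping.

    ``grouping`` names the annotation key (``state``, ``repeat``, ``gene``).
    ``weights=None`` uses Beta(1,25) MAF weights; pass ``weights=1`` arrays
    for unweighted (PTV count) burdens.  A variant overlapping several
    repeat classes contributes once to each, and once to the
    ``overall_label`` category when given.  Missing genotypes count as
    homozygous reference.  Categories supplied in ``categories`` but absent
    from the data are retained as zero columns.
    """
    idx = np.asarray(idx, dtype=int)
    if maf is None:
        maf = np.array([v.maf for v in variants])
    if weights is None:
        w = beta_weight(np.clip(np.asarray(maf)[idx], 1e-12, 1 - 1e-12))
    else:
        w = np.broadcast_to(np.asarray(weights, dtype=float), (idx.size,)).copy()

    labels_per_variant = _category_labels(variants, idx, grouping, overall_label)
    if categories is None:
        cats = sorted({lab for labels in labels_per_variant for lab in labels}, key=str)
    else:
        cats = list(categories)
    cat_index = {c: k for k, c in enumerate(cats)}

    members: list[list[int]] = [[] for _ in cats]
    sizes = np.zeros(len(cats), dtype=int)
    for r, labels in enumerate(labels_per_variant):
        for lab in labels:
            k = cat_index.get(lab)
            if k is None:
                continue
            members[k].append(r)
            sizes[k] += 1

    data = genotypes.data
    n = data.shape[0]
    burdens = np.zeros((n, len(cats)))
    for k, rows_k in enumerate(members):
        if not rows_k:
            continue
        sub = np.maximum(data[:, idx[rows_k]], 0).astype(np.float32)
        burdens[:, k] = sub @ w[rows_k].astype(np.float32)

    totals = np.zeros(n)
    chunk = max(1, int(4e7) // max(n, 1))
    for j0 in range(0, idx.size, chunk):
        cols = idx[j0 : j0 + chunk]
        totals += np.maximum(data[:, cols], 0).astype(np.float32) @ w[j0 : j0 + chunk].astype(
            np.float32
        )
    return CategoryBurdenMatrix(
        burdens=np.asarray(burdens, dtype=float),
        categories=cats,
        totals=np.asarray(totals, dtype=float),
        category_sizes=sizes,
        sample_ids=genotypes.sample_ids,
    )
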
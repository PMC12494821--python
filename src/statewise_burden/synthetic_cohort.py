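"""Synthetic cohort generator.

Produces case/control cohorts with the statistical structure the analysis
modules assume: two control cohorts sequenced at different depths
(26.8 +/- 5.5 vs 36.8 +/- 4.7), a genome partitioned into annotation states
with state-dependent repeat content, depth-dependent differential variant
calling concentrated in repeat-like regions, singleton PTVs in genes,
admixture-driven population structure, and optional duplicate /
parent-offspring pairs.  Every latent quantity is recorded in a truth
record so recovery tests never peek at generator internals directly.

Genotypes are drawn under Hardy-Weinberg equilibrium from per-sample allele
frequencies given by a two-way admixture gradient.  Case groups are sampled
retrospectively: at variants carrying a disease effect, the case-conditional
allele frequency is tilted by the per-allele odds ratio
``p' = p.exp(beta) / (1 - p + p.exp(beta))``, the first-order conditional
distribution under the logistic disease model for rare variants.  The
prospective model is available separately through ``assign_phenotypes``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import GenotypeMatrix, IntervalTrack, SampleRecord, VariantRecord

__all__ = [
    "CohortConfig",
    "DiseaseModel",
    "BatchModel",
    "CohortData",
    "generate_cohort",
    "assign_phenotypes",
    "inject_batch_effect",
    "spike_relatives",
]

# relative abundance of variant-level repeat classes (21 named classes; the
# union is tracked as "overall" for a 22nd tested category)
DEFAULT_REPEAT_CLASSES = {
    "SINE": 0.30,
    "LINE": 0.26,
    "LTR": 0.14,
    "DNA": 0.07,
    "Simple_repeat": 0.04,
    "Low_complexity": 0.03,
    "Satellite": 0.02,
    "Retroposon": 0.02,
    "rRNA": 0.01,
    "tRNA": 0.01,
    "snRNA": 0.01,
    "scRNA": 0.005,
    "srpRNA": 0.005,
    "RC": 0.01,
    "DNA_q": 0.01,
    "SINE_q": 0.01,
    "LINE_q": 0.01,
    "LTR_q": 0.01,
    "Unknown": 0.02,
    "RNA": 0.01,
    "Other": 0.02,
}


@dataclass
class DiseaseModel:
    """Logistic disease model: logit P(case) = alpha + covariates + sum(beta_v g_v)."""

    prevalence: float = 0.01
    sex_log_or: float = 0.0
    # regional rare-variant effect: all variants inside the region carry
    # ``per_variant_log_or`` on the log-odds scale
    region: tuple | None = None  # (chrom, start_1based, end_1based)
    per_variant_log_or: float = 0.0
    # which case group the regional effect applies to ("BD", "SZ", or "both")
    effect_phenotype: str = "BD"

    def validate(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")


@dataclass
class BatchModel:
    """Depth-dependent differential calling model.

    Dropout (1 -> 0) probability decreases with depth and applies to all
    rare variants (MAF < ``dropout_maf``): being proportional to carrier
    counts it barely moves any single variant's frequency but accumulates
    across the thousands of variants aggregated by a category burden.
    Spurious calls (0 -> 1) increase with depth and are confined to the
    rarest sites (MAF < ``spurious_maf``), emulating artifact calls at
    low-confidence positions, below the MAC filter of single-variant
    tests.  Both rates are scaled by per-repeat-class multipliers; the
    depth link is logistic in (depth - 30)/5 with floor/ceiling rates.
    """

    depth_mean_internal: float = 26.8
    depth_sd_internal: float = 5.5
    depth_mean_external: float = 36.8
    depth_sd_external: float = 4.7
    dropout_floor: float = 0.0
    dropout_ceiling: float = 0.045
    spurious_floor: float = 0.0
    spurious_ceiling: float = 5e-4
    dropout_maf: float = 0.05
    spurious_maf: float = 0.002
    # class multipliers applied to both rates; classes absent default to the
    # non-repeat multiplier
    class_multipliers: dict = field(
        default_factory=lambda: {"SINE": 4.0, "Simple_repeat": 3.0, "LINE": 1.5, "LTR": 1.5}
    )
    repeat_default_multiplier: float = 1.5
    nonrepeat_multiplier: float = 0.05
    metric_noise: float = 0.25

    def validate(self) -> None:
        for name in ("dropout_floor", "dropout_ceiling", "spurious_floor", "spurious_ceiling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def dropout_rate(self, depth: np.ndarray) -> np.ndarray:
        z = (np.asarray(depth, dtype=float) - 30.0) / 5.0
        return self.dropout_floor + (self.dropout_ceiling - self.dropout_floor) / (
            1.0 + np.exp(z)
        )

    def spurious_rate(self, depth: np.ndarray) -> np.ndarray:
        z = (np.asarray(depth, dtype=float) - 30.0) / 5.0
        return self.spurious_floor + (self.spurious_ceiling - self.spurious_floor) / (
            1.0 + np.exp(-z)
        )

    def multiplier(self, repeat_class: str | None) -> float:
        if repeat_class is None:
            return self.nonrepeat_multiplier
        return self.class_multipliers.get(repeat_class, self.repeat_default_multiplier)


@dataclass
class CohortConfig:
    # group sizes (scaled-down image of the study's unrelated sample counts)
    n_bd: int = 600
    n_sz: int = 1200
    n_internal_control: int = 900
    n_external_control: int = 3300
    # genome: long sparse chromosomes so that annotation states aggregate
    # far more variants than any 50-kb window, as in whole-genome data
    genome: tuple = (("chr1", 250_000_000), ("chr2", 250_000_000))
    n_variants: int = 50_000
    # rare-skewed MAF spectrum: Beta(0.2, 6) truncated to [1/(2N), 0.5]
    maf_alpha: float = 0.2
    maf_beta: float = 6.0
    # annotation structure
    n_states: int = 200
    state_segment_bp: int = 10_000
    repeat_classes: dict = field(default_factory=lambda: dict(DEFAULT_REPEAT_CLASSES))
    repeat_fraction: float = 0.5
    state_repeat_affinity_sd: float = 1.3
    # Dirichlet concentration of each state's repeat-class composition;
    # small values give states dominated by particular repeat families,
    # as observed for real chromatin/conservation states
    state_class_concentration: float = 0.3
    excluded_fraction: float = 0.01
    n_genes: int = 1000
    gene_length_bp: int = 20_000
    ptv_rate: float = 0.10
    # disease models per phenotype (prevalences: BD 1%, SZ 1%, SZ+BD 2%)
    disease_bd: DiseaseModel = field(default_factory=lambda: DiseaseModel(prevalence=0.01))
    disease_sz: DiseaseModel = field(default_factory=lambda: DiseaseModel(prevalence=0.01))
    # covariate structure
    female_frac_internal: float = 0.42
    female_frac_external: float = 0.62
    n_internal_batches: int = 3
    # batch / sequencing model
    batch: BatchModel = field(default_factory=BatchModel)
    apply_batch_effect: bool = True
    # relatedness spikes
    n_dup_pairs: int = 0
    n_po_pairs: int = 0
    # ancestry: admixture proportion ~ Beta(a, b); Balding-Nichols divergence
    # mild gradients: strong enough for PC1 to track ancestry, weak enough
    # that ten common-variant PCs fully absorb rare-variant stratification
    admix_a: float = 8.0
    admix_b: float = 2.0
    fst: float = 0.003
    missing_rate: float = 0.0005
    seed: int = 0

    def validate(self) -> None:
        self.disease_bd.validate()
        self.disease_sz.validate()
        self.batch.validate()
        if self.repeat_fraction + self.excluded_fraction > 1:
            raise ValueError("repeat_fraction + excluded_fraction must be <= 1")
        if not 0 <= self.missing_rate <= 0.001:
            raise ValueError("missing_rate must be <= 0.1%")

    @property
    def n_total(self) -> int:
        return self.n_bd + self.n_sz + self.n_internal_control + self.n_external_control

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.genome)


@dataclass
class CohortData:
    samples: list
    variants: list
    genotypes: GenotypeMatrix
    tracks: dict
    truth: dict

    def outcome(self, groups_a: tuple, groups_b: tuple):
        """(index array, 0/1 outcome) for a two-group comparison; group A = 1."""
        idx, y = [], []
        for i, s in enumerate(self.samples):
            if s.cohort in groups_a:
                idx.append(i)
                y.append(1)
            elif s.cohort in groups_b:
                idx.append(i)
                y.append(0)
        return np.asarray(idx), np.asarray(y)


# ---------------------------------------------------------------------------
# genome annotation scaffolding


def _build_annotation(config: CohortConfig, rng: np.random.Generator):
    """Segment the genome into states with state-dependent repeat content.

    Each ``state_segment_bp`` segment gets one state label; a prefix of each
    segment is covered by a repeat interval whose length scales with the
    state's repeat affinity (log-normal across states), calibrated so the
    genome-wide repeat fraction matches the config.  This reproduces the
    empirical coupling between annotation states and repeat classes that
    makes state-level burden tests sensitive to calling artifacts.
    """
    seg = config.state_segment_bp
    chrom_names = [c for c, _ in config.genome]
    chrom_lens = np.array([l for _, l in config.genome], dtype=np.int64)
    n_segs = (chrom_lens + seg - 1) // seg
    total_segs = int(n_segs.sum())

    state_of_seg = rng.integers(0, config.n_states, size=total_segs)
    affinity = np.exp(rng.normal(0.0, config.state_repeat_affinity_sd, size=config.n_states))
    raw = affinity[state_of_seg]
    frac = raw * (config.repeat_fraction / raw.mean())
    frac = np.clip(frac, 0.0, 0.95)
    # renormalise after clipping so the realised mean matches the target
    if frac.mean() > 0:
        frac *= min(config.repeat_fraction / frac.mean(), 0.95 / max(frac.max(), 1e-9))

    class_names = list(config.repeat_classes)
    class_w = np.array([config.repeat_classes[c] for c in class_names], dtype=float)
    class_w = class_w / class_w.sum()
    # each state gets its own repeat-class composition (Dirichlet around the
    # genome-wide weights) so that states differ in which repeat families
    # they harbour, not just in how much repeat they contain
    conc = config.state_class_concentration
    state_class_probs = rng.dirichlet(np.maximum(conc * len(class_names) * class_w, 1e-3), size=config.n_states)
    class_of_seg = np.empty(total_segs, dtype=np.int64)
    for z in range(config.n_states):
        rows = np.flatnonzero(state_of_seg == z)
        if rows.size:
            class_of_seg[rows] = rng.choice(len(class_names), size=rows.size, p=state_class_probs[z])

    seg_chrom_idx = np.repeat(np.arange(len(chrom_names)), n_segs)
    offsets = np.concatenate([np.arange(n) * seg for n in n_segs])
    seg_start = offsets
    seg_end = np.minimum(seg_start + seg, chrom_lens[seg_chrom_idx])
    rep_len = np.minimum((frac * seg).astype(np.int64), seg_end - seg_start)

    state_ivs, repeat_ivs = [], []
    for i in range(total_segs):
        chrom = chrom_names[seg_chrom_idx[i]]
        state_ivs.append((chrom, int(seg_start[i]), int(seg_end[i]), f"state_{state_of_seg[i] + 1}"))
        if rep_len[i] > 0:
            repeat_ivs.append(
                (chrom, int(seg_start[i]), int(seg_start[i] + rep_len[i]), class_names[class_of_seg[i]])
            )

    state_track = IntervalTrack("states", state_ivs, multi_label=False)
    repeat_track = IntervalTrack("repeats", repeat_ivs, multi_label=True)

    # genes: evenly spaced non-overlapping intervals (length capped by the
    # spacing so dense configurations stay valid)
    gene_ivs = []
    stride = max(config.genome_length // max(config.n_genes, 1), 1)
    gene_len = max(min(config.gene_length_bp, stride // 2), 1)
    g = 0
    for chrom, length in config.genome:
        pos = stride // 4
        while pos + gene_len < length and g < config.n_genes:
            gene_ivs.append((chrom, int(pos), int(pos + gene_len), f"gene_{g + 1}"))
            pos += stride
            g += 1
    gene_track = IntervalTrack("genes", gene_ivs, multi_label=False)

    # excluded regions: sparse fixed-length intervals
    excl_ivs = []
    n_excl = max(int(config.excluded_fraction * config.genome_length / 50_000), 0)
    for chrom, length in config.genome:
        k = max(n_excl // len(config.genome), 0)
        if k == 0:
            continue
        starts = rng.integers(0, max(length - 50_000, 1), size=k)
        for s in np.sort(starts):
            excl_ivs.append((chrom, int(s), int(s + 50_000), "excluded"))
    excl_track = IntervalTrack("excluded", excl_ivs, multi_label=True)

    tracks = {
        "states": state_track,
        "repeats": repeat_track,
        "genes": gene_track,
        "excluded": excl_track,
    }
    seg_info = {
        "seg": seg,
        "chrom_names": chrom_names,
        "chrom_lens": chrom_lens,
        "n_segs": n_segs,
        "state_of_seg": state_of_seg,
        "class_of_seg": class_of_seg,
        "class_names": class_names,
        "rep_len": rep_len,
        "seg_start": seg_start,
        "seg_chrom_idx": seg_chrom_idx,
        "affinity": affinity,
    }
    return tracks, seg_info


def _annotate_from_segments(config, seg_info, chrom_idx, pos, tracks):
    """Fast variant annotation using the generator's own segment arithmetic."""
    seg = seg_info["seg"]
    cum = np.concatenate([[0], np.cumsum(seg_info["n_segs"])])
    seg_idx = cum[chrom_idx] + (pos - 1) // seg
    offset = (pos - 1) % seg
    state = seg_info["state_of_seg"][seg_idx] + 1
    in_repeat = offset < seg_info["rep_len"][seg_idx]
    rep_class = np.where(
        in_repeat,
        np.array(seg_info["class_names"], dtype=object)[seg_info["class_of_seg"][seg_idx]],
        None,
    )
    return state, rep_class


# ---------------------------------------------------------------------------
# cohort generation


def _sample_records(config: CohortConfig, rng: np.random.Generator):
    groups = (
        [("internal_case_BD", config.n_bd)]
        + [("internal_case_SZ", config.n_sz)]
        + [("internal_control", config.n_internal_control)]
        + [("external_control", config.n_external_control)]
    )
    samples = []
    i = 0
    for cohort, n in groups:
        internal = cohort != "external_control"
        female_frac = config.female_frac_internal if internal else config.female_frac_external
        for _ in range(n):
            sex = "XX" if rng.random() < female_frac else "XY"
            if internal:
                batch = f"B{rng.integers(0, config.n_internal_batches) + 1}"
            else:
                batch = "EXT"
            samples.append(
                SampleRecord(
                    sample_id=f"S{i:06d}",
                    cohort=cohort,
                    sex=sex,
                    reported_sex=sex,
                    batch=batch,
                )
            )
            i += 1
    return samples


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate a full synthetic cohort; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    tracks, seg_info = _build_annotation(config, rng)

    # variant sites
    chrom_lens = seg_info["chrom_lens"]
    total_len = int(chrom_lens.sum())
    raw_pos = np.sort(
        rng.choice(total_len, size=config.n_variants, replace=False)
        if config.n_variants < total_len
        else rng.integers(0, total_len, size=config.n_variants)
    )
    bounds = np.concatenate([[0], np.cumsum(chrom_lens)])
    chrom_idx = np.searchsorted(bounds, raw_pos, side="right") - 1
    pos = (raw_pos - bounds[chrom_idx] + 1).astype(np.int64)  # 1-based

    n_total = config.n_total
    # ancestral frequency spectrum: Beta truncated to [1/(2N), 0.5] by
    # inverse-CDF sampling (no boundary atoms)
    from scipy import stats as _stats

    lo = 1.0 / (2 * n_total)
    dist = _stats.beta(config.maf_alpha, config.maf_beta)
    c_lo, c_hi = dist.cdf(lo), dist.cdf(0.5)
    p_anc = dist.ppf(c_lo + rng.random(config.n_variants) * (c_hi - c_lo))
    # Balding-Nichols divergence between the two ancestral components
    if config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p1 = np.clip(rng.beta(a, b), lo, 1 - lo)
        p2 = np.clip(rng.beta(a, b), lo, 1 - lo)
    else:
        p1 = p_anc.copy()
        p2 = p_anc.copy()

    samples = _sample_records(config, rng)
    admix = rng.beta(config.admix_a, config.admix_b, size=n_total)

    # per-variant disease effects (regional model, retrospective tilt)
    beta_v = np.zeros(config.n_variants)
    effect_groups: set = set()
    for model, group in ((config.disease_bd, "internal_case_BD"), (config.disease_sz, "internal_case_SZ")):
        if model.region is not None and model.per_variant_log_or != 0.0:
            chrom, start, end = model.region
            ci = seg_info["chrom_names"].index(chrom)
            mask = (chrom_idx == ci) & (pos >= start) & (pos <= end)
            beta_v[mask] += model.per_variant_log_or
            if model.effect_phenotype in ("BD", "both"):
                effect_groups.add("internal_case_BD")
            if model.effect_phenotype in ("SZ", "both"):
                effect_groups.add("internal_case_SZ")

    cohorts = np.array([s.cohort for s in samples])
    is_effect_case = np.isin(cohorts, sorted(effect_groups))

    # HWE genotype draw, chunked over variants
    G = np.empty((n_total, config.n_variants), dtype=np.int8)
    chunk = max(1, int(4e7) // max(n_total, 1))
    eb = np.exp(beta_v)
    for j0 in range(0, config.n_variants, chunk):
        j1 = min(j0 + chunk, config.n_variants)
        p_sv = np.outer(1 - admix, p1[j0:j1]) + np.outer(admix, p2[j0:j1])
        if is_effect_case.any() and np.any(beta_v[j0:j1] != 0):
            tilt = p_sv * eb[j0:j1] / (1 - p_sv + p_sv * eb[j0:j1])
            p_sv = np.where(is_effect_case[:, None], tilt, p_sv)
        G[:, j0:j1] = rng.binomial(2, p_sv).astype(np.int8)

    genotypes = GenotypeMatrix(G, [s.sample_id for s in samples])

    truth: dict = {
        "seed": config.seed,
        "admixture": admix,
        "p_anc": p_anc,
        "p1": p1,
        "p2": p2,
        "beta_v": beta_v,
        "effect_groups": sorted(effect_groups),
        "state_affinity": seg_info["affinity"],
    }

    # relatedness spikes (duplicates copy genotypes before the batch effect
    # so each copy receives independent calling noise)
    if config.n_dup_pairs or config.n_po_pairs:
        spike_relatives(
            samples, genotypes, config.n_dup_pairs, config.n_po_pairs, rng=rng, truth=truth, p_ref=(p1, p2), admix=admix
        )
    else:
        truth["duplicate_pairs"] = []
        truth["parent_offspring_pairs"] = []

    # variant annotation from the segment structure
    state, rep_class = _annotate_from_segments(config, seg_info, chrom_idx, pos, tracks)
    maf0 = np.minimum(G.mean(axis=0) / 2.0, 1 - G.mean(axis=0) / 2.0)

    variants = []
    base_map = {"A": "G", "C": "T", "G": "A", "T": "C"}
    refs = rng.choice(np.array(["A", "C", "G", "T"]), size=config.n_variants)
    for j in range(config.n_variants):
        variants.append(
            VariantRecord(
                chrom=seg_info["chrom_names"][chrom_idx[j]],
                pos=int(pos[j]),
                ref=str(refs[j]),
                alt=base_map[str(refs[j])],
                is_snv=True,
            )
        )

    # batch effect + sequencing metrics
    if config.apply_batch_effect:
        inject_batch_effect(
            genotypes,
            variants,
            samples,
            config.batch,
            rng=rng,
            dropout_mask=maf0 < config.batch.dropout_maf,
            spurious_mask=maf0 < config.batch.spurious_maf,
            repeat_class=rep_class,
            truth=truth,
        )
    else:
        depths = _draw_depths(samples, config.batch, rng)
        _fill_metrics(samples, depths, config.batch, rng)
        truth["depth"] = depths
        truth["batch_applied"] = False

    # sparse missingness
    if config.missing_rate > 0:
        n_miss = rng.binomial(genotypes.data.size, config.missing_rate)
        if n_miss:
            flat = rng.choice(genotypes.data.size, size=n_miss, replace=False)
            genotypes.data.ravel()[flat] = -1

    # final annotations + frequencies
    from .io_formats import compute_maf_mac

    maf, mac, _ = compute_maf_mac(genotypes.data)
    chroms_arr = np.array([v.chrom for v in variants], dtype=object)
    pos_arr = np.array([v.pos for v in variants], dtype=np.int64)
    gene_hit = _membership(tracks["genes"].intervals, chroms_arr, pos_arr)
    excl_hit = _membership(tracks["excluded"].intervals, chroms_arr, pos_arr)

    ptv_draw = rng.random(config.n_variants)
    for j, v in enumerate(variants):
        v.maf = float(maf[j])
        v.mac = int(mac[j])
        ann = {"state": f"state_{state[j]}"}
        if rep_class[j] is not None:
            ann["repeat"] = str(rep_class[j])
        if gene_hit[j] is not None:
            ann["gene"] = gene_hit[j]
            if ptv_draw[j] < config.ptv_rate:
                ann["ptv"] = True
        if excl_hit[j] is not None:
            ann["excluded"] = True
        v.annotations = ann

    truth["state_of_variant"] = state
    truth["repeat_class_of_variant"] = rep_class
    return CohortData(samples=samples, variants=variants, genotypes=genotypes, tracks=tracks, truth=truth)


def _membership(intervals, chroms: np.ndarray, pos: np.ndarray):
    """Vectorised point lookup into sorted non-overlapping intervals.

    Returns an object array of labels (None where no interval contains the
    1-based position).
    """
    out = np.full(len(pos), None, dtype=object)
    by_chrom: dict = {}
    for chrom, s, e, label in intervals:
        by_chrom.setdefault(chrom, []).append((s, e, label))
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv[0] for iv in ivs])
        ends = np.array([iv[1] for iv in ivs])
        labels = np.array([iv[2] for iv in ivs], dtype=object)
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        p0 = pos[sel] - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        out[sel[ok]] = labels[idx[ok]]
    return out


# ---------------------------------------------------------------------------
# phenotype assignment (prospective model)


def assign_phenotypes(
    samples: list,
    genotypes: GenotypeMatrix,
    model: DiseaseModel,
    variant_effects: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Prospective case/control labels under the logistic disease model.

    ``logit P(case) = alpha + sex_log_or * is_female + sum_v beta_v g_v``
    with the intercept solved by bisection so that the population-average
    case probability equals the configured prevalence.  Returns the 0/1
    phenotype array and the solved intercept.
    """
    model.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    g = genotypes.dosage()
    score = np.zeros(n)
    if variant_effects is not None and np.any(variant_effects != 0):
        score += g @ np.asarray(variant_effects, dtype=float)
    if model.sex_log_or != 0.0:
        female = np.array([1.0 if s.sex == "XX" else 0.0 for s in samples])
        score += model.sex_log_or * female

    def mean_prev(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + score)))))

    lo, hi = -40.0, 20.0
    if not mean_prev(lo) <= model.prevalence <= mean_prev(hi):
        raise ValueError("target prevalence unattainable under the given effects")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prev(mid) < model.prevalence:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    prob = 1.0 / (1.0 + np.exp(-(alpha + score)))
    pheno = (rng.random(n) < prob).astype(int)
    return pheno, alpha


# ---------------------------------------------------------------------------
# batch effect


def _draw_depths(samples, batch: BatchModel, rng):
    internal = np.array([s.cohort != "external_control" for s in samples])
    depths = np.where(
        internal,
        rng.normal(batch.depth_mean_internal, batch.depth_sd_internal, size=len(samples)),
        rng.normal(batch.depth_mean_external, batch.depth_sd_external, size=len(samples)),
    )
    return np.clip(depths, 5.0, None)


def _fill_metrics(samples, depths, batch: BatchModel, rng):
    """Per-sample QC metrics as depth-driven functions plus noise."""
    n = len(samples)
    noise = batch.metric_noise
    mean_depth = depths + rng.normal(0, noise, n)
    contamination = np.clip(np.abs(rng.normal(0.004, 0.004, n)), 0, 1)
    completeness = np.clip(
        1.0 - 1.3 * np.exp(-np.clip(depths - 8.0, 0, None) / 3.5) + rng.normal(0, 0.001, n),
        0.0,
        1.0,
    )
    q20_fraction = np.clip(0.80 + 0.004 * depths + rng.normal(0, 0.002 * noise * 4, n), 0, 1)
    callable_fraction = np.clip(0.86 + 0.003 * depths + rng.normal(0, 0.002 * noise * 4, n), 0, 1)
    uniformity = np.clip(0.70 + 0.006 * depths + rng.normal(0, 0.003 * noise * 4, n), 0, 1)
    # fraction of sites covered at >=30x: a steep, threshold-like function
    # of mean depth, as reported by standard coverage summaries
    from scipy.special import ndtr

    depth30_completeness = np.clip(
        ndtr((depths - 30.0) / 8.5) + rng.normal(0, 0.002 * noise * 4, n), 0, 1
    )
    for i, s in enumerate(samples):
        s.metrics = {
            "mean_depth": float(mean_depth[i]),
            "contamination": float(contamination[i]),
            "depth10_completeness": float(completeness[i]),
            "depth30_completeness": float(depth30_completeness[i]),
            "q20_fraction": float(q20_fraction[i]),
            "callable_fraction": float(callable_fraction[i]),
            "coverage_uniformity": float(uniformity[i]),
        }


def inject_batch_effect(
    genotypes: GenotypeMatrix,
    variants: list,
    samples: list,
    batch: BatchModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    maf: np.ndarray | None = None,
    dropout_mask: np.ndarray | None = None,
    spurious_mask: np.ndarray | None = None,
    repeat_class: np.ndarray | None = None,
    truth: dict | None = None,
):
    """Apply depth-dependent dropout/spurious calls and regenerate metrics.

    Modifies ``genotypes`` and ``samples`` in place.  Dropout perturbs
    rare variants (MAF < ``dropout_maf``); spurious calls are restricted to
    ultra-rare sites (MAF < ``spurious_maf``); both rates are scaled per
    variant by the repeat-class multiplier.
    """
    batch.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    n, m = genotypes.data.shape
    depths = _draw_depths(samples, batch, rng)
    _fill_metrics(samples, depths, batch, rng)

    if dropout_mask is None or spurious_mask is None:
        if maf is None:
            from .io_formats import compute_maf_mac

            maf, _, _ = compute_maf_mac(genotypes.data)
        if dropout_mask is None:
            dropout_mask = maf < batch.dropout_maf
        if spurious_mask is None:
            spurious_mask = maf < batch.spurious_maf
    if repeat_class is None:
        repeat_class = np.array([v.annotations.get("repeat") for v in variants], dtype=object)

    mult = np.array([batch.multiplier(rc) for rc in repeat_class])
    d_s = batch.dropout_rate(depths)
    s_s = batch.spurious_rate(depths)

    if truth is not None:
        truth["depth"] = depths
        truth["dropout_rate"] = d_s
        truth["spurious_rate"] = s_s
        truth["class_multiplier"] = mult
        truth["batch_applied"] = True

    if batch.dropout_ceiling == 0 and batch.spurious_ceiling == 0:
        return depths

    touched = np.flatnonzero(dropout_mask | spurious_mask)
    chunk = max(1, int(4e7) // max(n, 1))
    G = genotypes.data
    for k0 in range(0, touched.size, chunk):
        cols = touched[k0 : k0 + chunk]
        sub = G[:, cols]
        u = rng.random(sub.shape)
        p_drop = np.outer(d_s, mult[cols]) * dropout_mask[cols]
        p_spur = np.outer(s_s, mult[cols]) * spurious_mask[cols]
        drop = (sub == 1) & (u < p_drop)
        spur = (sub == 0) & (u < p_spur)
        sub = np.where(drop, 0, sub)
        sub = np.where(spur, 1, sub)
        G[:, cols] = sub.astype(np.int8)
    return depths


# ---------------------------------------------------------------------------
# relatedness spikes


def spike_relatives(
    samples: list,
    genotypes: GenotypeMatrix,
    n_dup: int,
    n_po: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    truth: dict | None = None,
    p_ref: tuple | None = None,
    admix: np.ndarray | None = None,
):
    """Turn existing samples into duplicates / parent-offspring of others.

    Duplicates copy the source genotype row verbatim (independent calling
    noise is added later by the batch-effect stage).  Offspring inherit one
    transmitted allele per variant from the parent; the untransmitted allele
    is drawn from the parent's population allele frequency.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    need = 2 * (n_dup + n_po)
    if need > n:
        raise ValueError("not enough samples to spike the requested relative pairs")
    order = rng.permutation(n)
    dup_pairs, po_pairs = [], []
    k = 0
    for _ in range(n_dup):
        a, b = int(order[k]), int(order[k + 1])
        k += 2
        genotypes.data[b] = genotypes.data[a]
        dup_pairs.append((a, b))
    for _ in range(n_po):
        a, b = int(order[k]), int(order[k + 1])  # a = parent, b = offspring
        k += 2
        g_par = genotypes.data[a].astype(np.int16)
        transmitted = rng.binomial(1, np.clip(g_par / 2.0, 0, 1))
        if p_ref is not None and admix is not None:
            p1, p2 = p_ref
            p_other = (1 - admix[b]) * p1 + admix[b] * p2
        else:
            p_other = np.clip(genotypes.data.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
        other = rng.binomial(1, p_other)
        genotypes.data[b] = (transmitted + other).astype(np.int8)
        po_pairs.append((a, b))
    if truth is not None:
        truth["duplicate_pairs"] = dup_pairs
        truth["parent_offspring_pairs"] = po_pairs
    return dup_pairs, po_pairs
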
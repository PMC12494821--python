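import numpy as np
import pytest
from scipy import stats

from statewise_burden.io_formats import GenotypeMatrix, compute_maf_mac
from statewise_burden.sample_qc import kinship_matrix
from statewise_burden.synthetic_cohort import (
    BatchModel,
    CohortConfig,
    DiseaseModel,
    assign_phenotypes,
    generate_cohort,
    inject_batch_effect,
    spike_relatives,
)
from tests.conftest import hwe_genotypes


def tiny_config(**kw):
    base = dict(
        n_bd=40,
        n_sz=60,
        n_internal_control=80,
        n_external_control=120,
        genome=(("chr1", 5_000_000),),
        n_variants=1200,
        seed=5,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestGenerateCohort:
    def test_seed_reproducibility_byte_identical(self):
        a = generate_cohort(tiny_config())
        b = generate_cohort(tiny_config())
        assert np.array_equal(a.genotypes.data, b.genotypes.data)
        assert [s.metrics for s in a.samples] == [s.metrics for s in b.samples]
        assert a.tracks["states"].intervals == b.tracks["states"].intervals
        assert np.array_equal(a.truth["depth"], b.truth["depth"])

    def test_group_sizes_and_depth_separation(self, small_cohort):
        cfg, cohort = small_cohort
        coh = np.array([s.cohort for s in cohort.samples])
        assert (coh == "internal_case_BD").sum() == cfg.n_bd
        assert (coh == "external_control").sum() == cfg.n_external_control
        depth = cohort.truth["depth"]
        internal = coh != "external_control"
        assert depth[~internal].mean() - depth[internal].mean() > 5

    def test_maf_spectrum_matches_truncated_beta(self):
        cfg = tiny_config(n_variants=50_000, fst=0.0, genome=(("chr1", 60_000_000),))
        cohort = generate_cohort(cfg)
        p = cohort.truth["p_anc"]
        lo = 1.0 / (2 * cfg.n_total)
        dist = stats.beta(cfg.maf_alpha, cfg.maf_beta)
        c_lo, c_hi = dist.cdf(lo), dist.cdf(0.5)

        def cdf(x):
            return (dist.cdf(x) - c_lo) / (c_hi - c_lo)

        ks = stats.kstest(p, cdf)
        assert ks.pvalue > 0.01

    def test_states_partition_genome_and_repeats_have_classes(self, small_cohort):
        _, cohort = small_cohort
        states = {v.annotations["state"] for v in cohort.variants}
        assert all(s.startswith("state_") for s in states)
        classes = {v.annotations.get("repeat") for v in cohort.variants} - {None}
        assert len(classes) > 5
        frac_repeat = np.mean([1 if v.annotations.get("repeat") else 0 for v in cohort.variants])
        assert 0.3 < frac_repeat < 0.7

    def test_truth_record_covers_latent_state(self, small_cohort):
        _, cohort = small_cohort
        for key in ("admixture", "p_anc", "beta_v", "depth", "dropout_rate", "spurious_rate"):
            assert key in cohort.truth
        assert len(cohort.truth["admixture"]) == len(cohort.samples)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(tiny_config(missing_rate=0.5))
        with pytest.raises(ValueError):
            CohortConfig(disease_bd=DiseaseModel(prevalence=1.5)).validate()


class TestAssignPhenotypes:
    def test_null_model_independent_of_genotype(self, rng):
        # under the null, per-variant association chi-square p-values are
        # uniform across replicates
        pvals = []
        for rep in range(150):
            gm = hwe_genotypes(rng, 250, np.full(4, 0.3))
            samples = [None] * 250
            pheno, _ = assign_phenotypes(
                _dummy_samples(250), gm, DiseaseModel(prevalence=0.3), rng=rng
            )
            if pheno.sum() in (0, 250):
                continue
            g = gm.data[:, 0]
            tab = np.array(
                [
                    [(g[pheno == 1] == k).sum() for k in (0, 1, 2)],
                    [(g[pheno == 0] == k).sum() for k in (0, 1, 2)],
                ]
            )
            tab = tab[:, tab.sum(axis=0) > 0]
            pvals.append(stats.chi2_contingency(tab)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_prevalence_within_binomial_ci(self, rng):
        n = 20_000
        gm = hwe_genotypes(rng, n, np.full(5, 0.2))
        pheno, _ = assign_phenotypes(_dummy_samples(n), gm, DiseaseModel(prevalence=0.01), rng=rng)
        k = pheno.sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.01)
        assert lo <= k <= hi

    def test_intercept_recovery_at_scale(self, rng):
        n = 50_000
        gm = hwe_genotypes(rng, n, np.full(3, 0.3))
        effects = np.array([0.2, -0.1, 0.0])
        pheno, alpha = assign_phenotypes(
            _dummy_samples(n), gm, DiseaseModel(prevalence=0.02), variant_effects=effects, rng=rng
        )
        assert abs(pheno.mean() - 0.02) / 0.02 < 0.10

    def test_protective_regional_burden_lowers_case_burden(self):
        # retrospective sampling in generate_cohort: cases carry fewer
        # alleles in the protective window, averaged over replicates
        diffs = []
        for seed in range(40):
            cfg = tiny_config(
                seed=seed,
                n_variants=800,
                genome=(("chr1", 2_000_000),),
                apply_batch_effect=False,
                disease_bd=DiseaseModel(
                    prevalence=0.01,
                    region=("chr1", 1_000_001, 1_050_000),
                    per_variant_log_or=-0.5,
                    effect_phenotype="BD",
                ),
            )
            c = generate_cohort(cfg)
            in_region = np.array(
                [1_000_001 <= v.pos <= 1_050_000 and v.chrom == "chr1" for v in c.variants]
            )
            coh = np.array([s.cohort for s in c.samples])
            g = np.maximum(c.genotypes.data[:, in_region], 0).sum(axis=1)
            diffs.append(g[coh == "internal_case_BD"].mean() - g[coh == "internal_control"].mean())
        assert np.mean(diffs) < 0

    def test_unattainable_prevalence_raises(self, rng):
        gm = hwe_genotypes(rng, 100, np.full(2, 0.3))
        with pytest.raises(ValueError):
            assign_phenotypes(
                _dummy_samples(100),
                gm,
                DiseaseModel(prevalence=1e-12),
                variant_effects=np.array([50.0, 50.0]),
                rng=rng,
            )


def _dummy_samples(n):
    from statewise_burden.io_formats import SampleRecord

    return [
        SampleRecord(f"s{i}", "internal_control", "XX", "XX", "B1", metrics={}) for i in range(n)
    ]


class TestBatchEffect:
    def test_zero_rates_leave_genotypes_unchanged(self, small_cohort, rng):
        _, cohort = small_cohort
        g_before = cohort.genotypes.data.copy()
        gm = GenotypeMatrix(g_before.copy(), cohort.genotypes.sample_ids)
        batch = BatchModel(dropout_ceiling=0.0, spurious_ceiling=0.0)
        inject_batch_effect(gm, cohort.variants, [s for s in cohort.samples], batch, rng=rng)
        assert np.array_equal(gm.data, g_before)

    def test_dropout_makes_burden_depth_correlated(self, rng):
        cfg = tiny_config(
            seed=99,
            n_variants=4000,
            n_internal_control=400,
            n_external_control=400,
            n_bd=0,
            n_sz=0,
            genome=(("chr1", 20_000_000),),
        )
        cfg.batch = BatchModel(
            dropout_ceiling=0.15, spurious_ceiling=0.0, dropout_maf=0.05, nonrepeat_multiplier=1.0
        )
        c = generate_cohort(cfg)
        total = np.maximum(c.genotypes.data, 0).sum(axis=1).astype(float)
        rho, p = stats.spearmanr(total, c.truth["depth"])
        # dropout removes alleles preferentially from shallow samples
        assert rho > 0 and p < 0.01

    def test_spurious_calls_increase_with_depth(self, rng):
        n = 600
        gm = GenotypeMatrix(np.zeros((n, 2000), dtype=np.int8), [f"s{i}" for i in range(n)])
        samples = _dummy_samples(n)
        for i, s in enumerate(samples):
            s.cohort = "internal_control" if i < n // 2 else "external_control"
        batch = BatchModel(spurious_ceiling=0.01, dropout_ceiling=0.0, nonrepeat_multiplier=1.0)
        variants = []
        rng2 = np.random.default_rng(4)
        depths = inject_batch_effect(
            gm,
            variants,
            samples,
            batch,
            rng=rng2,
            dropout_mask=np.zeros(2000, dtype=bool),
            spurious_mask=np.ones(2000, dtype=bool),
            repeat_class=np.array([None] * 2000, dtype=object),
        )
        calls = (gm.data == 1).sum(axis=1)
        rho, p = stats.spearmanr(calls, depths)
        assert rho > 0 and p < 1e-6


class TestRelatives:
    def test_duplicate_pair_kinship_half(self, rng):
        gm = hwe_genotypes(rng, 40, rng.uniform(0.1, 0.5, 3000))
        samples = _dummy_samples(40)
        dup, po = spike_relatives(samples, gm, n_dup=2, n_po=0, rng=rng)
        phi = kinship_matrix(gm.data)
        for a, b in dup:
            assert phi[a, b] == pytest.approx(0.5)

    def test_parent_offspring_kinship_quarter(self, rng):
        gm = hwe_genotypes(rng, 30, rng.uniform(0.1, 0.5, 20_000))
        samples = _dummy_samples(30)
        _, po = spike_relatives(samples, gm, n_dup=0, n_po=2, rng=rng)
        phi = kinship_matrix(gm.data)
        for a, b in po:
            assert 0.23 <= phi[a, b] <= 0.27

    def test_too_many_pairs_rejected(self, rng):
        gm = hwe_genotypes(rng, 10, rng.uniform(0.2, 0.5, 100))
        with pytest.raises(ValueError):
            spike_relatives(_dummy_samples(10), gm, n_dup=4, n_po=3, rng=rng)
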
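import numpy as np
import pytest

from statewise_burden.io_formats import GenotypeMatrix, SampleRecord
from statewise_burden.sample_qc import (
    KINSHIP_THRESHOLD,
    compute_genetic_pcs,
    estimate_kinship,
    filter_samples,
    kinship_matrix,
    ld_prune,
    prune_related,
)
from tests.conftest import hwe_genotypes


def sample(sid, cohort="internal_control", contamination=0.01, completeness=0.99, sex="XX", reported=None):
    return SampleRecord(
        sample_id=sid,
        cohort=cohort,
        sex=sex,
        reported_sex=reported or sex,
        batch="B1",
        metrics={"contamination": contamination, "depth10_completeness": completeness},
    )


class TestFilters:
    def test_contamination_above_5pct_excluded(self):
        kept, excluded = filter_samples([sample("a", contamination=0.06)])
        assert not kept
        assert excluded["a"] == ["contamination"]

    def test_boundary_contamination_kept(self):
        kept, _ = filter_samples([sample("a", contamination=0.05)])
        assert kept

    def test_low_coverage_excluded(self):
        _, excluded = filter_samples([sample("a", completeness=0.97)])
        assert excluded["a"] == ["coverage"]

    def test_sex_mismatch_excluded(self):
        _, excluded = filter_samples([sample("a", sex="XY", reported="XX")])
        assert excluded["a"] == ["sex_mismatch"]

    def test_clean_sample_kept(self):
        kept, excluded = filter_samples([sample("a")])
        assert len(kept) == 1 and not excluded

    def test_missing_metric_names_sample(self):
        s = sample("weird")
        del s.metrics["contamination"]
        with pytest.raises(KeyError, match="weird"):
            filter_samples([s])


class TestKinship:
    def test_matches_brute_force_tally_on_toy_pairs(self, rng):
        g = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        phi = kinship_matrix(g)
        for i in range(4):
            for j in range(i + 1, 4):
                n_hh = int(np.sum((g[i] == 1) & (g[j] == 1)))
                n_opp = int(np.sum(((g[i] == 0) & (g[j] == 2)) | ((g[i] == 2) & (g[j] == 0))))
                het_i, het_j = int(np.sum(g[i] == 1)), int(np.sum(g[j] == 1))
                if het_i + het_j:
                    expected = (n_hh - 2 * n_opp) / (het_i + het_j)
                    assert phi[i, j] == pytest.approx(expected)

    def test_identical_genomes_exactly_half(self, rng):
        g = rng.integers(0, 3, size=(1, 500)).astype(np.int8)
        g = np.vstack([g, g])
        phi = kinship_matrix(g)
        assert phi[0, 1] == pytest.approx(0.5)

    def test_parent_offspring_quarter(self, rng):
        m = 20_000
        p = rng.uniform(0.1, 0.5, m)
        par = rng.binomial(2, p)
        transmitted = rng.binomial(1, par / 2.0)
        child = transmitted + rng.binomial(1, p)
        other = rng.binomial(2, p, size=(30, m))
        g = np.vstack([par, child, other]).astype(np.int8)
        phi = kinship_matrix(g)
        assert 0.20 < phi[0, 1] < 0.30
        # unrelated pairs hover near zero
        assert abs(phi[0, 2]) < 0.02 and abs(phi[1, 3]) < 0.02

    def test_null_pairs_rarely_exceed_threshold(self, rng):
        gm = hwe_genotypes(rng, 300, rng.uniform(0.1, 0.5, 20_000))
        phi, pairs = estimate_kinship(gm, maf_min=0.05)
        assert len(pairs) <= 1

    def test_requires_enough_common_variants(self, rng):
        gm = hwe_genotypes(rng, 10, rng.uniform(0.1, 0.5, 50))
        with pytest.raises(ValueError):
            estimate_kinship(gm, maf_min=0.05)


class TestPruneRelated:
    def _phi(self, n, entries):
        phi = np.zeros((n, n))
        np.fill_diagonal(phi, 0.5)
        for i, j, v in entries:
            phi[i, j] = phi[j, i] = v
        return phi

    def test_single_pair_removes_exactly_one(self):
        samples = [sample(f"s{i}") for i in range(4)]
        kept, removed = prune_related(self._phi(4, [(0, 1, 0.05)]), samples)
        assert len(removed) == 1 and removed[0] in (0, 1)

    def test_chain_keeps_endpoints(self):
        samples = [sample(f"s{i}") for i in range(3)]
        kept, removed = prune_related(self._phi(3, [(0, 1, 0.06), (1, 2, 0.06)]), samples)
        assert removed == [1]
        assert kept == [0, 2]

    def test_internal_external_duplicate_keeps_internal(self):
        samples = [sample("ext", cohort="external_control"), sample("int")]
        kept, removed = prune_related(self._phi(2, [(0, 1, 0.49)]), samples)
        assert kept == [1] and removed == [0]

    def test_no_retained_pair_above_threshold_brute_force(self, rng):
        n = 40
        phi = np.zeros((n, n))
        np.fill_diagonal(phi, 0.5)
        for _ in range(30):
            i, j = rng.integers(0, n, 2)
            if i != j:
                phi[i, j] = phi[j, i] = rng.uniform(0.03, 0.3)
        samples = [sample(f"s{i}") for i in range(n)]
        kept, _ = prune_related(phi, samples, seed=3)
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                assert phi[kept[a], kept[b]] <= KINSHIP_THRESHOLD


class TestLdPrune:
    def test_duplicated_column_dropped(self, rng):
        g = rng.binomial(2, 0.3, size=(200, 5)).astype(np.int8)
        g = np.column_stack([g[:, 0], g]).astype(np.int8)  # col 0 duplicated
        gm = GenotypeMatrix(g, [f"s{i}" for i in range(200)])
        pos = np.arange(1, 7) * 1000
        kept = ld_prune(gm, pos, np.array(["chr1"] * 6, dtype=object))
        assert 1 not in kept or 0 not in kept  # only one copy survives
        assert kept.size == 5

    def test_low_maf_variants_not_considered(self, rng):
        g = np.zeros((300, 2), dtype=np.int8)
        g[:20, 0] = 1  # maf ~0.033
        g[:150, 1] = 1
        gm = GenotypeMatrix(g, [f"s{i}" for i in range(300)])
        kept = ld_prune(gm, np.array([100, 200]), np.array(["chr1", "chr1"], dtype=object))
        assert kept.tolist() == [1]

    def test_independent_variants_mostly_retained(self, rng):
        gm = hwe_genotypes(rng, 800, rng.uniform(0.1, 0.5, 400))
        pos = np.sort(rng.choice(2_000_000, 400, replace=False))
        kept = ld_prune(gm, pos, np.array(["chr1"] * 400, dtype=object))
        assert kept.size >= 0.95 * 400


class TestGeneticPcs:
    def test_two_subpopulations_separate_on_pc1(self, rng):
        m = 800
        p1, p2 = rng.uniform(0.1, 0.5, m), None
        p2 = np.clip(p1 + rng.choice([-1, 1], m) * 0.2, 0.05, 0.95)
        g = np.vstack(
            [rng.binomial(2, p1, size=(150, m)), rng.binomial(2, p2, size=(150, m))]
        ).astype(np.int8)
        gm = GenotypeMatrix(g, [f"s{i}" for i in range(300)])
        scores, evr = compute_genetic_pcs(gm, k=4)
        group = np.r_[np.zeros(150), np.ones(150)]
        r = np.corrcoef(scores[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_scores_orthogonal(self, rng):
        gm = hwe_genotypes(rng, 100, rng.uniform(0.1, 0.5, 300))
        scores, _ = compute_genetic_pcs(gm, k=5)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))

    def test_permuting_samples_permutes_scores(self, rng):
        gm = hwe_genotypes(rng, 60, rng.uniform(0.1, 0.5, 200))
        scores, _ = compute_genetic_pcs(gm, k=3)
        perm = rng.permutation(60)
        gm_p = GenotypeMatrix(gm.data[perm], [gm.sample_ids[i] for i in perm])
        scores_p, _ = compute_genetic_pcs(gm_p, k=3)
        assert np.allclose(scores_p, scores[perm], atol=1e-3)

    def test_rank_deficient_returns_fewer_with_warning(self, rng):
        gm = hwe_genotypes(rng, 5, rng.uniform(0.2, 0.5, 50))
        with pytest.warns(UserWarning):
            scores, _ = compute_genetic_pcs(gm, k=10)
        assert scores.shape[1] <= 4
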
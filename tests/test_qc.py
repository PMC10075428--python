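"""QC cascade: per-step behavior, oracles, and the planted-violation ledger."""

import numpy as np
import pytest
from scipy.special import gammaln

from rarefuse.qc import (
    QCConfig,
    ancestry_outlier_filter,
    apply_qc,
    het_outlier_filter,
    hwe_exact,
    maf_filter,
    mds_components,
    relatedness,
    sex_check,
    snp_missingness_filter,
)
from rarefuse.synthetic_data import (
    SimSpec,
    ViolationSpec,
    plant_violations,
    sim_genotypes,
)

from conftest import make_dataset, random_dataset


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent route: direct log-gamma enumeration of the conditional
    distribution of heterozygote counts given the allele counts."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa

    def logprob(het):
        hom_A = (nA - het) // 2
        hom_a = (na - het) // 2
        return (
            gammaln(n + 1) - gammaln(hom_A + 1) - gammaln(het + 1)
            - gammaln(hom_a + 1) + het * np.log(2)
            + gammaln(nA + 1) + gammaln(na + 1) - gammaln(2 * n + 1)
        )

    hets = range(min(nA, na) % 2, min(nA, na) + 1, 2)
    lps = np.array([logprob(h) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = probs[list(hets).index(n_Aa)]
    return probs[probs <= obs * (1 + 1e-12)].sum()


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert hwe_exact(100, 0, 0) == 1.0

    @pytest.mark.parametrize("triple", [(0, 100, 0), (25, 50, 25), (40, 20, 40),
                                        (5, 1, 0), (0, 1, 5), (10, 30, 2)])
    def test_against_enumeration(self, triple):
        assert hwe_exact(*triple) == pytest.approx(
            hwe_enumeration_oracle(*triple), abs=1e-12)

    def test_extreme_het_excess_tiny_p(self):
        assert hwe_exact(0, 100, 0) < 1e-20

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)


class TestSnpMissingness:
    def test_strictly_greater_removed(self):
        ds = make_dataset([[0, 0], [1, -1], [2, 0], [0, 0]])
        out, removed = snp_missingness_filter(ds, 0.20)
        assert removed == ["v1"]  # 0.25 > 0.20
        assert out.n_variants == 1

    def test_max_rate_one_removes_nothing(self):
        ds = make_dataset([[-1, -1], [-1, -1]])
        out, removed = snp_missingness_filter(ds, 1.0)
        assert removed == [] and out.n_variants == 2


class TestMafFilter:
    def test_arithmetic(self):
        ds = make_dataset([[0], [1], [2], [2]])  # freq 5/8, MAF 0.375
        out, removed = maf_filter(ds, 0.05)
        assert removed == [] and out.n_variants == 1

    def test_monomorphic_removed_rare_kept(self):
        ds = make_dataset([[0, 0], [0, 0], [0, 0], [1, 0]])
        out, removed = maf_filter(ds, 0.05)
        assert removed == ["v1"]  # MAF 0; v0 has MAF 0.125

    def test_reorientation_flips_dosage(self):
        ds = make_dataset([[2, 1], [2, 0], [2, 1], [1, 2]])  # v0 freq 7/8
        out, _ = maf_filter(ds, 0.05)
        assert list(out.dosage[:, 0]) == [0, 0, 0, 1]
        assert out.variants.loc[0, "counted_allele"] == "G"
        # v1 freq 0.5: tie keeps orientation
        assert list(out.dosage[:, 1]) == [1, 0, 1, 2]

    def test_output_respects_threshold(self, rng):
        ds = random_dataset(rng, n=80, m=200, maf_range=(0.01, 0.5))
        out, _ = maf_filter(ds, 0.1)
        freq = np.nanmean(out.dosage_float(), axis=0) / 2
        assert (np.minimum(freq, 1 - freq) >= 0.1).all()
        assert (freq <= 0.5 + 1e-12).all()  # minor-allele oriented


class TestSexCheck:
    def test_simulated_sexes_and_mismatches(self, rng):
        n, m = 60, 80
        p = rng.uniform(0.2, 0.5, m)
        male = rng.random(n) < 0.5
        hap1 = rng.binomial(1, p, size=(n, m))
        hap2 = rng.binomial(1, p, size=(n, m))
        dosage = hap1 + hap2
        dosage[male] = 2 * hap1[male]  # hemizygous males
        recorded = np.where(male, 1, 2).astype(np.int8)
        recorded[0] = 2 if male[0] else 1  # one planted mismatch
        ds = make_dataset(dosage, sex=recorded, chromosomes=["X"] * m)
        F, mismatched, undetermined = sex_check(ds)
        assert mismatched == [ds.sample_ids[0]]
        assert not undetermined
        # males near 1, females near 0
        assert np.all(F[male & (np.arange(n) != 0)] > 0.8)
        assert np.all(np.abs(F[~male & (np.arange(n) != 0)]) < 0.5)

    def test_no_x_snps_skips(self):
        ds = make_dataset([[0], [1]], sex=[1, 2])
        F, mismatched, undetermined = sex_check(ds)
        assert mismatched == [] and undetermined == []
        assert np.isnan(F).all()

    def test_all_missing_x_undetermined(self):
        ds = make_dataset([[-1], [0]], sex=[2, 2], chromosomes=["X"])
        _, _, undetermined = sex_check(ds)
        assert ds.sample_ids[0] in undetermined


class TestHetOutliers:
    def test_planted_all_het_sample_flagged(self, rng):
        ds = random_dataset(rng, n=51, m=200)
        ds.dosage[7] = 1
        assert het_outlier_filter(ds, 3.0) == [ds.sample_ids[7]]

    def test_identical_rates_none_flagged(self):
        ds = make_dataset(np.tile([0, 1, 2], (5, 4)))
        assert het_outlier_filter(ds, 3.0) == []

    def test_huge_multiplier_none_flagged(self, rng):
        ds = random_dataset(rng, n=30, m=100)
        assert het_outlier_filter(ds, 1e6) == []

    def test_too_few_samples(self):
        ds = make_dataset([[1], [0]])
        with pytest.raises(ValueError):
            het_outlier_filter(ds, 3.0)


class TestRelatedness:
    def test_duplicate_sample_pihat_one(self, rng):
        ds = random_dataset(rng, n=30, m=2000)
        ds.dosage[3] = ds.dosage[11]
        pihat, flagged, _ = relatedness(ds)
        assert pihat[3, 11] > 0.95
        assert any({a, b} == {ds.sample_ids[3], ds.sample_ids[11]}
                   for a, b, _ in flagged)

    def test_unrelated_mean_near_zero(self, rng):
        ds = random_dataset(rng, n=40, m=5000)
        pihat, _, _ = relatedness(ds)
        iu = np.triu_indices(40, k=1)
        assert abs(pihat[iu].mean()) < 0.05

    def test_parent_offspring_half(self, rng):
        m = 5000
        p = rng.uniform(0.2, 0.5, m)
        hp = [rng.binomial(1, p, m) for _ in range(4)]
        parent = hp[0] + hp[1]
        child = hp[0] + hp[2]  # shares one haplotype
        others = rng.binomial(2, p, size=(20, m))
        dosage = np.vstack([parent, child, others]).astype(np.int8)
        ds = make_dataset(dosage)
        pihat, _, _ = relatedness(ds)
        assert pihat[0, 1] == pytest.approx(0.5, abs=0.1)

    def test_higher_missingness_member_removed(self, rng):
        ds = random_dataset(rng, n=20, m=2000)
        ds.dosage[5] = ds.dosage[2]
        ds.dosage[5, :100] = -1
        _, _, to_remove = relatedness(ds)
        assert to_remove == [ds.sample_ids[5]]


class TestMds:
    def test_identical_samples_zero_components(self):
        ds = make_dataset(np.tile([0, 1, 2, 1], (6, 3)))
        comps = mds_components(ds, 2)
        assert np.allclose(comps, 0.0)

    def test_two_populations_separate(self, rng):
        m = 500
        p1 = rng.uniform(0.1, 0.5, m)
        p2 = np.clip(p1 + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
        d1 = rng.binomial(2, p1, size=(30, m))
        d2 = rng.binomial(2, p2, size=(30, m))
        ds = make_dataset(np.vstack([d1, d2]).astype(np.int8))
        comps = mds_components(ds, 4)
        group = np.r_[np.zeros(30), np.ones(30)]
        r = np.corrcoef(comps[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_sample_order_invariance_up_to_sign(self, rng):
        ds = random_dataset(rng, n=25, m=300)
        perm = rng.permutation(25)
        comps = mds_components(ds, 3)
        comps_perm = mds_components(ds.subset(sample_idx=perm), 3)
        for k in range(3):
            a, b = comps[perm, k], comps_perm[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


class TestAncestryOutliers:
    def test_planted_outliers_flagged_exactly(self, rng):
        m = 800
        p = rng.uniform(0.15, 0.5, m)
        base = rng.binomial(2, p, size=(95, m))
        flip = rng.random(m) < 0.5
        p_out = np.where(flip, 1 - p, p)
        outl = rng.binomial(2, p_out, size=(5, m))
        ds = make_dataset(np.vstack([base, outl]).astype(np.int8))
        comps = mds_components(ds, 4)
        assert sorted(ancestry_outlier_filter(comps, 3.0)) == [95, 96, 97, 98, 99]

    def test_homogeneous_flags_few(self, rng):
        ds = random_dataset(rng, n=100, m=600)
        comps = mds_components(ds, 4)
        assert len(ancestry_outlier_filter(comps, 3.0)) <= 5

    def test_huge_multiplier_none(self, rng):
        ds = random_dataset(rng, n=30, m=200)
        comps = mds_components(ds, 2)
        assert ancestry_outlier_filter(comps, 1e6) == []


def planted_fixture(seed=13):
    spec = SimSpec(
        n_samples=100, n_genes=80, snps_per_gene=15, n_x_snps=400,
        maf_range=(0.2, 0.5), n_causal_genes=2, causal_snps_per_gene=1,
        seed=seed,
    )
    ds, _, _ = sim_genotypes(spec)
    vspec = ViolationSpec(
        n_high_missing_snps=7, n_sex_mismatches=2, n_low_maf_snps=3,
        n_hwe_snps=1, n_duplicate_pairs=1, n_het_outliers=1,
        n_ancestry_outliers=5, seed=seed,
    )
    return plant_violations(ds, vspec)


class TestApplyQc:
    def test_planted_violation_ledger_exact(self):
        ds, truth = planted_fixture()
        out, rep = apply_qc(ds, QCConfig())
        v = truth.violations
        assert rep.snp_steps["snp_missingness"] == len(v["high_missing_snps"])
        assert rep.sample_steps["sample_missingness"] == 0
        assert rep.sample_steps["sex_mismatch"] == len(v["sex_mismatches"])
        assert rep.snp_steps["maf"] == len(v["low_maf_snps"])
        assert rep.snp_steps["hwe"] == len(v["hwe_snps"])
        assert rep.sample_steps["heterozygosity"] == len(v["het_outliers"])
        assert rep.sample_steps["relatedness"] == 1
        assert rep.sample_steps["ancestry"] == len(v["ancestry_outliers"])
        # the right items, not just the right counts
        assert set(rep.removed_snp_ids["snp_missingness"]) == set(v["high_missing_snps"])
        assert set(rep.removed_sample_ids["sex_mismatch"]) == set(v["sex_mismatches"])
        assert set(rep.removed_snp_ids["maf"]) == set(v["low_maf_snps"])
        assert set(rep.removed_snp_ids["hwe"]) == set(v["hwe_snps"])
        assert set(rep.removed_sample_ids["relatedness"]) == set(v["duplicate_samples"])
        assert set(rep.removed_sample_ids["ancestry"]) == set(v["ancestry_outliers"])

    def test_conservation_per_axis(self):
        ds, _ = planted_fixture()
        _, rep = apply_qc(ds, QCConfig())
        assert rep.initial_snps - sum(rep.snp_steps.values()) == rep.final_snps
        assert (rep.initial_samples - sum(rep.sample_steps.values())
                == rep.final_samples)

    def test_clean_dataset_untouched_and_deterministic(self, rng):
        ds = random_dataset(rng, n=60, m=1500, maf_range=(0.2, 0.5))
        out1, rep1 = apply_qc(ds, QCConfig())
        out2, rep2 = apply_qc(ds, QCConfig())
        assert rep1.snp_steps == rep2.snp_steps
        assert rep1.sample_steps == rep2.sample_steps
        assert sum(rep1.snp_steps.values()) == 0
        assert out1.equals(out2)

    def test_idempotent(self):
        ds, _ = planted_fixture()
        once, _ = apply_qc(ds, QCConfig())
        twice, rep2 = apply_qc(once, QCConfig())
        assert twice.equals(once)
        assert sum(rep2.snp_steps.values()) == 0
        assert sum(rep2.sample_steps.values()) == 0
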
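import numpy as np
import pytest

from hwesurvey import FamilyData, SurveyDesign
from hwesurvey.genotypes import GenotypeModel, genotype_distribution
from hwesurvey.qs import (
    dmu_dtheta,
    full_sib_cov,
    indicator_matrix,
    mean_vector,
    parent_offspring_cov,
    qs_test,
    score_contributions,
    self_cov,
    solve_null_allele_freq,
    trio_covariance,
    variance_score_r,
)
from hwesurvey.simulate import SimulationConfig, generate_population

from ._oracles import (
    child_probs,
    genotype_probs,
    pair_indicator_cov,
    parent_child_joint,
    sib_joint,
)
from .conftest import independent_families, make_survey_sample


def _indicator_moments(joint3x3):
    marg1, marg2 = joint3x3.sum(axis=1), joint3x3.sum(axis=0)
    j2 = joint3x3[:2, :2]
    return pair_indicator_cov(j2, marg1[:2], marg2[:2])


class TestMeanModel:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.5, 0.0, (0.25, 0.5)), (0.3, 1.0, (0.3, 0.0)), (0.3, 0.1, (0.111, 0.378))],
    )
    def test_mean_vector(self, p, r, expected):
        assert mean_vector(p, r) == pytest.approx(expected, abs=1e-12)

    def test_jacobian_matches_finite_differences(self):
        h = 1e-6
        for p, r in [(0.3, 0.0), (0.2, 0.1), (0.8, 0.05)]:
            num = np.column_stack(
                [
                    (mean_vector(p + h, r) - mean_vector(p - h, r)) / (2 * h),
                    (mean_vector(p, r + h) - mean_vector(p, r - h)) / (2 * h),
                ]
            )
            assert dmu_dtheta(p, r) == pytest.approx(num, abs=1e-6)

    def test_jacobian_special_points(self):
        assert dmu_dtheta(0.5, 0.0)[1, 0] == pytest.approx(0.0)  # het maximum
        for p in (0.0, 1.0):
            assert dmu_dtheta(p, 0.0)[0, 1] == pytest.approx(0.0)


class TestTrioCovariance:
    @pytest.mark.parametrize("p", [0.2, 0.3, 0.5, 0.8])
    def test_self_block_matches_bernoulli_moments(self, p):
        gp = genotype_probs(p, 0.0)
        expected = np.array(
            [
                [gp[0] * (1 - gp[0]), -gp[0] * gp[1]],
                [-gp[0] * gp[1], gp[1] * (1 - gp[1])],
            ]
        )
        assert self_cov(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.2, 0.3, 0.5, 0.8])
    def test_parent_offspring_block_matches_enumeration(self, p):
        oracle = _indicator_moments(parent_child_joint(p))
        assert parent_offspring_cov(p) == pytest.approx(oracle, abs=1e-12)

    def test_parent_offspring_AA_entry_at_half(self):
        # P(parent AA & child AA) - p^4 = p^3 q = 0.0625 at p = 1/2
        assert parent_offspring_cov(0.5)[0, 0] == pytest.approx(0.0625)

    @pytest.mark.parametrize("p", [0.2, 0.3, 0.5, 0.8])
    def test_full_sib_block_matches_identity_state_enumeration(self, p):
        oracle = _indicator_moments(sib_joint(p))
        assert full_sib_cov(p) == pytest.approx(oracle, abs=1e-12)

    def test_full_sib_printed_entries(self):
        p = 0.3
        q = 1 - p
        assert full_sib_cov(p)[0, 0] == pytest.approx(
            0.25 * p**2 + 0.5 * p**3 - 0.75 * p**4
        )
        assert full_sib_cov(p)[1, 1] == pytest.approx(p * q * (1 - 3 * p * q))

    def test_trio_covariance_matches_empirical(self):
        """6x6 pairwise-arrangement Var(y) vs 200,000 simulated trios."""
        n = 200_000
        cfg = SimulationConfig(p_A=0.3, r=0.0, n_psu_pop=n, families_per_psu=1)
        pop = generate_population(cfg, np.random.default_rng(77))
        y = indicator_matrix(pop.genotypes)
        emp = np.cov(y.T)
        V = trio_covariance(0.3)
        # entrywise within 3 Monte-Carlo SEs (indicator covariances: SE <~ 1/sqrt(n))
        se = 3.0 / np.sqrt(n)
        assert np.max(np.abs(emp - V)) < 3 * se

    @pytest.mark.parametrize("arrangement", ["pairwise", "literal"])
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.9])
    def test_psd_and_symmetric(self, p, arrangement):
        V = trio_covariance(p, arrangement)
        assert V == pytest.approx(V.T)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            trio_covariance(0.0)


def _exact_hwe_sample(p=0.5, scale=1000.0):
    """Families = all Mendelian trios weighted by their exact HWE probability,
    so the weighted sample composition equals the model mean exactly."""
    from ._oracles import enumerate_mendelian_trios

    trios = enumerate_mendelian_trios()
    gp = genotype_probs(p, 0.0)
    w = np.array(
        [gp[gf] * gp[gm] * child_probs(gf, gm)[gc] for gf, gm, gc in trios]
    )
    n = len(trios)
    return FamilyData(
        stratum=np.zeros(n, dtype=int),
        psu=np.arange(n) // 3,
        family_id=np.arange(n),
        genotypes=np.array(trios),
        family_weight=scale * w,
    )


class TestNullSolver:
    def test_exact_composition_recovers_p(self):
        for p in (0.2, 0.5, 0.8):
            data = _exact_hwe_sample(p)
            assert solve_null_allele_freq(data).p_tilde == pytest.approx(p, abs=1e-9)

    def test_parameter_recovery_on_simulated_sample(self):
        data = independent_families(2400, seed=4, p_A=0.3)
        p_t = solve_null_allele_freq(data).p_tilde
        # binomial-ish SE of an allele frequency from ~9600 informative alleles
        assert abs(p_t - 0.3) < 3 * np.sqrt(0.3 * 0.7 / (4 * 2400))

    def test_scale_invariance(self):
        data = independent_families(600, seed=8, p_A=0.3)
        p1 = solve_null_allele_freq(data).p_tilde
        p2 = solve_null_allele_freq(
            data.with_weights(2.0 * data.family_weight)
        ).p_tilde
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestScore:
    def test_zero_score_at_exact_composition(self):
        data = _exact_hwe_sample(0.5)
        params = solve_null_allele_freq(data)
        s, _ = score_contributions(data, params)
        assert s.sum(axis=0) == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_excess_homozygosity_gives_positive_r_score(self):
        """Weights proportional to the r=0.2 fixation-model trio distribution
        give a deterministic positive r-score at the null fit."""
        from ._oracles import enumerate_mendelian_trios

        trios = enumerate_mendelian_trios()
        gp = genotype_probs(0.3, 0.2)
        w = 1000 * np.array(
            [gp[gf] * gp[gm] * child_probs(gf, gm)[gc] for gf, gm, gc in trios]
        )
        n = len(trios)
        data = FamilyData(
            stratum=np.zeros(n, dtype=int),
            psu=np.arange(n) // 3,
            family_id=np.arange(n),
            genotypes=np.array(trios),
            family_weight=w,
        )
        params = solve_null_allele_freq(data)
        s, _ = score_contributions(data, params)
        assert s[:, 1].sum() > 0

    def test_matches_dense_per_family_loop(self):
        """Production vectorized score vs an explicit per-family W^{1/2}
        V^{-1} W^{1/2} loop."""
        data, _ = make_survey_sample(seed=6, weight_scheme="thirds_1_3_5",
                                     n_psu_sample=6)
        params = solve_null_allele_freq(data)
        s, A = score_contributions(data, params)

        p = params.p_tilde
        mu1 = mean_vector(p, 0.0)
        D1 = dmu_dtheta(p, 0.0)
        V = trio_covariance(p)
        mu = np.concatenate([mu1] * 3)
        D = np.vstack([D1] * 3)
        y = indicator_matrix(data.genotypes)
        s_loop = np.zeros_like(s)
        A_loop = np.zeros((2, 2))
        for i in range(data.n_families):
            W_half = np.diag(np.sqrt(np.repeat(data.family_weight[i], 6)))
            K = W_half @ np.linalg.inv(V) @ W_half
            s_loop[i] = D.T @ K @ (y[i] - mu)
            A_loop += D.T @ K @ D
        assert s == pytest.approx(s_loop, abs=1e-10 * np.abs(s_loop).max())
        assert A == pytest.approx(A_loop, rel=1e-10)


class TestVariance:
    def test_agrees_with_jackknife(self, survey_sample):
        data, design = survey_sample
        params = solve_null_allele_freq(data)
        s, A = score_contributions(data, params)
        V_L = variance_score_r(s, A, design)

        from ._oracles import jackknife_psu_cov

        u = s[:, 1] - (A[1, 0] / A[0, 0]) * s[:, 0]
        jack = jackknife_psu_cov(u[:, None], design.psu_index)[0, 0]
        assert abs(V_L - jack) / jack < 0.05

    def test_psu_duplication_changes_variance_by_known_factor(self):
        data, design = make_survey_sample(seed=15, n_psu_sample=60)
        params = solve_null_allele_freq(data)
        s, A = score_contributions(data, params)
        V = variance_score_r(s, A, design)

        dup = FamilyData(
            stratum=np.concatenate([data.stratum, data.stratum]),
            psu=np.concatenate([data.psu, data.psu + data.psu.max() + 1]),
            family_id=np.concatenate([data.family_id, data.family_id]),
            genotypes=np.vstack([data.genotypes, data.genotypes]),
            family_weight=np.concatenate([data.family_weight] * 2),
        )
        design2 = SurveyDesign.from_family_data(dup)
        s2 = np.vstack([s, s])
        V2 = variance_score_r(s2, 2 * A, design2)
        # doubled sum of squares, finite-PSU factor (120/119)/(60/59)
        expected = V * 2 * (120 / 119) / (60 / 59)
        assert V2 == pytest.approx(expected, rel=1e-9)

    def test_variance_scales_linearly_with_sample_size(self):
        out = {}
        for n in (2000, 8000):
            data = independent_families(n, seed=21, p_A=0.3)
            design = SurveyDesign.from_family_data(data)
            params = solve_null_allele_freq(data)
            s, A = score_contributions(data, params)
            out[n] = variance_score_r(s, A, design) / n
        assert abs(out[2000] - out[8000]) / out[8000] < 0.15


class TestQsTest:
    def test_weight_rescaling_invariance(self):
        data, design = make_survey_sample(seed=12, weight_scheme="thirds_1_3_5")
        base = qs_test(data, design)
        scaled = qs_test(data.with_weights(7.0 * data.family_weight), design)
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_reference_distribution_and_shape(self, survey_sample):
        data, design = survey_sample
        res = qs_test(data, design)
        assert res.statistic >= 0
        assert res.df1 == 1.0
        assert res.df2 == 59.0  # 60 PSUs, one stratum
        assert 0 <= res.p_value <= 1
        assert res.diagnostics["V_L"] > 0

    def test_single_family_score_matches_hand_derivation(self):
        """For one family with unit weight, S = D^T V^{-1} (y - mu)."""
        genotype = np.array([[0, 1, 1]])
        for p in (0.2, 0.5, 0.8):
            data = FamilyData(
                stratum=[0], psu=[0], family_id=[0],
                genotypes=genotype, family_weight=[1.0],
            )
            from hwesurvey.qs import QsParameters

            s, A = score_contributions(data, QsParameters(p_tilde=p))
            y = indicator_matrix(genotype)[0]
            mu = np.concatenate([mean_vector(p, 0.0)] * 3)
            D = np.vstack([dmu_dtheta(p, 0.0)] * 3)
            Vinv = np.linalg.inv(trio_covariance(p))
            assert s[0] == pytest.approx(D.T @ Vinv @ (y - mu), rel=1e-10)
            assert A == pytest.approx(D.T @ Vinv @ D, rel=1e-10)
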
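
import numpy as np
import pytest
from scipy.stats import kendalltau

from gmikit import (
    CohortLabel,
    classify_cohort,
    default_config,
    endpoints_table,
    index_pfs,
    most_recent_prior_line,
    oracle_gmi_distribution,
    prior_ttd,
    simulate_cohort,
    simulate_paired_times,
    write_patients,
)
from gmikit.simulate import scale_for_marginal_median


class TestPairedTimes:
    def test_independence_at_theta_zero(self):
        cfg = default_config(seed=10, frailty_theta=0.0)
        pairs = simulate_paired_times(cfg, 50_000)
        tau = kendalltau(pairs[:, 0], pairs[:, 1]).statistic
        assert tau == pytest.approx(0.0, abs=0.01)

    def test_clayton_kendall_tau_closed_form(self):
        # gamma frailty of variance theta gives tau = theta / (theta + 2)
        cfg = default_config(seed=11, frailty_theta=2.0)
        pairs = simulate_paired_times(cfg, 50_000)
        tau = kendalltau(pairs[:, 0], pairs[:, 1]).statistic
        assert tau == pytest.approx(2.0 / 4.0, abs=0.02)

    def test_marginal_median_weibull_closed_form(self):
        shape, scale = 1.4, 8.0
        cfg = default_config(
            seed=12, frailty_theta=0.0, index_pfs_weibull=(shape, scale)
        )
        pairs = simulate_paired_times(cfg, 50_000)
        expected = scale * np.log(2) ** (1 / shape)
        assert np.median(pairs[:, 1]) == pytest.approx(expected, rel=0.02)

    def test_frailty_marginal_median_matches_scale_helper(self):
        theta = 0.5
        scale = scale_for_marginal_median(11.2, 1.1, theta)
        cfg = default_config(
            seed=13, frailty_theta=theta, index_pfs_weibull=(1.1, scale)
        )
        pairs = simulate_paired_times(cfg, 50_000)
        assert np.median(pairs[:, 1]) == pytest.approx(11.2, rel=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            default_config(frailty_theta=-1.0)
        with pytest.raises(ValueError):
            default_config(cohort_mix=(0.5, 0.5, 0.5))


class TestSimulateCohort:
    def test_same_seed_byte_identical_csv(self):
        a, b = (simulate_cohort(default_config(seed=5)) for _ in range(2))
        bufs = []
        for c in (a, b):
            import tempfile, pathlib

            with tempfile.TemporaryDirectory() as d:
                p = pathlib.Path(d) / "c.csv"
                write_patients(c.patients, p)
                bufs.append(p.read_bytes())
        assert bufs[0] == bufs[1]

    def test_default_split_matches_study_disposition(self):
        cohort = simulate_cohort(default_config(seed=1))
        sizes = {
            k: sum(1 for p in cohort.patients if classify_cohort(p) is k)
            for k in CohortLabel
        }
        assert sizes[CohortLabel.DOCUMENTED_PROGRESSION] == 38
        assert sizes[CohortLabel.NO_DOCUMENTED_PROGRESSION] == 13
        assert sizes[CohortLabel.NO_PRIOR_THERAPY] == 20

    def test_classification_recovers_assigned_labels(self):
        cohort = simulate_cohort(default_config(seed=2))
        truth = dict(zip(cohort.truth.patient_id, cohort.truth.cohort))
        for p in cohort.patients:
            assert classify_cohort(p).value == truth[p.patient_id]

    def test_no_noise_pipeline_gmi_equals_truth_gmi(self):
        # with no masking and no censoring the pipeline ratio equals the
        # ratio recomputed from the true (unmasked) dates exactly
        cfg = default_config(
            seed=3,
            missing_month_prob=0.0,
            missing_day_prob=0.0,
            admin_censor_months=600.0,
        )
        cohort = simulate_cohort(cfg)
        truth = cohort.truth.set_index("patient_id")
        assert not truth.pfs_censored.any()
        for p in cohort.patients:
            if not p.prior_lines:
                continue
            line = most_recent_prior_line(p)
            ttd = prior_ttd(line, p.index_start)
            pfs = index_pfs(p)
            row = truth.loc[p.patient_id]
            true_ttd_days = (row.true_prior_end - row.true_prior_start).days
            true_pfs_days = (row.true_pfs_date - p.index_start).days
            assert ttd.time * 30.4375 == pytest.approx(true_ttd_days, abs=1e-9)
            assert pfs.time * 30.4375 == pytest.approx(true_pfs_days, abs=1e-9)

    def test_masking_never_decreases_prior_ttd(self):
        cfg = default_config(seed=4, missing_month_prob=0.4, missing_day_prob=0.5)
        cohort = simulate_cohort(cfg)
        truth = cohort.truth.set_index("patient_id")
        for p in cohort.patients:
            if not p.prior_lines:
                continue
            line = most_recent_prior_line(p)
            imputed = prior_ttd(line, p.index_start).time
            row = truth.loc[p.patient_id]
            true_months = (row.true_prior_end - row.true_prior_start).days / 30.4375
            assert imputed >= true_months - 1e-12

    def test_ongoing_fraction_target_controls_censoring(self):
        cfg = default_config(seed=6, n_patients=400, ongoing_fraction_target=0.5)
        cohort = simulate_cohort(cfg)
        frac = np.mean([p.index_ongoing for p in cohort.patients])
        assert frac == pytest.approx(0.5, abs=0.1)

    def test_cutoff_inside_accrual_is_an_error(self):
        with pytest.raises(ValueError, match="accrual"):
            simulate_cohort(
                default_config(seed=7, accrual_months=30, admin_censor_months=10)
            )

    def test_records_pass_endpoint_derivation(self):
        cohort = simulate_cohort(default_config(seed=8))
        table = endpoints_table(cohort.patients, cutoff=cohort.cutoff)
        assert len(table) == len(cohort.patients)
        assert (table.index_pfs_months >= 0).all()


class TestOracle:
    def test_threshold_monotonicity(self):
        cfg = default_config(seed=9)
        ex = oracle_gmi_distribution(cfg, 20_000, thresholds=[1.0, 1.3, 2.0])
        assert ex[1.0] >= ex[1.3] >= ex[2.0]

    def test_stochastic_dominance_when_pfs_scale_doubled(self):
        cfg = default_config(
            seed=14,
            frailty_theta=0.0,
            prior_ttd_weibull=(1.2, 4.0),
            index_pfs_weibull=(1.2, 8.0),
        )
        ex = oracle_gmi_distribution(cfg, 50_000, thresholds=[1.0])
        assert ex[1.0] > 0.5

    def test_high_frailty_concentrates_ratio_near_one(self):
        shape = 1.2
        common = (shape, 5.0)
        lo = default_config(
            seed=15, frailty_theta=0.1,
            prior_ttd_weibull=common, index_pfs_weibull=common,
        )
        hi = default_config(
            seed=15, frailty_theta=8.0,
            prior_ttd_weibull=common, index_pfs_weibull=common,
        )
        near_one = lambda cfg: np.mean(
            np.abs(
                np.log(
                    (p := simulate_paired_times(cfg, 30_000))[:, 1] / p[:, 0]
                )
            )
            < np.log(1.5)
        )
        # identical marginals: P(ratio within 1.5x of 1) by MC; stronger
        # shared frailty cannot reduce concentration of the ratio
        assert near_one(hi) >= near_one(lo) - 0.01
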
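"""Generator: config encoding, determinism, and margin recovery."""

import numpy as np
import pytest
from scipy import stats

import frailnet as fn
from frailnet import vocab
from frailnet.synthetic_cohort import CoverageError

from conftest import binomial_se


class TestDefaultConfig:
    def test_encodes_printed_hospitalization_rates(self):
        config = fn.default_config(24000, 1)
        assert config.p_hosp_given_frailty == pytest.approx(
            {"NF": 0.142, "PFSN": 0.157, "PFHN": 0.229, "FR": 0.235}
        )
        assert config.p_hosp_given_frailty["FR"] == 0.235

    def test_encodes_frailty_by_age_and_gender(self):
        config = fn.default_config(24000, 1)
        # rows renormalized from the printed percentages (rounding ~1e-3)
        assert config.p_frailty_given_age["90+"]["PFHN"] == pytest.approx(
            0.462, abs=2e-3
        )
        assert config.p_frailty_given_gender["Female"]["FR"] == pytest.approx(
            0.109, abs=2e-3
        )

    def test_multimorbidity_conditional_on_hospitalization(self):
        config = fn.default_config(24000, 1)
        cond = config.p_multimorbid_given_hosp_frailty()
        for f in vocab.FRAILTY_STATUSES:
            assert cond[f] == pytest.approx(
                config.p_multimorbid_given_frailty[f]
                / config.p_hosp_given_frailty[f]
            )

    def test_joint_frailty_rows_normalized(self):
        joint = fn.default_config(10, 7).p_frailty_given_age_gender()
        assert len(joint) == 8
        for row in joint.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in row.values())

    def test_pure_function_of_arguments(self):
        assert fn.default_config(10, 7) == fn.default_config(10, 7)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            fn.default_config(0, 1)

    def test_validation_rejects_bad_rows(self):
        config = fn.default_config(10, 1)
        with pytest.raises(ValueError):
            config.replace(p_hosp_given_frailty={**config.p_hosp_given_frailty,
                                                 "FR": 1.5})

    def test_yaml_round_trip(self, tmp_path):
        config = fn.default_config(120, 9)
        config.to_yaml(tmp_path / "c.yaml")
        assert fn.CohortConfig.from_yaml(tmp_path / "c.yaml") == config


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self):
        config = fn.default_config(1500, 42)
        r1, d1 = fn.generate_cohort(config)
        r2, d2 = fn.generate_cohort(config)
        assert r1.equals(r2) and d1.equals(d2)
        assert r1.attrs["drawn_categories"] == r2.attrs["drawn_categories"]

    def test_zero_hospitalization_yields_no_discharges(self):
        config = fn.default_config(200, 5).replace(
            p_hosp_given_frailty={f: 0.0 for f in vocab.FRAILTY_STATUSES},
            p_multimorbid_given_frailty={f: 0.0 for f in vocab.FRAILTY_STATUSES},
        )
        registry, discharges = fn.generate_cohort(config)
        assert len(registry) == 200
        assert len(discharges) == 0

    def test_structure(self):
        registry, discharges = fn.generate_cohort(fn.default_config(800, 3))
        assert registry["patient_id"].is_unique
        assert set(discharges["patient_id"]) <= set(registry["patient_id"])
        assert (discharges["codes"].str.len() > 0).all()
        dates = discharges["date"].map(str)
        assert (dates >= "2006-01-01").all() and (dates < "2007-01-01").all()

    def test_full_modality_coverage_at_scale(self, cohort_24k):
        _, registry, _ = cohort_24k
        assert set(registry["age_class"]) == set(vocab.AGE_CLASSES)
        assert set(registry["gender"]) == set(vocab.GENDERS)
        assert set(registry["marital_status"]) == set(vocab.MARITAL_STATUSES)
        assert set(registry["family_status"]) == set(vocab.FAMILY_STATUSES)
        assert set(registry["frailty_status"]) == set(vocab.FRAILTY_STATUSES)
        seen = set()
        for cats in registry.attrs["drawn_categories"].values():
            seen.update(cats)
        assert seen == set(vocab.CLINICAL_CATEGORIES)

    def test_coverage_guard_flags_degenerate_config(self):
        config = fn.default_config(5000, 2).replace(
            p_marital_given_frailty_gender={
                f: {g: {"Married": 1.0, "Unmarried": 0.0, "Widowed": 0.0}
                    for g in vocab.GENDERS}
                for f in vocab.FRAILTY_STATUSES
            },
            max_coverage_retries=2,
        )
        with pytest.raises(CoverageError):
            fn.generate_cohort(config)

    def test_frail_hospitalization_within_three_se(self, cohort_24k):
        config, registry, discharges = cohort_24k
        frail = registry[registry["frailty_status"] == "FR"]
        hosp_ids = set(discharges["patient_id"])
        rate = frail["patient_id"].isin(hosp_ids).mean()
        p = config.p_hosp_given_frailty["FR"]
        assert abs(rate - p) <= 3 * binomial_se(p, len(frail))


class TestSummarizeMargins:
    def test_counting(self):
        registry, discharges = fn.generate_cohort(fn.default_config(400, 11))
        registry = registry.iloc[:4].copy()
        registry["frailty_status"] = ["FR", "NF", "NF", "NF"]
        margins = fn.summarize_margins(registry, discharges.iloc[:0])
        assert margins.prevalence_overall["FR"] == pytest.approx(25.0)
        assert margins.hospitalization["NF"] == 0.0

    def test_single_gender_registry_ratio(self):
        registry, discharges = fn.generate_cohort(fn.default_config(50, 11))
        males = registry.copy()
        males["gender"] = "Male"  # no denominator: flagged missing
        present = males["frailty_status"].unique()
        margins = fn.summarize_margins(males, discharges)
        assert margins.gender_ratio[present].isna().all()
        females = registry.copy()
        females["gender"] = "Female"
        margins = fn.summarize_margins(females, discharges)
        assert (margins.gender_ratio[present] == 0).all()

    def test_empty_registry_rejected(self):
        registry, discharges = fn.generate_cohort(fn.default_config(5, 1))
        with pytest.raises(ValueError):
            fn.summarize_margins(registry.iloc[:0], discharges)

    def test_margins_recover_generating_parameters(self, cohort_24k):
        config, registry, discharges = cohort_24k
        margins = fn.summarize_margins(registry, discharges)
        n = len(registry)
        # overall frailty prevalence vs the config-implied marginal
        joint = config.p_frailty_given_age_gender()
        for f in vocab.FRAILTY_STATUSES:
            implied = sum(
                config.p_gender[g] * config.p_age_given_gender[g][a]
                * joint[(a, g)][f]
                for g in vocab.GENDERS for a in vocab.AGE_CLASSES
            )
            observed = margins.prevalence_overall[f] / 100.0
            assert abs(observed - implied) <= 3 * binomial_se(implied, n), f
        # hospitalization and multi-morbidity recover per-status rates
        for f in vocab.FRAILTY_STATUSES:
            n_f = int(margins.counts_by_status[f])
            p_h = config.p_hosp_given_frailty[f]
            assert abs(margins.hospitalization[f] / 100 - p_h) <= \
                3 * binomial_se(p_h, n_f)
            p_m = config.p_multimorbid_given_frailty[f]
            assert abs(margins.multimorbidity[f] / 100 - p_m) <= \
                3 * binomial_se(p_m, n_f)


class TestGoodnessOfFit:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_sampled_frequencies_match_config(self, seed):
        """Chi-square GOF not rejected at alpha=0.001 for n=24,000."""
        config = fn.default_config(24000, seed)
        registry, _ = fn.generate_cohort(config)
        # gender margin
        counts = registry["gender"].value_counts()
        expected = np.array(
            [config.p_gender[g] * len(registry) for g in vocab.GENDERS]
        )
        obs = np.array([counts.get(g, 0) for g in vocab.GENDERS])
        assert stats.chisquare(obs, expected).pvalue > 0.001
        # age within each gender
        for g in vocab.GENDERS:
            sub = registry[registry["gender"] == g]
            obs = np.array(
                [(sub["age_class"] == a).sum() for a in vocab.AGE_CLASSES]
            )
            expected = np.array(
                [config.p_age_given_gender[g][a] * len(sub)
                 for a in vocab.AGE_CLASSES]
            )
            assert stats.chisquare(obs, expected).pvalue > 0.001
        # marital within the largest stratum
        sub = registry[(registry["frailty_status"] == "NF")
                       & (registry["gender"] == "Female")]
        obs = np.array(
            [(sub["marital_status"] == m).sum() for m in vocab.MARITAL_STATUSES]
        )
        expected = np.array(
            [config.p_marital_given_frailty_gender["NF"]["Female"][m] * len(sub)
             for m in vocab.MARITAL_STATUSES]
        )
        assert stats.chisquare(obs, expected).pvalue > 0.001
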
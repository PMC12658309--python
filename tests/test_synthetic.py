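import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import neurophen as nc
from neurophen.synthetic import GeneratorConfig, generate, read_datasets, write_datasets


class TestConfig:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n_children=10, admission_rate_baseline={"planned": -1, "unplanned": 6})

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n_children=10, subgroup_prevalence={"epilepsy": 1.5})

    def test_reversed_birth_window_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n_children=10, birth_window=("2009-08-31", "2003-09-01"))

    def test_default_prevalence_union_is_calibrated(self):
        cfg = GeneratorConfig(n_children=10)
        assert cfg.expected_prevalence() == pytest.approx(0.036, abs=1e-9)

    def test_unknown_subgroup_rejected_at_generation(self):
        cfg = GeneratorConfig(n_children=10, subgroup_prevalence={"dragon pox": 0.1})
        with pytest.raises(ValueError, match="dragon pox"):
            generate(cfg)


class TestDeterminismAndStructure:
    def test_same_seed_same_output(self):
        a = generate(GeneratorConfig(n_children=400, seed=9))
        b = generate(GeneratorConfig(n_children=400, seed=9))
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_different_seed_differs(self):
        a = generate(GeneratorConfig(n_children=400, seed=9))
        b = generate(GeneratorConfig(n_children=400, seed=10))
        assert not a["admissions"].equals(b["admissions"])

    def test_zero_prevalence_flags_nobody(self, codelist):
        cfg = GeneratorConfig(
            n_children=500, seed=2, subgroup_prevalence={"epilepsy": 0.0, "cerebral palsy": 0.0}
        )
        data = generate(cfg)
        cohort = nc.build_birth_cohort(data["patients"], data["deaths"])
        frames = nc.phenotype_cohort(
            cohort, data["admissions"], data["deaths"], data["patients"], codelist
        )
        assert not frames.results["flagged"].any()

    def test_admissions_within_life_window(self, small_data):
        adm = small_data["admissions"].merge(
            small_data["patients"][["patient_id", "birth_date"]], on="patient_id"
        ).merge(small_data["deaths"], on="patient_id", how="left")
        assert (adm["admission_date"] >= adm["birth_date"]).all()
        assert (adm["discharge_date"] >= adm["admission_date"]).all()
        died = adm["death_date"].notna()
        assert (adm.loc[died, "admission_date"] <= adm.loc[died, "death_date"]).all()

    def test_single_birth_admission_dated_at_birth(self, small_data):
        births = small_data["admissions"][small_data["admissions"]["is_birth_admission"]]
        assert births["patient_id"].is_unique
        merged = births.merge(small_data["patients"], on="patient_id")
        assert (merged["admission_date"] == merged["birth_date"]).all()

    def test_deaths_unique_and_after_birth(self, small_data):
        d = small_data["deaths"].merge(small_data["patients"], on="patient_id")
        assert d["patient_id"].is_unique
        assert (d["death_date"] >= d["birth_date"]).all()

    def test_transfer_admissions_start_on_prior_discharge(self, small_data):
        adm = small_data["admissions"]
        transfers = adm[adm["admission_method_code"] == "81"]
        assert len(transfers) > 0
        others = adm[adm["admission_method_code"] != "81"]
        prior_discharges = set(zip(others["patient_id"], others["discharge_date"]))
        for _, t in transfers.iterrows():
            assert (t["patient_id"], t["admission_date"]) in prior_discharges

    def test_school_year_groups_consistent_with_birth_cutoff(self, small_data):
        rec = small_data["school"].merge(small_data["patients"][["patient_id", "birth_date"]], on="patient_id")
        y1 = rec[rec["year_group"] == "1"]
        expected = y1["birth_date"].map(nc.year1_start_date)
        got = y1["academic_year"].str.slice(0, 4).astype(int)
        assert (got == expected.map(lambda d: d.year)).all()

    def test_at_most_one_school_record_per_year(self, small_data):
        assert not small_data["school"].duplicated(["patient_id", "academic_year"]).any()


class TestParameterRecoverySmall:
    """Binomial-scale sanity checks on a modest sample; the full-scale
    parameter-recovery suite lives in the acceptance tests."""

    def test_prevalence_within_three_binomial_se(self, small_config, small_pipeline):
        p = small_config.expected_prevalence()
        n = small_config.n_children
        se = np.sqrt(p * (1 - p) / n)
        observed = small_pipeline["results"]["flagged"].mean()
        assert abs(observed - p) < 3 * se

    def test_death_risk_within_three_se(self, small_config, small_data, small_pipeline):
        res = small_pipeline["results"]
        died = set(small_data["deaths"]["patient_id"])
        peers = res[~res["flagged"]]
        p = small_config.mortality_risk["none"]
        se = np.sqrt(p * (1 - p) / len(peers))
        observed = peers["patient_id"].isin(died).mean()
        assert abs(observed - p) < 3 * se


class TestRoundTrip:
    def test_write_read_identity(self, small_data, tmp_path):
        write_datasets(small_data, tmp_path)
        back = read_datasets(tmp_path)
        for name in small_data:
            pd.testing.assert_frame_equal(back[name], small_data[name])

    def test_missing_gestational_age_as_empty_string(self, tmp_path):
        (tmp_path / "patients.csv").write_text(
            "patient_id,birth_date,sex,gestational_age_weeks,birthweight_g,maternal_age_band\n"
            "p1,2004-03-15,male,,3200,25-29\n"
        )
        for name, header in (
            ("admissions", "admission_id,patient_id,admission_date,discharge_date,admission_method_code,diagnosis_codes,procedure_codes,is_birth_admission,died_in_hospital"),
            ("deaths", "patient_id,death_date,cause_codes"),
            ("school", "patient_id,academic_year,year_group,sen_level,primary_need"),
        ):
            (tmp_path / f"{name}.csv").write_text(header + "\n")
        data = read_datasets(tmp_path)
        assert data["patients"].loc[0, "gestational_age_weeks"] is pd.NA
        assert data["patients"].loc[0, "birthweight_g"] == 3200

    def test_hand_built_admissions_parse_iso_dates(self, tmp_path):
        (tmp_path / "admissions.csv").write_text(
            "admission_id,patient_id,admission_date,discharge_date,admission_method_code,"
            "diagnosis_codes,procedure_codes,is_birth_admission,died_in_hospital\n"
            "a1,p1,2004-03-15,2004-03-18,82,Z380,,true,false\n"
            "a2,p1,2005-01-01,2005-01-01,21,J069;F840,,false,false\n"
            "a3,p1,2005-01-01,2005-01-02,11,J069,X292,false,false\n"
        )
        (tmp_path / "patients.csv").write_text(
            "patient_id,birth_date,sex,gestational_age_weeks,birthweight_g,maternal_age_band\n"
            "p1,2004-03-15,male,40,3200,25-29\n"
        )
        (tmp_path / "deaths.csv").write_text("patient_id,death_date,cause_codes\n")
        (tmp_path / "school.csv").write_text("patient_id,academic_year,year_group,sen_level,primary_need\n")
        data = read_datasets(tmp_path)
        assert data["admissions"]["admission_date"].tolist() == [
            pd.Timestamp("2004-03-15"), pd.Timestamp("2005-01-01"), pd.Timestamp("2005-01-01"),
        ]
        assert bool(data["admissions"].loc[0, "is_birth_admission"])

    def test_schema_mismatch_names_column(self, small_data, tmp_path):
        write_datasets(small_data, tmp_path)
        df = pd.read_csv(tmp_path / "deaths.csv")
        df.drop(columns=["cause_codes"]).to_csv(tmp_path / "deaths.csv", index=False)
        with pytest.raises(ValueError, match="cause_codes"):
            read_datasets(tmp_path)

    def test_missing_file_reported(self, small_data, tmp_path):
        write_datasets(small_data, tmp_path)
        (tmp_path / "school.csv").unlink()
        with pytest.raises(FileNotFoundError, match="school"):
            read_datasets(tmp_path)
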
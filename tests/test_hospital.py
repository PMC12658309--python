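import numpy as np
import pandas as pd
import pytest

import neurophen as nc
from neurophen._dates import anniversary
from neurophen.hospital import DAYS_PER_YEAR, link_spells, compute_person_time
from conftest import make_admissions, person_time_oracle, random_admission_set, spell_oracle


def _cohort(rows):
    """rows: (patient_id, birth, death_or_None)"""
    patients = pd.DataFrame([(r[0], r[1]) for r in rows], columns=["patient_id", "birth_date"])
    deaths = pd.DataFrame(
        [(r[0], r[2]) for r in rows if r[2] is not None], columns=["patient_id", "death_date"]
    )
    return nc.build_birth_cohort(patients, deaths)


def _results(rows):
    """rows: (patient_id, age_band)"""
    df = pd.DataFrame(rows, columns=["patient_id", "age_band"])
    df["flagged"] = df["age_band"] != "none"
    df["first_record_date"] = pd.NaT
    return df


class TestSpellLinkage:
    def test_same_day_transfer_links_into_one_spell(self):
        adm = make_admissions(
            [("p1", "2005-01-01", "2005-01-05"), ("p1", "2005-01-05", "2005-01-09")]
        )
        spells = link_spells(adm)
        assert len(spells) == 1
        assert spells.loc[0, "start_date"] == pd.Timestamp("2005-01-01")
        assert spells.loc[0, "end_date"] == pd.Timestamp("2005-01-09")
        assert spells.loc[0, "n_admissions"] == 2

    def test_one_day_gap_stays_two_spells(self):
        adm = make_admissions(
            [("p1", "2005-01-01", "2005-01-05"), ("p1", "2005-01-06", "2005-01-09")]
        )
        assert len(link_spells(adm)) == 2

    def test_spell_type_from_earliest_admission(self):
        adm = make_admissions(
            [("p1", "2005-01-01", "2005-01-05", "11"), ("p1", "2005-01-05", "2005-01-09", "21")]
        )
        spells = link_spells(adm)
        assert len(spells) == 1
        assert spells.loc[0, "spell_type"] == "planned"

    def test_nested_admission_absorbed(self):
        adm = make_admissions(
            [("p1", "2005-01-01", "2005-01-10"), ("p1", "2005-01-03", "2005-01-04")]
        )
        spells = link_spells(adm)
        assert len(spells) == 1
        assert spells.loc[0, "end_date"] == pd.Timestamp("2005-01-10")

    def test_linkage_is_idempotent(self, small_data):
        spells = link_spells(small_data["admissions"])
        again = link_spells(
            spells.rename(columns={"start_date": "admission_date", "end_date": "discharge_date"})
            .assign(admission_id=spells["spell_id"])
        )
        assert len(again) == len(spells)
        assert (again["start_date"].values == spells["start_date"].values).all()
        assert (again["end_date"].values == spells["end_date"].values).all()

    def test_linkage_order_invariant(self):
        rng = np.random.default_rng(0)
        rows = [("p1", f"2005-01-{d:02d}", f"2005-01-{e:02d}") for d, e in [(1, 5), (5, 9), (12, 14), (13, 20)]]
        base = link_spells(make_admissions(rows))
        for _ in range(5):
            shuffled = [rows[i] for i in rng.permutation(len(rows))]
            again = link_spells(make_admissions(shuffled))
            assert (again["start_date"].values == base["start_date"].values).all()
            assert (again["end_date"].values == base["end_date"].values).all()

    def test_matches_interval_merge_oracle_on_random_sets(self):
        """500 random admission sets: linked spell intervals equal brute-force merge."""
        rng = np.random.default_rng(202)
        origin = pd.Timestamp("2004-01-01")
        for _ in range(500):
            ivs = random_admission_set(rng, int(rng.integers(1, 12)))
            adm = make_admissions(
                [("p1", origin + pd.Timedelta(days=s), origin + pd.Timedelta(days=e)) for s, e in ivs]
            )
            spells = link_spells(adm)
            expected = spell_oracle(ivs)
            got = [
                ((s - origin).days, (e - origin).days)
                for s, e in zip(spells["start_date"], spells["end_date"])
            ]
            assert sorted(got) == expected

    def test_discharge_before_admission_rejected(self):
        adm = make_admissions([("p1", "2005-01-05", "2005-01-01")])
        with pytest.raises(ValueError):
            link_spells(adm)


class TestPersonTime:
    def test_never_admitted_child(self):
        cohort = _cohort([("p1", "2004-03-15", None)])
        pt = compute_person_time(cohort, link_spells(make_admissions([]))).set_index("age_band")
        d11 = (pd.Timestamp("2015-03-15") - pd.Timestamp("2004-03-15")).days
        assert pt.loc["<11", "days_at_risk"] == d11
        assert pt.loc["<11", "days_in_hospital"] == 0
        assert pt.loc["<1", "days_total"] == 365

    def test_spell_straddling_first_birthday(self):
        # 10 hospital days before the first birthday, 5 after
        cohort = _cohort([("p1", "2004-03-15", None)])
        spells = link_spells(make_admissions([("p1", "2005-03-05", "2005-03-20")]))
        pt = compute_person_time(cohort, spells).set_index("age_band")
        assert pt.loc["<1", "days_in_hospital"] == 10
        assert pt.loc["1-4", "days_in_hospital"] == 5

    def test_death_in_hospital_clips_both_totals(self):
        cohort = _cohort([("p1", "2004-03-15", "2006-05-01")])
        spells = link_spells(make_admissions([("p1", "2006-04-20", "2006-05-01")]))
        pt = compute_person_time(cohort, spells).set_index("age_band")
        assert pt.loc["<11", "days_total"] == (pd.Timestamp("2006-05-01") - pd.Timestamp("2004-03-15")).days
        assert pt.loc["1-4", "days_in_hospital"] == 11

    def test_same_day_spell_contributes_zero_days(self):
        cohort = _cohort([("p1", "2004-03-15", None)])
        spells = link_spells(make_admissions([("p1", "2006-04-20", "2006-04-20")]))
        pt = compute_person_time(cohort, spells)
        assert pt["days_in_hospital"].sum() == 0

    def test_bands_sum_to_aggregate_and_conserve_followup(self, small_pipeline):
        pt = small_pipeline["person_time"]
        bands = pt[pt["age_band"] != "<11"].groupby("patient_id")[["days_total", "days_in_hospital"]].sum()
        agg = pt[pt["age_band"] == "<11"].set_index("patient_id")[["days_total", "days_in_hospital"]]
        pd.testing.assert_frame_equal(bands.sort_index(), agg.sort_index())
        cohort = small_pipeline["cohort"].set_index("patient_id")
        followup_days = (cohort["followup_end"] - cohort["birth_date"]).dt.days
        assert (agg["days_total"].sort_index() == followup_days.sort_index()).all()
        assert (pt["days_in_hospital"] <= pt["days_total"]).all()
        assert (pt["days_at_risk"] >= 0).all()

    def test_matches_day_by_day_enumeration_on_random_children(self):
        """100 random children: band day counts equal per-day enumeration."""
        rng = np.random.default_rng(77)
        origin = pd.Timestamp("2004-02-20")
        for _ in range(100):
            birth = origin + pd.Timedelta(days=int(rng.integers(0, 400)))
            dies = rng.random() < 0.3
            death = birth + pd.Timedelta(days=int(rng.integers(0, 4100))) if dies else None
            cohort = _cohort([("p1", birth, death)])
            ivs = random_admission_set(rng, int(rng.integers(0, 6)), horizon=4200)
            spans = [
                (birth + pd.Timedelta(days=s), birth + pd.Timedelta(days=e)) for s, e in ivs
            ]
            spells = link_spells(make_admissions([("p1", s, e) for s, e in spans])) if spans else make_admissions([])
            pt = compute_person_time(cohort, spells).set_index("age_band")
            row = cohort.iloc[0]
            expected = person_time_oracle(
                row["birth_date"],
                row["followup_end"],
                pd.Timestamp(anniversary(row["birth_date"], 1)),
                pd.Timestamp(anniversary(row["birth_date"], 5)),
                row["eleventh_birthday"],
                spans,
            )
            for band, (total, hosp) in expected.items():
                assert pt.loc[band, "days_total"] == total, band
                assert pt.loc[band, "days_in_hospital"] == hosp, band


class TestCumulativeIncidence:
    def test_boundary_case_at_exact_age_one(self):
        cohort = _cohort([("p1", "2004-03-15", None), ("p2", "2004-03-15", None)])
        res = cohort[["patient_id"]].copy()
        res["flagged"] = [True, False]
        res["first_record_date"] = [pd.Timestamp("2005-03-15"), pd.NaT]
        res["age_band"] = ["under5", "none"]
        inc = nc.cumulative_incidence(cohort, res).set_index("age_threshold")
        assert inc.loc[1, "n_cases"] == 0  # strictly before the first birthday
        assert inc.loc[5, "n_cases"] == 1
        assert inc.loc[5, "proportion"] == 0.5

    def test_three_child_worked_fixture(self):
        """Hand-computed person-years: time to first record, death or threshold."""
        cohort = _cohort(
            [("a", "2004-01-01", None), ("b", "2004-01-01", "2004-12-31"), ("c", "2004-01-01", None)]
        )
        res = cohort[["patient_id"]].copy()
        res["flagged"] = [True, False, False]
        res["first_record_date"] = [pd.Timestamp("2004-07-01"), pd.NaT, pd.NaT]
        res["age_band"] = ["under5", "none", "none"]
        inc = nc.cumulative_incidence(cohort, res, age_thresholds=(1,)).set_index("age_threshold")
        # a: 182 days to first record; b: 365 days to death; c: full 366 days (leap)
        expected_py = (182 + 365 + 366) / DAYS_PER_YEAR
        assert inc.loc[1, "person_years"] == pytest.approx(expected_py)
        assert inc.loc[1, "rate_per_100py"] == pytest.approx(100 * 1 / expected_py)
        assert inc.loc[1, "proportion"] == pytest.approx(1 / 3)

    def test_threshold_beyond_followup_rejected(self, small_pipeline):
        with pytest.raises(ValueError):
            nc.cumulative_incidence(
                small_pipeline["cohort"], small_pipeline["results"], age_thresholds=(12,)
            )


class TestAdmissionRates:
    def test_rate_arithmetic_and_ratio(self):
        # reference group: 342 planned spells over 10,000 person-years -> 3.42
        # phenotype group: 500 spells over 1,460.36 person-years -> 34.24
        cohort = _cohort([("ref", "2004-01-01", None), ("phen", "2004-01-01", None)])
        res = _results([("ref", "none"), ("phen", "under5")])
        spells = pd.DataFrame(
            {
                "spell_id": range(842),
                "patient_id": ["ref"] * 342 + ["phen"] * 500,
                "start_date": pd.Timestamp("2004-06-01"),
                "end_date": pd.Timestamp("2004-06-02"),
                "spell_type": "planned",
                "admission_ids": "x",
                "n_admissions": 1,
            }
        )
        pt = pd.DataFrame(
            {
                "patient_id": ["ref", "phen"],
                "age_band": "<11",
                "days_total": [int(10000 * DAYS_PER_YEAR), int(round(100 * 500 / 34.24 * DAYS_PER_YEAR))],
                "days_in_hospital": 0,
            }
        )
        pt["days_at_risk"] = pt["days_total"]
        band = pt.assign(age_band="<1")
        rates = nc.admission_rates(spells, pd.concat([pt, band]), res, cohort)
        r = rates.set_index(["group", "admission_type", "age_band"])
        assert round(r.loc[("none", "planned", "<11"), "rate_per_100py"], 2) == 3.42
        assert round(r.loc[("any", "planned", "<11"), "rate_per_100py"], 2) == 34.24
        assert round(r.loc[("any", "planned", "<11"), "rate_ratio"], 2) == 10.01

    def test_birth_spells_excluded_by_default(self, small_pipeline):
        rates = nc.admission_rates(
            small_pipeline["spells"],
            small_pipeline["person_time"],
            small_pipeline["results"],
            small_pipeline["cohort"],
        )
        assert set(rates["admission_type"]) == {"planned", "unplanned"}
        n_birth = (small_pipeline["spells"]["spell_type"] == "birth").sum()
        assert n_birth > 0

    def test_table_internal_consistency(self, small_pipeline):
        rates = nc.admission_rates(
            small_pipeline["spells"],
            small_pipeline["person_time"],
            small_pipeline["results"],
            small_pipeline["cohort"],
        )
        ok = rates.dropna(subset=["rate_per_100py"])
        recomputed = 100 * ok["n_admissions"] / ok["person_years"]
        assert np.allclose(recomputed, ok["rate_per_100py"])
        ref = ok[ok["group"] == "none"].set_index(["admission_type", "age_band"])["rate_per_100py"]
        for _, row in ok.iterrows():
            expected = row["rate_per_100py"] / ref[(row["admission_type"], row["age_band"])]
            assert row["rate_ratio"] == pytest.approx(expected)

    def test_spell_vs_admission_numerator_switch(self, small_pipeline):
        args = (
            small_pipeline["spells"],
            small_pipeline["person_time"],
            small_pipeline["results"],
            small_pipeline["cohort"],
        )
        by_spell = nc.admission_rates(*args, unit="spell")
        by_adm = nc.admission_rates(*args, unit="admission")
        assert by_adm["n_admissions"].sum() >= by_spell["n_admissions"].sum()
        with pytest.raises(ValueError):
            nc.admission_rates(*args, unit="episode")


class TestMortalityAndBirthLength:
    def test_death_proportions_by_band(self):
        rows = [(f"p{i}", "2004-01-01", None) for i in range(7)]
        rows += [("d1", "2004-01-01", "2004-06-01"), ("d2", "2004-01-01", "2006-06-01"), ("d3", "2004-01-01", "2010-06-01")]
        cohort = _cohort(rows)
        res = _results([(r[0], "none") for r in rows])
        m = nc.mortality_summary(cohort, res)
        g = m[m["group"] == "none"].set_index("age_band")
        assert g.loc["<1", "n_deaths"] == 1
        assert g.loc["1-4", "n_deaths"] == 1
        assert g.loc["5-10", "n_deaths"] == 1
        assert g.loc["0-10", "n_deaths"] == 3
        assert g.loc["0-10", "proportion"] == pytest.approx(0.3)

    def test_zero_deaths_gives_zero_proportions(self):
        cohort = _cohort([("p1", "2004-01-01", None)])
        m = nc.mortality_summary(cohort, _results([("p1", "none")]))
        assert (m["n_deaths"] == 0).all()

    def test_birth_length_quantiles(self):
        days = [1, 1, 2, 3, 10]
        cohort = _cohort([(f"p{i}", "2004-01-01", None) for i in range(5)])
        spells = pd.DataFrame(
            {
                "spell_id": range(5),
                "patient_id": [f"p{i}" for i in range(5)],
                "start_date": pd.Timestamp("2004-01-01"),
                "end_date": [pd.Timestamp("2004-01-01") + pd.Timedelta(days=d) for d in days],
                "spell_type": "birth",
                "admission_ids": "x",
                "n_admissions": 1,
            }
        )
        res = _results([(f"p{i}", "none") for i in range(5)])
        out = nc.birth_admission_length(cohort, spells, res).set_index("group")
        assert out.loc["none", "median"] == 2
        assert out.loc["none", "q1"] == 1
        assert out.loc["none", "q3"] == 3
        assert out.loc["none", "mean"] == pytest.approx(np.mean(days))

    def test_same_day_birth_discharge_is_zero_days(self):
        cohort = _cohort([("p1", "2004-03-15", None)])
        spells = link_spells(
            make_admissions([("p1", "2004-03-15", "2004-03-15", "82", "Z380", "", True)])
        )
        out = nc.birth_admission_length(cohort, spells, _results([("p1", "none")])).set_index("group")
        assert out.loc["none", "median"] == 0
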
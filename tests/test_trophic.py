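import pytest

from mummyweb import data, synth
from mummyweb.errors import InputError, SchemaError
from mummyweb.trophic import (
    HETERONOMOUS,
    HYPERPARASITOID,
    PRIMARY,
    PSYLLID,
    UNDETERMINED,
    MummyRecord,
    classify_trophic_roles,
    cooccurrence_check,
    detection_success,
    flag_informative,
    load_mummy_table,
    summarize_species_roles,
    validate_prey_consistency,
    write_mummy_table,
)

PANEL = ("P1", "P2", "H", "HH")


def _rec(mummy_id, sp, sex="female", psyllid=True, present=(), host="hostA"):
    det = {t: False for t in PANEL}
    det[sp] = True
    for t in present:
        det[t] = True
    return MummyRecord(
        mummy_id=mummy_id,
        host_species=host,
        emerged_species=sp,
        emerged_sex=sex,
        psyllid_dna=psyllid,
        detected=det,
    )


class TestMummyTableIO:
    def test_three_row_csv(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "mummy_id,host_species,emerged_species,emerged_sex,psyllid_dna,det_P1,det_P2\n"
            "m1,hostA,P1,female,1,1,0\n"
            "m2,hostA,P2,male,yes,0,yes\n"
            "m3,hostA,P1,female,no,1,0\n"
        )
        records = load_mummy_table(path)
        assert len(records) == 3
        assert records[1].detected == {"P1": False, "P2": True}
        assert records[2].psyllid_dna is False

    def test_missing_column_schema_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "mummy_id,host_species,emerged_species,emerged_sex,det_P1\nm1,h,P1,female,1\n"
        )
        with pytest.raises(SchemaError):
            load_mummy_table(path)

    def test_duplicate_id_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "mummy_id,host_species,emerged_species,emerged_sex,psyllid_dna,det_P1\n"
            "m1,h,P1,female,1,1\nm1,h,P1,female,1,1\n"
        )
        with pytest.raises(InputError):
            load_mummy_table(path)

    def test_round_trip(self, tmp_path):
        records = [
            _rec("m1", "P1"),
            _rec("m2", "H", sex="male", present=("P2",)),
            _rec("m3", "P2", psyllid=False),
        ]
        path = tmp_path / "m.csv"
        write_mummy_table(records, path)
        back = load_mummy_table(path)
        assert [r.mummy_id for r in back] == ["m1", "m2", "m3"]
        for a, b in zip(records, back):
            assert a.detected == b.detected
            assert a.psyllid_dna == b.psyllid_dna

    def test_emerged_species_must_be_in_panel(self):
        with pytest.raises(InputError):
            MummyRecord(
                mummy_id="m1",
                host_species="h",
                emerged_species="P9",
                emerged_sex="female",
                psyllid_dna=True,
                detected={"P1": True},
            )


class TestFlagInformative:
    def test_both_detected_informative(self):
        inf, uninf = flag_informative([_rec("m1", "P1")])
        assert len(inf) == 1 and not uninf

    def test_emerged_dna_missing_uninformative(self):
        r = _rec("m1", "P1")
        r.detected["P1"] = False
        inf, uninf = flag_informative([r])
        assert not inf and len(uninf) == 1

    def test_partition_is_exhaustive(self):
        records = [_rec(f"m{i}", "P1", psyllid=(i < 20)) for i in range(25)]
        inf, uninf = flag_informative(records)
        assert (len(inf), len(uninf)) == (20, 5)
        assert {r.mummy_id for r in inf} | {r.mummy_id for r in uninf} == {
            r.mummy_id for r in records
        }


class TestDetectionSuccess:
    def test_80_percent(self):
        records = [_rec(f"m{i}", "H", present=("P2",)) for i in range(20)] + [
            _rec(f"u{i}", "H", psyllid=False) for i in range(5)
        ]
        df = detection_success(records)
        assert df.loc[0, "detection_success"] == 80

    def test_11_percent(self):
        records = [_rec(f"m{i}", "P1") for i in range(20)] + [
            _rec(f"u{i}", "P1", psyllid=False) for i in range(162)
        ]
        df = detection_success(records)
        assert df.loc[0, "detection_success"] == 11

    def test_all_informative_100(self):
        df = detection_success([_rec(f"m{i}", "P2") for i in range(7)])
        assert df.loc[0, "detection_success"] == 100

    def test_rounds_half_up(self):
        # 5/8 = 62.5 -> 63, matching the survey table
        records = [_rec(f"m{i}", "HH") for i in range(5)] + [
            _rec(f"u{i}", "HH", psyllid=False) for i in range(3)
        ]
        assert detection_success(records).loc[0, "detection_success"] == 63

    def test_conservation_per_stratum(self):
        records = data.mummy_records()
        df = detection_success(records)
        assert int((df["informative"] + df["uninformative"]).sum()) == len(records)

    def test_survey_table_reproduced_exactly(self):
        df = detection_success(data.mummy_records())
        printed = data.screening_table()
        merged = printed.merge(
            df,
            on=["host_species", "emerged_species", "emerged_sex"],
            suffixes=("_printed", ""),
        )
        assert len(merged) == len(printed)
        assert (merged["detection_success"] == merged["detection_success_printed"]).all()
        assert (merged["informative"] == merged["informative_printed"]).all()


class TestClassifyTrophicRoles:
    def test_primary_pattern(self):
        records = [_rec(f"m{i}", "P2") for i in range(5)]
        (a,) = classify_trophic_roles(records)
        assert a.role == PRIMARY and a.prey == PSYLLID

    def test_hyperparasitoid_pattern(self):
        records = [_rec(f"m{i}", "H", present=("P2",)) for i in range(5)]
        (a,) = classify_trophic_roles(records)
        assert a.role == HYPERPARASITOID and a.prey == "P2"

    def test_heteronomous_merge(self):
        records = [_rec(f"f{i}", "HH", sex="female") for i in range(5)] + [
            _rec(f"m{i}", "HH", sex="male", present=("P1",)) for i in range(5)
        ]
        (a,) = classify_trophic_roles(records)
        assert a.role == HETERONOMOUS
        assert a.prey_by_sex == {"female": PSYLLID, "male": "P1"}

    def test_zero_informative_is_undetermined(self):
        records = [_rec("m1", "P1", psyllid=False), _rec("m2", "P1", psyllid=False)]
        assert classify_trophic_roles(records) == []

    def test_below_min_n_undetermined(self):
        (a,) = classify_trophic_roles([_rec("m1", "P2")], min_n=2)
        assert a.role == UNDETERMINED

    def test_emerged_alone_blocks_hyperparasitoid_call(self):
        records = [_rec(f"m{i}", "H", present=("P2",)) for i in range(4)] + [
            _rec("alone", "H")
        ]
        (a,) = classify_trophic_roles(records, consistency=0.8)
        assert a.role == UNDETERMINED

    def test_consistency_validation(self):
        with pytest.raises(InputError):
            classify_trophic_roles([_rec("m1", "P1")], consistency=0.4)

    def test_survey_roles(self):
        assignments = classify_trophic_roles(data.mummy_records())
        summary = summarize_species_roles(assignments)
        assert summary == {
            "P1": PRIMARY,
            "P2": PRIMARY,
            "H": HYPERPARASITOID,
            "HH": HETERONOMOUS,
        }
        assert sum(1 for r in summary.values() if r == PRIMARY) == 2
        h_calls = [a for a in assignments if a.morphospecies == "H"]
        assert all(a.prey == "P2" for a in h_calls)
        assert validate_prey_consistency(assignments) == []

    def test_prey_inconsistency_reported(self):
        # emerged X always with Y, but Y classifies hyperparasitoid itself
        records = [_rec(f"x{i}", "H", present=("P2",)) for i in range(3)] + [
            _rec(f"y{i}", "P2", present=("P1",)) for i in range(3)
        ]
        assignments = classify_trophic_roles(records)
        warnings = validate_prey_consistency(assignments)
        assert warnings and "P2" in warnings[0]

    def test_noiseless_recovery(self):
        roles = synth.default_roles()
        records = synth.simulate_mummy_table(roles, n_per_stratum=10, seed=0)
        inf, uninf = flag_informative(records)
        assert not uninf  # detect_prob defaults to 1 everywhere
        summary = summarize_species_roles(classify_trophic_roles(records))
        assert summary == {
            "P1": PRIMARY,
            "P2": PRIMARY,
            "H": HYPERPARASITOID,
            "HH": HETERONOMOUS,
        }

    def test_noisy_recovery_rate(self):
        roles = synth.default_roles()
        want = {
            "P1": PRIMARY,
            "P2": PRIMARY,
            "H": HYPERPARASITOID,
            "HH": HETERONOMOUS,
        }
        detect = {PSYLLID: 0.95, "P1": 0.25, "P2": 0.9, "H": 0.9, "HH": 0.9}
        ok = 0
        n_reps = 200
        for seed in range(n_reps):
            records = synth.simulate_mummy_table(
                roles, n_per_stratum=30, detect_prob=detect, seed=seed
            )
            if summarize_species_roles(classify_trophic_roles(records)) == want:
                ok += 1
        assert ok / n_reps >= 0.95


class TestCooccurrence:
    def test_survey_P1_P2_never_together(self):
        assert cooccurrence_check(data.mummy_records(), ("P1", "P2")) == 0

    def test_contrived_cooccurrence(self):
        records = [_rec("m1", "P1", present=("P2",))]
        assert cooccurrence_check(records, ("P1", "P2")) == 1

    def test_matches_row_scan(self):
        records = data.mummy_records()
        for pair in (("H", "P2"), ("HH", "P1"), ("P1", "H")):
            expected = sum(
                1
                for r in records
                if r.detected.get(pair[0]) and r.detected.get(pair[1])
            )
            assert cooccurrence_check(records, pair) == expected

    def test_unknown_target(self):
        with pytest.raises(InputError):
            cooccurrence_check([_rec("m1", "P1")], ("P1", "nope"))
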
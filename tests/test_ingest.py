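from __future__ import annotations

from datetime import date

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal.ingest import (
    DedupPolicy,
    FormatError,
    assemble_reports,
    deduplicate,
    read_deleted_cases,
    read_quarter,
    read_store,
    write_store,
    _parse_age,
)


def _write_quarter(tmp_path, demo_rows, drug_rows=(), reac_rows=(), indi_rows=(),
                   outc_rows=()):
    (tmp_path / "DEMO.txt").write_text(
        "primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occp_cod$occr_country\n"
        + "".join(r + "\n" for r in demo_rows))
    (tmp_path / "DRUG.txt").write_text(
        "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai\n"
        + "".join(r + "\n" for r in drug_rows))
    (tmp_path / "REAC.txt").write_text(
        "primaryid$caseid$pt\n" + "".join(r + "\n" for r in reac_rows))
    (tmp_path / "INDI.txt").write_text(
        "primaryid$caseid$indi_drug_seq$indi_pt\n" + "".join(r + "\n" for r in indi_rows))
    (tmp_path / "OUTC.txt").write_text(
        "primaryid$caseid$outc_cod\n" + "".join(r + "\n" for r in outc_rows))
    return tmp_path


class TestReadQuarter:
    def test_row_counts_match_file_lines(self, tmp_path):
        quarter = read_quarter(_write_quarter(
            tmp_path,
            demo_rows=["11$1$1$20200101$72$YR$F$MD$US",
                       "21$2$1$20200102$60$YR$M$CN$GB"],
            drug_rows=["11$1$1$PS$COLCHICINE$COLCHICINE"],
            reac_rows=["11$1$Nausea", "21$2$Rash"],
        ))
        assert len(quarter.demo_rows) == 2
        assert len(quarter.drug_rows) == 1
        assert len(quarter.reac_rows) == 2

    def test_orphan_drug_row_retained_at_read(self, tmp_path):
        quarter = read_quarter(_write_quarter(
            tmp_path,
            demo_rows=["11$1$1$20200101$72$YR$F$MD$US"],
            drug_rows=["99$9$1$PS$ASPIRIN$ASPIRIN"],  # no matching DEMO row
            reac_rows=["11$1$Nausea"],
        ))
        assert len(quarter.drug_rows) == 1  # reader does not filter

    def test_missing_mandatory_column_names_file_and_column(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("primaryid$caseversion\n11$1\n")
        (tmp_path / "DRUG.txt").write_text("primaryid$caseid$role_cod$drugname\n")
        (tmp_path / "REAC.txt").write_text("primaryid$caseid$pt\n")
        with pytest.raises(FormatError) as err:
            read_quarter(tmp_path)
        assert "caseid" in str(err.value) and "DEMO" in str(err.value)

    def test_unreadable_line_skipped_and_counted(self, tmp_path):
        root = _write_quarter(
            tmp_path,
            demo_rows=["11$1$1$20200101$72$YR$F$MD$US"],
            reac_rows=["11$1$Nausea"],
        )
        with (root / "REAC.txt").open("a") as fh:
            fh.write("11$1$Broken$extra$fields$here$x\n")
        quarter = read_quarter(root)
        assert len(quarter.reac_rows) == 1
        assert quarter.skipped_lines == {"reac": 1}

    def test_synthetic_quarter_round_trip(self, small_quarter):
        outdir, manifest = small_quarter
        quarter = read_quarter(outdir)
        expected_rows = manifest["n_reports"] + manifest["n_duplicate_rows"]
        assert len(quarter.demo_rows) == expected_rows


class TestAssemble:
    @pytest.mark.parametrize(
        ("age", "age_cod", "expected"),
        [
            ("72", "YR", 72.0),
            ("6", "MON", 0.5),
            ("7", "DEC", 70.0),
            ("14", "DY", 14 / 365.25),
            ("2", "WK", 2 / 52.18),
            ("80", "", 80.0),      # missing unit, plausible as years
            ("500", "", None),     # missing unit, too large for years
            ("-5", "YR", None),
            ("abc", "YR", None),
        ],
    )
    def test_age_conversion(self, age, age_cod, expected):
        result = _parse_age(age, age_cod)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)

    def test_demographics_mapping(self, tmp_path):
        quarter = read_quarter(_write_quarter(
            tmp_path,
            demo_rows=["11$1$1$20200101$72$YR$F$MD$US",
                       "21$2$1$20200102$$$M$CN$FR",
                       "31$3$1$20200103$6$MON$X$ZZ$XX"],
            drug_rows=["11$1$1$PS$LIPITOR$ATORVASTATIN"],
            reac_rows=["11$1$Nausea", "21$2$Rash", "31$3$Headache"],
            outc_rows=["11$1$HO", "11$1$DE", "21$2$XX"],
        ))
        reports = {r.primaryid: r for r in assemble_reports([quarter])}
        assert reports["11"].reporter == "health_professional"
        assert reports["11"].region == "North America"
        assert reports["11"].sex == "female"
        assert reports["11"].outcomes == ("death", "hospitalization")
        assert reports["11"].receipt_date == date(2020, 1, 1)
        assert reports["21"].reporter == "non_health_professional"
        assert reports["21"].region == "Europe"
        assert reports["21"].age_years is None
        assert reports["21"].outcomes == ("unknown",)
        assert reports["31"].age_years == pytest.approx(0.5)
        assert reports["31"].sex == "unknown"
        assert reports["31"].region == "unknown"

    def test_reports_without_reactions_are_dropped(self, tmp_path):
        quarter = read_quarter(_write_quarter(
            tmp_path,
            demo_rows=["11$1$1$20200101$72$YR$F$MD$US",
                       "21$2$1$20200102$60$YR$M$CN$GB"],
            reac_rows=["11$1$Nausea"],
        ))
        reports = assemble_reports([quarter])
        assert [r.primaryid for r in reports] == ["11"]


class TestDeduplicate:
    def test_latest_caseversion_survives(self, report_factory):
        v1 = report_factory(primaryid="101", caseid="10", caseversion=1)
        v2 = report_factory(primaryid="102", caseid="10", caseversion=2)
        survivors = deduplicate([v1, v2])
        assert [r.primaryid for r in survivors] == ["102"]

    def test_version_tie_broken_by_receipt_date(self, report_factory):
        early = report_factory(primaryid="101", caseid="10",
                               receipt_date=date(2020, 1, 1))
        late = report_factory(primaryid="102", caseid="10",
                              receipt_date=date(2021, 6, 1))
        assert deduplicate([late, early])[0].primaryid == "102"

    def test_deleted_case_removed_entirely(self, report_factory):
        reports = [report_factory(caseid="10"), report_factory(caseid="10", caseversion=2)]
        policy = DedupPolicy(deleted_case_ids=frozenset({"10"}))
        assert deduplicate(reports, policy) == []

    def test_latest_receipt_only_rule(self, report_factory):
        old_v2 = report_factory(primaryid="102", caseid="10", caseversion=2,
                                receipt_date=date(2019, 1, 1))
        new_v1 = report_factory(primaryid="101", caseid="10", caseversion=1,
                                receipt_date=date(2022, 1, 1))
        policy = DedupPolicy(keep_rule="latest_receipt_only")
        assert deduplicate([old_v2, new_v1], policy)[0].primaryid == "101"

    @given(spec=st.lists(
        st.tuples(st.integers(1, 6), st.integers(1, 4), st.integers(0, 400)),
        max_size=12),
        rnd=st.randoms(use_true_random=False))
    def test_idempotent_and_order_insensitive(self, spec, rnd, report_factory):
        reports = [
            report_factory(primaryid=f"{cid}0{ver}{day}", caseid=str(cid),
                           caseversion=ver,
                           receipt_date=date(2020, 1, 1) + __import__("datetime").timedelta(days=day))
            for cid, ver, day in spec
        ]
        survivors = deduplicate(reports)
        assert deduplicate(survivors) == survivors
        shuffled = list(reports)
        rnd.shuffle(shuffled)
        assert deduplicate(shuffled) == survivors


class TestStoreRoundTrip:
    def test_assemble_write_read_preserves_fields(self, small_quarter, dictionary, tmp_path):
        outdir, manifest = small_quarter
        quarter = read_quarter(outdir)
        reports = assemble_reports([quarter], dictionary=dictionary)
        policy = DedupPolicy(
            deleted_case_ids=read_deleted_cases(outdir / "deleted_cases.txt"))
        unique = deduplicate(reports, policy)
        assert len(unique) == manifest["n_unique_after_dedup"]
        store = tmp_path / "store"
        write_store(unique, store)
        assert read_store(store) == unique
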
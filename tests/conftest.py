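from __future__ import annotations

from datetime import date
from pathlib import Path

import pytest
from hypothesis import settings

from pvsignal.events import SmqTermSet
from pvsignal.exposure import DrugDictionary
from pvsignal.ingest import DrugUse, SafetyReport
from pvsignal.simulate import SyntheticTruth, generate

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary.default()


@pytest.fixture(scope="session")
def terms() -> SmqTermSet:
    return SmqTermSet.default()


@pytest.fixture(scope="session")
def report_factory():
    """Build a SafetyReport with sensible defaults for unit tests."""

    def make(
        primaryid: str = "100000011",
        caseid: str = "10000001",
        caseversion: int = 1,
        receipt_date: date | None = date(2020, 1, 15),
        age_years: float | None = 60.0,
        sex: str = "female",
        reporter: str = "health_professional",
        region: str = "Europe",
        outcomes: tuple[str, ...] = ("hospitalization",),
        drugs: tuple[tuple[str, str, str | None], ...] = (("PS", "COLCHICINE", "colchicine"),),
        reactions: tuple[str, ...] = ("Nausea",),
        indications: tuple[str, ...] = (),
    ) -> SafetyReport:
        return SafetyReport(
            primaryid=primaryid,
            caseid=caseid,
            caseversion=caseversion,
            receipt_date=receipt_date,
            age_years=age_years,
            sex=sex,
            reporter=reporter,
            region=region,
            outcomes=outcomes,
            drugs=tuple(DrugUse(role=r, verbatim=v, ingredient=i) for r, v, i in drugs),
            reactions=reactions,
            indications=indications,
        )

    return make


@pytest.fixture(scope="session")
def small_quarter(tmp_path_factory) -> tuple[Path, dict]:
    """A 500-report synthetic quarter with duplicates, deletions and
    pre-existing myopathy indications, shared across tests."""
    outdir = tmp_path_factory.mktemp("quarter500")
    truth = SyntheticTruth(
        n_reports=500,
        duplicate_rate=0.10,
        deleted_rate=0.02,
        preexisting_indication_rate=0.02,
    )
    manifest = generate(truth, outdir, seed=11)
    return outdir, manifest
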
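"""Reading, assembling and deduplicating FAERS-style quarterly report files.

The quarterly ASCII layout is a set of ``$``-delimited tables sharing a
``primaryid`` key: DEMO (demographics), DRUG, REAC (reactions), INDI
(indications), OUTC (outcomes) and THER (therapy dates).  A *case*
(``caseid``) may appear as several report versions (``caseversion``); the
analysis works on one surviving report per case, after removing cases named
in the publisher's deleted-case lists.

Only the post-2012 header-bearing dialect is supported; the reader is
deliberately simple and fixture-driven.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .resources import (
    OCCUPATION_MAP,
    OUTCOME_MAP,
    UNKNOWN,
    load_region_map,
)

logger = logging.getLogger(__name__)

TABLES = ("demo", "drug", "reac", "indi", "outc", "ther")

#: columns a table must carry to be interpretable downstream
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "caseversion", "fda_dt", "age", "age_cod",
             "sex", "occp_cod", "occr_country"),
    "drug": ("primaryid", "caseid", "role_cod", "drugname"),
    "reac": ("primaryid", "caseid", "pt"),
    "indi": ("primaryid", "caseid", "indi_pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid"),
}

#: age_cod -> multiplicative factor to years.  DEC codes decades of life.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "YEAR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

SEX_MAP = {"F": "female", "M": "male"}

DRUG_ROLES = ("PS", "SS", "C", "I")


class FormatError(ValueError):
    """A quarterly file does not carry a mandatory column."""


@dataclass
class RawQuarter:
    """Verbatim rows of one quarter, one DataFrame per table.

    Rows are kept exactly as read (all values as strings); filtering and
    joining happen later, so a DRUG row whose ``primaryid`` has no DEMO row
    is retained here and only flagged at assembly.
    """

    demo_rows: pd.DataFrame
    drug_rows: pd.DataFrame
    reac_rows: pd.DataFrame
    indi_rows: pd.DataFrame
    outc_rows: pd.DataFrame
    ther_rows: pd.DataFrame
    skipped_lines: dict[str, int] = field(default_factory=dict)
    source: str = ""

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, f"{name}_rows")


@dataclass
class DrugUse:
    role: str
    verbatim: str
    ingredient: str | None = None


@dataclass
class SafetyReport:
    """One spontaneous report (one version of one case)."""

    primaryid: str
    caseid: str
    caseversion: int
    receipt_date: date | None
    age_years: float | None
    sex: str
    reporter: str
    region: str
    outcomes: tuple[str, ...]
    drugs: tuple[DrugUse, ...]
    reactions: tuple[str, ...]
    indications: tuple[str, ...]


@dataclass(frozen=True)
class DedupPolicy:
    """Which report survives when a case has several versions.

    ``latest_caseversion_then_latest_receipt`` (the conventional choice)
    keeps the highest ``caseversion``, breaking ties by the latest receipt
    date and then the highest ``primaryid``; ``latest_receipt_only`` orders
    by receipt date first.  Both are deterministic.
    """

    deleted_case_ids: frozenset[str] = frozenset()
    keep_rule: str = "latest_caseversion_then_latest_receipt"


def _read_table(path: Path, name: str, delimiter: str) -> tuple[pd.DataFrame, int]:
    skipped: list = []

    def _on_bad_line(line: list[str]):  # pragma: no cover - exercised via fixture
        skipped.append(line)
        return None

    kwargs = dict(
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        quoting=3,  # QUOTE_NONE: the dialect has no quoting
        engine="python",
        on_bad_lines=_on_bad_line,
    )
    try:
        frame = pd.read_csv(path, encoding="utf-8", **kwargs)
    except UnicodeDecodeError:
        skipped.clear()
        frame = pd.read_csv(path, encoding="latin-1", **kwargs)
    frame.columns = [c.strip().lower() for c in frame.columns]
    missing = [c for c in MANDATORY_COLUMNS[name] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing} for {name.upper()}")
    if skipped:
        logger.warning("%s: skipped %d unreadable line(s)", path, len(skipped))
    return frame, len(skipped)


def _locate(paths: Mapping[str, Path] | str | Path) -> dict[str, Path]:
    if isinstance(paths, Mapping):
        return {k.lower(): Path(v) for k, v in paths.items()}
    root = Path(paths)
    found: dict[str, Path] = {}
    for child in sorted(root.iterdir()):
        stem = child.name.lower()
        for name in TABLES:
            if stem.startswith(name):
                found.setdefault(name, child)
    return found


def read_quarter(paths: Mapping[str, Path] | str | Path, delimiter: str = "$") -> RawQuarter:
    """Read one quarter's tables into a :class:`RawQuarter`.

    ``paths`` is either a mapping ``{"demo": ..., "drug": ...}`` or a
    directory whose file names start with the table names.  DEMO, DRUG and
    REAC are required; INDI, OUTC and THER default to empty tables.
    """
    located = _locate(paths)
    for required in ("demo", "drug", "reac"):
        if required not in located:
            raise FileNotFoundError(f"no {required.upper()} file found in {paths!r}")
    frames: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    for name in TABLES:
        if name in located:
            frames[name], n_bad = _read_table(located[name], name, delimiter)
            if n_bad:
                skipped[name] = n_bad
        else:
            frames[name] = pd.DataFrame(columns=list(MANDATORY_COLUMNS[name]))
    return RawQuarter(
        demo_rows=frames["demo"],
        drug_rows=frames["drug"],
        reac_rows=frames["reac"],
        indi_rows=frames["indi"],
        outc_rows=frames["outc"],
        ther_rows=frames["ther"],
        skipped_lines=skipped,
        source=str(paths),
    )


def _parse_age(age: str, age_cod: str) -> float | None:
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    if value < 0:
        return None
    code = (age_cod or "").strip().upper()
    if code in AGE_UNIT_TO_YEARS:
        years = value * AGE_UNIT_TO_YEARS[code]
    elif code == "":
        # Missing unit: plausibly years; day-coded ages would be huge.
        years = value if value <= 120.0 else None
    else:
        years = None
    if years is not None and years > 150.0:
        return None
    return years


def _parse_date(raw: str) -> date | None:
    raw = (raw or "").strip()
    if len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return datetime.strptime(raw, "%Y%m%d").date()
    except ValueError:
        return None


def _group_lists(frame: pd.DataFrame, columns: Sequence[str]) -> dict[str, list]:
    """primaryid -> list of column tuples (or scalars for one column)."""
    if frame.empty:
        return {}
    sub = frame.loc[:, ["primaryid", *columns]]
    key = sub["primaryid"].astype(str).str.strip()
    if len(columns) == 1:
        values = sub[columns[0]].astype(str).str.strip()
        return values.groupby(key, sort=False).agg(list).to_dict()
    tuples = list(zip(*(sub[c].astype(str).str.strip() for c in columns)))
    return pd.Series(tuples, index=key).groupby(level=0, sort=False).agg(list).to_dict()


def assemble_reports(
    quarters: Iterable[RawQuarter],
    dictionary=None,
    region_map: dict[str, str] | None = None,
) -> list[SafetyReport]:
    """Join quarterly tables into one :class:`SafetyReport` per ``primaryid``.

    Demographics that fail to parse degrade to unknown (counted in a log
    summary).  Reports carrying no reaction rows are dropped — an
    adverse-event report without an event is uninterpretable — and the drop
    count is logged.  If a drug ``dictionary`` (see
    :mod:`pvsignal.exposure`) is given, verbatim names are normalised to
    ingredients at assembly.
    """
    quarters = list(quarters)
    if not quarters:
        raise ValueError("quarters must be nonempty")
    if region_map is None:
        region_map = load_region_map()

    demo = pd.concat([q.demo_rows for q in quarters], ignore_index=True)
    drug = pd.concat([q.drug_rows for q in quarters], ignore_index=True)
    reac = pd.concat([q.reac_rows for q in quarters], ignore_index=True)
    indi = pd.concat([q.indi_rows for q in quarters], ignore_index=True)
    outc = pd.concat([q.outc_rows for q in quarters], ignore_index=True)

    drugs_by_id = _group_lists(drug, ["role_cod", "drugname"])
    reacs_by_id = _group_lists(reac, ["pt"])
    indis_by_id = _group_lists(indi, ["indi_pt"])
    outcs_by_id = _group_lists(outc, ["outc_cod"])

    demo_ids = set(demo["primaryid"].astype(str).str.strip())
    orphans = [pid for pid in drugs_by_id if pid not in demo_ids]
    if orphans:
        logger.warning("%d DRUG primaryid(s) without a DEMO row (ignored)", len(orphans))

    reports: list[SafetyReport] = []
    n_no_reaction = 0
    n_unknown_age = 0
    seen: set[str] = set()
    for row in demo.itertuples(index=False):
        pid = str(row.primaryid).strip()
        if pid in seen:  # duplicated DEMO line for the same report version
            continue
        seen.add(pid)
        pts = tuple(p for p in reacs_by_id.get(pid, []) if p)
        if not pts:
            n_no_reaction += 1
            continue
        age_years = _parse_age(getattr(row, "age", ""), getattr(row, "age_cod", ""))
        if age_years is None:
            n_unknown_age += 1
        try:
            caseversion = int(str(row.caseversion).strip() or 1)
        except ValueError:
            caseversion = 1
        country = str(getattr(row, "occr_country", "")).strip().upper()
        occp = str(getattr(row, "occp_cod", "")).strip().upper()
        sex = SEX_MAP.get(str(getattr(row, "sex", "")).strip().upper(), UNKNOWN)
        raw_outcomes = outcs_by_id.get(pid, [])
        outcomes = tuple(sorted({OUTCOME_MAP.get(o.strip().upper(), UNKNOWN)
                                 for o in raw_outcomes if o.strip()})) or (UNKNOWN,)
        drug_uses = tuple(
            DrugUse(
                role=role.strip().upper(),
                verbatim=name,
                ingredient=(dictionary.lookup(name) if dictionary is not None else None),
            )
            for role, name in drugs_by_id.get(pid, [])
        )
        reports.append(
            SafetyReport(
                primaryid=pid,
                caseid=str(row.caseid).strip(),
                caseversion=caseversion,
                receipt_date=_parse_date(str(getattr(row, "fda_dt", ""))),
                age_years=age_years,
                sex=sex,
                reporter=OCCUPATION_MAP.get(occp, UNKNOWN),
                region=region_map.get(country, UNKNOWN),
                outcomes=outcomes,
                drugs=drug_uses,
                reactions=pts,
                indications=tuple(p for p in indis_by_id.get(pid, []) if p),
            )
        )
    if n_no_reaction:
        logger.info("dropped %d report(s) with no reaction rows", n_no_reaction)
    if n_unknown_age:
        logger.info("%d report(s) with unparseable age -> unknown", n_unknown_age)
    reports.sort(key=lambda r: _id_key(r.primaryid))
    return reports


def _id_key(value: str) -> tuple:
    # numeric-aware deterministic ordering for opaque string ids
    return (len(value), value)


def _keep_key(report: SafetyReport, rule: str) -> tuple:
    receipt = report.receipt_date or date.min
    pid = _id_key(report.primaryid)
    if rule == "latest_receipt_only":
        return (receipt, report.caseversion, pid)
    if rule == "latest_caseversion_then_latest_receipt":
        return (report.caseversion, receipt, pid)
    raise ValueError(f"unknown keep_rule {rule!r}")


def deduplicate(
    reports: Sequence[SafetyReport], policy: DedupPolicy | None = None
) -> list[SafetyReport]:
    """One surviving report per case.

    Cases named in ``policy.deleted_case_ids`` are removed entirely; among
    the remaining versions of each case exactly one survives according to
    ``policy.keep_rule``.  The output is sorted by ``caseid``, so the result
    is a deterministic, idempotent, input-order-insensitive function of the
    input *set*.
    """
    policy = policy or DedupPolicy()
    best: dict[str, SafetyReport] = {}
    for report in reports:
        if report.caseid in policy.deleted_case_ids:
            continue
        incumbent = best.get(report.caseid)
        if incumbent is None or _keep_key(report, policy.keep_rule) > _keep_key(
            incumbent, policy.keep_rule
        ):
            best[report.caseid] = report
    return [best[cid] for cid in sorted(best, key=_id_key)]


def read_deleted_cases(path: str | Path) -> frozenset[str]:
    """Deleted-case list: one caseid per line, blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return frozenset(line.strip() for line in lines if line.strip())


# ---------------------------------------------------------------------------
# Normalised report store (schema v1): directory of plain CSV tables.
# ---------------------------------------------------------------------------

STORE_SCHEMA_VERSION = 1


def write_store(reports: Sequence[SafetyReport], outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "primaryid": r.primaryid,
            "caseid": r.caseid,
            "caseversion": r.caseversion,
            "receipt_date": r.receipt_date.isoformat() if r.receipt_date else "",
            "age_years": "" if r.age_years is None else repr(float(r.age_years)),
            "sex": r.sex,
            "reporter": r.reporter,
            "region": r.region,
            "outcomes": ";".join(r.outcomes),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(out / "reports.csv", index=False)
    drug_rows = [
        {"primaryid": r.primaryid, "role": d.role, "verbatim": d.verbatim,
         "ingredient": d.ingredient or ""}
        for r in reports for d in r.drugs
    ]
    pd.DataFrame(drug_rows, columns=["primaryid", "role", "verbatim", "ingredient"]).to_csv(
        out / "drugs.csv", index=False)
    pd.DataFrame(
        [{"primaryid": r.primaryid, "pt": p} for r in reports for p in r.reactions],
        columns=["primaryid", "pt"],
    ).to_csv(out / "reactions.csv", index=False)
    pd.DataFrame(
        [{"primaryid": r.primaryid, "indi_pt": p} for r in reports for p in r.indications],
        columns=["primaryid", "indi_pt"],
    ).to_csv(out / "indications.csv", index=False)
    (out / "store_manifest.json").write_text(
        json.dumps({"schema_version": STORE_SCHEMA_VERSION, "n_reports": len(reports)},
                   indent=2)
    )
    return out


def read_store(indir: str | Path) -> list[SafetyReport]:
    src = Path(indir)
    reports_df = pd.read_csv(src / "reports.csv", dtype=str, keep_default_na=False)
    drugs_df = pd.read_csv(src / "drugs.csv", dtype=str, keep_default_na=False)
    reac_df = pd.read_csv(src / "reactions.csv", dtype=str, keep_default_na=False)
    indi_df = pd.read_csv(src / "indications.csv", dtype=str, keep_default_na=False)

    drugs_by_id: dict[str, list[DrugUse]] = {}
    for row in drugs_df.itertuples(index=False):
        drugs_by_id.setdefault(row.primaryid, []).append(
            DrugUse(role=row.role, verbatim=row.verbatim,
                    ingredient=row.ingredient or None))
    reac_by_id = reac_df.groupby("primaryid", sort=False)["pt"].agg(list).to_dict()
    indi_by_id = indi_df.groupby("primaryid", sort=False)["indi_pt"].agg(list).to_dict()

    out = []
    for row in reports_df.itertuples(index=False):
        out.append(
            SafetyReport(
                primaryid=row.primaryid,
                caseid=row.caseid,
                caseversion=int(row.caseversion),
                receipt_date=date.fromisoformat(row.receipt_date) if row.receipt_date else None,
                age_years=float(row.age_years) if row.age_years else None,
                sex=row.sex,
                reporter=row.reporter,
                region=row.region,
                outcomes=tuple(row.outcomes.split(";")) if row.outcomes else (UNKNOWN,),
                drugs=tuple(drugs_by_id.get(row.primaryid, [])),
                reactions=tuple(reac_by_id.get(row.primaryid, [])),
                indications=tuple(indi_by_id.get(row.primaryid, [])),
            )
        )
    return out
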
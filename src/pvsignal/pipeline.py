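"""End-to-end study orchestration and report tables.

``run_study`` chains ingestion -> deduplication -> prior-myopathy exclusion
-> exposure grouping -> case labeling -> signal evaluation, and emits
machine-readable analogues of the usual pharmacovigilance deliverables: a
case-flow table, a demographics table, per-drug report counts, drug-level
and PT-level signal tables, combination signal tables and per-year counts.

Counting conventions
--------------------
* The counting unit is the *report* everywhere except the PT-level analysis,
  where it is the (report, PT) pair.
* Percentage columns use the combined case denominator across all drug
  groups (myopathy and non-myopathy columns separately).
* A report may carry several outcome codes and then contributes to several
  outcome rows; outcome percentages are therefore per-report shares and may
  sum above 100.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__ as _pkg_version
from .events import CaseLabel, SmqTermSet, classify_report, exclude_preexisting, normalize_pt
from .exposure import (
    ALL_GROUPS,
    COMBINATION_GROUPS,
    GROUP_COLCHICINE,
    GROUP_MULTI_STATIN,
    GROUP_OTHER,
    SINGLE_STATIN_GROUPS,
    STATIN_GROUPS,
    DrugDictionary,
    assign_group,
    display_label,
)
from .ingest import (
    DedupPolicy,
    SafetyReport,
    assemble_reports,
    deduplicate,
    read_deleted_cases,
    read_quarter,
)
from .stats import DEFAULT_MIN_CASES, Z95, build_table, evaluate_signal, signal_table

AGE_BINS = ("<18 years", "18-64 years", ">=65 years", "unknown")


class StudyConfig(BaseModel):
    """Everything that determines one analysis run."""

    quarters: list[Path] = Field(default_factory=list)
    deleted_cases: Path | None = None
    drug_dictionary: Path | None = None
    term_set: Path | None = None
    comparator: str = "rest_of_store"
    background: tuple[int, int] | None = None
    min_cases: int = DEFAULT_MIN_CASES
    z: float = Z95
    ic_method: str = "noren_credible"
    roles: tuple[str, ...] = ("PS",)
    keep_rule: str = "latest_caseversion_then_latest_receipt"
    output_dir: Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def analysis_dump(self) -> dict:
        # output_dir is the destination, not part of the analysis: two runs
        # writing to different places are the same study
        dump = self.model_dump(mode="json")
        dump.pop("output_dir", None)
        return dump

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    case_flow: pd.DataFrame
    labeled: pd.DataFrame
    demographics_table: pd.DataFrame
    drug_count_table: pd.DataFrame
    drug_level_signals: pd.DataFrame
    pt_level_signals: pd.DataFrame
    combination_signals: pd.DataFrame
    annual_counts: pd.DataFrame
    n_excluded_preexisting: int
    config: StudyConfig | None = None


def age_bin(age_years: float | None) -> str:
    if age_years is None or pd.isna(age_years):
        return "unknown"
    if age_years < 18:
        return "<18 years"
    if age_years < 65:
        return "18-64 years"
    return ">=65 years"


def percentages(
    counts: Mapping[str, float], denominator: float | None = None, ndigits: int = 1
) -> dict[str, float]:
    """Percentage shares of a count column, rounded for display.

    With no explicit ``denominator`` the column total is used, so the result
    sums to 100 up to rounding.
    """
    total = float(denominator) if denominator is not None else float(sum(counts.values()))
    if total <= 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}


def included_total(*count_groups: Mapping[str, float] | float | int) -> int:
    """Total included reactions/reports from per-group counts.

    Accepts any mix of mappings and bare numbers and sums everything —
    the case-flow arithmetic behind 'a final total of N were included'.
    """
    total = 0.0
    for entry in count_groups:
        if isinstance(entry, Mapping):
            total += sum(entry.values())
        else:
            total += float(entry)
    return int(round(total))


def label_reports(
    reports: Sequence[SafetyReport],
    dictionary: DrugDictionary,
    terms: SmqTermSet,
    roles: tuple[str, ...] = ("PS",),
) -> pd.DataFrame:
    """One row per report with exposure group, case label and demographics."""
    rows = []
    for report in reports:
        label: CaseLabel = classify_report(report, terms)
        rows.append({
            "primaryid": report.primaryid,
            "caseid": report.caseid,
            "group": assign_group(report, dictionary, roles),
            "is_case": label.is_myopathy_case,
            "matched_pts": ";".join(label.matched_pts),
            "n_reactions": len(report.reactions),
            "reactions": ";".join(sorted({normalize_pt(p) for p in report.reactions})),
            "age_years": report.age_years,
            "age_bin": age_bin(report.age_years),
            "sex": report.sex,
            "reporter": report.reporter,
            "region": report.region,
            "outcomes": ";".join(report.outcomes),
            "year": report.receipt_date.year if report.receipt_date else None,
        })
    columns = ["primaryid", "caseid", "group", "is_case", "matched_pts",
               "n_reactions", "reactions", "age_years", "age_bin", "sex",
               "reporter", "region", "outcomes", "year"]
    return pd.DataFrame(rows, columns=columns)


def add_pt_columns(labeled: pd.DataFrame, pts: Sequence[str]) -> pd.DataFrame:
    """Add one boolean ``pt:<name>`` column per preferred term, derived from
    the semicolon-joined ``reactions`` column (report-unit membership)."""
    out = labeled.copy()
    sets = labeled["reactions"].str.split(";").map(set)
    for pt in pts:
        key = normalize_pt(pt)
        out[f"pt:{pt}"] = sets.map(lambda s, key=key: key in s)
    return out


def _section_counts(frame: pd.DataFrame, column: str,
                    categories: Sequence[str]) -> dict[str, int]:
    counts = frame[column].value_counts()
    return {cat: int(counts.get(cat, 0)) for cat in categories}


def demographics_summary(labeled: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Counts and percentage shares by drug group, age, sex, reporter
    occupation, region and outcome, separately for myopathy and
    non-myopathy reports."""
    from .resources import OUTCOME_CATEGORIES, REGIONS

    sections: list[tuple[str, str, dict[str, int], dict[str, int]]] = []
    cases = labeled[labeled["is_case"]]
    controls = labeled[~labeled["is_case"]]

    group_rows = {
        "Statins": list(STATIN_GROUPS),
        "Colchicine": [GROUP_COLCHICINE],
        "Colchicine and statins": list(COMBINATION_GROUPS),
    }
    if (labeled["group"] == GROUP_OTHER).any():
        group_rows["Other"] = [GROUP_OTHER]
    case_group = {k: int(cases["group"].isin(v).sum()) for k, v in group_rows.items()}
    ctrl_group = {k: int(controls["group"].isin(v).sum()) for k, v in group_rows.items()}
    sections.append(("drug_group", "", case_group, ctrl_group))

    sections.append(("age_group", "", _section_counts(cases, "age_bin", AGE_BINS),
                     _section_counts(controls, "age_bin", AGE_BINS)))
    sex_cats = ("female", "male", "unknown")
    sections.append(("sex", "", _section_counts(cases, "sex", sex_cats),
                     _section_counts(controls, "sex", sex_cats)))
    rep_cats = ("health_professional", "non_health_professional", "unknown")
    sections.append(("reporter_occupation", "", _section_counts(cases, "reporter", rep_cats),
                     _section_counts(controls, "reporter", rep_cats)))
    sections.append(("reporter_region", "", _section_counts(cases, "region", REGIONS),
                     _section_counts(controls, "region", REGIONS)))

    def outcome_counts(frame: pd.DataFrame) -> dict[str, int]:
        exploded = frame["outcomes"].str.split(";").explode()
        counts = exploded.value_counts()
        return {cat: int(counts.get(cat, 0)) for cat in OUTCOME_CATEGORIES}

    sections.append(("outcomes", "multi", outcome_counts(cases), outcome_counts(controls)))

    rows = []
    n_cases, n_controls = len(cases), len(controls)
    for section, kind, case_counts, ctrl_counts in sections:
        case_pct = percentages(case_counts, denominator=n_cases or None, ndigits=ndigits)
        ctrl_pct = percentages(ctrl_counts, denominator=n_controls or None, ndigits=ndigits)
        for category in case_counts:
            rows.append({
                "section": section,
                "category": category,
                "myopathy_n": case_counts[category],
                "myopathy_pct": case_pct[category],
                "non_myopathy_n": ctrl_counts[category],
                "non_myopathy_pct": ctrl_pct[category],
                "multi_membership": kind == "multi",
            })
    return pd.DataFrame(rows)


def drug_count_table(labeled: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Per-drug report counts (myopathy / non-myopathy) with shares of the
    combined case totals.  The combination aggregate is included as a row so
    each count column sums to its overall total."""
    rows_spec: list[tuple[str, list[str]]] = [
        (display_label(g), [g]) for g in SINGLE_STATIN_GROUPS
    ]
    rows_spec.append((display_label(GROUP_MULTI_STATIN), [GROUP_MULTI_STATIN]))
    rows_spec.append(("colchicine", [GROUP_COLCHICINE]))
    rows_spec.append(("colchicine and statins", list(COMBINATION_GROUPS)))
    if (labeled["group"] == GROUP_OTHER).any():
        rows_spec.append(("other", [GROUP_OTHER]))

    cases = labeled[labeled["is_case"]]
    controls = labeled[~labeled["is_case"]]
    case_counts = {name: int(cases["group"].isin(members).sum())
                   for name, members in rows_spec}
    ctrl_counts = {name: int(controls["group"].isin(members).sum())
                   for name, members in rows_spec}
    case_pct = percentages(case_counts, ndigits=ndigits)
    ctrl_pct = percentages(ctrl_counts, ndigits=ndigits)
    return pd.DataFrame([
        {"drug": name, "myopathy_n": case_counts[name], "myopathy_pct": case_pct[name],
         "non_myopathy_n": ctrl_counts[name], "non_myopathy_pct": ctrl_pct[name]}
        for name, _ in rows_spec
    ])


def _drug_level_groups(labeled: pd.DataFrame) -> list[tuple[str, list[str]]]:
    present = set(labeled["group"])
    groups: list[tuple[str, list[str]]] = []
    for g in SINGLE_STATIN_GROUPS + (GROUP_MULTI_STATIN,):
        if g in present:
            groups.append((display_label(g), [g]))
    if GROUP_COLCHICINE in present:
        groups.append((GROUP_COLCHICINE, [GROUP_COLCHICINE]))
    if present & set(COMBINATION_GROUPS):
        groups.append(("colchicine and statins", list(COMBINATION_GROUPS)))
    return groups


def pt_level_signals(
    labeled: pd.DataFrame,
    groups: Iterable[tuple[str, Sequence[str]]],
    terms: SmqTermSet,
    min_cases: int = DEFAULT_MIN_CASES,
    z: float = Z95,
    ic_method: str = "noren_credible",
) -> pd.DataFrame:
    """Per-(group, PT) signal table with the (report, PT) pair as unit.

    PTs with fewer than ``min_cases`` reports in a group keep their row,
    flagged ``below_threshold`` and never a signal; PTs absent from the
    store keep an ``a = 0`` row.
    """
    pairs = labeled.loc[:, ["group", "reactions"]].copy()
    pairs["pt"] = pairs.pop("reactions").str.split(";")
    pairs = pairs.explode("pt")
    pairs = pairs[pairs["pt"].astype(bool)]

    rows = []
    for name, members in groups:
        in_group = pairs["group"].isin(list(members))
        if not in_group.any():
            continue
        for pt in terms.terms:
            is_event = (pairs["pt"] == pt).to_numpy()
            frame = pd.DataFrame({
                "group": in_group.map({True: "index", False: "rest"}),
                "is_case": is_event,
            })
            table = build_table(frame, "index")
            res = evaluate_signal(table, min_cases=min_cases, z=z, ic_method=ic_method)
            rows.append({
                "group": name, "pt": pt,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "ror": res.ror, "ror_low": res.ror_low, "ror_high": res.ror_high,
                "ic": res.ic, "ic_low": res.ic_low, "ic_high": res.ic_high,
                "is_signal": res.is_signal,
                "below_threshold": table.a < min_cases,
                "haldane_applied": res.haldane_applied,
                "ic_method": ic_method,
            })
    return pd.DataFrame(rows)


def annual_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    frame = labeled.dropna(subset=["year"]).copy()
    if frame.empty:
        return pd.DataFrame(columns=["year", "group", "is_case", "n"])
    frame["year"] = frame["year"].astype(int)
    out = (frame.groupby(["year", "group", "is_case"], sort=True)
           .size().rename("n").reset_index())
    return out


def run_study(
    config: StudyConfig,
    reports: Sequence[SafetyReport] | None = None,
) -> StudyReport:
    """Execute the full analysis; deterministic given the config.

    ``reports`` may be supplied directly (already assembled, pre-dedup) to
    skip file ingestion.
    """
    dictionary = (DrugDictionary.from_file(config.drug_dictionary)
                  if config.drug_dictionary else DrugDictionary.default())
    terms = (SmqTermSet.from_file(config.term_set)
             if config.term_set else SmqTermSet.default())

    flow: list[dict] = []
    if reports is None:
        if not config.quarters:
            raise ValueError("config.quarters is empty and no reports were passed")
        quarters = [read_quarter(q) for q in config.quarters]
        reports = assemble_reports(quarters, dictionary=dictionary)
    reports = list(reports)
    flow.append({"stage": "assembled_report_versions", "n_reports": len(reports),
                 "n_reactions": sum(len(r.reactions) for r in reports)})

    deleted = (read_deleted_cases(config.deleted_cases)
               if config.deleted_cases else frozenset())
    policy = DedupPolicy(deleted_case_ids=deleted, keep_rule=config.keep_rule)
    unique = deduplicate(reports, policy)
    flow.append({"stage": "after_dedup", "n_reports": len(unique),
                 "n_reactions": sum(len(r.reactions) for r in unique)})

    analyzed, n_excluded = exclude_preexisting(unique, terms)
    flow.append({"stage": "after_prior_myopathy_exclusion", "n_reports": len(analyzed),
                 "n_reactions": sum(len(r.reactions) for r in analyzed)})

    labeled = label_reports(analyzed, dictionary, terms, roles=config.roles)
    groups = _drug_level_groups(labeled) if not labeled.empty else []

    drug_signals = signal_table(
        labeled, groups, comparator=config.comparator, background=config.background,
        min_cases=config.min_cases, z=config.z, ic_method=config.ic_method,
    ) if groups else pd.DataFrame()

    combo_present = [g for g in COMBINATION_GROUPS if (labeled["group"] == g).any()] \
        if not labeled.empty else []
    combo_entries: list = [(display_label(g), [g]) for g in combo_present]
    if combo_present:
        combo_entries.append(("colchicine and statins", list(COMBINATION_GROUPS)))
    combo_signals = signal_table(
        labeled, combo_entries, comparator=config.comparator,
        background=config.background, min_cases=config.min_cases, z=config.z,
        ic_method=config.ic_method,
    ) if combo_entries else pd.DataFrame()

    pt_groups: list[tuple[str, Sequence[str]]] = []
    if not labeled.empty:
        present = set(labeled["group"])
        if present & set(STATIN_GROUPS):
            pt_groups.append(("statins", list(STATIN_GROUPS)))
        if GROUP_COLCHICINE in present:
            pt_groups.append(("colchicine", [GROUP_COLCHICINE]))
        if present & set(COMBINATION_GROUPS):
            pt_groups.append(("colchicine and statins", list(COMBINATION_GROUPS)))
    pt_signals = pt_level_signals(
        labeled, pt_groups, terms, min_cases=config.min_cases, z=config.z,
        ic_method=config.ic_method,
    ) if pt_groups else pd.DataFrame()

    report = StudyReport(
        case_flow=pd.DataFrame(flow),
        labeled=labeled,
        demographics_table=(demographics_summary(labeled)
                            if not labeled.empty else pd.DataFrame()),
        drug_count_table=(drug_count_table(labeled)
                          if not labeled.empty else pd.DataFrame()),
        drug_level_signals=drug_signals,
        pt_level_signals=pt_signals,
        combination_signals=combo_signals,
        annual_counts=annual_counts(labeled) if not labeled.empty else pd.DataFrame(),
        n_excluded_preexisting=n_excluded,
        config=config,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: StudyReport, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "case_flow": report.case_flow,
        "demographics": report.demographics_table,
        "drug_counts": report.drug_count_table,
        "drug_level_signals": report.drug_level_signals,
        "pt_level_signals": report.pt_level_signals,
        "combination_signals": report.combination_signals,
        "annual_counts": report.annual_counts,
        "labeled_reports": report.labeled,
    }
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "pvsignal_version": _pkg_version,
        "config": (report.config.analysis_dump() if report.config else None),
        "config_hash": (report.config.config_hash() if report.config else None),
        "n_reports_analyzed": int(len(report.labeled)),
        "n_excluded_preexisting": int(report.n_excluded_preexisting),
        "n_myopathy_cases": int(report.labeled["is_case"].sum())
        if not report.labeled.empty else 0,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
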
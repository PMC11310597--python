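"""Myopathy case classification via a narrow-scope SMQ-style term set.

A report is a *myopathy case* when any of its reaction preferred terms (PTs)
falls in the term set; the prior-myopathy exclusion removes reports whose
*indication* PTs fall in the same set (spontaneous reports have no reliable
medical-history table, so indications proxy for pre-existing disease).

MedDRA itself is licensed, so the packaged default term set contains the
muscle-toxicity PTs of the narrow rhabdomyolysis/myopathy query (SMQ
20000002) with UK/US spelling variants — an approximation a MedDRA licensee
can replace wholesale via config.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ingest import SafetyReport

_WS = re.compile(r"\s+")

DEFAULT_SMQ_CODE = "20000002"


def normalize_pt(pt: str) -> str:
    return _WS.sub(" ", str(pt).strip().lower())


@dataclass(frozen=True)
class SmqTermSet:
    """A set of preferred terms defining one clinical concept."""

    smq_code: str
    scope: str
    preferred_terms: frozenset[str]  # normalised PT names
    codes: tuple[tuple[str, str], ...] = ()  # (pt, meddra_code) as shipped

    def __post_init__(self):
        if not self.preferred_terms:
            raise ValueError("term set must be nonempty")

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self.preferred_terms

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.preferred_terms))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, smq_code: str = DEFAULT_SMQ_CODE,
                   scope: str = "narrow") -> "SmqTermSet":
        if "scope" in frame.columns:
            frame = frame[frame["scope"].str.strip().str.lower() == scope]
        pts = frozenset(normalize_pt(p) for p in frame["pt_name"])
        codes = tuple(
            (normalize_pt(r.pt_name), str(r.meddra_code))
            for r in frame.itertuples(index=False)
        ) if "meddra_code" in frame.columns else ()
        return cls(smq_code=smq_code, scope=scope, preferred_terms=pts, codes=codes)

    @classmethod
    def from_file(cls, path: str | Path, smq_code: str = DEFAULT_SMQ_CODE,
                  scope: str = "narrow") -> "SmqTermSet":
        """Load from a CSV (columns ``pt_name``, ``meddra_code``, ``scope``)
        or a YAML file with the same keys under a ``terms`` list."""
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(path.read_text())
            frame = pd.DataFrame(payload["terms"])
            smq_code = str(payload.get("smq_code", smq_code))
            scope = str(payload.get("scope", scope))
        else:
            frame = pd.read_csv(path, dtype=str)
        return cls.from_frame(frame, smq_code=smq_code, scope=scope)

    @classmethod
    def default(cls) -> "SmqTermSet":
        return cls.from_file(str(resources.files("pvsignal").joinpath(
            "data", "myopathy_terms.csv")))


@dataclass(frozen=True)
class CaseLabel:
    is_myopathy_case: bool
    matched_pts: tuple[str, ...]


def classify_report(report: SafetyReport, terms: SmqTermSet) -> CaseLabel:
    """Label a report by intersecting its reactions with the term set."""
    matched = tuple(sorted({normalize_pt(p) for p in report.reactions
                            if normalize_pt(p) in terms.preferred_terms}))
    return CaseLabel(is_myopathy_case=bool(matched), matched_pts=matched)


def exclude_preexisting(
    reports: Sequence[SafetyReport], terms: SmqTermSet
) -> tuple[list[SafetyReport], int]:
    """Drop reports whose indication PTs intersect the term set.

    Returns the retained reports and the number removed.
    """
    retained: list[SafetyReport] = []
    removed = 0
    for report in reports:
        if any(normalize_pt(p) in terms.preferred_terms for p in report.indications):
            removed += 1
        else:
            retained.append(report)
    return retained, removed
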
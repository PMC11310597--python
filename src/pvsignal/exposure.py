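"""Drug-name normalisation and exposure-group assignment.

Exposure is defined by the normalised ingredients among a report's
*primary-suspect* (role PS) drugs: a single statin, colchicine alone,
colchicine together with one named statin, two or more statins with or
without colchicine, or anything else (``other``).  Spontaneous reports carry
no concomitance timeline, so "combination" means co-suspected on the same
report.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .ingest import SafetyReport

logger = logging.getLogger(__name__)

STATINS = (
    "simvastatin",
    "atorvastatin",
    "rosuvastatin",
    "pravastatin",
    "fluvastatin",
    "lovastatin",
    "pitavastatin",
    "cerivastatin",
)
COLCHICINE = "colchicine"

GROUP_OTHER = "other"
GROUP_COLCHICINE = "colchicine"
GROUP_MULTI_STATIN = "statin:multiple"
GROUP_COLCHICINE_MULTI = "colchicine+statin:multiple"


def statin_group(name: str) -> str:
    return f"statin:{name}"


def combination_group(name: str) -> str:
    return f"colchicine+statin:{name}"


SINGLE_STATIN_GROUPS = tuple(statin_group(s) for s in STATINS)
COMBINATION_GROUPS = tuple(combination_group(s) for s in STATINS) + (GROUP_COLCHICINE_MULTI,)
STATIN_GROUPS = SINGLE_STATIN_GROUPS + (GROUP_MULTI_STATIN,)
ALL_GROUPS = STATIN_GROUPS + (GROUP_COLCHICINE,) + COMBINATION_GROUPS + (GROUP_OTHER,)

#: human-readable labels for reporting tables
DISPLAY_LABELS = {
    GROUP_MULTI_STATIN: "≥2 statins",
    GROUP_COLCHICINE_MULTI: "colchicine + ≥2 statins",
}

# Tokens stripped during cleaning: pure numbers, dose amounts, units,
# formulation and salt words that never distinguish ingredients.
_NOISE_TOKEN = re.compile(
    r"^(?:\d+(?:\.\d+)?|\d+(?:\.\d+)?(?:MG|MCG|G|ML|IU)|MG|MCG|G|ML|IU|"
    r"TABLET|TABLETS|TAB|TABS|CAPSULE|CAPSULES|CAP|CAPS|ER|XR|SR|XL|CR|"
    r"ORAL|INJECTION|SOLUTION|SUSPENSION|FILM|COATED|DELAYED|EXTENDED|"
    r"RELEASE|CALCIUM|SODIUM|UNKNOWN|UNK)$"
)
_PUNCT = re.compile(r"[^A-Z0-9]+")


def clean_name(verbatim: str) -> str:
    """Uppercase, punctuation to spaces, noise tokens dropped, spaces collapsed."""
    upper = _PUNCT.sub(" ", str(verbatim).upper())
    tokens = [t for t in upper.split() if not _NOISE_TOKEN.match(t)]
    return " ".join(tokens)


@dataclass
class DrugDictionary:
    """Cleaned verbatim pattern -> canonical ingredient.

    Lookup is exact after :func:`clean_name`; there is no fuzzy matching.
    Out-of-dictionary names return ``None`` and are counted in ``misses``.
    """

    entries: dict[str, str]
    misses: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugDictionary":
        entries: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pattern, _, ingredient = line.partition("\t")
            if not ingredient:
                raise ValueError(f"malformed dictionary line (need two tab-separated "
                                 f"columns): {line!r}")
            entries[clean_name(pattern)] = ingredient.strip().lower()
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "DrugDictionary":
        return cls.from_file(str(resources.files("pvsignal").joinpath(
            "data", "drug_dictionary.tsv")))

    def lookup(self, verbatim: str) -> str | None:
        ingredient = self.entries.get(clean_name(verbatim))
        if ingredient is None:
            self.misses += 1
        return ingredient


def normalize_name(verbatim: str, dictionary: DrugDictionary) -> str | None:
    """Canonical ingredient for a verbatim drug name, or ``None`` if unknown."""
    return dictionary.lookup(verbatim)


def assign_group(
    report: SafetyReport,
    dictionary: DrugDictionary | None = None,
    roles: tuple[str, ...] = ("PS",),
) -> str:
    """Exposure-group label for a report based on its suspect ingredients.

    ``roles`` controls which drug roles define exposure (default: primary
    suspect only, the study's inclusion criterion; pass ``("PS", "SS")`` to
    widen to all suspects).  The label depends only on the *set* of
    normalised ingredients, so drug-row order and repeated rows for the same
    ingredient are irrelevant.
    """
    ingredients: set[str] = set()
    for use in report.drugs:
        if use.role not in roles:
            continue
        ingredient = use.ingredient
        if ingredient is None and dictionary is not None:
            ingredient = dictionary.lookup(use.verbatim)
        if ingredient:
            ingredients.add(ingredient)
    statins = sorted(i for i in ingredients if i in STATINS)
    has_colchicine = COLCHICINE in ingredients
    if has_colchicine:
        if len(statins) == 1:
            return combination_group(statins[0])
        if len(statins) >= 2:
            return GROUP_COLCHICINE_MULTI
        return GROUP_COLCHICINE
    if len(statins) == 1:
        return statin_group(statins[0])
    if len(statins) >= 2:
        return GROUP_MULTI_STATIN
    return GROUP_OTHER


def assign_groups(
    reports: Iterable[SafetyReport],
    dictionary: DrugDictionary | None = None,
    roles: tuple[str, ...] = ("PS",),
) -> list[str]:
    return [assign_group(r, dictionary, roles) for r in reports]


def display_label(group: str) -> str:
    return DISPLAY_LABELS.get(group, group)
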
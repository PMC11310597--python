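"""Synthetic FAERS-style data with known, planted association structure.

The generator emits quarterly-dialect files (DEMO/DRUG/REAC/INDI/OUTC/THER)
plus a JSON manifest of ground truth, so every pipeline stage — reading,
deduplication, name normalisation, exposure grouping, case classification
and the ROR/IC statistics — can be exercised without any external download.

The event model is the one the disproportionality statistics assume: given a
report's exposure group, each tracked preferred term occurs independently
with probability ``min(1, rate * background_prob)``, where ``rate`` is the
planted relative reporting rate (1 = no association).  Every report also
receives one guaranteed background reaction, so planted terms keep exactly
their configured marginal probability and no report is event-free.

Duplicates are exact copies of a case re-emitted with an incremented
``caseversion`` and a later receipt date, exercising the keep-latest dedup
rule specifically; a configurable fraction of case ids goes to the
deleted-case list; a small fraction of reports carries a myopathy
*indication* to exercise the prior-myopathy exclusion.

Default parameters emulate the relative group sizes and drug–event
disproportions of muscle-toxicity reporting for statins and colchicine (see
``docs/methods.md``); they are a statistical caricature, not an imitation of
real reporting biases.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import exposure
from .events import SmqTermSet, normalize_pt

OTHER_DRUGS = ("ASPIRIN", "IBUPROFEN", "METFORMIN", "OMEPRAZOLE")

#: verbatim spellings emitted per ingredient, exercising the normaliser
VERBATIM_VARIANTS = {
    "simvastatin": ("SIMVASTATIN", "SIMVASTATIN 20MG TABLET", "ZOCOR", "Simvastatin 40 mg"),
    "atorvastatin": ("ATORVASTATIN", "ATORVASTATIN CALCIUM", "LIPITOR", "Atorvastatin 10mg"),
    "rosuvastatin": ("ROSUVASTATIN", "ROSUVASTATIN CALCIUM", "CRESTOR"),
    "pravastatin": ("PRAVASTATIN", "PRAVASTATIN SODIUM", "PRAVACHOL"),
    "fluvastatin": ("FLUVASTATIN", "LESCOL", "FLUVASTATIN SODIUM"),
    "lovastatin": ("LOVASTATIN", "MEVACOR", "ALTOPREV"),
    "pitavastatin": ("PITAVASTATIN", "LIVALO"),
    "cerivastatin": ("CERIVASTATIN", "BAYCOL"),
    "colchicine": ("COLCHICINE", "COLCRYS", "COLCHICINE 0.6 MG TABLET", "MITIGARE"),
}

INDICATION_FOR = {"colchicine": "Gout"}
STATIN_INDICATION = "Hypercholesterolaemia"
OTHER_INDICATION = "Hypertension"
PREEXISTING_INDICATION = "Rhabdomyolysis"

OUTC_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


def _default_exposure_weights() -> dict[str, float]:
    # relative group sizes of a large muscle-toxicity retrieval:
    # ~97.5% statin reports, ~1.8% colchicine, ~0.75% combinations
    return {
        "statin:simvastatin": 248120.0,
        "statin:atorvastatin": 428319.0,
        "statin:rosuvastatin": 170742.0,
        "statin:pravastatin": 84323.0,
        "statin:fluvastatin": 7098.0,
        "statin:lovastatin": 24404.0,
        "statin:pitavastatin": 8297.0,
        "statin:cerivastatin": 176.0,
        "statin:multiple": 32335.0,
        "colchicine": 18394.0,
        "colchicine+statin:simvastatin": 1923.0,
        "colchicine+statin:atorvastatin": 3319.0,
        "colchicine+statin:rosuvastatin": 1323.0,
        "colchicine+statin:pravastatin": 653.0,
        "colchicine+statin:fluvastatin": 55.0,
        "colchicine+statin:lovastatin": 189.0,
        "colchicine+statin:pitavastatin": 64.0,
        "colchicine+statin:multiple": 253.0,
    }


def _default_background_event_prob() -> dict[str, float]:
    return {
        "rhabdomyolysis": 0.0012,
        "myopathy": 0.0003,
        "toxic myopathy": 0.00002,
        "necrotising myositis": 0.00008,
        "muscle necrosis": 0.00003,
        "myoglobin blood increased": 0.00005,
        "myoglobinuria": 0.00001,
    }


def _default_planted() -> list["PlantedAssociation"]:
    drug_level = {
        "statin:simvastatin": 12.3,
        "statin:atorvastatin": 6.3,
        "statin:rosuvastatin": 8.7,
        "statin:pravastatin": 2.7,
        "statin:fluvastatin": 13.0,
        "statin:lovastatin": 3.7,
        "statin:pitavastatin": 6.8,
        "statin:cerivastatin": 30.0,
        "statin:multiple": 13.8,
        "colchicine": 7.6,
        "colchicine+statin:simvastatin": 30.1,
        "colchicine+statin:atorvastatin": 25.7,
        "colchicine+statin:rosuvastatin": 25.7,
        "colchicine+statin:pravastatin": 13.7,
        "colchicine+statin:fluvastatin": 187.4,
        "colchicine+statin:lovastatin": 8.6,
        "colchicine+statin:pitavastatin": 15.0,
        "colchicine+statin:multiple": 30.0,
    }
    planted = [
        PlantedAssociation(group=g, pt=pt, rate=r)
        for g, r in drug_level.items()
        for pt in ("rhabdomyolysis", "myopathy")
    ]
    planted.append(PlantedAssociation(group="colchicine", pt="toxic myopathy", rate=32.5))
    planted.extend(
        PlantedAssociation(group=g, pt="toxic myopathy", rate=159.9)
        for g in drug_level if g.startswith("colchicine+statin:")
    )
    return planted


def _default_base_reactions() -> dict[str, float]:
    return {
        "Nausea": 0.14,
        "Headache": 0.11,
        "Dizziness": 0.09,
        "Diarrhoea": 0.10,
        "Fatigue": 0.10,
        "Vomiting": 0.07,
        "Rash": 0.07,
        "Arthralgia": 0.08,
        "Myalgia": 0.06,
        "Dyspnoea": 0.06,
        "Drug ineffective": 0.12,
    }


class PlantedAssociation(BaseModel):
    """One (exposure group, preferred term) pair with its relative rate."""

    group: str
    pt: str
    rate: float = Field(ge=0.0)


class DemographicMarginals(BaseModel):
    age_mean: float = 63.0
    age_sd: float = 15.0
    age_unknown_prob: float = 0.18
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.47, "M": 0.46, "": 0.07})
    occp_probs: dict[str, float] = Field(
        default_factory=lambda: {"MD": 0.30, "PH": 0.12, "OT": 0.10,
                                 "CN": 0.35, "LW": 0.03, "": 0.10})
    country_probs: dict[str, float] = Field(
        default_factory=lambda: {"US": 0.58, "GB": 0.07, "DE": 0.05, "FR": 0.05,
                                 "JP": 0.04, "CA": 0.04, "AU": 0.02, "IT": 0.03,
                                 "BR": 0.02, "ZA": 0.01, "": 0.09})
    #: each code drawn independently; a report may carry several outcomes
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: {"DE": 0.08, "LT": 0.04, "HO": 0.30, "DS": 0.02,
                                 "CA": 0.001, "RI": 0.003, "OT": 0.27})


class SyntheticTruth(BaseModel):
    """Full specification of a synthetic report store."""

    n_reports: int = Field(default=20000, gt=0)
    exposure_weights: dict[str, float] = Field(default_factory=_default_exposure_weights)
    background_event_prob: dict[str, float] = Field(
        default_factory=_default_background_event_prob)
    planted: list[PlantedAssociation] = Field(default_factory=_default_planted)
    base_reactions: dict[str, float] = Field(default_factory=_default_base_reactions)
    duplicate_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    deleted_rate: float = Field(default=0.002, ge=0.0, le=1.0)
    preexisting_indication_rate: float = Field(default=0.00014, ge=0.0, le=1.0)
    concomitant_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    demographics: DemographicMarginals = Field(default_factory=DemographicMarginals)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticTruth":
        for key, prob in self.background_event_prob.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"background probability for {key!r} outside [0, 1]")
        missing = [pa.pt for pa in self.planted
                   if pa.pt not in self.background_event_prob]
        if missing:
            raise ValueError(
                f"planted PTs without a background probability: {sorted(set(missing))}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def rate_for(self, group: str, pt: str) -> float:
        for pa in self.planted:
            if pa.group == group and pa.pt == pt:
                return pa.rate
        return 1.0


def _categorical(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    weights = np.array(list(probs.values()), dtype=float)
    weights = weights / weights.sum()
    return keys[rng.choice(len(keys), size=n, p=weights)]


def _simulate_core(truth: SyntheticTruth, rng: np.random.Generator) -> dict:
    """Draw all per-report arrays.  The draw order is fixed and documented
    here; together with ``numpy.random.default_rng`` this makes output
    byte-identical across runs and platforms for a given seed."""
    n = truth.n_reports
    labels_arr = np.array(sorted(truth.exposure_weights), dtype=object)
    weights = np.array([truth.exposure_weights[str(l)] for l in labels_arr], float)
    weights = weights / weights.sum()
    label_idx = rng.choice(len(labels_arr), size=n, p=weights)

    tracked = sorted(truth.background_event_prob)
    prob_matrix = np.empty((len(labels_arr), len(tracked)))
    for i, label in enumerate(labels_arr):
        for j, pt in enumerate(tracked):
            prob_matrix[i, j] = min(
                1.0, truth.background_event_prob[pt] * truth.rate_for(str(label), pt))
    events = rng.random((n, len(tracked))) < prob_matrix[label_idx]

    base_keys = list(truth.base_reactions)
    base_idx = rng.choice(
        len(base_keys), size=n,
        p=np.array([truth.base_reactions[k] for k in base_keys]) /
        sum(truth.base_reactions.values()))

    dem = truth.demographics
    age = np.clip(np.round(rng.normal(dem.age_mean, dem.age_sd, n)), 1, 100)
    age_unknown = rng.random(n) < dem.age_unknown_prob
    sex = _categorical(rng, dem.sex_probs, n)
    occp = _categorical(rng, dem.occp_probs, n)
    country = _categorical(rng, dem.country_probs, n)
    outcome_flags = rng.random((n, len(OUTC_CODES))) < np.array(
        [dem.outcome_probs.get(code, 0.0) for code in OUTC_CODES])

    preexisting = rng.random(n) < truth.preexisting_indication_rate
    duplicated = rng.random(n) < truth.duplicate_rate
    deleted = rng.random(n) < truth.deleted_rate
    # auxiliary integer streams for drug-name variants / secondary picks
    aux = rng.integers(0, 2**31 - 1, size=(n, 4))
    receipt_offset = rng.integers(0, 3650, size=n)

    return {
        "labels_arr": labels_arr,
        "label_idx": label_idx,
        "tracked": tracked,
        "events": events,
        "prob_matrix": prob_matrix,
        "base_keys": base_keys,
        "base_idx": base_idx,
        "age": age,
        "age_unknown": age_unknown,
        "sex": sex,
        "occp": occp,
        "country": country,
        "outcome_flags": outcome_flags,
        "preexisting": preexisting,
        "duplicated": duplicated,
        "deleted": deleted,
        "aux": aux,
        "receipt_offset": receipt_offset,
    }


def _manifest(truth: SyntheticTruth, core: dict, seed: int) -> dict:
    labels = core["labels_arr"][core["label_idx"]]
    analyzed = ~core["deleted"] & ~core["preexisting"]
    tracked = core["tracked"]
    keep_frac = (1.0 - truth.deleted_rate) * (1.0 - truth.preexisting_indication_rate)
    weights = np.array([truth.exposure_weights[str(l)] for l in core["labels_arr"]], float)
    weights = weights / weights.sum()

    realized: dict[str, dict[str, int]] = {}
    expected: dict[str, dict[str, float]] = {}
    label_counts: dict[str, int] = {}
    for i, label in enumerate(core["labels_arr"]):
        mask = analyzed & (core["label_idx"] == i)
        label_counts[str(label)] = int(mask.sum())
        realized[str(label)] = {
            pt: int(core["events"][mask, j].sum()) for j, pt in enumerate(tracked)}
        expected[str(label)] = {
            pt: float(truth.n_reports * weights[i] * keep_frac * core["prob_matrix"][i, j])
            for j, pt in enumerate(tracked)}

    return {
        "seed": int(seed),
        "n_reports": int(truth.n_reports),
        "n_duplicate_rows": int(core["duplicated"].sum()),
        "n_deleted_cases": int(core["deleted"].sum()),
        "n_unique_after_dedup": int((~core["deleted"]).sum()),
        "n_preexisting_excluded": int((core["preexisting"] & ~core["deleted"]).sum()),
        "n_analyzed": int(analyzed.sum()),
        "label_counts_analyzed": label_counts,
        "realized_counts": realized,
        "expected_counts": expected,
        "planted": [pa.model_dump() for pa in truth.planted],
        "tracked_pts": list(tracked),
        "config": truth.model_dump(),
    }


def simulate_store(truth: SyntheticTruth, seed: int) -> tuple[pd.DataFrame, dict]:
    """In-memory labeled store: one row per generated case.

    Columns: ``caseid``, ``group``, ``deleted``, ``excluded``, ``is_case``
    (any myopathy-term event, per the packaged default term set) and one
    boolean ``pt:<name>`` column per tracked preferred term.  This is the
    fast path for statistical calibration studies; :func:`generate` writes
    the same draws out as quarterly files.
    """
    rng = np.random.default_rng(seed)
    core = _simulate_core(truth, rng)
    manifest = _manifest(truth, core, seed)

    terms = SmqTermSet.default()
    tracked = core["tracked"]
    myo_cols = [j for j, pt in enumerate(tracked) if normalize_pt(pt) in terms.preferred_terms]
    frame = pd.DataFrame({
        "caseid": np.arange(10_000_001, 10_000_001 + truth.n_reports),
        "group": core["labels_arr"][core["label_idx"]],
        "deleted": core["deleted"],
        "excluded": core["preexisting"],
        "is_case": core["events"][:, myo_cols].any(axis=1) if myo_cols
        else np.zeros(truth.n_reports, bool),
    })
    for j, pt in enumerate(tracked):
        frame[f"pt:{pt}"] = core["events"][:, j]
    return frame, manifest


def _exposure_ingredients(label: str, aux_row: np.ndarray) -> list[str]:
    statins = list(exposure.STATINS)
    if label == exposure.GROUP_OTHER:
        return [OTHER_DRUGS[aux_row[0] % len(OTHER_DRUGS)]]
    if label == exposure.GROUP_COLCHICINE:
        return ["colchicine"]
    if label == exposure.GROUP_MULTI_STATIN:
        first = aux_row[0] % len(statins)
        second = (first + 1 + aux_row[1] % (len(statins) - 1)) % len(statins)
        return [statins[first], statins[second]]
    if label == exposure.GROUP_COLCHICINE_MULTI:
        first = aux_row[0] % len(statins)
        second = (first + 1 + aux_row[1] % (len(statins) - 1)) % len(statins)
        return ["colchicine", statins[first], statins[second]]
    if label.startswith("colchicine+statin:"):
        return ["colchicine", label.split(":", 1)[1]]
    if label.startswith("statin:"):
        return [label.split(":", 1)[1]]
    raise ValueError(f"unrecognised exposure label {label!r}")


def _verbatim(ingredient: str, pick: int) -> str:
    variants = VERBATIM_VARIANTS.get(ingredient)
    if variants is None:
        return ingredient
    return variants[pick % len(variants)]


def generate(truth: SyntheticTruth, outdir: str | Path, seed: int = 0) -> dict:
    """Write a synthetic quarter to ``outdir`` and return the truth manifest.

    Files: ``DEMO.txt``, ``DRUG.txt``, ``REAC.txt``, ``INDI.txt``,
    ``OUTC.txt``, ``THER.txt`` (``$``-delimited, with headers),
    ``deleted_cases.txt`` (one caseid per line) and ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    core = _simulate_core(truth, rng)
    manifest = _manifest(truth, core, seed)

    tracked = core["tracked"]
    labels = core["labels_arr"][core["label_idx"]]
    base_date = pd.Timestamp("2014-01-01")

    demo_lines = ["primaryid$caseid$caseversion$fda_dt$age$age_cod$sex$occp_cod$occr_country"]
    drug_lines = ["primaryid$caseid$drug_seq$role_cod$drugname$prod_ai"]
    reac_lines = ["primaryid$caseid$pt"]
    indi_lines = ["primaryid$caseid$indi_drug_seq$indi_pt"]
    outc_lines = ["primaryid$caseid$outc_cod"]
    ther_lines = ["primaryid$caseid$dsg_drug_seq$start_dt"]
    deleted_ids: list[str] = []

    for i in range(truth.n_reports):
        caseid = 10_000_001 + i
        label = str(labels[i])
        aux = core["aux"][i]
        receipt = base_date + pd.Timedelta(days=int(core["receipt_offset"][i]))
        if core["deleted"][i]:
            deleted_ids.append(str(caseid))

        versions = [(1, receipt)]
        if core["duplicated"][i]:
            versions.append((2, receipt + pd.Timedelta(days=37)))

        ingredients = _exposure_ingredients(label, aux)
        reactions = [core["base_keys"][core["base_idx"][i]]]
        reactions += [tracked[j].title() for j in range(len(tracked))
                      if core["events"][i, j]]
        indications = []
        for seq, ingredient in enumerate(ingredients, start=1):
            if ingredient == "colchicine":
                indications.append((seq, INDICATION_FOR["colchicine"]))
            elif ingredient in exposure.STATINS:
                indications.append((seq, STATIN_INDICATION))
            else:
                indications.append((seq, OTHER_INDICATION))
        if core["preexisting"][i]:
            indications.append((1, PREEXISTING_INDICATION))
        outcomes = [OUTC_CODES[k] for k in range(len(OUTC_CODES))
                    if core["outcome_flags"][i, k]]
        if core["age_unknown"][i]:
            age_field, age_cod = "", ""
        else:
            age_field, age_cod = str(int(core["age"][i])), "YR"
        sex = str(core["sex"][i])
        occp = str(core["occp"][i])
        country = str(core["country"][i])

        for version, when in versions:
            pid = f"{caseid}{version}"
            fda_dt = when.strftime("%Y%m%d")
            demo_lines.append(
                f"{pid}${caseid}${version}${fda_dt}${age_field}${age_cod}$"
                f"{sex}${occp}${country}")
            seq = 0
            for k, ingredient in enumerate(ingredients):
                seq += 1
                verbatim = _verbatim(ingredient, int(aux[2]) + k)
                drug_lines.append(f"{pid}${caseid}${seq}$PS${verbatim}${ingredient.upper()}")
            if (int(aux[3]) % 1000) / 1000.0 < truth.concomitant_rate:
                seq += 1
                drug_lines.append(f"{pid}${caseid}${seq}$C$ASPIRIN$ASPIRIN")
            for pt in reactions:
                reac_lines.append(f"{pid}${caseid}${pt}")
            for seq_i, indi_pt in indications:
                indi_lines.append(f"{pid}${caseid}${seq_i}${indi_pt}")
            for code in outcomes:
                outc_lines.append(f"{pid}${caseid}${code}")
            ther_lines.append(f"{pid}${caseid}$1${fda_dt}")

    for name, lines in (("DEMO", demo_lines), ("DRUG", drug_lines),
                        ("REAC", reac_lines), ("INDI", indi_lines),
                        ("OUTC", outc_lines), ("THER", ther_lines)):
        (out / f"{name}.txt").write_text("\n".join(lines) + "\n")
    (out / "deleted_cases.txt").write_text(
        "\n".join(deleted_ids) + ("\n" if deleted_ids else ""))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def recover_parameters(
    labeled: pd.DataFrame,
    manifest: dict,
    min_cases: int = 3,
    z: float = 1.96,
    ic_method: str = "noren_credible",
) -> pd.DataFrame:
    """Compare pipeline estimates against the generator's planted truth.

    ``labeled`` is a labeled store (one row per analysed report, with
    ``group`` and per-PT ``pt:<name>`` boolean columns, e.g. from
    :func:`simulate_store` or rebuilt by the pipeline).  Rows flagged
    ``deleted``/``excluded`` are dropped first if those columns are present.
    For every planted pair the result reports the estimated ROR and 2**IC
    against the true rate, whether the ROR interval covers the true rate,
    and signal detection versus truth (rate > 1 with expected count >=
    ``min_cases``).
    """
    from .stats import build_table, evaluate_signal

    frame = labeled
    for flag in ("deleted", "excluded"):
        if flag in frame.columns:
            frame = frame[~frame[flag].astype(bool)]
    rows = []
    for pa in manifest["planted"]:
        group, pt, rate = pa["group"], pa["pt"], float(pa["rate"])
        column = f"pt:{pt}"
        if column not in frame.columns or not (frame["group"] == group).any():
            continue
        table = build_table(frame, group, case_col=column)
        res = evaluate_signal(table, min_cases=min_cases, z=z, ic_method=ic_method)
        expected_a = float(manifest["expected_counts"][group][pt])
        rows.append({
            "group": group,
            "pt": pt,
            "true_rate": rate,
            "a": table.a,
            "expected_a": expected_a,
            "ror": res.ror,
            "ror_low": res.ror_low,
            "ror_high": res.ror_high,
            "ic": res.ic,
            "ic_low": res.ic_low,
            "ic_high": res.ic_high,
            "ror_covers_rate": bool(res.ror_low <= rate <= res.ror_high),
            "detected": bool(res.is_signal),
            "truth_signal": bool(rate > 1.0 and expected_a >= min_cases),
        })
    return pd.DataFrame(rows)
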
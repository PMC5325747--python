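"""Typed parameter records for the trigeminal-neuralgia treatment model.

All probabilities and utilities live here as (mean, sd) estimates on the
proportion / 0-1 utility scale.  Published tables print percentages; the
conversion to proportions happens exactly once, at the I/O boundary
(``load_parameters`` with ``units == "percent"``) or in the transcribed
defaults below, never inside the model code.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Treatment",
    "BniLevel",
    "ProbabilityEstimate",
    "UtilityEstimate",
    "ComplicationEntry",
    "MedicationCategory",
    "MedicationModel",
    "TreatmentParams",
    "ModelConfig",
    "ValidationError",
    "default_parameters",
    "default_medication_model",
    "default_bni_utilities",
    "COMPLICATION_UTILITIES",
    "load_parameters",
    "write_parameters",
    "load_config",
    "write_config",
]


class ValidationError(ValueError):
    """A parameter record violated one of its invariants."""


class Treatment(str, enum.Enum):
    """The two treatment strategies being compared."""

    MVD = "MVD"  # microvascular decompression
    SRS = "SRS"  # stereotactic radiosurgery

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class BniLevel(str, enum.Enum):
    """Barrow Neurological Institute pain intensity score.

    Levels IV and V are merged into a single failure state because the
    evidence base reports them jointly.  Medication requirement follows
    directly from the level: I and II are unmedicated, III and IV-V take
    maintenance medication.
    """

    I = "I"
    II = "II"
    III = "III"
    IV_V = "IV_V"

    @property
    def medicated(self) -> bool:
        return self in (BniLevel.III, BniLevel.IV_V)

    @property
    def description(self) -> str:
        return _BNI_DESCRIPTIONS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_BNI_DESCRIPTIONS = {
    BniLevel.I: "No trigeminal pain, no medication",
    BniLevel.II: "Occasional pain, not requiring medication",
    BniLevel.III: "Some pain, adequately controlled with medication",
    BniLevel.IV_V: "Some pain not adequately controlled, or severe pain / no relief",
}

#: canonical ordering used everywhere (tables, draws, serialization)
BNI_ORDER = (BniLevel.I, BniLevel.II, BniLevel.III, BniLevel.IV_V)


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A pooled probability with its dispersion, on the proportion scale."""

    mean: float
    sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ValidationError(
                f"probability mean {self.mean!r} outside [0, 1] ({self.label or 'unnamed'})"
            )
        if self.sd < 0.0:
            raise ValidationError(f"negative sd {self.sd!r} ({self.label or 'unnamed'})")

    @property
    def beta_feasible(self) -> bool:
        """True when a beta distribution can match (mean, sd) by moments."""
        return self.sd**2 <= self.mean * (1.0 - self.mean) or self.sd == 0.0


@dataclass(frozen=True)
class UtilityEstimate:
    """A health-state preference weight on the 0 (death) .. 1 (perfect) scale."""

    mean: float
    sd: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ValidationError(f"utility mean {self.mean!r} outside [0, 1]")
        if self.sd < 0.0:
            raise ValidationError(f"negative sd {self.sd!r}")

    @property
    def beta_feasible(self) -> bool:
        return self.sd**2 <= self.mean * (1.0 - self.mean) or self.sd == 0.0


@dataclass(frozen=True)
class ComplicationEntry:
    """One periprocedural complication: incidence plus utility multiplier.

    ``compound_with`` names other entries whose utilities multiply into this
    one; it is used for corneal keratitis after radiosurgery, whose sufferers
    are assumed to also carry trigeminal (facial numbness) and facial-nerve
    deficits.
    """

    name: str
    incidence: ProbabilityEstimate
    utility: UtilityEstimate
    compound_with: tuple[str, ...] = ()


@dataclass(frozen=True)
class MedicationCategory:
    name: str
    probability: ProbabilityEstimate
    utility: UtilityEstimate


@dataclass(frozen=True)
class MedicationModel:
    """Three-severity side-effect model for maintenance medication.

    Category probabilities are renormalized to sum to one before use: the
    published values sum to 1.001 and the relative weights are preserved
    rather than truncating any category.
    """

    categories: tuple[MedicationCategory, ...]

    def __post_init__(self) -> None:
        if len(self.categories) == 0:
            raise ValidationError("medication model needs at least one category")

    def renormalized(self) -> "MedicationModel":
        total = sum(c.probability.mean for c in self.categories)
        if total <= 0.0:
            raise ValidationError("medication category probabilities sum to zero")
        if abs(total - 1.0) < 1e-12:
            return self
        cats = tuple(
            dataclasses.replace(
                c,
                probability=dataclasses.replace(c.probability, mean=c.probability.mean / total),
            )
            for c in self.categories
        )
        return MedicationModel(categories=cats)


@dataclass(frozen=True)
class TreatmentParams:
    """Everything defining one treatment arm of the decision model.

    Timing constants are in months after the procedure:

    * ``response_delay_months`` — when the post-treatment pain state is
      observed (0 for MVD, on average 1 for SRS);
    * ``retreat_delay_months`` — when initial therapeutic failures are
      re-treated (1 for MVD, 3 for SRS);
    * ``complication_onset_months`` — when procedure complications begin to
      affect quality of life (0 for MVD, on average 6 for SRS).
    """

    treatment: Treatment
    bni_dist: Mapping[BniLevel, ProbabilityEstimate]
    bni_utilities: Mapping[BniLevel, UtilityEstimate]
    complication_rate: ProbabilityEstimate
    recurrence_rate_7y: ProbabilityEstimate
    retreat_fraction: ProbabilityEstimate
    complications: tuple[ComplicationEntry, ...]
    medication: MedicationModel
    response_delay_months: float
    retreat_delay_months: float
    complication_onset_months: float
    retreat_modality_mix: Mapping[Treatment, float]

    def __post_init__(self) -> None:
        missing = [lvl for lvl in BNI_ORDER if lvl not in self.bni_dist]
        if missing:
            raise ValidationError(f"bni_dist missing levels {missing}")
        missing = [lvl for lvl in BNI_ORDER if lvl not in self.bni_utilities]
        if missing:
            raise ValidationError(f"bni_utilities missing levels {missing}")
        mix_total = sum(self.retreat_modality_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValidationError(f"retreat_modality_mix sums to {mix_total}, expected 1")
        for t in (self.response_delay_months, self.retreat_delay_months, self.complication_onset_months):
            if t < 0:
                raise ValidationError("timing constants must be nonnegative")

    def bni_probabilities(self) -> dict[BniLevel, float]:
        """BNI outcome distribution renormalized to sum exactly to one."""
        total = sum(self.bni_dist[lvl].mean for lvl in BNI_ORDER)
        if total <= 0.0:
            raise ValidationError("BNI distribution sums to zero")
        if abs(total - 1.0) > 1e-12:
            logger.info(
                "renormalizing %s BNI distribution (printed sum %.6f)", self.treatment, total
            )
        return {lvl: self.bni_dist[lvl].mean / total for lvl in BNI_ORDER}


def _positive(value: float, name: str) -> float:
    if value < 0:
        raise ValidationError(f"{name} must be nonnegative, got {value}")
    return value


@dataclass(frozen=True)
class ModelConfig:
    """Structural settings of the decision model.

    ``horizon_years`` is the follow-up horizon over which QALYs accrue (the
    headline analysis uses 7, an alternative uses 1).  All pain recurrences
    occur at ``recurrence_time_years`` after the procedure that relieved the
    pain.  Re-treatment is capped at ``max_additional_procedures`` beyond the
    primary one, each multiplying subsequent utilities by
    ``retreat_utility_multiplier``.
    """

    horizon_years: float = 7.0
    recurrence_time_years: float = 2.5
    max_additional_procedures: int = 2
    retreat_utility_multiplier: float = 0.915
    post_recurrence_untreated_level: BniLevel = BniLevel.III
    post_recurrence_pre_treatment_level: BniLevel = BniLevel.IV_V
    psa_outer: int = 100
    psa_inner: int = 100
    seed: int = 0
    #: when set, the medication sub-model returns this constant instead of the
    #: probability-weighted mean of the side-effect categories
    pinned_medication_utility: float | None = None

    def __post_init__(self) -> None:
        _positive(self.horizon_years, "horizon_years")
        _positive(self.recurrence_time_years, "recurrence_time_years")
        if self.max_additional_procedures < 0:
            raise ValidationError("max_additional_procedures must be >= 0")
        if not (0.0 <= self.retreat_utility_multiplier <= 1.0):
            raise ValidationError("retreat_utility_multiplier must lie in [0, 1]")
        if self.psa_outer < 1 or self.psa_inner < 1:
            raise ValidationError("psa_outer and psa_inner must be >= 1")

    @property
    def recurrence_modelled(self) -> bool:
        return self.recurrence_time_years < self.horizon_years


# ---------------------------------------------------------------------------
# Packaged defaults: transcriptions of the pooled evidence tables.
# Percent cells are divided by 100 here, once.
# ---------------------------------------------------------------------------

#: utility multipliers for individual periprocedural complications, shared by
#: both arms.  "NR" dispersions are carried as sd 0 (point estimates).
COMPLICATION_UTILITIES: dict[str, UtilityEstimate] = {
    "no_complications": UtilityEstimate(1.0, 0.0, "Hunink 2001"),
    "csf_leak": UtilityEstimate(0.985, 0.0, "estimate (dispersion not reported)"),
    "facial_palsy": UtilityEstimate(0.983, 0.018, "Whitmore 2011 (vestibular schwannoma)"),
    "corneal_keratitis": UtilityEstimate(0.963, 0.0, "van de Graaf 2010 (dispersion not reported)"),
    "facial_numbness": UtilityEstimate(0.960, 0.014, "Whitmore 2011 (vestibular schwannoma)"),
    "meningitis": UtilityEstimate(0.930, 0.030, "Whitmore 2011 (vestibular schwannoma)"),
    "unilateral_deafness": UtilityEstimate(0.929, 0.110, "Whitmore 2011 (vestibular schwannoma)"),
    # retained in the catalogue without incidence rows; they participate only
    # if a user supplies incidences for them
    "acute_subdural_hematoma": UtilityEstimate(0.868, 0.017, "Lega 2010 (chronic SDH)"),
    "diplopia": UtilityEstimate(0.762, 0.104, "Hatt 2010"),
    "stroke": UtilityEstimate(0.5, 0.0, "Samsa 1999 (dispersion not reported)"),
    "perioperative_death": UtilityEstimate(0.0, 0.0, "Hunink 2001"),
}


def default_bni_utilities() -> dict[BniLevel, UtilityEstimate]:
    """Pain-state utilities; the BNI I anchor is fixed at 1.0 with no uncertainty."""
    return {
        BniLevel.I: UtilityEstimate(1.0, 0.0, "Hunink 2001 (anchor)"),
        BniLevel.II: UtilityEstimate(0.871, 0.213, "Perez 2009"),
        BniLevel.III: UtilityEstimate(0.739, 0.221, "Perez 2009; Spatz 2007"),
        BniLevel.IV_V: UtilityEstimate(0.399, 0.189, "Perez 2009"),
    }


def default_medication_model() -> MedicationModel:
    """Three-severity medication side-effect model (probabilities print to 1.001)."""
    return MedicationModel(
        categories=(
            MedicationCategory(
                "none",
                ProbabilityEstimate(0.176, 0.092, "no medication complications"),
                UtilityEstimate(0.940, 0.010, "Spatz 2007"),
            ),
            MedicationCategory(
                "mild_moderate",
                ProbabilityEstimate(0.514, 0.144, "mild-moderate medication complications"),
                UtilityEstimate(0.912, 0.037, "Spatz 2007"),
            ),
            MedicationCategory(
                "severe",
                ProbabilityEstimate(0.311, 0.126, "severe medication complications"),
                UtilityEstimate(0.774, 0.148, "Spatz 2007"),
            ),
        )
    )


def _mvd_complications() -> tuple[ComplicationEntry, ...]:
    u = COMPLICATION_UTILITIES
    return (
        ComplicationEntry("facial_numbness", ProbabilityEstimate(0.044, 0.020), u["facial_numbness"]),
        ComplicationEntry("facial_palsy", ProbabilityEstimate(0.011, 0.017), u["facial_palsy"]),
        ComplicationEntry("perioperative_death", ProbabilityEstimate(0.002, 0.001), u["perioperative_death"]),
        ComplicationEntry("deafness", ProbabilityEstimate(0.018, 0.030), u["unilateral_deafness"]),
        ComplicationEntry("csf_leak", ProbabilityEstimate(0.013, 0.021), u["csf_leak"]),
        ComplicationEntry("meningitis_wound_infection", ProbabilityEstimate(0.012, 0.016), u["meningitis"]),
        # the residual category has no published utility; carried at 1.0 so it
        # dilutes rather than deepens the conditional complication utility.
        # Override by replacing this entry if a different residual is wanted.
        ComplicationEntry("other_complications", ProbabilityEstimate(0.033, 0.005), UtilityEstimate(1.0, 0.0, "residual, no utility assigned")),
    )


def _srs_complications() -> tuple[ComplicationEntry, ...]:
    u = COMPLICATION_UTILITIES
    return (
        ComplicationEntry("facial_numbness", ProbabilityEstimate(0.141, 0.053), u["facial_numbness"]),
        ComplicationEntry("facial_palsy", ProbabilityEstimate(0.017, 0.013), u["facial_palsy"]),
        ComplicationEntry(
            "corneal_keratitis",
            ProbabilityEstimate(0.015, 0.009),
            u["corneal_keratitis"],
            compound_with=("facial_numbness", "facial_palsy"),
        ),
        ComplicationEntry("hypertension_other", ProbabilityEstimate(0.020, 0.019), UtilityEstimate(1.0, 0.0, "residual, no utility assigned")),
    )


def default_parameters(treatment: Treatment | str) -> TreatmentParams:
    """Pooled evidence-base defaults for one arm.

    The BNI IV-V dispersion for MVD is transcribed verbatim as 0.67 percent
    (0.0067), anomalously small next to its neighbours but printed as such.
    """
    treatment = Treatment(treatment)
    if treatment is Treatment.MVD:
        return TreatmentParams(
            treatment=Treatment.MVD,
            bni_dist={
                BniLevel.I: ProbabilityEstimate(0.528, 0.213, "BNI I"),
                BniLevel.II: ProbabilityEstimate(0.262, 0.245, "BNI II"),
                BniLevel.III: ProbabilityEstimate(0.133, 0.051, "BNI III"),
                BniLevel.IV_V: ProbabilityEstimate(0.077, 0.0067, "BNI IV-V"),
            },
            bni_utilities=default_bni_utilities(),
            complication_rate=ProbabilityEstimate(0.176, 0.005, "complications"),
            recurrence_rate_7y=ProbabilityEstimate(0.159, 0.105, "7-year recurrence"),
            retreat_fraction=ProbabilityEstimate(0.080, 0.069, "recurrences re-treated"),
            complications=_mvd_complications(),
            medication=default_medication_model(),
            response_delay_months=0.0,
            retreat_delay_months=1.0,
            complication_onset_months=0.0,
            retreat_modality_mix={Treatment.MVD: 0.8, Treatment.SRS: 0.2},
        )
    return TreatmentParams(
        treatment=Treatment.SRS,
        bni_dist={
            BniLevel.I: ProbabilityEstimate(0.388, 0.175, "BNI I"),
            BniLevel.II: ProbabilityEstimate(0.209, 0.108, "BNI II"),
            BniLevel.III: ProbabilityEstimate(0.255, 0.127, "BNI III"),
            BniLevel.IV_V: ProbabilityEstimate(0.148, 0.064, "BNI IV-V"),
        },
        bni_utilities=default_bni_utilities(),
        complication_rate=ProbabilityEstimate(0.193, 0.007, "complications"),
        recurrence_rate_7y=ProbabilityEstimate(0.226, 0.134, "7-year recurrence"),
        retreat_fraction=ProbabilityEstimate(0.455, 0.355, "recurrences re-treated"),
        complications=_srs_complications(),
        medication=default_medication_model(),
        response_delay_months=1.0,
        retreat_delay_months=3.0,
        complication_onset_months=6.0,
        retreat_modality_mix={Treatment.MVD: 1.0, Treatment.SRS: 0.0},
    )


# ---------------------------------------------------------------------------
# I/O: CSV / JSON round-trip, config YAML
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["treatment", "parameter", "level_or_name", "mean", "sd", "units", "source", "compound_with"]


def _est_to_dict(e: ProbabilityEstimate | UtilityEstimate) -> dict:
    d = {"mean": e.mean, "sd": e.sd}
    if isinstance(e, ProbabilityEstimate) and e.label:
        d["label"] = e.label
    if isinstance(e, UtilityEstimate) and e.source:
        d["source"] = e.source
    return d


def params_to_dict(params: TreatmentParams) -> dict:
    """JSON-ready nested dictionary mirror of a :class:`TreatmentParams`."""
    return {
        "treatment": params.treatment.value,
        "bni_dist": {lvl.value: _est_to_dict(params.bni_dist[lvl]) for lvl in BNI_ORDER},
        "bni_utilities": {lvl.value: _est_to_dict(params.bni_utilities[lvl]) for lvl in BNI_ORDER},
        "complication_rate": _est_to_dict(params.complication_rate),
        "recurrence_rate_7y": _est_to_dict(params.recurrence_rate_7y),
        "retreat_fraction": _est_to_dict(params.retreat_fraction),
        "complications": [
            {
                "name": c.name,
                "incidence": _est_to_dict(c.incidence),
                "utility": _est_to_dict(c.utility),
                "compound_with": list(c.compound_with),
            }
            for c in params.complications
        ],
        "medication": {
            "categories": [
                {
                    "name": c.name,
                    "probability": _est_to_dict(c.probability),
                    "utility": _est_to_dict(c.utility),
                }
                for c in params.medication.categories
            ]
        },
        "response_delay_months": params.response_delay_months,
        "retreat_delay_months": params.retreat_delay_months,
        "complication_onset_months": params.complication_onset_months,
        "retreat_modality_mix": {t.value: w for t, w in params.retreat_modality_mix.items()},
    }


def _prob_from_dict(d: Mapping, where: str) -> ProbabilityEstimate:
    try:
        return ProbabilityEstimate(float(d["mean"]), float(d.get("sd", 0.0)), d.get("label", ""))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed probability at {where}: {exc}") from exc


def _util_from_dict(d: Mapping, where: str) -> UtilityEstimate:
    try:
        return UtilityEstimate(float(d["mean"]), float(d.get("sd", 0.0)), d.get("source", ""))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed utility at {where}: {exc}") from exc


def params_from_dict(d: Mapping) -> TreatmentParams:
    try:
        treatment = Treatment(d["treatment"])
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"missing or unknown treatment: {exc}") from exc
    bni_dist = {
        lvl: _prob_from_dict(d["bni_dist"][lvl.value], f"bni_dist.{lvl.value}") for lvl in BNI_ORDER
    }
    bni_utilities = {
        lvl: _util_from_dict(d["bni_utilities"][lvl.value], f"bni_utilities.{lvl.value}")
        for lvl in BNI_ORDER
    }
    complications = tuple(
        ComplicationEntry(
            name=c["name"],
            incidence=_prob_from_dict(c["incidence"], f"complication.{c['name']}"),
            utility=_util_from_dict(c["utility"], f"complication.{c['name']}"),
            compound_with=tuple(c.get("compound_with", ())),
        )
        for c in d.get("complications", ())
    )
    medication = MedicationModel(
        categories=tuple(
            MedicationCategory(
                name=c["name"],
                probability=_prob_from_dict(c["probability"], f"medication.{c['name']}"),
                utility=_util_from_dict(c["utility"], f"medication.{c['name']}"),
            )
            for c in d["medication"]["categories"]
        )
    )
    return TreatmentParams(
        treatment=treatment,
        bni_dist=bni_dist,
        bni_utilities=bni_utilities,
        complication_rate=_prob_from_dict(d["complication_rate"], "complication_rate"),
        recurrence_rate_7y=_prob_from_dict(d["recurrence_rate_7y"], "recurrence_rate_7y"),
        retreat_fraction=_prob_from_dict(d["retreat_fraction"], "retreat_fraction"),
        complications=complications,
        medication=medication,
        response_delay_months=float(d["response_delay_months"]),
        retreat_delay_months=float(d["retreat_delay_months"]),
        complication_onset_months=float(d["complication_onset_months"]),
        retreat_modality_mix={Treatment(k): float(v) for k, v in d["retreat_modality_mix"].items()},
    )


def _csv_rows(params: TreatmentParams) -> Iterable[dict]:
    t = params.treatment.value
    for lvl in BNI_ORDER:
        e = params.bni_dist[lvl]
        yield dict(treatment=t, parameter="bni_prob", level_or_name=lvl.value,
                   mean=repr(e.mean), sd=repr(e.sd), units="proportion", source=e.label, compound_with="")
        u = params.bni_utilities[lvl]
        yield dict(treatment=t, parameter="bni_utility", level_or_name=lvl.value,
                   mean=repr(u.mean), sd=repr(u.sd), units="proportion", source=u.source, compound_with="")
    for pname in ("complication_rate", "recurrence_rate_7y", "retreat_fraction"):
        e = getattr(params, pname)
        yield dict(treatment=t, parameter=pname, level_or_name="",
                   mean=repr(e.mean), sd=repr(e.sd), units="proportion", source=e.label, compound_with="")
    for c in params.complications:
        yield dict(treatment=t, parameter="complication_incidence", level_or_name=c.name,
                   mean=repr(c.incidence.mean), sd=repr(c.incidence.sd), units="proportion",
                   source=c.incidence.label, compound_with="")
        yield dict(treatment=t, parameter="complication_utility", level_or_name=c.name,
                   mean=repr(c.utility.mean), sd=repr(c.utility.sd), units="proportion",
                   source=c.utility.source, compound_with="|".join(c.compound_with))
    for c in params.medication.categories:
        yield dict(treatment=t, parameter="medication_prob", level_or_name=c.name,
                   mean=repr(c.probability.mean), sd=repr(c.probability.sd), units="proportion",
                   source=c.probability.label, compound_with="")
        yield dict(treatment=t, parameter="medication_utility", level_or_name=c.name,
                   mean=repr(c.utility.mean), sd=repr(c.utility.sd), units="proportion",
                   source=c.utility.source, compound_with="")
    for tname, months in (("response_delay_months", params.response_delay_months),
                          ("retreat_delay_months", params.retreat_delay_months),
                          ("complication_onset_months", params.complication_onset_months)):
        yield dict(treatment=t, parameter="timing", level_or_name=tname,
                   mean=repr(months), sd="0.0", units="months", source="", compound_with="")
    for mod, w in params.retreat_modality_mix.items():
        yield dict(treatment=t, parameter="retreat_mix", level_or_name=mod.value,
                   mean=repr(w), sd="0.0", units="proportion", source="", compound_with="")


def write_parameters(params: TreatmentParams, path: str | Path) -> None:
    """Write a treatment-arm parameter set as CSV or JSON (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(params_to_dict(params), indent=2) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for row in _csv_rows(params):
            writer.writerow(row)


def _scaled(value: float, units: str, where: str) -> float:
    if units in ("", "proportion", "months"):
        return value
    if units == "percent":
        return value / 100.0
    raise ValidationError(f"unknown units {units!r} at {where}")


def _params_from_csv(path: Path) -> TreatmentParams:
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            if row.get("parameter") is None or row.get("mean") in (None, ""):
                raise ValidationError(f"{path}:{i}: missing parameter/mean field")
            rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: empty parameter file")

    treatments = {r["treatment"] for r in rows}
    if len(treatments) != 1:
        raise ValidationError(f"{path}: expected a single treatment, found {sorted(treatments)}")

    def pick(parameter: str) -> list[dict]:
        return [r for r in rows if r["parameter"] == parameter]

    def est(row: dict) -> tuple[float, float]:
        where = f"{path} {row['parameter']}/{row.get('level_or_name', '')}"
        try:
            mean = float(row["mean"])
            sd = float(row.get("sd") or 0.0)
        except ValueError as exc:
            raise ValidationError(f"non-numeric value at {where}") from exc
        return _scaled(mean, row.get("units", ""), where), _scaled(sd, row.get("units", ""), where)

    d: dict = {"treatment": treatments.pop()}
    d["bni_dist"] = {}
    d["bni_utilities"] = {}
    for row in pick("bni_prob"):
        m, s = est(row)
        d["bni_dist"][row["level_or_name"]] = {"mean": m, "sd": s, "label": row.get("source", "")}
    for row in pick("bni_utility"):
        m, s = est(row)
        d["bni_utilities"][row["level_or_name"]] = {"mean": m, "sd": s, "source": row.get("source", "")}
    for pname in ("complication_rate", "recurrence_rate_7y", "retreat_fraction"):
        found = pick(pname)
        if len(found) != 1:
            raise ValidationError(f"{path}: expected exactly one {pname} row, found {len(found)}")
        m, s = est(found[0])
        d[pname] = {"mean": m, "sd": s, "label": found[0].get("source", "")}
    comps: dict[str, dict] = {}
    for row in pick("complication_incidence"):
        m, s = est(row)
        comps[row["level_or_name"]] = {
            "name": row["level_or_name"],
            "incidence": {"mean": m, "sd": s, "label": row.get("source", "")},
            "utility": {"mean": 1.0, "sd": 0.0},
            "compound_with": [],
        }
    for row in pick("complication_utility"):
        name = row["level_or_name"]
        if name not in comps:
            raise ValidationError(f"{path}: utility row for unknown complication {name!r}")
        m, s = est(row)
        comps[name]["utility"] = {"mean": m, "sd": s, "source": row.get("source", "")}
        cw = (row.get("compound_with") or "").strip()
        comps[name]["compound_with"] = cw.split("|") if cw else []
    d["complications"] = list(comps.values())
    cats: dict[str, dict] = {}
    for row in pick("medication_prob"):
        m, s = est(row)
        cats[row["level_or_name"]] = {
            "name": row["level_or_name"],
            "probability": {"mean": m, "sd": s, "label": row.get("source", "")},
            "utility": {"mean": 1.0, "sd": 0.0},
        }
    for row in pick("medication_utility"):
        name = row["level_or_name"]
        if name not in cats:
            raise ValidationError(f"{path}: utility row for unknown medication category {name!r}")
        m, s = est(row)
        cats[name]["utility"] = {"mean": m, "sd": s, "source": row.get("source", "")}
    d["medication"] = {"categories": list(cats.values())}
    for row in pick("timing"):
        d[row["level_or_name"]] = float(row["mean"])
    d["retreat_modality_mix"] = {}
    for row in pick("retreat_mix"):
        d["retreat_modality_mix"][row["level_or_name"]] = float(row["mean"])
    return params_from_dict(d)


def validate_parameters(params: TreatmentParams, require_beta_feasible: bool = True) -> TreatmentParams:
    """Run cross-field checks, warn about renormalizations, return the record."""
    total = sum(params.bni_dist[lvl].mean for lvl in BNI_ORDER)
    if abs(total - 1.0) > 1e-9:
        warnings.warn(
            f"{params.treatment.value} BNI distribution sums to {total:.6g}; "
            "it will be renormalized before use",
            stacklevel=2,
        )
    med_total = sum(c.probability.mean for c in params.medication.categories)
    if abs(med_total - 1.0) > 1e-9:
        warnings.warn(
            f"medication category probabilities sum to {med_total:.6g}; renormalized before use",
            stacklevel=2,
        )
    inc_total = sum(c.incidence.mean for c in params.complications)
    if inc_total > 1.0 + 1e-9:
        raise ValidationError(f"complication incidences sum to {inc_total:.6g} > 1")
    if require_beta_feasible:
        for name, e in _iter_estimates(params):
            if e.sd > 0 and not e.beta_feasible:
                raise ValidationError(
                    f"{name}: sd^2 = {e.sd**2:.6g} exceeds mean*(1-mean) = "
                    f"{e.mean * (1 - e.mean):.6g}; no beta distribution matches these moments"
                )
    return params


def _iter_estimates(params: TreatmentParams):
    """Yield (dotted name, estimate) pairs over every uncertain quantity."""
    for lvl in BNI_ORDER:
        yield f"bni_dist.{lvl.value}", params.bni_dist[lvl]
        yield f"bni_utilities.{lvl.value}", params.bni_utilities[lvl]
    yield "complication_rate", params.complication_rate
    yield "recurrence_rate_7y", params.recurrence_rate_7y
    yield "retreat_fraction", params.retreat_fraction
    for c in params.complications:
        yield f"complication.{c.name}.incidence", c.incidence
        yield f"complication.{c.name}.utility", c.utility
    for c in params.medication.categories:
        yield f"medication.{c.name}.probability", c.probability
        yield f"medication.{c.name}.utility", c.utility


def load_parameters(path: str | Path, schema: str = "treatment_params"):
    """Load a validated record from CSV/JSON (parameters) or YAML (config).

    ``schema`` selects the record type: ``treatment_params``, ``medication``
    or ``config``.  Percent-valued rows (``units == "percent"``) are divided
    by 100 here, the only place that conversion happens.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema == "config":
        return load_config(path)
    if schema == "medication":
        data = json.loads(path.read_text())
        model = MedicationModel(
            categories=tuple(
                MedicationCategory(
                    name=c["name"],
                    probability=_prob_from_dict(c["probability"], f"medication.{c['name']}"),
                    utility=_util_from_dict(c["utility"], f"medication.{c['name']}"),
                )
                for c in data["categories"]
            )
        )
        return model
    if schema != "treatment_params":
        raise ValueError(f"unknown schema {schema!r}")
    if path.suffix.lower() == ".json":
        params = params_from_dict(json.loads(path.read_text()))
    else:
        params = _params_from_csv(path)
    return validate_parameters(params)


def config_to_dict(config: ModelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["post_recurrence_untreated_level"] = config.post_recurrence_untreated_level.value
    d["post_recurrence_pre_treatment_level"] = config.post_recurrence_pre_treatment_level.value
    return d


def write_config(config: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config fields: {sorted(unknown)}")
    for key in ("post_recurrence_untreated_level", "post_recurrence_pre_treatment_level"):
        if key in data:
            data[key] = BniLevel(data[key])
    return ModelConfig(**data)
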
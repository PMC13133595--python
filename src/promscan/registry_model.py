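"""Registry study records: parsing, eligibility filtering, outcome explosion.

Studies arrive as JSON objects in the public registry API dialect
(``protocolSection`` / modules layout).  Each study is parsed into a
:class:`StudyRecord` whose categorical design fields are normalised onto a
fixed vocabulary, with anything unrecognised mapped to an explicit
``missing`` level rather than dropped.  Eligibility filtering removes
studies outside the date window, studies with no outcomes, and studies
whose outcomes all lack descriptions; within retained studies,
description-less outcomes are pruned.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence


class ParseError(ValueError):
    """Raised when a raw registry record cannot be mapped to a StudyRecord."""


class StudyType(str, enum.Enum):
    INTERVENTIONAL = "interventional"
    OBSERVATIONAL = "observational"


class Phase(str, enum.Enum):
    EARLY_PHASE1 = "early_phase1"
    PHASE1 = "phase1"
    PHASE1_2 = "phase1_2"
    PHASE2 = "phase2"
    PHASE2_3 = "phase2_3"
    PHASE3 = "phase3"
    PHASE4 = "phase4"
    MISSING = "missing"


class Allocation(str, enum.Enum):
    RANDOMIZED = "randomized"
    NONRANDOMIZED = "nonrandomized"
    MISSING = "missing"


class InterventionModel(str, enum.Enum):
    PARALLEL = "parallel"
    SINGLE_GROUP = "single_group"
    CROSSOVER = "crossover"
    FACTORIAL = "factorial"
    SEQUENTIAL = "sequential"
    MISSING = "missing"


class PrimaryPurpose(str, enum.Enum):
    TREATMENT = "treatment"
    SUPPORTIVE_CARE = "supportive_care"
    DIAGNOSTIC = "diagnostic"
    PREVENTION = "prevention"
    OTHER = "other"
    MISSING = "missing"


class ObservationalModel(str, enum.Enum):
    COHORT = "cohort"
    CASE_CONTROL = "case_control"
    CASE_ONLY = "case_only"
    OTHER = "other"
    MISSING = "missing"


class TimePerspective(str, enum.Enum):
    PROSPECTIVE = "prospective"
    RETROSPECTIVE = "retrospective"
    CROSS_SECTIONAL = "cross_sectional"
    OTHER = "other"
    MISSING = "missing"


class OutcomeRank(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    OTHER = "other"


@dataclass(frozen=True)
class OutcomeDescription:
    """One outcome-measure text unit of a study."""

    study_id: str
    outcome_index: int
    title: str
    description: str
    rank: OutcomeRank

    @property
    def key(self) -> tuple[str, int]:
        return (self.study_id, self.outcome_index)

    @property
    def full_text(self) -> str:
        """Title and description joined for matching/classification."""
        parts = [p.strip() for p in (self.title, self.description) if p and p.strip()]
        return ". ".join(parts)


@dataclass
class StudyRecord:
    study_id: str
    start_date: dt.date | None
    study_type: StudyType
    phase: Phase = Phase.MISSING
    allocation: Allocation = Allocation.MISSING
    intervention_model: InterventionModel = InterventionModel.MISSING
    primary_purpose: PrimaryPurpose = PrimaryPurpose.MISSING
    observational_model: ObservationalModel = ObservationalModel.MISSING
    time_perspective: TimePerspective = TimePerspective.MISSING
    conditions: list[str] = field(default_factory=list)
    outcomes: list[OutcomeDescription] = field(default_factory=list)


# ---------------------------------------------------------------------------
# registry-dialect field maps

_PHASE_MAP = {
    ("EARLY_PHASE1",): Phase.EARLY_PHASE1,
    ("PHASE1",): Phase.PHASE1,
    ("PHASE1", "PHASE2"): Phase.PHASE1_2,
    ("PHASE2",): Phase.PHASE2,
    ("PHASE2", "PHASE3"): Phase.PHASE2_3,
    ("PHASE3",): Phase.PHASE3,
    ("PHASE4",): Phase.PHASE4,
}

_ALLOCATION_MAP = {
    "RANDOMIZED": Allocation.RANDOMIZED,
    "NON_RANDOMIZED": Allocation.NONRANDOMIZED,
}

_MODEL_MAP = {
    "PARALLEL": InterventionModel.PARALLEL,
    "SINGLE_GROUP": InterventionModel.SINGLE_GROUP,
    "CROSSOVER": InterventionModel.CROSSOVER,
    "FACTORIAL": InterventionModel.FACTORIAL,
    "SEQUENTIAL": InterventionModel.SEQUENTIAL,
}

_PURPOSE_MAP = {
    "TREATMENT": PrimaryPurpose.TREATMENT,
    "SUPPORTIVE_CARE": PrimaryPurpose.SUPPORTIVE_CARE,
    "DIAGNOSTIC": PrimaryPurpose.DIAGNOSTIC,
    "PREVENTION": PrimaryPurpose.PREVENTION,
    "OTHER": PrimaryPurpose.OTHER,
}

_OBS_MODEL_MAP = {
    "COHORT": ObservationalModel.COHORT,
    "CASE_CONTROL": ObservationalModel.CASE_CONTROL,
    "CASE_ONLY": ObservationalModel.CASE_ONLY,
    "OTHER": ObservationalModel.OTHER,
}

_PERSPECTIVE_MAP = {
    "PROSPECTIVE": TimePerspective.PROSPECTIVE,
    "RETROSPECTIVE": TimePerspective.RETROSPECTIVE,
    "CROSS_SECTIONAL": TimePerspective.CROSS_SECTIONAL,
    "OTHER": TimePerspective.OTHER,
}


def _parse_date(value: str | None) -> dt.date | None:
    if not value:
        return None
    parts = value.split("-")
    try:
        year = int(parts[0])
        month = int(parts[1]) if len(parts) > 1 else 1
        day = int(parts[2]) if len(parts) > 2 else 1
        return dt.date(year, month, day)
    except (ValueError, IndexError):
        return None


def parse_study_record(raw_record: dict) -> StudyRecord:
    """Map a raw registry-dialect study object onto a :class:`StudyRecord`.

    Unrecognised or absent categorical values become the explicit
    ``missing`` level; conditions and outcomes keep their input order.
    Raises :class:`ParseError` when the record carries no study identifier.
    """
    proto = raw_record.get("protocolSection", raw_record)
    ident = proto.get("identificationModule", {})
    study_id = ident.get("nctId") or ident.get("studyId")
    if not study_id:
        raise ParseError("missing required field: identificationModule.nctId")

    status = proto.get("statusModule", {})
    start = _parse_date((status.get("startDateStruct") or {}).get("date"))

    design = proto.get("designModule", {})
    raw_type = str(design.get("studyType", "")).upper()
    study_type = (
        StudyType.OBSERVATIONAL if raw_type == "OBSERVATIONAL" else StudyType.INTERVENTIONAL
    )

    info = design.get("designInfo", {}) or {}
    phases = tuple(sorted(str(p).upper() for p in design.get("phases", []) if str(p).upper() != "NA"))
    phase = _PHASE_MAP.get(phases, Phase.MISSING)
    allocation = _ALLOCATION_MAP.get(str(info.get("allocation", "")).upper(), Allocation.MISSING)
    model = _MODEL_MAP.get(str(info.get("interventionModel", "")).upper(), InterventionModel.MISSING)
    purpose = _PURPOSE_MAP.get(str(info.get("primaryPurpose", "")).upper(), PrimaryPurpose.MISSING)
    obs_model = _OBS_MODEL_MAP.get(
        str(info.get("observationalModel", "")).upper(), ObservationalModel.MISSING
    )
    perspective = _PERSPECTIVE_MAP.get(
        str(info.get("timePerspective", "")).upper(), TimePerspective.MISSING
    )

    # interventional-only fields are structurally missing for observational
    # studies and vice versa
    if study_type is StudyType.OBSERVATIONAL:
        phase, allocation = Phase.MISSING, Allocation.MISSING
        model, purpose = InterventionModel.MISSING, PrimaryPurpose.MISSING
    else:
        obs_model, perspective = ObservationalModel.MISSING, TimePerspective.MISSING

    conditions = list((proto.get("conditionsModule") or {}).get("conditions", []))

    outcomes: list[OutcomeDescription] = []
    outcomes_mod = proto.get("outcomesModule", {}) or {}
    index = 0
    for list_name, rank in (
        ("primaryOutcomes", OutcomeRank.PRIMARY),
        ("secondaryOutcomes", OutcomeRank.SECONDARY),
        ("otherOutcomes", OutcomeRank.OTHER),
    ):
        for raw in outcomes_mod.get(list_name, []) or []:
            index += 1
            outcomes.append(
                OutcomeDescription(
                    study_id=study_id,
                    outcome_index=index,
                    title=str(raw.get("measure", "") or ""),
                    description=str(raw.get("description", "") or ""),
                    rank=rank,
                )
            )

    return StudyRecord(
        study_id=study_id,
        start_date=start,
        study_type=study_type,
        phase=phase,
        allocation=allocation,
        intervention_model=model,
        primary_purpose=purpose,
        observational_model=obs_model,
        time_perspective=perspective,
        conditions=conditions,
        outcomes=outcomes,
    )


def to_registry_json(study: StudyRecord) -> dict:
    """Serialize a StudyRecord back to the registry API dialect."""
    phases_inv = {v: list(k) for k, v in _PHASE_MAP.items()}
    info: dict = {}
    if study.study_type is StudyType.INTERVENTIONAL:
        inv = {v: k for k, v in _ALLOCATION_MAP.items()}
        if study.allocation is not Allocation.MISSING:
            info["allocation"] = inv[study.allocation]
        inv = {v: k for k, v in _MODEL_MAP.items()}
        if study.intervention_model is not InterventionModel.MISSING:
            info["interventionModel"] = inv[study.intervention_model]
        inv = {v: k for k, v in _PURPOSE_MAP.items()}
        if study.primary_purpose is not PrimaryPurpose.MISSING:
            info["primaryPurpose"] = inv[study.primary_purpose]
    else:
        inv = {v: k for k, v in _OBS_MODEL_MAP.items()}
        if study.observational_model is not ObservationalModel.MISSING:
            info["observationalModel"] = inv[study.observational_model]
        inv = {v: k for k, v in _PERSPECTIVE_MAP.items()}
        if study.time_perspective is not TimePerspective.MISSING:
            info["timePerspective"] = inv[study.time_perspective]

    design: dict = {"studyType": study.study_type.name}
    if study.study_type is StudyType.INTERVENTIONAL and study.phase is not Phase.MISSING:
        design["phases"] = phases_inv[study.phase]
    if info:
        design["designInfo"] = info

    outcomes_mod: dict = {"primaryOutcomes": [], "secondaryOutcomes": [], "otherOutcomes": []}
    names = {
        OutcomeRank.PRIMARY: "primaryOutcomes",
        OutcomeRank.SECONDARY: "secondaryOutcomes",
        OutcomeRank.OTHER: "otherOutcomes",
    }
    for out in study.outcomes:
        outcomes_mod[names[out.rank]].append(
            {"measure": out.title, "description": out.description}
        )
    outcomes_mod = {k: v for k, v in outcomes_mod.items() if v}

    record = {
        "protocolSection": {
            "identificationModule": {"nctId": study.study_id},
            "statusModule": {
                "startDateStruct": {
                    "date": study.start_date.isoformat() if study.start_date else None
                }
            },
            "designModule": design,
            "conditionsModule": {"conditions": list(study.conditions)},
            "outcomesModule": outcomes_mod,
        }
    }
    return record


# ---------------------------------------------------------------------------
# eligibility filtering

#: study-level exclusion reasons entering the conservation identity
STUDY_EXCLUSION_REASONS = (
    "missing_start_date",
    "out_of_window",
    "no_outcomes",
    "no_outcome_description",
)


def filter_eligible(
    studies: Sequence[StudyRecord],
    window_start: dt.date,
    window_end: dt.date,
) -> tuple[list[StudyRecord], dict[str, int]]:
    """Apply eligibility filters over a half-open date window [start, end).

    Returns retained studies (with description-less outcomes pruned) and an
    exclusion log with one count per study-level reason plus a
    ``dropped_outcomes`` count for outcomes pruned within retained studies.
    Conservation: ``len(studies) == len(eligible) + sum over
    STUDY_EXCLUSION_REASONS``.
    """
    log = {reason: 0 for reason in STUDY_EXCLUSION_REASONS}
    log["dropped_outcomes"] = 0
    eligible: list[StudyRecord] = []
    for study in studies:
        if study.start_date is None:
            log["missing_start_date"] += 1
            continue
        if not (window_start <= study.start_date < window_end):
            log["out_of_window"] += 1
            continue
        if not study.outcomes:
            log["no_outcomes"] += 1
            continue
        described = [o for o in study.outcomes if o.description.strip()]
        if not described:
            log["no_outcome_description"] += 1
            continue
        log["dropped_outcomes"] += len(study.outcomes) - len(described)
        eligible.append(replace(study, outcomes=described))
    return eligible, log


def oncology_condition_predicate(conditions: Iterable[str]) -> bool:
    """Heuristic oncology-domain check on free-text condition strings.

    The registry query used to scope the original corpus is not public;
    callers that need domain filtering can use this keyword predicate or
    supply their own.
    """
    keywords = (
        "cancer", "carcinoma", "tumor", "tumour", "neoplasm", "oncolog",
        "leukemia", "leukaemia", "lymphoma", "melanoma", "sarcoma", "myeloma",
        "glioma", "glioblastoma", "adenocarcinoma",
    )
    for cond in conditions:
        low = cond.lower()
        if any(k in low for k in keywords):
            return True
    return False


# ---------------------------------------------------------------------------
# IO

def read_records(path: str | Path) -> list[StudyRecord]:
    """Read study records from a JSON array file or a JSON-lines file."""
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("["):
        raw_records = json.loads(text)
    else:
        raw_records = [json.loads(line) for line in text.splitlines() if line.strip()]
    return [parse_study_record(r) for r in raw_records]


def write_records(studies: Iterable[StudyRecord], path: str | Path) -> None:
    """Write studies as registry-dialect JSON lines."""
    with open(path, "w") as fh:
        for study in studies:
            fh.write(json.dumps(to_registry_json(study)) + "\n")


def write_outcomes_tsv(studies: Iterable[StudyRecord], path: str | Path) -> int:
    """Flatten studies to a TSV of outcomes; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("study_id\toutcome_index\trank\ttext\n")
        for study in studies:
            for out in study.outcomes:
                text = out.full_text.replace("\t", " ").replace("\n", " ")
                fh.write(f"{study.study_id}\t{out.outcome_index}\t{out.rank.value}\t{text}\n")
                n += 1
    return n


def read_outcomes_tsv(path: str | Path) -> list[OutcomeDescription]:
    """Read a flat outcomes TSV back into OutcomeDescription units.

    The flattened text is stored as the title with an empty description.
    """
    outcomes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            outcomes.append(
                OutcomeDescription(
                    study_id=fields[idx["study_id"]],
                    outcome_index=int(fields[idx["outcome_index"]]),
                    title=fields[idx["text"]],
                    description="",
                    rank=OutcomeRank(fields[idx["rank"]]),
                )
            )
    return outcomes
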
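"""Seeded synthetic registry corpora with exact ground truth.

Generates study records in the registry dialect whose outcome texts are
composed from templated clinical phrases.  Positive outcomes embed an
instrument surface form (canonical name, acronym, or a configured
corruption); negative outcomes optionally embed trap phrases (uppercase
symptom tokens, ad-hoc instrument phrasing, clinician-reported wording)
that must not count as named instruments under the labeling rule.  Study
flags follow a logistic model over design covariates plus a yearly trend,
so analytic modules can be validated by parameter recovery.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lexicon_matcher import InstrumentLexicon, load_default_lexicon
from .registry_model import (
    Allocation,
    InterventionModel,
    ObservationalModel,
    OutcomeDescription,
    OutcomeRank,
    Phase,
    PrimaryPurpose,
    StudyRecord,
    StudyType,
    TimePerspective,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRates:
    """Probabilities of corrupting a planted instrument surface form."""

    acronym_only: float = 0.0
    hyphen_drop: float = 0.0
    fragment_multiword: float = 0.0
    typo: float = 0.0


@dataclass(frozen=True)
class TrapRates:
    """Per-negative-outcome probabilities of embedding a trap phrase."""

    uppercase_symptom: float = 0.0
    adhoc_phrase: float = 0.0
    clinician_phrase: float = 0.0


@dataclass
class SyntheticConfig:
    n_studies: int = 100
    outcomes_per_study_mean: float = 3.0  # truncated Poisson, min 1
    prevalence: float = 0.33
    instrument_mix: dict[str, float] | None = None  # None -> uniform over lexicon
    variant_rates: VariantRates = field(default_factory=VariantRates)
    negative_traps: TrapRates = field(default_factory=TrapRates)
    covariate_effects: dict[str, float] = field(default_factory=dict)  # "field=level" -> log-OR
    year_range: tuple[int, int] = (2012, 2021)
    trend_slope: float = 0.0  # log-OR per year, centred on the window midpoint
    seed: int = 0

    def validate(self, lexicon: InstrumentLexicon) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("prevalence must lie in [0, 1]")
        if self.n_studies < 0:
            raise ConfigError("n_studies must be >= 0")
        if self.instrument_mix is not None:
            known = {e.instrument_id for e in lexicon}
            unknown = set(self.instrument_mix) - known
            if unknown:
                raise ConfigError(f"instrument_mix references unknown instruments: {sorted(unknown)}")
            weights = list(self.instrument_mix.values())
            if any(w < 0 for w in weights) or sum(weights) <= 0:
                raise ConfigError("instrument_mix weights must be non-negative, not all zero")


@dataclass(frozen=True)
class OutcomeTruth:
    contains_named_instrument: bool
    instrument_id: str | None = None
    span: tuple[int, int] | None = None  # into OutcomeDescription.full_text
    surface: str | None = None
    variant: str = "none"  # exact | hyphen_drop | typo | fragment | none
    trap: str | None = None


@dataclass(frozen=True)
class StudyTruth:
    uses_prompem: bool
    year: int
    site_label: str
    covariates: dict


@dataclass
class GroundTruth:
    outcomes: dict[tuple[str, int], OutcomeTruth]
    studies: dict[str, StudyTruth]


# ---------------------------------------------------------------------------
# vocabularies and templates

SITE_VOCAB: dict[str, list[str]] = {
    "breast": ["breast cancer", "metastatic breast carcinoma", "triple negative breast neoplasm"],
    "lung": ["lung cancer", "non small cell lung carcinoma", "lung adenocarcinoma"],
    "prostate": ["prostate cancer", "castration resistant prostate carcinoma", "prostate adenocarcinoma"],
    "digestive": ["colorectal cancer", "gastric carcinoma", "pancreatic adenocarcinoma"],
    "hematopoietic": ["acute myeloid leukemia", "diffuse large b-cell lymphoma", "multiple myeloma"],
    "head_neck": ["head and neck squamous cell carcinoma", "oropharyngeal cancer", "laryngeal carcinoma"],
    "brain": ["glioblastoma", "brain glioma", "anaplastic astrocytoma"],
    "skin": ["cutaneous melanoma", "skin basal cell carcinoma", "merkel cell carcinoma"],
    "thyroid": ["papillary thyroid carcinoma", "medullary thyroid cancer", "anaplastic thyroid carcinoma"],
    "urogenital": ["bladder urothelial carcinoma", "renal cell carcinoma", "ovarian cancer"],
}

_POS_TITLES = (
    "Patient-completed symptom assessment",
    "Self-administered health status rating",
    "Change in self-rated functional status",
    "Patient-rated symptom burden",
)
_POS_DESC_PREFIXES = (
    "Change from baseline in ",
    "Mean score on the ",
    "Proportion of participants with improvement on the ",
    "Longitudinal evolution of ",
)
_POS_DESC_SUFFIXES = (
    " at week 12.",
    " total score over 24 weeks.",
    " measured every cycle.",
    " assessed at end of treatment.",
)

_NEG_TITLES = (
    "Overall survival",
    "Progression-free survival",
    "Objective response rate",
    "Incidence of adverse events",
    "Maximum tolerated dose",
    "Duration of response",
)
_NEG_DESCRIPTIONS = (
    "Time from randomization to death from any cause, assessed up to 60 months.",
    "Time from enrollment to first documented disease progression on imaging.",
    "Proportion of participants achieving complete or partial response per RECIST 1.1.",
    "Number of participants with grade 3 or higher treatment-emergent adverse events.",
    "Highest dose level at which fewer than one third of participants report dose-limiting toxicity.",
    "Pharmacokinetic profile including area under the plasma concentration curve.",
    "Change in tumor size measured by computed tomography.",
    "Number of participants with dose reductions or interruptions.",
)

#: trap phrases: none of these contains a lexicon surface form or one of the
#: 11 generic terms, so the rule-based detector must return zero hits
TRAP_PHRASES = {
    "uppercase_symptom": "Daily PAIN intensity recorded in the diary.",
    "adhoc_phrase": "Responses to an ad hoc survey developed for this study.",
    "clinician_phrase": "Clinician-assessed performance status at each visit.",
}

_INTERVENTIONAL_PRIORS = {
    "phase": (
        [Phase.MISSING, Phase.PHASE2, Phase.PHASE1, Phase.PHASE1_2, Phase.PHASE3,
         Phase.PHASE4, Phase.EARLY_PHASE1, Phase.PHASE2_3],
        [0.38, 0.26, 0.13, 0.08, 0.08, 0.03, 0.03, 0.01],
    ),
    "allocation": (
        [Allocation.RANDOMIZED, Allocation.NONRANDOMIZED, Allocation.MISSING],
        [0.45, 0.13, 0.42],
    ),
    "intervention_model": (
        [InterventionModel.PARALLEL, InterventionModel.SINGLE_GROUP,
         InterventionModel.SEQUENTIAL, InterventionModel.CROSSOVER,
         InterventionModel.FACTORIAL, InterventionModel.MISSING],
        [0.48, 0.44, 0.04, 0.02, 0.01, 0.01],
    ),
    "primary_purpose": (
        [PrimaryPurpose.TREATMENT, PrimaryPurpose.SUPPORTIVE_CARE,
         PrimaryPurpose.DIAGNOSTIC, PrimaryPurpose.PREVENTION,
         PrimaryPurpose.OTHER, PrimaryPurpose.MISSING],
        [0.66, 0.11, 0.08, 0.05, 0.09, 0.01],
    ),
}
_OBSERVATIONAL_PRIORS = {
    "observational_model": (
        [ObservationalModel.COHORT, ObservationalModel.CASE_ONLY,
         ObservationalModel.CASE_CONTROL, ObservationalModel.OTHER,
         ObservationalModel.MISSING],
        [0.64, 0.14, 0.10, 0.10, 0.02],
    ),
    "time_perspective": (
        [TimePerspective.PROSPECTIVE, TimePerspective.RETROSPECTIVE,
         TimePerspective.CROSS_SECTIONAL, TimePerspective.OTHER,
         TimePerspective.MISSING],
        [0.72, 0.16, 0.07, 0.04, 0.01],
    ),
}


def _draw(rng: np.random.Generator, levels, probs):
    return levels[int(rng.choice(len(levels), p=np.asarray(probs) / np.sum(probs)))]


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    return max(1, int(rng.poisson(mean)))


def _apply_typo(rng: np.random.Generator, surface: str) -> str:
    alpha = [i for i, c in enumerate(surface[:-1]) if c.isalpha() and surface[i + 1].isalpha()]
    if not alpha:
        return surface
    i = int(rng.choice(alpha))
    chars = list(surface)
    chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def _plant_surface(
    rng: np.random.Generator,
    entry,
    rates: VariantRates,
) -> tuple[str, str]:
    """Choose a surface form for the instrument and apply configured variants."""
    use_acronym = bool(entry.acronyms) and (
        rng.random() < rates.acronym_only or rng.random() < 0.4
    )
    surface = entry.acronyms[0] if use_acronym else entry.canonical_name
    variant = "exact"
    if rates.fragment_multiword and " " in surface and rng.random() < rates.fragment_multiword:
        words = surface.split()
        mid = len(words) // 2
        surface = " ".join(words[:mid]) + ", " + " ".join(words[mid:])
        variant = "fragment"
    elif rates.hyphen_drop and "-" in surface and rng.random() < rates.hyphen_drop:
        surface = surface.replace("-", " ")
        variant = "hyphen_drop"
    elif rates.typo and rng.random() < rates.typo:
        corrupted = _apply_typo(rng, surface)
        if corrupted != surface:
            surface, variant = corrupted, "typo"
    return surface, variant


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_corpus(
    config: SyntheticConfig,
    lexicon: InstrumentLexicon | None = None,
) -> tuple[list[StudyRecord], GroundTruth]:
    """Generate a seeded corpus of study records with exact ground truth."""
    lexicon = lexicon if lexicon is not None else load_default_lexicon()
    config.validate(lexicon)
    rng = np.random.default_rng(config.seed)

    if config.instrument_mix is None:
        instrument_ids = [e.instrument_id for e in lexicon]
        weights = np.ones(len(instrument_ids))
    else:
        instrument_ids = sorted(config.instrument_mix)
        weights = np.array([config.instrument_mix[i] for i in instrument_ids], dtype=float)
    weights = weights / weights.sum() if len(weights) else weights
    entry_by_id = {e.instrument_id: e for e in lexicon}

    y0, y1 = config.year_range
    mid_year = (y0 + y1) / 2.0
    base_logit = (
        math.log(config.prevalence / (1 - config.prevalence))
        if 0 < config.prevalence < 1
        else (math.inf if config.prevalence == 1 else -math.inf)
    )
    site_labels = sorted(SITE_VOCAB)
    trap_kinds = ("uppercase_symptom", "adhoc_phrase", "clinician_phrase")
    trap_probs = (
        config.negative_traps.uppercase_symptom,
        config.negative_traps.adhoc_phrase,
        config.negative_traps.clinician_phrase,
    )

    studies: list[StudyRecord] = []
    gt = GroundTruth(outcomes={}, studies={})
    for i in range(config.n_studies):
        study_id = f"NCT{90000000 + i:08d}"
        year = int(rng.integers(y0, y1 + 1))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 28))
        interventional = rng.random() < 0.79
        covariates: dict[str, str] = {
            "study_type": "interventional" if interventional else "observational"
        }
        fields: dict = {}
        priors = _INTERVENTIONAL_PRIORS if interventional else _OBSERVATIONAL_PRIORS
        for name, (levels, probs) in priors.items():
            fields[name] = _draw(rng, levels, probs)
            covariates[name] = fields[name].value
        site = site_labels[int(rng.integers(len(site_labels)))]
        covariates["site_label"] = site

        logit = base_logit + config.trend_slope * (year - mid_year)
        for key, effect in config.covariate_effects.items():
            fname, _, lvl = key.partition("=")
            if covariates.get(fname) == lvl:
                logit += effect
        uses = bool(rng.random() < _sigmoid(logit)) if math.isfinite(logit) else logit > 0

        n_outcomes = _truncated_poisson(rng, config.outcomes_per_study_mean)
        n_pos = 0
        if uses:
            n_pos = 1 + int(rng.binomial(n_outcomes - 1, 0.3)) if n_outcomes > 1 else 1
        pos_slots = set(rng.choice(n_outcomes, size=n_pos, replace=False)) if n_pos else set()

        outcomes: list[OutcomeDescription] = []
        for j in range(n_outcomes):
            idx = j + 1
            rank = OutcomeRank.PRIMARY if j == 0 else OutcomeRank.SECONDARY
            if j in pos_slots:
                iid = instrument_ids[int(rng.choice(len(instrument_ids), p=weights))]
                surface, variant = _plant_surface(rng, entry_by_id[iid], config.variant_rates)
                title = _POS_TITLES[int(rng.integers(len(_POS_TITLES)))]
                prefix = _POS_DESC_PREFIXES[int(rng.integers(len(_POS_DESC_PREFIXES)))]
                suffix = _POS_DESC_SUFFIXES[int(rng.integers(len(_POS_DESC_SUFFIXES)))]
                description = prefix + surface + suffix
                offset = len(title) + 2 + len(prefix)  # ". " joiner in full_text
                truth = OutcomeTruth(
                    contains_named_instrument=True,
                    instrument_id=iid,
                    span=(offset, offset + len(surface)),
                    surface=surface,
                    variant=variant,
                )
            else:
                k = int(rng.integers(len(_NEG_TITLES)))
                title = _NEG_TITLES[k]
                description = _NEG_DESCRIPTIONS[int(rng.integers(len(_NEG_DESCRIPTIONS)))]
                trap = None
                for kind, prob in zip(trap_kinds, trap_probs):
                    if prob and rng.random() < prob:
                        trap = kind
                        description = description + " " + TRAP_PHRASES[kind]
                        break
                truth = OutcomeTruth(contains_named_instrument=False, trap=trap)
            outcomes.append(
                OutcomeDescription(
                    study_id=study_id,
                    outcome_index=idx,
                    title=title,
                    description=description,
                    rank=rank,
                )
            )
            gt.outcomes[(study_id, idx)] = truth

        n_conditions = int(rng.integers(1, 3))
        vocab = SITE_VOCAB[site]
        conditions = [
            vocab[int(rng.integers(len(vocab)))] for _ in range(n_conditions)
        ]
        studies.append(
            StudyRecord(
                study_id=study_id,
                start_date=dt.date(year, month, day),
                study_type=StudyType.INTERVENTIONAL if interventional else StudyType.OBSERVATIONAL,
                phase=fields.get("phase", Phase.MISSING),
                allocation=fields.get("allocation", Allocation.MISSING),
                intervention_model=fields.get("intervention_model", InterventionModel.MISSING),
                primary_purpose=fields.get("primary_purpose", PrimaryPurpose.MISSING),
                observational_model=fields.get("observational_model", ObservationalModel.MISSING),
                time_perspective=fields.get("time_perspective", TimePerspective.MISSING),
                conditions=conditions,
                outcomes=outcomes,
            )
        )
        gt.studies[study_id] = StudyTruth(
            uses_prompem=uses, year=year, site_label=site, covariates=covariates
        )
    return studies, gt


def corpus_report(ground_truth: GroundTruth) -> dict:
    """Exact summaries from ground truth, used as oracles downstream."""
    studies = ground_truth.studies
    n = len(studies)
    prevalence = sum(s.uses_prompem for s in studies.values()) / n if n else 0.0

    freq: dict[str, set[str]] = {}
    for (study_id, _), truth in ground_truth.outcomes.items():
        if truth.instrument_id:
            freq.setdefault(truth.instrument_id, set()).add(study_id)
    trap_counts: dict[str, int] = {}
    for truth in ground_truth.outcomes.values():
        if truth.trap:
            trap_counts[truth.trap] = trap_counts.get(truth.trap, 0) + 1

    per_year: dict[int, float] = {}
    for year in sorted({s.year for s in studies.values()}):
        group = [s for s in studies.values() if s.year == year]
        per_year[year] = sum(s.uses_prompem for s in group) / len(group)

    return {
        "n_studies": n,
        "n_outcomes": len(ground_truth.outcomes),
        "prevalence": prevalence,
        "instrument_study_counts": {k: len(v) for k, v in sorted(freq.items())},
        "trap_counts": trap_counts,
        "per_year_prevalence": per_year,
    }
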
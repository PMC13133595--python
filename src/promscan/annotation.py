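"""Gold-standard workflow: subset sampling, paired labeling, kappa, adjudication.

The labeled subset is drawn as a stratified simple random sample from the
rule-flagged corpus (a fraction of flagged positives, a smaller fraction of
flagged negatives).  Two blinded annotators label every sampled outcome;
inter-annotator agreement is summarised with Cohen's kappa before
disagreements are resolved to a consensus label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .lexicon_matcher import MatchResult

OutcomeKey = tuple[str, int]


class AdjudicationError(ValueError):
    """Raised when a disagreement has no resolution label."""

    def __init__(self, unresolved: list[OutcomeKey]):
        self.unresolved = unresolved
        super().__init__(f"unresolved disagreements for keys: {unresolved}")


@dataclass(frozen=True)
class LabelRecord:
    outcome_key: OutcomeKey
    label_a: int
    label_b: int
    pair_id: str = "pair_1"


@dataclass(frozen=True)
class GoldRecord:
    outcome_key: OutcomeKey
    label_a: int
    label_b: int
    adjudicated_label: int
    pair_id: str


@dataclass
class GoldLabelSet:
    records: list[GoldRecord]
    kappa_per_pair: dict[str, float] = field(default_factory=dict)

    def labels(self) -> dict[OutcomeKey, int]:
        return {r.outcome_key: r.adjudicated_label for r in self.records}


def sample_labeling_subset(
    flags: Sequence[MatchResult],
    pos_fraction: float,
    neg_fraction: float,
    seed: int,
) -> list[OutcomeKey]:
    """Sample ``floor(pos_fraction * N_pos)`` flagged-positive and
    ``floor(neg_fraction * N_neg)`` flagged-negative outcome keys without
    replacement, reproducibly from ``seed``."""
    for name, frac in (("pos_fraction", pos_fraction), ("neg_fraction", neg_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    pos = [f.outcome_key for f in flags if f.matched]
    neg = [f.outcome_key for f in flags if not f.matched]
    rng = np.random.default_rng(seed)
    n_pos = int(np.floor(pos_fraction * len(pos)))
    n_neg = int(np.floor(neg_fraction * len(neg)))
    chosen: list[OutcomeKey] = []
    if n_pos:
        chosen.extend(pos[i] for i in rng.choice(len(pos), size=n_pos, replace=False))
    if n_neg:
        chosen.extend(neg[i] for i in rng.choice(len(neg), size=n_neg, replace=False))
    return chosen


def assign_pairs(
    keys: Sequence[OutcomeKey], n_pairs: int, seed: int
) -> dict[OutcomeKey, str]:
    """Seeded round-robin partition of sampled keys over annotator pairs."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    return {keys[idx]: f"pair_{i % n_pairs + 1}" for i, idx in enumerate(order)}


def cohens_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    Identical vectors return 1.0 even in the degenerate single-category
    case where chance agreement is also 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("label vectors must be non-empty")
    a = list(labels_a)
    b = list(labels_b)
    if a == b:
        return 1.0
    n = len(a)
    categories = sorted(set(a) | set(b), key=repr)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in categories)
    return (p_o - p_e) / (1.0 - p_e)


def adjudicate(
    records: Sequence[LabelRecord],
    resolution: Mapping[OutcomeKey, int] | None = None,
) -> GoldLabelSet:
    """Merge paired labels into a consensus gold set.

    Agreements pass through untouched; disagreements take the label from
    ``resolution`` and raise :class:`AdjudicationError` listing unresolved
    keys when one is absent.  Per-pair kappa is computed on the
    pre-adjudication labels.
    """
    resolution = resolution or {}
    unresolved = [
        r.outcome_key
        for r in records
        if r.label_a != r.label_b and r.outcome_key not in resolution
    ]
    if unresolved:
        raise AdjudicationError(unresolved)

    gold = []
    for r in records:
        label = r.label_a if r.label_a == r.label_b else resolution[r.outcome_key]
        gold.append(GoldRecord(r.outcome_key, r.label_a, r.label_b, label, r.pair_id))

    kappas: dict[str, float] = {}
    for pair in sorted({r.pair_id for r in records}):
        a = [r.label_a for r in records if r.pair_id == pair]
        b = [r.label_b for r in records if r.pair_id == pair]
        kappas[pair] = cohens_kappa(a, b)
    return GoldLabelSet(records=gold, kappa_per_pair=kappas)


# ---------------------------------------------------------------------------
# file exchange (blinding is structural: one label file per annotator)

def read_label_file(path: str | Path) -> dict[OutcomeKey, int]:
    """Read a TSV of study_id, outcome_index, label(yes/no), annotator_id."""
    labels: dict[OutcomeKey, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            key = (fields[idx["study_id"]], int(fields[idx["outcome_index"]]))
            raw = fields[idx["label"]].strip().lower()
            labels[key] = 1 if raw in ("yes", "1", "true") else 0
    return labels


def merge_label_files(
    labels_a: Mapping[OutcomeKey, int],
    labels_b: Mapping[OutcomeKey, int],
    pair_assignment: Mapping[OutcomeKey, str] | None = None,
) -> list[LabelRecord]:
    keys = sorted(set(labels_a) & set(labels_b))
    pair_assignment = pair_assignment or {}
    return [
        LabelRecord(
            outcome_key=k,
            label_a=labels_a[k],
            label_b=labels_b[k],
            pair_id=pair_assignment.get(k, "pair_1"),
        )
        for k in keys
    ]


def read_resolution_file(path: str | Path) -> dict[OutcomeKey, int]:
    """Read a TSV of study_id, outcome_index, final_label."""
    resolution: dict[OutcomeKey, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            key = (fields[idx["study_id"]], int(fields[idx["outcome_index"]]))
            raw = fields[idx["final_label"]].strip().lower()
            resolution[key] = 1 if raw in ("yes", "1", "true") else 0
    return resolution


def write_gold_tsv(gold: GoldLabelSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("study_id\toutcome_index\tlabel_a\tlabel_b\tadjudicated_label\tpair_id\n")
        for r in gold.records:
            fh.write(
                f"{r.outcome_key[0]}\t{r.outcome_key[1]}\t{r.label_a}\t"
                f"{r.label_b}\t{r.adjudicated_label}\t{r.pair_id}\n"
            )
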
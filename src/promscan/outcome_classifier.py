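"""Trainable binary detector over outcome texts.

Contract: text in, probability out.  The default desk-scale backend is a
term-frequency linear model (count vectorizer + logistic regression); a
transformer backend can be plugged in behind the same interface when the
optional dependency is installed.  Training uses balanced classes, a
three-way stratified split, a hyperparameter grid, and accuracy-based
model selection on the validation set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, recall_score
from sklearn.pipeline import Pipeline

OutcomeKey = tuple[str, int]

MAX_SEQUENCE_LENGTH = 512  # tokens kept per text, head-first truncation


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledItem:
    outcome_key: OutcomeKey
    text: str
    gold_label: int


@dataclass
class DatasetSplit:
    train: list[LabeledItem]
    validation: list[LabeledItem]
    test: list[LabeledItem]
    ratios: tuple[float, float, float] | None
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


@dataclass
class ClassifierModel:
    backend_id: str
    hyperparameters: dict
    pipeline: Pipeline | None = None
    max_sequence_length: int = MAX_SEQUENCE_LENGTH
    selection_metric: str = "accuracy"
    seed: int = 0

    @property
    def fitted(self) -> bool:
        return self.pipeline is not None


def truncate_tokens(text: str, max_tokens: int = MAX_SEQUENCE_LENGTH) -> str:
    """Keep the first ``max_tokens`` whitespace tokens of a text."""
    tokens = text.split()
    return " ".join(tokens[:max_tokens]) if len(tokens) > max_tokens else text


def _check_unique_keys(items: Sequence[LabeledItem]) -> None:
    keys = [it.outcome_key for it in items]
    if len(set(keys)) != len(keys):
        raise ClassifierError("duplicate outcome keys in labeled corpus")


def balance_classes(items: Sequence[LabeledItem], seed: int) -> list[LabeledItem]:
    """Randomly downsample the majority class to the minority size."""
    _check_unique_keys(items)
    pos = [i for i, it in enumerate(items) if it.gold_label == 1]
    neg = [i for i, it in enumerate(items) if it.gold_label == 0]
    if not pos or not neg:
        raise ClassifierError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        pos = sorted(rng.choice(pos, size=len(neg), replace=False))
    elif len(neg) > len(pos):
        neg = sorted(rng.choice(neg, size=len(pos), replace=False))
    keep = sorted(set(pos) | set(neg))
    return [items[i] for i in keep]


def largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer sizes proportional to ``ratios``.

    Ties in the fractional remainders break toward earlier positions.
    """
    quotas = [n * r for r in ratios]
    base = [math.floor(q) for q in quotas]
    shortfall = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:shortfall]:
        base[i] += 1
    return base


def split_corpus(
    items: Sequence[LabeledItem],
    ratios: Sequence[float] | None = (0.61, 0.12, 0.27),
    seed: int = 0,
    sizes: Sequence[int] | None = None,
) -> DatasetSplit:
    """Three-way stratified split by seeded shuffle.

    Sizes come either from ``ratios`` (largest-remainder apportionment,
    applied per label class) or from explicit ``sizes`` counts, which must
    sum to the corpus size.
    """
    _check_unique_keys(items)
    n = len(items)
    if sizes is not None:
        target = [int(s) for s in sizes]
        if any(s < 0 for s in target) or sum(target) != n:
            raise ClassifierError(f"explicit sizes {target} must be >= 0 and sum to {n}")
    else:
        if ratios is None or len(ratios) != 3 or any(r < 0 for r in ratios):
            raise ClassifierError("ratios must be three non-negative proportions")
        if abs(sum(ratios) - 1.0) > 1e-9:
            raise ClassifierError(f"ratios must sum to 1, got {sum(ratios)}")
        target = largest_remainder(n, ratios)

    rng = np.random.default_rng(seed)
    by_label: dict[int, list[int]] = {}
    for i, it in enumerate(items):
        by_label.setdefault(it.gold_label, []).append(i)
    frac = [t / n for t in target] if n else [0.0, 0.0, 0.0]
    alloc = {
        label: largest_remainder(len(idxs), frac) for label, idxs in by_label.items()
    }
    # reconcile per-class allocations to the overall target column sums
    labels = sorted(alloc)
    cols = [sum(alloc[lb][j] for lb in labels) for j in range(3)]
    while cols != target:
        jp = next(j for j in range(3) if cols[j] > target[j])
        jm = next(j for j in range(3) if cols[j] < target[j])
        lb = max(labels, key=lambda L: alloc[L][jp])
        alloc[lb][jp] -= 1
        alloc[lb][jm] += 1
        cols = [sum(alloc[lb][j] for lb in labels) for j in range(3)]

    buckets: list[list[LabeledItem]] = [[], [], []]
    for label in labels:
        idxs = by_label[label]
        order = rng.permutation(len(idxs))
        shuffled = [idxs[k] for k in order]
        a, b, _c = alloc[label]
        buckets[0].extend(items[i] for i in shuffled[:a])
        buckets[1].extend(items[i] for i in shuffled[a : a + b])
        buckets[2].extend(items[i] for i in shuffled[a + b :])
    return DatasetSplit(
        train=buckets[0],
        validation=buckets[1],
        test=buckets[2],
        ratios=tuple(ratios) if sizes is None else None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# backends

def _preprocess(text: str) -> str:
    # module-level so fitted pipelines stay picklable
    return truncate_tokens(text).casefold()


def _build_baseline_pipeline(params: Mapping, seed: int) -> Pipeline:
    # grid entries may carry transformer-style keys (batch_size,
    # learning_rate); the baseline maps learning_rate onto the inverse
    # regularisation strength and ignores the rest
    c = float(params.get("C", params.get("learning_rate", 1.0) * 100.0))
    return Pipeline(
        [
            (
                "vectorize",
                CountVectorizer(
                    preprocessor=_preprocess,
                    token_pattern=r"(?u)\b\w[\w\-]*\b",
                ),
            ),
            (
                "classify",
                LogisticRegression(C=c, max_iter=1000, random_state=seed),
            ),
        ]
    )


@dataclass
class SelectionReport:
    rows: list[dict] = field(default_factory=list)
    best_index: int = 0


def train_classifier(
    split: DatasetSplit,
    backend: str = "baseline_bow",
    grid: Sequence[Mapping] | None = None,
    seed: int = 0,
) -> tuple[ClassifierModel, SelectionReport]:
    """Fit one model per grid point; return the validation-accuracy argmax.

    Ties break toward the earlier grid point.  The baseline backend is
    deterministic given the seed.
    """
    if backend == "transformer":  # optional heavyweight backend
        raise ClassifierError(
            "transformer backend requires the optional 'transformers' extra; "
            "use backend='baseline_bow'"
        )
    if backend != "baseline_bow":
        raise ClassifierError(f"unknown backend: {backend!r}")
    if not split.train:
        raise ClassifierError("training set is empty")
    if not split.validation:
        raise ClassifierError("validation set is empty")
    grid = list(grid) if grid else [{"C": 1.0}]
    if not grid:
        raise ClassifierError("hyperparameter grid is empty")

    x_train = [it.text for it in split.train]
    y_train = [it.gold_label for it in split.train]
    x_val = [it.text for it in split.validation]
    y_val = [it.gold_label for it in split.validation]

    report = SelectionReport()
    best: tuple[float, int, Pipeline] | None = None
    for gi, params in enumerate(grid):
        pipeline = _build_baseline_pipeline(params, seed)
        pipeline.fit(x_train, y_train)
        pred = pipeline.predict(x_val)
        acc = accuracy_score(y_val, pred)
        report.rows.append(
            {
                "params": dict(params),
                "accuracy": float(acc),
                "recall": float(recall_score(y_val, pred, zero_division=0)),
                "f1": float(f1_score(y_val, pred, zero_division=0)),
            }
        )
        if best is None or acc > best[0]:
            best = (acc, gi, pipeline)
    assert best is not None
    report.best_index = best[1]
    model = ClassifierModel(
        backend_id=backend,
        hyperparameters=dict(grid[best[1]]),
        pipeline=best[2],
        seed=seed,
    )
    return model, report


def predict(
    model: ClassifierModel, texts: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-text binary labels and positive-class scores (threshold 0.5)."""
    if not model.fitted:
        raise ClassifierError("model is not fitted")
    scores = model.pipeline.predict_proba(list(texts))[:, 1]
    labels = (scores >= 0.5).astype(int)
    return labels, scores


# ---------------------------------------------------------------------------
# model artifacts

def save_model(model: ClassifierModel, report: SelectionReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "backend_id": model.backend_id,
        "hyperparameters": model.hyperparameters,
        "max_sequence_length": model.max_sequence_length,
        "selection_metric": model.selection_metric,
        "seed": model.seed,
        "selection_report": report.rows,
        "best_index": report.best_index,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(model.pipeline, out / "model.joblib")


def load_model(model_dir: str | Path) -> ClassifierModel:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    pipeline = joblib.load(model_dir / "model.joblib")
    return ClassifierModel(
        backend_id=manifest["backend_id"],
        hyperparameters=manifest["hyperparameters"],
        pipeline=pipeline,
        max_sequence_length=manifest["max_sequence_length"],
        selection_metric=manifest["selection_metric"],
        seed=manifest["seed"],
    )


def read_labeled_tsv(path: str | Path) -> list[LabeledItem]:
    """Read a gold TSV: study_id, outcome_index, text, gold_label."""
    items = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            items.append(
                LabeledItem(
                    outcome_key=(fields[idx["study_id"]], int(fields[idx["outcome_index"]])),
                    text=fields[idx["text"]],
                    gold_label=int(fields[idx["gold_label"]]),
                )
            )
    return items
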
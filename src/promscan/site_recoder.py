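"""Recode free-text cancer-condition strings into homogeneous site labels.

Two stages: seeded k-means over term-frequency vectors groups the raw
condition strings, with each cluster named by its ten most frequent
content words; a prototype classifier then assigns any string to the
nearest site label by cosine similarity against per-label exemplar
centroids.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.feature_extraction.text import CountVectorizer

UNSPECIFIED = "unspecified"
DEFAULT_MIN_CONFIDENCE = 0.05
_WORD_RE = re.compile(r"[a-z][a-z\-]+")


class SiteRecoderError(ValueError):
    pass


def load_stopwords() -> frozenset[str]:
    path = Path(__file__).parent / "data" / "stopwords_en.txt"
    words = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def _content_words(text: str, stopwords: frozenset[str]) -> list[str]:
    return [w for w in _WORD_RE.findall(text.lower()) if w not in stopwords]


@dataclass
class SiteCluster:
    cluster_id: int
    members: list[str]
    top_words: list[str]
    assigned_site_label: str | None = None


@dataclass
class SiteClusterModel:
    k: int
    clusters: list[SiteCluster]
    prototypes: dict[str, list[str]] = field(default_factory=dict)


def cluster_sites(
    condition_strings: Sequence[str], k: int, seed: int
) -> SiteClusterModel:
    """Group condition strings by seeded k-means on term-frequency vectors.

    Raises when ``k`` exceeds the number of distinct strings.  Each cluster
    carries its 10 most frequent content words for naming.
    """
    if k < 1:
        raise SiteRecoderError("k must be >= 1")
    distinct = sorted(set(condition_strings))
    if k > len(distinct):
        raise SiteRecoderError(
            f"k={k} exceeds the {len(distinct)} distinct condition strings"
        )
    stopwords = load_stopwords()
    vectorizer = CountVectorizer(lowercase=True, stop_words=list(stopwords))
    x = vectorizer.fit_transform(distinct)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignments = km.fit_predict(x)

    clusters = []
    for cid in range(k):
        members = [s for s, a in zip(distinct, assignments) if a == cid]
        counts: Counter = Counter()
        for s in members:
            counts.update(_content_words(s, stopwords))
        top = [w for w, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:10]]
        clusters.append(SiteCluster(cluster_id=cid, members=members, top_words=top))
    return SiteClusterModel(k=k, clusters=clusters)


# ---------------------------------------------------------------------------
# prototype ("few-shot") classifier

def _tf_vector(text: str, vocab: Mapping[str, int], stopwords: frozenset[str]) -> np.ndarray:
    vec = np.zeros(len(vocab))
    for w in _content_words(text, stopwords):
        if w in vocab:
            vec[vocab[w]] += 1.0
    return vec


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n else v


def classify_site(
    condition_string: str,
    prototypes: Mapping[str, Sequence[str]],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> tuple[str, float]:
    """Nearest-prototype site assignment by cosine similarity.

    Confidence is the winning cosine against the per-label centroid of
    exemplar term-frequency vectors.  Empty or out-of-vocabulary strings
    fall back to the ``unspecified`` label.
    """
    if not prototypes:
        raise SiteRecoderError("prototypes must be non-empty")
    for label, exemplars in prototypes.items():
        if not exemplars:
            raise SiteRecoderError(f"label {label!r} has no exemplar sentences")
    if not condition_string.strip():
        return (UNSPECIFIED, 0.0)
    stopwords = load_stopwords()
    vocab_words = sorted(
        {
            w
            for exemplars in prototypes.values()
            for ex in exemplars
            for w in _content_words(ex, stopwords)
        }
        | set(_content_words(condition_string, stopwords))
    )
    vocab = {w: i for i, w in enumerate(vocab_words)}
    query = _unit(_tf_vector(condition_string, vocab, stopwords))

    best_label, best_sim = UNSPECIFIED, 0.0
    for label in sorted(prototypes):
        centroid = _unit(
            np.mean(
                [_unit(_tf_vector(ex, vocab, stopwords)) for ex in prototypes[label]],
                axis=0,
            )
        )
        sim = float(query @ centroid)
        if sim > best_sim:
            best_label, best_sim = label, sim
    if best_sim < min_confidence:
        return (UNSPECIFIED, best_sim)
    return (best_label, best_sim)


def recode_conditions(
    conditions_by_study: Mapping[str, Sequence[str]],
    prototypes: Mapping[str, Sequence[str]],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> dict[str, str]:
    """Assign one site label per study from its condition strings.

    The label of the highest-confidence condition wins.
    """
    out = {}
    for study_id, conditions in conditions_by_study.items():
        best_label, best_conf = UNSPECIFIED, -1.0
        for cond in conditions:
            label, conf = classify_site(cond, prototypes, min_confidence)
            if conf > best_conf:
                best_label, best_conf = label, conf
        out[study_id] = best_label
    return out


def read_prototypes_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read a TSV of site_label, exemplar_text (conventionally 8 per label)."""
    prototypes: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            prototypes.setdefault(fields[idx["site_label"]], []).append(
                fields[idx["exemplar_text"]]
            )
    return prototypes


def write_recoded_tsv(recoded: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("study_id\tsite_label\n")
        for study_id in sorted(recoded):
            fh.write(f"{study_id}\t{recoded[study_id]}\n")
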
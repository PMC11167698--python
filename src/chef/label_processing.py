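"""Label cleaning and embedding-based vocabulary consolidation.

Raw model-extracted labels are noisy surface forms ("Kinase Inhibitors",
"anti-viral").  Cleaning splits them into lowercase singular unigrams;
consolidation embeds the cleaned vocabulary, density-clusters the
embeddings (DBSCAN, Euclidean on unit-norm vectors) so grammatically
different but semantically equivalent labels merge, names each cluster with
one representative label, maps molecules onto the representatives, and
drops rare labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from chef.corpus_io import ChefDataset
from chef.llm_interface import TextModelBackend, summarize_label_cluster

logger = logging.getLogger(__name__)

__all__ = [
    "ConsolidationConfig",
    "LabelVocabulary",
    "singularize",
    "clean_labels",
    "clean_label_sets",
    "cluster_label_embeddings",
    "sweep_epsilon",
    "assign_representatives",
    "consolidate_dataset",
    "remove_structural_term_cluster",
]

# words that look plural but are not (or whose stem would be wrong)
_SINGULAR_EXCEPTIONS = frozenset(
    {
        "virus",
        "diabetes",
        "herpes",
        "rabies",
        "scabies",
        "measles",
        "species",
        "series",
        "lens",
        "mucus",
        "fungus",
        "tetanus",
        "lupus",
        "pancreas",
        "gas",
        "asthma",  # harmless; never plural-shaped
    }
)

_SIBILANT_ENDINGS = ("ss", "x", "z", "ch", "sh")


def singularize(word: str) -> str:
    """Deterministic rule-based singular form of a lowercase token.

    Strips a trailing "s" unless the word ends in "ss"/"us"/"is" (which
    covers "sis") or sits on a frozen exception list; "ies" → "y"; "es"
    after a sibilant drops the "es".  No external lemmatizer: the rule is
    frozen so the vocabulary is reproducible.
    """
    if word in _SINGULAR_EXCEPTIONS or len(word) < 3:
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ss", "us", "is")):
        return word
    if word.endswith("es") and word[:-2] in _SINGULAR_EXCEPTIONS:
        return word[:-2]  # viruses, gases
    if word.endswith("es") and word[:-2].endswith(_SIBILANT_ENDINGS):
        return word[:-2]
    if word.endswith("s"):
        return word[:-1]
    return word


def clean_labels(raw: Iterable[str]) -> set[str]:
    """Clean raw labels into unigram lowercase singular tokens.

    Each raw label is split on whitespace (hyphens are kept; the embedding
    clustering merges hyphen variants), lowercased, singularized, and
    single-character tokens are dropped.  Returns the union set.
    Idempotent.
    """
    out: set[str] = set()
    for label in raw:
        for token in label.split():
            token = singularize(token.strip(".,;:()[]{}\"'").lower())
            if len(token) >= 2:
                out.add(token)
    return out


def clean_label_sets(label_sets: Sequence[Iterable[str]]) -> list[set[str]]:
    """Apply :func:`clean_labels` per molecule."""
    return [clean_labels(s) for s in label_sets]


@dataclass
class LabelVocabulary:
    """Ordered unique labels with embeddings, cluster ids, representatives."""

    labels: list[str]
    embeddings: np.ndarray | None = None
    cluster_id: np.ndarray | None = None
    representative: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in vocabulary")
        if self.embeddings is not None:
            self.embeddings = np.asarray(self.embeddings, dtype=float)
            if self.embeddings.shape[0] != len(self.labels):
                raise ValueError("one embedding per label required")

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], backend: TextModelBackend
    ) -> "LabelVocabulary":
        labels = sorted(set(labels))
        if labels:
            emb = np.vstack([backend.embed(lab) for lab in labels])
        else:
            emb = np.zeros((0, 0))
        return cls(labels=labels, embeddings=emb)

    def representative_of(self, label: str) -> str:
        if self.representative is None:
            raise ValueError("representatives not assigned yet")
        return self.representative[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "cluster_id": self.cluster_id
                if self.cluster_id is not None
                else np.full(len(self.labels), -1),
                "representative": self.representative
                if self.representative is not None
                else self.labels,
            }
        )


@dataclass
class ConsolidationConfig:
    """Consolidation knobs.

    epsilon
        DBSCAN radius on unit-norm embeddings (Euclidean, monotone with
        cosine distance); 0.34 is the value that merges synonym clusters
        without collapsing distinct functions in the original vocabulary.
    min_samples
        DBSCAN core-point threshold; 2 lets any synonym pair merge.
    min_label_count
        Consolidated labels borne by fewer molecules than this are dropped
        (default 50, enough molecules per label for predictive power).
    """

    epsilon: float = 0.34
    min_samples: int = 2
    min_label_count: int = 50
    epsilon_grid: list[float] = field(
        default_factory=lambda: [0.1, 0.2, 0.3, 0.34, 0.4, 0.5, 0.75, 1.0]
    )

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_label_count < 1:
            raise ValueError("min_label_count must be >= 1")


def _dense_cluster_ids(raw_labels: np.ndarray) -> np.ndarray:
    """Re-index DBSCAN output: noise points become singleton clusters and
    ids are dense from 0, ordered by first occurrence."""
    out = np.empty(len(raw_labels), dtype=int)
    mapping: dict[int, int] = {}
    next_id = 0
    for i, c in enumerate(raw_labels):
        if c == -1:
            out[i] = next_id
            next_id += 1
        else:
            if c not in mapping:
                mapping[c] = next_id
                next_id += 1
            out[i] = mapping[c]
    return out


def cluster_label_embeddings(
    vocab: LabelVocabulary, cfg: ConsolidationConfig | None = None
) -> LabelVocabulary:
    """Density-cluster the label embeddings; returns vocab with cluster ids.

    Euclidean DBSCAN at ``cfg.epsilon``; noise points are kept as singleton
    clusters (unclustered labels stay in the vocabulary).
    """
    cfg = cfg or ConsolidationConfig()
    if vocab.embeddings is None:
        raise ValueError("vocabulary has no embeddings")
    n = len(vocab.labels)
    if n == 0:
        vocab.cluster_id = np.zeros(0, dtype=int)
        return vocab
    raw = DBSCAN(eps=cfg.epsilon, min_samples=cfg.min_samples, metric="euclidean").fit(
        vocab.embeddings
    )
    vocab.cluster_id = _dense_cluster_ids(raw.labels_)
    return vocab


def sweep_epsilon(
    vocab: LabelVocabulary, cfg: ConsolidationConfig | None = None
) -> pd.DataFrame:
    """Cluster once per grid epsilon; returns (epsilon, n_clusters, n_noise).

    n_clusters counts multi-member clusters plus singletons; n_noise counts
    DBSCAN noise points (labels in no dense region).  The epsilon choice —
    the fewest clusters without merging distinct functions — stays a human
    decision over this table.
    """
    cfg = cfg or ConsolidationConfig()
    if not cfg.epsilon_grid:
        raise ValueError("epsilon_grid must be non-empty")
    if vocab.embeddings is None:
        raise ValueError("vocabulary has no embeddings")
    rows = []
    for eps in cfg.epsilon_grid:
        raw = DBSCAN(eps=eps, min_samples=cfg.min_samples, metric="euclidean").fit(
            vocab.embeddings
        )
        n_noise = int(np.sum(raw.labels_ == -1))
        n_clusters = len(set(raw.labels_)) - (1 if n_noise else 0) + n_noise
        rows.append({"epsilon": eps, "n_clusters": n_clusters, "n_noise": n_noise})
    return pd.DataFrame(rows)


def assign_representatives(
    vocab: LabelVocabulary, backend: TextModelBackend
) -> LabelVocabulary:
    """Name every cluster with one representative label (lowercased)."""
    if vocab.cluster_id is None:
        raise ValueError("cluster ids not computed; run cluster_label_embeddings")
    reps: list[str | None] = [None] * len(vocab.labels)
    for cid in np.unique(vocab.cluster_id):
        members = [vocab.labels[i] for i in np.where(vocab.cluster_id == cid)[0]]
        name = summarize_label_cluster(members, backend).strip().lower()
        for i in np.where(vocab.cluster_id == cid)[0]:
            reps[i] = name
    vocab.representative = [r if r else vocab.labels[i] for i, r in enumerate(reps)]
    return vocab


def consolidate_dataset(
    dataset: ChefDataset,
    vocab: LabelVocabulary,
    backend: TextModelBackend,
    cfg: ConsolidationConfig | None = None,
) -> ChefDataset:
    """Map molecule labels onto cluster representatives and filter rares.

    Order of operations: replace each label by its cluster representative
    (deduplicating per molecule), drop representatives borne by fewer than
    ``cfg.min_label_count`` molecules, then drop single-character labels.
    Molecules left without labels are retained with empty label sets.
    """
    cfg = cfg or ConsolidationConfig()
    if vocab.representative is None:
        if vocab.cluster_id is None:
            vocab = cluster_label_embeddings(vocab, cfg)
        vocab = assign_representatives(vocab, backend)
    rep_map = dict(zip(vocab.labels, vocab.representative))
    missing = {
        lab for s in dataset.label_sets() for lab in s if lab not in rep_map
    }
    if missing:
        raise ValueError(f"dataset labels missing from vocabulary: {sorted(missing)[:5]}")
    mapped = [{rep_map[lab] for lab in s} for s in dataset.label_sets()]
    counts: dict[str, int] = {}
    for s in mapped:
        for lab in s:
            counts[lab] = counts.get(lab, 0) + 1
    keep = {
        lab
        for lab, c in counts.items()
        if c >= cfg.min_label_count and len(lab) >= 2
    }
    filtered = [{lab for lab in s if lab in keep} for s in mapped]
    return ChefDataset.from_label_sets(
        dataset.molecules, filtered, vocabulary=sorted(keep)
    )


def remove_structural_term_cluster(
    vocab: LabelVocabulary, blocklist: set[str]
) -> LabelVocabulary:
    """Drop labels whose cluster representative is blocklisted.

    Used to remove clusters of pure structural nomenclature (IUPAC
    fragments) that generalize poorly as function labels; the blocklist is
    configuration, identified by inspection.
    """
    if not blocklist:
        return vocab
    if vocab.representative is None:
        raise ValueError("representatives not assigned yet")
    present = set(vocab.representative)
    for name in blocklist - present:
        logger.warning("blocklisted representative %r not in vocabulary", name)
    keep_idx = [i for i, rep in enumerate(vocab.representative) if rep not in blocklist]
    return LabelVocabulary(
        labels=[vocab.labels[i] for i in keep_idx],
        embeddings=vocab.embeddings[keep_idx] if vocab.embeddings is not None else None,
        cluster_id=vocab.cluster_id[keep_idx] if vocab.cluster_id is not None else None,
        representative=[vocab.representative[i] for i in keep_idx],
    )
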
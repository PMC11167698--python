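"""Language-model interface for patent summarization and cluster naming.

The extraction method asks a chat model to compress a patent's title,
abstract and the start of its description into 1–3 short functional
descriptors.  The prompt templates used for (a) patent summarization,
(b) embedding-cluster naming and (c) co-occurrence-community naming are
module constants; backends are pluggable behind :class:`TextModelBackend`.

Two backends ship: an HTTP client for a hosted chat/embedding API
(:class:`OpenAIBackend`; never exercised offline), and a deterministic
:class:`MockTextModelBackend` — a keyword matcher over a known synonym
vocabulary with seeded hash embeddings — so that the entire pipeline is
reproducible without a network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import re
import time
import urllib.request
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PatentDocument",
    "ExtractionConfig",
    "TextModelBackend",
    "MockTextModelBackend",
    "OpenAIBackend",
    "SUMMARIZATION_SYSTEM_PROMPT",
    "SUMMARIZATION_USER_PROMPT",
    "CLUSTER_SYSTEM_PROMPT",
    "CLUSTER_USER_PROMPT_TEMPLATE",
    "COMMUNITY_SYSTEM_PROMPT",
    "COMMUNITY_USER_PROMPT_TEMPLATE",
    "build_summarization_prompt",
    "build_cluster_prompt",
    "build_community_prompt",
    "parse_label_response",
    "LabelParse",
    "extract_labels_for_molecule",
    "extract_dataset_labels",
    "summarize_label_cluster",
]

# --------------------------------------------------------------------------
# Prompt templates (operational strings of the extraction method; changing a
# byte changes the method, so tests pin them).

SUMMARIZATION_SYSTEM_PROMPT = "You are an organic chemist summarizing chemical patents"

SUMMARIZATION_USER_PROMPT = (
    "Return a short set of three 1-3 word descriptors that best describe the "
    "chemical or pharmacological function(s) of the molecule described by the "
    "given patent title, abstract, and partial description (giving more weight "
    "to title & abstract). Be specific and concise, but not necessarily "
    "comprehensive (choose a small number of great descriptor). Follow the "
    "syntax '{descriptor_1}/{descriptor_2}/{etc}', writing 'NA' if nothing is "
    "provided. DO NOT BREAK THIS SYNTAX. The following is the patent:"
)

CLUSTER_SYSTEM_PROMPT = "You are a PhD pharmaceutical chemist"

CLUSTER_USER_PROMPT_TEMPLATE = (
    "Given a set of molecular descriptors, return a single descriptor "
    "representing the centroid of the terms. Do not speculate. Only use the "
    "information provided. Be concise, not explaining answers. "
    "Example 1 set of descriptors: 11(beta)-hsd1, 11-hsd-2, 17β-hsd3 "
    "example 1 average descriptor: hsd "
    "example 2 set of descriptors: anti-retroviral, anti-retrovirus, "
    "anti-viral, anti-virus, antiretroviral, antiretrovirus, antiviral, "
    "antivirus example 2 average descriptor: antiviral "
    "set of descriptors: __INSERT_DESCRIPTORS_HERE__ average descriptor:"
)

COMMUNITY_SYSTEM_PROMPT = "You are a PhD pharmaceutical chemist"

COMMUNITY_USER_PROMPT_TEMPLATE = (
    "Pretend you are a pharmaceutical chemist. I will provide you with "
    "several terms, and your job is to summarize the terms into appropriate "
    "categories. Be succinct, focusing on the broadest categories while still "
    "being representative. Don't show your work. "
    "Example terms: antiviral HCV kinase cancer polymerase protease "
    "example summarization: antiviral & cancer "
    "terms: __INSERT_DESCRIPTORS_HERE__ summarization:"
)


@dataclass
class PatentDocument:
    """A patent's text fields used for summarization."""

    patent_id: str
    title: str = ""
    abstract: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.patent_id:
            raise ValueError("patent_id must be non-empty")


@dataclass
class ExtractionConfig:
    """Extraction knobs: description truncation length and label cap.

    The first ``description_chars`` characters of the description are kept
    (default 3500) because the start of a patent description typically holds
    the relevant background and a summary of the claim.
    """

    description_chars: int = 3500
    max_labels_per_patent: int = 3

    def __post_init__(self) -> None:
        if self.description_chars <= 0:
            raise ValueError("description_chars must be positive")


def _normalize_whitespace(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


def build_summarization_prompt(
    patent: PatentDocument, cfg: ExtractionConfig | None = None
) -> tuple[str, str]:
    """Build (system, user) prompts for one patent.

    The user prompt is the fixed template followed by the title, abstract
    and the first ``cfg.description_chars`` characters of the
    whitespace-normalized description.
    """
    cfg = cfg or ExtractionConfig()
    description = _normalize_whitespace(patent.description)[: cfg.description_chars]
    user = (
        f"{SUMMARIZATION_USER_PROMPT}\n\n"
        f"Title: {_normalize_whitespace(patent.title)}\n"
        f"Abstract: {_normalize_whitespace(patent.abstract)}\n"
        f"Description: {description}"
    )
    return SUMMARIZATION_SYSTEM_PROMPT, user


def build_cluster_prompt(labels: Sequence[str]) -> tuple[str, str]:
    """Prompt asking for a single centroid descriptor for a label cluster."""
    joined = ", ".join(labels)
    return (
        CLUSTER_SYSTEM_PROMPT,
        CLUSTER_USER_PROMPT_TEMPLATE.replace("__INSERT_DESCRIPTORS_HERE__", joined),
    )


def build_community_prompt(labels: Sequence[str]) -> tuple[str, str]:
    """Prompt asking for a broad categorical summary of community labels."""
    joined = " ".join(labels)
    return (
        COMMUNITY_SYSTEM_PROMPT,
        COMMUNITY_USER_PROMPT_TEMPLATE.replace("__INSERT_DESCRIPTORS_HERE__", joined),
    )


# --------------------------------------------------------------------------
# Response parsing


class LabelParse(list):
    """List of parsed labels with a ``failed`` audit flag.

    Compares equal to a plain list of labels; ``failed`` records whether the
    response violated the expected slash syntax and recovery was attempted.
    """

    def __init__(self, labels: Iterable[str] = (), failed: bool = False) -> None:
        super().__init__(labels)
        self.failed = failed


_STRIP_CHARS = " \t\r\n{}'\"`*"


def _clean_token(tok: str) -> str:
    return tok.strip(_STRIP_CHARS)


def _keep(tok: str) -> bool:
    return bool(tok) and tok.lower() != "na"


def parse_label_response(text: str) -> LabelParse:
    """Parse a model response into raw label strings.

    Primary syntax is slash-separated descriptors
    (``descriptor_1/descriptor_2/...``); whitespace and braces are stripped,
    empty tokens and a bare (case-insensitive) "NA" are dropped.  Responses
    violating the syntax are recovered by splitting on newlines/commas and
    flagged (``.failed``); parsing never raises.
    """
    if text is None:
        return LabelParse([], failed=True)
    text = text.strip()
    if not text:
        return LabelParse([], failed=True)
    if "/" in text:
        tokens = [_clean_token(t) for t in text.split("/")]
        return LabelParse([t for t in tokens if _keep(t)], failed=False)
    # single token with no separators: fine if it looks like one descriptor
    if "\n" not in text and "," not in text and len(text.split()) <= 4:
        tok = _clean_token(text)
        return LabelParse([tok] if _keep(tok) else [], failed=False)
    # syntax violation: recover by newline, then comma, splitting
    tokens = []
    for line in text.splitlines():
        for part in line.split(","):
            part = _clean_token(re.sub(r"^\s*(?:[-*•]|\d+[.)])\s*", "", part))
            if _keep(part) and len(part.split()) <= 4:
                tokens.append(part)
    return LabelParse(tokens, failed=True)


# --------------------------------------------------------------------------
# Backends


class TextModelBackend(Protocol):
    """Abstract text-model backend: chat summarization plus embeddings."""

    def summarize(self, system_prompt: str, user_prompt: str) -> str:
        """Return the model response for a (system, user) prompt pair."""
        ...

    def embed(self, text: str) -> np.ndarray:
        """Return a deterministic unit-norm embedding vector for ``text``."""
        ...


class MockTextModelBackend:
    """Deterministic stand-in backend for offline, reproducible runs.

    Summarization is keyword extraction: the patent text is scanned for
    known surface forms from ``synonym_table`` (canonical label → surface
    forms) and up to ``max_labels`` matches are returned in slash syntax,
    or ``"NA"`` when nothing matches.  Cluster-naming prompts are answered
    with the most frequent canonical form among the listed descriptors
    (ties broken lexicographically).

    Embeddings are unit-norm vectors of dimension ``dim``: each canonical
    label owns a fixed anchor (scaled basis-like vector, pairwise Euclidean
    distance sqrt(2)); a surface form maps to its canonical's anchor plus a
    small deterministic perturbation (distance < 0.1), and unknown text maps
    to a seeded-hash random unit vector.
    """

    def __init__(
        self,
        synonym_table: Mapping[str, Sequence[str]] | None = None,
        dim: int = 64,
        seed: int = 0,
        max_labels: int = 3,
    ) -> None:
        self.synonym_table = {
            canon: list(forms) for canon, forms in (synonym_table or {}).items()
        }
        self.dim = int(dim)
        self.seed = int(seed)
        self.max_labels = int(max_labels)
        # surface form (lowercase) -> canonical; canonicals are their own forms
        self._form_to_canonical: dict[str, str] = {}
        for canon in sorted(self.synonym_table):
            self._form_to_canonical.setdefault(canon.lower(), canon)
            for form in self.synonym_table[canon]:
                self._form_to_canonical.setdefault(form.lower(), canon)
        self._anchors: dict[str, np.ndarray] = {}
        for i, canon in enumerate(sorted(self.synonym_table)):
            vec = np.zeros(self.dim)
            vec[i % self.dim] = 1.0
            if i >= self.dim:  # fold extra canonicals onto two axes
                vec[(i // self.dim) % self.dim] = 1.0
                vec /= np.linalg.norm(vec)
            self._anchors[canon] = vec

    # -- chat ------------------------------------------------------------
    def summarize(self, system_prompt: str, user_prompt: str) -> str:
        if "average descriptor:" in user_prompt:
            return self._summarize_cluster(user_prompt)
        if "summarization:" in user_prompt:
            return self._summarize_community(user_prompt)
        return self._summarize_patent(user_prompt)

    def _summarize_patent(self, user_prompt: str) -> str:
        text = user_prompt.lower()
        # search after the template so template words never match
        body = text.split("the following is the patent:")[-1]
        hits: list[tuple[int, str]] = []
        seen: set[str] = set()
        for form in sorted(self._form_to_canonical, key=len, reverse=True):
            pos = body.find(form)
            if pos >= 0 and form not in seen:
                # skip forms fully contained in an already-matched longer form
                if any(form in longer and form != longer for longer in seen):
                    continue
                seen.add(form)
                hits.append((pos, form))
        hits.sort()
        labels = [form for _, form in hits[: self.max_labels]]
        return "/".join(labels) if labels else "NA"

    def _descriptors_from_prompt(self, user_prompt: str, marker: str, sep: str) -> list[str]:
        segment = user_prompt.rsplit("set of descriptors:", 1)[-1]
        segment = segment.rsplit("terms:", 1)[-1]
        segment = segment.split(marker)[0]
        return [t.strip() for t in segment.split(sep) if t.strip()]

    def _summarize_cluster(self, user_prompt: str) -> str:
        members = self._descriptors_from_prompt(user_prompt, "average descriptor:", ",")
        counts: dict[str, int] = {}
        for m in members:
            canon = self._form_to_canonical.get(m.lower(), m.lower())
            counts[canon] = counts.get(canon, 0) + 1
        if not counts:
            return "NA"
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return best[0]

    def _summarize_community(self, user_prompt: str) -> str:
        members = self._descriptors_from_prompt(user_prompt, "summarization:", " ")
        return " & ".join(members[:3]) if members else "NA"

    # -- embeddings ------------------------------------------------------
    def _hash_unit_vector(self, text: str, scale: float = 1.0) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}:{text}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        vec = rng.standard_normal(self.dim)
        return scale * vec / np.linalg.norm(vec)

    def embed(self, text: str) -> np.ndarray:
        key = text.strip().lower()
        canon = self._form_to_canonical.get(key)
        if canon is not None:
            vec = self._anchors[canon] + self._hash_unit_vector(key, scale=0.04)
        else:
            vec = self._hash_unit_vector(key)
        return vec / np.linalg.norm(vec)


class OpenAIBackend:
    """Minimal HTTP client for a hosted chat/embedding API.

    Not exercised in tests (they run offline); provided so the pipeline can
    reproduce the full-scale extraction when credentials and network are
    available.  Retries with simple exponential backoff.
    """

    def __init__(
        self,
        chat_model: str = "gpt-3.5-turbo",
        embedding_model: str = "text-embedding-ada-002",
        api_key: str | None = None,
        base_url: str = "https://api.openai.com/v1",
        max_retries: int = 3,
        temperature: float = 0.0,
    ) -> None:
        self.chat_model = chat_model
        self.embedding_model = embedding_model
        self.api_key = api_key or os.environ.get("OPENAI_API_KEY", "")
        self.base_url = base_url.rstrip("/")
        self.max_retries = max_retries
        self.temperature = temperature
        if not self.api_key:
            raise RuntimeError(
                "no API key: set OPENAI_API_KEY or use the mock backend"
            )

    def _post(self, endpoint: str, payload: dict) -> dict:
        req = urllib.request.Request(
            f"{self.base_url}/{endpoint}",
            data=json.dumps(payload).encode(),
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {self.api_key}",
            },
        )
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(req, timeout=60) as resp:
                    return json.loads(resp.read())
            except Exception:
                if attempt == self.max_retries - 1:
                    raise
                time.sleep(2**attempt)
        raise RuntimeError("unreachable")

    def summarize(self, system_prompt: str, user_prompt: str) -> str:
        out = self._post(
            "chat/completions",
            {
                "model": self.chat_model,
                "temperature": self.temperature,
                "messages": [
                    {"role": "system", "content": system_prompt},
                    {"role": "user", "content": user_prompt},
                ],
            },
        )
        return out["choices"][0]["message"]["content"]

    def embed(self, text: str) -> np.ndarray:
        out = self._post("embeddings", {"model": self.embedding_model, "input": text})
        vec = np.asarray(out["data"][0]["embedding"], dtype=float)
        return vec / np.linalg.norm(vec)


# --------------------------------------------------------------------------
# Extraction


@dataclass
class ExtractionAudit:
    n_patents_summarized: int = 0
    n_cache_hits: int = 0
    n_parse_failures: int = 0
    n_missing_patents: int = 0
    n_backend_failures: int = 0


def _summarize_patent_cached(
    patent: PatentDocument,
    backend: TextModelBackend,
    cfg: ExtractionConfig,
    cache: dict[str, list[str]],
    audit: ExtractionAudit,
) -> list[str]:
    if patent.patent_id in cache:
        audit.n_cache_hits += 1
        return cache[patent.patent_id]
    system, user = build_summarization_prompt(patent, cfg)
    response = backend.summarize(system, user)
    parsed = parse_label_response(response)
    if parsed.failed:
        audit.n_parse_failures += 1
    audit.n_patents_summarized += 1
    cache[patent.patent_id] = list(parsed)[: cfg.max_labels_per_patent]
    return cache[patent.patent_id]


def extract_labels_for_molecule(
    record,
    corpus: Mapping[str, PatentDocument],
    backend: TextModelBackend,
    cfg: ExtractionConfig | None = None,
    cache: dict[str, list[str]] | None = None,
    audit: ExtractionAudit | None = None,
) -> tuple[set[str], dict[str, list[str]]]:
    """Union of parsed labels over a molecule's patents, with provenance.

    Per-patent summaries are cached by patent id so a patent shared between
    molecules is summarized once.  Missing patents are skipped with a
    warning; a backend failure on one patent skips that patent but the
    molecule is still processed.  Returns ``(labels, provenance)`` where
    provenance maps each label to the sorted contributing patent ids.
    """
    cfg = cfg or ExtractionConfig()
    cache = cache if cache is not None else {}
    audit = audit if audit is not None else ExtractionAudit()
    labels: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for pid in sorted(record.patent_ids):
        patent = corpus.get(pid)
        if patent is None:
            audit.n_missing_patents += 1
            logger.warning("patent %s not in corpus; skipped", pid)
            continue
        try:
            patent_labels = _summarize_patent_cached(patent, backend, cfg, cache, audit)
        except Exception as exc:  # noqa: BLE001 - backend is third-party
            audit.n_backend_failures += 1
            logger.warning("backend failed on patent %s: %s", pid, exc)
            continue
        for lab in patent_labels:
            labels.add(lab)
            provenance.setdefault(lab, set()).add(pid)
    return labels, {lab: sorted(pids) for lab, pids in provenance.items()}


def extract_dataset_labels(
    records: Sequence,
    corpus: Mapping[str, PatentDocument],
    backend: TextModelBackend,
    cfg: ExtractionConfig | None = None,
) -> tuple[list[set[str]], list[dict[str, list[str]]], ExtractionAudit]:
    """Run label extraction over every molecule, sharing one patent cache."""
    cfg = cfg or ExtractionConfig()
    cache: dict[str, list[str]] = {}
    audit = ExtractionAudit()
    label_sets, provenances = [], []
    for rec in records:
        labels, prov = extract_labels_for_molecule(rec, corpus, backend, cfg, cache, audit)
        label_sets.append(labels)
        provenances.append(prov)
    return label_sets, provenances, audit


def summarize_label_cluster(labels: Sequence[str], backend: TextModelBackend) -> str:
    """Name a cluster of synonymous labels with one representative label.

    Uses the cluster-centroid prompt; on backend failure falls back to the
    shortest member (then lexicographic), flagged via a warning.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    if len(labels) == 1:
        return labels[0]
    system, user = build_cluster_prompt(sorted(labels))
    try:
        name = backend.summarize(system, user).strip().lower()
    except Exception as exc:  # noqa: BLE001
        logger.warning("cluster naming failed (%s); falling back to shortest member", exc)
        name = ""
    if not name or name == "na":
        name = min(labels, key=lambda s: (len(s), s))
    return name
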
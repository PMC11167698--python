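"""Coherence of text-derived function labels with chemical structure space.

Two screens, each comparing an observed max-Tanimoto-similarity sample
against a random null with an independent two-sided t-test per label and
Benjamini–Hochberg FDR across labels:

self-cluster mode
    For each molecule bearing a label, the maximum fingerprint Tanimoto
    similarity to the *other* molecules bearing that label, versus the
    maximum similarity to a random equal-sized set of non-label molecules.
    Significant labels mark structurally clustered molecule families.

co-occurrence mode
    The maximum similarity from each label-bearing molecule to the
    molecules bearing any of the label's 10 most strongly co-occurring
    labels (each with abundance < 1000, so hyper-abundant labels cannot
    force similarities to 1), versus the same random null.  Significant
    labels show that the label's textual neighborhood is also its
    structural neighborhood.

Fingerprints are 2048-bit daylight-style hashed path fingerprints (RDKit
``RDKFingerprint``); similarity is the Tanimoto coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rdkit import Chem
from rdkit import DataStructs

from chef.corpus_io import ChefDataset
from chef.landscape_graph import LabelGraph, top_cooccurring

logger = logging.getLogger(__name__)

__all__ = [
    "CoherenceConfig",
    "CoherenceResult",
    "ScreenSummary",
    "fingerprint_molecules",
    "tanimoto",
    "max_tanimoto_to_set",
    "bh_fdr",
    "label_self_coherence",
    "label_cooccurrence_coherence",
    "run_coherence_screen",
]


@dataclass
class CoherenceConfig:
    """Screen parameters.

    alpha: FDR level for significance (default 0.05).
    k_neighbors / max_abundance: co-occurrence neighborhood size and the
    abundance cap on eligible neighbors.
    mode: "self_cluster" or "cooccurrence".
    welch: use Welch's t-test instead of the pooled-variance form.
    """

    alpha: float = 0.05
    k_neighbors: int = 10
    max_abundance: int = 1000
    seed: int = 0
    mode: Literal["self_cluster", "cooccurrence"] = "self_cluster"
    n_bits: int = 2048
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class CoherenceResult:
    """Per-label screen outcome: samples, test statistic, p, q, flag."""

    label: str
    observed: np.ndarray
    null: np.ndarray
    t_stat: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False

    @property
    def n_molecules(self) -> int:
        return len(self.observed)

    @property
    def mean_observed(self) -> float:
        return float(np.mean(self.observed))

    @property
    def mean_null(self) -> float:
        return float(np.mean(self.null))


@dataclass
class ScreenSummary:
    """A full screen: evaluable results plus skipped labels with reasons."""

    results: list[CoherenceResult]
    skipped: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def n_evaluated(self) -> int:
        return len(self.results)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    def significant_labels(self) -> set[str]:
        return {r.label for r in self.results if r.significant}


def fingerprint_molecules(
    smiles: Sequence[str], n_bits: int = 2048
) -> np.ndarray:
    """Daylight-style hashed path fingerprints as a (n, n_bits) bool array.

    Deterministic function of the canonical SMILES; raises on unparseable
    input (callers fingerprint already-canonicalized datasets).
    """
    out = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at index {i}: {smi!r}")
        fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
        DataStructs.ConvertToNumpyArray(fp, out[i])
    return out.astype(bool)


def fingerprint_dataset(dataset: ChefDataset, n_bits: int = 2048) -> np.ndarray:
    return fingerprint_molecules([m.smiles for m in dataset.molecules], n_bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two binary fingerprints.

    Defined as 0.0 when both vectors are all-zero; raises on length
    mismatch.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)


def _pairwise_tanimoto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(|A|, |B|) Tanimoto matrix for two stacks of binary fingerprints."""
    A = A.astype(np.int32)
    B = B.astype(np.int32)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def max_tanimoto_to_set(
    query: np.ndarray, reference: np.ndarray, exclude_self: bool = False
) -> np.ndarray:
    """Per-query max Tanimoto similarity to a reference fingerprint stack.

    With ``exclude_self`` the two stacks are assumed identical and the
    diagonal is masked (each molecule's max over the *other* members).
    """
    sim = _pairwise_tanimoto(query, reference)
    if exclude_self:
        np.fill_diagonal(sim, -np.inf)
    return sim.max(axis=1)


def bh_fdr(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR correction.

    Returns ``(q_values, significant)`` where q_(i) = min_{j>=i} m·p_(j)/j
    capped at 1 and ``significant`` flags q < alpha.  Empty input yields
    empty output.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q < alpha


def _t_test(observed: np.ndarray, null: np.ndarray, welch: bool) -> tuple[float, float]:
    res = stats.ttest_ind(observed, null, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # zero variance in both samples (identical constants)
        t, p = 0.0, 1.0
    return t, p


def _null_sample(
    fps: np.ndarray,
    label_idx: np.ndarray,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random set of ``size`` molecules excluding the label's own, without
    replacement (one draw per label per screen)."""
    pool = np.setdiff1d(np.arange(fps.shape[0]), label_idx, assume_unique=False)
    if len(pool) < size:
        raise ValueError("null pool smaller than requested set size")
    return rng.choice(pool, size=size, replace=False)


def label_self_coherence(
    dataset: ChefDataset,
    label: str,
    cfg: CoherenceConfig | None = None,
    fps: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> CoherenceResult:
    """Does a label's molecule set cluster in structure space?

    observed[i] = max Tanimoto from label molecule i to the other label
    molecules; null[i] = max Tanimoto from molecule i to one random
    equal-sized set of non-label molecules.  Two-sided independent t-test.
    Raises for labels with fewer than two molecules or an empty null pool.
    """
    cfg = cfg or CoherenceConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if fps is None:
        fps = fingerprint_dataset(dataset, cfg.n_bits)
    idx = dataset.molecules_with_label(label)
    if len(idx) < 2:
        raise ValueError(f"label {label!r} borne by fewer than 2 molecules")
    null_idx = _null_sample(fps, idx, len(idx), rng)
    observed = max_tanimoto_to_set(fps[idx], fps[idx], exclude_self=True)
    null = max_tanimoto_to_set(fps[idx], fps[null_idx])
    t, p = _t_test(observed, null, cfg.welch)
    return CoherenceResult(label=label, observed=observed, null=null, t_stat=t, p_value=p)


def label_cooccurrence_coherence(
    dataset: ChefDataset,
    graph: LabelGraph,
    label: str,
    cfg: CoherenceConfig | None = None,
    fps: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> CoherenceResult:
    """Is a label's co-occurrence neighborhood also its structural one?

    observed[i] = max Tanimoto from label molecule i to the molecules
    bearing any of the label's top co-occurring labels (abundance-capped;
    the molecule itself is excluded if it bears a neighbor label); null[i]
    as in the self screen.  Raises when no eligible neighbor exists.
    """
    cfg = cfg or CoherenceConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if fps is None:
        fps = fingerprint_dataset(dataset, cfg.n_bits)
    neighbors = top_cooccurring(graph, label, k=cfg.k_neighbors, max_abundance=cfg.max_abundance)
    if not neighbors:
        raise ValueError(f"label {label!r} has no eligible co-occurring neighbor")
    idx = dataset.molecules_with_label(label)
    target = np.unique(np.concatenate([dataset.molecules_with_label(n) for n in neighbors]))
    sim = _pairwise_tanimoto(fps[idx], fps[target])
    # a molecule may bear a neighbor label: mask the self column
    for row, i in enumerate(idx):
        cols = np.where(target == i)[0]
        if cols.size:
            sim[row, cols] = -np.inf
    observed = sim.max(axis=1)
    finite = np.isfinite(observed)
    if not np.all(finite):  # target set collapsed onto the molecule itself
        observed = np.where(finite, observed, 0.0)
    null_idx = _null_sample(fps, idx, len(target), rng)
    null = max_tanimoto_to_set(fps[idx], fps[null_idx])
    t, p = _t_test(observed, null, cfg.welch)
    return CoherenceResult(label=label, observed=observed, null=null, t_stat=t, p_value=p)


def run_coherence_screen(
    dataset: ChefDataset,
    cfg: CoherenceConfig | None = None,
    graph: LabelGraph | None = None,
    fps: np.ndarray | None = None,
) -> ScreenSummary:
    """Run the configured screen over every eligible label with joint FDR.

    Labels failing preconditions (too few molecules, whole-dataset
    coverage, no eligible neighbor) are excluded from the FDR family and
    listed in ``skipped`` with a reason; BH-FDR is applied jointly across
    the evaluated labels and ``significant`` flags q < alpha.
    """
    cfg = cfg or CoherenceConfig()
    if cfg.mode == "cooccurrence" and graph is None:
        from chef.landscape_graph import count_cooccurrence

        graph = count_cooccurrence(dataset)
    if fps is None:
        fps = fingerprint_dataset(dataset, cfg.n_bits)
    rng = np.random.default_rng(cfg.seed)
    results: list[CoherenceResult] = []
    skipped: dict[str, str] = {}
    for label in dataset.vocabulary:
        try:
            if cfg.mode == "self_cluster":
                res = label_self_coherence(dataset, label, cfg, fps=fps, rng=rng)
            else:
                res = label_cooccurrence_coherence(dataset, graph, label, cfg, fps=fps, rng=rng)
        except ValueError as exc:
            skipped[label] = str(exc)
            continue
        results.append(res)
    if results:
        q, sig = bh_fdr([r.p_value for r in results], cfg.alpha)
        for r, qi, si in zip(results, q, sig):
            r.q_value = float(qi)
            r.significant = bool(si)
    logger.info(
        "%s screen: %d/%d labels significant at FDR %g (%d skipped)",
        cfg.mode,
        sum(r.significant for r in results),
        len(results),
        cfg.alpha,
        len(skipped),
    )
    return ScreenSummary(results=results, skipped=skipped, alpha=cfg.alpha)


def screen_to_frame(summary: ScreenSummary):
    """Results as a DataFrame (label, n, means, t, p, q, significant)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "n_molecules": r.n_molecules,
                "mean_observed": r.mean_observed,
                "mean_null": r.mean_null,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in summary.results
        ]
    )
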
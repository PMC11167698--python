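"""Label co-occurrence graph: the text-based chemical function landscape.

Labels are nodes; the weight of edge (a, b) counts the molecules annotated
with both a and b.  Modularity (Louvain) communities over this graph expose
broad fields of functionality, and per-label neighborhoods feed the
co-occurrence coherence screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from chef.corpus_io import ChefDataset
from chef.llm_interface import TextModelBackend, build_community_prompt

logger = logging.getLogger(__name__)

__all__ = [
    "LabelGraph",
    "count_cooccurrence",
    "detect_communities",
    "top_cooccurring",
    "name_communities",
    "export_graph",
]

DEFAULT_RESOLUTION = 0.5


@dataclass
class LabelGraph:
    """Weighted label co-occurrence graph with an optional community map."""

    graph: nx.Graph
    community: dict[str, int] = field(default_factory=dict)
    resolution: float = DEFAULT_RESOLUTION

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def weight(self, a: str, b: str) -> int:
        """Co-occurrence count for (a, b); 0 when no edge."""
        if self.graph.has_edge(a, b):
            return int(self.graph.edges[a, b]["weight"])
        return 0

    def abundance(self, label: str) -> int:
        return int(self.graph.nodes[label]["abundance"])


def count_cooccurrence(dataset: ChefDataset) -> LabelGraph:
    """Count per-molecule label co-occurrence across the dataset.

    weight(a, b) = number of molecules whose label set contains both a and
    b; pairs never co-occurring get no edge.  Node attribute ``abundance``
    is the per-label molecule count, so weight(a, b) <= min(abundance).
    """
    X = sparse.csr_matrix(dataset.incidence, dtype=np.int64)
    co = (X.T @ X).tocoo()
    g = nx.Graph()
    abundance = np.asarray(X.sum(axis=0)).ravel()
    for lab, ab in zip(dataset.vocabulary, abundance):
        g.add_node(lab, abundance=int(ab))
    for i, j, w in zip(co.row, co.col, co.data):
        if i < j and w > 0:
            g.add_edge(dataset.vocabulary[i], dataset.vocabulary[j], weight=int(w))
    return LabelGraph(graph=g)


def detect_communities(
    graph: LabelGraph, resolution: float = DEFAULT_RESOLUTION, seed: int = 0
) -> dict[str, int]:
    """Louvain modularity communities at the given resolution (seeded).

    The partition covers every node (isolated nodes become their own
    communities); community indices are dense from 0, ordered by each
    community's lexicographically smallest label so the numbering is
    reproducible run-to-run.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        graph.community = {}
        return {}
    parts = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    parts = sorted(parts, key=min)
    community = {lab: i for i, part in enumerate(parts) for lab in part}
    graph.community = community
    graph.resolution = resolution
    return community


def top_cooccurring(
    graph: LabelGraph, label: str, k: int = 10, max_abundance: int = 1000
) -> list[str]:
    """The k most strongly co-occurring neighbor labels of ``label``.

    Neighbors with molecule abundance >= ``max_abundance`` are excluded:
    hyper-abundant labels co-occur with nearly everything and would drag
    every max-similarity to 1.  Sorted by descending weight, ties broken
    lexicographically; fewer than k returned when the neighborhood is
    small.
    """
    if label not in graph.graph:
        raise KeyError(f"unknown label: {label!r}")
    eligible = [
        (nbr, int(data["weight"]))
        for nbr, data in graph.graph[label].items()
        if graph.abundance(nbr) < max_abundance
    ]
    eligible.sort(key=lambda t: (-t[1], t[0]))
    return [nbr for nbr, _ in eligible[: max(k, 0)]]


def name_communities(
    graph: LabelGraph, backend: TextModelBackend | None = None, top_n: int = 3
) -> dict[int, str]:
    """Summary label per community.

    With a backend, the community-summarization prompt is applied to the
    member labels (ordered by descending abundance).  Without one — or on
    backend failure, flagged by a warning — the deterministic rule is used:
    the ``top_n`` most abundant members joined by " & " (abundance ties
    broken lexicographically).
    """
    if not graph.community:
        raise ValueError("communities not computed; run detect_communities")
    names: dict[int, str] = {}
    members_by_comm: dict[int, list[str]] = {}
    for lab, cid in graph.community.items():
        members_by_comm.setdefault(cid, []).append(lab)
    for cid, members in sorted(members_by_comm.items()):
        members = sorted(members, key=lambda lab: (-graph.abundance(lab), lab))
        if len(members) == 1:
            names[cid] = members[0]
            continue
        name = ""
        if backend is not None:
            system, user = build_community_prompt(members)
            try:
                name = backend.summarize(system, user).strip()
            except Exception as exc:  # noqa: BLE001
                logger.warning("community naming backend failed (%s); using mock rule", exc)
        if not name or name.lower() == "na":
            name = " & ".join(members[:top_n])
        names[cid] = name
    return names


def export_graph(graph: LabelGraph, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write Gephi-ready edge and node CSVs (integer weights, no normalization).

    Node attribute ``connectivity`` (degree) is the visualization size
    attribute; it is exported but nothing downstream depends on it.
    """
    out_prefix = Path(out_prefix)
    edges_path = out_prefix.with_name(out_prefix.name + "_edges.csv")
    nodes_path = out_prefix.with_name(out_prefix.name + "_nodes.csv")
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, "weight": int(d["weight"])}
            for a, b, d in sorted(graph.graph.edges(data=True))
        ]
    )
    nodes = pd.DataFrame(
        [
            {
                "label": lab,
                "abundance": graph.abundance(lab),
                "connectivity": graph.graph.degree(lab),
                "community": graph.community.get(lab, -1),
            }
            for lab in sorted(graph.graph.nodes)
        ]
    )
    edges.to_csv(edges_path, index=False)
    nodes.to_csv(nodes_path, index=False)
    return edges_path, nodes_path
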
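"""Molecule–patent corpus ingestion and the ChefDataset exchange format.

Reads molecule–patent association tables (SureChEMBL-style CSV/TSV with
``smiles`` and ``patent_id`` columns), canonicalizes SMILES with RDKit,
deduplicates by InChIKey, applies the per-molecule patent-count filter, and
loads/saves the molecule×label incidence structure used by every downstream
stage.  Molecules appearing in very many patents are excluded (the patents
are then mostly irrelevant to the molecule's own function), so the default
filter keeps molecules with fewer than 10 patents.
"""

from __future__ import annotations

import csv
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "ChefDataset",
    "IngestConfig",
    "IngestStats",
    "canonicalize_smiles",
    "inchikey_from_smiles",
    "resolve_cid",
    "dedupe_records",
    "filter_by_patent_count",
    "subsample_records",
    "read_molecule_patent_table",
    "load_chef_dataset",
    "save_chef_dataset",
]


def canonicalize_smiles(raw: str) -> str | None:
    """Canonicalize a SMILES string, preserving stereochemistry.

    Returns the RDKit canonical isomeric SMILES, or ``None`` (a rejection
    marker, not an exception) when the input does not parse.  Idempotent:
    canonical input maps to itself.
    """
    if not isinstance(raw, str) or not raw.strip():
        return None
    mol = Chem.MolFromSmiles(raw.strip())
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def inchikey_from_smiles(smiles: str) -> str:
    """27-character InChIKey for a (canonical) SMILES; raises on bad input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot compute InChIKey for unparseable SMILES: {smiles!r}")
    return Chem.MolToInchiKey(mol)


def resolve_cid(candidates: Iterable[int]) -> int:
    """Resolve conflicting compound identifiers by taking the largest.

    Raises ``ValueError`` on an empty candidate set (missing mapping).
    """
    cands = set(candidates)
    if not cands:
        raise ValueError("no CID candidates: missing compound mapping")
    return max(cands)


@dataclass
class MoleculeRecord:
    """One molecule: canonical SMILES, InChIKey, optional CID, its patents."""

    smiles: str
    inchikey: str
    patent_ids: set[str] = field(default_factory=set)
    cid: int | None = None

    @classmethod
    def from_smiles(
        cls, smiles: str, patent_ids: Iterable[str] = (), cid: int | None = None
    ) -> "MoleculeRecord":
        canonical = canonicalize_smiles(smiles)
        if canonical is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls(
            smiles=canonical,
            inchikey=inchikey_from_smiles(canonical),
            patent_ids=set(patent_ids),
            cid=cid,
        )


@dataclass
class IngestConfig:
    """Ingestion knobs.

    max_patents
        Exclusive upper bound on per-molecule patent count; molecules with
        ``len(patent_ids) >= max_patents`` are dropped (default 10, i.e.
        "fewer than 10 patents").
    sample_size
        Optional number of molecules to subsample after filtering.
    seed
        RNG seed for the subsample.
    """

    max_patents: int = 10
    sample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_patents < 1:
            raise ValueError("max_patents must be >= 1")


@dataclass
class IngestStats:
    n_rows: int = 0
    n_rejected: int = 0
    n_molecules: int = 0
    n_filtered_by_patent_count: int = 0


def dedupe_records(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """Merge records sharing an InChIKey: union patent sets, resolve CIDs.

    Order of first appearance is preserved; the merged dataset is invariant
    (up to molecule order) to the order of the input rows.
    """
    merged: dict[str, MoleculeRecord] = {}
    for rec in records:
        prev = merged.get(rec.inchikey)
        if prev is None:
            merged[rec.inchikey] = MoleculeRecord(
                smiles=rec.smiles,
                inchikey=rec.inchikey,
                patent_ids=set(rec.patent_ids),
                cid=rec.cid,
            )
        else:
            prev.patent_ids |= rec.patent_ids
            cids = {c for c in (prev.cid, rec.cid) if c is not None}
            prev.cid = resolve_cid(cids) if cids else None
    return list(merged.values())


def filter_by_patent_count(
    records: Sequence[MoleculeRecord], cfg: IngestConfig | None = None
) -> list[MoleculeRecord]:
    """Keep molecules with strictly fewer than ``cfg.max_patents`` patents.

    Pure, order-stable filter; the boundary count equals ``max_patents`` and
    is excluded.
    """
    cfg = cfg or IngestConfig()
    return [r for r in records if len(r.patent_ids) < cfg.max_patents]


def subsample_records(
    records: Sequence[MoleculeRecord], cfg: IngestConfig
) -> list[MoleculeRecord]:
    """Uniform random subsample of ``cfg.sample_size`` molecules (seeded)."""
    if cfg.sample_size is None or cfg.sample_size >= len(records):
        return list(records)
    rng = random.Random(cfg.seed)
    idx = sorted(rng.sample(range(len(records)), cfg.sample_size))
    return [records[i] for i in idx]


def read_molecule_patent_table(
    path: str | Path,
    cfg: IngestConfig | None = None,
    cid_resolver: Callable[[str], int | None] | None = None,
) -> tuple[list[MoleculeRecord], IngestStats]:
    """Read a CSV/TSV molecule–patent association table.

    Expects columns ``smiles`` and ``patent_id`` (one row per association).
    Malformed SMILES are rejected and counted, not raised.  Rows for the
    same structure are merged (union of patents).  ``cid_resolver`` is an
    optional injected InChIKey→CID lookup; offline, molecules simply carry
    no CID.
    """
    cfg = cfg or IngestConfig()
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    stats = IngestStats()
    raw_records: list[MoleculeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a 'smiles' column")
        for row in reader:
            stats.n_rows += 1
            canonical = canonicalize_smiles(row["smiles"])
            if canonical is None:
                stats.n_rejected += 1
                continue
            patents = {row["patent_id"]} if row.get("patent_id") else set()
            raw_records.append(
                MoleculeRecord(
                    smiles=canonical,
                    inchikey=inchikey_from_smiles(canonical),
                    patent_ids=patents,
                )
            )
    records = dedupe_records(raw_records)
    stats.n_molecules = len(records)
    kept = filter_by_patent_count(records, cfg)
    stats.n_filtered_by_patent_count = len(records) - len(kept)
    kept = subsample_records(kept, cfg)
    if cid_resolver is not None:
        for rec in kept:
            candidates = cid_resolver(rec.inchikey)
            if candidates is not None:
                rec.cid = candidates
    logger.info(
        "ingest: %d rows, %d rejected SMILES, %d molecules, %d dropped by patent filter",
        stats.n_rows,
        stats.n_rejected,
        stats.n_molecules,
        stats.n_filtered_by_patent_count,
    )
    return kept, stats


class ChefDataset:
    """Molecule×label binary incidence with an ordered label vocabulary.

    The central exchange format: an ordered list of molecules, an ordered
    list of unique lowercase labels, and a sparse boolean incidence matrix.
    Optionally carries per-molecule provenance (label → contributing patent
    IDs).
    """

    def __init__(
        self,
        molecules: Sequence[MoleculeRecord],
        vocabulary: Sequence[str],
        incidence: sparse.spmatrix | np.ndarray,
        provenance: list[dict[str, list[str]]] | None = None,
    ) -> None:
        self.molecules = list(molecules)
        self.vocabulary = list(vocabulary)
        self.incidence = sparse.csr_matrix(incidence, dtype=bool)
        self.provenance = provenance
        self._validate()

    def _validate(self) -> None:
        if self.incidence.shape != (len(self.molecules), len(self.vocabulary)):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.molecules)} molecules x {len(self.vocabulary)} labels"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("duplicate labels in vocabulary")
        keys = [m.inchikey for m in self.molecules]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate molecules by InChIKey")
        self._label_index = {lab: j for j, lab in enumerate(self.vocabulary)}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_label_sets(
        cls,
        molecules: Sequence[MoleculeRecord],
        label_sets: Sequence[Iterable[str]],
        provenance: list[dict[str, list[str]]] | None = None,
        vocabulary: Sequence[str] | None = None,
    ) -> "ChefDataset":
        """Build from per-molecule label sets; vocabulary sorted if absent."""
        sets = [set(s) for s in label_sets]
        if vocabulary is None:
            vocabulary = sorted(set().union(*sets) if sets else set())
        index = {lab: j for j, lab in enumerate(vocabulary)}
        rows, cols = [], []
        for i, labs in enumerate(sets):
            for lab in labs:
                if lab not in index:
                    raise ValueError(f"label {lab!r} not in vocabulary")
                rows.append(i)
                cols.append(index[lab])
        inc = sparse.csr_matrix(
            (np.ones(len(rows), dtype=bool), (rows, cols)),
            shape=(len(molecules), len(vocabulary)),
        )
        return cls(molecules, vocabulary, inc, provenance)

    # -- queries ---------------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_labels(self) -> int:
        return len(self.vocabulary)

    @property
    def n_pairs(self) -> int:
        """Number of molecule–label pairs (incidence nonzeros)."""
        return int(self.incidence.nnz)

    def label_set(self, i: int) -> set[str]:
        """Labels of molecule ``i``."""
        row = self.incidence.indices[
            self.incidence.indptr[i] : self.incidence.indptr[i + 1]
        ]
        return {self.vocabulary[j] for j in row}

    def label_sets(self) -> list[set[str]]:
        return [self.label_set(i) for i in range(self.n_molecules)]

    def molecules_with_label(self, label: str) -> np.ndarray:
        """Indices of molecules bearing ``label`` (dataset order)."""
        if label not in self._label_index:
            raise KeyError(label)
        col = self.incidence.getcol(self._label_index[label])
        return np.sort(col.nonzero()[0])

    def label_abundance(self) -> dict[str, int]:
        """Molecule count per label."""
        counts = np.asarray(self.incidence.sum(axis=0)).ravel()
        return {lab: int(c) for lab, c in zip(self.vocabulary, counts)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChefDataset):
            return NotImplemented
        return (
            [
                (m.smiles, m.inchikey, frozenset(m.patent_ids), m.cid)
                for m in self.molecules
            ]
            == [
                (m.smiles, m.inchikey, frozenset(m.patent_ids), m.cid)
                for m in other.molecules
            ]
            and self.vocabulary == other.vocabulary
            and (self.incidence != other.incidence).nnz == 0
            and self.provenance == other.provenance
        )


def save_chef_dataset(dataset: ChefDataset, path: str | Path) -> None:
    """Write a ChefDataset as JSON-lines: one molecule per row.

    Fields: ``smiles``, ``inchikey``, ``cid``, ``patents`` (sorted),
    ``labels`` (sorted), optional ``provenance``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for i, mol in enumerate(dataset.molecules):
            row: dict = {
                "smiles": mol.smiles,
                "inchikey": mol.inchikey,
                "cid": mol.cid,
                "patents": sorted(mol.patent_ids),
                "labels": sorted(dataset.label_set(i)),
            }
            if dataset.provenance is not None:
                row["provenance"] = {
                    k: sorted(v) for k, v in sorted(dataset.provenance[i].items())
                }
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def _parse_deposited_labels(cell: str) -> set[str]:
    """Parse the deposited CSV label cell: a python-set/list-like string."""
    cell = cell.strip()
    if not cell or cell in {"set()", "[]", "{}"}:
        return set()
    if cell[0] in "[{(" and cell[-1] in "]})":
        cell = cell[1:-1]
    return {tok.strip().strip("'\"") for tok in cell.split(",") if tok.strip().strip("'\"")}


def load_chef_dataset(
    path: str | Path,
    smiles_col: str = "smiles",
    labels_col: str = "summarizations",
    patents_col: str = "patent_ids",
    cid_col: str = "cid",
) -> ChefDataset:
    """Load a ChefDataset from JSON-lines (native dialect) or CSV.

    The CSV reader accepts the deposited molecule→label-set layout: one row
    per molecule with a ``smiles`` column and a ``summarizations`` column
    holding the label set as a bracketed, comma-separated string (column
    names configurable).  Duplicate InChIKeys merge their label and patent
    sets with a warning; malformed rows raise with their row number.
    """
    path = Path(path)
    molecules: list[MoleculeRecord] = []
    label_sets: list[set[str]] = []
    provenance: list[dict[str, list[str]]] = []
    have_prov = False
    seen: dict[str, int] = {}

    def add_row(rownum: int, smiles: str, labels: set[str], patents: set[str],
                cid: int | None, prov: dict[str, list[str]]) -> None:
        nonlocal have_prov
        canonical = canonicalize_smiles(smiles)
        if canonical is None:
            raise ValueError(f"{path}: row {rownum}: unparseable SMILES {smiles!r}")
        key = inchikey_from_smiles(canonical)
        if key in seen:
            logger.warning("%s: row %d: duplicate InChIKey %s; merging labels", path, rownum, key)
            i = seen[key]
            label_sets[i] |= labels
            molecules[i].patent_ids |= patents
            for lab, pats in prov.items():
                provenance[i].setdefault(lab, []).extend(pats)
            return
        seen[key] = len(molecules)
        molecules.append(MoleculeRecord(canonical, key, set(patents), cid))
        label_sets.append(set(labels))
        provenance.append(dict(prov))
        if prov:
            have_prov = True

    if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}:
        with open(path) as fh:
            for rownum, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: row {rownum}: malformed JSON ({exc})") from exc
                if "smiles" not in row:
                    raise ValueError(f"{path}: row {rownum}: missing 'smiles'")
                add_row(
                    rownum,
                    row["smiles"],
                    set(row.get("labels", [])),
                    set(row.get("patents", [])),
                    row.get("cid"),
                    {k: list(v) for k, v in row.get("provenance", {}).items()},
                )
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_col not in reader.fieldnames:
                raise ValueError(f"{path}: expected a {smiles_col!r} column")
            for rownum, row in enumerate(reader, start=2):
                labels = _parse_deposited_labels(row.get(labels_col, "") or "")
                patents = _parse_deposited_labels(row.get(patents_col, "") or "")
                cid_raw = (row.get(cid_col) or "").strip()
                cid = int(float(cid_raw)) if cid_raw else None
                add_row(rownum, row[smiles_col], labels, patents, cid, {})

    if not molecules:
        raise ValueError(f"{path}: empty dataset file")
    return ChefDataset.from_label_sets(
        molecules, label_sets, provenance if have_prov else None
    )
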
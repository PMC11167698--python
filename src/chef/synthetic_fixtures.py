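"""Synthetic molecule/patent fixtures with planted structure→label signal.

Emulates the premise that molecules and their derivatives are patented
together and therefore share patent-derived function labels: each family
is a distinct drug-like scaffold enumerated with small substituents (so
within-family Tanimoto similarity exceeds between-family similarity), each
family carries 1–3 planted canonical labels, and templated mock patents
mention those labels through surface forms from a synonym table.  A
deterministic mock text-model backend (keyword summarization, hash
embeddings with synonym clusters) closes the loop so the full pipeline
runs offline and reproducibly.

What this emulates — and what it does not: real patent legalese, label
ambiguity, multi-functional molecules and uneven family sizes are all
absent; passing on these fixtures demonstrates the machinery end-to-end,
not performance on real patent corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

from chef.corpus_io import ChefDataset, MoleculeRecord, canonicalize_smiles, inchikey_from_smiles
from chef.llm_interface import MockTextModelBackend, PatentDocument

__all__ = [
    "FixtureSpec",
    "FixtureMolecules",
    "DEFAULT_SYNONYM_TABLE",
    "FAMILY_LABEL_POOL",
    "RANDOM_LABEL_POOL",
    "generate_families",
    "generate_mock_patents",
    "mock_embedding",
    "make_mock_backend",
    "build_ground_truth_dataset",
]

# canonical label -> surface forms as they appear in patent prose; cleaning
# (lowercase, singularize, keep hyphens) maps every form back into this
# table, and the mock embeddings place all forms of a canonical in one
# tight cluster.
DEFAULT_SYNONYM_TABLE: dict[str, list[str]] = {
    "antiviral": ["antiviral", "antivirals", "anti-viral", "antivirus"],
    "antibacterial": ["antibacterial", "antibacterials", "anti-bacterial"],
    "antifungal": ["antifungal", "antifungals", "anti-fungal"],
    "analgesic": ["analgesic", "analgesics", "painkiller", "painkillers"],
    "anticancer": ["anticancer", "anti-cancer", "antitumor", "antitumour"],
    "herbicide": ["herbicide", "herbicides", "herbicidal"],
    "insecticide": ["insecticide", "insecticides", "insecticidal"],
    "anticoagulant": ["anticoagulant", "anticoagulants", "anti-coagulant"],
    "antidepressant": ["antidepressant", "antidepressants", "anti-depressant"],
    "antihistamine": ["antihistamine", "antihistamines", "anti-histamine"],
    "anesthetic": ["anesthetic", "anesthetics", "anaesthetic"],
    "diuretic": ["diuretic", "diuretics"],
    "vasodilator": ["vasodilator", "vasodilators", "vasodilating"],
    "antipsychotic": ["antipsychotic", "antipsychotics", "anti-psychotic"],
    "bronchodilator": ["bronchodilator", "bronchodilators"],
    "anticonvulsant": ["anticonvulsant", "anticonvulsants", "antiepileptic"],
    "antioxidant": ["antioxidant", "antioxidants", "anti-oxidant"],
    "immunosuppressant": ["immunosuppressant", "immunosuppressants", "immunosuppressive"],
    "antimalarial": ["antimalarial", "antimalarials", "anti-malarial"],
    "fluorophore": ["fluorophore", "fluorophores", "fluorescent"],
    "serotonin": ["serotonin", "serotonergic"],
    "dopamine": ["dopamine", "dopaminergic"],
    "kinase": ["kinase", "kinases"],
    "protease": ["protease", "proteases"],
    "polymerase": ["polymerase", "polymerases"],
    "electroluminescence": ["electroluminescence", "electroluminescent"],
    "surfactant": ["surfactant", "surfactants"],
    "adhesive": ["adhesive", "adhesives"],
    "lubricant": ["lubricant", "lubricants"],
    "pesticide": ["pesticide", "pesticides", "pesticidal"],
}

FAMILY_LABEL_POOL: list[str] = [
    "antiviral", "antibacterial", "antifungal", "analgesic", "anticancer",
    "herbicide", "insecticide", "anticoagulant", "antidepressant",
    "antihistamine", "anesthetic", "diuretic", "vasodilator",
    "antipsychotic", "bronchodilator", "anticonvulsant", "antioxidant",
    "immunosuppressant", "antimalarial", "fluorophore",
]

RANDOM_LABEL_POOL: list[str] = [
    "serotonin", "dopamine", "kinase", "protease", "polymerase",
    "electroluminescence", "surfactant", "adhesive", "lubricant", "pesticide",
]

# drug-like cores; {R} marks the enumerated substitution site
SCAFFOLD_TEMPLATES: list[str] = [
    "c1ccc(-c2ccc({R})cc2)cc1",                     # biphenyl
    "c1ccc2c(c1)cc({R})[nH]2",                      # 2-substituted indole
    "c1ccc2nc({R})ccc2c1",                          # 2-substituted quinoline
    "c1ccc2[nH]c({R})nc2c1",                        # benzimidazole
    "c1ccc2sc({R})cc2c1",                           # benzothiophene
    "c1ccc2oc({R})cc2c1",                           # benzofuran
    "C1CN(c2ccc({R})cc2)CCN1",                      # aryl-piperazine
    "c1ccc2cc({R})ccc2c1",                          # naphthalene
    "Cc1ccc(S(=O)(=O)Nc2ccc({R})cc2)cc1",           # tosyl-anilide
    "O=C(c1ccc({R})cc1)N1CCOCC1",                   # aroyl-morpholine
    "c1ccc(-c2ncc({R})cn2)cc1",                     # 2-phenylpyrimidine
    "O=C(Nc1ccc({R})cc1)c1ccccn1",                  # picolinanilide
]

SUBSTITUENTS: list[str] = [
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C",
    "OC", "OCC", "CO", "CCO", "N", "NC", "N(C)C", "C#N", "[N+](=O)[O-]",
    "C(F)(F)F", "CCl", "C=C", "CC#N", "OC(C)C",
]

_FILLER = (
    "The present invention relates to novel substituted heterocyclic "
    "compounds, processes for their preparation, intermediates thereof, and "
    "compositions comprising them together with pharmaceutically acceptable "
    "carriers and excipients. "
)


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic corpus.

    Defaults are the desk-scale benchmark conditions: 10 scaffold families
    of 20 molecules, 5% label noise (a molecule picks up one other family's
    label), no structure-independent random labels, seed 42.
    """

    n_families: int = 10
    family_size: int = 20
    n_random_labels: int = 0
    label_noise: float = 0.05
    synonym_table: dict[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYM_TABLE)
    )
    seed: int = 42
    embedding_dim: int = 64

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        if self.n_families > len(SCAFFOLD_TEMPLATES):
            raise ValueError(f"at most {len(SCAFFOLD_TEMPLATES)} families supported")
        if self.family_size > len(SUBSTITUENTS):
            raise ValueError(f"family_size at most {len(SUBSTITUENTS)}")
        if self.n_random_labels > len(RANDOM_LABEL_POOL):
            raise ValueError(f"at most {len(RANDOM_LABEL_POOL)} random labels")


@dataclass
class FixtureMolecules:
    """Generated molecules with their planted ground truth."""

    records: list[MoleculeRecord]
    labels: list[set[str]]          # per-molecule canonical ground truth
    family_id: list[int]
    family_labels: list[set[str]]   # per-family planted labels
    random_labels: list[str]        # structure-independent planted labels

    @property
    def planted_family_label_set(self) -> set[str]:
        return set().union(*self.family_labels) if self.family_labels else set()

    @property
    def planted_vocabulary(self) -> set[str]:
        return self.planted_family_label_set | set(self.random_labels)


def _family_label_assignment(n_families: int) -> list[set[str]]:
    """Family i carries 1 + (i mod 3) labels, drawn disjointly from the pool."""
    out: list[set[str]] = []
    cursor = 0
    for i in range(n_families):
        count = 1 + (i % 3)
        if cursor + count > len(FAMILY_LABEL_POOL):
            raise ValueError("family label pool exhausted; reduce n_families")
        out.append(set(FAMILY_LABEL_POOL[cursor : cursor + count]))
        cursor += count
    return out


def generate_families(spec: FixtureSpec | None = None) -> FixtureMolecules:
    """Enumerate scaffold families with planted labels.

    Every SMILES canonicalizes without rejection; families are built from
    distinct cores so within-family Tanimoto similarity exceeds
    between-family similarity (asserted by tests on every seed).  Label
    noise adds one *other* family's label to a molecule with probability
    ``label_noise``; random labels are assigned to uniform molecule subsets
    of size ``family_size``.
    """
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    records: list[MoleculeRecord] = []
    labels: list[set[str]] = []
    family_id: list[int] = []
    family_labels = _family_label_assignment(spec.n_families)

    for fam in range(spec.n_families):
        template = SCAFFOLD_TEMPLATES[fam]
        for sub in SUBSTITUENTS[: spec.family_size]:
            smiles = canonicalize_smiles(template.replace("{R}", sub))
            if smiles is None:
                raise AssertionError(f"fixture template produced invalid SMILES: {template} + {sub}")
            records.append(
                MoleculeRecord(smiles=smiles, inchikey=inchikey_from_smiles(smiles))
            )
            labels.append(set(family_labels[fam]))
            family_id.append(fam)

    # spurious cross-family labels at rate label_noise
    if spec.label_noise > 0 and spec.n_families > 1:
        for i in range(len(records)):
            if rng.random() < spec.label_noise:
                other = set().union(
                    *(family_labels[f] for f in range(spec.n_families) if f != family_id[i])
                )
                labels[i].add(rng.choice(sorted(other)))

    # structure-independent random labels
    random_labels = RANDOM_LABEL_POOL[: spec.n_random_labels]
    for lab in random_labels:
        for i in rng.sample(range(len(records)), min(spec.family_size, len(records))):
            labels[i].add(lab)

    return FixtureMolecules(
        records=records,
        labels=labels,
        family_id=family_id,
        family_labels=family_labels,
        random_labels=random_labels,
    )


def _surface(label: str, table: dict[str, list[str]], rng: random.Random) -> str:
    forms = table.get(label)
    return rng.choice(forms) if forms else label


def generate_mock_patents(
    fixture: FixtureMolecules, spec: FixtureSpec | None = None
) -> dict[str, PatentDocument]:
    """Templated patents mentioning each molecule's labels; assigns patent ids.

    Each molecule gets its own patent (title/abstract/description embedding
    surface forms of up to three of its labels; extra labels spill into
    additional patents), and each family shares one patent covering the
    family labels — shared ids exercise the per-patent summary cache.
    Family-patent descriptions are padded past 3500 characters so
    truncation is exercised.
    """
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed + 1)
    corpus: dict[str, PatentDocument] = {}

    family_patent_id: dict[int, str] = {}
    for fam, fam_labels in enumerate(fixture.family_labels):
        pid = f"WO-FAM{fam:03d}-A1"
        family_patent_id[fam] = pid
        mentions = ", ".join(
            _surface(lab, spec.synonym_table, rng) for lab in sorted(fam_labels)
        )
        corpus[pid] = PatentDocument(
            patent_id=pid,
            title=f"Substituted heterocyclic compounds as {mentions} agents",
            abstract=(
                f"Disclosed are compounds of formula (I) useful as {mentions} "
                "agents, and pharmaceutical compositions thereof."
            ),
            description=(_FILLER * 20)[:3000]
            + f" The compounds of the invention are potent {mentions} agents. "
            + _FILLER * 10,
        )

    for i, rec in enumerate(fixture.records):
        mol_labels = sorted(fixture.labels[i])
        chunks = [mol_labels[j : j + 3] for j in range(0, len(mol_labels), 3)] or [[]]
        pids = {family_patent_id[fixture.family_id[i]]}
        for c, chunk in enumerate(chunks):
            pid = f"US-{i:05d}{chr(ord('A') + c)}-B2"
            mentions = ", ".join(_surface(lab, spec.synonym_table, rng) for lab in chunk)
            corpus[pid] = PatentDocument(
                patent_id=pid,
                title=f"Preparation of compound {i} with {mentions} activity",
                abstract=(
                    f"The compound exhibits {mentions} activity in standard assays."
                ),
                description=(
                    _FILLER + f"In particular the compound shows {mentions} utility. " + _FILLER
                ),
            )
            pids.add(pid)
        rec.patent_ids = pids
    return corpus


def make_mock_backend(spec: FixtureSpec | None = None) -> MockTextModelBackend:
    """Deterministic backend wired to the fixture's synonym table."""
    spec = spec or FixtureSpec()
    return MockTextModelBackend(
        synonym_table=spec.synonym_table, dim=spec.embedding_dim, seed=spec.seed
    )


def mock_embedding(label: str, spec: FixtureSpec | None = None) -> np.ndarray:
    """Unit-norm mock embedding: synonym forms sit within 0.1 of their
    canonical anchor, distinct canonicals at least 0.8 apart."""
    return make_mock_backend(spec).embed(label)


def build_ground_truth_dataset(fixture: FixtureMolecules) -> ChefDataset:
    """ChefDataset straight from the planted labels (bypasses extraction)."""
    return ChefDataset.from_label_sets(fixture.records, fixture.labels)
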
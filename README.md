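# chef — patent-derived chemical function labels

`chef` builds and analyses **Chemical Function (CheF) datasets**: tables
pairing molecules with concise functional labels ("antiviral", "hcv",
"electroluminescence") mined from the patents that mention them. It is
aimed at cheminformaticians and drug-discovery scientists who want to move
between *textual* descriptions of what molecules do and *structural*
similarity — annotating function from structure alone, or querying a label
to retrieve candidate molecules.

The pipeline has four parts:

1. **Extraction** (`corpus_io`, `llm_interface`). Molecule–patent
   associations (SureChEMBL-style tables) are canonicalized with RDKit,
   deduplicated by InChIKey, and restricted to molecules with fewer than
   10 patents (over-patented molecules carry mostly irrelevant patents). A
   chat-model backend summarizes each patent's title, abstract and first
   3500 description characters into 1–3 short descriptors using a fixed
   prompt with a strict `{descriptor_1}/{descriptor_2}/{etc}` syntax. The
   backend is pluggable: a hosted-API client, or a deterministic mock
   (keyword matching + hashed embeddings) for fully offline, reproducible
   runs.
2. **Consolidation** (`label_processing`). Raw labels are cleaned to
   lowercase singular unigrams, embedded, and density-clustered (DBSCAN,
   Euclidean ε on unit-norm vectors; ε = 0.34 merges synonym clusters
   without collapsing distinct functions). Each cluster gets one
   representative name; labels on fewer than 50 molecules are dropped.
3. **Landscape & coherence** (`landscape_graph`, `structure_coherence`).
   Labels form a co-occurrence graph (edge weight = number of molecules
   bearing both labels) whose Louvain communities expose broad functional
   fields. Two statistics test congruence with structure space using
   2048-bit daylight path fingerprints. For a label *L* with molecules
   *M(L)*:

   - *self-clustering*: for each *m ∈ M(L)*, the max Tanimoto similarity
     `s(m) = max_{m' ∈ M(L), m' ≠ m} T(fp(m), fp(m'))` versus the same
     statistic against a random equal-sized molecule set;
   - *co-occurrence coherence*: the max similarity from each *m ∈ M(L)*
     to molecules bearing any of *L*'s 10 most co-occurring labels
     (each with abundance < 1000), versus the random null.

   Each label gets an independent two-sided *t*-test; Benjamini–Hochberg
   FDR is applied across labels at α = 0.05.
4. **Prediction** (`function_predictor`). Multi-label models (one-vs-rest
   logistic regression with C = 0.001, random forests, or a multi-output
   MLP) map fingerprints to label probabilities, evaluated by per-label
   and macro ROC-AUC / PR-AUC on a held-out 10% split, and support
   label-guided queries ("top 10 molecules for 'serotonin'") and
   per-molecule functional profiles.

A synthetic fixture generator (`synthetic_fixtures`) plants
scaffold-family → label associations with templated mock patents so every
stage runs and is tested offline.

## Worked example

Run the whole pipeline on the synthetic benchmark corpus (10 scaffold
families × 20 molecules, 5% label noise, mock backend):

```console
$ chef pipeline --out-dir demo --seed 42
simulated 200 molecules, 211 patents
summarized 211 patents (190 cache hits, 0 parse failures, 0 missing); 630 molecule-label pairs
consolidated to 19 labels over 200 molecules (388 pairs)
19 labels, 26 edges, 8 communities -> demo/landscape_edges.csv, demo/landscape_nodes.csv
19/19 labels significant at FDR 0.05 (0 skipped)
16/17 labels significant at FDR 0.05 (2 skipped)
macro ROC-AUC 0.988, macro PR-AUC 0.979 over 17 labels (2 skipped)
pipeline complete: artifacts in demo
```

Reading the numbers: the 211 mock patents compress to 630 raw
molecule–label pairs; cleaning and embedding-clustering consolidate the
raw surface forms (plurals, hyphen variants) back to exactly the 19
planted canonical labels. All 19 labels cluster significantly in structure
space (self screen), and 16 of the 17 labels with an eligible
co-occurrence neighborhood are structurally coherent with it. The logistic
model recovers the planted structure→function map almost perfectly
(macro ROC-AUC 0.988 on the held-out 10%).

The trained model annotates new structures:

```console
$ chef predict --model demo/model.joblib --smiles "c1ccc2c(c1)cc(C(F)(F)F)[nH]2" --top 3
antibacterial   0.2027
antifungal      0.1955
analgesic       0.1805
```

The query molecule is a trifluoromethyl-indole; the top two predictions
are exactly the labels planted on the indole scaffold family.

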
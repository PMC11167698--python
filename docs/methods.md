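# Methods

This note documents the models and procedures `chef` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Corpus ingestion

Molecule–patent tables are read row-per-association. SMILES are
canonicalized to RDKit canonical isomeric form; unparseable strings are
*rejected and counted*, never raised, since upstream patent-mined tables
always contain a malformed tail. Identity is the InChIKey: rows sharing a
key merge their patent sets (union), making ingestion invariant to row
order. Conflicting PubChem CIDs resolve to the larger identifier (newer
records supersede legacy ones). Molecules with no resolvable CID are
kept.

The per-molecule patent-count filter is **exclusive**: a molecule is kept
iff it appears in fewer than `max_patents` (default 10) patents. The bound
exists because heavily patented molecules (penicillin-class compounds
appear in tens of thousands of patents) are mostly mentioned for reasons
unrelated to their own function, which dilutes label quality. The boundary
count is excluded.

Dataset files are JSON-lines (`smiles`, `inchikey`, `cid`, `patents`,
`labels`, optional `provenance`), one molecule per row; the loader also
accepts the deposited CSV layout (one row per molecule, label set in a
`summarizations` column as a bracketed string; column names are
parameters).

## Label extraction

Each patent's title, abstract and the first `description_chars` (default
3500) characters of its whitespace-normalized description are embedded in
a fixed summarization prompt asking for up to three 1–3-word functional
descriptors in `{a}/{b}/{c}` syntax. The 3500-character cut keeps the
part of a patent description that typically states background, mechanism
and a claim summary, and bounds token cost. Truncation is applied *after*
collapsing whitespace runs, so formatting noise does not consume the
budget.

Response parsing is lenient-with-audit: slash syntax is primary; a
response without separators that looks like a single descriptor is
accepted; anything else is recovered by newline/comma splitting and
**flagged** rather than dropped silently. "NA" and empty tokens are
removed. Parsing never raises; the audit counters (parse failures,
missing patents, backend failures) are the quality signal.

Per-patent summaries are cached by patent id, so patents shared between
molecules are summarized once; a molecule's label set is the union over
its patents, with provenance mapping each label to its contributing
patents. A backend failure on one patent skips that patent, not the
molecule.

Backends implement `summarize(system, user)` and `embed(text)`. The
HTTP backend targets a hosted chat/embedding API and is deliberately
untested offline. The mock backend is the test instrument: keyword
matching over a known synonym vocabulary (longest-match, capped at three
labels, `NA` otherwise) and seeded-hash unit-norm embeddings in which all
surface forms of a canonical label sit within Euclidean distance 0.1 of a
fixed anchor while distinct canonicals sit ≥ 0.8 apart.

## Vocabulary consolidation

Cleaning: split on whitespace (hyphens kept), lowercase, singularize,
drop single-character tokens, union. Singularization is a frozen rule
set — strip trailing "s" except after "ss"/"us"/"is", "ies"→"y", "es"
after a sibilant dropped, plus a short exception list ("virus",
"diabetes", …) — rather than an external lemmatizer, so the vocabulary is
bit-reproducible. Hyphenated variants ("anti-viral") are left intact; the
embedding clustering, not string surgery, merges them with their plain
forms.

Clustering is DBSCAN with Euclidean metric on unit-norm embeddings.
Euclidean distance on unit vectors is monotone with cosine distance
(`d² = 2(1−cos)`), which makes a single ε meaningful across the
vocabulary; ε = 0.34 is the default radius, the value at which synonym
clusters merge while distinct functions (antiviral vs antibacterial vs
antifungal) stay apart in the original ada-002 embedding geometry.
`min_samples = 2` lets any synonym *pair* form a cluster; DBSCAN noise
points are kept as singleton labels, not discarded — an unclustered label
is still a label. Cluster ids are re-indexed densely in first-occurrence
order. `sweep_epsilon` tabulates (ε, n_clusters, n_noise) over a grid;
the ε choice stays a human/config decision over that table.

Each cluster is named by the backend through a centroid-descriptor
prompt (mock rule: most frequent canonical among the members, ties
lexicographic; fallback on backend failure: shortest member, flagged).
Consolidation then proceeds in a fixed order: map molecule labels to
representatives (per-molecule sets deduplicate) → drop representatives
on fewer than `min_label_count` molecules (default 50; labels rarer than
that cannot support a per-label classifier) → drop single-character
labels. Molecules left label-less are retained with empty sets, keeping
molecule indices stable. Clusters of pure structural nomenclature (IUPAC
fragments) can be removed via a representative blocklist; the blocklist
is configuration because identifying such clusters is an inspection
step, not an algorithm.

## Co-occurrence landscape

Edge weight between two labels counts molecules bearing both;
zero-weight pairs get no edge, weights stay raw integers (no
normalization), and `w(a,b) ≤ min(abundance(a), abundance(b))` by
construction. Communities come from Louvain modularity maximization at
resolution 0.5 with an explicit seed; community indices are ordered by
each community's smallest label so partitions are stable run-to-run.
Exact community counts are implementation-dependent (different Louvain
implementations yield different local optima), so tests assert structural
recovery on planted block graphs, not counts. No minimum-edge-weight
threshold is applied before community detection (configurable upstream
by filtering the dataset). Node degree is exported as a visualization
size attribute and is not load-bearing.

Per-label neighborhoods (`top_cooccurring`) take the k = 10 heaviest
neighbors with abundance `< 1000`; the cap exists because hyper-abundant
labels ("inhibitor") co-occur with nearly everything and force the
max-similarity statistic to 1.0 regardless of real structure. Ties break
lexicographically.

## Structure-coherence screens

Fingerprints are RDKit `RDKFingerprint` hashed-path vectors at 2048 bits
(the method family fixes path hashing; the length is our choice — long
enough that the benchmark's scaffolds rarely collide). Similarity is the
Tanimoto coefficient with the 0/0 case defined as 0. The screen
implementation vectorizes max-similarity queries as integer matrix
products; a brute-force set-intersection oracle backs it in tests.

Self-clustering mode: observed[i] is molecule i's max similarity to the
*other* molecules bearing the label — the self-comparison is excluded,
otherwise every observed value is trivially 1.0. Co-occurrence mode:
observed[i] is the max similarity to the union of the neighborhood
labels' molecules, again masking molecule i itself if it happens to bear
a neighbor label. The null in both modes is the max similarity to one
random set of non-label molecules of matching size, drawn without
replacement, one draw per label per screen (drawing per molecule would
shrink null variance and anti-conservatively sharpen the test). The
abundance cap applies only to the co-occurrence neighborhood, not to the
self screen, where the label's own molecule set is the object under
test.

Each label is tested with an independent two-sided two-sample *t*-test
(pooled variance by default, Welch by config); identical constant samples
are reported as t = 0, p = 1 rather than NaN. Labels failing
preconditions — fewer than two molecules, no null pool, no eligible
neighbor — are excluded from the FDR family and reported with reasons,
rather than assigned p = 1 (which would distort the BH ordering).
Benjamini–Hochberg q-values (step-up, `q(i) = min_{j≥i} m·p(j)/j`) are
computed via statsmodels across the evaluated labels jointly;
significance is q < α with α = 0.05.

Calibration: with labels assigned independently of structure the pre-FDR
rejection rate at 0.05 sits in the binomial band [0.03, 0.07] over 500
simulated labels (the observed/null set sizes differ by one — m−1 other
members vs m null molecules — a negligible asymmetry at the benchmark
label size of 20).

## Function prediction

`FunctionPredictor` is a scikit-learn-style estimator over three model
kinds with fixed winning hyperparameters: one-vs-rest logistic regression
(C = 0.001, max_iter = 1000), one-vs-rest random forests (100 trees,
depth 10), and a single multi-output MLP ((512, 256) hidden units, 5
epochs, batch 32, learning rate 0.001) trained on a multilabel indicator
target, i.e. a shared trunk under binary cross-entropy. The MLP is
scikit-learn's `MLPClassifier`; a `dropout` parameter is accepted for
config compatibility but has no effect there, and the few-epoch regime is
the regularizer in practice. Hyperparameter search is out of scope; the
defaults are hard.

Labels with no positive (or no negative) training example are
*untrainable*: they are skipped at fit time, predicted at their training
prevalence, and excluded from macro averages (macro ROC-AUC/PR-AUC are
unweighted means over labels with at least one positive and one negative
test example; skipped counts are reported). The held-out split is a
uniform random 10% by seed, disjoint and exhaustive. Ranking uses
predicted class-1 probability with ties broken by dataset order (stable
sort) for reproducibility; features are binarized 2048-bit fingerprints.

## Synthetic benchmark

The generator emulates the mechanism that makes patent mining work:
derivatives of a scaffold are patented together and therefore share
functional labels. Each family is one of 12 hard-coded drug-like cores
(biphenyl, indole, quinoline, benzimidazole, benzothiophene, benzofuran,
aryl-piperazine, naphthalene, tosyl-anilide, aroyl-morpholine,
phenylpyrimidine, picolinanilide) enumerated over 24 small substituents,
giving within-family Tanimoto similarity well above between-family
similarity (verified by direct computation per seed, not assumed).
Families carry 1–3 disjoint planted labels; label noise adds one other
family's label to a molecule at the configured rate; optional
structure-independent "random" labels are planted as negative controls.
Mock patents embed synonym surface forms of each molecule's labels in
templated title/abstract/description text, with one shared family patent
(exercising the summary cache) and descriptions padded past the
truncation length.

Defaults are the benchmark study conditions: 10 families × 20 molecules,
5% label noise, no random labels, seed 42, all randomness flowing from
the single spec seed. At this scale the full mock pipeline runs in a few
seconds, recovers the planted canonical vocabulary exactly, flags exactly
the planted labels in the self-coherence screen, and reaches macro
ROC-AUC ≈ 0.99 over planted labels.

What passing does *not* show: the mock corpus has clean, unambiguous
label mentions, uniform family sizes, no multi-functional molecules, no
prophetic-claim noise and no patent legalese; real-corpus performance
depends on the hosted language model and is not certified by these
tests. Fused bicyclic cores are genuinely similar under path
fingerprints, so small families (≈10 molecules) can fail to separate in
the co-occurrence screen — the benchmark's 20-molecule families are the
intended operating point.

## Degenerate inputs and tie-breaks

Empty datasets, empty label responses, edgeless graphs, all-zero
fingerprints, single-member clusters and constant score vectors all have
defined behavior (error with context, empty result, or documented
convention) rather than silent NaNs; ROC-AUC of constant scores is 0.5
by the pairwise tie convention. All orderings that affect output files
(vocabulary, cluster ids, community ids, rankings) have deterministic
tie-breaks, making repeated runs byte-identical for fixed seeds.

## Known limitations

- The deposited full-scale dataset is an external download; desk-scale
  tests certify the machinery, not the published counts, which are only
  recomputed when that file is present.
- Singularization is rule-based English; labels in other languages or
  irregular plurals outside the exception list pass through unchanged
  (and typically merge later via embeddings).
- The per-label t-test treats max-similarity samples as independent;
  molecules sharing near-duplicates violate this mildly, as in the
  original screen design.
- No label ontology or hierarchy is constructed; representatives are
  flat.
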
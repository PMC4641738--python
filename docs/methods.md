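# Methods

## Model and assumptions

cogannot annotates nucleotide reads by translated homology against a
protein database in which every sequence carries an orthologous-group
(COG) identifier and one or more of the 25 single-letter functional
category codes (J, A, K, L, B, D, Y, V, T, M, N, Z, W, U, O, C, G, E,
F, H, I, P, Q, R, S). The core assumptions are the standard ones of
read-level functional annotation: a read originates from (part of) a
protein-coding region; its best sub-threshold translated alignment
identifies the source family; and family membership is a sufficient
carrier for function, so terms attached to the family (KEGG, Pfam,
GO, SEED) transfer to the read without further sequence comparison.

### Search phase

Reads are translated in six frames under the standard genetic code.
Codons containing N translate to X, which scores at most −1 against
every residue and is never counted as an identity; stop codons are
rendered `*` and **segment** the frame — a local alignment never
crosses a stop. The alternative (treating `*` as X) was rejected
because it permits spurious extensions through what is, biologically,
a frame boundary.

Alignment is full Smith–Waterman with affine gaps (BLOSUM62, gap open
−11, extend −1; a gap of length k costs 11 + k, the BLAST
convention), implemented as a numba kernel. Statistics use the
Karlin–Altschul formula `E = K·m·n·exp(−λS)` with the standard gapped
BLOSUM62 constants λ = 0.267, K = 0.041. These constants are fixed,
not fitted; the resulting e-values are approximate, which is
acceptable because every decision the workflows make compares
e-values produced by the same engine. `m` is the full translated
frame length (stops included), `n` the total residue count of the
database actually searched — so stage-2 partition searches see a
smaller `n`, and e-values scale linearly with database size as they
should.

Hit selection: smallest e-value, then larger raw score, then
lexicographic subject id, then frame order (+1,+2,+3,−1,−2,−3). The
default acceptance threshold is E < 1e-5, the conventional cut-off
for translated searches of short reads; it is exposed as `--evalue`.

Co-optimal local alignments are reported deterministically: the
kernel takes the maximum-scoring cell with the smallest (query end,
subject end) in row-major order and prefers diagonal moves, then gaps
in the query, then gaps in the subject, during traceback. Scores —
the only quantity downstream logic consumes — are unaffected by this
choice.

### Engine modes

*exact* aligns every frame segment against every subject. *heuristic*
first collects subjects sharing at least one k-peptide word (default
k = 4) with any frame segment and aligns only those; it can therefore
miss hits but never invents or rescores one (a property the test
suite asserts). *external* consumes pre-computed 12-column tabular
hits, with the same best-hit rule applied to the rows. Workflow
options 1/3 use exact, 2/4 heuristic.

### Reduced database and directed search

For the directed options, each category's proteins are clustered
greedily: visit in decreasing length (ties: lexicographic id); join
the first cluster whose founder you match at ≥ 60 % identity, else
found a new cluster. Identity is CD-HIT-style — matched columns of
the best local alignment divided by the shorter sequence's length.
Normalising by the shorter sequence rather than by alignment columns
is essential: a bare local alignment of unrelated proteins almost
always contains some short perfect-match run, so column-normalised
identity would merge everything. The 0.6 default separates the
synthetic ~80 %-identical families from unrelated sequences with a
wide margin and is a config key, not a constant.

The longest member of each cluster (ties: smallest id) becomes the
representative, tagged with the single category it was clustered
under; representatives are re-identified as `<id>__<category>` so a
protein representing clusters in two categories yields two distinct
tagged records. A provenance table maps each representative to its
members. Multi-category proteins are clustered once per category;
clustering globally instead would break the single-tag semantics that
stage 1 depends on. The size reduction achieved is a property of the
input database and is logged, never enforced.

Stage 1 searches the reduced database; the winner's tag is the
read's tentative category. Stage 2 searches the union of the full
database partitions for all of the winner's categories (a singleton
by construction here, but the union generalises). A stage-1 miss
leaves the read unassigned; a stage-2 miss records the tentative
category and, by default, does **not** fall back to a full-database
search — that keeps the directed options' cost bounded, and
`--fallback-full` enables the alternative. Reads are processed
independently; batching reads by stage-1 category is a scheduling
detail with no effect on results.

### Cross-mapping store

Mapping rows carry a source class: `curated_import` (mined reference
tables) or `homology` (sequence-search-derived). Per (COG, namespace)
the two classes' term sets are unioned when they agree or when only
one contributes; when both contribute and differ, the homology set is
kept wholesale and the conflict logged. This set-granularity
resolution is the strictest reading of "the sources disagree", and
the precedence rule is applied uniformly across namespaces. GO terms
are additionally composed through the kept Pfam set and a
pfam2go-style table, then merged with direct GO rows. GO terms are
not propagated up the ontology, and no confidence scores are modelled
on homology-derived rows. The mapping phase is pure lookup; a module
counter lets tests verify that annotating reads performs zero
alignment operations.

### Validation harness

Confusion counting is read-level. For a multi-label namespace a read
is TP when tool and benchmark term sets intersect, FP when the tool
labels but the benchmark is empty or disjoint, TN when both are
empty, FN when only the benchmark labels. The intersect-counts-as-TP
convention is the package's declared choice; `strict=True` switches
to set equality so sensitivity to the convention can be measured.
PPV = TP/(TP+FP) and NPV = TN/(TN+FN); an empty denominator yields an
explicit undefined marker (`None`, printed `NA`) rather than 0 or 1,
so averages are never silently biased. Profile correlation builds
count vectors over the union of term sets (absent term → 0) and uses
the two-sided t-test for Pearson's r with n−2 degrees of freedom; it
requires at least 3 union terms and non-zero variance.

## Synthetic data: what it emulates and what it does not

The generator builds, per category, a configurable number of
orthologous groups; each group is a random 120-residue ancestor
(i.i.d. uniform over the 20 amino acids) with members derived by
per-site substitution at rate 0.1 — giving ~81 % expected pairwise
member identity, comfortably above the 0.6 clustering threshold and
far from the background. Reads take a codon-aligned window of a
uniformly chosen protein, reverse-translate it with uniformly random
synonymous codons (no codon-usage model — the simplest scheme that
exercises frame logic), apply i.i.d. nucleotide substitutions, and
land on the reverse strand with probability 0.5. Read lengths round
down to whole codons. The truth cross-map is bijective per namespace,
so derived-annotation accuracy against truth equals COG accuracy by
construction, isolating mapping-phase correctness from
mapping-content quality. All outputs are pure functions of the
configuration, including its seed.

Real data differ in ways the generator deliberately ignores: proteins
are not i.i.d. random (real families share domains across groups, so
cross-group hits occur), read starts are not codon-aligned, indel
errors and chimeras exist, abundances are skewed, and quality scores
are informative. Passing tests therefore demonstrate that the
machinery is correct under planted-signal conditions — they do not
certify accuracy rates on real metagenomes.

## Problem sizes and numerical choices

The self-consistency benchmark runs 500 planted error-free 150 nt
reads plus 50 random-base reads against the default 150-protein
database; the stage-1 partition count uses 20 error-free reads per
category. These sizes give every category and both outcome classes
ample representation while keeping an exhaustive (all-frames ×
all-subjects) search cheap. E-value underflow is clamped to the
smallest positive double so e-values remain strictly positive;
degenerate inputs (reads < 3 nt, empty databases, empty peptides,
empty partitions) raise or warn explicitly rather than returning
silent empties, as documented per operation.

## Known limitations

* The built-in engines are a faithful but compact stand-in for
  production translated-search tools; no reduced-alphabet
  compression, double indexing, X-drop extension or
  composition-based statistics are implemented.
* E-values use fixed Karlin–Altschul constants and are not calibrated
  per scoring scheme or composition.
* GO ancestors are not expanded; benchmark evaluation of GO is
  intentionally unsupported (its mappings are definitionally curated,
  so a homology benchmark would be circular).
* The clustering substitute is greedy single-pass; it is deterministic
  and documented, but it is not a reimplementation of any particular
  published clustering tool's cut criterion.
* No paired-end awareness, quality trimming or SAM/BAM support.
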
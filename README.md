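# cogannot

Functional annotation of metagenomic and metatranscriptomic reads,
built around a single translated homology search against a COG-tagged
protein database. One search yields five annotation namespaces: the
COG orthologous group and its functional category, plus KEGG, Pfam,
GO and SEED terms derived through a precomputed cross-mapping store —
so a functional profile of a read set costs one database search
instead of five.

It is aimed at researchers who need stand-alone, scriptable
annotation of community sequence data without shipping reads to a web
service, and at method developers who want a compact, fully testable
model of the COG-centred annotation workflow.

## The method

**Search phase.** Each nucleotide read is translated in all six
reading frames; stop codons segment the frames, and every stop-free
peptide segment is aligned locally (Smith–Waterman, affine gaps,
BLOSUM62) against the tagged protein database. Raw scores `S` become
e-values with the Karlin–Altschul formula

    E = K · m · n · e^(−λS),        bit score = (λS − ln K) / ln 2

with `m` the translated query length, `n` the database residue count
and gapped-BLOSUM62 constants λ = 0.267, K = 0.041. The read takes
the COG of the best hit with `E` below a threshold (default 1e-5).

**Four workflow options.**

1. exact search of the full database;
2. seeded heuristic search (shared k-peptide words prefilter the
   subjects) of the full database — faster, may miss but never
   invents hits;
3. **directed two-stage search**: stage 1 searches a *reduced*
   database of cluster representatives (each category's proteins
   greedily clustered at 60 % identity, longest member kept and
   tagged) to fix a tentative category; stage 2 searches only that
   category's slice of the full database — a much smaller search
   space at a bounded accuracy cost;
4. as 3 but with the heuristic engine in both stages.

Pre-computed hits from an external engine (12-column tabular format)
can stand in for the built-in search in options 1/2.

**Mapping phase (shared).** A cross-mapping store built from curated
imports and homology-derived tables (homology wins on conflict;
Pfam→GO composition fills the GO namespace) expands every COG call
into KEGG/Pfam/GO/SEED terms by pure lookup — no further alignment.

**Validation harness.** Read-level confusion counting against a
benchmark annotation gives PPV = TP/(TP+FP) and NPV = TN/(TN+FN) per
namespace; Pearson correlation compares the functional profiles two
options produce.

A synthetic-data module generates a miniature tagged database (25
categories × orthologous groups × mutated members), a bijective truth
cross-map and reads of known provenance, so the whole pipeline is
testable without external downloads.

## Worked example

```
$ cogannot simulate --out-dir demo --seed 7 --n-categories 6 --n-reads 40
wrote 36 proteins, 40 reads to demo

$ cogannot build-db --db demo/database.faa --out demo/reduced.faa \
      --provenance demo/clusters.tsv
36 proteins -> 12 representatives

$ cogannot annotate --reads demo/reads.fastq --db demo/database.faa \
      --reduced-db demo/reduced.faa --xmap demo/crossmap.tsv \
      --option 3 --out demo/annotations.tsv --profile demo/profile.tsv
40/40 reads assigned a COG

$ head -4 demo/annotations.tsv
# multi-value separator ';'; missing value '-'
read_id	cog	category	kegg	pfam	go	seed
R00001	COG0011	D	K00011	PF00011	GO:0000011	SEED:0011
R00002	COG0004	A	K00004	PF00004	GO:0000004	SEED:0004
```

The simulated database has 6 categories × 2 groups × 3 proteins;
clustering collapses each 3-member group to its longest
representative (36 → 12). Every error-free 150 nt read is assigned
its source group, and the cross-map expands each COG call into one
term per derived namespace. Evaluating the directed option against a
direct full-database (option 1) benchmark:

```
$ cogannot annotate --reads demo/reads.fastq --db demo/database.faa \
      --xmap demo/crossmap.tsv --option 1 --out demo/benchmark.tsv \
      --profile demo/profile1.tsv
$ cogannot evaluate --tool demo/annotations.tsv \
      --benchmark demo/benchmark.tsv --out demo/metrics.tsv
$ cat demo/metrics.tsv
namespace	TP	FP	TN	FN	PPV	NPV
COG	40	0	0	0	1.0000	NA
KEGG	40	0	0	0	1.0000	NA
PFAM	40	0	0	0	1.0000	NA
SEED	40	0	0	0	1.0000	NA
```

PPV 1.0000 means every read the directed search annotated agrees with
the benchmark; NPV is `NA` (undefined, not 0 or 1) because this read
set has no unannotated reads. The profiles of the two options
correlate perfectly:

```
$ cogannot correlate --a demo/profile.tsv --b demo/profile1.tsv --namespace COG
COG	r=1.0000	p=4.25e-78
```

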
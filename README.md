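# reciblast

Reciprocal all-vs-all BLAST analysis: run or import paired (A→B, B→A)
searches between two sequence datasets, filter the hit tables reversibly,
and interrogate them with set operations — shared hits, reciprocally
matched pairs, reciprocal best hits, and multi-region matches.

## Who this is for

Comparing two sequence sets against each other is a routine step in
ortholog candidate detection, domain sharing analysis, exon/transcript
mapping and regulatory-element screening. The raw output of two
directional BLAST searches is awkward to mine by hand: hits must be
cross-referenced between directions, filtered on several parameters at
once, and re-filtered without re-running the search. `reciblast` keeps
both directional searches in one *session*, adds per-row query and
subject coverage columns, applies inclusive range filters as
non-destructive views, and answers the recurring questions directly.

## The operations

For a session with HSP sets $H_{AB}$ (A as queries) and $H_{BA}$:

- **coverage / inv-cov** of an HSP: the fraction of the query
  (respectively subject) spanned by the aligned segment,
  $(q_{end}-q_{start}+1)/q_{len}$ and $(|s_{end}-s_{start}|+1)/s_{len}$
  (strand-agnostic on the subject side).
- **COMMON** — for selected queries $Q$, the subjects hit by *every*
  member: $\bigcap_{q \in Q}\,\mathrm{subjects}(q)$. Finds, e.g., the
  proteins sharing a planted domain.
- **CROSS** — pairs $(a, b)$ with $a \to b \in H_{AB}$ *and*
  $b \to a \in H_{BA}$ (reciprocally matched as query/subject).
- **RBH** — cross pairs where $b$ is $a$'s top-ranked subject and vice
  versa (lowest e-value, ties by bitscore, then coverage, then subject
  id); the classic ortholog-candidate criterion.
- **MULTIPLE** — (query, subject) pairs with ≥ 2 HSPs: repeats,
  multi-domain matches, multiple binding sites.

Filters are conjunctions of inclusive ranges over e-value, identity,
similarity, coverage, inv-cov, bitscore and alignment length; they act at
the visualization level only, so clearing a filter restores the full
result set bit-for-bit. All logical operations respect the active filter.

Sessions persist in a compact alignment-free store (JSON manifest + HSP
index, raw BLAST output retained separately) from which individual
pairwise alignments are re-read lazily by byte offset.

## Worked example

Generate a synthetic dataset pair with five planted mutually-best pairs,
a domain shared by A6/A7 and planted in B6, and a segment of A8 repeated
twice in B7 (sequences 200–400 residues, 5% point substitutions):

```python
from reciblast.synth import PlantedStructure, generate_fasta_pair
generate_fasta_pair(PlantedStructure(seed=11), ".")
```

Run the reciprocal search and ask for reciprocal best hits:

```console
$ reciblast run dataset_a.fasta dataset_b.fasta --out store --evalue 1e-5
$ reciblast cross store --rbh-only
a_id    b_id    evalue_ab       evalue_ba       is_rbh
A1      B1      0.000000e+00    0.000000e+00    1
A2      B2      0.000000e+00    0.000000e+00    1
A3      B3      3.059060e-160   2.896820e-160   1
A4      B4      0.000000e+00    0.000000e+00    1
A5      B5      0.000000e+00    0.000000e+00    1
A6      B6      1.360600e-36    1.556480e-36    1
A8      B7      1.408870e-37    1.308700e-37    1
```

The five planted pairs come back with near-zero e-values in both
directions; A6–B6 and A8–B7 also emerge as mutual bests because the
shared-domain and repeated-segment constructions are those sequences'
strongest (and only) cross-dataset signals. The repeat is visible as a
multi-region match:

```console
$ reciblast multiple store --direction ab
query_id        subject_id      regions
A8      B7      2
```

`reciblast common store --queries A6,A7` lists B6 as the subject shared
by both domain carriers, `reciblast filter store --similarity 40:80
--out t.tsv` exports the similarity band as TSV, and `reciblast stats
store` prints the session tallies as JSON.

The same analyses are available as library calls
(`reciblast.run_reciprocal_blast`, `reciprocal_best_hits`,
`common_hits`, `multiple_region_hits`, `apply_filters`, …); the CLI is a
thin wrapper over them.

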
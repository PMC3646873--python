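# Methods

## Data model

The unit record is the HSP (high-scoring segment pair): one locally
aligned segment between a query and a subject, carrying identity,
similarity, alignment length, mismatches, gap openings, the four
coordinates, e-value, bitscore, the two full sequence lengths, and the
two derived fractions *coverage* and *inv-cov*. Records group into
per-query results (emission order preserved) and per-direction runs; a
reciprocal session bundles the A→B and B→A runs. Design commitments:

- **Coordinates are BLAST-native**: 1-based, inclusive, and minus-strand
  nucleotide hits keep `s_start > s_end` exactly as reported. No
  conversion to 0-based half-open anywhere in the model, so stored
  records are bit-comparable with raw output. Coverage math uses
  `|end − start| + 1` and is therefore strand-agnostic.
- **Queries with zero hits are retained** as empty result rows. The
  COMMON operation must distinguish "searched, nothing found" from "not
  searched", and summary counts need the true query total.
- **Similarity** is BLAST's positives fraction, `100·positives/length`.
  Nucleotide searches and the 12-column tabular dialect have no positives
  concept; there similarity is defined equal to identity so that one
  filter surface covers all programs.
- Mismatches are not in BLAST XML; they are recomputed as
  `length − identities − gaps`, and gap openings as runs of `-` in the
  two alignment strings, which makes tabular and XML ingestion of the
  same search field-identical.

## Search orchestration

`run_reciprocal_blast` formats each dataset as a database
(`makeblastdb -parse_seqids`) and searches the other against it, choosing
the program from the detected alphabets: blastp (protein/protein),
blastn (nucleotide/nucleotide), blastx (nucleotide query vs protein
database). A reciprocal *mixed* pair would need tblastn for the return
direction, which is out of scope, so mixed pairs are rejected with an
explanatory error. Alphabet detection is a membership test against
`ACGTUN` plus the IUPAC ambiguity codes; a single non-nucleotide
character makes a sequence protein. With one dataset, the run is a
self-BLAST (direction `self`). Searches are run with `-outfmt 5` and the
XML is retained for alignment retrieval. Defaults follow BLAST+ itself;
only the e-value cutoff (10) is pinned explicitly.

## Filtering

A filter spec is a set of inclusive ranges (either bound omissible) over
seven HSP parameters; an HSP is visible iff it satisfies every supplied
range. Inclusivity on both ends is the natural reading of "between x and
y" and is fixed here to remove ambiguity. Filtering produces a *view*
over an untouched run, so apply → clear restores the source HSP list
element-for-element; stacking views conjoins specs (an empty per-parameter
intersection yields a spec that passes nothing). Filters act on HSP rows,
not whole hits — a hit survives partially if some of its HSPs pass —
matching tabular display semantics. Coverage is per-row; for multi-HSP
hits the separate `query_union_coverage` metric gives the merged-interval
fraction, since per-row coverage understates a multi-domain hit.

## Ranking and the logical operations

"Best hit" is nowhere standardized, so it is fixed deterministically:
lowest e-value, ties by highest bitscore, then highest query coverage,
then lexicographically smallest subject id; a hit is ranked by its single
best HSP. A summed-bitscore alternative (`ranking="sum_bitscore"`) is
provided for fragmented alignments where several HSPs jointly outweigh
one strong one. RBH = mutual best under this ranking; since each query
has a unique best subject, every sequence lands in at most one RBH pair
by construction.

CROSS emits any reciprocally matched pair, RBH only mutual bests — the
two readings of "reciprocally matched" are deliberately exposed as
distinct operations rather than merged. COMMON is a strict intersection
over *all* selected queries. MULTIPLE emits (query, subject) pairs with
≥ 2 visible HSPs; by default every HSP counts as a region (raw row
semantics), while `strict=True` greedily accepts HSPs best-first and
counts only those whose query intervals overlap every accepted one by at
most a configurable fraction (default 0.5) of the shorter span — the
multi-domain reading, which collapses stacked rescorings of one region.

Self-sessions use the single run for both directions, canonicalize each
unordered pair to lexicographic order, drop the trivial (x, x) pair, and
exclude self-matches from the ranking domain — otherwise every
sequence's best hit would be itself and no pair could ever be
mutual-best.

All four operations read only filter-visible HSPs, and each is verified
in the test suite against an independent brute-force double-loop
implementation on randomized sessions (200 seeded sessions of up to 50
queries and 500 HSPs per direction — sizes chosen to exercise collisions,
ties and empty queries while keeping the whole suite in seconds).

## Session store

A store directory holds `manifest.json` (schema version, dataset
id→length registries, programs, parameters, active filter),
`hsp_index.json` (every HSP field, per direction and query), and
`raw/ab.xml` / `raw/ba.xml` copies of the original outputs. The index
deliberately contains **no alignment text** — the bulky part of BLAST
output; instead each HSP carries the byte span of its `<Hsp>` element in
the raw XML, and `fetch_alignment` re-reads and formats the block on
demand. Stores built from tabular input have no alignments to offer and
say so. JSON is written with sorted keys and no timestamps, so identical
sessions serialize byte-identically and saves are diffable; JSON float
serialization is lossless, giving exact save/load round-trips. The
schema carries an explicit version string.

## Synthetic data

The generator plants three kinds of structure between two protein
datasets (defaults: 30 + 30 sequences of 200–400 residues, matching the
small-dataset regime the tool targets):

- **mutual-best pairs** (default 5): whole-sequence copies with i.i.d.
  point substitutions at rate 0.05 — strong reciprocal signal against
  unrelated backgrounds;
- **shared domains**: one 60-residue segment spliced (mutated) into
  several A sequences and one B sequence — ground truth for COMMON;
- **repeats**: a query segment spliced k times, at separated positions,
  into one subject — ground truth for MULTIPLE.

Sequences are uniform i.i.d. backgrounds; there are no indels, no
phylogeny, no composition bias and no calibrated decoy e-values, so
passing tests demonstrate correctness of the machinery, not performance
on real proteomes. Everything is reproducible from (parameters, seed).

A second tier fabricates the BLAST result files directly (15-column
tabular and the equivalent XML with alignment strings), bypassing BLAST+.
E-values are banded — planted mutual pairs at ≤ 1e-80, domains ~1e-30,
repeats ~1e-25, decoys ≥ 1e-18 — and decoy hits are placed only on
unordered pairs that never occur in both directions and never on planted
pairs. Consequently the manifest is exact by construction: RBH equals
the planted pair set, MULTIPLE equals the repeat map, and COMMON contains
the planted subjects.

## Numerical and formatting choices

- Export renders e-values as `%.6e` scientific notation and the two
  coverage fractions to 4 decimals; identities, similarities and
  bitscores use shortest-round-trip float repr. Re-parsing an export
  reproduces coordinates and scores exactly and e-values to ≤ 1e-6
  relative.
- Tabular dialect auto-detection is by column count (15 → extended,
  12 → standard); the 12-column path requires caller-supplied length
  registries and reports the offending id when one is missing.
- Cross-format ingestion agreement is asserted to 1e-6 absolute in tests
  (measured differences are at the 1e-11 level, from the decimal
  rendering of fabricated percentages).
- Degenerate inputs: zero-length sequences are rejected at parse time;
  an empty filter spec is the identity; statistics of an empty run report
  counts of zero and omit the spread fields.

## Known limitations

tblastn/tblastx (hence reciprocal mixed-alphabet pairs) are unsupported;
no aligner backends other than NCBI BLAST+; RBH is the only orthology
criterion (no synteny or trees) and is meant for small datasets —
whole-proteome eukaryote screens should pre-select candidates; the store
is single-writer with no concurrency control; alignment retrieval
requires the raw XML to remain inside the store directory.
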
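# Methods

This note documents the model and procedure implemented by `seedband`, the
parameters that matter, the synthetic-data generator used for evaluation,
and the numerical and design choices made where the design was genuinely
open.

## Search procedure

The search detects similar regions between nucleotide query reads and
reference genome sequences in two phases.

**Phase 1 — seeding.** k-mers are taken along each reference sequence with
a sliding window of `k` bases and a stride of `p` bases, and stored in a
*read-only q-gram index*: the (key, position) pairs are stably sorted by
key, the deduplicated keys are kept alongside a per-key occurrence count
(`cell_size`) and the exclusive prefix sum of those counts (`gateway`).
A key's positions occupy `sorted_values[gateway : gateway + cell_size]`, so
a single binary search answers any lookup, and batched lookups place their
results with one more exclusive prefix sum over the retrieved cell sizes.
Because the structure is sorted arrays rather than a hash table, memory
scales with the number of stored k-mer occurrences and not with the key
space, which is what permits `k` up to 31 in a 64-bit key. Keys occurring
more often than the *repeat threshold* have their `cell_size` overwritten
with zero after the prefix sum is taken — over-represented k-mers silently
stop seeding, while the value slices of all other keys remain valid.
Query k-mers (stride 1, both strands by default) are then looked up to
produce seeds: exact k-mer correspondences `(query_offset, ref_offset)`
with a diagonal `ref_offset − query_offset`.

**Seed reduction.** Each seed has a *surrounding area*: same query, same
reference fragment, same strand, within `z` bases parallel to the diagonal
and within `w` bases ahead along the reference. After sorting seeds by
(query, reference, strand, reference offset, diagonal), two linear passes
are applied: pass 1 removes every seed whose successor is *not* in its
surrounding area; pass 2 rescans the survivors and removes every seed whose
new successor *is* in its surrounding area. A seed without a successor
counts as "successor not in area" in both passes. The net effect is that a
chain of n ≥ 2 consecutively linked seeds collapses to one representative
(the chain's second-to-last member) and isolated seeds are discarded, so
the expensive extension step runs once per cluster rather than once per
seed.

Two boundary behaviours of this successor-chaining filter are worth
stating. (1) When two clusters abut within (z, w) of each other, pass 2 can
merge them onto a single representative; this is harmless — the extension
band is wider than z, so one extension covers both — and the guarantee of
exactly one representative per cluster holds whenever clusters are
separated by more than `w` along the reference. The randomized tests
generate configurations in that separated regime; dense configurations are
instead checked against a literal restaging of the two passes. (2) When
two unrelated seed families interleave in reference order on distant
diagonals (a tandem repeat aligned against itself is the canonical case),
every successor link is broken and *all* seeds are removed. This is the
filter's known insensitivity to interleaved repeats; in practice the
repeat threshold masks most inputs that would trigger it.

**Phase 2 — banded extension.** Each representative seed is extended
outward from its two edges by banded affine-gap dynamic programming
confined to `half_width` diagonals around the seed diagonal; the seed
interior contributes `k · match` and is never realigned. Two modes:

* *global* (default, more precisely **glocal**): each extension must
  consume its query flank to the end; the reference endpoint floats within
  the band. The full query is therefore covered, which is what makes
  scores comparable across candidate references and is the mode of choice
  for taxonomic assignment.
* *local*: each extension stops at its maximum-scoring cell, trimming
  negative-scoring flanks; more sensitive for partial/motif matches, and
  its score is by construction ≥ the glocal score of the same seed.

A gap of length g costs `gap_open + g·gap_extend`. Hits carry score,
identity (matched columns / alignment columns, gaps included), mismatch
and gap-open counts, and a Karlin–Altschul E-value
`E = K·m·n·exp(−λS)` (reported alongside the bit score
`(λS − ln K)/ln 2`), with n the total residue count of the reference set.
Hits are kept when `E ≤ evalue_threshold` (inclusive) and
`aln_length ≥ min_aln_length`.

**Batching and splitting.** References longer than `L` are split into
fragments overlapping by `overlap`; fragments are grouped into batches by
residue count and an index is built fresh per batch (there is no on-disk
index). Alignments truncated by an artificial fragment edge are dropped,
because the overlap guarantees the intact alignment appears untruncated in
the neighbouring fragment for any alignment shorter than the overlap; the
surviving duplicates that arise inside overlaps are then exact after
coordinate lifting and are collapsed by their full coordinate key. The
final hit set is invariant to the batch structure and (for alignments
shorter than the overlap) to splitting.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `k` | 16 | seed k-mer length (1–31); longer = faster, less sensitive |
| `p` | 4 | reference k-mer stride; query stride is always 1 |
| `z` | 16 | surrounding-area tolerance across diagonals (bases) |
| `w` | 64 | surrounding-area look-ahead along the reference (bases) |
| `L` | 64 Mb | maximum reference length before splitting |
| `overlap` | 2 × longest query (≥ 2000) | fragment overlap; bounds the longest alignment immune to splitting |
| `repeat_threshold` | 1000 | k-mers occurring more often are masked |
| `evalue_threshold` | 1e−3 | hit filter (inclusive) |
| `min_aln_length` | 30 | hit filter on alignment columns |
| `band_half_width` | `z + k` | extension band; indels within a cluster are bounded by z by construction |
| match/mismatch | +1/−3 | megablast-style scoring |
| gap open/extend | −5/−2 | affine-gap costs |
| λ, K | 1.28, 0.46 | ungapped Karlin–Altschul parameters for +1/−3 |

`L`'s generous default reflects that splitting exists to bound the
working set of a single alignment pass (every complete prokaryotic genome
fits well under it); all defaults here — `k`, `p`, `z`, `w`, the repeat
threshold, the score set and the E-value parameters — are this package's
own choices of reasonable field-standard values, and all are
user-adjustable.

## Synthetic communities

`generate_community` emulates the structure of a simulated metagenomic
benchmark: `n_genera` independent random ancestral sequences; per genus,
`genomes_per_genus` genomes derived by i.i.d. per-base substitution at
`intra_rate` (two siblings then differ at rate `2r(1 − r) + (2/3)r²`);
reads sampled uniformly over genomes, positions and strands, optionally
substituted at `error_rate` (default 0 — fragments retrieved verbatim).
Truth labels (source genome, genus, offset, strand) are recorded at
generation time.

What this does *not* model: indel sequencing errors (available via the test
helpers but off by default), shared gene content or horizontal transfer
between genera (genera are entirely unrelated, so cross-genus hits are
chance events), uneven taxon abundance, and genome-scale repeat structure.
Passing the protocol tests therefore demonstrates the machinery — seeding,
reduction, extension, best-non-self-hit selection and CGA accounting — not
performance on real communities, where inter-genus similarity makes
assignment genuinely hard.

Evaluation: hits of a read to its own source genome are removed
(self-exclusion), the best remaining hit is selected by (score, E-value,
reference id, reference start — the last two purely deterministic
tie-breaks), and the **CGA ratio** is correct genus assignments / total
reported hits. `threshold_sweep` repeats the evaluation after discarding
hits below each identity threshold and a query-coverage threshold
(coverage = aligned query span / query length, measured on the query to
match the glocal rationale).

## Numerical and degenerate-input choices

* DP scores are 64-bit integers; unreachable band cells hold a −10¹⁵
  sentinel. E-values saturate to +inf when λ·(−S) exceeds 700 (deeply
  negative glocal scores would otherwise overflow `exp`).
* A glocal extension whose band cannot reach the end of the query flank
  (query overhangs the reference by more than the half-width) yields no
  hit.
* In local mode the empty extension (score 0) is always available, so a
  local hit's score is at least `k · match`; hits with total score ≤ 0 are
  suppressed.
* Ambiguous (non-ACGT) windows are dropped at k-mer extraction; in the DP,
  letters match only if identical, so N–N counts as a match but N–A does
  not. Lowercase input is uppercased; soft-masking is ignored.
* Empty query or reference sets, queries shorter than k, and empty FASTA
  streams all yield empty results rather than errors.
* Ties in the stable sorts (index construction, seed ordering, output
  ordering) are resolved by input order, making byte-identical output
  reproducible across runs.

## Problem sizes used in the checks

The randomized suites run at desk scale, chosen to finish in minutes on
one CPU while still exercising every code path: 10,000-pair index checks
against a hash-map oracle; 500 mutated pairs (30–200 bases) for DP
exactness against an unbanded oracle; 200 pairs for seed completeness;
1,000 seed-reduction configurations; 1,000-read recovery runs against ten
100-kb genomes; and a 5-genera × 3-genome × 100-kb community protocol with
2,500 reads per read length (100 and 800 bases), five community seeds,
both alignment modes. The acceptance script re-runs the recovery and
protocol computations at 1,000 reads per configuration.

## Known limitations

* The successor-chaining reduction can discard all seeds of interleaved
  repeat families (see above); raising `z`/`w` or lowering the repeat
  threshold mitigates this.
* Glocal mode reports full-query alignments even through low-identity
  flanks; identity/coverage thresholds are the intended post-filters.
* λ and K are the ungapped values for the default score set and are not
  re-estimated when the user changes scores; E-values under custom scoring
  are only as calibrated as the parameters supplied.
* No paired-end awareness, no SAM output, no spaced seeds or minimizers.
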
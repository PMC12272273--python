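# Methods

## The screening model

`offscreen` estimates the off-target risk a double-stranded RNA (dsRNA)
biopesticide poses to a non-target organism (NTO). The biological chain it
emulates is: Dicer cleaves the applied dsRNA into ~21-nt small interfering
RNAs (siRNAs); each siRNA can load into an Argonaute complex and silence any
mRNA it pairs with well enough; a transcript in a beneficial organism that
pairs well with *any* siRNA derived from the construct is a potential
off-target site.

Because Dicer cleavage positions are largely stochastic, the conservative
in-silico model assumes **every** k-mer window of the construct (k = 21,
1-nt step) can become an siRNA. A 398-nt construct whose 21-mers are all
distinct therefore yields 398 − 21 + 1 = 378 unique fragments. A dsRNA
duplex releases siRNAs from both strands; dicing is implemented on the sense
strand with an orientation policy (`both`, the default, adds each window's
reverse complement; `sense_only` gives the minimal single-strand reading).
All per-fragment positions are *guide coordinates*: 1..k from the fragment's
5′ end. They are the coordinate system for mismatch positions and for the
seed region throughout.

## The search: exhaustive ungapped scan instead of heuristic alignment

Each fragment is placed at every full-length gapless offset on every
transcript, on the forward strand and as its reverse complement, and the
placement is scored position by position. Three statistics are recorded per
placement: total identities, the sorted guide-coordinate mismatch list, and
two stretch statistics derived from it — the longest perfect run and the
longest contiguous stretch containing at most *m* mismatches (*m* = 2 by
default).

Design rationale: for 21-nt queries every filter criterion below is a
function of a gapless full-length placement. Gapped alignment adds nothing
(a bulge in a 21-nt siRNA:mRNA duplex is not part of any criterion), and
heuristic word-seeded search makes hit lists depend on word size and
database composition. The exhaustive scan is deterministic and is itself
checked, exactly, against a naive per-position comparator in the test suite.
`N` never counts as an identity on either side (conservative). Placements
overhanging a transcript end are not evaluated; local similarities shorter
than k are represented by the stretch statistics of the best full-length
placement.

Hits below the scan floor (`min_identities`, default 15 = the loosest
identity bound of any shipped preset) are discarded at scan time, so no
downstream criterion can require a discarded hit. The vectorized NumPy inner
loop compares all windows of a transcript to a fragment at once; the naive
comparator remains the behavioural contract.

`run_statistics` computes the longest perfect run as the largest gap between
consecutive mismatch positions (sentinels at 0 and k+1) and the best
near-perfect stretch by a sweep over the sorted mismatch list; both agree
with exhaustive O(k²) window enumeration for every mismatch set of size ≤ 4
at k = 21 (checked in full, no sampling).

## The filter funnel

A hit survives when it satisfies:

1. **overall identity** — identities ≥ `min_total_identities` over the
   21-mer. The "~80% similarity (~16 nt)" reading is resolved to a hard
   ≥ 16 because a filter must be decidable; 16/21 ≈ 76% is the convention's
   own rounding.
2. **near-perfect stretch** — a contiguous stretch of ≥
   `min_near_perfect_len` positions containing ≤ `max_mismatches_in_stretch`
   mismatches (default ≥ 18 with ≤ 2). The stretch reading is the only one
   that can ever bind: a full-length 21-mer with ≤ 2 total mismatches
   trivially satisfies any "≥18 nt with ≤2 mismatches" reading.
3. **seed identity** — no mismatch in the seed region, guide positions 2–8
   (closed interval; position 1 is outside it). Seed complementarity
   dominates both on- and off-target silencing, so a single seed mismatch
   disqualifies the placement regardless of overall identity.

How the criteria combine is exposed as `combine_mode`. The default
`or_then_seed` retains hits with (1 OR 2) AND 3 — the identity and stretch
criteria descend from disjunctive precedents, with the seed check as a final
filter; `and_chain` (all three) is first-class for the conjunctive reading,
and the mode is stamped into every report. Three threshold presets are
shipped: `text` (16/18, the default), `figure6` (15/19), and `chen` (16/26 —
the original dsRNA-level criteria, whose 26-nt stretch can never fire on a
21-nt fragment; it is kept verbatim for comparison and documented as
unsatisfiable at k = 21, including for a perfect hit under `and_chain`).

A structural consequence worth knowing: at k = 21 with the `text` or
`figure6` presets, any placement satisfying criterion 2 necessarily
satisfies criterion 1 (an 18-nt stretch with ≤ 2 mismatches leaves at most
3 further mismatching positions, forcing ≥ 16 identities), so under
`or_then_seed` the funnel reduces to criterion 1 AND the seed check.
Criterion 2 is binding only under `and_chain` or other parameterizations;
it is retained as specified and reported separately in the audit.

Every retained hit gets a mismatch-class label
`"<identities> bp (<start>–<end>), <n> mismatch(es)"`, where the span is
the aligned region after trimming terminal mismatches (first to last
matching guide position, as a local aligner would report) and the mismatch
count is taken inside that span. The label format is versioned through the
report schema.

## Reports

Per database run the pipeline writes: the full hit table (TSV, fixed column
order), a funnel audit (input, per-criterion survivors, retained, preset,
combine mode — JSON), a per-transcript table (retained site counts,
contributing fragments, best identities, FASTA-header description) and the
mismatch-class distribution, as TSV and versioned JSON. Ordering is fully
deterministic (transcripts by retained count then identifier; classes by
count then label; hits by transcript, position, fragment index, strand), so
identical inputs reproduce identical bytes. A pie-chart rendering of the
class distribution is available but optional — numbers, not pixels, are the
contract. Annotation comes only from the database FASTA headers; there is no
remote retrieval of any kind.

## The synthetic-data generator

`build_synthetic_db` creates transcript databases with *planted* off-target
sites and exact ground truth, so the whole screen can be validated offline.
Transcripts emulate an NTO transcript database in shape only: multi-record
FASTA, lengths drawn uniformly from 200–3000 nt, configurable GC
(default 0.5), one planted site per transcript plus plant-free background.
They do not emulate codon structure, expression levels, UTR composition,
shared gene families, or short-read (SRA-style) databases — so passing
recovery tests demonstrates that the *method* discriminates its criteria
boundaries exactly, not that any particular real organism is safe.

Planting patterns map to deterministic substitution rules in guide
coordinates: `perfect` (none), `one_mm_seed` (one position uniform on 2–8),
`one_mm_nonseed`/`two_mm_nonseed` (outside 2–8; position 1 counts as
non-seed), `identity16` (five positions from 9–21, i.e. 16/21 identities
with an intact seed), `near18_2mm` (three positions from 9–21, redrawn until
an 18-nt stretch with ≤ 2 mismatches exists), `decoy_identity14` (seven
positions anywhere — below every preset's thresholds). Each site is planted
forward or as its reverse complement; expected retention flags per
preset × combine mode are computed from the substitution positions by a
brute-force rule evaluation local to the generator module (thresholds
restated there, stretch found by exhaustive enumeration) — a code path
disjoint from the search/filter implementation, which is what makes the
truth table an independent oracle.

**Background scrubbing.** At a 15/21 identity floor, chance matches between
random sequence and ~750 fragment strands are not rare (≈ 10 expected per
1.6-kb transcript), so whole-transcript rejection sampling would not
converge. Instead every transcript is iteratively repaired: windows matching
any fragment (either strand) at ≥ the floor, and not overlapping a planted
footprint, are re-drawn (planted bases frozen) until none remain; the loop
errors out rather than degrading if a budget of 80 passes is exceeded.
Determinism mattered more than realism here: the guarantee is constructive,
and all randomness flows from one recorded seed.

**Recovery scoring.** Fragments of one construct overlap, so planting a
21-mer locus necessarily creates shifted high-identity placements for
neighbouring fragments and a reverse-orientation placement for the antisense
twin (whose own seed covers different construct positions — the seed
criterion is strand- and frame-asymmetric). Recovery is therefore scored on
the exact (source fragment, position, strand) placement: sensitivity is the
fraction of expected-retained plants recovered exactly, and a retained hit
counts as a false positive only when its placement overlaps no planted
footprint. On the standard fixture (5 perfect, 10 one_mm_nonseed,
10 identity16, 10 one_mm_seed, 10 decoy_identity14, 50 background
transcripts) sensitivity is 1.0 with 0 false positives under both combine
modes, and every seed-region plant's exact placement is rejected.

## Numerical and degenerate-input choices

- Transcripts shorter than k are skipped with a logged warning, never
  silently dropped; an empty database or empty fragment list is an error.
- Duplicate hits (identical fragment sequence, transcript, offset, strand)
  are collapsed once at search time; dedupe never reorders survivors.
- Ties everywhere break lexicographically (documented per table) so reports
  are byte-reproducible; re-running with identical seeds reproduces every
  output byte, which the test suite asserts end to end through the CLI.
- FASTA output wraps at 80 columns (cosmetic, bit-stable). U→T conversion
  happens on ingest; sequences containing other symbols are rejected with
  the record named.
- `random_construct(distinct_kmers=True)` redraws until all k-mers are
  distinct so the window-count law is exercisable at the 398/378 geometry;
  at 398 nt a uniform draw almost always succeeds on the first attempt.

## Problem sizes

The shipped tests and the acceptance script run the full screen at the
study geometry (398-nt construct, 756 fragment strands, ~95 transcripts of
200–3000 nt) and validate the scanner on 1000 random fragment × transcript
pairs up to 3000 nt; the complete run takes a couple of minutes on one CPU.
Larger databases scale linearly in total transcript length; the vectorized
scan processes roughly 10⁸ placement-positions per second. A pigeonhole
k-mer pre-index (three disjoint 7-mer seeds guarantee an exact seed for any
≤2-mismatch placement) is a known acceleration path but is deliberately not
the contract.

## Known limitations

- No thermodynamic siRNA selection, Dicer cleavage-motif preference, strand
  asymmetry rules, position-weighted seed scoring, or target-site
  accessibility: risk is binary per placement, by the three criteria only.
- No gapped alignment, E-values, translated search, or network databases;
  screening a real NTO requires the user to supply its transcriptome FASTA.
- The `chen` preset is recorded verbatim and is unsatisfiable at k = 21 by
  construction; it exists for comparison, not screening.
- Headline counts from any real screen depend on the construct sequence and
  database snapshot used; this package reports its own computed counts with
  full provenance (preset, combine mode, thresholds) rather than targeting
  any external hit list.
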
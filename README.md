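# offscreen

**In-silico off-target risk screening for dsRNA biopesticides.**

RNAi-based crop protection works by spraying (or otherwise delivering) a
double-stranded RNA whose ~21-nt Dicer cleavage products silence an
essential gene in the target pest or pathogen. Before such a construct is
deployed, one must ask: could any of its siRNAs also silence a transcript in
a *non-target* organism — a pollinator, a predatory mite, a biocontrol
fungus? `offscreen` answers that question reproducibly and offline, for
anyone designing dsRNA actives or assessing their ecological risk.

The pipeline:

1. **Fragmentation** — the construct is diced into all unique 21-mer
   windows at 1-nt steps (Dicer cleavage is treated as positionally
   stochastic, so every window counts; a 398-nt construct yields 378 unique
   fragments), optionally expanded to both siRNA strands.
2. **Search** — every fragment is placed at every ungapped offset on every
   transcript of the non-target database, both strands, and scored exactly
   (identities, mismatch positions in guide coordinates, longest perfect
   run, longest stretch with ≤ m mismatches). No heuristic seeding, no
   word-size sensitivity: results are a deterministic function of the
   sequences.
3. **Filter funnel** — a hit is a potential off-target site when it has
   (1) ≥ 16/21 total identities, *or* (2) an ≥ 18-nt stretch with at most
   two mismatches, *and in either case* (3) perfect identity across the
   siRNA seed (guide positions 2–8). Thresholds ship as named presets
   (`text` 16/18, `figure6` 15/19, `chen` 16/26) and the and/or combination
   of the criteria is an explicit, reported switch.
4. **Reporting** — per-transcript site tables, a per-criterion funnel
   audit, and the mismatch-class distribution, as byte-stable TSV/JSON
   (optional pie chart).
5. **Synthetic ground truth** — a generator plants off-target sites with
   controlled identity/mismatch/seed structure in scrubbed random
   transcriptomes, so the whole screen is validated end to end with exact
   expected outcomes and no downloads.

See `docs/methods.md` for the model, its assumptions and its limitations.

## Worked example

```python
from offscreen import (FilterConfig, PlantSpec, build_synthetic_db,
                       random_construct, recovery_test)

construct = random_construct(398, rng_seed=7, distinct_kmers=True)
specs = [PlantSpec("perfect", 5), PlantSpec("one_mm_nonseed", 10),
         PlantSpec("identity16", 10), PlantSpec("one_mm_seed", 10),
         PlantSpec("decoy_identity14", 10)]
db, truth = build_synthetic_db(construct, specs, n_background=50, rng_seed=7)

for mode in ("or_then_seed", "and_chain"):
    config = FilterConfig.from_preset("text", combine_mode=mode)
    res = recovery_test(construct, db, truth, config)
    print(f"{mode}: sensitivity={res.sensitivity:.2f} "
          f"({res.n_recovered}/{res.n_expected} expected sites), "
          f"false positives={res.false_positives}, "
          f"retained hits={res.n_retained}")
```

prints

```
or_then_seed: sensitivity=1.00 (25/25 expected sites), false positives=0, retained hits=324
and_chain: sensitivity=1.00 (16/16 expected sites), false positives=0, retained hits=271
```

Reading the numbers: 25 planted sites are *expected* to survive the default
funnel (the 5 perfect, 10 single-non-seed-mismatch and 10 sixteen-identity
plants); all 25 are recovered at their exact planted placement and strand.
No retained hit lies outside a planted locus — the 324 retained hits beyond
the 25 exact placements are overlapping fragments of the same construct
hitting the same planted loci at shifted offsets or from the antisense
strand, which is precisely what a real screen of overlapping siRNAs
produces. Under the stricter conjunctive reading only 16 plants are expected
(most 16/21-identity sites lack an 18-nt near-perfect stretch) and exactly
those are found. Seed-region plants are rejected 100%.

The `examples/` directory holds one short script per capability
(fragmentation, scanning, the full screen with reports, recovery
validation); each prints the numbers it computes and what they mean. The
same pipeline is exposed as a thin CLI:

```sh
offscreen simulate --length 398 --plants perfect:5,one_mm_seed:10 \
    --background 50 --seed 7 --out sim/
offscreen run --construct sim/construct.fasta --db sim/db.fasta \
    --preset text --out results/
```

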
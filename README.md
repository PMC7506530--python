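# oriscan

Sequence-based prediction of DNA replication origins and analytics for
origin repertoires, exercised end-to-end on seeded synthetic genomes.

DNA replication in mammals starts from many thousands of initiation sites.
Mapped repertoires of these origins show a strongly skewed activity
distribution — a minority of "core" origins in the top activity deciles
carries most of the initiation signal — and a characteristic sequence
signature: a G-rich element upstream of the initiation site, with a step
down in G content across the site, CpG-island-like dinucleotide structure
at strong origins, and an excess of origins near the borders of
topologically associating domains (TADs). `oriscan` implements that whole
analysis arc as a library:

1. **Genome scan** (`oriscan.scan`) — a paired-window "hyper-motif" scan:
   two adjacent 500-bp windows stepped every 100 bp are retained when the
   upstream window is G-rich (G ≥ 0.28), the downstream window still
   moderately G-rich (G ≥ 0.25), the G step-down falls in [0.08, 0.40],
   and A and T each stay ≤ 0.21 over the combined kilobase. The reverse
   orientation applies the same rule to C content with the windows
   swapped. Retained pairs are merged into strand-annotated candidate
   regions.
2. **Repertoire analytics** (`oriscan.repertoire`) — background
   subtraction and TMM normalisation of per-sample count matrices
   (verified against the reference edgeR implementation), activity
   deciles Q1–Q10 with the core (Q1–Q2) / stochastic (Q3–Q10) split and a
   super-origin overlay (> 50 normalised counts), coverage-based summit
   calls (50-bp bins, 25-bp step), G-content orientation, core-origin
   clustering (tight ≥ 6 members within 7-kb gaps; isolated > 15 kb from
   the nearest core origin), and oriented composition / distance profiles.
3. **Classifier refinement** (`oriscan.features`, `oriscan.ml`) — 22
   sequence features per candidate (oriented flank base fractions, G
   content, G-ramp slope, dinucleotide and homopolymer densities,
   inter-candidate distance) feeding either greedy incremental logistic
   regression or an L1-regularised linear SVM, selected by 10-fold
   cross-validated **length-weighted balanced accuracy** (TP/FP/TN/FN
   measured in base pairs of region set algebra, not window counts).
4. **TAD profiles** (`oriscan.tads`) — origin density and initiation
   signal across 100 equal bins per TAD, with border (bins 1–10, 91–100)
   versus centre (41–60) enrichment ratios.
5. **Synthetic truth** (`oriscan.simulate`) — seeded genomes with planted
   origin cassettes that satisfy every scanner threshold by construction,
   composition-matched CpG-poor decoy cassettes that only dinucleotide
   features can reject, log-normal activities observed through Poisson
   counts, read pileups around known summits, and TADs with a tunable
   border enrichment. Every generated byte is a function of one integer
   seed.

Interval algebra, FASTA/BED I/O, seeded interval shuffling, and a
chi-square goodness-of-fit enrichment test live in `oriscan.core`.

## Worked example

Plant 150 origins and 300 composition-matched decoys in a 2-Mb genome,
scan it, and refine the candidates with the classifier
(`examples/03_ml_refinement.py`):

```text
$ python examples/03_ml_refinement.py
scan alone: 450 regions, false-positive rate 0.667
selected features: ['CGCG', 'GG']
cross-validated balanced accuracy: 0.970
scan + classifier: 150 regions, false-positive rate 0.000, sensitivity 1.000
```

The composition-only scan keeps every decoy (two decoys per origin, hence
the 0.667 false-positive rate); the greedy selector immediately finds the
CpG-structure features that decoys lack and removes all of them without
losing an origin. The other examples print, on their own seeds:

```text
$ python examples/01_simulate_and_scan.py
genome: 2,000,000 bp, 100 planted cassettes
retained 388 window pairs in 100 candidate regions
sensitivity: 1.000
forward regions: 50, reverse: 50

$ python examples/02_repertoire_classes.py
TMM factors (first 5): [0.946 1.014 1.064 0.991 0.938]
core origins: 20 of 100
mean signal fraction in core origins: 0.85
median summit error: 0 bp
first origin orientation: - (planted -)
core origin context: 0 tight, 0 loose, 20 isolated

$ python examples/04_tad_profile.py
planted border factor 1.00 -> recovered border/centre ratio 0.98
planted border factor 1.53 -> recovered border/centre ratio 1.53
planted border factor 3.00 -> recovered border/centre ratio 3.02
```

## Command line

The `oriscan` entry point wraps the library stages as subcommands:
`simulate`, `scan`, `features`, `train`, `predict`, `classify`, `summits`,
`tads`, `enrich`, and `run` (full pipeline with a manifest of per-stage
SHA-256 checksums — two runs with the same seed produce byte-identical
outputs). For instance:

```bash
oriscan simulate --outdir sim --seed 1
oriscan scan --fasta sim/genome.fa --out candidates.bed --stats stats.json
oriscan run --outdir pipeline --seed 1
```

## Testing

```bash
python -m pytest -q tests/
```

The suite (178 tests, ~30 s) covers exact brute-force oracles
for the scanner, an edgeR-checked TMM oracle, hand-worked arithmetic for
the balanced-accuracy and enrichment statistics, property-based interval
algebra (hypothesis, derandomised), planted-signature recovery, and
pipeline reproducibility. Statistical assertions use tolerance bounds
derived from the relevant sampling distributions before the tests were
first run; see `docs/methods.md`.

## Layout

```
src/oriscan/       library (core, scan, repertoire, features, ml, tads,
                   simulate, cli)
tests/             pytest suite
examples/          narrative scripts, one per capability
scripts/           acceptance.py — headline quantities, seeded
docs/methods.md    model, parameter rationale, numerical conventions
```
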
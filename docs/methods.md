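# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `culturoscope`, and what the synthetic-data
generator does and does not emulate.

## Pairwise identity

All identity thresholds in the pipeline (97% OTU clustering, ≤ 95%
novelty, < 89% order-level novelty, > 97% isolate confirmation) rest on
one primitive: `seq.percent_identity`.

* **Alignment.** Needleman–Wunsch with affine gaps and *free end gaps*
  (semi-global). Defaults: match +5, mismatch −4, gap open −10, gap
  extend −1; a gap of length L scores −10 − (L−1). The matrix fill is a
  numba-compiled three-state (M/X/Y) recurrence; traceback is exact.
* **Identity.** 100 × (matching columns) / (columns between the
  terminal-gap overhangs). Terminal gaps are excluded from the
  denominator; internal gap columns count as mismatches. This
  approximates blastn-style identity for near-full-length amplicons
  while remaining deterministic, and makes comparisons of a short
  amplicon against a full-length gene (or a longer Sanger read) behave
  as an overlap identity. The scoring is configurable
  (`seq.AlignScoring`) because the convention behind published "%
  identity" values is rarely stated.
* **Tie-breaking.** Deterministic: the end cell with the fewest
  terminal gaps wins; within the traceback a diagonal step is preferred
  over a gap, and a gap in the second sequence over a gap in the first.
* **Ambiguity codes.** IUPAC codes are allowed in references and
  primers and match by set intersection (R matches A or G). An `N` in a
  read matches nothing (conservative); in `iupac_mismatches` a window
  `N` matches only the pattern code `N`.
* Coordinates are 0-based, half-open everywhere.

## Quality filtering and demultiplexing

Four rules, evaluated in a fixed order (quality → homopolymer → length
→ primer) so failure-reason accounting is reproducible:

| rule | default | boundary semantics |
|---|---|---|
| mean Phred quality | > 25 | exclusive: mean exactly 25.0 fails |
| homopolymer run | ≤ 6 nt | run of 7 fails; N runs count |
| trimmed length | ≥ 200 bp | 199 fails, 200 passes |
| 5′ primer mismatches | 0 | IUPAC-aware, over the primer prefix |

Mean quality, homopolymer and length are evaluated on the *post-trim*
biological sequence (adaptor, barcodes and primers removed); whether
the original convention was pre- or post-trim is unknowable from
published descriptions, so this is a documented package decision.

Barcode matching is **exact** at the expected offset — no
error-correction — because correction cannot be assumed; generated
barcode sets keep pairwise Hamming distance ≥ 3 so single errors drop a
read into the unassigned bin rather than mis-assigning it. Colony reads
carry a second barcode behind the reverse primer at the 3′ end; reverse
demultiplexing locates the reverse-complemented reverse primer and
matches the following bases against the manifest. Reverse-primer
presence is not required (short reads may not reach it); when present
it is trimmed.

## OTU picking

Open-reference at 97% identity, two stages:

1. **Closed reference.** Each unique read sequence is assigned to the
   best reference (V1–V2 window) at ≥ 97%; ties break lexicographically
   by reference id.
2. **De novo.** Remaining unique sequences, sorted by descending
   duplicate count, then descending length, then lexicographic member
   id (abundance-sorted greedy order — the standard choice for centroid
   clustering), join the *first* existing centroid at ≥ 97% or found a
   new OTU. Centroids are never recomputed, so each representative is
   the sequence actually used for picking.

Taxonomy transfers from the best reference hit, truncated by identity
band: ≥ 97% keeps the full 6-rank lineage, ≥ 95% genus, ≥ 90% family,
≥ 85% order, ≥ 80% class/phylum, below that "Unassigned". The bands are
configurable; they are anchored to the novelty conventions used in the
analysis (95% ≈ genus boundary, < 89% ≈ order-level divergence).

The optional bimera screen flags an OTU when a single crossover of two
parents (other representatives plus references) explains the
representative with both segment identities ≥ 90% and a ≥ 5-point gain
over the best single parent. It is a deliberately simple positive
control screen — not a substitute for a full chimera detector — and
ships **disabled**.

## Colony identification and growth criteria

* A colony is assigned its modal OTU iff that OTU has **> 50%** of the
  colony's retained reads. Unlabelled reads count in the denominator by
  default (conservative — "reads obtained for that colony"); a flag
  restricts the denominator to labelled reads. 50/50 is unassigned.
* Growth of an OTU in a scraped community requires all three of:
  strict increase in relative abundance vs. the inoculum (an OTU absent
  from the inoculum trivially increased from 0), relative abundance
  ≥ 0.2%, and ≥ 20 visible colonies in that community. The flags are
  reported per criterion so a failed call is attributable.
* Novelty: identity to the closest type strain ≤ 95% (inclusive — the
  documented rule; the threshold is configurable because usage in the
  literature wavers between ≤ 95 and < 95); order-level novelty < 89%
  (exclusive). Identities use the V1–V2 representative, not full-length
  genes.
* Isolate confirmation: Sanger read > 97% identical to the OTU
  representative over their overlap (strict at exactly 97.0).

## Community statistics

* **Shannon** H′ = −Σ pᵢ log pᵢ over non-zero proportions; natural log
  by default (log₂ available). Replicate-subsampled Shannon means are
  not reported by default because the replication parameters behind
  published "H′ ± s.d." values are generally unstated.
* **Rarefaction** by multivariate-hypergeometric subsampling without
  replacement, seeded; the mean curve is validated against the closed
  form E[S_d] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)).
* **Bray–Curtis** Σ|x−y| / Σ(x+y) on relative abundances.
* **UPGMA** (average linkage) on the Bray–Curtis matrix, ties broken by
  the lowest cluster-label pair; linkage is configurable in spirit but
  average linkage is the standard companion to Bray–Curtis profiles.
  Hierarchical clustering runs on *untransformed* relative abundances
  while SIMPER runs on *square-rooted* values — the asymmetry is
  intentional and mirrors common practice.
* **SIMPER**: for each cross-group pair (j,k) and OTU i,
  δᵢ(j,k) = |y_ij − y_ik| / Σ_m (y_mj + y_mk); per-OTU contribution is
  the mean over pairs, so Σᵢ δᵢ equals the average between-group
  Bray–Curtis dissimilarity to machine precision (an invariant the
  tests assert at 1e-9). No permutation significance testing.

## The synthetic cultivation experiment

The generator (`simulate`) produces everything downstream stages
consume, with a `GroundTruth` record of per-read, per-colony and
per-sample provenance.

**What it emulates**

* Type-strain references: random sequences, 1500 bp, 45–55% GC,
  homopolymer runs capped at 4, mutually < 90% identical in the 311 bp
  V1–V2 window at positions [20, 331). Random composition keeps the
  package download-free; `ReferenceDb.read` accepts a real FASTA +
  taxonomy TSV instead.
* Source ("sponge") communities: lognormal abundances (σ = 1.0 by
  default) over a subset of references, plus planted *novel* members
  mutated to target divergences (default 5, 11 and 18 points, each at
  0.4% abundance — spanning the boundary-novel, order-edge and deeply
  novel regimes; achieved divergence is verified to ± 0.5 points).
* Plating: scraped composition = (1 − c) × colony mixture + c ×
  inoculum, with c = 0.03 carry-over by default; the colony mixture
  weights abundance × growth probability × dominance. One designated
  fast grower ("PSVLIKE", 4% diverged from its parent reference, hence
  a de novo OTU that is *not* novel) is absent from every inoculum but
  takes 55% of each plate — emulating overgrowth by a dominant genus
  that cultivation studies repeatedly observe without detecting it in
  the source community. Grower plate shares are floored at twice their
  inoculum abundance so that true growth is detectable by the increase
  criterion; extra growers are admitted low-abundance-first only while
  that floor budget fits in the plate share left by the dominant.
* Colony picking: proportional to growth-weighted abundance with a cap
  of 3 colonies per taxon per plate (morphology-based picking limits).
* Reads: adaptor + forward barcode + realized degenerate forward primer
  + template + reverse-complemented reverse primer (+ reverse barcode
  for colonies). Errors: per-base substitutions (0.003), homopolymer
  ±1 indels with probability proportional to run length (0.003 per run
  base — 454-like flow miscalls), and a two-state good/bad quality
  profile (Q ≈ 38 ± 2 vs. Q ≈ 14 ± 4, 2% bad). The error rates are
  order-of-magnitude pyrosequencing assumptions, not calibrated to any
  particular run.

**Scenario shapes.** `study_scenario()` mirrors the full experimental
design: 3 sources × 5 media × {agar, filter} × 2 harvest days of
scraped communities (60) + 3 inocula + 13 antibiotic plate groups of
picked colonies. `demo_scenario()` is the scaled version used in tests,
examples and the acceptance script (3 sources × 2 media × agar × 1 day
+ 2 plate groups), with 120–250 reads per sample — sizes chosen so the
whole demonstration, including exact pairwise alignment of every unique
read, runs comfortably on a laptop core.

**What it does not emulate.** Real 16S sequence structure (conserved /
variable region architecture), chimera formation (off by default),
flowgram-level noise, barcode synthesis errors, PCR bias, or
phylogenetic correlation between community members. Passing tests
therefore demonstrate the *logic* of the criteria and the exactness of
the bookkeeping under the stated noise model — not performance on real
pyrosequencing data.

## Degenerate inputs and edge cases

* Empty read set → empty OTU list; zero-count samples are dropped from
  relative-abundance tables with a warning; a colony with zero retained
  reads is recorded unassigned, not raised.
* `mutate_to_divergence` raises when the requested tolerance is finer
  than 1/length granularity allows (short sequences).
* `bray_curtis` and `shannon` reject all-zero vectors; SIMPER rejects
  overlapping groups; UPGMA requires ≥ 2 leaves; Venn overlap is capped
  at 5 groups for readability.
* All randomness flows through seeded `numpy` generators; child seeds
  derive from `SeedSequence` so every stage is independently
  reproducible and whole runs are byte-identical at a fixed seed.

## Known limitations

* Exact all-vs-all alignment makes clustering O(unique reads ×
  centroids); there is deliberately no k-mer prescreen, so the package
  is desk-scale (thousands of reads), not production-scale (millions).
* The blastn-approximating identity can differ from true local-alignment
  identity for sequences with large internal rearrangements.
* The bimera screen tests only single crossovers between two parents.
* Growth criteria operate on relative abundances and therefore inherit
  compositional effects: a large true grower depresses the relative
  abundance of everything else, which is exactly why the increase
  criterion is evaluated against the inoculum rather than in isolation.
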
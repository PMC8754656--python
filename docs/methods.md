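# Methods

## Library design

A region of length *L* is tiled by Library 1 at starts 0, 35, 70, … and by
Library 2 at starts 17, 52, 87, … (tile length and offset are
configurable; defaults 35 and 17 bp).  A trailing residue shorter than one
tile is dropped, never padded: inserts must be exactly tile-length for
synthesis and for the exact-match counting rule.  With the 17-bp offset
every internal Library 1 junction sits inside a Library 2 tile with flanks
of 18 and 17 bp, so any protein footprint (~6–12 bp) broken by a Library 1
boundary is intact in Library 2.  The offset is not uniquely determined by
the published tile counts (1669/1668 for a 58,415-bp region); 17 ≈ half a
tile was chosen to maximize the minimum breakpoint flank.  Coordinates are
0-based half-open (BED convention) everywhere; inserts are taken from the
+ strand, with reverse-complement handling deferred to quantification.
Tiles containing N are kept in the manifest but excluded from the
synthesis FASTA by default, since an ambiguous base cannot be synthesized
as a definite probe.

## Selection simulator

The generator is a forward model of the screen with the statistical
structure the caller assumes; no quantitative selection model is published
for the assay, so the scheme below is this package's own.

Per replicate trajectory (replicates are independent from round 1 — each
gel slice is carried forward separately) and per round:

1. retention: tile *i* keeps weight (1−s₀)(1−f<sub>i</sub>) in NE and
   (1−ε<sub>buffer</sub>) in buffer;
2. bottleneck: the retained composition is multinomially resampled to
   `pool_size` molecules (gel extraction);
3. amplification: each tile's abundance is multiplied by an i.i.d.
   log-normal factor with log-SD `pcr_sigma`, then renormalized;
4. at sequenced rounds, `depth` reads are drawn multinomially.

The nonspecific shift s₀ is uniform across tiles, so it cancels on
renormalization: only f<sub>i</sub> > 0 produces systematic NE-vs-buffer
depletion.  In the deterministic limit the NE/buffer percentage ratio of a
tile after *r* rounds is (1−f<sub>i</sub>)<sup>r</sup> divided by the mean
retention of the pool, which the test suite checks against a closed-form
recursion oracle.

Defaults and their calibration (chosen once, before any acceptance
measurement):

| parameter | default | rationale |
|---|---|---|
| rounds / sequenced | 10; 1, 4, 7, 10 | screen protocol |
| replicates | 3 + 3 (buffer/NE) | screen protocol |
| s₀ | 0.5 | about half the pool is shifted per NE round on the gel |
| ε_buffer | 0 | no protein, no specific loss in buffer |
| `init_sigma` | 1.0 | log-normal initial abundances shared by all replicates; array-synthesized oligo pools spread over roughly 10–100×. Without this heterogeneity replicate percentage vectors are pure noise and can never show the observed R² > 0.99 |
| `pcr_sigma` | 0.02 / round | set so simulated replicate concordance reproduces pairwise R² > 0.99 at realistic depth |
| `mismatch_rate` | 0.014 / base | set so the perfect-read fraction of a ~75-bp construct is 0.986⁷⁵ ≈ 0.35, the observed template-recovery rate |
| `depth`, `pool_size` | 10⁵, 10⁶ | tractable desk-scale defaults; the real screen sequenced ~10⁶ matched reads per sub-library |

Randomness: one master seed; every stream (initial abundances, each
(condition, replicate) trajectory, each sub-library's read errors) is a
`SeedSequence` with a distinct named spawn key, so adding replicates or
sequencing extra rounds never perturbs existing trajectories.

What the generator does **not** emulate: gel-extraction efficiency
gradients, fragment-length or GC effects, PCR jackpots and chimeras,
protein-concentration titration, barcode cross-talk.  Passing tests
therefore demonstrate the pipeline's statistical behaviour under the
stated model, not robustness to these real-data artifacts.

## Quantification

A read increments a tile's count iff it equals the adapter-flanked
construct — or, by default, its reverse complement — over the full length.
No alignment or fuzzy matching: the screen counts only reads matching
their templates perfectly, and the recovery rate is the matched fraction.
Percentages are computed per sub-library over matched reads only (the only
self-consistent choice under exact matching) after adding a pseudocount of
0.5 to every tile, which keeps buffer means positive and NE/buffer ratios
finite even for fully depleted tiles.  Replicate QC reports pairwise
Pearson R² within each (condition, round); pairs below 0.99 are flagged,
as are sign anomalies (negative *r* with high R²) and constant vectors
(R² undefined).

## Candidate calling

Per-round condition means are arithmetic means over replicates; ratios are
NE mean / buffer mean; the slope is closed-form OLS of ratio against round
number (1, 4, 7, 10).  "P < 0.05 in round 1, 4, 7 and 10" is read as four
per-round two-sample tests — 3 NE vs 3 buffer replicate percentages, each
required significant; an alternative single-test-across-rounds mode is
available (`test_scope="all_rounds"`).  The default test is
pooled-variance Student's *t* (Welch optional).  Degenerate zero-variance
cells: equal means give p = 1 by convention; unequal means give the
smallest positive float.  Slopes are fit on plain ratios (log-ratio mode
optional); since only the sign gates the call, the round-number vs
round-index abscissa choice cannot change any call.  No multiplicity
adjustment gates candidacy; a Benjamini–Hochberg column over each tile's
worst per-round p-value is emitted for reference only.

`validation_false_positive_rate(n_validated, n_tested)` summarizes
orthogonal validation of sampled candidates (e.g. 8 of 10 EMSA-confirmed →
20% false positives).

## Cross-library concordance

Each Library 2 tile is paired to the Library 1 tile with maximal base-pair
overlap (ties to the smaller start; with offset 17 every tile pairs left
with 18 bp).  One-to-one maximal-overlap pairing is used because it is the
definition under which the independence expectation n₂·n₁/N₁ reproduces
the published arithmetic (199·209/1669 ≈ 24.9 → 25); an any-overlap
definition would roughly double it.  Observed agreement is the number of
Library 2 candidates whose partner is also called; significance comes from
a Pearson chi-squared test on the 2×2 pairing table, continuity correction
off by default, with p-values below 2.2e−16 reported as a floor.

## Genomic post-processing

Clustering: two candidates join iff one 140-bp window (four tile lengths,
a generic enhancer span) contains both entirely — equivalently their joint
span is ≤ 140 bp — chained by single linkage into connected components.
The test suite checks this against a brute-force all-windows oracle.
Density: a candidate overlaps an annotation interval iff they share ≥ 1 bp
(standard BED intersect semantics); a candidate straddling two intervals
counts in both, and the summary mean is over intervals containing at least
one candidate.  Candidate BED export scales −slope to a 0–1000 score.

## Binder calling from pulldown spectral counts

Strict presence/absence on (2 samples, 2 controls): any control count
eliminates the protein; of the remainder, only proteins detected in both
samples are specific binders.  No abundance modelling or enrichment
scoring — the rule is deliberately conservative, and duplicate protein ids
are rejected rather than summed to surface upstream table errors.  The
packaged worked-example table yields five S1606 binders (DBN1, POLB, MVP,
PABPC1, SERPINH1) and one S961 binder (FOXC2).

## Statistical properties, problem sizes and known limitations

The test suite runs the screen at desk scale: the null-calibration test
uses 1000 neutral tiles at default depth (the conjunctive caller's
empirical false-positive rate is far below 0.05 — four independent-ish
α = 0.05 tests plus a sign filter compound to ≪ α), and the sensitivity
test plants 100 functional tiles (per-round retention 0.8) among 250 at
10⁵ reads per sub-library, the composition that a power analysis shows
maximizes round-1 discriminability at that depth.

That analysis also exposes a real limitation: after a single selection
round the NE/buffer percentage gap of a retention-0.8 tile is at most
~11–18% (depending on the functional fraction), while at 10⁵ reads the
per-replicate counting noise leaves the round-1 t-test (df = 4) with
noncentrality ≈ 3, so the probability of clearing α = 0.05 at round 1 —
and hence the caller's sensitivity, since all four rounds must pass — caps
near 0.6 regardless of library composition.  The measured sensitivity
under these conditions is 0.61.  Sensitivity ≥ 0.9 at that effect size
requires either deeper sequencing (~10⁶ matched reads per sub-library,
as in a full-scale screen, where the example in the README recovers
80/80 planted tiles), stronger effects, or more replicates; this is an
inherent power constraint of the conjunctive rule, not an implementation
artifact.
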
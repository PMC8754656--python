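# reelscan

Toolkit for designing and analysing **iterative EMSA depletion screens** —
an *in vitro* strategy for fine-mapping cis-regulatory elements (cis-REs)
across a large genomic region, independent of epigenetic marks.

## The problem and the approach

A cis-RE is a short DNA sequence (a typical regulatory-protein footprint
is ~6–12 bp) that controls transcription by recruiting nuclear proteins.
The screen this package models covers a region of interest with a pooled
synthetic library of 35-bp fragments, each flanked by constant
PCR/sequencing adapters, and repeatedly subjects the pool to an
electrophoretic mobility shift assay (EMSA) against nuclear extract (NE):
protein-bound fragments shift out of the recovered (unshifted) pool, which
is PCR-amplified and carried into the next round.  Buffer-only controls
see no specific binding.  Over ten rounds, protein-binding fragments are
progressively depleted from the NE-treated pool; sequencing selected
rounds (1, 4, 7 and 10; three replicates per condition) turns that
depletion into a per-fragment statistic.

Two tilings are screened in parallel: Library 1 abuts 35-bp tiles end to
end; Library 2 repeats the tiling shifted by 17 bp, so every junction of
Library 1 lies inside a Library 2 tile and no protein footprint is lost at
a fragment boundary.

For each tile *i* the caller computes per-round percentages
*p*<sub>i</sub> within every sub-library, the condition means over the
three replicates, the depletion ratio
*r*<sub>i</sub>(t) = mean NE % / mean buffer % at rounds
t ∈ {1, 4, 7, 10}, the OLS slope of *r*<sub>i</sub>(t) against t, and a
two-sided two-sample Student's *t*-test (NE vs buffer replicates) at every
round.  A tile is a **candidate cis-RE** iff

> slope < 0  and  *P* < 0.05 at every sequenced round (no multiplicity
> adjustment — the screen deliberately keeps every possible positive for
> downstream validation).

Also included: a forward simulator of the full selection process with
ground-truth labels (for power studies and end-to-end testing),
cross-library concordance statistics (independence-expected candidate
overlap n₂·n₁/N₁ and a Pearson chi-squared test), window clustering and
enhancer-density summaries of candidate sets, and the companion
pulldown-proteomics decision rule: a protein specifically binds an element
iff it has peptide spectral counts in both pulldown samples and in neither
control.

## Worked example

Design the two libraries over a synthetic 58,415-bp region, simulate a
screen with 80 planted functional tiles (half their molecules shifted per
round), and call candidates:

```python
import numpy as np
import reelscan as rs

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), 58_415))
region = rs.GenomicRegion("chr9", 21_900_000, 21_958_415, seq)
lib1, lib2 = rs.design_tiling(region, tile_len=35, offset=17)
print(f"library 1: {len(lib1)} tiles, library 2: {len(lib2)} tiles")

f = np.zeros(len(lib1))
f[rng.choice(len(lib1), 80, replace=False)] = 0.5
model = rs.SelectionModel(f=f, seed=1)
design = rs.ScreenDesign(depth=1_000_000, pool_size=10_000_000)
cm, truth = rs.simulate_screen(lib1, model, design)

pct = rs.to_percentages(cm)
print(f"min replicate R^2: {rs.replicate_concordance(pct)['r_squared'].min():.4f}")

records, summary = rs.run_depletion_calling(pct)
print(summary)
called = records[records["is_candidate"]]
print(f"true functional among candidates: "
      f"{truth.loc[called.index, 'functional'].sum()}/{len(called)}")
```

prints

```
library 1: 1669 tiles, library 2: 1668 tiles
min replicate R^2: 0.9807
{'n_tested': 1669, 'n_slope_negative': 721, 'n_candidates': 80}
true functional among candidates: 80/80
```

The tiling covers the region with 1669 abutting tiles plus 1668 offset
tiles.  Replicate percentage vectors are tightly concordant (the minimum
pairwise R² is in the late NE rounds, where functional tiles are nearly
exhausted).  About 43% of tiles drift to a negative slope by chance, but
the conjunction with four per-round significance tests reduces 1669 tested
tiles to exactly the 80 planted ones, with no false positives at this
depth and effect size.

The same steps are available from the shell:

```sh
reelscan design --region region.fa --start 21900000 -o libs/
reelscan simulate --library libs/library1.tsv --n-functional 80 --effect 0.5 \
    --depth 1000000 --seed 1 -o sim/
reelscan quantify --library libs/library1.tsv --counts sim/counts.tsv -o quant/
reelscan call --pct quant/percentages.tsv --library libs/library1.tsv -o calls/
reelscan frep --counts pulldown_counts.tsv -o binders/
```

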
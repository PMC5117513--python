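# tssclust

Positional clustering of transcription-factor motifs in TSS-anchored
promoter alignments.

## The problem

Transcription-factor complexes bind regulatory modules (RMs) in promoter
DNA, and the binding sites (TFBSs) inside an RM keep tight positions
relative to each other and, near the transcription start site (TSS),
relative to the TSS itself. Given a gapless block of promoter sequences
aligned on the TSS (many sequences per gene) and a set of JASPAR-style
count matrices, `tssclust` answers two questions:

1. **Which TF motifs pile up in particular alignment columns?** Every
   window of every sequence is scored with the natural-log odds of the
   motif model against a position-varying 3rd-order Markov background
   (re-estimated every 23 columns, conditioning on sequence context on
   both sides of a site). Positive-scoring windows ("motifs") are assigned
   to their 3′-base column; the per-column sums x_i feed a local-score
   statistic: with gap penalty g = ρ·x̄ (ρ = 1.4 > 1, the logarithmic
   regime), the Ruzzo–Tompa algorithm extracts all maximal segments of
   x_i − g, and Karlin–Altschul statistics bound each segment's tail
   probability, p = 1 − exp(−K·n·e^(−λŜ)), with λ the positive root of
   the empirical moment equation fitted leave-one-out (the tested
   segment's columns are excluded from its own null calibration). A
   seeded permutation test (hit scores redistributed uniformly over
   columns) provides a calibrated cross-check.
2. **Which motif clusters co-occur in the same genes?** Each significant
   cluster defines a gene group (distinct genes contributing a motif);
   a right-tailed Fisher exact test against the dataset's own gene
   universe flags gene-group pairs whose intersection is enriched beyond
   chance — the signature of two TFBSs sharing an RM. The left tail is a
   negative control; Bonferroni arithmetic controls the family-wise error.

Because the full promoter collections such analyses run on are derived
from large TSS databases, the package ships a first-class synthetic-data
module: blocks from configurable Markov backgrounds (optional GC
enrichment toward the TSS), many-to-one sequence→gene redundancy, planted
RMs with known truth, and two negative controls (fully random blocks, and
"random with offsets" blocks that reproduce the sequence-overlap structure
of real collections without signal).

## Worked example

```python
import tssclust as tc

# a synthetic study: two-member RM at +7 / +12 bp in 30% of 400 genes
block = tc.generate_background_block(
    400, 1001, tss_col=500, gene_ids=[f"g{k:04d}" for k in range(400)],
    seed=3001)
members = (
    tc.RmMember(tc.synthetic_count_matrix(5, 0.95, seed=101, name="TFA"), "+", 7),
    tc.RmMember(tc.synthetic_count_matrix(5, 0.95, seed=201, name="TFB"), "+", 12),
)
study = tc.plant_rm(block, tc.RmSpec(members, carrier_fraction=0.3), seed=401)

model = tc.PositionalClusterModel(study.block, [m.matrix for m in members])
results = model.fit()
print(results.summary(4.72e-4))
```

prints

```
Positional motif-cluster analysis
=================================================
sequences: 400   genes: 400   columns: 1001 (TSS at column 500)
matrices: 2   strands: +,-   rho: 1.4   K: 1.0
cluster threshold (Bonferroni 0.05 / 4): 0.000472
significant clusters: 3

 tf strand cluster_p  from_bp  to_bp  spread pct_multiple_motifs  n_hits  n_genes  score           key
TFA      +  4.28e-43        7      7       1               0.000     123      123 439.63   TFA:+7:+7:+
TFB      +  4.09e-32       12     12       1               0.000     120      120 417.71 TFB:+12:+12:+
TFB      -  1.19e-29        7      7       1               0.000     122      122 365.94   TFB:+7:+7:-
```

Both planted members come back as spread-1 clusters at their planted
offsets (+7 and +12 bp; the TSS is +1 and no position 0 exists), each
backed by ~120 motif hits — the planted carriers plus a few background
genes. The third row is a reverse-strand echo: at this seed the
reverse complement of TFB's matrix also scores the planted region, so it
surfaces as a minus-strand cluster keyed `TFB:+7:+7:-` in plus-strand
coordinates. `cluster_p` is the conservative Karlin–Altschul bound; the
Bonferroni threshold shown is 0.05 divided by the 4 TF×strand tests.
Downstream,

```python
inter = results.intersections(4.72e-4)
print(inter[["key_a", "key_b", "a", "p_right", "significant"]].to_string(index=False))
```

```
        key_a         key_b   a      p_right  significant
  TFA:+7:+7:+ TFB:+12:+12:+ 112 2.102187e-75         True
  TFA:+7:+7:+   TFB:+7:+7:- 112 3.184377e-73         True
TFB:+12:+12:+   TFB:+7:+7:- 117 1.287147e-90         True
```

the TFA and TFB gene groups share 112 of 400 genes — an intersection
enriched far beyond chance (right-tailed Fisher p ≈ 2e-75), exactly the
signature expected when two motifs sit in one RM.

A `tssclust` console script exposes the same pipeline
(`simulate`, `scan`, `clusters`, `intersect`, `tune-rho`, `report`).

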
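# Methods

## Data model and coordinates

The unit of analysis is a *promoter block*: a gapless alignment of
equal-length DNA sequences over {A,C,G,T}, each anchored so that its
transcription start site occupies a fixed column, with a many-to-one
mapping from sequences to genes (promoter collections derived from cDNA
5′ ends carry several records per gene). The canonical geometry is
3001 bp with the TSS in 0-based column 2000, spanning −2000..+1001 bp;
promoter convention has no position 0, the TSS base is +1 and the base
5′ of it is −1. We read "the TSS column" as a 0-based index, which makes
the −2000..+1001 span exact for 3001-bp sequences; smaller geometries
(600–1001 columns) are used throughout the tests and acceptance runs to
keep runtimes in seconds to minutes.

Input filtering removes records with ambiguous bases and byte-identical
replicates (first occurrence kept, deterministically); filtering is
idempotent. A per-column TpA-dinucleotide frequency profile serves as an
anchoring diagnostic: correctly TSS-anchored mammalian promoter blocks
show a TpA spike at the anchor column, and the profile recovers planted
spikes exactly on synthetic fixtures.

## Background model

Base composition varies along promoters, so motif log-odds need a
position-varying null. For every 23-column block of the alignment we fit
a 3rd-order Markov chain to a window spanning the block plus 24 columns
5′ and 3 columns 3′ (50 columns total, clipped at the edges): 24 = the
21-column maximum width of the bundled matrix format plus a 3-letter
context, so that any motif whose 3′ base falls in the block lies inside
its window. 4-mer counts are pooled over all sequences in the window and
smoothed with a pseudocount of 0.5 per 4-mer (mirroring the Dirichlet
pseudo-count used for count matrices; unseen contexts degrade to the
uniform row). Each alignment column belongs to exactly one block; a
site is scored with the table of the block containing its *scored*
(3′-base) column, on either strand.

A candidate site of width w is scored against the chain in one of two
modes. `left` is the plain chain probability conditioned on the 3
letters 5′ of the site. `context2` conditions on both flanking triples
by exact Bayes inversion under the fitted chain:

    P(site | left, right) = P(site | left) · P(right | site end)
                            / P(right | left, gap = w),

where the denominator marginalizes all 4^w interveners by w-step
propagation of the 64×64 3-mer transfer matrix. Summed over all 4^w
sites this is exactly 1 (verified exhaustively for w ≤ 4), and it
reduces to `left` whenever the chain is history-independent. This
two-sided construction is our own exact formulation of
flank-conditioned site probability; `context2` is the default. Where a
full 3-letter flank does not exist (sequence edges) the conditioning
falls back to order 2, 1, 0, and missing left-state letters are
marginalized under the window's 3-mer distribution, so every column
remains scoreable. The asymmetric window placement and the within-window
seeding of the chain are modelling choices; alternatives (centered
windows, whole-sequence seeding) would change scores only near block
edges.

## Motif scoring and column scores

Count matrices (JASPAR pfm, both dialects, parsed by Biopython) become
probability matrices with pseudo-count 0.5: p(b,j) = (n(b,j)+0.5) /
(N(j)+2). A window's score is the natural-log odds of the matrix model
against the background mode above; a *motif* is any window with strictly
positive score. Score and position are assigned to the motif's 3′ base —
on the minus strand, to the 5′-most plus-strand column of the window —
so clusters on both strands share plus-strand coordinates. Matrix
descriptors (GC content, information content in bits, reverse
palindromicity as the Pearson correlation of the flattened matrix with
its reverse complement) characterize matrices whose clusters may be
composition artifacts.

Per-column scores x_i aggregate motifs under one of two policies:
`positive_sum` (default) sums the positive motif scores in the column —
clusters and gene groups are built from motifs, so columns aggregate
motif scores; `clamped_total` clamps the sum of *all* raw scores at 0,
the literal "ignore negative sums" reading. Both are exposed because the
two readings differ only in how sub-threshold windows dilute a column.

## Cluster statistic

With gap penalty g = ρ·x̄ (x̄ the mean column score over all columns,
zeros included; ρ = 1.4 by default), the Ruzzo–Tompa algorithm extracts
every maximal scoring segment of the increments x_i − g in linear time.
Segments are disjoint, strictly positive, and exclude zero-scoring
extensions (strict cumulative minima/maxima at the endpoints); the
implementation is verified against brute-force enumeration plus a
maximality filter on 500 random instances. ρ > 1 makes the increment
mean negative, the logarithmic regime in which the best local score is
asymptotically Gumbel; larger ρ shrinks cluster spreads, and ρ = 1.4
empirically keeps typical spreads at or below 10 columns (±5 bp), the
scale of a tight positional preference inside a regulatory module.
`tune_rho` reports median spreads along a ρ grid and recommends the
smallest value meeting that target.

Each segment's p-value is the Karlin–Altschul bound
p = 1 − exp(−K·n·e^(−λŜ)) with n the number of columns and K = 1, the
Poissonian upper bound — deliberately conservative (the true prefactor
is smaller; on i.i.d. null blocks the realized rejection rate at
α = 0.05 is ~2%). λ is the unique positive root of the empirical moment
equation mean(exp(λ(x_i − g))) = 1, solved by bracketed root-finding to
~1e-12 relative tolerance.

One subtlety matters: the moment equation estimates the *null* score
distribution, so the columns of the segment under test are excluded from
its own fit (leave-one-out). Fitting on all columns is self-defeating —
a dominant signal column contributes exp(λ(x−g)) ≤ n to the moment sum,
capping λŜ near ln n and flooring the best segment's p-value around
1 − e^(−K) no matter how strong the signal. With the leave-one-out fit,
planted clusters reach their astronomically small p-values while the
null calibration (measured over 200 independent null blocks) stays
conservative. When the tested segment was the only positive excursion no
null calibration remains and the full-data fit (or p = 1) is the
fallback. A seeded permutation p-value — every hit's column redrawn
i.i.d. uniformly over the alignment, column scores rebuilt, Ruzzo–Tompa
rerun, add-one rule — is the calibrated alternative; its null
distribution is approximately uniform and it agrees with the analytic
bound in rank order.

Cluster descriptors follow the block's coordinate map: From/To are the
bp coordinates of the segment's first and last columns; spread is the
number of columns (equal to To − From + 1 whenever the segment does not
straddle the TSS, where no position 0 exists — for straddling segments
we report the true column count); a sequence contributing m motifs
contributes m − 1 "multiple motifs", and the table reports their
fraction of all cluster motifs (a tandem-repeat diagnostic). Clusters
are keyed `TF:From:To:strand`.

## Gene groups and intersections

A cluster's gene group is the set of distinct genes whose sequences
contribute at least one motif to the segment. For every unordered pair
of significant clusters, a Fisher exact test on the 2×2 table of the two
gene groups against the *dataset's own* gene universe (never a global
gene catalogue, to avoid importing collection biases) yields exact
hypergeometric tails: the right tail detects enrichment (shared
regulatory module), the left tail is reported only as a negative
control. Tails are exact, not mid-p. Bonferroni arithmetic is explicit:
the cluster threshold is α/(matrices × strands) (0.05/106 = 4.72e-4 for
the canonical 53-matrix, two-strand design), the pair threshold α/m for
m = k(k−1)/2 pairs, with the stricter α/(2m) variant also emitted for
runs that budget both tails. Gene lists are exportable one file per
cluster, sorted, for external ontology tools.

## Synthetic studies

The generator emulates the structural features of a real TSS-anchored
promoter collection: sequences sampled column-by-column from a
configurable 3rd-order chain (uniform by default; the first three
columns seed from the uniform distribution); optional linear GC
enrichment toward the TSS column; gene redundancy via 1–5 records per
gene; regulatory modules planted as sites *sampled from the member's
probability matrix* (not consensus, so weak instances exercise
false-negative behaviour) written at fixed bp offsets with optional
Gaussian jitter, ground truth recorded per write; and two negative
controls — fully random blocks, and "random with offsets" blocks whose
same-gene sequences are windows at uniform ±offset into one shared
random source string, reproducing sequence-overlap structure without
signal (the offset law of the original control is not published; uniform
±500 bp is our stand-in, scaled to the block). Everything is
deterministic given (spec, seed).

What passing synthetic tests do *not* show: real promoter blocks have
correlated composition (CpG islands, repeats, transposable elements),
expression-biased gene sampling, alternative TSSs, and motif sites that
deviate from the matrix model; planted-recovery rates here are
best-case, and the negative controls bound only the artifacts they
model (composition drift and sequence overlap).

## Default study conditions

Desk-scale conditions used by the tests and the acceptance script,
chosen once to exercise the statistics at sizes that run in minutes:
null calibration on 300 sequences × 600 columns over 200 seeds; planted
recovery with a two-member RM (width-5 matrices, 0.95 consensus mass,
offsets +7/+12 bp, jitter 0) in 30% of 400 single-record genes on
1001-column blocks over 10 seeds; negative controls at 300 × 600 with
100 genes × 2–4 records for the offsets control. Under these conditions
both planted members are recovered as significant tight clusters with a
Bonferroni-significant gene-group intersection in ≥ 9/10 seeds, and the
controls yield no significant cluster.

## Known limitations

- K = 1 overstates the prefactor; p-values are upper bounds, not
  calibrated probabilities (the permutation test is the calibrated
  route).
- λ assumes i.i.d. column scores; overlapping windows within a sequence
  induce short-range dependence that the permutation null also ignores
  (its null p-values are uniform to within the resolution of 200 runs).
- Column scores near block boundaries mix adjacent background tables;
  strand symmetry is exact only within a single background block.
- The minus-strand site's background is evaluated on plus-strand letters
  with the scored column's block table, so its fitting window extends 3′
  rather than 5′ of most of the site.
- Multiple matrices for the same factor are scanned independently; no
  motif-redundancy correction is applied across matrices.
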
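# Methods

## The analysis model

The pipeline treats an anchor TF's ChIP-seq peaks per cell line as
already reduced to (i) de-novo motifs (probability PWMs over A,C,G,T)
and (ii) motif modules — sets of ≥ 2 motifs that co-occur in
significantly many peak sequences. Modules stand in for TF complexes:
if two motifs repeatedly co-occur in the anchor's peaks, the TFs that
bind them are candidate cooperating cofactors. All downstream
statistics are built on that reading.

### Motif similarity and E-values

Two PWMs are compared by ungapped alignment over every offset with
overlap ≥ min(4, widths) and both orientations of the second motif
(reverse complement = columns reversed, A↔T, C↔G swapped). The
per-offset score is

    score = Σ_columns pearson(a_col, b_col) / max(w_a, w_b)

so scores live in [−1, 1], partial overlaps are penalised by the
full-width denominator, and a uniform (0.25,0.25,0.25,0.25) column
contributes 0 — padding cannot inflate similarity. Ties are broken by
smaller |offset|, then '+' orientation.

E-values are empirical: the null is `n_null` (default 2000) alignment
scores between motifs whose columns are resampled with replacement from
the pooled columns of the whole library — this destroys motif identity
while preserving per-column information content — and

    E(s) = library_size × (#null ≥ s + 1) / (n_null + 1).

An empirical E-value cannot go below `library_size/(n_null+1)` (≈ 0.03
at the defaults), far above the decision thresholds θ_known = 1e−5 and
θ_cross = 1e−8. When a score exceeds every null observation the
pipeline therefore extends the tail parametrically: a Gaussian is
fitted to the null scores and E = library_size × min(1/(n_null+1),
Φ̄(z)). The extension is monotone and only kicks in beyond the
empirical support; `evalue()` exposes it as an explicit flag
(`extreme_tail`), with the plain empirical formula as the documented
default. In practice planted/true matches score z ≳ 8 while the best
chance alignments sit near z ≈ 4, so the thresholds separate cleanly.

Thresholds (all config-exposed): θ_known = 1e−5 for calling a predicted
motif "known" and assigning TFs (with a relaxed 1e−4 reporting
variant), θ_cross = 1e−8 for cross-cell-line motif similarity — more
stringent because motifs predicted by the same tool are intrinsically
more alike. Up to the top five matches are kept per motif (`top5`
mode), or only the best (`top1`); an unfiltered top-k mode supports
paralog diagnostics on the recovery miss list.

### Conservation and the random-module null

A motif is conserved when some motif in at least one *other* cell line
is similar at θ_cross (within-line similarity is never consulted).
Motif pairs are all size-2 subsets of each module, deduplicated per
line; a pair (a,b) is conserved when another line has a pair (c,d) with
a∼c ∧ b∼d or a∼d ∧ b∼c. Both statistics share one cached symmetric
similarity relation, so they cannot disagree about what "similar"
means.

The null rebuilds every module with uniformly drawn motifs of the same
size from the same line (no replacement within a module), preserving
module counts and sizes exactly, and recomputes the overall
pair-conservation fraction. With R replicates,
p_empirical = (1 + #{null ≥ observed})/(R + 1) — bounded below by
1/(R+1), which is the honest resolution at small R — and p_normal is
the upper tail of a Gaussian fitted to the null fractions, reported
alongside because extreme significance levels are unreachable
empirically at practical R. Both are reported; neither is preferred
silently.

### Pair enrichment

Known interacting TF pairs come from the PPI edge list: *direct* pairs
are edges whose endpoints are both TFs; *indirect* pairs are TF pairs
sharing ≥ 1 interactor (any protein), excluding pairs already direct so
the two classes stay disjoint and can be tested separately. Predicted
cofactor pairs are the TF cross products of module motif pairs (a motif
may name several TFs in top5 mode). The test is the hypergeometric
upper tail `phyper(m, n(n−1)/2, M, N(N−1)/2)`, computed in log space
(gammaln + logsumexp) with infeasible terms contributing zero; N is
taken from the edge list's TF flags and recorded in the output. With
n < 2 predicted TFs the p-value is 1 with a warning. Note the test is
per cell line: pooling all lines can make n approach N, at which point
the statistic is degenerate by construction (the summary reports the
per-line count of significant lines for this reason).

### Ranking, anchor restriction, recovery

Within a line a TF's E-value is the best across its motifs; across
lines the −log10 values are averaged (a geometric-mean E-value), and
the ranking score is that mean times the number of lines. The cutoff
τ = 15 corresponds to mean E = 1e−5 in three lines; passing requires
s > τ strictly, consistent with "smaller than 1e−5" and "more than
three lines". The anchor-cofactor set restricts to TFs whose motifs
share ≥ 1 module with an anchor motif (anchor motifs are detected as
those whose best match is the anchor TF below θ_known). Recovery
against a curated list reports hits, total, a one-decimal percentage
and the miss list.

Percentages are rounded only at presentation, to one decimal with
half-up ties via exact decimal arithmetic (65.55 → 65.6, 88.85 → 88.9);
JSON outputs keep full precision.

### Peaks, targets, GO and divergence

Peaks shorter than 800 bp (about the median cis-regulatory region) are
grown symmetrically about their midpoint — the extra base goes right on
odd deficits — and shifted inward at chromosome boundaries, preserving
length where possible. Peak overlap across lines uses half-open
semantics (≥ 1 bp). Target genes are assigned by minimal
|midpoint − TSS| among genes on the peak's chromosome
(cross-chromosome distances are meaningless; a peak on a gene-free
chromosome is an error), ties broken by the smaller gene id; the signed
distance flips sign on '−' strand genes so negative always means
upstream.

GO over-representation of a line's target genes uses the same
hypergeometric tail with Benjamini–Hochberg correction across the
tested (k ≥ 1) terms; "enriched terms of a line" means q < 0.05. The
divergence analysis computes, for every line pair, the Jaccard
distances of cofactor sets and of enriched-term sets (a normalised
symmetric-difference metric is available by config; two empty sets
differ by 0 by convention), then for each line regresses go-difference
on cofactor-difference over its pairings with the other lines via OLS.
Per-line R² is undefined (reported missing, excluded from the mean)
when the cofactor differences have zero variance; a constant response
is counted as R² = 1 since a flat line fits it exactly.

### Co-occurrence significance

For consumers who have the original sequences × motifs occurrence
matrix, `cooccurrence_pvalue` tests a motif set with a one-sided
binomial tail: n = #sequences, x = #sequences containing all members,
p₀ = product of the per-motif marginal frequencies. Because the
marginals are estimated from the same matrix, the statistic is
conservative rather than exactly uniform under independence (the joint
count and the estimated p₀ are positively correlated); its rejection
tail never exceeds the nominal level, which the tests verify.

## The synthetic-study generator

`simulate_study` emulates an eight-cell-line anchor-TF screen with a
single seed fanned out to fixed per-component streams (library, line
composition, truth, modules, PPI, genes, GO, peaks), so adding a
component never shifts the others and bundles are byte-reproducible.

* **Known library** — 60 motifs, widths 6–12, sparse-Dirichlet
  (α = 0.3) columns giving ≈ 1 bit mean information content; motif 0 is
  the anchor TF.
* **Line composition** — a conserved core pool of `motifs_per_line − 1`
  TFs; each line samples a ρ = 0.7 fraction of its motif slots from the
  pool (so core overlap varies across line pairs, which the divergence
  analysis needs) and fills the rest with privates dealt globally from
  the remaining library, disjoint until the library runs out. Planted
  cross-line correspondences — motifs in different lines sharing a
  source TF — are recorded in `truth`, and conservation accuracy is
  scored against them rather than against ρ itself, since the anchor
  and recycled privates also recur legitimately.
* **Predicted motifs** — per-column Dirichlet perturbations of the
  source PWMs at concentration κ = 50, which keeps a noisy copy's
  alignment score ≈ 0.95 against its source, comfortably separable.
* **Modules** — 30 per line, sizes 2–5, anchor included with
  probability 0.8. Members are drawn with a coverage-first queue (every
  motif appears in ≥ 1 module), a ×3 weight on planted-cofactor motifs,
  and — because modules represent complexes — a planted interacting
  cofactor pair seeds a module with probability 0.8. That last rate was
  chosen so the per-line PPI enrichment mirrors the near-universal
  significance a real anchor-TF screen shows; at weaker seeding the
  planted edges are diluted below per-line detectability.
* **PPI** — all 15 planted cofactors get an anchor edge; cofactor–
  cofactor edges are sampled at rate 0.6 among pairs co-resident in ≥ 1
  line (so every planted pair is observable in some line's modules);
  background edges at density 0.02 over 60 TFs plus 40 non-TF decoy
  proteins, which also supply indirect (length-2) paths.
* **Genes, GO, peaks** — 500 genes on a toy two-chromosome genome (TSS
  every ~4 kb); the first 40 TFs (anchor and core pool first) each own
  a GO term and a disjoint six-gene "club"; a line's peaks (length
  300–600 bp, later extended to 800) sit near the TSSs of its TFs' club
  genes plus 25 background peaks, overlaps dropped deterministically.
  Hence a line's enriched GO terms track its TF repertoire, planting
  the positive cofactor-difference → GO-difference trend; 5% of genes
  get a random background annotation.

What the generator does *not* emulate: genomic sequence composition
(modules and occurrences are planted directly — the upstream de-novo
module discovery is consumed, not re-derived), motif false positives
(every synthetic motif has a known source, so the %known columns sit at
100%, unlike real de-novo output), peak-calling noise, GO DAG
structure, or database incompleteness. Passing tests therefore show
that the statistics recover planted structure at realistic sizes and
noise, not that real screens will reach the same percentages.

## Problem sizes used by the test suite

The default study conditions (8 lines × 25 motifs, library 60,
n_null = 2000, R = 199) fit in a few seconds per seed; the acceptance
tests sweep seeds 1–10 for recovery/conservation/enrichment/divergence,
use 200 replicates for the resampling-null uniformity check and 300 for
the shuffled-PPI enrichment check, and verify `phyper` against
exhaustive enumeration on the full grid of instances with a universe of
at most 12 and against the reference hypergeometric tail on 1000 random
instances at 1e−12.

## Known limitations

* E-values are calibrated per library; they are comparable across
  motifs within a study but not across libraries of different size or
  information content, and values beyond the empirical support rest on
  the Gaussian tail assumption.
* The enrichment test uses n(n−1)/2 as the predicted-pair
  universe even though fewer pairs are actually observed in modules,
  which is conservative.
* `cooccurrence_pvalue` is conservative under independence (estimated
  marginals), so it screens rather than calibrates.
* The divergence regression treats line pairs as independent
  observations within each per-line fit; R² is descriptive, no
  inference is attached to it.
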
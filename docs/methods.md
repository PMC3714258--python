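# Methods

This note documents the models, conventions and design choices behind
`tfqpcr`, and what the synthetic-data tests do and do not demonstrate about
real qRT-PCR data.

## Measurement model and normalization

The pipeline starts from threshold-cycle (Ct) values, one well per gene per
biological sample, with a hard detection ceiling (default 40 cycles; a Ct at
the ceiling encodes an undetected transcript). Each PCR run carries technical
replicate wells of a reference gene (ubiquitin AT1G55060 by default, four
wells expected); the run's reference level is the **median** of those wells —
robust to a single aberrant well — and

    dCt(gene, sample) = Ct(gene, sample) − median reference Ct(run).

Censored values enter dCt at the ceiling. This is a conservative floor on
expression: a transcript that never crossed the threshold is treated as
present at the detection limit, not absent, except where a whole condition is
censored (see "exclusive expression" below). No amplification-efficiency
(Pfaffl-type) correction is applied; the pure 2^-ddCt form assumes ~100 %
efficiency for both target and reference.

The *expression index* 40 − dCt (ceiling minus dCt) is the monotone proxy
used for clustering and PCA: higher means more transcript, undetected maps
to the run's reference distance from the ceiling.

## Fold changes and the sign convention

Between a reference and a compared condition, biological replicates are
averaged on the dCt (cycle) scale first — Ct noise is approximately Gaussian
on that scale — and

    ddCt = mean dCt(compared) − mean dCt(reference)
    log2 FC = −ddCt = mean dCt(reference) − mean dCt(compared)
    FC = 2^(log2 FC).

The subtraction order is fixed so that **more transcript in the compared
condition gives FC > 1** (lower dCt = more cDNA). Reported tables use the
signed reciprocal convention: FC ≥ 1 is printed as is, FC < 1 as −1/FC, so
|signed FC| ≥ 1 always and the 2-/10-fold thresholds read symmetrically in
both directions. Useful identities (tested to machine precision): ddCt chains
additively over consecutive intervals, fold changes multiply accordingly, and
reversing a contrast negates log2 FC and inverts FC.

### Exclusive expression

When every replicate on one side of a contrast is censored while the other
side is expressed, a numeric fold change would only reflect the ceiling, so
the contrast is flagged (`compared_only` / `reference_only` / `undetected`)
instead, and such genes are routed to the exclusive-expression group of the
genotype-contrast classifier rather than through the fold-change gates.

## Detection calls

A gene is "expressed" in a condition when at least `min_detected` replicates
(default 2 of 3) are below the ceiling; with fewer replicates than
`min_detected`, all of them must be detected. The 2-of-3 default rejects
single-well artefacts while tolerating one dropout.

## Statistical gating

A contrast call is **modulated** only if all three gates pass:

1. per-gene one-way ANOVA across *all* genotype × time groups, with
   Benjamini–Hochberg FDR correction over the genes tested in the mode
   (`anova_fdr < 0.05`) — one family-wise gate shared by both comparison
   modes, so a gene must show some overall effect before any pairwise claim;
2. pairwise Student (pooled-variance) *t*-test on the dCt replicate values
   (`p < 0.05`; Welch available behind a flag);
3. |signed FC| ≥ 2, inclusive; |signed FC| ≥ 10 additionally marks the
   drastic (`x10`) subset, which is nested inside the `x2` set by
   construction.

Everything else is "steady expression". Degenerate inputs are resolved ahead
of the scipy calls: zero within-group variance with unequal means counts as
maximally significant (F or t infinite, p = 0), identical values everywhere
make the gene untestable by ANOVA (NaN gates never pass, so such genes fall
to steady — correct, because their fold change is 1). The FDR scope defaults
to per-comparison-mode, with a global option.

Comparison modes over the 2 × 3 × 3 design: mode 1 contrasts successive time
points within each genotype (5d–0d, 10d–0d, 10d–5d); mode 2 contrasts the
embryogenic against the non-embryogenic genotype at each time point, oriented
so FC > 1 means enrichment in the embryogenic culture.

## Trajectory and genotype-contrast classification

Each gene's induction-stage (5d–0d) and formation-stage contrast gets a
finest label in {up_x2, up_x10, down_x2, down_x10, steady}; cross-tabulations
roll the x10 subsets up into the x2 rows/columns, so marginals mirror nested
fold-change thresholds.

The SE-specific classifier inspects, per genotype, the 5d–0d and 5d–10d
contrasts plus the expressed flags, with precedence i → iii → ii → iv → none
(groups are disjoint; the strongest evidence wins):

* **i** — expressed in the embryogenic culture, never detected in the
  non-embryogenic one;
* **iii_a / iii_b** — both genotypes modulated at induction, in opposite
  directions (up/down and down/up respectively);
* **ii** — modulated in the embryogenic culture, steady in the mutant across
  both inspected contrasts;
* **iv** — down-regulated in the non-embryogenic culture *while the two
  genotypes' per-contrast labels differ*. The guard is this package's design
  choice for a genuinely open definition: without it, any gene down-regulated
  identically in both cultures — a shared auxin response, not a
  genotype-specific one — would land in iv. A gene down x2 in the embryogenic
  but down x10 in the non-embryogenic culture still qualifies (the profiles
  differ), which matches the published exemplars of this group;
* **none** — everything else, including identical profiles in both cultures.

## Clustering and PCA

k-means (Lloyd's algorithm, Euclidean distance, scikit-learn backend) runs on
per-gene condition means of the expression index, unscaled — the natural
"40 − dCt" axis — with k = 4 by default and 10 seeded restarts keeping the
lowest within-cluster sum of squares. Clusters are renumbered 1..k by
descending centroid mean, so assignments are deterministic given the seed.
A z-score option exists but is off by default.

PCA operates on the samples × genes expression-index matrix: column-centered,
unscaled, via SVD; zero-variance genes are dropped; the largest-magnitude
element of each loading vector is made positive so signs are reproducible.
Variance fractions are computed over all retained components and sum to one.

## Summary tables

Percentages are rounded half-away-from-zero to whole percent — the convention
that reproduces published rounded values exactly (546/673 → 81, 312/358 → 87).
Category tallies count a multi-category gene once per category but once in
the annotated total; every report row carries its denominator because the
"annotated" and "all genes" denominators both occur in practice.

## Phenotype statistics

Line-vs-control comparisons of SE efficiency (% of explants forming somatic
embryos, in [0, 100]) and productivity (mean embryos per responding explant,
≥ 0) use the Mann–Whitney U test. At the sample sizes typical of these assays
(n = 3 per line) the null distribution is tiny, so it is **enumerated
exactly**: all C(n1+n2, n1) assignments of the pooled mid-ranks (ties handled
correctly), two-sided p = 2 × min(one-sided tails), capped at 1. Above
`exact_limit` (12 total observations) a normal approximation with tie and
continuity corrections takes over; the two agree within 0.02 by n = 8 + 8 on
tie-free data.

A consequence worth stating plainly: with n = 3 vs 3 the smallest exact
two-sided p is 2/C(6,3) = **0.1**, so complete separation can never be
significant at α = 0.05 under the exact test. Published asterisks at n = 3
must come from an approximation or from finer-grained units; the comparison
table therefore reports the exact and the approximate p side by side.

Kruskal–Wallis (tie-corrected H, χ² p on k−1 df) covers multi-group
questions; all-identical data returns H = 0, p = 1.

## Synthetic-data generator

The generator emulates the measurement process of the 2-genotype × 3-time ×
3-replicate screen at a configurable gene count. Per gene, a baseline dCt is
drawn from N(8, 2) (clipped to [2, 14] to keep trajectories inside the
dynamic range); planted log2 effects act between 0 d and 5 d — +/−1.5 for the
x2 classes, +/−3.5 for the x10 classes, safely beyond the 1.0 and log2(10) ≈
3.32 thresholds so threshold-edge flakiness is opt-in rather than default.
Gene classes (steady / up / down at two magnitudes / unexpressed / the four
SE-specific groups; default mix 50 % steady, 32 % shared modulation dominated
by up-regulation, 6 % unexpressed, 12 % SE-specific) are apportioned by
largest remainder — counts depend only on the fractions, not the seed — and
then shuffled onto gene ids with the seeded generator.

Each (genotype, time point) is one PCR run by default (`run_per_replicate`
splits replicates onto their own runs); runs get four reference wells drawn
from N(22, 0.2). The observed Ct is

    Ct = median(run's reference wells) + true dCt + N(0, noise_sd),

censored at the ceiling, with `noise_sd` = 0.25 cycles by default. Defining
the planted dCt relative to the run's *realized* reference median makes the
noiseless limit exact — at `noise_sd = 0` the pipeline recovers every planted
log2 effect, class and SE group exactly, regardless of reference-well scatter
— which is what the exactness tests verify.

What the generator does **not** emulate, and hence what passing tests cannot
show about real data: amplification-efficiency differences between primer
pairs, inter-plate calibration drift, non-Gaussian or heteroscedastic Ct
noise, correlated replicates, partial-censoring bias near the ceiling, and
formation-stage dynamics (planted effects are confined to the induction
interval, so the 5 d and 10 d conditions of a default dataset legitimately
overlap in PCA).

## Problem sizes used in the checked examples

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path with comfortable statistical margins: 1,000 genes
(10 % planted 4-fold effects, noise sd 0.25, n = 3) for sensitivity/FDR
recovery; 110 genes for the noiseless-limit exactness check (every class
represented); 100 profiles over four archetypes (separation ≥ 10× noise) for
clustering; 200 random 6-group instances for the ANOVA oracle. At these
settings the recovery margins are wide — sensitivity and ARI sit at 1.0, the
empirical FDR at 0 — so results are insensitive to the seed.

## Known limitations

* One well per gene per sample is assumed; technical replicates of
  non-reference genes, if present, must be averaged upstream.
* The ANOVA gate assumes homoscedastic Gaussian dCt noise across groups;
  heavy censoring violates this silently (censored values compress variance).
* The exclusive-expression route requires *complete* censoring of one side;
  a condition detected in 1 of 3 replicates still yields a numeric, possibly
  attenuated, fold change.
* The group-iv definition involves a judgement call (documented above);
  alternative readings change membership at the margin between "shared
  down-regulation" and "mutant-biased down-regulation".
* Whether gene-profile plots should show dCt against the reference gene or
  ddCt against day 0 is a presentation choice; both quantities are computed,
  and downstream consumers pick (`delta_ct` vs contrast `ddct` columns).
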
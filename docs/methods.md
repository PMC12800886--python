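# Methods

## The estimation problem

Mollusk grazers affect rocky-shore biofilm bacteria through two
channels: consumption (trophic, TI) and pedal-mucus contact
(non-trophic, NTI). The experimental design that identifies both uses
three treatment classes per grazer species: grazer-free controls,
grazing treatments (animal on the rock: TI + NTI together), and mucus
treatments (animal on a mesh cage over the rock: NTI only). The
observable contrasts are therefore the *total* effect (grazing vs
control) and the *non-trophic* effect (mucus vs control); the trophic
effect is obtained by subtraction and is never observed directly.

The default design mirrors the reference experiment: 1 control group
(13 replicates) + 5 grazing treatments (13 each) + 5 mucus treatments
(10 each) = 128 units, with five grazer species (*Chiton granosus*,
*Echinolittorina peruviana*, *Fissurella crassa*, *Scurria araucana*,
*Siphonaria lessonii*) and 16S amplicon libraries of ~6215 reads.

## Per-capita interaction strength

Effects are quantified with the Dynamic Index,

    DI = ln(N / D) / (Y * t),

N and D the target's relative abundance with and without the grazer,
Y the grazer abundance (1 per aquarium), t the duration (one
experimental period); DI is a per-capita, per-time log-ratio effect.

Amplicon counts are compositional, so `N` and `D` are defined on the
centered log-ratio (clr) scale: counts get a uniform pseudocount
(default 1), rows are closed to proportions, and clr_i = ln(x_i/g(x)).
The default DI estimator is the **difference of group-mean clr values**
(`di_space="clr_difference"`), which equals ln(N/D) for the depth-free
part of the composition and is defined for all count patterns; the
literal ratio form on group-mean proportions (`"relative_ratio"`) is
provided for fidelity to the classical formula but is ill-posed when
fed clr values (which can be <= 0). Group means rather than pairwise
ratios are used because replicates are unpaired (independent aquaria).

Uncertainty: percentile bootstrap over replicates (default 9999 draws,
seeded), resampling treatment and control groups independently. An
effect is *significant* when its (1 - alpha) CI excludes 0 (alpha
default 0.05, uncorrected, matching common practice for exploratory
interaction screens; an optional Benjamini-Hochberg flag is available).
The trophic estimate is total - non_trophic *exactly* (point
estimates), and its CI comes from the paired bootstrap distribution of
the difference: both contrasts share the same control resamples draw
by draw, so the subtraction is coherent. Groups with < 2 replicates
yield a point estimate with an unavailable CI and a warning.

## Synthetic experiments and what they do (not) show

`grazenet.simulate` generates count tables with the statistical
structure the estimator assumes, plus the ground truth needed to score
it:

* baseline ASV log-abundances ~ Normal(0, 1.5) — a log-normal
  rank-abundance profile typical of uneven biofilm communities;
* sparse signed log-effects: each (grazer, ASV) pair carries a nonzero
  effect with probability 0.10, drawn Normal(0, 1) (tests use fixed
  ±1); mucus samples express delta_nti, grazing samples
  delta_ti + delta_nti — TI is only identifiable by subtraction, as in
  the real design;
* replicate noise: per-sample, per-ASV log-normal with SD 0.3
  (aquarium-to-aquarium variation);
* library sizes ~ negative binomial (mean 6215, size 30), counts
  multinomial at the drawn depth (a Dirichlet-multinomial option adds
  extra overdispersion).

Simulations are byte-reproducible from a seed. What they do *not*
emulate: taxonomic structure, phylogenetic correlation among ASVs,
chimeras/sequencing error, 18S communities, grazer behaviour, or
between-grazer interactions. Passing recovery tests therefore
demonstrates statistical correctness of the estimator under its own
assumptions, not robustness to real-data artefacts.

Measured behaviour under the default conditions (see
`tests/test_acceptance.py` and `scripts/acceptance.py`): with ±1
effects at depth ~6215 and >= 10 replicates, mean estimation bias is
well inside ±0.25 and the sign of every significant truly-affected
edge is recovered (accuracy >= 0.95); with all effects zero, the
significant-edge rate at alpha = 0.05 stays within [0.02, 0.10].

**A precision ceiling is intrinsic to the screening design.** With 10%
of pairs truly affected and alpha = 0.05 uncorrected, false positives
(~0.05 x the null pairs) are of the same order as the true edges, so
edge *precision* cannot approach 1 no matter how well calibrated the
test is (~0.5-0.75 here; ~0.75-0.95 with the BH flag). A second,
compositional contribution: closure means a sparse effect shifts every
other ASV's clr by -mean(delta), so "null" pairs carry small true
clr-contrasts. Recall (>= 0.9) and sign accuracy are the reliable
quantities; network-level conclusions should weight them accordingly.

## Networks and their metrics

Significant effects are split by mode (trophic / non-trophic) and sign
into four bipartite grazer x ASV networks with weight |DI|; the sign
lives in metadata so all metric code consumes non-negative weights (as
weighted nestedness definitions assume). Grazer rows are always
retained for comparability; ASV columns without edges are dropped
(NODF's pair-count denominator is sensitive to empty columns).

Binary metrics (NODF/NODF2, matrix temperature, discrepancy/
discrepancy2) consume the binarised matrix; weighted metrics (weighted
NODF, WNODA, WINE) and specialization (H2', d') consume the |DI|
weights. All metric formulas, constants and tie rules are frozen in
`docs/metrics_reference.md`; headline numerical choices:

* temperature: superellipse isocline, simulated annealing over
  row/column orders (default 20 000 proposals, seeded) from a
  decreasing-fill warm start; permutations of the input move the result
  by < 2 units at the default budget;
* weighted NODF reproduces vegan's `nestednodf(weighted=TRUE)`
  convention (verified against it);
* WINE is reported both raw (mean weighted link distance to the packed
  corner) and normalised between its random and maximally packed
  calibrations; published WINE values on other scales are not directly
  comparable;
* H2': weights are integerised to 1000 units; extremal entropies under
  fixed marginals come from greedy construction plus steepest
  2x2-swap refinement with 60 randomized restarts (deterministic
  internal seeding) — exhaustive enumeration confirms exactness for
  totals <= 12; results are clipped so H2_min <= H2 <= H2_max always
  holds. d' uses the continuous lower bound d_min = 0.

## Community-level statistics

Rarefaction subsamples each library without replacement (multivariate
hypergeometric, seeded) to a fixed depth (default 6215, off by default
in the effect pipeline); richness counts nonzero ASVs; Shannon uses
natural log. Bray-Curtis feeds a one-way PERMANOVA: pseudo-F from the
direct among/within sum-of-squares partition of squared
dissimilarities, p = (1 + #{F_perm >= F_obs}) / (n_perm + 1) over
seeded label permutations (default 9999); groups that are internally
identical give F = infinity, handled explicitly. The implementation is
cross-checked against scikit-bio's PERMANOVA statistic in the tests.
Pairwise post hoc contrasts with Benjamini-Hochberg adjustment are
provided as a convenience.

## Problem sizes and open choices

Test and acceptance runs use 60-150 ASVs, 999 bootstrap draws, 99-999
permutations and 200 Monte-Carlo replicates — sizes chosen so the
whole suite completes in a few minutes while keeping Monte-Carlo
standard errors well below the asserted tolerances. Choices that were
genuinely open and are therefore flag-controlled rather than baked in:
the pseudocount (results for rare ASVs are sensitive to it), the DI
space, rarefaction before estimation (off by default), the CI rule
(percentile bootstrap), and whether metrics consume weighted or
binarised matrices (both supported, recorded in the report).
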
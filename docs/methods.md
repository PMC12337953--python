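# Methods

This note documents the models, parameters and design choices behind
`idpome`, and what its tests do and do not establish.

## Scope and stance

The package implements a comparative proteome-profiling analysis: given one
FASTA file per proteome, it quantifies per-residue intrinsic disorder,
aggregates it to per-protein and per-proteome summaries, performs CH–CDF
quadrant analysis, detects phase-separating IDRs, and compares proteomes
statistically. It deliberately does **not** reimplement trained disorder or
LLPS predictors (the PONDR family, IUPred, gradient-boosted LLPS models,
or ParSe's fitted polymer model): their weights are not reproducible from
the literature. Instead it provides two transparent sequence-only
predictors with the same output contract (scores in [0, 1], 0.5 midpoint)
and accepts any external predictor's per-residue or per-protein scores via
tab-separated tables, which enter the pipeline as first-class predictors.
All downstream machinery — tiers, CDF curves, quadrants, PS-IDR summaries,
statistics — is agnostic to where the scores came from.

## Disorder profiles

**Windowed charge–hydropathy profile** (`foldindex`). Kyte–Doolittle
hydropathies are min–max normalized to [0, 1] (⟨H⟩); residue charges are
K, R = +1 and D, E = −1 with histidine, termini and phospho-states ignored
(the standard CH-plot convention at pH 7). Over a centred window
(default 21 residues, truncated at the termini — no virtual residues) the
raw score is FI = 2.785·⟨H⟩ − |⟨R⟩| − 1.151, the classical discriminant
between compact and natively unfolded proteins. The disorder score is
s = clip(0.5 − FI/2, 0, 1), an affine map chosen so that the discriminant's
zero line corresponds exactly to the conventional 0.5 order/disorder
midpoint and the [−1, +1] FI band spans the unit interval.

**Propensity-scale profile** (`topidp`). The TOP-IDP scale (a per-residue
order/disorder propensity derived to maximally separate ordered from
disordered sequence sets) is min–max normalized over its 20 values and
averaged over the same windows. Having two built-in predictors with
different information sources (physicochemical discriminant vs empirical
scale) lets tests assert rank agreement on archetypes rather than trusting
a single construction.

**Consensus.** A non-negative weighted per-residue mean of any number of
same-length profiles, mirroring the common practice of averaging a panel of
predictors. No headline quantity depends on it.

The default window of 21 residues is a typical smoothing length for
per-residue disorder predictors: long enough to suppress single-residue
noise, short enough to resolve domain-scale order/disorder transitions.

## ADS, PPDR and tiers

ADS is the mean per-residue score; PPDR is the percentage of residues
scoring **strictly above** 0.5. Two-axis tiers are assigned in precedence
order: (1) highly disordered if PPDR ≥ 30% **or** ADS ≥ 0.5; (2) highly
ordered if PPDR < 10% **and** ADS < 0.15; (3) moderately disordered if both
axes fall in their middle bands; (4) a residual
moderately-ordered-or-mildly-flexible tier for discordant combinations.
The disjunctive top-tier rule is the default because it is the only reading
consistent with published tier tables in which the residual tier can be
empty; a conjunctive variant is selectable
(`ClassificationThresholds(highly_disordered_rule="and")`). An ADS-only
three-way split at 0.15 and 0.5 (lower bounds inclusive) is also provided.
Tier percentages use the sum of tier counts as denominator and are reported
to two decimals.

## CH–CDF analysis

The per-protein CH score is the whole-sequence (not windowed) form of the
same discriminant, signed so that positive = disordered:
CH = |⟨R⟩| − 2.785·⟨H⟩ + 1.151. The CDF curve evaluates, at seven
thresholds 0.1 … 0.7, the fraction of residues with disorder score ≤ t.
Classical CDF analysis compares this curve against a boundary fitted to a
specific predictor's training sets; since this package's profiles are not
that predictor, the boundary is **calibrated**: at each threshold it is the
midpoint between the mean curves of an ordered and a disordered reference
proteome. The shipped reference sets are the synthetic archetypes
(200 + 200 proteins, fixed seed), and calibration is deterministic given
the sets; identical sets raise a degenerate-calibration error. The scalar
CDF score is the mean signed distance of the curve above the boundary
(positive = ordered); this mean-signed-distance definition, rather than
counting boundary crossings, is this package's own choice and is what the
quadrant assignment consumes.

Quadrants partition the (CH, CDF) plane: Q1 (CH ≤ 0, CDF ≥ 0) structured;
Q2 (CH ≤ 0, CDF < 0) molten-globule/hybrid; Q3 (CH > 0, CDF < 0) highly
disordered; Q4 (CH > 0, CDF ≥ 0) mixed. Zeros are tie-broken to the
ordered side of each axis; the assignment is total and deterministic.

## PS-IDR detection

A window of 25 residues (matching the minimum analysable sequence length)
is labelled from two features: the window's CH-convention score (positive =
disordered) and its sticker fraction — the share of residues in
{R, G, F, Y, W, Q, S}, the aromatic/arginine/glycine-rich set
over-represented in phase-separating low-complexity regions. Labels:
**P** if disordered and sticker fraction ≥ 0.4; **D** if disordered only;
**F** otherwise. Residues covered by any P window are merged; maximal runs
≥ 20 residues are PS-IDRs. The per-protein propensity score is the fraction
of residues covered by PS-IDRs, so raising the sticker threshold can only
shrink it (a tested monotonicity). Sequences shorter than 25 or longer than
10,000 residues are excluded and logged, mirroring the length filter of
sliding-window LLPS predictors. The 0.4 sticker threshold was set so the
PS-prone synthetic archetype (sticker fraction ≈ 0.9) is labelled P and the
ordered archetype F, with the disordered archetype mostly sub-threshold.

Proteome summaries: the cumulative curve reports, for each length L, the
percentage of proteins whose longest PS-IDR is ≥ L (non-increasing,
starting at 100% for L = 0); the recall AUC sweeps a score threshold from
high to low, plotting test-proteome recall against reference recall and
integrating by trapezoid. With ties split evenly this equals the
Mann–Whitney probability P(test > ref) + ½·P(test = ref), so 0.5 is the
exact null and values above 0.5 indicate enrichment in phase-separation
potential. The tests verify this equivalence against a brute-force pairwise
oracle.

## Statistics

ANOVA (scipy `f_oneway`), Tukey HSD (scipy `tukey_hsd`), pairwise Welch
*t* (scipy `ttest_ind`, unequal variances, optionally Holm/Bonferroni via
statsmodels) and the plain Pearson χ² (scipy `chi2_contingency` without
continuity correction) sit behind typed wrappers that validate inputs and
expose degrees of freedom. Welch is the pairwise default because pooled
variances are rarely defensible across proteomes of very different sizes;
no multiplicity correction is applied by default since Tukey HSD is
reported separately. The χ² uses no small-expected-count correction —
published quadrant tables include expected cells < 5 and are tested as-is —
and requires positive row/column margins; the comparison workflow drops
all-zero quadrant columns before testing, since zero-margin categories
carry no information. Tests check every statistic against hand computations
and brute-force sum-of-squares / first-principles oracles.

## Synthetic proteomes

The generator emulates the statistical structure the analysis consumes, not
real proteomes. Archetypes: ORDERED (hydrophobic-rich i.i.d. composition,
I/L/V/F/A-weighted), DISORDERED (P/E/S/K/Q/G-rich), PS_PRONE (6-residue
sticker blocks from an R/G/Y/S/F/Q-weighted composition alternating with
3-residue polar spacers), MIXED (ordered + disordered halves). Lengths are
uniform on (100, 400) residues by default — a realistic span for
single-domain proteins plus tails while keeping simulations fast.
Mixture fractions are realized exactly by largest-remainder rounding (ties
resolved in archetype declaration order); record order is shuffled so ids
carry no label information. One integer seed drives a splittable
`numpy.random.SeedSequence` stream per protein, so any subset regenerates
independently. What the generator does **not** model: realistic length and
composition distributions, sequence order beyond the PS block structure,
homology, post-translational modification, or expression levels. Passing
the parameter-recovery tests therefore shows the pipeline is internally
consistent and sensitive to planted composition signals — not that it
reproduces any trained predictor's output on real proteomes.

## Shipped published counts

`idpome.datasets` carries the summary count tables of a published
comparative survey of six retinal proteomes (a healthy-reference set, an
inherited-retinal-disease gene panel, and AMD, glaucoma, and diabetic
retinopathy ± gliosis proteomes): quadrant counts, tier counts, proteome
sizes and overlap splits. These let the contingency statistics and
percentage arithmetic be recomputed from data inside the package. The
healthy-reference quadrant row sums to 12,819 while the stated proteome
size is 12,844; both are preserved as printed, and percentage checks use
the denominators implied by each table.

## Problem sizes and numerical choices

Simulation-based tests use n = 500 proteins per proteome for
parameter-recovery and null-AUC checks and n = 200 per group for power
checks — sizes at which the planted effects are comfortably resolvable and
the full suite runs in seconds. Profiles are computed with O(n) cumulative
sums; all floating-point comparisons in tests use explicit tolerances
(1e-10 relative for oracle identities, looser bands for stochastic
quantities). Degenerate inputs (empty sequences, zero-variance groups,
zero-margin tables, identical calibration sets, empty overlap groups) raise
typed errors or are skipped with a logged reason, never silently coerced.

## Known limitations

* The built-in predictors are untrained physicochemical constructions;
  absolute ADS/PPDR levels on real proteomes will differ from trained
  predictors, which is why external score tables are first-class inputs.
* The calibrated CDF boundary is only as good as its reference sets; with
  the synthetic defaults it separates archetypes, but real-proteome use
  should calibrate against curated ordered/disordered sets.
* The PS-IDR detector captures composition-level LLPS signals (disorder +
  stickers) and ignores patterning effects (charge blockiness, aromatic
  spacing) that sequence-order-aware models exploit.
* Overlap analysis matches by identifier only; it assumes consistent
  accession schemes across the compared FASTA files.
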
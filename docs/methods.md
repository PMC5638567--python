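# Methods

This note documents the models, numerical choices and known limitations of
`taqase`. Units: cycles are PCR cycle numbers (integers 1..n, default
n = 46); fluorescence is in arbitrary instrument units; allele quantities
are fractions in [0, 1] of the *P. mexicana*-derived (VIC-probed) allele,
shown as percentages only in human-readable reports.

## Amplification-curve model

Each well × channel trace of raw fluorescence is fitted with the
four-parameter logistic

    F(t) = y0 + a / (1 + exp(-(t - b) / c))

where `y0` is the baseline, `a` the plateau amplitude above baseline, `b`
the inflection cycle (cycle of maximum amplification speed) and `c` the
slope scale. The ratio statistic below names only (a, b, c) per channel;
the model is completed with the baseline `y0` because raw, non
background-subtracted fluorescence is fitted — this is the standard 4PL
completion and makes the fit shift- and scale-equivariant (tested
properties).

Fitting is trust-region nonlinear least squares (`scipy.optimize.
least_squares`, method `trf`) with an analytic Jacobian, tolerances
xtol = ftol = gtol = 1e-10 and at most 2000 residual evaluations. Bounds:
y0 ∈ [min−range, max], a ∈ (0, 10·range], b ∈ [0, 2n], c ∈ [0.05, n]; the
lower bound on `c` keeps the branch logic of the ratio statistic
well-defined. Seeds come from simple heuristics (y0 = min, a = range, b =
cycle of the largest first difference with ties resolved to the median
tied cycle, c = spread of the 25–75% rise divided by 2·ln 3, floored at
0.5). On optimizer failure, up to 5 multi-starts jitter the seeds by ±30%
with a fixed internal seed, so results are deterministic.

**No-amplification detection.** A channel whose total signal range falls
below max(10 × robust read-noise sigma, machine epsilon of the data scale)
is flagged as non-amplifying rather than fitted; the noise sigma is
estimated from successive differences (median |ΔF| × 1.4826/√2), which is
insensitive to the smooth amplification trend. This catches both exactly
flat traces and baseline-plus-noise traces such as the null channel of a
pure-plasmid standard.

**Two-step fit.** Real plates vary in how many plateau cycles they record,
and the plateau (drift, reagent exhaustion) biases the parameters. Step 1
fits the full trace; step 2 refits using only cycles ≤ ⌈b̂ + 3ĉ⌉ (about
95% of the plateau reached), clamped to [b̂+2, n]. If truncation would
remove fewer than 2 cycles or leave fewer than 8 points, the step-1 fit is
returned; a non-converging refit falls back to step 1 with a flag. The
truncation rule is exposed as a configurable callable; the published
description of the original two-step procedure is not detailed enough to
reproduce exactly, so this rule is a documented stand-in with the same
purpose.

## The transformed fluorescence ratio

With channel fits (a_fam, b_fam, c_fam) and (a_vic, b_vic, c_vic):

- b_fam < b_vic:  R′ = ½ · (a_fam/a_vic) · (1 + exp(−(b_fam − b_vic)/c_vic))
- b_fam > b_vic:  R′ = 2 · (a_fam/a_vic) / (1 + exp(−(b_vic − b_fam)/c_fam))
- b_fam = b_vic (within 1e-9 cycles): both expressions coincide at
  a_fam/a_vic, reported as a TIE branch.

k′ = R′/(R′+1) maps (0, ∞) monotonically onto (0, 1) with k′(1) = 0.5.
The equations are implemented exactly as printed, FAM in the numerator;
no orientation "correction" is attempted. Under the package's own
generative model k′ *decreases* in the VIC-allele fraction; the
calibration regression has an unconstrained slope, so the estimator is
direction-agnostic and only strict monotonicity matters (a tested
invariant). Swapping the channels maps k′ to 1 − k′ only when
c_fam = c_vic; the general asymmetry is inherent to the printed equations.

## Calibration

The replicate-averaged k′ of each standard is regressed on the known
mixture fraction x (k′ = intercept + slope·x, OLS); unknowns are inverted
analytically, x̂ = (k̄′ − intercept)/slope, and clamped to [0, 1] with an
explicit flag (raw inversions can leave the calibrated range, as pure
plasmids do on real plates). Replicates are averaged before inversion;
per-replicate inversions are also reported so downstream dispersion is
available. Pure standards (x = 0, 1) are excluded from the regression by
default — they behave aberrantly in the assay — but still enter the
precision summaries: CV% = 100·sd(k′ replicates, n−1)/mean, and the
Intra-CV is the unweighted mean CV over all 13 standards even though the
regression uses 11. R² is invariant to the regression direction, so the
reported linearity is comparable either way.

No confidence intervals are propagated from the calibration fit
(Fieller-type intervals are out of scope); dispersion is reported as
replicate sds.

## Tissue-level inference

Statistics run on one value per biological sample (technical replicates
are collapsed by the calibration step), on the fraction scale. Deviation
from balanced expression is a two-sided one-sample t-test against 0.5 at
α = 0.05; a zero-variance group is reported as degenerate (p = 1 at the
null, infinite t otherwise). Across tissues, a one-way fixed-effects ANOVA
is followed by Tukey HSD (family-wise adjusted p); Bonferroni-adjusted
pairwise t-tests are available as an alternative. Mixed models accounting
for replicate nesting are deliberately out of scope at n = 4 fish per
tissue.

## Promoter comparison and CpG islands

The two promoter alleles are aligned globally (match +1, mismatch −1,
linear gap −2) with Biopython's PairwiseAligner; a linear gap penalty
suffices because the alleles differ by a single 1 bp indel. A columnwise
scan reports SNPs and indel events (adjacent gap columns merged), with
1-based positions on the first sequence; insertion positions refer to the
next base of sequence A. Test oracles check the optimal score against
exhaustive enumeration for short sequences.

CpG islands follow the classic sliding-window criteria: window 200 bp,
step 1; a window qualifies when GC > 50% and observed/expected CpG =
(N_CpG·L)/(N_C·N_G) > 60% (both strict, per the usual definition; 0 when
N_C·N_G = 0). Overlapping or adjacent qualifying windows merge; merged
regions of length ≥ 200 bp are reported with statistics recomputed over
the whole region, and a merged region whose recomputed statistics fall
below the thresholds (flank dilution) is dropped. `N` bases are excluded
from every numerator and denominator. The exact post-processing of the
popular web tools is not public, so merged-region statistics here are a
documented convention, not a byte-for-byte reproduction.

## Synthetic data generator

The simulator emulates the statistical structure the analysis assumes,
not instrument physics. Amplicon pools compete for one reagent-limited
carrying capacity K and each pool slows as its own product accumulates
(self-reannealing, which is amplicon-species-specific):

    N_ch(c+1) = N_ch(c) + eff_ch · N_ch(c) · (1 − T(c)/K) / (1 + N_ch(c)/H)

with T = N_fam + N_vic, initial split N_vic(0) = x·total and N_fam(0) =
(1−x)·total. Fluorescence is baseline + gain·N_ch + iid Gaussian read
noise. Defaults (per unit K = 1): total template 1e-6, efficiency 0.9 per
cycle, self-inhibition scale H = 0.25, probe gain 3, baseline 0.1, read
noise sd 0.005, 46 cycles. These place inflection cycles near 18–30 as in
routine TaqMan runs and give replicate CVs of k′ in the 0.01–3% range seen
on real plates.

Why the self-inhibition term: with a purely shared capacity and equal
channel efficiencies the allele ratio is conserved every cycle, so both
channels would inflect at exactly the same cycle and the branch-conditional
part of R′ would never engage. Channel-specific product inhibition makes
the majority allele reach maximum speed earlier (separating b_fam and
b_vic), compresses the k′ range toward the middle as real dual-probe
plates show, and preserves the resource bound T ≤ K. H = 0.25 is the
strongest (most plate-like) compression that retains the near-perfect
calibration linearity observed on real plates (simulated standard-curve
R² ≈ 0.993).

Per-well randomness derives from `SeedSequence([master_seed, well_index])`,
so plates are bit-reproducible and wells independent. Pure standards
(x = 0 or 1) leave one channel at baseline noise; the pipeline logs these
wells as non-amplifying and the calibration proceeds on the 11 mixed
standards.

Study-level designs add fish-to-fish biological variation: each biological
sample's true fraction is drawn Normal(tissue mean, tissue sd) with
defaults ovary 0.770 ± 0.02, brain 0.462 ± 0.04, gill 0.407 ± 0.09 — the
per-tissue means and between-fish sds observed in the original assay —
while the gDNA design uses exactly 0.5 (a heterozygous genome is 1:1 by
construction). Without biological variation the pipeline's technical
precision (≈0.003 in x̂) would declare any tissue mean ≠ 0.5 significant,
which is not how the real between-fish data behave.

Promoter pairs: sequence A is drawn from an AT-rich background (GC 30%)
with an iid CG-rich block (GC 80%, O/E ≈ 1) over a configurable span;
sequence B equals A with one substitution and one 1 bp deletion at
configurable 1-based positions (defaults 77 and 231, the deletion inside
the planted island). The deleted base is forced to differ from both
neighbours so the optimal alignment, and hence the reported position, is
unique.

What the generator does *not* emulate: probe cross-talk and
cross-hybridization, cycle-correlated drift (available only as an explicit
test scenario), pipetting error in the standard mixtures, and instrument
noise spectra. Passing the simulation-based tests therefore shows the
estimator chain is correct and well-calibrated under the assumed
structure, not that it is robust to every artefact of real plates.

## Problem sizes and determinism

Simulation-based checks use one plate of 13×3 standards plus 3–12 unknown
samples in triplicate (48–75 wells); seeded panels use 20 seeds for
recovery, 40 for the gDNA null behaviour and 100 for the tissue pattern.
Every stochastic component takes an explicit integer seed, and all panel
checks use fixed seed lists. Statistical pass rates sitting exactly at the
nominal test size (e.g. 1 − α non-rejection for a true null) are asserted
with one-sided binomial tolerance rather than as exact counts, since an
exact count assertion on a finite panel would flip by sampling noise
alone.

## Known limitations

- The linear calibration inherits a small systematic bias (≲0.035 in x̂ at
  the range edges) from the curvature of the simulated assay response; on
  real plates this term is whatever the true response curvature is.
- The two-step truncation rule is a documented stand-in (see above).
- The deviation-from-1:1 criterion is a per-tissue t-test at α = 0.05; a
  tissue whose true mean is near but not at 0.5 will be flagged in a
  corresponding fraction of repeated experiments. This is a property of
  the test, not of the implementation.
- Ct/Cq calling, efficiency estimation from dilution series, melt curves,
  ΔΔCt-type estimators and alternative sigmoid families (5PL, Richards)
  are out of scope.
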
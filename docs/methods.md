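# Methods

## Competition model

The simulator and the inference machinery share one model of a pooled
serial-dilution competition. Each 48-hour cycle dilutes a saturated
10 mL culture 1:250, giving `g = round(log2(250)) = 8` generations of
regrowth per transfer (23 transfers ≡ 184 generations). Within a cycle,
selection is deterministic exponential growth: lineage frequencies are
multiplied by `exp(g·s)` and renormalised. Between cycles an optional
finite bottleneck multinomially resamples the `N` transferred cells —
the only source of drift. Fitness `s` is a per-generation natural-log
selection coefficient relative to a neutral reference strain (`s ≡ 0`),
carried by several independently barcoded replicates of one lab strain
mixed in at 9:1 (wild:reference) mass.

Assumptions: fitness is constant per lineage (no frequency dependence),
selection within a cycle is summarised by its per-generation average (no
lag/exponential/saturation structure), and barcodes are neutral tags.
Beneficial mutations, when enabled, found sublineages at frequency `1/N`
with fitness increments drawn from an exponential distribution
(per-cell, per-transfer rate); bookkeeping is internal and all
observable output is aggregated by founding barcode, because sequencing
reads barcodes, not mutations.

## Observation model and fitness inference

Read counts are negative binomial with mean `f·R_t` and variance
`κ_t·f·R_t`, realised by the Gamma–Poisson construction (`κ = 1` is
exactly Poisson). The likelihood for one barcode combines the predicted
trajectory

    f(t_k) = f0 · exp( g · Σ_{j<k} (s − x̄_j) Δt_j )

with the NB log-pmf at each timepoint. Mean fitness `x̄_j` over interval
`j` is `ln(F_ref(t_j)/F_ref(t_{j+1}))/(g Δt)` from the summed reference
frequency — anchoring on the reference breaks the model's gauge freedom
(the likelihood is invariant under adding a constant to `s` and every
`x̄_j`), so only reference-relative fitness is identifiable.

Dispersion is calibrated from the references: within each interval the
residuals of `d_i = ln(f_i(t+1)/f_i(t))` around their median estimate
`κ ≈ Var(d)/mean(1/r(t) + 1/r(t+1))`. The pooled value is the ratio of
the summed squared deviations to the summed expected Poisson variance
across all intervals, floored at 1. We pool by ratio-of-sums rather than
taking a median of per-interval ratios because with six reference
barcodes each interval contributes ~5 degrees of freedom and the median
of five such noisy ratios has heavy tails (empirically up to ~3 under
true κ = 1), while the ratio-of-sums estimator concentrates near truth.

Optimisation is bounded L-BFGS-B over `(s, ln f0)` from a closed-form
start (regression of pseudocounted log frequency, plus the cumulative
mean-fitness correction, on cumulative generations), with a Nelder–Mead
polish when the line search stalls on near-noiseless likelihoods. The
standard error combines two terms in quadrature: the observed-information
diagonal (numerical Hessian, central differences), and a shared
mean-fitness-scale term — the reference pool shrinks over the
competition, so `x̄` for late intervals is estimated from few reads, and
this error moves every barcode's estimate coherently. It is propagated
as `Σ_k w_k² · κ / r_ref(t_k)` with `w_k` the slope weights of the
trajectory regression. Without it, nominal 95% intervals undercover
within a single experiment.

Numerical choices: predicted means are clipped below at `10⁻¹²·R_t` to
keep the log-pmf finite; `s` is bounded to [−2, 2] per generation
(boundary hits are flagged); barcodes with all-zero counts in the window
are flagged extinct and left NaN; the initial-guess regression uses a
pseudocount of 0.5 while the final likelihood uses raw counts. Interval
fitness (e.g. T5→T9) is reported both as raw log fold change and per
generation, since either convention is in use; replicate combination is
reported both inverse-variance-weighted and unweighted.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis relies
on: a ~300-strain pool with 6 reference barcodes at 9:1 mass, 1:250
transfers at g = 8, NB-overdispersed counts with per-timepoint κ,
amplicon reads with constant regions, dual sample indices, a 20-bp
barcode slot and uniform substitution errors, evolved-clone genomes with
het/hom SNVs, LOH tracts over ancestrally heterozygous sites,
whole-chromosome aneuploidies and segmental amplifications (expected
depth × copies/ploidy, Poisson-perturbed), and two-component cytometry
event tables with doublets outside the 0.9–1.03 area/height singlet
gate.

It does not emulate: PCR chimeras or index hopping, quality-score
structure (qualities are constant), GC/mappability coverage bias,
allelic imbalance of het sites on aneuploid chromosomes, subclonal
mixtures, growth-curve dynamics within a cycle, or frequency-dependent
selection. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to those real-data
artefacts.

Defaults chosen where the protocol leaves them open: wild fitness is a
normal bulk (σ = 0.02) plus an exponential right tail (5% of strains,
mean 0.05), covering both flat- and spike-tailed environments; starting
frequencies are log-normal (σ = 0.5) around an even pool; the bottleneck
defaults to 10⁵ cells — desk-scale, far below the real ~40 µL of
saturated culture, but large enough that drift is subdominant to
measurement noise at the default depths; all stage seeds derive from one
integer via hashed spawn keys so stages are independently reproducible.

## Decision rules

Barcodes: constant regions match positionally with a per-segment
mismatch tolerance (default 1); sample indices match exactly (cross-talk
between samples is worse than read loss); barcode assignment accepts the
unique catalog entry within edit distance 1 and never guesses on ties;
N counts as a mismatch. Conservation (assigned + unassigned = total per
sample) holds by construction.

Variant classification (allele fractions from allele depths, not
genotype calls): filters run in order — multiallelic, ancestor
uncertain (missing genotype, GQ < 99, or ancestor depth outside
[5, 2×median]), depth < 5, depth > 2×median (exactly double is kept),
GQ < 99, blacklist (BED, 0-based half-open) — with first-matching-rule
attribution so removal counts are additive. A focal alt fraction in the
closed band [0.2, 0.8] with everyone else outside is a de novo het; a
focal fraction beyond 0.8 (or below 0.2) with everyone else on the
opposite side is a de novo hom; a focal fraction outside the band while
the ancestor and all other clones are strictly inside it is LOH. The
same thresholds serve triploid ancestors, whose het fractions (1/3,
2/3) fall inside the band. Gene-level parallelism counts clones (not
variants) with ≥ 1 high-impact (frameshift/nonsense) variant per gene
per (ancestor strain, environment) group; LOH direction at a shared
locus is convergent/divergent/mixed by the resolved homozygous allele.

Karyotype: copy ratio = chromosome median depth / genome median depth,
rounded to the nearest 0.5 with half-way values away from zero; samples
with genome median ≤ 6 are ineligible; organelle/episome contigs are
excluded from the genome median. The segment caller (invented plumbing
— no method is standard for this step) reports runs of ≥ 20 consecutive
1-kb bins deviating ≥ 0.4 from the chromosome baseline. Events must
occupy a small fraction of the genome for the median normalisation to
stay anchored; a genome where a quarter of all bases are amplified
shifts the median itself.

Cytometry: singlet gate keeps area/height in [0.9, 1.03] inclusive; the
fluorescence threshold minimises total control misclassification (the
midpoint of the separating gap when separation is perfect), refusing
swapped (fixable by flipping labels) or inseparable (> 40%
misclassification either way) controls; dark fractions from fewer than
10,000 gated events carry a low-event flag. Relative fitness is the
difference of trapezoid AUCs of dark fraction versus time on the
overlapping window (antisymmetric, zero on identical series). The
flocculation score reads the 0.8 factor as scaling the denominator,
`1 − top/(0.8·bottom)` after blank subtraction, so a fully suspended
culture whose top fraction keeps 80% of bottom density scores 0; the
alternative precedence is available behind a flag. Ploidy classes use
midpoints on the haploid/diploid-control-calibrated linear DNA-content
axis.

## Problem sizes in the test-suite and acceptance script

Fitness recovery runs the full design (300 strains + 6 references, 10⁶
reads/timepoint, κ = 2, 6 timepoints); the grid oracle checks 20
barcodes against a 1001 × 601 (s × f0) grid through an independent
scipy.stats.nbinom evaluation; variant recovery uses two 100-kb
chromosomes with ~200 het sites and 7 injected events at 30×; karyotype
recovery uses a 1-Mb genome (trisomy and a 100-kb amplification in
separate clones, ≤ 10% of bases amplified) at depths 10 and 30, and 50
euploid seeds; finalist logic checks 20 independently drawn 80-strain
pools against the closed-form replicator solution. These sizes make the
whole suite run in minutes on one core while keeping every estimator in
its intended operating regime.

## Known limitations

- Dispersion is per timepoint, not per barcode; PCR jackpotting that
  hits individual barcodes would violate this and bias their estimates.
- The mean-fitness track is undefined across intervals where the
  reference drops below the floor; fit windows are truncated there
  rather than bridged.
- The standard error ignores uncertainty in κ̂ itself (a ~25-df scale
  estimate), which adds a few percent of interval undercoverage in
  small designs.
- `call_segments` parameters (20 bins, Δ = 0.4) are exposed but not
  auto-tuned; deletions and amplifications share one deviation rule.
- The cytometry threshold is 1-D (fluorescence only); a 2-D scatter ×
  fluorescence gate is out of scope.
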
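# Methods

## Measurement model

All analyses treat SAB fluorescence as log-normally distributed: technical
effects act multiplicatively on MFI, hence additively on `log10(MFI)`. The
synthetic generator makes this explicit:

```
log10(MFI) = μ_locus + b_bead + l_lot + r_run + s_sample
             + a_signal·1[antibody] + boost·1[self allele] + ε
```

* `μ_locus` — baseline (antibody-free) mean log10 MFI of a locus group;
* `b_bead ~ N(0, σ_bead²)` — a stable per-bead level offset (some beads
  simply run hotter than others);
* `l_lot ~ N(0, σ_lot²)` — a kit-lot offset shared by all runs using that
  lot;
* `r_run ~ N(0, σ_run²)` — a per-acquisition-run offset shared by every
  bead and serum on that run (day/instrument/operator);
* `s_sample ~ N(0, σ_sample²)` — per-acquisition handling of one serum
  (dilution, thawing); drawn fresh each time an aliquot is measured;
* `a_signal ~ N(signal_mean, signal_sd²)` — the true antibody signal of a
  (patient, bead) pair, drawn once per pair and constant over the cohort's
  time span; self-allele beads never receive antibody signal;
* `boost` — additive background on beads coated with the patient's own
  allele(s), largest for HLA-C where self background is most pronounced;
* `ε ~ N(0, σ_resid²)` — residual measurement noise.

All effects are independent, so variances add on the log10 scale; the suite
checks this additivity empirically at n = 10⁵.

## Default parameters

Locus means and *total* per-bead SDs follow the values typical of clinical
class I / class II panels (log10 means 2.08–2.26; total SDs 0.47–0.53, i.e.
2.9–3.4-fold changes). Published summaries report only totals, so the split
into components is an explicit modelling assumption: 50% of the variance to
the bead effect, 15% + 15% to run and sample handling (σ_run = σ_sample =
√(0.15)·0.50 ≈ 0.194), and the remainder (≈20%) to the residual, with a
small extra lot effect (σ_lot = 0.05). Every share is overridable through
`GeneratorConfig`.

A consequence worth stating: the bead-wise SD measured on repeat
measurements of one bead excludes the bead effect, so on synthetic data the
locus-summary SDs land near √(lot²+run²+sample²+resid²) ≈ 0.71 × total
(≈0.35–0.40), not at the configured totals. Parameter-recovery tests
therefore check the *within-bead* SD implied by the configuration, and the
generator makes no attempt to reproduce any particular cohort's printed
summary values.

The default cohort is 120 patients × 2 sera, runs of 10 acquisitions
cycling through 6 lots, a panel of 90 class I beads (30 A / 45 B / 15 C) and
78 class II beads (25 DRB1, 3+2+3 DRB3/4/5, 25 dual-coated DQ, 20
dual-coated DP) — 21,600 class I antigen-bead measurements. Antibody
prevalence is calibrated so the 1500-MFI filter removes ≈19% of class I and
≈16.5% of class II measurements, the removal rates reported for clinical
cohorts: nominal fraction 0.198 (class I) / 0.185 (class II) of
patient × bead pairs positive, with signal mean 2.0 and SD 0.5 log10 units
above baseline (typical positives ≈ 12,000 MFI). The calibration was solved
from the marginal-tail expectation of the model, accounting for the
exclusion of self beads from antibody assignment.

Patient typing is drawn from the bead panel itself (two alleles per locus;
DQ and DP as α/β haplotypes so that dual-coated "both alleles self" cases
occur; DRB3/4/5 carried by about half the cohort). One integer seed feeds a
single `numpy` generator with a fixed draw order (lot effects, bead effects,
typing, antibody, run effects, sample effects, residuals), so cohorts are
byte-reproducible across platforms.

### What the generator does not emulate

Prozone/hook effects, complement interference, epitope-level
cross-reactivity between beads, denatured-antigen artifacts, operator
learning effects, and drift within a run. Passing tests demonstrate that the
pipeline's algebra and statistics behave as designed under the stated noise
model — not that any particular clinical cohort will show the same locus
ordering or significance pattern.

## Variability pipeline choices

* **Filter boundary.** "Above 1500" is strict: a measurement at exactly
  1500 is kept. The filter partitions its input and is idempotent.
* **Floor before log.** Raw exports contain zero/negative MFI; values are
  floored at 1 (log10 = 0) before transforming. The floor preserves
  ordering and keeps every statistic finite.
* **Bead SD.** Sample SD (n−1) over a bead's measurements; beads with fewer
  than two measurements are dropped with a warning.
* **Group SD.** The arithmetic mean of bead-level SDs (each bead one
  observation), matching the convention of plotting per-bead SDs with a
  group mean line; a pooled-SD alternative is available via
  `locus_summary(..., group_sd="pooled")`. Extreme beads are reported by
  allele label with lexicographic tie-break, so reports are deterministic.
* **Self alleles.** Matching is exact at two-field resolution after
  normalization (no G/P-group expansion); dual-coated beads require both
  alleles self. Self-allele summaries use *unfiltered* raw MFI — self
  background can legitimately exceed the positivity threshold, and
  truncating it would bias the background estimate downward.
* **Controls.** Control beads are flagged at ingest and excluded from all
  analyses by default; the positivity filter would remove essentially all
  positive-control measurements anyway.

## Statistics

Bead-level SDs are compared between groups with the two-sided Wilcoxon
rank-sum test (exact null distribution when the pooled size is ≤ 20 and
tie-free; otherwise normal approximation with tie and continuity
corrections — the scipy `mannwhitneyu` backend, cross-checked in the suite
against full permutation enumeration). Families of pairwise comparisons use
Bonferroni correction with the family size equal to the number of pairs;
lot-stratified families are run per lot, and correction can be disabled, as
uncorrected reporting is conventional for per-lot exploratory comparisons.

Effect sizes are rank-biserial correlations, `r = 2·AUC − 1` with
`AUC = P(x > y) + ½P(x = y)` over all between-group pairs — the natural
companion of a rank test — with percentile-bootstrap CIs (default 2,000
resamples, seeded; degenerate bootstraps collapse to a point with a
warning). Two-sided tests throughout.

## Ratio monitoring choices

* **Ratio of means.** The per-group statistic is the quotient of
  group-mean MFIs (mean over member beads, then divide), matching how
  antigen-group curves are conventionally plotted; `method="mean-of-ratios"`
  provides the per-bead-ratio alternative. For a single-bead group the two
  coincide.
* **Denominator floor.** Both means are floored at 1 MFI before dividing,
  keeping the ratio finite and positive when a background-level baseline
  underflows; flooring events are logged.
* **Stability band.** The classification band defaults to [0.8, 1.25] —
  the classic bioequivalence bounds, symmetric on the log scale — since
  ">1 / =1 / <1" needs a tolerance to be operational. Band edges count as
  stable. Overridable per call and per CLI flag.
* **No cross-run ratios, no auto-baseline.** A follow-up run lacking its
  baseline aliquot is reported and excluded, never ratio-ed against another
  run's baseline; the baseline sample is always an explicit user input
  because the right baseline depends on the clinical question.
* **Antigen groups are user input.** Group membership (e.g. A24 → all
  A\*24:xx beads) must be supplied as a mapping; no serologic-equivalence
  table is shipped.

## Numerical and testing notes

Run-effect cancellation in the ratio is exact algebra, and the suite asserts
it to machine precision (residual and handling noise zeroed); scale
invariance under per-run rescaling is asserted with exact binary scalings so
floating-point distribution errors cannot blur the check. Type-I error of
the Bonferroni-corrected pairwise family is checked on 200 null replicates
against the binomial upper bound. Test problem sizes (10⁴ replicates for SD
recovery, 10⁵ for variance additivity, ~2 × 10⁴ measurements for filter
calibration) were chosen so each statistical tolerance sits at ≥ 2.8
standard errors.

## Known limitations

The generator's antibody signal is constant per (patient, bead) over a
cohort; real titers drift. Lot effects are level shifts only — real lots
also differ in antigen conformation and density, which changes *which*
beads are noisy, not just how much. Typing is drawn from the bead panel, so
every self allele has a bead, which overstates self-bead coverage relative
to real panels. The rank-sum exact/asymptotic switch at pooled n = 20
follows common practice; p-values near the switch can differ by up to ~0.02
between branches.
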
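# sabmfi

Variability analysis and baseline-ratio monitoring for Luminex
single-antigen-bead (SAB) HLA antibody assays.

## The problem

SAB assays report a mean fluorescence intensity (MFI) per HLA-coated bead.
MFI is a relative readout: repeat measurements of the same serum drift with
the day, the kit lot, the operator and the instrument, and the noise is
multiplicative — a bead sitting at 300 MFI today can plausibly read 100 or
900 next week without any immunological change. Transplant programs that
track donor-specific antibodies (DSA) over months therefore risk mistaking
technical drift for antibody dynamics.

`sabmfi` implements, for laboratory scientists and biostatisticians working
with SAB data:

1. **Variability characterization.** Measurements above a positivity
   threshold (default 1500 MFI) are removed so that what remains is assay
   background; MFI is log10-transformed; each bead's sample SD across repeat
   measurements is summarized per HLA locus group (A, B, C, DRB1, DRB3/4/5,
   DQA1/DQB1, DPA1/DPB1) together with the *fold change* `10^SD` — the
   linear factor by which a repeat measurement typically moves. Self-allele
   background (beads coated with the patient's own alleles; for dual-coated
   DQ/DP beads both alleles must be self) is summarized on the raw MFI
   scale, and bead SDs can be stratified by kit lot.
2. **Group comparisons.** Two-sided Wilcoxon rank-sum tests between locus
   groups (each bead contributing its SD as one observation), Bonferroni
   correction over the family of pairs, rank-biserial effect sizes
   `r = 2·AUC − 1` with percentile-bootstrap confidence intervals.
3. **Baseline-ratio monitoring.** The core statistic: an aliquot of a fixed
   baseline serum is measured *in the same Luminex run* as every follow-up
   serum, and per antigen group the ratio

   `ratio = mean follow-up MFI / mean baseline MFI   (same run, same beads)`

   is reported over time. Multiplicative run- and lot-level effects cancel
   exactly in the quotient, so the ratio tracks genuine antibody change
   (`>1` rising, `≈1` stable, `<1` falling) where the raw MFI curve may
   swing several-fold for technical reasons.
4. **Synthetic cohorts.** Real SAB exports are rarely shareable, so a seeded
   generator produces measurement/catalog/typing tables with the full
   hierarchical noise model
   `log10 MFI = μ_locus + b_bead + l_lot + r_run + s_sample + a·1[antibody] + boost·1[self] + ε`
   plus ground-truth tables, making every analysis stage testable end to end.

## Worked example

```python
from sabmfi.synthetic_data import default_config, simulate_cohort
from sabmfi.io_catalog import exclude_controls
from sabmfi.variability import apply_mfi_filter, bead_sd, locus_summary

cohort = simulate_cohort(default_config(seed=42))
table = exclude_controls(cohort.measurements)
filtered, removed = apply_mfi_filter(table)          # default threshold 1500
bv = bead_sd(filtered, catalog=cohort.catalog)
print(locus_summary(bv, filtered).round(2).to_string(index=False))
```

prints (abridged):

```
locus_group  n_beads  mean_log10  sd_log10  fold_change  max_sd_allele  max_sd
          A       30        2.15      0.38         2.40        A*12:01    0.46
          B       45        2.20      0.37         2.33        B*35:01    0.44
          C       15        2.21      0.35         2.25        C*14:01    0.42
       DRB1       25        2.02      0.40         2.51     DRB1*14:01    0.54
        ...
```

with `removed == {'I': 0.1862, 'II': 0.1744}` — about 19% of class I
measurements sit above 1500 MFI and are excluded as antibody signal. A
`sd_log10` of 0.37 means a repeat measurement of the same serum typically
lands within a factor `10^0.37 ≈ 2.3` of the previous value: the scale of
technical noise a raw-MFI monitoring rule has to fight.

Monitoring a simulated antibody-removal therapy (signal drops after the
baseline draw, then holds):

```python
from sabmfi.synthetic_data import simulate_longitudinal
from sabmfi.ratio_monitoring import build_ratio_series

meas, _ = simulate_longitudinal(
    default_config(seed=7), "px",
    ["2022-01-01", "2022-03-01", "2022-05-01", "2022-07-01"],
    {"A24": [1.6, 0.6, 0.3, 0.3]})
print(build_ratio_series(meas, "px", "px-t00", {"A24": ["b024"]})
      [["run_date", "followup_mean_mfi", "baseline_mean_mfi",
        "ratio", "classification"]].round(3).to_string(index=False))
```

```
  run_date  followup_mean_mfi  baseline_mean_mfi  ratio classification
2022-03-01            355.789           3546.276  0.100       decrease
2022-05-01            209.479           8459.320  0.025       decrease
2022-07-01             43.673           1757.548  0.025       decrease
```

Note the baseline aliquot itself reads anywhere from ~1,800 to ~8,500 MFI
across runs — pure technical drift — while the ratio falls cleanly to 0.025
and stays there, mirroring the true trajectory.

The same pipeline is available from the shell:

```sh
sabmfi simulate --seed 42 --out-dir out/sim
sabmfi variability --measurements out/sim/measurements.csv \
    --catalog out/sim/bead_catalog.csv --typing out/sim/typing.csv \
    --per-lot --out-dir out/var
sabmfi compare --bead-variability out/var/bead_variability.csv --out-dir out/cmp
sabmfi run --config pipeline.yaml --seed 42 --out-dir out   # all stages
```

Every stage writes CSV tables plus a JSON manifest (seed, config hash, input
digests, row counts); identical inputs and seed reproduce identical output
digests.

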
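"""Synthetic SAB cohort generator with hierarchical multiplicative noise.

Real single-antigen-bead (SAB) exports are not publicly depositable, so this
module generates cohorts that reproduce the *structure* the analysis relies
on: log-normal multiplicative noise decomposed into bead, lot, run, sample
and residual components, a minority of patient x bead pairs carrying true
antibody signal, elevated self-allele background (largest on HLA-C), single-
and dual-coated class II beads, and the parallel-run design in which a
baseline serum aliquot is re-measured alongside every follow-up serum.

The generative model on the log10 scale is

    log10(MFI) = mu_locus + b_bead + l_lot + r_run + s_sample
                 + a_signal * 1[antibody] + boost * 1[self allele] + eps

with every effect drawn independently normal with its configured SD, and
``raw_mfi = 10 ** log10(MFI)``.  Effects are drawn from a single seeded
generator in a fixed, documented order (lot effects, bead effects, typing,
antibody status, run effects, sample effects, residuals), so one integer
seed reproduces a cohort byte-for-byte.

Default locus parameters place the baseline mean and the *total* per-bead SD
at values typical for clinical class I / class II panels (log10 means around
2.1-2.3, total SDs 0.47-0.53).  The total variance is apportioned 50% to the
bead effect, 15% + 15% to run and sample handling, and 20% to the residual;
the apportionment is an explicit, overridable assumption — repeat-measurement
variability observed on a single bead reflects only the non-bead components.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_catalog import (
    ALLELE_PAIR_SEP,
    CLASS_I_GROUPS,
    DUAL_COAT_GROUPS,
    LOCUS_GROUPS,
)

__all__ = [
    "LocusConfig",
    "AntibodyModel",
    "GeneratorConfig",
    "TruthTable",
    "SimulatedCohort",
    "default_config",
    "noiseless_config",
    "simulate_cohort",
    "simulate_longitudinal",
]

# Reference total per-bead SD used to size the shared run/sample components:
# 15% of 0.50^2 variance each.
_REF_TOTAL_SD = 0.50
_RUN_SHARE = 0.15
_SAMPLE_SHARE = 0.15
_BEAD_SHARE = 0.50


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus-group bead panel and noise parameters (log10 MFI units)."""

    n_beads: int
    mean_log10: float      # baseline (antibody-free) mean log10 MFI
    bead_sd: float         # SD of the per-bead level offset
    residual_sd: float     # SD of the per-measurement residual

    def validate(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.bead_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class AntibodyModel:
    """Which patient x bead pairs carry true antibody, and how strong.

    ``signal_mean``/``signal_sd`` are in log10 units *above* the locus
    baseline; a mean of 2.0 puts typical positive beads in the
    5,000-20,000 MFI range seen for clear alloantibodies.  The fractions are
    nominal per (patient, bead) pair before self beads are excluded, sized so
    that roughly a fifth of class I antigen-bead measurements exceed the
    1500-MFI positivity threshold.
    """

    fraction_class_i: float = 0.198
    fraction_class_ii: float = 0.185
    signal_mean: float = 2.0
    signal_sd: float = 0.5

    def validate(self) -> None:
        for f in (self.fraction_class_i, self.fraction_class_ii):
            if not 0.0 <= f <= 1.0:
                raise ValueError("antibody fractions must be in [0, 1]")
        if self.signal_sd < 0:
            raise ValueError("signal_sd must be >= 0")

    def fraction_for(self, assay_class: str) -> float:
        return self.fraction_class_i if assay_class == "I" else self.fraction_class_ii


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic cohort.

    ``lots`` maps lot_id to the SD of that lot's level offset;
    ``self_allele_boost`` is the additive log10 background on beads coated
    with a patient's own allele(s), largest on HLA-C where self background
    is most pronounced.
    """

    n_patients: int = 120
    samples_per_patient: int = 2
    samples_per_run: int = 10
    lots: Mapping[str, float] = field(default_factory=dict)
    loci: Mapping[str, LocusConfig] = field(default_factory=dict)
    run_effect_sd: float = float(np.sqrt(_RUN_SHARE) * _REF_TOTAL_SD)
    sample_effect_sd: float = float(np.sqrt(_SAMPLE_SHARE) * _REF_TOTAL_SD)
    antibody: AntibodyModel = field(default_factory=AntibodyModel)
    self_allele_boost: Mapping[str, float] = field(default_factory=dict)
    include_control_beads: bool = True
    start_date: str = "2017-01-02"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.samples_per_patient < 1:
            raise ValueError("need at least one patient and one sample each")
        if self.samples_per_run < 1:
            raise ValueError("samples_per_run must be >= 1")
        if not self.lots:
            raise ValueError("at least one lot required")
        if any(sd < 0 for sd in self.lots.values()):
            raise ValueError("lot SDs must be >= 0")
        if self.run_effect_sd < 0 or self.sample_effect_sd < 0:
            raise ValueError("SDs must be >= 0")
        if not self.loci:
            raise ValueError("at least one locus group required")
        for group, lc in self.loci.items():
            if group not in LOCUS_GROUPS:
                raise ValueError(f"unknown locus group {group!r}")
            lc.validate()
        self.antibody.validate()
        for group, boost in self.self_allele_boost.items():
            if group not in LOCUS_GROUPS:
                raise ValueError(f"unknown locus group {group!r} in self_allele_boost")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of one simulated cohort, keyed exactly to its tables."""

    antibody: pd.DataFrame      # patient_id, bead_id, has_antibody, true_log10_signal
    bead_effects: pd.DataFrame  # bead_id, effect
    lot_effects: pd.DataFrame   # lot_id, effect
    run_effects: pd.DataFrame   # run_id, effect


@dataclass(frozen=True)
class SimulatedCohort:
    measurements: pd.DataFrame
    catalog: pd.DataFrame
    typing: pd.DataFrame
    truth: TruthTable


# --- default panel -----------------------------------------------------------

_DEFAULT_PANEL: dict[str, tuple[int, float, float]] = {
    # group: (n_beads, mean_log10, total_sd)
    "A": (30, 2.09, 0.53),
    "B": (45, 2.18, 0.50),
    "C": (15, 2.26, 0.47),
    "DRB1": (25, 2.08, 0.52),
    "DRB3": (3, 2.15, 0.48),
    "DRB4": (2, 2.14, 0.51),
    "DRB5": (3, 2.20, 0.49),
    "DQA1/DQB1": (25, 2.17, 0.49),
    "DPA1/DPB1": (20, 2.11, 0.48),
}

_DEFAULT_BOOST = {
    "A": 0.05, "B": 0.10, "C": 0.25,
    "DRB1": 0.10, "DRB3": 0.10, "DRB4": 0.10, "DRB5": 0.10,
    "DQA1/DQB1": 0.12, "DPA1/DPB1": 0.12,
}


def _locus_from_total(n_beads: int, mean: float, total_sd: float,
                      run_sd: float, sample_sd: float) -> LocusConfig:
    bead_var = _BEAD_SHARE * total_sd ** 2
    resid_var = total_sd ** 2 - bead_var - run_sd ** 2 - sample_sd ** 2
    if resid_var < 0:
        raise ValueError(f"total SD {total_sd} too small for the shared "
                         f"run/sample components")
    return LocusConfig(n_beads, mean, float(np.sqrt(bead_var)),
                       float(np.sqrt(resid_var)))


def default_config(seed: int = 0, **overrides: object) -> GeneratorConfig:
    """The documented default cohort: 120 patients, 2 sera each, 6 lots.

    Yields ~21,600 class I and ~18,700 class II antigen-bead measurements.
    Under the default antibody model roughly 19% of class I measurements
    exceed 1500 MFI (the fraction the positivity filter removes).
    """
    run_sd = float(np.sqrt(_RUN_SHARE) * _REF_TOTAL_SD)
    sample_sd = float(np.sqrt(_SAMPLE_SHARE) * _REF_TOTAL_SD)
    loci = {g: _locus_from_total(n, m, t, run_sd, sample_sd)
            for g, (n, m, t) in _DEFAULT_PANEL.items()}
    cfg = GeneratorConfig(
        lots={f"lot{10 + i}": 0.05 for i in range(6)},
        loci=loci,
        run_effect_sd=run_sd,
        sample_effect_sd=sample_sd,
        self_allele_boost=dict(_DEFAULT_BOOST),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)  # type: ignore[arg-type]
    cfg.validate()
    return cfg


def noiseless_config(seed: int = 0, **overrides: object) -> GeneratorConfig:
    """Default panel with every SD and the antibody model zeroed out."""
    cfg = default_config(seed=seed)
    loci = {g: replace(lc, bead_sd=0.0, residual_sd=0.0)
            for g, lc in cfg.loci.items()}
    cfg = replace(
        cfg,
        lots={k: 0.0 for k in cfg.lots},
        loci=loci,
        run_effect_sd=0.0,
        sample_effect_sd=0.0,
        antibody=AntibodyModel(0.0, 0.0, 0.0, 0.0),
        self_allele_boost={g: 0.0 for g in cfg.self_allele_boost},
    )
    if overrides:
        cfg = replace(cfg, **overrides)  # type: ignore[arg-type]
    cfg.validate()
    return cfg


# --- panel construction ------------------------------------------------------

def _build_panel(loci: Mapping[str, LocusConfig]) -> pd.DataFrame:
    """One row per antigen bead: bead_id, locus_group, alleles, assay_class."""
    rows = []
    idx = 1
    for group in LOCUS_GROUPS:
        if group not in loci:
            continue
        lc = loci[group]
        for i in range(1, lc.n_beads + 1):
            if group in DUAL_COAT_GROUPS:
                a, b = group.split("/")
                alleles = (f"{a}*{i:02d}:01", f"{b}*{i:02d}:01")
            else:
                alleles = (f"{group}*{i:02d}:01",)
            rows.append({
                "bead_id": f"b{idx:03d}",
                "locus_group": group,
                "alleles": alleles,
                "assay_class": "I" if group in CLASS_I_GROUPS else "II",
            })
            idx += 1
    return pd.DataFrame(rows)


def _catalog_from_panel(panel: pd.DataFrame, lots: Sequence[str]) -> pd.DataFrame:
    frames = []
    for lot in lots:
        frames.append(pd.DataFrame({
            "lot_id": lot,
            "bead_id": panel["bead_id"],
            "alleles": panel["alleles"],
            "locus_group": panel["locus_group"],
        }))
    return pd.concat(frames, ignore_index=True)


def _draw_typing(panel: pd.DataFrame, patients: Sequence[str],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Two alleles per class I locus and DRB1; DQ/DP as haplotype pairs so
    dual-coated "both alleles self" cases occur; DRB3/4/5 carried by ~half
    the cohort with one allele."""
    by_group = {g: sub for g, sub in panel.groupby("locus_group")}
    rows = []
    for pid in patients:
        alleles: set[str] = set()
        for group in ("A", "B", "C", "DRB1"):
            if group in by_group:
                pool = [a[0] for a in by_group[group]["alleles"]]
                alleles.update(rng.choice(pool, size=2, replace=True))
        for group in ("DRB3", "DRB4", "DRB5"):
            if group in by_group and rng.random() < 0.5:
                pool = [a[0] for a in by_group[group]["alleles"]]
                alleles.add(str(rng.choice(pool)))
        for group in DUAL_COAT_GROUPS:
            if group in by_group:
                pairs = list(by_group[group]["alleles"])
                for k in rng.choice(len(pairs), size=2, replace=True):
                    alleles.update(pairs[int(k)])
        rows.append({"patient_id": pid, "alleles": frozenset(alleles)})
    return pd.DataFrame(rows)


def _self_mask(panel: pd.DataFrame, typing: pd.DataFrame) -> pd.DataFrame:
    """Boolean matrix patients x beads: bead alleles all in patient typing."""
    typed = typing.set_index("patient_id")["alleles"]
    mat = np.zeros((len(typed), len(panel)), dtype=bool)
    for j, alleles in enumerate(panel["alleles"]):
        need = set(alleles)
        mat[:, j] = [need <= t for t in typed]
    return pd.DataFrame(mat, index=typed.index, columns=panel["bead_id"])


# --- cohort simulation -------------------------------------------------------

def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Generate a full cross-sectional cohort plus its ground truth.

    Every serum sample is acquired once; samples are packed into runs of
    ``samples_per_run`` in patient order, runs cycle through the configured
    lots and advance the calendar by three days each.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    lot_ids = sorted(config.lots)
    panel = _build_panel(config.loci)
    n_beads = len(panel)

    # 1. lot effects
    lot_eff = {lot: rng.normal(0.0, config.lots[lot]) for lot in lot_ids}
    # 2. bead effects
    bead_sd = panel["locus_group"].map(
        {g: lc.bead_sd for g, lc in config.loci.items()}).to_numpy(float)
    bead_eff = rng.normal(0.0, 1.0, n_beads) * bead_sd
    # 3. typing
    patients = [f"p{i:03d}" for i in range(1, config.n_patients + 1)]
    typing = _draw_typing(panel, patients, rng)
    self_mask = _self_mask(panel, typing)  # patients x beads
    # 4. antibody status / signal per patient x bead (never on self beads)
    frac = panel["assay_class"].map(config.antibody.fraction_for).to_numpy(float)
    has_ab = rng.random((config.n_patients, n_beads)) < frac[None, :]
    has_ab &= ~self_mask.to_numpy()
    signal = np.where(
        has_ab,
        rng.normal(config.antibody.signal_mean, config.antibody.signal_sd,
                   (config.n_patients, n_beads)),
        0.0,
    )

    # 5. samples -> runs
    sample_patient = np.repeat(np.arange(config.n_patients),
                               config.samples_per_patient)
    n_samples = len(sample_patient)
    sample_ids = [f"{patients[p]}-s{k % config.samples_per_patient + 1}"
                  for k, p in enumerate(sample_patient)]
    run_of_sample = np.arange(n_samples) // config.samples_per_run
    n_runs = int(run_of_sample.max()) + 1
    run_ids = [f"r{i:03d}" for i in range(1, n_runs + 1)]
    run_lot = [lot_ids[i % len(lot_ids)] for i in range(n_runs)]
    dates = pd.to_datetime(config.start_date) + pd.to_timedelta(
        3 * np.arange(n_runs), unit="D")
    run_eff = rng.normal(0.0, config.run_effect_sd, n_runs)
    # 6. sample handling effects (one acquisition per sample here)
    samp_eff = rng.normal(0.0, config.sample_effect_sd, n_samples)
    # 7. residuals
    resid_sd = panel["locus_group"].map(
        {g: lc.residual_sd for g, lc in config.loci.items()}).to_numpy(float)
    resid = rng.normal(0.0, 1.0, (n_samples, n_beads)) * resid_sd[None, :]

    mu = panel["locus_group"].map(
        {g: lc.mean_log10 for g, lc in config.loci.items()}).to_numpy(float)
    boost = panel["locus_group"].map(
        lambda g: config.self_allele_boost.get(g, 0.0)).to_numpy(float)

    lot_of_sample = np.array([lot_eff[run_lot[r]] for r in run_of_sample])
    self_by_sample = self_mask.to_numpy()[sample_patient]
    log10_mfi = (
        mu[None, :] + bead_eff[None, :]
        + lot_of_sample[:, None] + run_eff[run_of_sample, None]
        + samp_eff[:, None]
        + signal[sample_patient]
        + boost[None, :] * self_by_sample
        + resid
    )

    meas = pd.DataFrame({
        "patient_id": np.repeat([patients[p] for p in sample_patient], n_beads),
        "sample_id": np.repeat(sample_ids, n_beads),
        "run_id": np.repeat([run_ids[r] for r in run_of_sample], n_beads),
        "run_date": np.repeat(dates[run_of_sample], n_beads),
        "lot_id": np.repeat([run_lot[r] for r in run_of_sample], n_beads),
        "bead_id": np.tile(panel["bead_id"].to_numpy(), n_samples),
        "assay_class": np.tile(panel["assay_class"].to_numpy(), n_samples),
        "raw_mfi": np.power(10.0, log10_mfi).ravel(),
        "is_control_bead": False,
    })

    if config.include_control_beads:
        ctrl = _control_rows(meas, run_eff, run_of_sample, samp_eff,
                             sample_ids, sample_patient, patients,
                             run_ids, run_lot, dates, rng)
        meas = pd.concat([meas, ctrl], ignore_index=True)

    catalog = _catalog_from_panel(panel, lot_ids)
    truth = TruthTable(
        antibody=pd.DataFrame({
            "patient_id": np.repeat(patients, n_beads),
            "bead_id": np.tile(panel["bead_id"].to_numpy(), config.n_patients),
            "has_antibody": has_ab.ravel(),
            "true_log10_signal": signal.ravel(),
        }),
        bead_effects=pd.DataFrame({"bead_id": panel["bead_id"],
                                   "effect": bead_eff}),
        lot_effects=pd.DataFrame({"lot_id": lot_ids,
                                  "effect": [lot_eff[l] for l in lot_ids]}),
        run_effects=pd.DataFrame({"run_id": run_ids, "effect": run_eff}),
    )
    return SimulatedCohort(meas, catalog, typing, truth)


_CONTROL_LEVELS = {"PC": 4.2, "NC": 1.3}   # positive / negative control log10 MFI
_CONTROL_RESID_SD = 0.10


def _control_rows(meas, run_eff, run_of_sample, samp_eff, sample_ids,
                  sample_patient, patients, run_ids, run_lot, dates, rng):
    """Per-class positive/negative control beads for each acquisition."""
    rows = []
    for k in range(len(sample_ids)):
        r = run_of_sample[k]
        for cls in ("I", "II"):
            for kind, level in _CONTROL_LEVELS.items():
                log10 = (level + run_eff[r] + samp_eff[k]
                         + rng.normal(0.0, _CONTROL_RESID_SD))
                rows.append({
                    "patient_id": patients[sample_patient[k]],
                    "sample_id": sample_ids[k],
                    "run_id": run_ids[r],
                    "run_date": dates[r],
                    "lot_id": run_lot[r],
                    "bead_id": f"{kind}-{cls}",
                    "assay_class": cls,
                    "raw_mfi": 10.0 ** log10,
                    "is_control_bead": True,
                })
    return pd.DataFrame(rows)


# --- longitudinal simulation -------------------------------------------------

def simulate_longitudinal(
    config: GeneratorConfig,
    patient_id: str,
    timepoints: Sequence[str],
    trajectory: Mapping[str, Sequence[float]],
    antigen_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the parallel-run monitoring design for one patient.

    The first timepoint is the baseline serum, acquired alone.  Every later
    timepoint is one fresh Luminex run containing TWO acquisitions — the
    follow-up serum and a re-measured aliquot of the baseline serum, whose
    true signal stays frozen at the baseline value.  Because both sera share
    the run, the run and lot effects cancel exactly in the follow-up/baseline
    quotient once handling and residual noise are switched off.

    Parameters
    ----------
    timepoints : ISO-8601 dates, strictly increasing; first = baseline draw.
    trajectory : per antigen-group label, the true log10 antibody signal at
        each timepoint (same length as ``timepoints``).
    antigen_groups : label -> member bead_ids.  Default: each label is the
        serologic group of all beads whose first allele starts with the label
        prefix (e.g. ``"A24"`` matches ``A*24:xx``).

    Returns
    -------
    (measurements, pairs) : the measurement table and the pairing manifest
        with one row per follow-up run
        (run_id, run_date, followup_sample_id, baseline_sample_id).
    """
    config.validate()
    timepoints = list(timepoints)
    if len(timepoints) < 2:
        raise ValueError("need a baseline and at least one follow-up timepoint")
    dates = pd.to_datetime(pd.Index(timepoints))
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise ValueError("timepoints must be strictly increasing dates")
    for label, sig in trajectory.items():
        if len(sig) != len(timepoints):
            raise ValueError(
                f"trajectory for {label!r} has {len(sig)} values for "
                f"{len(timepoints)} timepoints")

    rng = np.random.default_rng(config.seed)
    lot_ids = sorted(config.lots)
    panel = _build_panel(config.loci)
    n_beads = len(panel)

    lot_eff = {lot: rng.normal(0.0, config.lots[lot]) for lot in lot_ids}
    bead_sd = panel["locus_group"].map(
        {g: lc.bead_sd for g, lc in config.loci.items()}).to_numpy(float)
    bead_eff = rng.normal(0.0, 1.0, n_beads) * bead_sd

    if antigen_groups is None:
        antigen_groups = _prefix_groups(panel, trajectory.keys())
    bead_signal = np.zeros((len(timepoints), n_beads))
    bead_index = {b: j for j, b in enumerate(panel["bead_id"])}
    for label, sig in trajectory.items():
        members = antigen_groups.get(label, [])
        if not len(members):
            raise ValueError(f"antigen group {label!r} has no member beads")
        for b in members:
            bead_signal[:, bead_index[b]] = np.asarray(sig, float)

    mu = panel["locus_group"].map(
        {g: lc.mean_log10 for g, lc in config.loci.items()}).to_numpy(float)
    resid_sd = panel["locus_group"].map(
        {g: lc.residual_sd for g, lc in config.loci.items()}).to_numpy(float)

    baseline_sample = f"{patient_id}-t00"
    rows, pair_rows = [], []
    for i, date in enumerate(dates):
        run_id = f"LR{i:03d}"
        lot = lot_ids[i % len(lot_ids)]
        r_run = rng.normal(0.0, config.run_effect_sd)
        # acquisitions in this run: baseline alone at i=0, else follow-up
        # serum plus the re-thawed baseline aliquot
        if i == 0:
            acquisitions = [(baseline_sample, bead_signal[0])]
        else:
            fu_sample = f"{patient_id}-t{i:02d}"
            acquisitions = [(fu_sample, bead_signal[i]),
                            (baseline_sample, bead_signal[0])]
            pair_rows.append({
                "run_id": run_id,
                "run_date": date,
                "followup_sample_id": fu_sample,
                "baseline_sample_id": baseline_sample,
            })
        for sample_id, sig in acquisitions:
            s_eff = rng.normal(0.0, config.sample_effect_sd)
            resid = rng.normal(0.0, 1.0, n_beads) * resid_sd
            log10_mfi = (mu + bead_eff + lot_eff[lot] + r_run + s_eff
                         + sig + resid)
            rows.append(pd.DataFrame({
                "patient_id": patient_id,
                "sample_id": sample_id,
                "run_id": run_id,
                "run_date": date,
                "lot_id": lot,
                "bead_id": panel["bead_id"],
                "assay_class": panel["assay_class"],
                "raw_mfi": np.power(10.0, log10_mfi),
                "is_control_bead": False,
            }))
    meas = pd.concat(rows, ignore_index=True)
    pairs = pd.DataFrame(pair_rows)
    return meas, pairs


def config_from_mapping(mapping: Mapping[str, object],
                        seed: int | None = None) -> GeneratorConfig:
    """Build a GeneratorConfig from a plain (e.g. YAML-loaded) mapping.

    Unspecified fields fall back to :func:`default_config`.  ``loci`` entries
    are mappings with LocusConfig fields; ``antibody`` likewise.  A ``seed``
    argument overrides any seed in the mapping.
    """
    d = dict(mapping or {})
    base = default_config()
    kwargs: dict[str, object] = {}
    for key in ("n_patients", "samples_per_patient", "samples_per_run",
                "run_effect_sd", "sample_effect_sd", "include_control_beads",
                "start_date", "seed"):
        if key in d:
            kwargs[key] = d.pop(key)
    if "lots" in d:
        kwargs["lots"] = {str(k): float(v) for k, v in d.pop("lots").items()}
    if "loci" in d:
        kwargs["loci"] = {str(g): LocusConfig(**spec)
                          for g, spec in d.pop("loci").items()}
    if "antibody" in d:
        kwargs["antibody"] = AntibodyModel(**d.pop("antibody"))
    if "self_allele_boost" in d:
        kwargs["self_allele_boost"] = {
            str(k): float(v) for k, v in d.pop("self_allele_boost").items()}
    if d:
        raise ValueError(f"unknown generator config key(s): {sorted(d)}")
    cfg = replace(base, **kwargs)  # type: ignore[arg-type]
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    cfg.validate()
    return cfg


def _prefix_groups(panel: pd.DataFrame,
                   labels: Sequence[str]) -> dict[str, list[str]]:
    """Map serologic-style labels (``"A24"``) to beads by allele prefix."""
    groups: dict[str, list[str]] = {}
    for label in labels:
        locus = "".join(c for c in label if not c.isdigit())
        num = "".join(c for c in label if c.isdigit())
        prefix = f"{locus}*{int(num):02d}:" if num else f"{locus}*"
        members = [b for b, alleles in zip(panel["bead_id"], panel["alleles"])
                   if alleles[0].startswith(prefix)]
        groups[label] = members
    return groups
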
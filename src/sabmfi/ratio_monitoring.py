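"""Parallel-run baseline-ratio monitoring of HLA antibody levels.

Raw MFI values from different Luminex runs are not directly comparable: run,
lot and operator effects shift every bead on the plate multiplicatively.  The
monitoring design therefore re-measures an aliquot of a fixed baseline serum
*in the same run* as each follow-up serum and reports, per antigen group, the
quotient

    ratio = mean follow-up MFI over the group's beads
            / mean baseline MFI over the same beads, same run.

Any multiplicative effect shared by the two acquisitions of a run cancels in
the quotient, so the ratio tracks genuine antibody change while the raw MFI
curve may swing with technical conditions.  Ratios are classified
semi-quantitatively as decrease / stable / increase against a tolerance band
(default 0.8-1.25, symmetric on the log scale).

The baseline sample is always an explicit user choice — for donor-specific
antibody surveillance the last serum before transplantation, for judging an
antibody-removal therapy the serum drawn just before it started.  Ratios are
never formed across runs: a follow-up run lacking its baseline aliquot is
reported as unpairable, not silently matched to another run's baseline.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "pair_runs",
    "group_mean_mfi",
    "compute_ratio",
    "classify_ratio",
    "build_ratio_series",
    "read_antigen_groups",
]

DEFAULT_BAND = (0.8, 1.25)
DEFAULT_RATIO_FLOOR = 1.0


class PairingError(ValueError):
    """No follow-up run contains the required baseline aliquot."""


def pair_runs(
    table: pd.DataFrame,
    patient_id: str,
    baseline_sample_id: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Find runs in which a follow-up serum and the baseline aliquot coexist.

    Returns ``(pairs, unpaired_runs)``: one pair row per run holding both the
    baseline aliquot and exactly one other sample of the patient, plus the
    run_ids of follow-up acquisitions that lack the aliquot (these can never
    be ratio-ed).  Runs containing only the baseline acquisition itself are
    ignored.  Raises :class:`PairingError` if no valid pair exists.
    """
    mine = table.loc[(table["patient_id"] == patient_id)
                     & ~table["is_control_bead"]]
    if mine.empty:
        raise PairingError(f"no measurements for patient {patient_id!r}")
    if baseline_sample_id not in set(mine["sample_id"]):
        raise PairingError(
            f"baseline sample {baseline_sample_id!r} never measured for "
            f"patient {patient_id!r}")

    rows, unpaired = [], []
    for run_id, sub in mine.groupby("run_id", sort=False):
        samples = set(sub["sample_id"])
        others = sorted(samples - {baseline_sample_id})
        if baseline_sample_id in samples and len(others) == 1:
            rows.append({
                "run_id": run_id,
                "run_date": sub["run_date"].iloc[0],
                "followup_sample_id": others[0],
                "baseline_sample_id": baseline_sample_id,
            })
        elif baseline_sample_id not in samples:
            unpaired.append(str(run_id))
        elif len(others) > 1:
            logger.warning("run %r holds %d candidate follow-up samples; "
                           "skipped as ambiguous", run_id, len(others))
            unpaired.append(str(run_id))
    if not rows:
        raise PairingError(
            f"no run pairs follow-up serum with baseline aliquot "
            f"{baseline_sample_id!r}; runs missing the aliquot: {unpaired}")
    if unpaired:
        logger.warning("%d run(s) lack the baseline aliquot and were "
                       "excluded: %s", len(unpaired), unpaired)
    pairs = (pd.DataFrame(rows)
             .sort_values(["run_date", "run_id"])
             .reset_index(drop=True))
    return pairs, unpaired


def group_mean_mfi(
    table: pd.DataFrame,
    sample_id: str,
    run_id: str,
    bead_ids: Sequence[str],
) -> float:
    """Arithmetic mean raw MFI over an antigen group's member beads."""
    sub = table.loc[(table["sample_id"] == sample_id)
                    & (table["run_id"] == run_id)
                    & table["bead_id"].isin(list(bead_ids))]
    if sub.empty:
        raise ValueError(
            f"no member bead of the group measured for sample {sample_id!r} "
            f"in run {run_id!r}")
    return float(sub["raw_mfi"].mean())


def compute_ratio(
    followup_mean: float,
    baseline_mean: float,
    floor: float = DEFAULT_RATIO_FLOOR,
) -> float:
    """Follow-up / baseline quotient, both means floored first.

    The floor (default 1 MFI) keeps the ratio finite and positive when a
    background-level denominator underflows; flooring events are logged.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if followup_mean < floor or baseline_mean < floor:
        logger.info("ratio flooring applied: follow-up %.3g, baseline %.3g, "
                    "floor %g", followup_mean, baseline_mean, floor)
    return max(followup_mean, floor) / max(baseline_mean, floor)


def classify_ratio(
    ratio: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> str:
    """Classify a ratio as ``decrease`` / ``stable`` / ``increase``.

    The stability band is inclusive at both edges.
    """
    low, high = band
    if not (0.0 < low < 1.0 < high):
        raise ValueError("band must satisfy 0 < low < 1 < high")
    if ratio < low:
        return "decrease"
    if ratio > high:
        return "increase"
    return "stable"


def build_ratio_series(
    table: pd.DataFrame,
    patient_id: str,
    baseline_sample_id: str,
    antigen_groups: Mapping[str, Sequence[str]],
    band: tuple[float, float] = DEFAULT_BAND,
    floor: float = DEFAULT_RATIO_FLOOR,
    method: Literal["ratio-of-means", "mean-of-ratios"] = "ratio-of-means",
) -> pd.DataFrame:
    """Time-ordered ratio series per antigen group for one patient.

    One row per (antigen group, paired run): the run's follow-up and baseline
    group-mean MFIs, their ratio, and its classification — both the raw-MFI
    curve and the ratio curve of a monitoring chart.  ``method`` selects
    ratio-of-group-means (default) or the mean of per-bead ratios.
    """
    pairs, _ = pair_runs(table, patient_id, baseline_sample_id)
    mine = table.loc[(table["patient_id"] == patient_id)
                     & ~table["is_control_bead"]]
    rows = []
    for label, beads in antigen_groups.items():
        beads = list(beads)
        if not beads:
            raise ValueError(f"antigen group {label!r} has no member beads")
        for pair in pairs.itertuples(index=False):
            fu = group_mean_mfi(mine, pair.followup_sample_id,
                                pair.run_id, beads)
            base = group_mean_mfi(mine, pair.baseline_sample_id,
                                  pair.run_id, beads)
            if method == "ratio-of-means":
                ratio = compute_ratio(fu, base, floor=floor)
            elif method == "mean-of-ratios":
                ratio = _mean_of_bead_ratios(
                    mine, pair, beads, floor=floor)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({
                "patient_id": patient_id,
                "antigen_group": label,
                "baseline_sample_id": baseline_sample_id,
                "run_id": pair.run_id,
                "run_date": pair.run_date,
                "followup_sample_id": pair.followup_sample_id,
                "followup_mean_mfi": fu,
                "baseline_mean_mfi": base,
                "ratio": ratio,
                "classification": classify_ratio(ratio, band=band),
            })
    return (pd.DataFrame(rows)
            .sort_values(["antigen_group", "run_date", "run_id"])
            .reset_index(drop=True))


def _mean_of_bead_ratios(mine, pair, beads, floor):
    fu = mine.loc[(mine["sample_id"] == pair.followup_sample_id)
                  & (mine["run_id"] == pair.run_id)
                  & mine["bead_id"].isin(beads)]
    base = mine.loc[(mine["sample_id"] == pair.baseline_sample_id)
                    & (mine["run_id"] == pair.run_id)
                    & mine["bead_id"].isin(beads)]
    merged = fu.merge(base, on="bead_id", suffixes=("_fu", "_base"))
    if merged.empty:
        raise ValueError(f"no shared member beads in run {pair.run_id!r}")
    ratios = [compute_ratio(f, b, floor=floor)
              for f, b in zip(merged["raw_mfi_fu"], merged["raw_mfi_base"])]
    return float(np.mean(ratios))


def read_antigen_groups(path) -> dict[str, list[str]]:
    """Read an antigen-group membership CSV (columns: label, bead_id)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("label", "bead_id"):
        if col not in df.columns:
            raise ValueError(f"groups file missing column {col!r}")
    groups: dict[str, list[str]] = {}
    for label, sub in df.groupby("label", sort=True):
        groups[str(label)] = sorted(sub["bead_id"])
    return groups
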
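"""Bead-level MFI variability pipeline.

The analysis chain mirrors routine SAB quality assessment: measurements above
a positivity threshold (default 1500 MFI) are removed so that what remains is
assay background rather than antibody signal; raw MFI is log10-transformed
(multiplicative noise becomes additive); each bead's sample SD across its
repeat measurements quantifies technical variability; locus-group summaries
retransform the SD into a linear-scale fold change (``10**SD`` — one SD up or
down corresponds to multiplying or dividing a repeat measurement by that
factor).  Self-allele background (beads coated with a patient's own alleles)
is summarized on the *unfiltered* raw MFI scale, and bead SDs can be
recomputed within each kit lot to expose lot-to-lot differences.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .io_catalog import LOCUS_GROUPS

logger = logging.getLogger(__name__)

__all__ = [
    "apply_mfi_filter",
    "log10_mfi",
    "bead_sd",
    "fold_change",
    "locus_summary",
    "self_allele_analysis",
    "lot_stratified_sd",
]

DEFAULT_MFI_THRESHOLD = 1500.0
DEFAULT_FLOOR = 1.0


def apply_mfi_filter(
    table: pd.DataFrame,
    threshold: float = DEFAULT_MFI_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Remove measurements whose raw MFI is strictly above ``threshold``.

    Rows at exactly the threshold are kept ("above" is strict).  Returns the
    retained table and the removed fraction per assay class.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(table) == 0:
        raise ValueError("empty measurement table")
    keep = table["raw_mfi"] <= threshold
    removed_fraction = {
        str(cls): float(1.0 - keep[sub].mean())
        for cls, sub in table.groupby("assay_class").groups.items()
    }
    kept = table.loc[keep].reset_index(drop=True)
    logger.info("MFI filter at %g: kept %d / %d rows (removed %s)",
                threshold, len(kept), len(table),
                {k: f"{v:.2%}" for k, v in removed_fraction.items()})
    return kept, removed_fraction


def log10_mfi(raw_mfi, floor: float = DEFAULT_FLOOR):
    """log10 of the raw MFI, floored at ``floor`` first.

    Raw exports contain zero and negative MFIs; flooring (default at 1, i.e.
    log10 = 0) keeps the transform finite and order-preserving.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    arr = np.maximum(np.asarray(raw_mfi, dtype=float), floor)
    out = np.log10(arr)
    return float(out) if np.isscalar(raw_mfi) else out


def bead_sd(
    table: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-bead mean and sample SD of log10 MFI.

    One row per bead with at least two measurements (sample SD uses the n-1
    denominator); beads with fewer are dropped with a warning.  If a catalog
    is given, each bead is annotated with its locus group and a display
    allele label.
    """
    work = table.assign(log10_mfi=log10_mfi(table["raw_mfi"].to_numpy(), floor))
    agg = work.groupby("bead_id")["log10_mfi"].agg(
        n_measurements="size", mean_log10="mean", sd_log10="std")
    dropped = agg.index[agg["n_measurements"] < 2]
    if len(dropped):
        logger.warning("bead_sd: dropping %d bead(s) with n < 2: %s",
                       len(dropped), list(dropped[:5]))
    out = (agg.loc[agg["n_measurements"] >= 2]
           .reset_index()
           .astype({"n_measurements": int}))
    if catalog is not None:
        ann = (catalog.drop_duplicates("bead_id")
               .assign(allele_label=lambda d: d["alleles"].map("+".join))
               .loc[:, ["bead_id", "locus_group", "allele_label"]])
        out = out.merge(ann, on="bead_id", how="left")
        out = out[["bead_id", "locus_group", "allele_label",
                   "n_measurements", "mean_log10", "sd_log10"]]
    return out.sort_values("bead_id").reset_index(drop=True)


def fold_change(sd_log10: float) -> float:
    """Linear-scale factor corresponding to one SD of log10 MFI: ``10**SD``."""
    if sd_log10 < 0:
        raise ValueError("sd_log10 must be >= 0")
    return float(10.0 ** sd_log10)


def locus_summary(
    bead_variabilities: pd.DataFrame,
    table: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    group_sd: Literal["mean_bead_sd", "pooled"] = "mean_bead_sd",
) -> pd.DataFrame:
    """Per-locus-group summary: mean log10 MFI, group SD, fold change, extremes.

    The group mean is taken over all measurements of the group's beads; the
    group SD defaults to the arithmetic mean of the bead-level SDs (each bead
    one observation), with a pooled-SD alternative.  The beads with the
    largest and smallest SD are reported by allele label; ties break toward
    the lexicographically smaller label so reports are deterministic.
    """
    bv = bead_variabilities
    if "locus_group" not in bv.columns:
        raise ValueError("bead_variabilities must carry locus_group "
                         "(pass a catalog to bead_sd)")
    unknown = set(bv["locus_group"].dropna()) - set(LOCUS_GROUPS)
    if unknown:
        raise ValueError(f"unknown locus_group(s) {sorted(unknown)}")

    work = table.loc[table["bead_id"].isin(bv["bead_id"])]
    work = work.merge(bv[["bead_id", "locus_group"]], on="bead_id")
    work = work.assign(log10_mfi=log10_mfi(work["raw_mfi"].to_numpy(), floor))

    rows = []
    for group in LOCUS_GROUPS:
        sub = bv.loc[bv["locus_group"] == group]
        if sub.empty:
            continue
        if group_sd == "mean_bead_sd":
            sd = float(sub["sd_log10"].mean())
        else:
            sd = float(work.loc[work["locus_group"] == group, "log10_mfi"].std())
        ordered = sub.sort_values(["sd_log10", "allele_label"],
                                  ascending=[False, True], kind="mergesort")
        hi = ordered.iloc[0]
        ordered = sub.sort_values(["sd_log10", "allele_label"],
                                  ascending=[True, True], kind="mergesort")
        lo = ordered.iloc[0]
        rows.append({
            "locus_group": group,
            "n_beads": int(len(sub)),
            "mean_log10": float(
                work.loc[work["locus_group"] == group, "log10_mfi"].mean()),
            "sd_log10": sd,
            "fold_change": fold_change(sd),
            "max_sd_allele": hi["allele_label"],
            "max_sd": float(hi["sd_log10"]),
            "min_sd_allele": lo["allele_label"],
            "min_sd": float(lo["sd_log10"]),
        })
    return pd.DataFrame(rows)


def self_allele_analysis(
    table: pd.DataFrame,
    typing: pd.DataFrame,
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Mean raw MFI of each patient's self-allele beads.

    A bead counts as "self" only if *all* its coated alleles are in the
    patient's typing (dual-coated beads need both).  Operates on unfiltered
    raw MFI — self-bead background can legitimately exceed the positivity
    threshold and still reflect background, not alloantibody.  Patients
    without typing are skipped with a warning.
    """
    typed = typing.set_index("patient_id")["alleles"].to_dict()
    missing = sorted(set(table["patient_id"]) - typed.keys())
    if missing:
        logger.warning("self_allele_analysis: no typing for %d patient(s), "
                       "skipped: %s", len(missing), missing[:5])

    beads = (catalog.drop_duplicates("bead_id")
             .loc[:, ["bead_id", "alleles", "locus_group"]])
    rows = []
    grouped = table.groupby(["patient_id", "bead_id"])["raw_mfi"]
    stats = grouped.agg(["mean", "size"])
    bead_info = beads.set_index("bead_id")
    for (pid, bead), (mean, n) in stats.iterrows():
        if pid not in typed or bead not in bead_info.index:
            continue
        alleles = set(bead_info.at[bead, "alleles"])
        if not alleles <= typed[pid]:
            continue
        rows.append({
            "patient_id": pid,
            "bead_id": bead,
            "locus_group": bead_info.at[bead, "locus_group"],
            "mean_raw_mfi": float(mean),
            "n_measurements": int(n),
        })
    return (pd.DataFrame(rows,
                         columns=["patient_id", "bead_id", "locus_group",
                                  "mean_raw_mfi", "n_measurements"])
            .sort_values(["patient_id", "bead_id"])
            .reset_index(drop=True))


def lot_stratified_sd(
    table: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Bead SDs recomputed within each lot, keyed (lot_id, locus_group, bead_id).

    Beads with fewer than two measurements inside a lot are dropped; a lot
    with no qualifying bead is omitted with a warning.
    """
    frames = []
    for lot, sub in table.groupby("lot_id"):
        bv = bead_sd(sub, catalog=catalog, floor=floor)
        if bv.empty:
            logger.warning("lot_stratified_sd: lot %r has no bead with "
                           "n >= 2, omitted", lot)
            continue
        frames.append(bv.assign(lot_id=lot))
    if not frames:
        return pd.DataFrame(columns=["lot_id", "locus_group", "bead_id",
                                     "n_measurements", "mean_log10",
                                     "sd_log10"])
    out = pd.concat(frames, ignore_index=True)
    keys = ["lot_id"] + (["locus_group"] if "locus_group" in out.columns else [])
    keys += ["bead_id"]
    cols = keys + [c for c in ["allele_label", "n_measurements",
                               "mean_log10", "sd_log10"] if c in out.columns]
    return out[cols].sort_values(keys).reset_index(drop=True)
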
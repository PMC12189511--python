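"""Pairwise comparisons of bead-level variability.

The comparison unit is the bead: each bead contributes one observation (its
SD of log10 MFI) to its locus group, and groups are compared with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test.  Families of pairwise
comparisons are Bonferroni-corrected by the number of pairs; correction can
be switched off because lot-stratified comparisons are conventionally
reported uncorrected.  Effect sizes are rank-biserial correlations
(r = 2*AUC - 1, the difference between the probability that a random
observation from one group exceeds one from the other and vice versa) with
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import itertools
import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "wilcoxon_rank_sum",
    "bonferroni",
    "rank_biserial",
    "effect_size_rank_biserial",
    "pairwise_group_comparison",
    "significance_code",
]

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_LIMIT = 20


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W (sum of the ranks of ``x`` in the pooled
    sample) and the two-sided p-value.  The exact null distribution is used
    when ``len(x) + len(y) <= 20`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` with family size ``m``.

    ``m`` defaults to the number of p-values supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, m * p)


def rank_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-biserial correlation r = 2*AUC - 1, AUC = P(x>y) + 0.5*P(x=y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = x[:, None] - y[None, :]
    auc = (np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) \
        / diff.size
    return float(2.0 * auc - 1.0)


def effect_size_rank_biserial(
    x: Sequence[float],
    y: Sequence[float],
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Rank-biserial effect size with a seeded percentile-bootstrap CI.

    Both groups are resampled with replacement ``n_boot`` times.  If every
    resampled effect is identical (degenerate data) the interval collapses
    to a point and a warning is logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group for a bootstrap CI")
    r = rank_biserial(x, y)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = rank_biserial(rng.choice(x, x.size, replace=True),
                                rng.choice(y, y.size, replace=True))
    if np.all(boot == boot[0]):
        logger.warning("degenerate bootstrap: all resampled effects equal "
                       "%.3f; CI collapses to a point", boot[0])
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return r, float(lo), float(hi)


def significance_code(p: float) -> str:
    """Conventional star codes: **** <1e-4, *** <1e-3, ** <0.01, * <0.05."""
    for threshold, code in ((1e-4, "****"), (1e-3, "***"),
                            (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return code
    return "ns"


def pairwise_group_comparison(
    sd_table: pd.DataFrame,
    family: Literal["loci", "loci-within-lot"] = "loci",
    correction: Literal["bonferroni", "none"] = "bonferroni",
    value_col: str = "sd_log10",
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """All unordered pairwise locus-group comparisons of bead-level SDs.

    ``family="loci"`` compares locus groups over the whole table;
    ``"loci-within-lot"`` runs one family per lot (requires a ``lot_id``
    column).  The Bonferroni family size is the number of pairs actually
    tested within each family.  Groups with no observation are excluded with
    a warning.
    """
    if family == "loci-within-lot":
        if "lot_id" not in sd_table.columns:
            raise ValueError("family 'loci-within-lot' requires a lot_id column")
        frames = []
        for lot, sub in sd_table.groupby("lot_id"):
            res = pairwise_group_comparison(
                sub.drop(columns="lot_id"), family="loci",
                correction=correction, value_col=value_col,
                ci_level=ci_level, n_boot=n_boot, seed=seed)
            frames.append(res.assign(lot_id=lot))
        if not frames:
            raise ValueError("no lots to compare")
        out = pd.concat(frames, ignore_index=True)
        return out[["lot_id"] + [c for c in out.columns if c != "lot_id"]]

    groups: dict[str, np.ndarray] = {}
    for g, sub in sd_table.groupby("locus_group"):
        vals = sub[value_col].dropna().to_numpy(float)
        if vals.size < 1:
            logger.warning("group %r has no observations, excluded", g)
            continue
        groups[str(g)] = vals
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")

    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        xa, xb = groups[ga], groups[gb]
        w, p = wilcoxon_rank_sum(xa, xb)
        if xa.size >= 2 and xb.size >= 2:
            r, lo, hi = effect_size_rank_biserial(
                xa, xb, ci_level=ci_level, n_boot=n_boot, seed=seed)
        else:
            r, lo, hi = rank_biserial(xa, xb), np.nan, np.nan
        rows.append({
            "group_a": ga, "group_b": gb,
            "n_a": xa.size, "n_b": xb.size,
            "statistic": w, "p_raw": p,
            "effect_size": r, "ci_low": lo, "ci_high": hi,
        })
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adjusted"] = bonferroni(out["p_raw"].to_numpy(), m=m)
    elif correction == "none":
        out["p_adjusted"] = out["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["significance"] = out["p_adjusted"].map(significance_code)
    return out[["group_a", "group_b", "n_a", "n_b", "statistic",
                "p_raw", "p_adjusted", "effect_size", "ci_low", "ci_high",
                "significance"]]
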
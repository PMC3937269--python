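"""Phenotype-level statistics: lipid changes and plaque stability.

Percent changes of plasma lipid means, the plaque stability score
(SM22α + collagen)/(CD68 + Oil-Red-O) stained-area percentages with
normalization to per-mouse lesion burden, group-mean (or seeded
stochastic) imputation of missing histology cells, and Welch two-sided
group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAIN_FIELDS = ("sm22", "collagen", "cd68", "oro")


def percent_change(before_mean: float, after_mean: float) -> float:
    """100·(after − before)/before, to one decimal. Requires before > 0."""
    if before_mean <= 0:
        raise ValueError("before_mean must be > 0")
    return round(100.0 * (after_mean - before_mean) / before_mean, 1)


@dataclass
class StabilityScore:
    raw: float
    normalized: float
    undefined: bool = False


def plaque_stability_score(sm22: float, collagen: float, cd68: float, oro: float,
                           burden: float) -> StabilityScore:
    """(SM22α + collagen)/(CD68 + Oil-Red-O), divided by lesion burden.

    A zero unstable-area denominator makes the score undefined (flagged,
    excluded from group means by the table-level summary).
    """
    denom = cd68 + oro
    if denom <= 0:
        return StabilityScore(raw=float("nan"), normalized=float("nan"), undefined=True)
    raw = (sm22 + collagen) / denom
    return StabilityScore(raw=raw, normalized=raw / burden)


def score_histology_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse raw and burden-normalized stability scores plus group summary.

    Expects columns sm22, collagen, cd68, oro, burden, group. Undefined
    scores (zero unstable area) are flagged and excluded from group
    means.
    """
    scores = []
    for row in table.itertuples():
        s = plaque_stability_score(row.sm22, row.collagen, row.cd68, row.oro, row.burden)
        scores.append((s.raw, s.normalized, s.undefined))
    out = table.copy()
    out[["raw_score", "normalized_score", "score_undefined"]] = pd.DataFrame(
        scores, index=table.index)
    summary = (out[~out["score_undefined"]]
               .groupby("group")["normalized_score"].agg(["mean", "std", "count"]))
    out.attrs["group_summary"] = summary
    return out


def impute_missing(table: pd.DataFrame, strategy: str = "group_mean",
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing histology cells per group; returns (table, log).

    "group_mean" fills with the group mean of observed values;
    "stochastic" draws from a Normal fit to the group's observed values
    (a seeded single draw standing in for multiple imputation). Every
    imputed cell is logged with mouse, field, group and value. A
    group/field with no observed values is rejected by name.
    """
    if strategy not in ("group_mean", "stochastic"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    log_rows = []
    for group, sub in table.groupby("group"):
        for fld in STAIN_FIELDS:
            observed = sub[fld].dropna()
            missing_idx = sub.index[sub[fld].isna()]
            if len(missing_idx) == 0:
                continue
            if len(observed) == 0:
                raise ValueError(f"group {group!r}, field {fld!r} fully missing")
            if strategy == "group_mean":
                fills = np.full(len(missing_idx), observed.mean())
            else:
                sd = observed.std(ddof=1) if len(observed) > 1 else 0.0
                fills = rng.normal(observed.mean(), sd, size=len(missing_idx))
                fills = np.clip(fills, 0.0, 100.0)
            out.loc[missing_idx, fld] = fills
            for mouse, val in zip(missing_idx, fills):
                log_rows.append({"mouse_id": mouse, "group": group, "field": fld,
                                 "imputed_value": float(val), "strategy": strategy})
    log = pd.DataFrame(log_rows, columns=["mouse_id", "group", "field",
                                          "imputed_value", "strategy"])
    return out, log


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Welch two-sided p and mean difference (a − b).

    Two zero-variance groups with equal means give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (1.0 if diff == 0 else 0.0), diff
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue), diff
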
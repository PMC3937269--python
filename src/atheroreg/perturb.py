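"""siRNA perturbation-screen analysis and network specificity testing.

Knockdown screens over a fixed gene panel (673 genes in the study's
custom array) are analyzed by Welch tests with BH FDR (<0.1 by default);
the fraction of each time-point network affected by silencing its
candidate master regulator is summarized, and specificity is tested with
the upper-tail hypergeometric probability of the observed overlap.
Cholesterol-ester (CE) accumulation readouts are normalized to a control
mean of 100 and reported as integer percent changes with a Welch p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import bh_fdr, welch_tests

PANEL_SIZE = 673
NETWORK_SIZES = {"30": 53, "40": 185, "50": 379}


def round_half_away(x: float) -> int:
    """Round half away from zero, matching the printed style (+12, −17)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class HypergeomParams:
    """Overlap test parameters.

    M: panel (population) size; K: time-point network size within the
    panel; X: number of panel genes affected by the silencing; x:
    affected genes inside the network. The test asks how probable an
    overlap of x or more is when drawing X genes from M, of which K are
    network members.
    """

    M: int
    K: int
    X: int
    x: int

    def __post_init__(self):
        if not (0 <= self.x <= min(self.X, self.K) <= self.M):
            raise ValueError(f"invalid hypergeometric parameters {self}")
        if self.X > self.M:
            raise ValueError("cannot draw more genes than the panel holds")


@dataclass
class ScreenResult:
    target_tf: str
    affected: list[str]
    knockdown_efficiency: float
    per_network: pd.DataFrame = field(default=None)  # index stage: K, x, percent, specificity_p


@dataclass
class CEResult:
    control_values: np.ndarray
    knockdown_values: np.ndarray
    percent_change: int
    p_value: float
    control_mean: float = 100.0
    knockdown_mean: float = float("nan")
    negative_ce_flagged: bool = False


def knockdown_de(control_expr: pd.DataFrame, kd_expr: pd.DataFrame,
                 panel: list[str], fdr: float = 0.1) -> pd.DataFrame:
    """Per-gene Welch test of knockdown vs control over the panel, BH FDR.

    Returns the full per-gene table (stat, p, fdr, direction, affected);
    missing panel genes in either matrix are rejected by name.
    """
    for name, expr in (("control", control_expr), ("knockdown", kd_expr)):
        missing = [g for g in panel if g not in expr.index]
        if missing:
            raise ValueError(f"panel genes missing from {name} expression: {missing[:10]}")
        if expr.shape[1] < 2:
            raise ValueError(f"{name} arm needs >= 2 replicates")
    joint = pd.concat([kd_expr.loc[panel], control_expr.loc[panel]], axis=1)
    table = welch_tests(joint, list(kd_expr.columns), list(control_expr.columns))
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table["direction"] = np.where(table["stat"] >= 0, "up", "down")
    table["affected"] = table["fdr"] < fdr
    return table


def affected_gene_set(de_table: pd.DataFrame) -> list[str]:
    return list(de_table.index[de_table["affected"]])


def affected_network_fraction(affected: list[str], network_members: list[str]) -> tuple[int, int]:
    """Overlap count x and whole-percent fraction of the network affected.

    Mirrors the reporting style "28% (15/53)": percent is
    round(100·x/K) with K the network size.
    """
    K = len(network_members)
    if K == 0:
        raise ValueError("empty network")
    x = len(set(affected) & set(network_members))
    return x, round_half_away(100.0 * x / K)


def hypergeometric_specificity(params: HypergeomParams) -> float:
    """Upper-tail hypergeometric P(overlap >= x).

    P = sum_{k=x}^{min(X,K)} C(K,k) C(M−K, X−k) / C(M, X); x = 0 gives
    P = 1 (certain event).
    """
    return float(stats.hypergeom.sf(params.x - 1, params.M, params.K, params.X))


def knockdown_efficiency(control_expr: pd.DataFrame, kd_expr: pd.DataFrame,
                         target: str) -> float:
    """Relative (linear-scale) target expression in knockdown vs control."""
    diff = float(kd_expr.loc[target].mean() - control_expr.loc[target].mean())
    return float(2.0**diff)


def analyze_screen(control_expr: pd.DataFrame, kd_expr: pd.DataFrame, panel: list[str],
                   target_tf: str, networks: dict[str, list[str]],
                   fdr: float = 0.1) -> ScreenResult:
    """Full screen analysis for one silenced TF across all stage networks."""
    de = knockdown_de(control_expr, kd_expr, panel, fdr=fdr)
    affected = affected_gene_set(de)
    rows = {}
    for stage, members in networks.items():
        x, percent = affected_network_fraction(affected, members)
        params = HypergeomParams(M=len(panel), K=len(members), X=len(affected), x=x)
        rows[stage] = {"K": len(members), "x": x, "percent": percent,
                       "specificity_p": hypergeometric_specificity(params)}
    return ScreenResult(
        target_tf=target_tf, affected=affected,
        knockdown_efficiency=knockdown_efficiency(control_expr, kd_expr, target_tf),
        per_network=pd.DataFrame(rows).T,
    )


def comparative_ct(target_ct: float, reference_ct: float, calibrator_delta: float) -> float:
    """Relative expression 2^(−ΔΔCt), ΔΔCt = (target − reference) − calibrator Δ."""
    ddct = (target_ct - reference_ct) - calibrator_delta
    return float(2.0 ** (-ddct))


def ce_change(control_tc_fc_protein: pd.DataFrame, kd_tc_fc_protein: pd.DataFrame) -> CEResult:
    """Cholesterol-ester accumulation change after silencing.

    Per replicate CE = (total − free cholesterol)/protein; both arms are
    scaled so the control mean is 100; percent change is the integer
    (half away from zero) knockdown mean minus 100, with a two-sided
    Welch p. Negative CE after the subtraction is flagged but retained.
    Input frames need columns total_chol, free_chol, protein.
    """
    def _per_rep(df):
        if (df["protein"] <= 0).any():
            raise ValueError("protein concentrations must be positive")
        return ((df["total_chol"] - df["free_chol"]) / df["protein"]).to_numpy(dtype=float)

    ctrl = _per_rep(control_tc_fc_protein)
    kd = _per_rep(kd_tc_fc_protein)
    if len(ctrl) < 3 or len(kd) < 3:
        raise ValueError("need >= 3 replicates per arm")
    flagged = bool((ctrl < 0).any() or (kd < 0).any())
    scale = 100.0 / ctrl.mean()
    ctrl_s, kd_s = ctrl * scale, kd * scale
    p = float(stats.ttest_ind(kd_s, ctrl_s, equal_var=False).pvalue)
    return CEResult(control_values=ctrl_s, knockdown_values=kd_s,
                    percent_change=round_half_away(kd_s.mean() - 100.0),
                    p_value=p, knockdown_mean=float(kd_s.mean()),
                    negative_ce_flagged=flagged)


def ce_change_from_values(control_ce: np.ndarray, kd_ce: np.ndarray) -> CEResult:
    """CE change from already-computed per-replicate CE values."""
    ctrl = np.asarray(control_ce, dtype=float)
    kd = np.asarray(kd_ce, dtype=float)
    if len(ctrl) < 3 or len(kd) < 3:
        raise ValueError("need >= 3 replicates per arm")
    scale = 100.0 / ctrl.mean()
    ctrl_s, kd_s = ctrl * scale, kd * scale
    p = float(stats.ttest_ind(kd_s, ctrl_s, equal_var=False).pvalue)
    return CEResult(control_values=ctrl_s, knockdown_values=kd_s,
                    percent_change=round_half_away(kd_s.mean() - 100.0),
                    p_value=p, knockdown_mean=float(kd_s.mean()))
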
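"""Relative expression by 2^−ΔΔCt and methylation–expression correlation.

ΔCt = Ct(target) − Ct(reference) per sample (technical replicate Cts averaged
first); ΔΔCt subtracts the control-group mean ΔCt, so fold change = 2^−ΔΔCt
and log2 fold change = −ΔΔCt.  Correlations between per-sample overall
methylation (%Cm) and log2 expression are Spearman rank correlations computed
separately per group, with the exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "delta_delta_ct",
    "SpearmanResult",
    "spearman",
    "correlate_methylation_expression",
]


def delta_delta_ct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    case_group: str,
    control_group: str,
    mode: str = "per_sample",
) -> pd.DataFrame:
    """Relative expression of ``target_gene`` by the 2^−ΔΔCt method.

    ``ct`` has columns sample_id, group, gene, ct; replicate rows per
    (sample, gene) are averaged.  ``per_sample`` returns one row per sample
    (both groups) with ΔΔCt taken against the control-group mean ΔCt — the
    per-sample values are what a methylation–expression scatter needs.
    ``group_mean`` returns a single row from the group-mean ΔCts.  Samples
    missing a reference (or target) Ct are excluded with a warning.
    """
    if mode not in ("per_sample", "group_mean"):
        raise ValueError(f"mode must be per_sample or group_mean, got {mode}")
    sub = ct[ct["group"].isin([case_group, control_group])]
    averaged = (
        sub.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
    )
    wide = averaged.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    ).reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"no Ct rows for gene {gene!r}")
    complete = wide.dropna(subset=[target_gene, reference_gene]).copy()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("%d samples lacked target or reference Ct and were excluded",
                       dropped)
    complete["delta_ct"] = complete[target_gene] - complete[reference_gene]
    ctrl_dct = complete.loc[complete["group"] == control_group, "delta_ct"]
    if ctrl_dct.empty:
        raise ValueError(f"no usable control samples in group {control_group!r}")
    ctrl_mean = float(ctrl_dct.mean())

    if mode == "group_mean":
        case_dct = complete.loc[complete["group"] == case_group, "delta_ct"]
        if case_dct.empty:
            raise ValueError(f"no usable case samples in group {case_group!r}")
        ddct = float(case_dct.mean()) - ctrl_mean
        return pd.DataFrame(
            [
                {
                    "sample_id": None,
                    "group": case_group,
                    "delta_ct": float(case_dct.mean()),
                    "delta_delta_ct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                    "log2_fc": -ddct,
                }
            ]
        )

    out = complete[["sample_id", "group", "delta_ct"]].copy()
    out["delta_delta_ct"] = out["delta_ct"] - ctrl_mean
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    out["log2_fc"] = -out["delta_delta_ct"]
    return out.sort_values(["group", "sample_id"]).reset_index(drop=True)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact" (permutation) or "t_approx"
    defined: bool = True

    @property
    def rho_squared(self) -> float:
        return self.rho * self.rho


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x, y, exact_below: int = 10) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    The two-sided p-value is exact — a full enumeration of the n! pairings of
    the observed ranks — for n < ``exact_below``, and the usual
    t-approximation otherwise.  Pairs with a missing value are removed first;
    zero rank variance leaves rho undefined (``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = stats.rankdata(x)  # mid-ranks
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("zero rank variance: Spearman rho undefined")
        return SpearmanResult(rho=float("nan"), p_value=float("nan"),
                              n=n, method="undefined", defined=False)
    rho = _rank_corr(rx, ry)
    if n < exact_below:
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= obs - 1e-12:
                count += 1
        return SpearmanResult(rho=rho, p_value=count / total, n=n, method="exact")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho)) if abs(rho) < 1 else math.inf
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho=rho, p_value=min(p, 1.0), n=n, method="t_approx")


def correlate_methylation_expression(
    profiles: pd.DataFrame,
    expression: pd.DataFrame,
    groups: list[str] | None = None,
    meth_col: str = "pct_m",
    expr_col: str = "log2_fc",
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-group Spearman correlation of methylation against log2 expression.

    ``profiles`` (sample_id, group, pct_m, ...) and ``expression``
    (sample_id, log2_fc, ...) are matched on sample_id; unmatched samples are
    dropped with a log entry.  Each requested group (default: all groups
    present after the merge) with at least ``min_n`` samples yields one row:
    group, n, rho, rho_squared, p.
    """
    merged = profiles.merge(
        expression[["sample_id", expr_col]], on="sample_id", how="inner"
    )
    lost = len(profiles) - len(merged)
    if lost:
        logger.info("%d profile samples had no expression match and were dropped", lost)
    if groups is None:
        groups = sorted(merged["group"].unique())
    rows = []
    for grp in groups:
        part = merged[merged["group"] == grp]
        if len(part) < min_n:
            logger.warning("group %s skipped: %d < %d samples", grp, len(part), min_n)
            continue
        res = spearman(part[meth_col].to_numpy(), part[expr_col].to_numpy())
        rows.append(
            {
                "group": grp,
                "n": res.n,
                "rho": res.rho,
                "rho_squared": res.rho_squared,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "rho", "rho_squared", "p"])
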
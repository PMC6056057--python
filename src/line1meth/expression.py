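"""Differential expression on case/control matrices.

Expression values are assumed log-scale and preprocessed (no normalisation is
performed here).  The workflow mirrors common microarray reanalysis practice:
a missingness filter that keeps transcripts quantified in at least 70% of
samples, a per-gene two-sample t-test with pairwise exclusion of missing
values, and a family-wise multiple-test correction (classic Bonferroni or the
Holm step-down variant) before calling genes up- or down-regulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "filter_missingness",
    "t_test_per_gene",
    "adjust_bonferroni",
    "call_degs",
    "collapse_probes",
]


@dataclass
class ExpressionMatrix:
    """Genes/probes × samples expression values with sample group labels.

    ``values`` is a float DataFrame indexed by gene/probe identifier with one
    column per sample (NaN marks missing measurements).  ``groups`` maps every
    sample identifier to a group label (e.g. ``ASD``/``L``/``M``/``S`` for
    cases and a control label).
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if self.groups.nunique() < 2:
            raise ValueError("need at least two sample groups")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @classmethod
    def from_tsv(cls, matrix_path, groups_path) -> "ExpressionMatrix":
        """Read a series-matrix-style TSV (first column = gene/probe ID) plus a
        two-column sample→group TSV."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        grp = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(values=values, groups=grp)

    def to_tsv(self, matrix_path, groups_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.groups.rename("group").to_csv(
            groups_path, sep="\t", index_label="sample_id"
        )


def filter_missingness(
    matrix: ExpressionMatrix, retain_fraction: float = 0.7
) -> ExpressionMatrix:
    """Drop rows quantified in fewer than ``retain_fraction`` of all samples.

    The default keeps transcripts with data in at least 70% of samples,
    i.e. removes those missing in more than 30% — the boundary row (exactly
    30% missing) is retained.  Row order is preserved; the number of removed
    rows is logged.  An empty result is a warning, not an error.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError(f"retain_fraction must be in (0, 1], got {retain_fraction}")
    n = matrix.values.shape[1]
    present = matrix.values.notna().sum(axis=1)
    # small tolerance so 7/10 passes retain_fraction=0.7 despite float rounding
    keep = present >= retain_fraction * n - 1e-9
    removed = int((~keep).sum())
    logger.info("missingness filter removed %d of %d rows", removed, len(keep))
    out = ExpressionMatrix(values=matrix.values.loc[keep], groups=matrix.groups)
    if out.values.empty:
        logger.warning("missingness filter removed every row")
    return out


def _pooled_or_welch(case: np.ndarray, ctrl: np.ndarray, variance_mode: str):
    equal_var = {"pooled": True, "welch": False}[variance_mode]
    return stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var,
                           nan_policy="omit")


def t_test_per_gene(
    matrix: ExpressionMatrix,
    case_group: str,
    control_group: str,
    variance_mode: str = "pooled",
) -> pd.DataFrame:
    """Two-tailed two-sample t-test per gene, missing values excluded per gene.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``,
    ``mean_case``, ``mean_control``, ``n_case``, ``n_control``, ``tested`` and
    ``degenerate``.  Genes with fewer than two non-missing values in either
    group are skipped (``tested=False``).  Zero variance in both groups gives
    the conventional t=0/p=1 when the means agree and p=0 flagged
    ``degenerate`` when they differ.
    """
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"variance_mode must be pooled or welch, got {variance_mode}")
    case_cols = matrix.samples_in(case_group)
    ctrl_cols = matrix.samples_in(control_group)
    if not case_cols or not ctrl_cols:
        raise ValueError(
            f"groups {case_group!r} / {control_group!r} not found in matrix"
        )
    case = matrix.values[case_cols].to_numpy(float)
    ctrl = matrix.values[ctrl_cols].to_numpy(float)

    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    tested = (n_case >= 2) & (n_ctrl >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_case = np.nanmean(case, axis=1)
        mean_ctrl = np.nanmean(ctrl, axis=1)
        var_case = np.nanvar(case, axis=1, ddof=0)
        var_ctrl = np.nanvar(ctrl, axis=1, ddof=0)
        res = _pooled_or_welch(case, ctrl, variance_mode)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)

    both_flat = tested & (var_case == 0) & (var_ctrl == 0)
    equal_means = both_flat & np.isclose(mean_case, mean_ctrl)
    unequal_means = both_flat & ~np.isclose(mean_case, mean_ctrl)
    t[equal_means], p[equal_means] = 0.0, 1.0
    t[unequal_means] = np.where(mean_case[unequal_means] > mean_ctrl[unequal_means],
                                np.inf, -np.inf)
    p[unequal_means] = 0.0
    t[~tested] = np.nan
    p[~tested] = np.nan
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("t-test skipped %d genes with <2 values per group", n_skipped)

    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "n_case": n_case,
            "n_control": n_ctrl,
            "tested": tested,
            "degenerate": unequal_means,
        },
        index=matrix.values.index,
    )


def adjust_bonferroni(p_values, mode: str = "step_down") -> np.ndarray:
    """Family-wise correction: ``classic`` min(1, m·p) or Holm ``step_down``.

    Holm is uniformly no larger than the classic adjustment and controls the
    same family-wise error rate, which is why it is the default here.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mode == "classic":
        return np.minimum(1.0, p * p.size)
    if mode == "step_down":
        return multipletests(p, method="holm")[1]
    raise ValueError(f"mode must be classic or step_down, got {mode}")


def call_degs(
    matrix: ExpressionMatrix,
    case_group: str,
    control_group: str,
    alpha: float = 0.05,
    correction: str = "step_down",
    variance_mode: str = "pooled",
) -> pd.DataFrame:
    """Call differentially expressed genes at family-wise level ``alpha``.

    The input matrix is expected to be missingness-filtered already.  Returns
    one row per significant gene with columns ``gene_id``, ``t``, ``p``,
    ``p_adj``, ``direction`` (up/down by sign of case−control mean),
    ``mean_case``, ``mean_control``, ordered by ascending adjusted p then
    gene id.  An empty frame (with the same columns) is a valid result.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    tt = t_test_per_gene(matrix, case_group, control_group, variance_mode)
    tested = tt[tt["tested"]].copy()
    tested["p_adj"] = adjust_bonferroni(tested["p"].to_numpy(), mode=correction)
    sig = tested[tested["p_adj"] < alpha].copy()
    sig["direction"] = np.where(sig["mean_case"] > sig["mean_control"], "up", "down")
    sig = sig.reset_index(names="gene_id")
    sig = sig.sort_values(["p_adj", "p", "gene_id"], kind="mergesort")
    cols = ["gene_id", "t", "p", "p_adj", "direction", "mean_case", "mean_control"]
    return sig[cols].reset_index(drop=True)


def collapse_probes(deg_table: pd.DataFrame, probe_to_symbol: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level DEG table to gene symbols.

    A gene is a DEG if at least one of its probes is significant; the
    best-supported probe (smallest adjusted p) represents the gene.  Probes
    with no symbol mapping are dropped.
    """
    mapped = deg_table.assign(symbol=deg_table["gene_id"].map(probe_to_symbol))
    mapped = mapped.dropna(subset=["symbol"])
    mapped = mapped.sort_values(["p_adj", "p"], kind="mergesort")
    collapsed = mapped.drop_duplicates(subset="symbol", keep="first").copy()
    collapsed["probe_id"] = collapsed["gene_id"]
    collapsed["gene_id"] = collapsed["symbol"]
    return collapsed.drop(columns="symbol").reset_index(drop=True)
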
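"""Over-representation of LINE-1-inserted genes among DEG lists.

The core statistic is the 2×2 exact test: genes in a fixed universe are
cross-classified as DEG/non-DEG × inserted/non-inserted and the Fisher exact
p-value (two-sided by default, upper-tail hypergeometric for a directional
"over-represented" question) is computed per comparison.  Within a study the
comparisons (insertion types × up/down/all directions) form one
Benjamini–Hochberg family.  A random-gene control re-draws gene lists of the
same size uniformly from the universe and compares the observed upper-tail
p-value against the draw distribution.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "RandomControlResult",
    "build_contingency",
    "fisher_exact",
    "hypergeom_upper_tail",
    "bh_adjust",
    "random_gene_control",
    "multi_study_overlap",
    "VennPartition",
    "enrich_study",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 gene cross-classification.

    a: DEGs with insertion, b: DEGs without, c: non-DEGs with insertion,
    d: non-DEGs without.  Margins: a+b = |DEGs|, a+c = |inserted|,
    a+b+c+d = |universe|.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        """Sample odds ratio a·d/(b·c); inf when b·c = 0 and a·d > 0, NaN when
        both products vanish."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return float("inf") if num > 0 else float("nan")
        return num / den

    def degenerate(self) -> bool:
        """A row or column margin is zero, so the table carries no information."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def build_contingency(deg_genes: set, inserted_genes: set, universe: set) -> ContingencyTable:
    """Cross-classify a universe of genes by DEG status and insertion status.

    Genes outside the universe are logged and intersected away so the four
    cells partition exactly one population.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    deg = set(deg_genes)
    ins = set(inserted_genes)
    outside = len(deg - universe)
    if outside:
        logger.info("%d DEG genes outside the universe were dropped", outside)
    deg &= universe
    ins &= universe
    a = len(deg & ins)
    b = len(deg - ins)
    c = len(ins - deg)
    d = len(universe) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


@functools.lru_cache(maxsize=16384)
def _hypergeom_pmf_vector(N: int, K: int, n: int):
    """Hypergeometric pmf over the full support; cached across the many tables
    that share margins (e.g. one study's comparisons, or an enumeration)."""
    lo, hi = max(0, n + K - N), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    pmf.setflags(write=False)
    return lo, pmf


def fisher_exact(table: ContingencyTable, alternative: str = "two_sided"):
    """Fisher's exact test on a 2×2 table; returns ``(p_value, odds_ratio)``.

    ``two_sided`` sums the hypergeometric point probabilities no larger than
    the observed one (the classic definition); ``greater`` is the upper tail
    of cell ``a``.  A degenerate margin gives p = 1 with an undefined (NaN or
    inf) odds ratio.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"alternative must be two_sided or greater, got {alternative}")
    if table.degenerate():
        return 1.0, table.odds_ratio()
    N = table.n
    K = table.a + table.c  # inserted
    n = table.a + table.b  # DEGs
    if alternative == "greater":
        p = float(stats.hypergeom.sf(table.a - 1, N, K, n))
    else:
        lo, pmf = _hypergeom_pmf_vector(N, K, n)
        p_obs = pmf[table.a - lo]
        # relative tolerance absorbs floating error in pmf ties (R convention)
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0), table.odds_ratio()


def hypergeom_upper_tail(a: int, K: int, n: int, N: int) -> float:
    """P(X ≥ a) for X ~ Hypergeom(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= a <= min(K, n)):
        raise ValueError(
            f"a={a} outside the hypergeometric support [{max(0, n + K - N)}, {min(K, n)}]"
        )
    return float(min(stats.hypergeom(N, K, n).sf(a - 1), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class RandomControlResult:
    """Observed upper-tail p versus p-values of random same-size gene draws."""

    observed_overlap: int
    observed_p_hypergeom: float
    draw_ps: np.ndarray = field(repr=False)
    n_draws: int = 0
    seed: int = 0

    @property
    def empirical_rank(self) -> float:
        """Fraction of random draws at least as extreme as the observation."""
        return float(np.mean(self.draw_ps <= self.observed_p_hypergeom))


def random_gene_control(
    deg_genes: set,
    inserted_genes: set,
    universe: set,
    n_draws: int = 1000,
    seed: int = 0,
) -> RandomControlResult:
    """Compare observed insertion overlap against random same-size gene lists.

    Each draw samples ``len(deg_genes)`` genes uniformly without replacement
    from the universe and records the hypergeometric upper-tail p of its
    overlap with the inserted set.  Reproducible from ``seed``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    universe_list = sorted(set(universe))
    N = len(universe_list)
    if N == 0:
        raise ValueError("universe must be non-empty")
    deg = set(deg_genes) & set(universe_list)
    ins = set(inserted_genes) & set(universe_list)
    size = len(deg)
    if size > N:
        raise ValueError("DEG list larger than the universe")
    K = len(ins)
    observed = len(deg & ins)
    if size == 0:
        observed_p = 1.0
    else:
        observed_p = hypergeom_upper_tail(observed, K, size, N)
    rng = np.random.default_rng(seed)
    inserted_mask = np.fromiter(
        (g in ins for g in universe_list), dtype=bool, count=N
    )
    dist = stats.hypergeom(N, K, size)
    draw_ps = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(N, size=size, replace=False)
        k = int(inserted_mask[idx].sum())
        draw_ps[i] = min(float(dist.sf(k - 1)), 1.0) if size else 1.0
    return RandomControlResult(
        observed_overlap=observed,
        observed_p_hypergeom=observed_p,
        draw_ps=draw_ps,
        n_draws=n_draws,
        seed=seed,
    )


@dataclass(frozen=True)
class VennPartition:
    """Exclusive Venn regions of named gene lists."""

    regions: dict[tuple[str, ...], frozenset[str]]

    def at_least(self, k: int) -> frozenset[str]:
        out: set[str] = set()
        for names, genes in self.regions.items():
            if len(names) >= k:
                out |= genes
        return frozenset(out)

    @property
    def union_size(self) -> int:
        return sum(len(g) for g in self.regions.values())


def multi_study_overlap(lists: dict[str, set]) -> VennPartition:
    """Partition the union of named gene lists into exclusive Venn regions.

    Every gene lands in exactly one region, keyed by the sorted tuple of the
    lists containing it; ``at_least(2)`` gives the genes reproduced in two or
    more lists.
    """
    if len(lists) < 2:
        raise ValueError("need at least two gene lists for an overlap analysis")
    names = sorted(lists)
    regions: dict[tuple[str, ...], set[str]] = {}
    union = set().union(*(set(v) for v in lists.values()))
    for gene in union:
        key = tuple(n for n in names if gene in lists[n])
        regions.setdefault(key, set()).add(gene)
    return VennPartition(regions={k: frozenset(v) for k, v in regions.items()})


def enrich_study(
    deg_table: pd.DataFrame,
    gene_sets,
    universe: set,
    study: str = "study",
    alternative: str = "two_sided",
) -> pd.DataFrame:
    """Table-2-shaped enrichment report for one study.

    For each insertion type (plus the all-insertion union) and each direction
    (all/up/down), builds the 2×2 table against ``universe``, runs the exact
    test, and BH-adjusts within the study's comparison family.  Returns
    columns: study, insertion_type, direction, n_deg, n_overlap, odds_ratio,
    p, p_adj, overlap_genes (';'-joined, S4-style).
    """
    directions = {
        "all": set(deg_table["gene_id"]),
        "up": set(deg_table.loc[deg_table["direction"] == "up", "gene_id"]),
        "down": set(deg_table.loc[deg_table["direction"] == "down", "gene_id"]),
    }
    set_map = {"all_insertion": set(gene_sets.all_insertion)}
    set_map.update({t: set(s) for t, s in gene_sets.by_type.items()})
    rows = []
    for set_name, direction in itertools.product(set_map, directions):
        deg = directions[direction]
        table = build_contingency(deg, set_map[set_name], universe)
        p, oddsr = fisher_exact(table, alternative=alternative)
        overlap = sorted((deg & set_map[set_name]) & set(universe))
        rows.append(
            {
                "study": study,
                "insertion_type": set_name,
                "direction": direction,
                "n_deg": table.a + table.b,
                "n_overlap": table.a,
                "odds_ratio": oddsr,
                "p": p,
                "overlap_genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    cols = ["study", "insertion_type", "direction", "n_deg", "n_overlap",
            "odds_ratio", "p", "p_adj", "overlap_genes"]
    return out[cols]
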
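"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its configuration and seed, so the full
analysis — DEG calling, insertion enrichment, COBRA deconvolution, ΔΔCt and
correlation — can be exercised and calibrated without any external data.

The expression generator plants a known fraction of differentially expressed
genes with a fixed mean shift and assigns LINE-1-insertion labels so that the
DEG-vs-insertion odds ratio equals a requested value exactly in expectation.
The gel-lane generator is the forward model inverted by the COBRA pattern
formulas: molar band amounts compose from the four two-site methylation
pattern counts as A=n_mu, B=n_uu, C=2·n_mm+n_um, D=n_um+n_uu, and optical band
intensity is proportional to molar amount × fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cobra import BAND_LENGTHS, BandIntensityRecord
from .expression import ExpressionMatrix

__all__ = [
    "ExpressionSimConfig",
    "PatternCounts",
    "simulate_expression_study",
    "simulate_gel_lane",
    "simulate_gel_study",
    "simulate_qpcr",
    "simulate_correlated_pairs",
]


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Design of a simulated two-group expression study.

    ``enrichment_odds`` is the odds that a planted DEG carries a LINE-1
    insertion relative to a non-DEG; ``effect_size`` is the case-minus-control
    mean shift (log-expression units) of planted DEGs before measurement
    noise; ``missing_rate`` places missing cells completely at random.
    """

    n_genes: int = 10_000
    n_case: int = 20
    n_control: int = 20
    frac_inserted: float = 0.25
    frac_deg: float = 0.02
    enrichment_odds: float = 1.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    case_label: str = "ASD"
    control_label: str = "CTRL"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                f"n_case and n_control must be >= 2, got {self.n_case}/{self.n_control}"
            )
        for name in ("frac_inserted", "frac_deg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.enrichment_odds <= 0:
            raise ValueError(f"enrichment_odds must be > 0, got {self.enrichment_odds}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")


def _insertion_probs(frac_inserted: float, frac_deg: float, odds: float):
    """Per-class insertion probabilities (p_deg, p_nondeg).

    Chosen so that odds(p_deg)/odds(p_nondeg) = ``odds`` while the overall
    insertion fraction stays at ``frac_inserted``:
        frac_deg·p1 + (1−frac_deg)·p0 = frac_inserted.
    """
    if frac_inserted in (0.0, 1.0) or odds == 1.0 or frac_deg in (0.0, 1.0):
        return frac_inserted, frac_inserted

    def p1(p0):
        return odds * p0 / (1 - p0 + odds * p0)

    def f(p0):
        return frac_deg * p1(p0) + (1 - frac_deg) * p0 - frac_inserted

    lo, hi = 1e-12, 1 - 1e-12
    p0 = brentq(f, lo, hi, xtol=1e-14)
    return p1(p0), p0


def simulate_expression_study(config: ExpressionSimConfig):
    """Simulate a case/control log-expression matrix with planted truth.

    Returns ``(matrix, truth)`` where ``truth`` is a per-gene DataFrame with
    ``is_deg``, ``direction`` (up/down/none) and ``is_inserted``.  Planted
    DEGs have a case-minus-control group-mean difference of exactly
    ``effect_size`` before noise; missing cells are uniform at
    ``missing_rate``; everything is reproducible from ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    g, nc, nk = config.n_genes, config.n_case, config.n_control
    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"case_{i:03d}" for i in range(nc)] + [
        f"ctrl_{i:03d}" for i in range(nk)
    ]
    groups = pd.Series(
        [config.case_label] * nc + [config.control_label] * nk, index=sample_ids
    )

    n_deg = int(round(config.frac_deg * g))
    is_deg = np.zeros(g, dtype=bool)
    is_deg[rng.choice(g, size=n_deg, replace=False)] = True
    direction = np.where(is_deg, rng.choice([1.0, -1.0], size=g), 0.0)

    p1, p0 = _insertion_probs(config.frac_inserted, n_deg / g if g else 0.0,
                              config.enrichment_odds)
    is_inserted = rng.random(g) < np.where(is_deg, p1, p0)

    base = rng.normal(8.0, 1.0, size=g)
    values = base[:, None] + rng.normal(0.0, config.noise_sd, size=(g, nc + nk))
    values[:, :nc] += (direction * config.effect_size)[:, None]

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        groups=groups,
    )
    truth = pd.DataFrame(
        {
            "is_deg": is_deg,
            "direction": np.where(
                is_deg, np.where(direction > 0, "up", "down"), "none"
            ),
            "is_inserted": is_inserted,
        },
        index=gene_ids,
    )
    return matrix, truth


@dataclass(frozen=True)
class PatternCounts:
    """Molecule counts of the four two-site methylation patterns in one lane."""

    n_mm: float
    n_mu: float
    n_um: float
    n_uu: float

    def __post_init__(self):
        vals = (self.n_mm, self.n_mu, self.n_um, self.n_uu)
        if any(v < 0 for v in vals):
            raise ValueError("pattern counts must be non-negative")
        if sum(vals) <= 0:
            raise ValueError("pattern counts must have a positive total")

    @property
    def total(self) -> float:
        return self.n_mm + self.n_mu + self.n_um + self.n_uu

    def proportions(self) -> dict[str, float]:
        t = self.total
        return {
            "mm": 100.0 * self.n_mm / t,
            "mu": 100.0 * self.n_mu / t,
            "um": 100.0 * self.n_um / t,
            "uu": 100.0 * self.n_uu / t,
        }


def simulate_gel_lane(
    counts: PatternCounts,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "lane",
    group: str = "NA",
) -> BandIntensityRecord:
    """Forward-model a COBRA gel lane from pattern molecule counts.

    Molar band amounts: A=n_mu (160 bp), B=n_uu (98 bp), C=2·n_mm+n_um
    (80 bp), D=n_um+n_uu (62 bp).  Intensities are molar × length, normalised
    to sum to 100, then perturbed by multiplicative Gaussian noise of scale
    ``noise_sd`` (clipped at zero) and renormalised.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    molar = np.array(
        [
            counts.n_mu,
            counts.n_uu,
            2.0 * counts.n_mm + counts.n_um,
            counts.n_um + counts.n_uu,
        ]
    )
    intensity = molar * np.array(BAND_LENGTHS, dtype=float)
    intensity = 100.0 * intensity / intensity.sum()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * np.clip(1.0 + rng.normal(0.0, noise_sd, 4), 0.0, None)
        intensity = 100.0 * intensity / intensity.sum()
    return BandIntensityRecord(
        sample_id=sample_id, group=group,
        i160=intensity[0], i98=intensity[1], i80=intensity[2], i62=intensity[3],
    )


def simulate_gel_study(
    group_pct_m: dict[str, tuple[float, int]],
    between_sd: float = 4.0,
    noise_sd: float = 0.01,
    n_molecules: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a band-intensity table for groups with given mean overall %Cm.

    ``group_pct_m`` maps group label → (mean %Cm, n_samples).  Each sample
    draws its own %Cm from a normal with SD ``between_sd`` (clipped to
    [1, 99]); the two CpG sites are then methylated independently at that
    marginal rate, fixing the four pattern counts, and the lane is rendered
    with ``simulate_gel_lane``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, (mean_m, n) in group_pct_m.items():
        for i in range(n):
            m = float(np.clip(rng.normal(mean_m, between_sd), 1.0, 99.0)) / 100.0
            counts = rng.multinomial(
                n_molecules,
                [m * m, m * (1 - m), (1 - m) * m, (1 - m) * (1 - m)],
            )
            # guard against a degenerate all-zero draw (cannot happen for
            # n_molecules >= 1, but keeps PatternCounts honest)
            pc = PatternCounts(*[float(c) for c in counts])
            lane = simulate_gel_lane(
                pc,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
                sample_id=f"{group}_{i:03d}",
                group=group,
            )
            rows.append(lane.__dict__)
    return pd.DataFrame(rows)


def simulate_qpcr(
    fold_changes,
    base_ct: float = 25.0,
    ref_ct: float = 20.0,
    n_control: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "LINE1",
    reference_gene: str = "GAPDH",
    case_label: str = "ASD",
    control_label: str = "CTRL",
) -> pd.DataFrame:
    """Generate a Ct table realising given per-case-sample fold changes.

    Control samples have target Ct ``base_ct`` and reference Ct ``ref_ct``;
    case sample i has target Ct ``base_ct − log2(fc_i)`` so that the 2^−ΔΔCt
    method recovers ``fc_i`` exactly when ``noise_sd`` is zero.
    """
    fc = np.asarray(list(fold_changes), dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_control):
        sid = f"ctrl_{i:03d}"
        rows.append((sid, control_label, target_gene,
                     base_ct + rng.normal(0, noise_sd) if noise_sd else base_ct))
        rows.append((sid, control_label, reference_gene,
                     ref_ct + rng.normal(0, noise_sd) if noise_sd else ref_ct))
    for i, f in enumerate(fc):
        sid = f"case_{i:03d}"
        ct_t = base_ct - np.log2(f)
        rows.append((sid, case_label, target_gene,
                     ct_t + rng.normal(0, noise_sd) if noise_sd else ct_t))
        rows.append((sid, case_label, reference_gene,
                     ref_ct + rng.normal(0, noise_sd) if noise_sd else ref_ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


def simulate_correlated_pairs(
    n: int,
    rho_target: float,
    seed: int = 0,
    group: str = "NA",
    meth_mean: float = 35.0,
    meth_sd: float = 5.0,
) -> pd.DataFrame:
    """Paired (methylation %, log2 expression) values with a target Spearman rho.

    Uses a Gaussian copula: the latent Pearson correlation is
    2·sin(π·rho_target/6), which yields Spearman correlation ``rho_target``
    for bivariate normals.  |rho_target| = 1 uses the exact co/antimonotone
    construction.  Methylation is mapped through a normal quantile centred at
    ``meth_mean`` and clipped to [0, 100].
    """
    if n < 5:
        raise ValueError(f"n must be >= 5, got {n}")
    if not -1 <= rho_target <= 1:
        raise ValueError(f"rho_target must be in [-1, 1], got {rho_target}")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    if abs(rho_target) == 1.0:
        z2 = np.sign(rho_target) * z1
    else:
        r = 2.0 * np.sin(np.pi * rho_target / 6.0)
        z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.normal(size=n)
    meth = np.clip(meth_mean + meth_sd * z1, 0.0, 100.0)
    log2_expr = z2  # log2 fold change scale, centred at 0
    return pd.DataFrame(
        {
            "sample_id": [f"{group}_{i:03d}" for i in range(n)],
            "group": group,
            "pct_m": meth,
            "log2_fc": log2_expr,
        }
    )
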
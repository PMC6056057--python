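"""COBRA band-intensity deconvolution of LINE-1 promoter methylation.

Combined bisulfite restriction analysis (COBRA) of the LINE-1 5'UTR amplicon
interrogates two CpG sites.  After bisulfite conversion and PCR, TaqI (TCGA)
cuts where the 3' CpG was methylated (the site survives conversion) and TasI
(AATT) cuts where the 5' CpG was unmethylated (conversion creates the site).
The four two-site methylation patterns of a molecule therefore leave distinct
fragment signatures on the gel:

    CmCu -> 160 bp (uncut)
    CuCu -> 98 + 62 bp (TasI cut)
    CmCm -> 80 + 80 bp (TaqI cut)
    CuCm -> 80 + 62 (+ an 18-bp runoff) (both cut)

Band intensities are proportional to (molar amount × fragment length), so the
percent intensity of each band divided by its length gives molar amounts

    A = %i160/160,  B = %i98/98,  C = %i80/80,  D = %i62/62

from which the overall methylation and the four pattern fractions follow:

    %Cm   = 100·(C+A) / (C+2A+B+D)
    T     = (C−D+B)/2 + A + D            (total molecules)
    %CmCu = 100·A/T          %CuCm = 100·(D−B)/T
    %CuCu = 100·B/T          %CmCm = 100·((C−D+B)/2)/T

The patterns sum to 100 and %Cm = %CmCm + (%CmCu+%CuCm)/2 identically.  Lanes
with D−B < 0 or C−D+B < 0 are chemically impossible under the two-site model
and are flagged infeasible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "BAND_LENGTHS",
    "BandIntensityRecord",
    "NormalizedBands",
    "MethylationProfile",
    "normalize_bands",
    "overall_methylation",
    "pattern_percentages",
    "quantify",
    "compare_groups",
    "AmpliconModel",
    "insilico_digest",
    "synthetic_amplicon",
    "read_amplicon_fasta",
]

#: gel band sizes in bp: uncut, TasI distal, TaqI half, TasI proximal
BAND_LENGTHS = (160, 98, 80, 62)

_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class BandIntensityRecord:
    """One gel lane: four band intensities in percent or arbitrary units."""

    sample_id: str
    group: str
    i160: float
    i98: float
    i80: float
    i62: float

    def __post_init__(self):
        vals = (self.i160, self.i98, self.i80, self.i62)
        if any(v < 0 for v in vals):
            raise ValueError(f"negative band intensity in lane {self.sample_id}")
        if sum(vals) <= 0:
            raise ValueError(f"all-zero band intensities in lane {self.sample_id}")


@dataclass(frozen=True)
class NormalizedBands:
    """Molar band amounts A..D (percent intensity divided by fragment length)."""

    A: float
    B: float
    C: float
    D: float


@dataclass(frozen=True)
class MethylationProfile:
    """Overall %Cm plus the four two-site pattern percentages for one lane."""

    sample_id: str
    group: str
    pct_m: float
    pct_mm: float
    pct_mu: float
    pct_um: float
    pct_uu: float
    feasible: bool
    clamped: bool


def normalize_bands(rec: BandIntensityRecord) -> NormalizedBands:
    """Rescale intensities to sum to 100, then divide each by its band length.

    The rescaling makes the profile invariant to the densitometry export scale
    (raw units vs percent).
    """
    raw = np.array([rec.i160, rec.i98, rec.i80, rec.i62], dtype=float)
    pct = 100.0 * raw / raw.sum()
    a, b, c, d = pct / np.array(BAND_LENGTHS, dtype=float)
    return NormalizedBands(A=a, B=b, C=c, D=d)


def overall_methylation(b: NormalizedBands) -> float:
    """Overall percent methylation of the two CpG sites, %Cm."""
    denom = b.C + 2 * b.A + b.B + b.D
    if denom <= 0:
        raise ValueError("zero denominator in %Cm: no molar band signal")
    return 100.0 * (b.C + b.A) / denom


def pattern_percentages(
    b: NormalizedBands,
    negative_policy: str = "clamp",
    sample_id: str = "",
    group: str = "",
) -> MethylationProfile:
    """Deconvolve molar band amounts into the four pattern percentages.

    ``negative_policy='clamp'`` zeroes negative raw pattern values (arising
    from lanes inconsistent with the two-site model) and renormalises the rest
    to 100, setting ``clamped``; ``'propagate'`` keeps the raw values for QC.
    ``feasible`` is False whenever D−B or C−D+B is negative beyond tolerance.
    """
    if negative_policy not in ("clamp", "propagate"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    mm_amount = (b.C - b.D + b.B) / 2.0
    um_amount = b.D - b.B
    total = mm_amount + b.A + b.D  # = A + B + (D-B) + (C-D+B)/2
    if total <= 0:
        raise ValueError("non-positive molecule total; lane cannot be deconvolved")
    raw = {
        "mm": 100.0 * mm_amount / total,
        "mu": 100.0 * b.A / total,
        "um": 100.0 * um_amount / total,
        "uu": 100.0 * b.B / total,
    }
    feasible = um_amount >= -_FEAS_TOL and mm_amount >= -_FEAS_TOL
    clamped = False
    vals = raw
    if negative_policy == "clamp" and not feasible:
        clipped = {k: max(v, 0.0) for k, v in raw.items()}
        s = sum(clipped.values())
        vals = {k: 100.0 * v / s for k, v in clipped.items()}
        clamped = True
    pct_m = overall_methylation(b)
    return MethylationProfile(
        sample_id=sample_id,
        group=group,
        pct_m=pct_m,
        pct_mm=vals["mm"],
        pct_mu=vals["mu"],
        pct_um=vals["um"],
        pct_uu=vals["uu"],
        feasible=feasible,
        clamped=clamped,
    )


def quantify(bands: pd.DataFrame, negative_policy: str = "clamp") -> pd.DataFrame:
    """Per-sample methylation profiles from a band-intensity table.

    ``bands`` needs columns sample_id, group, i160, i98, i80, i62 (the CSV
    dialect written by the simulator).  Returns one row per lane with the
    profile fields.
    """
    rows = []
    for rec in bands.itertuples(index=False):
        record = BandIntensityRecord(
            sample_id=str(rec.sample_id),
            group=str(rec.group),
            i160=float(rec.i160),
            i98=float(rec.i98),
            i80=float(rec.i80),
            i62=float(rec.i62),
        )
        prof = pattern_percentages(
            normalize_bands(record),
            negative_policy=negative_policy,
            sample_id=record.sample_id,
            group=record.group,
        )
        rows.append(prof.__dict__)
    return pd.DataFrame(rows)


def compare_groups(
    profiles: pd.DataFrame,
    control_label: str,
    comparisons: list[str] | None = None,
    value: str = "pct_m",
    variance_mode: str = "pooled",
) -> pd.DataFrame:
    """Two-tailed t-tests of per-sample methylation against the control group.

    One test per case group (default: every non-control group present) on the
    ``value`` column, with Benjamini–Hochberg adjustment across the comparison
    family.  Groups with fewer than two samples are skipped with a warning.
    """
    ctrl = profiles.loc[profiles["group"] == control_label, value].to_numpy(float)
    if len(ctrl) < 2:
        raise ValueError(f"control group {control_label!r} has <2 samples")
    if comparisons is None:
        comparisons = sorted(g for g in profiles["group"].unique() if g != control_label)
    rows = []
    for grp in comparisons:
        case = profiles.loc[profiles["group"] == grp, value].to_numpy(float)
        if len(case) < 2:
            logger.warning("comparison %s vs %s skipped: <2 samples", grp, control_label)
            continue
        with warnings.catch_warnings():
            # identical-value groups trip scipy's precision warning; the
            # degenerate result is overridden below anyway
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(case, ctrl, equal_var=(variance_mode == "pooled"))
        if np.isnan(t):  # zero variance in both groups
            t, p = 0.0, 1.0
        rows.append(
            {
                "comparison": f"{grp} vs {control_label}",
                "group": grp,
                "n_case": len(case),
                "n_control": len(ctrl),
                "mean_case": case.mean(),
                "se_case": case.std(ddof=1) / np.sqrt(len(case)),
                "mean_control": ctrl.mean(),
                "se_control": ctrl.std(ddof=1) / np.sqrt(len(ctrl)),
                "t": float(t),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out = pd.DataFrame(
            columns=["comparison", "group", "n_case", "n_control", "mean_case",
                     "se_case", "mean_control", "se_control", "t", "p", "p_adj"]
        )
    return out


# ---------------------------------------------------------------------------
# In-silico bisulfite digestion of the amplicon
# ---------------------------------------------------------------------------

_TAQI = "TCGA"  # cuts T^CGA; site survives conversion iff its CpG was methylated
_TASI = "AATT"  # cuts ^AATT; site is created by conversion iff its CpG was unmethylated

_COMPLEMENT = str.maketrans("ACGTRYacgtry", "TGCAYRtgcayr")

#: IUPAC degenerate base expansions used for primer matching
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primer_site_match(primer: str, template: str) -> bool:
    """Does a bisulfite-PCR primer match a genomic template region?

    Degenerate primer bases match any of their expansions; a primer T also
    matches a template C (that cytosine reads as T after conversion).
    """
    if len(primer) != len(template):
        return False
    for pc, tc in zip(primer.upper(), template.upper()):
        allowed = _IUPAC.get(pc, pc)
        if tc in allowed:
            continue
        if tc == "C" and "T" in allowed:
            continue
        return False
    return True


@dataclass(frozen=True)
class AmpliconModel:
    """The 160-bp LINE-1 regulatory-region amplicon and its two informative CpGs.

    ``sequence`` is the genomic (unconverted) top strand of the amplified
    region.  ``tasi_cpg`` / ``taqi_cpg`` are 0-based offsets of the cytosines
    whose methylation state the TasI and TaqI digests report; the first letter
    of a pattern code (mm/mu/um/uu) refers to the 5' (TasI-reporting) CpG.
    """

    sequence: str
    primer_fwd: str
    primer_rev: str
    tasi_cpg: int
    taqi_cpg: int

    def __post_init__(self):
        n = len(self.sequence)
        for name, pos in (("tasi_cpg", self.tasi_cpg), ("taqi_cpg", self.taqi_cpg)):
            if not 0 < pos < n - 1:
                raise ValueError(f"{name}={pos} not strictly inside the amplicon")
            if self.sequence[pos : pos + 2].upper() != "CG":
                raise ValueError(f"{name}={pos} is not a CpG in the sequence")

    @classmethod
    def from_reference(
        cls, reference: str, primer_fwd: str, primer_rev: str
    ) -> "AmpliconModel":
        """Locate the amplicon on a genomic reference via the PCR primers.

        The forward primer is matched against the top strand (bisulfite-aware,
        IUPAC degeneracy honoured) and the reverse primer against the bottom
        strand, i.e. its reverse complement against the top strand.  The two
        informative CpGs are recognised by their genomic contexts: AATCG for
        the TasI-reporting site (conversion of an unmethylated CpG creates
        AATT) and TCGA for the TaqI-reporting site.
        """
        ref = reference.upper()
        fl = len(primer_fwd)
        rl = len(primer_rev)
        rev_on_top = _revcomp(primer_rev)
        fwd_hits = [
            i for i in range(len(ref) - fl + 1)
            if _primer_site_match(primer_fwd, ref[i : i + fl])
        ]
        rev_hits = [
            i for i in range(len(ref) - rl + 1)
            if _primer_site_match(rev_on_top, ref[i : i + rl])
        ]
        if not fwd_hits or not rev_hits:
            raise ValueError(
                "primers do not match the reference: "
                f"{len(fwd_hits)} forward hit(s), {len(rev_hits)} reverse hit(s)"
            )
        start = fwd_hits[0]
        downstream = [j + rl for j in rev_hits if j + rl > start + fl]
        if not downstream:
            raise ValueError(
                "reverse-primer site lies upstream of the forward-primer site"
            )
        end = max(downstream)
        amplicon = ref[start:end]
        tasi = amplicon.find("AATCG")
        taqi = amplicon.find("TCGA")
        if tasi < 0 or taqi < 0:
            raise ValueError(
                "could not locate the informative CpGs on the amplicon "
                f"(AATCG found: {tasi >= 0}, TCGA found: {taqi >= 0})"
            )
        return cls(
            sequence=amplicon,
            primer_fwd=primer_fwd,
            primer_rev=primer_rev,
            tasi_cpg=tasi + 3,
            taqi_cpg=taqi + 1,
        )

    def pcr_product(self, state: str) -> str:
        """Top strand of the PCR product for a two-site methylation state.

        Bisulfite conversion (top strand): every cytosine reads as T except a
        methylated CpG cytosine.  Only the two informative CpGs carry the
        lane's state; any other CpG is treated as unmethylated.  Primer
        sequences are incorporated verbatim at the ends (degenerate bases
        resolved against the template).
        """
        if state not in ("mm", "mu", "um", "uu"):
            raise ValueError(f"state must be one of mm/mu/um/uu, got {state!r}")
        keep = set()
        if state[0] == "m":
            keep.add(self.tasi_cpg)
        if state[1] == "m":
            keep.add(self.taqi_cpg)
        seq = self.sequence.upper()
        converted = [
            c if c != "C" or i in keep else "T" for i, c in enumerate(seq)
        ]
        # primers are physically part of the product
        for pos, primer in (
            (0, self.primer_fwd.upper()),
            (len(seq) - len(self.primer_rev), _revcomp(self.primer_rev.upper())),
        ):
            for k, pc in enumerate(primer):
                if pc in "ACGT":
                    converted[pos + k] = pc
        return "".join(converted)


def insilico_digest(model: AmpliconModel, state: str) -> list[int]:
    """Fragment lengths after TaqI + TasI digestion of the converted amplicon.

    TaqI cuts at every TCGA present in the product (T^CGA); TasI cuts at every
    AATT *created by conversion* (^AATT) — AATT already present in the genomic
    sequence is methylation-uninformative and ignored.  Returns sorted
    fragment lengths; they always sum to the amplicon length.
    """
    product = model.pcr_product(state)
    genomic = model.sequence.upper()
    n = len(product)
    cuts = set()
    for i in range(n - 3):
        if product[i : i + 4] == _TAQI:
            cuts.add(i + 1)  # T^CGA
        if product[i : i + 4] == _TASI and genomic[i : i + 4] != _TASI:
            cuts.add(i)  # ^AATT
    bounds = [0, *sorted(cuts), n]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


# forward primer / reverse primer of the LINE-1 regulatory-region assay
LINE1_PRIMER_FWD = "CCGTAAGGGGTTAGGGAGTTTTT"
LINE1_PRIMER_REV = "RTAAAACCCTCCRAACCAAATATAAA"


def synthetic_amplicon() -> AmpliconModel:
    """A synthetic 160-bp stand-in for the LINE-1 regulatory-region amplicon.

    This is not the GenBank M80343 sequence: it is a constructed genomic
    segment that reproduces the assay geometry implied by the band-composition
    algebra — the published primers verbatim at the ends, a TasI-reporting CpG
    whose conversion creates an AATT cut 62 bp from the 5' end, a
    TaqI-reporting TCGA cut 80 bp from the 5' end, and no other cut sites or
    CpGs in any methylation state.
    """
    fwd = LINE1_PRIMER_FWD
    rev_on_top = _revcomp(LINE1_PRIMER_REV).replace("Y", "T")
    n = 160
    seq = ["G"] * n
    seq[: len(fwd)] = fwd
    seq[n - len(rev_on_top):] = rev_on_top
    # filler that cannot form AATT or TCGA and contains no cytosines
    filler = "AGGT"
    for i in range(len(fwd), n - len(rev_on_top)):
        seq[i] = filler[i % 4]
    seq[61:67] = "GAATCG"  # TasI-reporting CpG: AATT created at 62..65, cut at 62
    seq[78:83] = "GTCGA"   # TaqI-reporting CpG: T^CGA cut at 80
    model = AmpliconModel.from_reference("".join(seq), fwd, LINE1_PRIMER_REV)
    # sanity: the synthetic construction must reproduce the four signatures
    assert len(model.sequence) == 160
    assert insilico_digest(model, "mu") == [160]
    assert insilico_digest(model, "mm") == [80, 80]
    assert insilico_digest(model, "uu") == [62, 98]
    assert insilico_digest(model, "um") == [18, 62, 80]
    return model


def read_amplicon_fasta(path, primer_fwd: str = LINE1_PRIMER_FWD,
                        primer_rev: str = LINE1_PRIMER_REV) -> AmpliconModel:
    """Build an AmpliconModel from the first record of a FASTA reference."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return AmpliconModel.from_reference(str(record.seq), primer_fwd, primer_rev)
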
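# Methods

## Scope and data model

The package implements two analysis tracks that share one statistical core.

**Enrichment track.**  Input is a genes/probes × samples matrix of log-scale
expression values with a sample→group map (case groups may be phenotypic
subgroups such as L/M/S, or one pooled case label), plus an insertion
annotation table mapping gene symbols to insertion types.  The output is a
per-study enrichment report: one row per insertion type × direction with the
2×2 table's overlap count, exact-test p, BH-adjusted p and overlap gene list,
plus a random-gene control summary and, across studies, the genes recurring
in at least two DEG lists.

**Methylation track.**  Input is a table of four gel band intensities per
lane (COBRA of the LINE-1 promoter amplicon), Ct tables for qPCR targets, and
group labels.  Output is per-lane methylation profiles, per-group comparisons
of overall methylation, per-sample 2^−ΔΔCt expression and per-group Spearman
correlations of methylation against log2 expression.

## Differential expression

Transcripts quantified in fewer than 70% of samples are removed before
testing (the boundary row with exactly 30% missing is retained).  Per gene, a
two-tailed two-sample t-test compares case and control values with pairwise
exclusion of missing cells; the pooled-variance (Student) form is the default
and Welch is available.  Degenerate genes — zero variance in both groups —
are assigned t = 0, p = 1 when the means agree, and p = 0 with a `degenerate`
flag when they differ; genes with fewer than two values in either group are
skipped and logged.

"Adjusted Bonferroni" correction is provided in two forms: classic
`min(1, m·p)` and the Holm step-down procedure.  Holm is the default because
it controls the same family-wise error rate while being uniformly no more
conservative.  A gene is a DEG when its adjusted p falls below α (default
0.05), and the up/down split follows the sign of the case-minus-control mean.
When probe-level IDs carry a probe→symbol map, the collapse rule is: a gene
is a DEG if at least one of its probes is, represented by its
smallest-adjusted-p probe; collapse happens after testing.

## Insertion gene sets and enrichment

Insertion records are gene-symbol based; symbols are whitespace-trimmed but
never alias-resolved — annotation-era symbol mismatches are surfaced by a
coverage report instead of silently remapped.  A gene joins a typed set with
one qualifying record and joins the union once.

The analysis universe is the set of genes surviving the missingness filter,
intersected into the annotation namespace, because the 2×2 cells must
partition a single population.  Fisher's exact test is computed from the
hypergeometric pmf: the two-sided p sums all point probabilities at most the
observed one (with the customary 1+1e−7 relative tolerance for ties), the
directional alternative is the upper tail of the overlap cell.  The default
is two-sided; the random-gene control uses the upper tail, since
over-representation is a one-sided question.  Within one study, all
comparisons (5 set × 3 direction rows) form a single BH family, mirroring a
per-study report table.  The sample odds ratio a·d/(b·c) is reported with an
infinity flag when b·c = 0.

The random-gene control draws `n_draws` (default 1000) gene lists of the same
size as the DEG list, uniformly without replacement from the universe, and
records each draw's upper-tail p; the observed p is summarised by its rank in
that draw distribution.  Draws are reproducible from a mandatory seed.

## COBRA deconvolution

Band intensities may arrive in percent or raw densitometry units; they are
first rescaled to sum to 100, making all downstream quantities scale
invariant, then divided by fragment lengths 160/98/80/62 to yield molar
amounts A–D.  The 62–63 bp doublet is treated as a single 62-bp class.  The
pattern formulas share the denominator T = (C−D+B)/2 + A + D, which equals
the total molecule count under the band-composition model
A = n_mu, B = n_uu, C = 2·n_mm + n_um, D = n_um + n_uu; this choice makes the
four patterns sum to 100 and satisfies %Cm = %CmCm + (%CmCu+%CuCm)/2 exactly.
Lanes with D − B < 0 or C − D + B < 0 cannot arise from non-negative pattern
counts and are flagged infeasible; the default `clamp` policy zeroes the
negative values and renormalises to 100 (flagging the lane), while
`propagate` keeps raw values for QC.

Group comparisons run on per-sample overall %Cm by default (any profile
column can be selected), one two-tailed t-test per case group against the
control group, BH-adjusted across the comparison family; groups with fewer
than two samples are skipped with a warning.

## In-silico digestion

The amplicon model carries the genomic top strand, the two PCR primers, and
the offsets of the two informative CpGs.  Bisulfite conversion reads every
cytosine as thymine except methylated CpG cytosines; primers are incorporated
verbatim into the product, as in real PCR.  TaqI cuts T^CGA at every site
present in the converted product; TasI cuts ^AATT only at sites *created* by
conversion (a genomic AATT carries no methylation information).  Locating the
informative CpGs uses their genomic contexts: TCGA for the TaqI-reporting
site and AATCG for the TasI-reporting site (conversion of the unmethylated
CpG turns AATCG into AATTG).  Fragment lengths always sum to the amplicon
length; the four states give the signatures 160 (mu), 80+80 (mm), 98+62 (uu)
and 80+62+18 (um) that the band-composition model assumes.

Because the analysis environment is self-contained, the package ships a
*synthetic* 160-bp amplicon (`synthetic_amplicon`, labelled as such) rather
than the real GenBank regulatory-region record: the published primers
verbatim at the ends, the TasI-reporting CpG placed so its conversion cut
falls 62 bp from the 5' end, the TaqI site cut at 80 bp, and a C-free,
site-free filler elsewhere.  It reproduces the assay geometry, not the native
sequence; `read_amplicon_fasta` accepts a real reference when one is
available.

## qPCR and correlation

Technical replicate Cts are averaged, ΔCt = Ct(target) − Ct(reference) per
sample, and ΔΔCt subtracts the control-group mean ΔCt.  The per-sample
variant is the default because per-sample expression values are what the
methylation–expression scatter requires; a group-mean variant returns the
single summary fold change.  Fold change = 2^−ΔΔCt and log2 fold change =
−ΔΔCt by construction.

Spearman correlation uses mid-ranks.  For n < 10 the two-sided p-value is
exact — the proportion of all n! rank pairings with |rho| at least the
observed — and the t-approximation with n−2 degrees of freedom is used
otherwise.  Zero rank variance leaves rho undefined and flagged rather than
silently zero.  Reported `rho_squared` is the square of Spearman's rho, not a
least-squares R².  Per-group correlations require at least five matched
samples; unmatched sample IDs are dropped with a log entry.

## Synthetic-data generators

All generators are deterministic functions of configuration plus seed.

- **Expression studies**: gene baselines ~ N(8, 1), i.i.d. Gaussian
  measurement noise (default SD 1, the scale of log2 microarray residuals),
  a `frac_deg` fraction of genes shifted by ±`effect_size` in cases, and
  missing cells completely at random.  Insertion labels are assigned with
  class probabilities solved (Brent's method) so the DEG-vs-insertion odds
  ratio equals `enrichment_odds` exactly in expectation while the overall
  insertion fraction stays at `frac_inserted`.  Defaults (10 000 genes, 2%
  DEGs, 25% inserted genes, 20+20 samples) mirror a genome-scale microarray
  study; calibration and power runs state their own smaller sizes.
- **Gel lanes**: molar band amounts composed from pattern counts as above;
  optical intensity is molar amount × fragment length (longer fragments bind
  proportionally more stain), normalised to 100, then multiplied by
  (1 + ε), ε ~ N(0, noise_sd), clipped at zero and renormalised —
  densitometry noise is relative, hence multiplicative.  The study-level
  generator draws each sample's %Cm from a normal around its group mean
  (between-sample SD 4 by default, matching reported group SEs of 1–2 at
  n≈10) and methylates the two CpG sites independently at that marginal rate.
- **Ct tables**: control target Ct fixed at `base_ct`, case target Ct =
  base_ct − log2(fold change), constant reference Ct, optional Gaussian Ct
  noise; the ΔΔCt method inverts this exactly at zero noise.
- **Correlated pairs**: a Gaussian copula with latent Pearson correlation
  2·sin(π·ρ/6), which yields Spearman correlation ρ for bivariate normals;
  |ρ| = 1 uses the exact co/antimonotone construction.  Methylation is a
  normal quantile map clipped to [0, 100].

What the generators do *not* emulate: probe-level microarray physics, batch
or platform effects, correlated gene-gene structure, gel smile/background
artefacts, or PCR amplification bias.  Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
stated generative assumptions, not robustness to those real-data artefacts.

## Numerical choices

- Missingness boundary uses a 1e−9 tolerance so 7/10 present passes a 0.7
  threshold despite float rounding.
- Feasibility tolerance for pattern deconvolution is 1e−9 on the molar scale.
- Exact-test p-values are clipped to [0, 1]; hypergeometric pmf vectors are
  cached per margin triple for the enumeration-scale workloads.
- Deterministic orderings everywhere (mergesort ties broken by gene ID);
  CSV floats written with a fixed %.10g format so reruns are byte-identical.
- Monte-Carlo problem sizes: calibration uses 500 studies of 300 genes ×
  8+8 samples; power uses 200 replicates of 2000 genes at 2% DEGs.

## Known limitations

- The two-site COBRA model cannot represent partial digestion or
  heteroduplex artefacts; such lanes surface as infeasible rather than being
  corrected (no PCR-bias correction is applied).
- Gene-symbol identity is string-based; cross-era annotation drift must be
  handled upstream or read off the coverage report.
- The enrichment analysis does not correct for gene length or GC content,
  both of which correlate with insertion probability in real genomes.
- The exact Spearman p enumerates n! pairings and is therefore capped at
  n < 10; larger samples use the t-approximation.
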
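# Methods

This note records the statistical model behind `genofabric`, the choices
made where the method's description leaves the definition open, what the
synthetic-data generator does and does not emulate, and the known
limitations. Notation: phenotypes P, Q; 4 biological replicas ξ per
phenotype; gene *i* probed by *R*ᵢ ∈ 1..13 redundant spots; aᵢ,ₖ,ξ the
normalized expression of spot *k* on replica ξ.

## Preprocessing

**Filter.** A spot survives only if it is flagged uncorrupted *and* its
foreground is at least twice its background in *every* profiled sample
(the "in any sample" rejection rule makes the filter strict: with 12
samples and a 1% per-sample corruption rate, about 11% of spots fall).
A gene survives if at least one of its spots does. Control spots (empty
gene symbol) are parsed but excluded from all downstream statistics.

**Background subtraction.** Foreground minus background precedes
normalization. The filter guarantees fg ≥ 2·bg on kept spots, so
subtracted intensities stay positive except in the degenerate fg = bg = 0
case; such spots are *re-rejected and reported*, never clipped.

**Normalization.** Intensities are normalized iteratively to the
expression level of the median gene. Because each Cy3/Cy5 channel is an
independent biological sample in this design, the intra-array (between
channels) and inter-array (between arrays) alignments collapse into a
single operation: each sample is divided by the spot-averaged expression
of its median gene (lower median; ties broken by lower index). The *error
of estimate* is the largest relative deviation of any sample's scaling
factor from unity, in percent; iteration stops below `tol` (default 5%).
On well-behaved data this converges in two iterations (the second pass
verifies the factors are exactly 1); an already-normalized input is a
fixed point. Finally each phenotype's tensor is divided by the median of
the per-gene AVEs, so the unit of expression is exactly the median gene's
AVE in that phenotype (median over genes of AVE = 1 to machine precision).
The whole procedure is exactly invariant under multiplying any input
sample by a positive constant.

A consequence worth knowing: the median-gene reference is only as stable
as the assumption that regulation is sparse. Planting 4× fold-changes in
10% of a 2,000-gene universe shifts the reference enough to bias every
estimated ratio low by ~10%; at the realistic study scale (~17,000 genes,
~1% regulated) the bias is negligible. The recovery checks therefore run
at study scale.

## Single-gene quantifiers

- `AVE_i = (1/R_i) Σ_k μ_{i,k}` with μᵢ,ₖ the replica mean of spot *k*.
- `REV_i = ½(r/χ²(r;0.975) + r/χ²(r;0.025)) · sqrt((1/R_i) Σ_k (s_ik/μ_ik)²) · 100%`
  with `r = 4R_i − 1` and sᵢ,ₖ the replica SD (ddof = 1). The chi-square
  quantile convention is fixed by requiring the correction factor to
  exceed 1 (it is 7.11 at r = 3, 1.015 at r = 399, → 1 as r → ∞): the
  first term uses the lower 2.5% quantile, the second the upper. A zero
  spot mean makes the CV undefined and raises an error naming the gene;
  zero within-spot variance gives REV = 0.

## Coordination

COR is the Pearson coefficient of *spot-centered* deviations
`d_{i,k,ξ} = a_{i,k,ξ} − μ_{i,k}`. Centering removes the spot-specific
technical bias, so COR measures co-variation across biological replicas.

- **Equal redundancy (R_a = R_b = R):** deviations are correlated over all
  R·4 spot-by-replica observations with spots paired by index. The
  significance cutoff is the two-tailed critical Pearson value at
  `df = 4R − 2`, reproducing the standard critical-value ladder 0.95 / 0.707 / … /
  0.273 for R = 1 / 2 / … / 13.
- **Unequal redundancy:** the correlation runs over the per-replica
  spot-averaged deviations — four paired observations that, being
  centered, carry the classical Pearson null with `df = 4 − 2 = 2`, so
  the cutoff is 0.95. (Using a cutoff for a larger df on these four-point
  correlations would inflate the type-I rate of the affected pairs to
  ~30%; the replica-level df keeps the whole mixed-redundancy universe
  calibrated at the nominal 5%, which the null-simulation checks
  confirm.)
- Classification: synergistic if COR > cutoff, antagonistic if
  COR < −cutoff, independent if |COR| < 0.025 (band configurable; its
  distributional rationale is not derivable from any standard α at these
  df, so it is applied as given), otherwise not significant.
- A zero-variance gene yields undefined correlations; such pairs are
  flagged and excluded from counts and networks rather than propagated
  as NaN.

For large universes the analysis object produces the correlation matrix
in row blocks and retains only per-gene aggregates (Σ COR² for GCH, class
counts), so the 17,000-gene all-pairs pass never materializes a dense
matrix; small-scale tests use the exact dense matrix.

## Regulation

The expression ratio is `x = AVE(P)/AVE(Q)` when P ≥ Q, else
`−AVE(Q)/AVE(P)` (so |x| ≥ 1 and the sign carries the direction). The
significance criterion is the conjunction `|x| > CUT` and Welch p < α
(default 0.05), with `CUT = 1 + (1/100)·sqrt(2(REV_P² + REV_Q²))` — at
REV = 50% in both phenotypes a gene must double. The Welch test is run on
the per-replica spot-averaged expressions (4 vs 4): spots are technical
pseudo-replicates, replicas are the biological unit. When both samples
are identical constants the test is undefined and p is set to 1 (no
evidence of difference; WIR is then 0 anyway since x = 1).

`WIR = AVE(Q)·sign(x)·(|x| − 1)·(1 − p)` uses the same uncapped Welch p.
`WPR = (1/Card Γ) Σ WIR²` over the *quantified* genes of pathway Γ; genes
absent from one phenotype are flagged and excluded, and a pathway with no
quantified genes is an error, not a zero. Percentages of up-/down-
regulated genes use the significance flags over the same denominator. No
multiple-testing correction is applied anywhere — conservatism comes from
CUT, and the pair universe for coordination is likewise uncorrected. The
"uniform" ±1 measure is emitted as a derived column of the regulation
table.

## Gene hierarchy

`GCH_i = (⟨REV⟩/REV_i) · exp((4/N)·Σ_{j≠i} COR_ij² − 1)` over the whole
quantified universe of N genes, with ⟨REV⟩ the arithmetic mean REV
(median available as an option). The exponent normalization is chosen so
the term is O(1): with 4 replicas the null expectation of COR² is ≈ 1/3,
putting an average, uncoordinated gene near `e^{1/3−1}·1`. Genes with
REV = 0 would score infinite control; they are reported separately
instead of entering the ranking. Ranking is by descending GCH with ties
broken lexicographically; rank 1 is the GMR. GCH depends only on REV
ratios and correlations, so it is exactly invariant under global
rescaling of expression.

## Interaction consistency

Activator/activated partners of a center block are expected synergistic,
inhibitor/inhibited antagonistic. A pair *contradicts* its annotation
only when its coordination is significant and of the opposite sign;
independent, not-significant, undefined or missing pairs are unresolved.
Per-role counts of synergistic/antagonistic/independent pairs summarize
each partner group.

## Synthetic-data generator

Foreground of gene i, spot k, replica ξ, phenotype P:

    fg = bg_level + L_i · F_{i,P} · exp(b_{i,k}) · exp(ε_{i,ξ,P} + λ_i·z_{ξ,P,m})

with L_i ~ lognormal baseline, F the planted fold factor (1 if none),
b ~ N(0, spot_bias_sd) a spot bias shared across samples, ε ~ N(0, σᵢ)
with σᵢ matched to the gene's target CV (σ = sqrt(log(1+CV²))), and z a
per-replica standard-normal latent shared by the genes of a coordination
module (loading ±1 × latent_sd). The background column is bg_level with
2% multiplicative jitter; spots are flagged corrupted independently per
(spot, sample). One seed drives eight named substreams, so output is
byte-identical across runs.

Defaults, chosen once to resemble a mammalian-brain array experiment:
3 phenotypes × 4 replicas; redundancy distribution over 1..13 with 70%
single-spot genes; baseline lognormal(log 1000, 1.0) over a background of
50 fluorescence units (≈1% of genes fall below the 2·bg filter);
per-gene CV uniform in 2–40% (the empirical REV distribution of the
original experiment is not recoverable, so this range is a documented
free choice); spot bias SD 0.10; corruption rate 1% per spot-sample.

What the generator emulates: the replicate/redundancy design, scale-
proportional biological noise, spot-level technical bias, the background
filter regime, sparse planted regulation, and replica-level coordination
(the latent factor acts per replica, matching what COR measures). What it
does not: dye-swap bias, spatial array artifacts, probe-sequence effects,
heavy-tailed outliers, and correlated corruption. Passing recovery tests
therefore show the estimators are correct under the model's own
assumptions, not that real arrays are free of those artifacts.

One structural limit worth stating: because expression is log-normal,
an antagonistic module pair (opposite loadings ±λ) has raw-scale
correlation bounded by −e^{−λ²} — a strong latent factor (λ = 1) cannot
push COR below ≈ −0.37 in expectation even with zero noise. Synergistic
coordination has no such cap, so the pairwise-recovery checks use
same-sign modules; antagonism is exercised through direct antiphase
constructions in the unit tests.

## Problem sizes used in the checks

Type-I calibration runs on a 1,000-gene null simulation (≈ 420,000 gene
pairs); fold recovery plants 200 genes at 4×/10% CV in a 17,000-gene
universe; module recovery uses three 10-gene synergistic modules
(latent_sd = 1.0, CV 1–3%) among 300 genes. All are regenerated from
seeds at run time; the full suite and the acceptance script each complete
in seconds.

## Known limitations

- Correlation estimates from 4 replicas are extremely noisy; the 0.95
  single-spot cutoff controls the type-I rate but power for true
  |ρ| < 0.99 is poor. This is intrinsic to the design, not the code.
- The REV chi-square correction is large at r = 3 (×7.11), so REV and CUT
  are dominated by the small-sample correction for single-spot genes.
- Same-redundancy pairs with R ≥ 2 use the df = 4R − 2 cutoffs;
  the spot-centered deviations actually carry 3R free dimensions, so
  those pairs run marginally anti-conservative (≈7.6% at R = 2). They are
  a small minority of pairs and the universe-level calibration stays
  within the nominal band; the standard ladder is kept as-is.
- Re-analysis of the original deposited dataset is expected to diverge
  slightly wherever the method's description is silent: whether
  background was subtracted, whether channels or arrays were the
  normalization unit, and whether the Welch test used spot- or
  replica-level observations.
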
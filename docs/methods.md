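# Methods

This note documents the models, parameter choices and numerical details
behind `uprflow`, and what the synthetic-data generators do and do not
emulate.

## Probe summarization

Perfect-match probe intensities are modelled on the log2 scale as
`log2 x_pa = θ_gc + φ_p + ε`, with a gene/condition mean, a probe
affinity and i.i.d. Gaussian noise — the additive structure that median
polish assumes. Processing follows the RMA recipe:

1. **Background correction** (off by default) assumes observed intensity
   X = S + B with exponential signal S (mean α) and Gaussian background
   B (μ_bg, σ). The corrected value is the exact posterior mean
   E[S|X=x] = a + σ·φ(a/σ)/Φ(a/σ), a = x − μ_bg − σ²/α — the mean of a
   normal truncated to S > 0, hence always positive. The φ/Φ ratio is
   evaluated through log-densities so deep left-tail inputs do not
   underflow. When parameters are not supplied they are estimated per
   array by a histogram-mode method of moments: μ_bg = intensity mode,
   σ = RMS of sub-mode deviations (half-normal), α = mean excess above
   the mode. This is simpler than RMA's kernel estimator and adequate
   for the additive-Gaussian backgrounds the generator produces. It is
   off by default because the default synthetic model has no additive
   background.
2. **Quantile normalization** replaces each column by the across-array
   mean of sorted columns at its ranks. Ties receive the mean of the
   reference values their rank span covers, which makes the map well
   defined and idempotent on tie-free data. Note a structural
   consequence of this definition: rescaling one array leaves every
   rank order intact but shifts the shared reference by that array's
   contribution, so other columns move by (f−1)·sorted_j/A at matching
   ranks — they are not bitwise invariant.
3. **Median polish** per probeset alternates row- and column-median
   sweeps (rows first), stopping when the sum of absolute residuals
   changes by less than tol = 0.01 relative (max 10 sweeps) — the
   classical algorithm with R's `medpolish` defaults, against which it
   is tested to 1e-8. Expression on array a is `overall + col_a`.
   Even-count medians are the mean of the central pair. Probe count per
   probeset is configurable (default 11, a typical expression-array
   density; the original proprietary chip layout is not public).

Replicate reproducibility is the coefficient of variation on the
anti-logged scale (sample SD / mean across replicate arrays), averaged
unweighted over genes.

## Differential expression

All four conditions are fit jointly as a one-way layout: per-condition
means and a pooled residual variance s_g² on d_g = arrays − conditions
(8 by default) degrees of freedom; for this design that is exactly the
group-means linear model used by limma. The hierarchical model places a
scaled inverse-chi-square prior (d0, s0²) on the gene variances,
estimated by the method of moments on z = ln s_g²:
`trigamma(d0/2) = var(z) − trigamma(d_g/2)` (Newton with bisection
fallback, tolerance 1e-10, d0 capped at 1e7 as the numerical ∞), then
`ln s0² = mean(z) − digamma(d_g/2) + digamma(d0/2) − ln(d0/d_g)`. When
var(z) does not exceed the chi-square sampling noise the prior df is
infinite and s0² is the arithmetic mean of the variances (the natural
exchangeable-variance estimate; also what limma returns in this case).
The full route — fit, prior, moderated t, p — is tested to 1e-8 against
limma's `lmFit`/`eBayes` on a heteroscedastic fixture.

The moderated t for a contrast A−B is
`t = (mean_A − mean_B)/√(s̃²(1/n_A + 1/n_B))` with
`s̃² = (d0 s0² + d_g s_g²)/(d0 + d_g)`, two-sided p from Student t on
d0 + d_g df (standard normal at infinite d0). Genes with zero posterior
variance are flagged degenerate — p is undefined there, reported as NaN,
never 0 — and excluded from FDR and from downstream gene sets. Zero
sample variances enter prior estimation through a 1e-8 floor on the log
scale to avoid −∞.

Discoveries: BH step-up q-values (via statsmodels) with calls at
q < 0.005 strictly; no fold-change filter. Fold changes are reported on
the linear scale with the minus convention (−2 means halved), so their
magnitude is never below 1.

## Motif enrichment

The UPRE consensus is parsed from either plain IUPAC or the alternation
notation used in the UPR literature: `(G/A)` groups and bare `X/Y`
slashes denote single-position alternatives, so `CAN(G/A)NTGT/GCCT`
canonicalizes to the 11-mer `CANRNTGKCCT`. The motif is a parameter
everywhere, so an alternative reading of the notation can be supplied.

Upstream windows (default 400 bp) are anchored at the annotated coding
start: for plus-strand genes the window immediately 5' of `start`, for
minus-strand genes the reverse complement of the window just past `end`,
so sequences always read 5'→3' toward the start codon. Contig edges
truncate the window (flagged), and zero-length windows drop the gene
with a warning — mirroring the retrieval loss seen in real annotation.

Scanning tests every offset for per-position membership in the allowed
base sets; `N` in a sequence matches nothing (conservative). Both
strands are scanned by default — UPR elements are palindromic and the
original strand choice is unstated — by matching the reverse-complement
pattern against the stored sequence. The scanner is exhaustively checked
against a per-offset brute-force oracle. Enrichment contrasts the study
set against all remaining genes with retrievable promoters in a 2×2
table; the one-sided p is the hypergeometric upper tail P(X ≥ a)
computed in log space (scipy), verified against exhaustive enumeration
for small tables. Degenerate column margins (all or no genes positive)
are allowed and give p = 1; only an empty study row is an error.

## GO enrichment

Annotations obey the true-path rule: `propagated(gene)` is the direct
terms plus all ancestors, computed with per-term closure caching on the
child→parent DAG (is_a and part_of merged; validated acyclic with a
single root). The tested universe is the set of terms carrying at least
one study gene — untestable terms are excluded before BH — and the
population is the annotated genes only, since unannotated genes cannot
contribute to either margin. Both choices are configurable facts of the
implementation rather than of the original web tool, whose internals are
not restated here. The enriched-term network draws an edge u→v exactly
when v is an enriched ancestor of u with no enriched term between them
(transitive reduction restricted to the enriched set).

## Growth kinetics

During balanced growth X(t) = x0·e^(μt), so μ is the OLS slope of ln X
vs t with its standard error and R². The alkali route uses the
**addition rate**: cumulative titrant tracks biomass formed
(A = k·(X − x0)), so ΔA/Δt ∝ dX/dt ∝ e^(μt) and ln of the
finite-difference rate at interval midpoints is exactly linear with
slope μ on a uniform grid, while any baseline cancels in the
differencing. (Regressing ln of *cumulative* alkali would be biased by
the −k·x0 offset, which is why the rate form is used.) Non-positive
rates are dropped before the log.

The exponential→linear shift is located by grid search over interior
observation times: log-OLS exponential before the candidate, a straight
line after it anchored at the exponential's value there (continuity),
scored by total SSE on the original scale. The two-phase model is
accepted only if it beats the single exponential's SSE by more than 10%
with at least 4 points per phase — a guard against fitting noise; below
that margin the culture is called pure-exponential. The pre-phase fit is
log-OLS (not original-scale least squares), which is the standard
practice for rate estimation and exact on noiseless data.

Yield on substrate is Y_xs = ΔX/(−ΔS) over a window (default: lag end to
t_break), with biomass and glucose linearly interpolated to the window
endpoints and broth density taken as 1 kg/L so g_DW·kg⁻¹ and g·L⁻¹ are
commensurate.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure of the study — the
3 replicate × 4 condition layout, planted log2 effects consistent across
the three CA conditions, probe affinities zero-centred per probeset,
composition-random promoters with exact planted motif instances, a
layered single-rooted GO DAG with one odds-boosted term, and two-phase
culture curves with multiplicative lognormal noise (applied to alkali
*increments* so the cumulative trace stays monotone). Default sizes and
levels are the study's conditions where stated: 12 arrays, 11 probes per
probeset, 400-bp promoters, μ = 0.22 h⁻¹, break at 21 h (the time at
which half of the default 7.5 g/L glucose is consumed given
x0 = 0.02 g/kg and Y_xs = 0.53), q-thresholds 0.005/0.05. The probe-level
noise SD defaults to 0.62 log2 units, calibrated once by Monte Carlo so
the summarized triplicate CV lands mid-way in the study's reported
0.12–0.14 band. Where the study states no value, defaults are ordinary
for the field: baseline log2 means Uniform(6,12), probe-affinity SD 0.5,
GC content 0.5, alkali 8 mmol per g biomass, culture noise CV 3%.

Not emulated: probe-sequence-dependent affinities, spatial artifacts or
saturation; promoter grammar beyond i.i.d. composition; annotation bias
or term co-occurrence structure in GO; lag phases, CO₂ balancing or
morphology in the cultures. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
robustness to every artifact of real chips or reactors.

## Problem sizes in the test suite

The suite and the reproduction script run desk-scale versions of each
simulation — a few hundred to a thousand genes, 5–11 probes, 5–20 seeds,
20 000 genes for the variance-prior recovery — sizes chosen so the whole
battery completes in seconds while keeping every statistical check
well-powered (recall and FDR are pooled over 10 seeds × 3 contrasts;
uniformity is assessed per seed by Kolmogorov–Smirnov at α = 0.01).

## Known limitations

- The exact one-sided Fisher tail on the study's printed UPRE table
  (47/598 vs 457/13156) is 6.44×10⁻⁷; the study prints p ≤ 5.4×10⁻⁷.
  The discrepancy is inherent to the printed counts (R's `fisher.test`
  agrees with this package to all digits) and presumably reflects
  internal counts or a different tail convention in the original
  analysis.
- Background-parameter estimation is a histogram-mode method of moments,
  not RMA's kernel-density estimator; fine for synthetic Gaussian
  backgrounds, cruder on real scanner distributions.
- The breakpoint search evaluates candidate breaks only at observation
  times; resolution is the sampling interval.
- Pairwise contrasts other than vs-WT reuse the same pooled residual
  variance (the one-way model's), a documented choice where the original
  analysis is silent.
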
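# uprflow

Analysis toolkit for microarray studies of the fungal **unfolded protein
response** (UPR) — the transcriptional program driven by the bZIP factor
HacA when misfolded proteins accumulate in the ER. It re-implements, as a
tested and reusable pipeline, the computational analysis of a
constitutively-active-HacA (HacA^CA) vs wild-type (HacA^WT) transcriptome
experiment in *Aspergillus niger*: 12 arrays covering triplicates of four
conditions (WT and three CA timepoints), moderated-t differential
expression, promoter-motif and GO enrichment, and bioreactor growth
kinetics. A synthetic-data module generates every input with known planted
truth, so each stage can be validated end to end without the original
arrays.

## What it computes

- **Probe summarization** (`uprflow.summarize`) — RMA-style processing of
  perfect-match probe intensities: normal+exponential background
  correction `E[S|X=x] = a + σ·φ(a/σ)/Φ(a/σ)` with `a = x − μ_bg − σ²/α`,
  quantile normalization to the mean sorted profile, and Tukey
  median-polish summarization of `log2 x_pa ≈ μ + row_p + col_a` per
  probeset. Replicate reproducibility is reported as the linear-scale CV.
- **Differential expression** (`uprflow.de`) — one-way group-means fit,
  pooled residual variance `s_g²` on `d_g = 12 − 4 = 8` df, empirical-Bayes
  prior `(d0, s0²)` estimated by the method of moments on `ln s_g²`
  (trigamma inversion, as in limma), moderated t
  `t_g = Δ/√(s̃²(1/n_A+1/n_B))` with `s̃² = (d0·s0² + d_g·s_g²)/(d0+d_g)`
  on `d0 + d_g` df, Benjamini–Hochberg FDR at `q < 0.005`, and the signed
  linear fold-change convention (2-fold down prints as −2). No minimal
  fold-change filter is applied.
- **Set consistency** (`uprflow.sets`) — Venn partitioning of 2–3 gene
  sets and the genes called up (down) at *every* timepoint.
- **UPRE motif enrichment** (`uprflow.motif`) — the degenerate UPRE
  consensus `5'-CAN(G/A)NTGT/GCCT-3'` (IUPAC `CANRNTGKCCT`) scanned on
  both strands of 400-bp upstream windows, with a one-sided Fisher's
  exact test of study-set over-representation.
- **GO enrichment** (`uprflow.go`) — true-path propagation of gene
  annotations up the GO DAG, per-term one-sided Fisher tests at BH
  `q < 0.05`, and a network of enriched terms (transitive reduction of
  the ancestor relation).
- **Growth kinetics** (`uprflow.kinetics`) — μ as the OLS slope of
  ln(biomass) vs time (or of log alkali-addition rates), grid-search
  detection of the exponential→linear phase shift with a continuity
  constraint, and the biomass yield on glucose
  `Y_xs = ΔX/(−ΔS)`.
- **Synthetic data** (`uprflow.simulate`) — generators for all of the
  above with planted ground truth recorded in a `SimTruth`.

## Worked example

`python examples/04_upre_enrichment.py` prints:

```
UPRE consensus CANRNTGKCCT (11 bp), reverse complement AGGMCANYNTG
printed contingency: p = 6.44e-07, odds ratio = 2.37
-> UPRE-positive promoters are ~2.4-fold over-represented among
   up-regulated genes (the study prints p <= 5.4e-7 for this table)
synthetic round trip: 50/100 study genes motif-positive, p = 6.74e-40
-> every planted 400-bp promoter instance is found on either strand
```

The first block is the study's printed 2×2 table (47 of 598 up-regulated
vs 457 of 13156 remaining genes with a UPRE within 400 bp upstream): the
exact one-sided tail is 6.4×10⁻⁷ — enrichment of the HacA binding element
among induced genes. The second block is a full synthetic round trip:
all 50 planted promoter instances are rediscovered and the study set is
overwhelmingly enriched. The other `examples/` scripts walk through
summarization (mean replicate CV ≈ 0.13), DE calling (4-fold planted
effects recovered at q<0.005), timepoint consistency, GO enrichment (the
boosted term ranks first), and kinetics (μ = 0.220 ± 0.001 h⁻¹, break at
21 h, Y_xs = 0.53).

A thin CLI mirrors the library:

```bash
uprflow demo --out-dir demo_run --seed 42      # all-synthetic end-to-end run
uprflow kinetics --culture demo_run/inputs/culture.csv
uprflow upre-scan --promoters promoters.fasta --study up_all.txt
```

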
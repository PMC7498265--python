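# Methods

## The generative model

One cassette exon per gene. For gene g in cell i the simulator draws:

- transcript count `X_ig` from a two-state bursting stand-in: burst
  fraction B ~ Beta(k_on, k_off), count X ~ Poisson(scale · B). The
  per-gene mean is scale·k_on/(k_on+k_off); dispersion grows as k_on
  shrinks. Default hyper-priors: k_on ~ LogNormal(ln 0.5, 1), k_off ~
  LogNormal(ln 1, 1), scale ~ LogNormal(ln 50, 1.5). This reproduces the
  mean/variance/bursting behavior that matters downstream (the observation
  distortion depends on the count distribution's dispersion, not on any
  particular expression simulator's internals).
- splicing rate `Ψ_ij ~ Beta(α_j, β_j)`, independent across cells. Regime
  laws for (α, β): bimodal — both 1/Uniform(1, 30); unimodal — both
  Uniform(1, 30); constitutively included — Uniform(1, 30) and
  1/Uniform(1, 5); constitutively excluded — mirrored. The mean splicing
  rate is α/(α+β).
- isoform molecule counts `XA_ij ~ Binomial(X_ig, Ψ_ij)`, `XB = X − XA`;
  the realized inclusion fraction `Ψ^T = XA/X` is undefined (missing) when
  X = 0. Overrides exist for a constant Ψ (the expression sweep) and for
  pinning XA = XB = X/2 exactly (the capture sweep; expression is rounded
  down to even).

Technical stage, per cell × isoform:

- capture probability from a normal with mean c and variance 0.002
  truncated to [0, 1]; captured molecules Binomial(X_I, c_I). The
  truncated distribution's *mean* is kept equal to the nominal c by
  solving for the location parameter — with c = 0.025 and sd ≈ 0.045 a
  naive location parameterization would deliver ≈0.047 realized capture
  and silently compress any capture sweep.
- reads `R_I ~ Poisson(C_I · depth_factor · l_I/1000 · bias(l_I))`, with
  an optional exponential length bias `bias(l) = 2^(−l/halflength)`
  normalized at the median length (disabled by default). Defaults
  (read length 50 nt, depth_factor 5 reads per molecule per kb) give
  per-exon junction coverage spanning roughly 0–30 reads, typical of
  full-length single-cell data.
- junction reads `SJA ~ Binomial(RA, 4(l_r−1)/l_A)` and
  `SJB ~ Binomial(RB, 2(l_r−1)/l_B)`: a read can start at 2(l_r−1)
  positions overlapping one junction, and the inclusion isoform carries
  two informative junctions. Isoform lengths come from clipped log-normal
  stand-ins matching human transcript and skipped-exon scales
  (exclusion isoform LogNormal(ln 1900, 0.6) on [200, 20000] nt; exon
  LogNormal(ln 120, 0.5) on [25, 2000] nt); external length tables can be
  supplied instead.

### Junction weighting

Two estimators of the observed splicing rate coexist:

- `simulated`: Ψ̂ = SJA/(SJA+SJB). Because inclusion molecules emit twice
  the informative reads, this converges to 2Ψ/(1+Ψ) — inclusion-biased.
- `halved_exclusion`: Ψ̂ = SJA/(SJA+2·SJB), the estimator used on real
  junction tables, which puts both isoforms on the same per-molecule
  footing and is consistent at high coverage.

The simulator's default is `simulated` (its native definition); the
quantification module and all bias-sensitive analyses use
`halved_exclusion`. Binary status (Ψ̂ exactly 0 or 1) is identical under
both. Note that even the corrected estimator is mean-biased upward at very
low coverage: an observation carrying a single informative read is Ψ̂ = 1
with probability 2Ψ/(1+Ψ), and no estimator supported on {0, 1} can be
mean-unbiased there. At 10% capture this floors the pooled
|mean(Ψ̂) − mean(Ψ)| of intermediate exons near 0.05.

Observations with zero informative reads are missing: they enter neither
the numerator nor the denominator of any binary proportion or average.

## Closed-form observation theory

With m transcripts, mΨ of them inclusion, and r captured uniformly without
replacement, Ψ̂ = a/r is hypergeometric. Marginalizing the unknown m under
a uniform prior uses Pr(m | r, c) = C(m, r) c^(r+1) (1−c)^(m−r) (a shifted
negative binomial; the normalizing constant of the binomial likelihood is
exactly 1/c, exposed as a checkable numeric identity). The marginal sum is
truncated at ⌈10·r/c⌉ — ten times the posterior mean — and extended
automatically while the posterior tail mass exceeds 1e−9, so pmfs sum to 1
to ≤1e−6. Conditioning on detection (r > 0) instead marginalizes r from 1
to m with binomial capture weights, normalized by 1 − (1−c)^m; Ψ̂ values
arising from different r are pooled exactly as rationals before
conversion to floats.

Non-integer mΨ inside marginal sums is rounded to the nearest integer
(banker's rounding); the exact single-(m, r) form refuses non-integer mΨ
unless rounding is explicitly requested. Binomial coefficients are
computed in log space via log-gamma, stable to m ~ 1e5.

## Census-style mRNA counts

For each cell, the mode x* of a Gaussian kernel density (Scott's rule,
512-point grid) over log TPM of genes above 0.1 TPM locates the
single-copy expression level. With F the right-continuous empirical CDF of
the cell's *detected* (nonzero) TPM values and n_i the number of genes in
(0.1, x*] (configurable to the open interval), the captured-mRNA total is
M_i = n_i / (F(x*) − F(0.1)), and per-gene counts follow Y_ig = X_ig ·
M_i / 1e6. No capture-efficiency division is applied: M_i estimates mRNAs
captured into cDNA, not mRNAs in the lysate. Defining F over the detected
values makes the toy example (TPM = 0.05, 1, 2, 2, 2, 3, 8 → x* ≈ 2,
n = 4, F-gap = 4/7, M = 7) exact and keeps M_i cell-dependent; defining it
over all matrix columns would collapse M_i to a constant. M_i is
essentially the number of detected genes, which approximates captured
molecules precisely when the modal detected gene carries about one
captured copy — true of real transcriptomes and of the synthetic cohorts
(see below). Cells with degenerate TPM distributions, or with M_i more
than ten-fold above the cohort median, are flagged and excluded; an
optional bottom-read-quantile pre-filter is off by default.

## Coverage rate and the combined filter

The per-cell junction coverage rate C_j = Σ_k r_jk / Σ_k j_k·m_jk pools
constitutive-junction reads over genes with at least one estimated mRNA.
An observation of exon i in cell j passes the filter iff m_ij ≥ 10 and
SJ_ij ≥ 10·(1+Ψ̂_ij)·C_j — at least ten captured mRNAs of the gene, and at
least the junction reads ten informative mRNAs would generate (a skipping
mRNA exposes one informative junction, an including mRNA two, hence the
1+Ψ̂). All thresholds are inclusive. Per-cluster exon retention requires
passing observations in ≥50% of the cluster's cells (boundary inclusive);
the flat benchmark filter instead requires ≥10 junction reads in ≥50% of
cells.

## Evaluation statistics

Kruskal–Wallis (tie-corrected, chi-square approximation) runs per exon
over clusters contributing ≥2 non-missing observations, needing ≥2 such
clusters; all-tied data is defined as p = 1. Filter evaluation computes,
over a p-value threshold grid (0.1 … 1e−5), the fold enrichment
(|M|·|p|)/(|P|·|m|) of the selected set for significant exons, the
upper-tail hypergeometric probability, Benjamini–Hochberg adjustment
across the grid, and precision/recall/specificity/accuracy/F1 with the
selected-and-significant exons as true positives.

The autocorrelation test normalizes Ψ̂ per cell (subtract the cell's mean
over tested exons, divide by its variance — as printed; dividing by the
standard deviation instead only rescales and leaves the score's ordering
unchanged), builds Gaussian K-nearest-neighbor weights
w_jk = exp(−d²_jk/σ²_j) with σ_j the distance to the K-th neighbor
(K = N/2 by default; self-weights excluded; ties broken by stable index
order), and scores each exon with C′ = 1 − (N−1)·Σw(Ψ′_j−Ψ′_k)² /
(2WΣ(Ψ′_j−Ψ̄′)²). Cells missing the exon are dropped from every sum; N and
W refer to the non-missing set. The null is built by permuting exon
columns across cells within bins of folded mean Ψ̂ ({0.05–0.1 ∪ 0.9–0.95},
{0.1–0.2 ∪ 0.8–0.9}, {0.2–0.3 ∪ 0.7–0.8}, {0.3–0.4 ∪ 0.6–0.7}, {0.4–0.6})
and missing fraction ({0–50, 50–60, 60–70, 70–80, 80–90, 90–100}%; the
0–50 bin extends the scheme so low-missingness simulated panels are
testable); n_perm shuffled exons are scored per bin (cycling over its
members) and p = (x+1)/(n_perm+1) with x the pooled permuted scores
strictly above the exon's own. Known limitation: when the tested panel is
dominated by exons sharing one trajectory, the per-cell normalization
transfers that structure into the other exons and the pooled null drifts;
calibration holds for diverse panels (and is verified on one).

`compute_embedding` is plumbing: PCA (full SVD, deterministic up to sign)
of log1p depth-normalized counts.

## Synthetic cohorts

`simulate_differential_cohort` builds the full quantification input set
(TPM from simulated reads per kilobase scaled to 1e6; long junction table;
constitutive-junction table with 2–10 junctions per transcript and Poisson
reads at the rate the technical parameters imply; cluster labels).
Defaults: 90 cells in 3 clusters, 75 planted differential + 225 null
cassette exons, 6000 low-expression background genes
(scale ~ LogNormal(ln 10, 1)), planted shift 0.12 between adjacent
clusters against Beta concentration 30, cassette kinetics with
k_on ~ LogNormal(ln 1.5, 1). Two deliberate design points: the background
keeps the modal detected gene near one captured molecule so the Census
total is sanely calibrated (without it the cassette panel dominates and
counts deflate ~10-fold), and the weak-shift/tight-Beta combination puts
detection of the planted effect in the coverage-limited regime — junction
read sampling, not biological Ψ dispersion, decides whether a cluster
difference is visible, which is the regime the filter exists for. With
strong planted effects the rank test detects every planted exon at any
coverage and no selection could be enriched.

`simulate_trajectory_panel` places cells on a latent pseudotime with
trajectory-tracking and flat genes (so PCA recovers the axis) and builds
smooth and scrambled Ψ̂ exon panels with randomized direction, base and
amplitude per exon.

What these generators do not emulate: amplification over-dispersion beyond
Poisson (junction counts in real data can exceed binomial variance),
correlated splicing across exons or with cell state, UMIs, doublets,
batch effects, or mapping artifacts. Passing tests show the pipeline
behaves correctly under the stated model, not that real libraries contain
no further nuisance structure.

## Problem sizes and reproducibility

All randomness descends from one integer seed through named substreams
(exons, kinetics, expression, psi, capture, reads, junctions,
constitutive, permutation, misc), so stages and replicates re-run
independently and bit-identically. The test suite runs the reference
cohort at 300 cells × 1500 genes, the expression sweep at three Ψ values ×
30 replicates, regime comparisons over five seeds, filter evaluation
pooled over three replicate cohorts, and the autocorrelation test at
2000 permutations on 120-cell panels; the acceptance script uses the
full 500-level expression sweep. These sizes give Monte-Carlo error
comfortably below the asserted tolerances while keeping a full run in the
minutes range on one CPU.
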
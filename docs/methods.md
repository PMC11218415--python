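# Methods

## Scope and data model

The package analyses paired single-nucleus RNA and ATAC count matrices
from a two-group (disease vs. control) multi-donor design. Cells live in
`AnnData` objects (sparse counts, per-cell metadata); peaks are 0-based
half-open intervals on a genome; interchange formats are plain text
(MatrixMarket + TSV, BED6, FASTA, VCF 4.2 with phased genotypes, JASPAR
motif text). Because the real data this design emulates are
access-controlled, the synthetic generator in `regnet.simulate` is a
first-class component: it produces every pipeline input with planted,
recorded ground truth.

## The synthetic study

**RNA.** Counts are negative binomial (NB2, `Var = μ + φμ²`) with
log-mean = per-gene baseline + subtype marker shift + diagnosis effect +
per-(gene, donor) random intercept + log per-cell depth factor.
Defaults are the reference study conditions used throughout: 12 + 12
donors × 200 cells, 2,000 genes, 10% planted DEGs at |log₂FC| = 1 with
random signs, donor SD 0.3 (natural-log scale), dispersion φ = 0.5,
log-normal depths (median 2,000, σ = 0.3). Baseline per-cell rates are
log-uniform on [0.2, 5] — the regime of genes that survive a
10%-detection filter in nuclei data; weak genes below that regime are
represented implicitly by the filter. Mitochondrial genes are a tagged
subset used only by QC. An optional donor-level confounder loads on all
genes with N(0,1) gene loadings scaled by `confounder_strength`.

**ATAC.** Accessibility varies at the level of *cell states*: groups of
`state_size` cells (default 50) share a latent chromatin state, and the
synthetic embedding encodes state proximity (it stands in for the LSI
embedding of real data, where nearby cells share state). Peaks inside a
planted coaccessibility block follow an AR(1) chain across the block —
adjacent peaks have latent correlation r (default 0.9), non-adjacent
peaks are conditionally independent given the chain. This choice is
deliberate: the downstream estimator is a sparse partial-correlation
method, and an exchangeable ("one shared factor") block is provably
unrecoverable by it — a positive-definite precision matrix on k
variables cannot have all partial correlations ≥ 1/(k−1), so a 10-peak
equicorrelated block can never produce all-pairs scores ≥ 0.2. A sparse
chain is both recoverable and the more realistic picture of a locus
where accessibility propagates between neighboring elements. Planted
DAPs shift the log-rate by the diagnosis effect (optionally in one
subtype only); per-cell counts are Poisson around state rates with
log-normal depth factors. The per-cell QC metrics (nucleosome signal,
TSS enrichment, FRiP, peak fragments, blacklist fraction) are drawn at
realistic assay scales, standing in for an upstream fragment processor —
the desk-scale count matrix itself is far shallower than a real assay.

**Sequences and motifs.** Each peak gets a 200 bp random sequence with
peak-specific GC content (Beta(5,5) clipped to [0.2, 0.8]); designated
target peaks receive the consensus of a built-in 8-bp motif
(`TFA: TGACTCAC`, `TFB: GGGCGGGG`, `TFC: CACGTGAC`; count matrices with
an 85/5/5/5 split per column). Eight base pairs keeps the consensus
null probability (0.25⁸ ≈ 1.5e-5) inside the 5e-5 scan threshold.

**Genes and GWAS.** Genes anchor to every third peak with alternating
strands; the promoter (2 kb upstream of the start codon), TSS, and a
first-intron interval are derived strand-aware, so promoter/intron
overlap logic is exercised on both strands. GWAS SNVs are placed so some
genes fall inside and others outside the ±500 kb window.

**Haplotypes.** For each configured variant pair the panel realizes the
target r² (within ±0.05) by converting (r², D′ sign, allele
frequencies) into the four haplotype frequencies, rounding to counts,
and making deterministic ±1 adjustments until the realized r² is within
tolerance; infeasible (r², frequency) combinations raise an error naming
the feasibility bound. Panels include at least one insertion and one
deletion (1–4 bp).

All generators are pure functions of `SimConfig` (seed included).

What the generator does *not* emulate: ambient RNA, doublet mixtures
beyond score-vector arguments, batch effects across libraries, realistic
genome-wide sparsity, fragment-level ATAC structure, and sequence
composition beyond GC. Passing tests therefore demonstrate that the
algorithms recover the statistical structure they model — not that they
are robust to every artifact of real tissue data.

## Statistical core

**NB mixed model.** Each feature is fitted with
`log μ = Xβ + u_donor + offset`, `u ~ N(0, σ²)`, NB2 dispersion φ. The
fitter is batched across features: penalized IRLS on the joint (β, u)
system (solved via the Schur complement on the diagonal random-effect
block), an EM-type update `σ² ← mean(u² + conditional variance)`, and
per-feature Newton updates of φ on the profile likelihood (φ clipped to
[1e-4, 1e4], σ² floored at 1e-8). Wald tests use the fixed-effect block
of the joint information matrix with a **t reference, df = n_donors −
p**: the diagnosis contrast lives at the donor level, so the donor count
sets the effective sample size; with a normal reference the null
type-I error measured ~0.07, with the t reference ~0.05. The Laplace
marginal log-likelihood is evaluated at the converged fit and used for
likelihood-ratio tests (composition testing). Measured on the reference
study: 97–99% of planted DEGs called with the correct sign, null type-I
≈ 0.05, σ̂² ≈ 0.08 at true 0.09, φ̂ ≈ 0.49 at true 0.5, ~80 s for 2,000
genes × 4,800 cells on one CPU. Note the estimate-accuracy ceiling: at
these conditions the sampling SD of the diagnosis effect is ≈ 0.18 log₂
units, so pointwise agreement within ±0.2 tops out near 72% even for a
perfect estimator; calling-based recovery is the meaningful target.

**Composition test.** Cell-level cluster membership is modeled with the
same machinery (binomial family, logit link) on diagnosis + donor-level
covariates with a donor random intercept; the diagnosis p-value is an
LRT between the full and diagnosis-free Laplace likelihoods, BH-adjusted
across clusters. Clusters absent from one group are flagged unstable
(p = NA). Measured: null rejection 0.03 at nominal 0.05; 3× planted
enrichment detected in 20/20 simulations at 12+12 donors.

**Covariate selection.** Donor pseudobulk (features with zeros in > 20%
of donors removed, CPM-log1p, centered/scaled) is decomposed by PCA;
PCs explaining > 10% of variance are regressed on every candidate
variable; while any association passes Bonferroni (q < 0.05), the
variable most associated with the top PC is selected, all features are
residualized on it, and the loop repeats. Per-iteration Bonferroni
implies an ~α family-wise false-selection rate per study, which the
tests account for on null metadata.

**Coaccessibility.** Metacells: greedy far-point seeds, k = 50 nearest
neighbors summed, metacells sharing > 80% members dropped, profiles
scaled to the median depth. Windows of 500 kb at 250 kb stride; within a
window, peak-standardized covariance enters a graphical lasso with
elementwise penalty `ρ_ij = s·d_ij/window + base_penalty` (block
coordinate descent, tol 1e-4, ≤ 200 sweeps; near-singular windows get a
1e-4 ridge with a warning). Scores are regularized partial correlations
−ω_ij/√(ω_iiω_jj), averaged over covering windows, and defined exactly 0
beyond 500 kb. `distance_param="auto"` binary-searches the smallest s
for which ≤ 5% of pairs beyond 0.75 × window are nonzero. The default
s = 0.25 and base penalty 1e-3 were fixed from the planted-chain
experiments (adjacent scores 0.3–0.5, cross-block ≈ 0). CCANs are
Louvain communities (seed 17) of the graph of edges ≥ 0.2 at
**resolution 0.25**: at resolution 1.0 modularity provably fragments
the sparse chain/band graphs that thresholded partial-correlation
structures produce (a 10-node path splits into 2–3 communities), while
any block dense enough to survive resolution 1.0 would need all-pairs
partial correlations that violate the positive-definiteness bound above.
Dropping the resolution, not densifying the truth, is the coherent fix;
it is configurable.

**Motif machinery.** PWMs are pseudocount-regularized (1e-3 of the
column total); scan scores are log-odds against a strand-symmetrized
background estimated from the full sequence set, binned at 1e-3; the
null distribution is an exact dynamic program over positions, so tail
p-values match brute-force enumeration to floating-point error (the
binning is part of the score definition, applied identically to scans).
Hits require p < 5e-5; overlapping same-TF hits collapse to the best
score; N bases contribute log-odds 0. Enrichment reweights background
peaks within GC deciles (edges from the pooled GC distribution, empty
deciles borrow from the nearest) so the weighted background GC matches
the target, then applies a one-sided binomial test with the weighted
background hit rate (floored at 1/(2·n_bg)); BH runs across all scanned
TFs within one cCRE family. The n-mer component of the original
GC+k-mer weighting scheme is deliberately omitted (GC-decile matching
only). The binomial treats the background rate as known: calibration is
clean when the background is much larger than the target set (measured
type-I 0.015 at 0.05 with 20 targets vs 300 background) but
anti-conservative when the two sets are comparable in size, because the
rate is estimated from the complementary split — use large backgrounds.

**Variant scoring.** The allele match score is
`Σ ic_i·p_i(b_i) / Σ ic_i·max_b p_i(b)` maximized over positions and
strands (ic in bits against a uniform reference, clipped to [0, 2]);
it is 1 exactly on consensus-containing windows. The match p-value is
the exact scan tail at the best position. Indels apply the REF→ALT edit
and rescan a window extending motif-length − 1 beyond the edit on both
sides (alignment-free). Effects are kept at min(ref_p, alt_p) < 1e-4;
gain/loss is the sign of alt − ref; the strong/weak boundary is
|Δscore| ≥ 0.4 (an explicit, configurable choice — the normalized score
scale makes 0.4 roughly "half the dynamic range of a sharp motif").
LD uses phased haplotype columns only: D = p_AB − p_A·p_B, D′ = D/D_max
with the sign-dependent bound, r² = D²/(p_A q_A p_B q_B); monomorphic
variants return NA with a reason. Prioritization keeps candidates with
MAF ≥ 0.01 and r², D′ ≥ 0.5, sorted by (r², |Δscore|), annotating
whether the binding-increasing allele rides the risk haplotype.

## Pipeline composition

`run_pipeline` chains the stages on one simulated bundle: QC → PCA/LSI →
Louvain cell clusters → gene-activity-based label transfer and cluster
linking → per-linked-cluster NB GLMM DE/DA → metacell coaccessibility on
disease cells of each cluster → cCREs → unidirectional CCANs → GWAS
mapping → per-GWAS-DEG motif enrichment → sign-matched network →
variant effects, LD, prioritization. The toy study (`run_toy`) is a
constructed two-subtype multiome sized so each object class has exactly
one planted instance: a three-peak chain confined to one subtype (both
the chain and the DAP shifts, so the other cluster stays clean), a TF
gene that is itself an up-DEG, motif insertions at a fixed offset with a
motif-breaking SNV at a consensus position, and an r² = 0.85 LD pair
with the GWAS index SNV. Cell-community resolution is 0.2 for the toy
(two well-separated subtypes); the small state size (8 cells) gives the
~150 metacells per cluster needed for a stable precision estimate.

## Problem sizes and determinism

The acceptance benchmarks use: the reference DE study (2,000 genes,
4,800 cells) plus a matched null; 20 seeds × (confounded + null)
covariate-selection studies (300 genes, 16 donors); a 120-peak, ~520-
metacell coaccessibility study with two 10-peak chains; exhaustive motif
enumeration at lengths 3 and 8; all ~1,500 polymorphic haplotype tables
up to n = 12; and the toy pipeline. Everything is seeded; the only
nondeterminism guard is Louvain, which runs with a fixed seed.

## Known limitations

- One random intercept (donor); no cell-level variance decomposition
  into separate nucleus- and donor-level overdispersions.
- PQL/EM fitting mildly shrinks σ² relative to full marginal ML
  (measured ≈ −0.01 at σ² = 0.09); Wald inference is calibrated by the
  donor-level t reference, not by profile likelihood.
- The coaccessibility stage assumes cell-state structure is visible in
  the supplied embedding; with too few distinct states the precision
  estimate is noisy and spurious edges at 0.2 appear.
- Enrichment ignores k-mer composition beyond GC and is approximate for
  small backgrounds (see above).
- Indel rescanning is alignment-free; long repeats and structural
  variants are out of scope, as is LD estimation from unphased
  genotypes.
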
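# Methods

This note documents the models, estimators, and numerical choices in
ribodyn, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed by the defaults

Five ordered stages (E12.5, E14, E15.5, E17, P0) with RNA-seq and
Ribo-seq in biological duplicate, mass spectrometry in triplicate, and
a tRNA qPCR array per stage. Stages are mapped to a real-time axis at
0, 36, 72, 108 and 132 h so degradation rates carry units of 1/h; the
inter-stage spacing is a convention (no measured value exists for it)
and is recorded in the output metadata of every simulation. All stage
counts, replicate numbers and the time axis are configurable.

## Translation-efficiency quantification

Densities are TPM-style: count/length(kb), rescaled so each sample sums
to 10⁶. Genes qualify as translated with ≥ 32 footprints (summed over
replicates) in at least one stage. TE = (RPF density + c)/(RNA density
+ c) on per-stage replicate means with pseudocount c = 0.5 (logged,
configurable); TE is *undefined* (not zero) where RNA density is zero
or the gene fails the footprint filter.

Differential testing is a deliberately transparent stand-in for the
moderated-t / bivariate-posterior machinery used on real datasets of
this design: per stage, the replicate variance of log2(value + c) is
shrunk halfway toward the across-gene mean variance of that stage
(weight 0.5; with 2–3 replicates the raw variance is unusable and the
across-gene mean supplies the missing degrees of freedom), and the
log2 fold change is z-tested against its quadrature SE. The TE-change
statistic is Δ = log2FC(RPF) − log2FC(RNA) with SE by quadrature of the
two assay SEs — a transcriptional change common to both assays cancels
exactly, which also makes the caller antisymmetric under swapping the
assays. BH adjustment runs within each contrast × assay family; calls
require ≥ 1.25-fold and adjusted p < 0.05. Genes with fewer than two
usable replicates in a stage are flagged untestable, never called.
Calibration under the no-change generator (raw false-positive rate at
nominal 0.05) is checked by the acceptance suite; the mild residual
anti-conservatism of the z-test at 2 replicates is within the ≤ 0.07
budget the tests enforce. Zero-variance degenerate input yields p = 1
(no change) or p = 0 (any change) rather than an undefined z.

Per-contrast calls are kept independent (a gene may be called up at one
transition and down at another); `dte_gene_groups` collapses them to
one label per gene, with 'both' for the genuinely bidirectional case.

## RUST, offset calibration, and site occupancy

Per transcript and read length, the footprint 5′-end count vector over
the CDS interior (first and last 20 codons trimmed — start/stop peaks
would otherwise dominate; trim configurable) is binarized at the
transcript mean. The observed RUST value for codon c at distance d is
the mean binarized value over positions d nt 5′ of occurrences of c;
expected is the global mean binarized value; enrichment is their ratio.
The binarization is what makes the estimator robust: a transcript
contributes presence/absence patterns, not its coverage magnitude. The
flip side is compression — at saturating per-position coverage the
enrichment understates large dwell differences, so occupancy ratios are
monotone but not proportional to dwell ratios outside the
sub-saturation regime. Tests that assert quantitative dwell recovery
run at depths where the binarization response is near-linear.

For each read length the between-codon variance of enrichment and the
KL divergence (base 2; observed codon distribution p_c ∝ enrichment_c ×
q_c against the background q) are computed per distance d. The A-site
offset is the variance argmax within a plausibility window of 10–18 nt
— terminus-proximal artifacts from RNase cut-site preference live at
d ≤ 2 and d ≥ length−3 and are thereby excluded by construction. The
background q is the footprint-weighted codon frequency by default
(uniform optional). A flat curve (window maximum < 1.05× the median of
informative distances; distances with no 5′-end coverage in frame are
structurally zero and excluded from the median) flags the length
uncalibrated instead of silently defaulting. Diagnostics record the
full curves and the secondary P-site bump 3 nt 5′ of the chosen offset.

A-site occupancy is the enrichment at the chosen offset; P at offset−3;
E at offset−6; read lengths are combined by footprint-count-weighted
mean, and per-length tables are emitted alongside. Replicates are
pooled into stages at the count level before RUST (the alternative —
RUST per replicate, then averaging — is equivalent at these depths and
was not taken).

## tRNA abundance, usage, availability, and the dwell partition

Isodecoder abundance is −ΔCt against the mean of the 5S and 18S rRNA
reference rows, averaged over replicates. Per-codon abundance sums the
isodecoders whose anticodon is the exact Watson–Crick partner of the
codon; a wobble flag adds G:U pairings (off by default — weighting by
wobble rules has no effect on the package's conclusions in the tested
generators, consistent with the source analyses). Codon usage counts
each codon across CDSs weighted by per-transcript RNA density,
normalized to sum to one; availability is the per-stage OLS residual of
usage on abundance (so availabilities sum to ~0 by construction, and
positive values mean demand exceeds supply).

The dwell partition regresses A-site occupancy on stage + amino acid +
tRNA abundance (+ stage × amino-acid interaction), one observation per
quantified codon per stage, reporting type-II sums of squares as
fractions of the total. Caveat stated plainly: the per-stage
observations replicate the same 61 codon values, so nominal OLS
p-values in this design overstate certainty; the variance fractions are
the meaningful output, and the test suite evaluates null covariates by
their median fraction across independent draws rather than by p-value.
Rank-deficient designs abort with the aliased columns named.

## Positional analyses

P-site vectors place each footprint's P site at 5′end + offset − 3.
One transcript per gene is retained (highest median per-sample
coverage; ties to the lexicographically smaller id) with CDS ≥ 192 nt.
Metagene profiles normalize each transcript by its mean CDS P-site
density (making the profile invariant to expression) before averaging;
position 0 is the first nucleotide of the start (or stop) codon.

The 15-bin scheme tiles the CDS with seven 4-codon bins anchored at the
start, seven anchored at the stop, and a variable mid bin; transcripts
under 57 codons cannot host the scheme and are excluded. "Anchored" is
the implemented reading of bins "centering" on start/stop — a layout
that straddles the anchor cannot tile the CDS and was rejected for
breaking that invariant. Per-gene significance is a chi-square test of
homogeneity on the 2 × 15 contingency table (genes under 64 total
counts untested), BH across genes; per-bin log2 fold changes use
library-size-normalized counts with pseudocount 0.5. This replaces a
negative-binomial positional framework with a fully specified test
calibrated on the generator (identical stages produce no calls).

5′-UTR density divides P-site counts in the UTR — excluding the 15 nt
immediately upstream of the start codon, where initiation-complex blur
contaminates the signal — by the transcript's RNA TPM. Thresholds: TPM
≥ 0.1 at both stages and ≥ 10 UTR P-site counts over the compared pair.
Group differences (dTE down/none/up) use two-sided rank-sum tests.

PQS scanning matches G{3,}(N{1,7}G{3,}){3} left to right, taking the
longest match at each leftmost start and resuming after its end. The
semantics are defined engine-independently (greedy regex backtracking
order differs between engines); one consequence is that G4 motifs
separated by ≤ 7 nt merge into a single match. The scanner is verified
against an independent exhaustive decomposition enumerator. This is a
lower-sensitivity stand-in for scored quadruplex searches: it finds
only the canonical four-run pattern, with no bulges, mismatched runs,
or stability scoring. Density is count per UTR nucleotide, undefined
under 15 nt.

## Kinetic modeling

dP/dt = K_s·R(t) − K_d·P(t), R(t) the piecewise-linear interpolation of
per-stage footprint density ("linear stepwise" is read as piecewise
linear; a piecewise-constant flag exists, both with closed forms). On
each interval with R = a + bτ the solution is written as
P(τ) = P_i·e^(−K_d τ) + K_s τ (a·φ1 + b τ·φ2) with φ1 = (1−e^−x)/x and
φ2 = (x−1+e^−x)/x², evaluated by series below x = 10⁻⁵ — algebraically
identical to the textbook variation-of-constants form but stable down
to K_d = 0 (where it degenerates to the exact integrator
P_i + K_s(aτ + bτ²/2)). Agreement with adaptive numerical integration
to 10⁻⁶ relative tolerance over random parameter draws is enforced by
the acceptance suite.

Likelihood is Gaussian on log abundances (MS noise is multiplicative)
with the noise variance profiled out; missing entries are simply
absent from the likelihood. Categories and parameter counts: stationary
(1: P0), linear (1: c = K_s/K_d, the K_d→large limit, fixed K_d =
10³/h), degradation (2: P0, K_d with K_s = 0), production (3), MSdev
(3 + T−1: production plus a free deviation per post-initial timepoint,
whose MLE is therefore the saturated per-timepoint mean). Stationary,
linear, degradation and MSdev have closed-form MLEs; production is fit
by multi-start Levenberg–Marquardt in log parameters (8 starts on a
log-spaced K_d grid, equilibrium-consistent K_s starts, fixed seed).
BIC = k·ln(n_obs) − 2·logL; on noiseless input an RSS floor of 10⁻¹²
per observation keeps logL finite, so nested parsimony decides.

Selection takes the minimal-BIC category among those whose standardized
residuals pass a Pearson χ² goodness-of-fit against N(0,1) (4 bins at
quartile boundaries, df 3, α = 0.05 — the exact residual-normality
recipe is a design choice here); if none pass, MSdev is the refuge.

The production model has two likelihood ridges: the equilibrium ridge
(K_s/K_d fixed — only the ratio identified when the trajectory stays
near steady state; this is what the identifiability flag tests, by
rescaling K_s and K_d jointly and requiring a noticeable logL change)
and the integrator ridge (K_d → 0 with K_s absorbing). The point
estimate is therefore a MAP with a weakly-informative log-normal prior
on K_d — centred on a 46-h half-life, typical of mammalian proteomes,
with a 1-decade sd — which pins ridge-sliding estimates to plausible
turnover while costing an identified fit essentially nothing (~one
noise-unit per decade of deviation). BIC uses the data likelihood at
the MAP, not the penalized objective. The prior is expressed in
absolute 1/h units, so point estimates are only approximately
equivariant under time-axis rescaling (BIC ordering is exactly
equivariant). Even so, per-gene K_d remains weakly identified for genes
generated near equilibrium; the rank correlation between true and
fitted K_d among production-selected genes sits at the information
ceiling of the design (it approaches 1 as MS noise → 0), which the
acceptance suite measures.

Shared-K_s half-lives: one K_s maximizes the summed production
likelihood with per-gene (P0, K_d) profiled out. The K_s grid search
runs on a random subsample of 300 genes (K_s is one global scalar;
the subsample only widens its CI marginally) with a bounded scalar
refinement; every gene then gets a multi-start (P0, K_d) refit at the
shared K_s and π½ = ln2/K_d. Fixing K_s removes the equilibrium ridge,
which is the entire point of the approximation: half-lives become
estimable for genes whose individual fits were ridge-bound, at the cost
of absorbing per-gene K_s misfit into K_d — half-lives are
order-of-magnitude estimates under heterogeneous true K_s.

## Variance decomposition

With P and R the log-scale protein and synthesis-proxy values across
genes (levels per stage, or fold changes per transition): OLS of P on R
gives b_all and the residual variance s²_all; with mean per-gene
measurement-error variances s²_P and s²_R and a fixed measurement bias
b_R (default 1; the explained fraction is flat over b_R ∈ [0.75, 1.5]
whenever s²_R is small, which the sensitivity helper quantifies):

    s²_PDT = s²_all − (b_all/b_R)²·s²_R − s²_P
    explained = (s²_MP − s²_P − s²_PDT)/(s²_MP − s²_P)

s²_all is deliberately read as the *residual* variance of the P-on-R
fit and s²_MP as the total variance of measured P: prose descriptions
of this decomposition sometimes call s²_all "total variance", but that
reading contradicts the subtraction formula itself; the residual
reading makes the two formulas a single consistent decomposition and
recovers an engineered explained fraction on synthetic data (the
acceptance suite checks 0.60 ± 0.05 at n = 2000). Method-of-moments
subtraction can go negative at finite n; negative components clip to 0
with a logged count. Per-gene error variances come from the quantify
module's shrunken replicate variances.

## Clustering and enrichment

Genes × 2(T−1) vs-first-stage log2 fold changes (RNA block then MS
block), complete cases only, unscaled (the columns share units; no
standardization before PCA). A full-rank PCA rotation precedes Ward
clustering — distance-preserving, so the partition equals clustering
the raw matrix up to numerical noise; retained to mirror the stated
procedure. Ward is the Ward.D2 variance-minimizing criterion on
Euclidean distances; the tree is cut at k = 13 by default (a flag — no
automatic k selection; the original choice was made by external
annotation inspection, out of scope here). Per-cluster dTE enrichment
is a two-sided Fisher exact test on the 2 × 2 membership × status
table, BH across clusters; the implementation is checked against
explicit hypergeometric tail enumeration.

## The synthetic-data generator

What it emulates: stage-resolved NB counts (Var = μ + φμ², default φ =
0.01) around log-normal baselines with a per-stage log-normal random
walk (sd 0.25) as the developmental program; TE shifts of 2-fold in 10%
+ 10% of genes from the middle stage onward (footprint means scale, RNA
unchanged); protein trajectories from the five kinetic categories with
K_d drawn log-uniform over 10–200 h half-lives, K_s log-uniform over 2
decades, initial displacement from equilibrium log-normal (sd 0.8),
multiplicative MS noise (sd 0.1) and 10% missing-at-random dropout;
footprints whose A-site codon is drawn ∝ transcript abundance × codon
dwell weight, 5′ ends at codon start − offset[length] with offsets
12–15 nt over lengths 25–31, and cut-site bias as multiplicative
nucleotide preference at both read termini; tRNA Ct values one
log2 unit per abundance doubling below the rRNA reference mean, over a
synthetic 151-isodecoder panel (two per sense-codon anticodon plus a
third for the first 29 — the commercial panel's composition is not
public, so this stand-in is labelled synthetic).

Setting the NB dispersion to 0 switches count noise off entirely
(counts equal rounded expected means) — a degenerate mode for exactness
tests, not the φ→0 Poisson limit.

What it does not emulate, hence what passing tests do not show:
intensity-dependent MS dropout (dropout is missing-at-random);
isoform mixtures and alignment artifacts (inputs begin post-alignment);
positional pausing beyond codon identity (no 5′ ramps, no stalling
sites — metagene flatness on the generator is by construction); tRNA
charging; library-preparation batch effects; and any coupling between
the dwell weights and tRNA abundances unless explicitly configured.
Recovery results on this generator bound what the estimators can do
when their model is right; they do not certify performance on real
libraries.

Ground truth (labels, rates, dwell weights, offsets, abundances) is
returned alongside every simulated dataset and written to
`truth_*.tsv` files by the CLI. Identical config + seed reproduces
byte-identical outputs.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open everywhere internally. Duplicate
sparse-profile rows sum with a warning. Ties in best-transcript
selection go to the smaller id. Zero-footprint transcripts are skipped
by RUST; empty clusters are skipped with a note; all-zero count columns
abort density normalization. Chi-square bins with zero column totals
are dropped from the positional contingency test. Seeds: every
stochastic routine takes an explicit seed or Generator; library
functions never consume global RNG state.
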
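# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic study the generator emulates, the numerical choices, and the
known limitations. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Normative charts and deviation scores

For each of the 34 left-hemisphere Desikan–Killiany regions, conditional
quantiles of cortical thickness (CTh, mm) are modeled linearly in age
(years) with an additive sex term (female = 1),

    q_τ(age, sex) = β₀ + β₁·age + β₂·sex,

fitted on healthy subjects by minimizing the mean pinball loss
ρ_τ(u) = u·(τ − 1{u<0}) at τ = 0.05, 0.50, 0.95 (statsmodels `QuantReg`,
IRLS). The contract is the attained loss, not the algorithm: the test
suite checks fitted losses against a brute-force grid search and the
in-sample quantile property (fraction of points below the τ-curve within
p/n of τ). Two degenerate inputs bypass IRLS exactly: a constant outcome,
and an outcome interpolated exactly by least squares (the noise-free
limit), both of which admit a zero-loss closed form.

A subject's deviation in region r is the standardized residual about the
median curve, Δz = (CTh − q̂₀.₅)/σ̂ᵣ, where σ̂ᵣ is the SD of healthy
residuals about the fitted median. The alternative reading — dividing by
the between-subject SD of raw CTh — differs only by the variance removed
by the age/sex terms; the residual SD keeps Δz on a unit scale under the
model. Categories are assigned against the outer curves (infra-normal
below 5%, supra-normal above 95%), with boundary values counted normal to
a 1e-9 relative tolerance so exact-fit limits behave. Quantile crossing,
possible because the three curves are fitted independently, is repaired
by sorting predictions across τ at each evaluation point (rearrangement
preserves each curve's marginal fit and enforces monotonicity); repairs
are counted on the model object.

In-sample band coverage under a correctly specified linear model is
pinned near 90% by the quantile property; the canonical n = 2000 study
gives a minimum over regions of 89.8% (`scripts/acceptance.py`). Bootstrap
confidence envelopes for the percentile curves (case resampling, pointwise
2.5/97.5 percentiles on an age grid per sex) are provided as a library
function; they are excluded from the default pipeline output because they
cost B full refits per region.

## Cell-type transcriptional maps

A cell-type map is the per-region mean expression of that type's marker
gene set, z-scored across the 34 regions with the sample (n−1) SD.
Z-scoring is idempotent, shift-invariant, and equivariant under region
permutation (all tested). Marker genes absent from the expression matrix
are dropped with a warning; a fully absent or zero-variance set is an
error naming the cell type. The association of each map with mean healthy
CTh uses Pearson correlation over regions (Spearman behind a flag) with
Benjamini–Hochberg adjustment across the seven cell types.

## Spatial coupling and the dispersion test

Coupling is the Pearson correlation, over regions, of a patient's Δz
profile with each cell-type map. The null model randomizes the regional
assignment of expression values: per iteration one shared permutation of
region labels is applied to all seven map columns (sharing preserves
inter-map correlation under the null), all patient correlations are
recomputed, and the null pools permutations × patients. Per cell type the
observed coupling distribution is compared to its null with the
Ansari–Bradley test: pooled midranks, scores s = min(rank, N+1−rank),
statistic T = Σ scores in the observed sample, and a two-sided normal
approximation with tie-robust moments E[T] = m·S₁/N and
Var[T] = m·n·(N·S₂ − S₁²)/(N²(N−1)). This implementation is cross-checked
against `scipy.stats.ansari` and against exact enumeration of all C(8,4)
assignments on a small instance.

Detection is directional. With genuinely coupled cell types present, the
coupling of a patient to an *uncoupled* map is under-dispersed relative
to the permutation null: the planted signal inflates the profile variance
in the correlation denominator while contributing nothing to the
numerator for an orthogonal map. A two-sided test therefore flags
under-dispersion for null cell types. Since the scientific hypothesis is
that coupling is *stronger* in some individuals than chance allows, a
cell type is flagged significant only when its BH-adjusted two-sided p
falls below α *and* its observed SD exceeds the null SD. The reported
p-values remain two-sided; the type-I calibration of the raw test is
verified by simulation (rejection ≈ α under a structureless generator).

## Subtyping

The patient × cell-type coupling matrix is column-centered (not
standardized — columns already share the correlation scale) and reduced
to four principal components. Ward's linkage clusters the PC scores; the
cluster count is chosen by the gap statistic, Gap(k) = E*[log Wₖ] −
log Wₖ, with Wₖ the within-cluster SSE of the Ward partition at k
(matching the clustering actually used) and the reference expectation
over B = 100 datasets drawn uniformly from the bounding box of the
scores. The SE includes the √(1+1/B) factor. Selection: the global
maximum is accepted when it beats the runner-up by one SE; otherwise the
gap curve has plateaued (splitting a true cluster leaves the gap nearly
flat), and the smallest k on the one-SE plateau of the maximum is chosen.
With no structure, k = 1 lies on the plateau and is returned; blob-null
simulations confirm k = 1 in ≥ 80% of runs and two separated blobs give
k = 2.

Soft membership of subject i in subtype s is inverse-distance to the
cluster centroids in PC space, mᵢₛ = (1/dᵢₛ)/Σₜ(1/dᵢₜ), with dᵢₛ = 0
mapped to full membership. Hard labels are the argmax of the memberships:
after the Ward cut defines centroids, each subject is assigned to its
nearest centroid (one k-means-style reassignment), keeping hard and soft
assignments mutually consistent. Subtype profiles report median and
quartiles of coupling per cell type with a Wilcoxon signed-rank test
against zero, BH-adjusted within subtype; a subtype's *signature* is its
set of FDR-significant negative medians.

## Cell-set polygenic scores and validation

A cell-type score is Σ dosage·β over SNPs within [gene start − b, gene
end + b] (closed interval, default b = 10 kb) of the type's marker genes
— with the synthetic annotation this coincides with gene membership —
z-standardized across subjects; a subtype score averages the standardized
scores of the subtype's signature cell types and is re-standardized.
Validation computes, within each subtype's members, the partial
correlation between the subtype score and whole-brain deviation severity
(mean Δz across regions), residualizing both on an intercept, sex, the
genome-wide score, and the familial-relatedness covariate; p is
two-sided on n − 2 − q degrees of freedom. The implementation is verified
against the precision-matrix identity and `pingouin.partial_corr`.
BH-FDR is applied across the matched subtype tests only; the full
score × subtype grid is reported unadjusted and labeled exploratory.
Constant covariate columns (e.g. no families) are dropped rather than
pseudo-inverted.

Because different subtypes' signatures share marker sets (subtype II
overlaps both I and III by construction), their scores are structurally
correlated, and a further positive crossed correlation is induced by
conditioning on the genome-wide score, which contains every cell set.
Full-grid specificity is therefore not attainable in principle; the
discriminant-validity property is tested on the structurally disjoint
pairs (neuronal/endothelial score in astrocyte/OPC members and vice
versa), which are non-significant in the large majority of replicates.
Keeping the cell sets a small fraction of the genome-wide SNP panel
(840 of 3000 by default) keeps the conditioning artifact small.

## The synthetic study

The generator is a pure function of (configuration, seed); every stream
(region parameters, profiles, expression, cohorts, genotypes) derives
from a named child of one seed sequence.

**Healthy CTh.** CTh_{i,r} = β₀ᵣ + β₁ᵣ·ageᵢ + β₂ᵣ·sexᵢ + uᵢ + εᵢᵣ with
ages uniform on 18–65, sex Bernoulli(0.5), a shared subject factor
uᵢ ~ N(0, 0.05² mm²) inducing inter-regional correlation, and
homoscedastic region noise εᵢᵣ ~ N(0, 0.12² mm²). Intercepts span
2.0–3.4 mm and age slopes −0.008..−0.002 mm/yr, the realistic adult
cortical range. The model is linear by construction, so the normative
stage is correctly specified; heteroscedastic or nonlinear aging is out
of scope of these study conditions.

**Cell-type profiles and expression.** The seven spatial profiles are a
random orthonormal frame (QR of a Gaussian matrix) standardized per
column, giving near-zero pairwise correlations so each planted signal is
identifiable; real transcriptional maps are more inter-correlated, and
passing tests here do not certify behavior under strongly collinear
maps. Marker genes track their profile plus N(0, 0.5) noise (40 markers
per type), background genes are independent noise.

**Patient deviations.** Each patient draws a subtype
(I/II/III, proportions 0.25/0.45/0.30) with coupling weights on cell-type
profiles: subtype I weights excitatory/inhibitory/endothelial (−1.2
each), subtype II weights excitatory/inhibitory/astrocyte/OPC weakly
(−0.6), subtype III weights astrocyte/OPC (−1.2); microglia and
oligodendrocyte carry zero weight everywhere (the planted null).
Within-subtype Gaussian jitter (SD 0.2) perturbs the weights of every
cell type that is weighted in *some* subtype: subtypes are graded
tendencies, not point masses — mirroring the observation that real
cell-based subtypes are not well differentiated — and without this
softness the dispersion signal of a cell type confined to a 25% subtype
sits at an Ansari–Bradley cancellation point between its member tail and
the under-dispersed non-members. The deviation field is

    Δᵢᵣ = sᵢ·(Σ_c w_{ic}·profile_{rc} + shift_s) + N(0, 1),

where shift_s (−1.0 / −0.85 / −0.55 for I/II/III) is a whole-brain
offset: profiles are zero-mean across regions, so without it the
severity signal would cancel in the regional mean and no
genetics-to-severity link could exist; it also realizes the observed
ordering of whole-brain deviation across subtypes (I most thinned, III
mildest). Severity is sᵢ = 1 + 0.3·burdenᵢ truncated at zero, with
burdenᵢ the standardized cell-set polygenic burden over the subtype's
weighted cell types, computed from the synthetic genotypes by exactly
the scoring the validation stage uses. Patient CTh adds Δ·0.12 mm to the
healthy mean structure plus shared factor; with all weights, shifts and
slope zero, patients are distributionally identical to controls.

**Genotypes.** 3000 SNPs, three per gene, covering all 280 marker genes
and 720 background genes; dosages Binomial(2, maf) with maf uniform on
0.05–0.5; effect sizes N(0, 0.1²); 20 sib-like family pairs share each
dosage value with probability 1/2, and the relatedness covariate is a
per-family shared Gaussian factor. No linkage disequilibrium, imputation
error, or realistic allele-frequency spectrum is modeled.

Under these defaults the planted structure is recoverable end to end:
the dispersion procedure flags exactly the five coupled cell types, the
gap statistic selects three clusters, clustering recovers the planted
labels with adjusted Rand > 0.8, matched validation correlations are
negative (≈ −0.3 to −0.5) and predominantly FDR-significant, and
subtype coupling signatures replicate across independent draws with
profile correlations ≈ 0.98.

## Numerical choices and edge cases

- Sample (n−1) SDs everywhere z-scores or standardized scores appear.
- Pearson correlation is the default coupling and association measure
  (Spearman available for the map–CTh association).
- Zero-variance deviation profiles yield NaN coupling with a warning and
  are dropped before clustering; constant map columns are an error.
- Subtypes smaller than 5 skip profile tests; smaller than 10 skip
  validation; membership-sweep rows that fall below n = 10 are reported
  as missing.
- All JSON outputs are written with sorted keys; reruns with identical
  inputs and seed are byte-identical.

## Limitations

- The membership sweep does not show increasing correlation strength with
  membership under these study conditions: inverse-distance membership
  selects subjects *near the cluster centroid*, whereas the
  highest-severity subjects lie far along the cluster's severity axis, so
  restricting to high membership does not enrich for the planted genetic
  effect. A membership definition aligned with coupling strength rather
  than centroid proximity would behave differently; the sweep's contract
  (threshold-0 equivalence, missing-row handling) is what the tests pin.
- Generator realism is deliberately minimal: no spatial autocorrelation
  of cortical noise, no scanner or site effects, no LD, no donor-level
  expression variability. Passing tests demonstrate internal consistency
  of the pipeline and recoverability of planted structure, not
  performance on real cohorts.
- The problem sizes used by the test suite and the acceptance script
  (n = 2000 healthy, 200 patients, 1000 permutations, B = 100 gap
  references) are the canonical study conditions of this package.
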
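# Methods

This note records the statistical model behind each stage, the
conventions chosen where more than one reasonable definition exists, and
what the synthetic-data experiments do and do not demonstrate.

## Normalization chain

The metabolomics chain is block correction → minimum imputation → PQN →
log2, enforced through a `scale_tag` on the matrix: each operation accepts
only inputs earlier in the chain than its own output, so running stages
out of order raises instead of silently renormalizing.

*Block correction* divides each (feature, run-day block) by the block
median of that feature, ignoring missing values; a feature entirely
missing within a block is an error because the scaling is undefined.
Medians use the midpoint convention for even counts. Because the
correction is a per-feature scalar within a block, ratios between samples
in the same block are preserved exactly.

*Minimum imputation* models left-censoring at the detection limit: a
missing entry is assigned the smallest observed value of that feature
across all samples. This biases censored values upward relative to their
(unknown) true values and reduces within-feature variance — consequences
shared by any single-value imputation and accepted here for fidelity to
standard practice in semiquantitative panels.

*PQN* takes the per-feature median across all samples as the reference
spectrum (a designated reference group can be substituted); the per-sample
quotient is the median over features of sample/reference, and the sample
is divided by it. With ≥ 500 features and unit-free multiplicative
dilution in (0.5, 2), the estimated quotients track planted dilutions with
Spearman ≈ 0.99; the residual error comes from the finite-feature median,
not from bias.

*Freeze-time screen*: per-feature Spearman correlation against hours to
freezing, tie-corrected. For n ≤ 8 samples the p-value is the exact
permutation tail over all n! orderings; above that the usual t
approximation. Flags use BH q < 0.05 by default (both raw p and q are
reported, since "significant" is convention-dependent); flagged features
are annotated, never dropped.

## Differential testing

Mann-Whitney U is two-sided throughout. With combined n ≤ 12 and no ties
the p-value is exact by enumeration; otherwise the normal approximation
with midranks, tie correction and continuity correction. The continuity
correction makes small-sample p-values slightly conservative; a KS test of
null p-values against the uniform therefore rejects at n = 15/15 over
thousands of features, while at n = 20/20 the approximation is good
(KS p ≈ 0.3). Rejection-rate calibration at nominal 0.05 is within ±0.012
of 0.05 over 2000 null simulations at n = 20/20.

Fold changes default to `log2(mean(a)/mean(b))` on the unlogged
normalized scale; a median-ratio estimator is selectable and the choice is
recorded in the output metadata, since published fold changes rarely state
their estimator. The significance indicator is x = +1 if q < α and
log2FC ≥ 0, −1 if q < α and log2FC < 0, else 0, with α recorded in the
result.

BH adjustment is the standard step-up (q₍ᵢ₎ = min over j ≥ i of
p₍ⱼ₎·m/j, capped at 1), computed by statsmodels and verified against hand
evaluation and R's `p.adjust`. One caution: **BH is not idempotent under
re-application.** bh(bh(p)) ≠ bh(p) in general — e.g. p = (1.0, 0.25)
adjusts to (1.0, 0.5), which re-adjusts to (1.0, 1.0) — because the m/j
multipliers act again on already-adjusted values. q-values must therefore
be computed once from raw p-values. One acceptance-suite check asserts
re-application idempotence and is intentionally left failing as
documentation of this property.

The moderated t shrinks each gene's pooled variance s²_g (df residual d_g)
toward a prior: s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with the statistic
referred to t with d₀ + d_g df. (d₀, s₀²) are estimated by method of
moments on log s²: the excess of var(log s²) over trigamma(d_g/2)
determines d₀ via the inverse trigamma (Newton iteration), and the mean
equation gives s₀². When the observed spread shows no excess, d₀ = ∞ and
s₀² is the arithmetic mean of the variances. These conventions reproduce
limma's `eBayes` to rtol 1e-6 on a shared fixture (cross-checked via
Rscript in the test suite); forcing d₀ = 0 recovers the ordinary pooled t
exactly, and hyperparameters planted at (d₀ = 4, s₀² = 0.05) are recovered
within 0.2% on 5000 simulated genes.

## Pathway scores

The weighted DA score is the |log2FC|-weighted mean of the indicators
over a pathway's *measured* members (those present in the tested feature
universe, matched by case-folded exact string; an optional two-column map
translates platform names first). Pathways with fewer than `min_measured`
(default 3) measured members are excluded and logged. If every measured
member has log2FC exactly 0 the score is reported as 0 with a degenerate
flag. The score is invariant to rescaling all weights, bounded in [−1, 1],
and equals a brute-force elementwise evaluation on every random instance
tested (1000 pathways of ≤ 5 members).

Pre-ranked GSEA: features are sorted by decreasing metric; the ES is the
maximal deviation between the |metric|^α-weighted cumulative distribution
of in-set features and the unweighted cumulative distribution of out-of-set
features (α default 1). The null permutes set membership — random sets of
matching size — rather than sample labels, because with ≤ 28 samples per
cluster the sample-permutation null is too coarse. The permutation p is
two-sided on |ES| over all permutations: this makes p ≤ 1/(n_perm+1)
attainable for extreme sets and keeps null p-values uniform, which a
within-sign one-sided p cannot do simultaneously. NES divides ES by the
mean |null ES| of matching sign. BH families are kept separate for
metabolite-based and RNA-based enrichment.

## Consensus clustering and COCA

Features are ranked by unscaled MAD (the 1.4826 consistency factor would
not change the ranking) with ties broken lexicographically by feature
identifier, making selection deterministic. Clustering is Ward linkage on
Euclidean distances over sample columns (scipy's implementation, verified
against an independent O(n³) Lance-Williams implementation on hundreds of
random instances).

Each candidate k gets its own seeded substream; every iteration draws
⌈0.8·n⌉ samples without replacement, clusters them, and tallies
co-clustering among co-sampled pairs. Consensus_ij is the co-clustering
frequency conditioned on co-sampling; never-co-sampled pairs are flagged
undefined and excluded. The model-selection statistic — the paper-level
notion of "concordance" is not uniquely defined in the literature this
package follows — is the mean of |2·consensus − 1| over defined off-diagonal
pairs: 1 exactly when every pair is always or never co-clustered.
Two caveats discovered in validation and worth knowing:

* The statistic has a **k-dependent null baseline**: on structureless data
  it rises with k (≈ 0.5–0.7 for k = 2..4 at n = 24), so the null curve is
  not flat. Model selection is trustworthy when some k approaches 1, as it
  does on separable data (argmax at the true k with ARI = 1 at 4-SD
  separation); the proportion-of-ambiguous-pairs statistic would shift but
  not remove the baseline.
* Final memberships cut a Ward tree built on (1 − consensus) as the
  distance; undefined entries enter as 0.5 (no evidence either way).

COCA one-hot encodes per-modality cluster calls (row sums = number of
modalities) and runs the same consensus procedure on the binary matrix
with Euclidean distance. `k_override` substitutes the concordance argmax
(the study-shaped configuration selects k = 4); the full concordance curve
is always returned so the override is auditable. Cluster labels C1..Ck
sort by nondecreasing proportion of aggressive tumors (widely invasive or
recurrent), ties broken by ascending cluster size then lowest original
index.

**Information limit of two-modality COCA.** If each modality's labels are
corrupted independently with probability r, a fraction 2r(1−r) of samples
is corrupted in exactly one modality; for such a sample the one-hot
evidence is exactly tied between its true and its corrupted cluster
(equal Euclidean distance to both cluster cores), so any clustering
resolves it by chance. At r = 0.15 and n = 28, ~26% of samples are
ambiguous, bounding the expected ARI near 0.7. The measured mean ARI over
20 seeds is ≈ 0.67, i.e. the implementation operates essentially at the
ceiling; the acceptance-suite check asserting mean ARI ≥ 0.9 under these
exact conditions is intentionally left failing, as that bar exceeds the
information the inputs contain.

## Microenvironment scoring

The ssGSEA convention here: per-sample midranks of expression, genes
walked in decreasing order, in-set steps weighted rank^0.25, out-of-set
steps 1/(N − n_set), and the score is the *integrated* (summed) ECDF
difference over the list — not the max deviation. No cross-sample
normalization is applied by the scorer itself; z-scoring across samples is
an explicit separate step so that single-sample scores remain
single-sample. At weight exponent 0, scores depend on ranks alone and are
invariant to any strictly increasing per-sample transform.

ImmuneScore/StromalScore are ssGSEA scores of user-supplied infiltration
signatures (published signatures are inputs, not shipped; the tumor-purity
conversion applied downstream of such scores in other tools depends on
constants external to this package and is excluded). CYT is
exp(mean(log(GZMA + δ), log(PRF1 + δ))) on the unlogged scale with
δ = 0.01 to keep zero counts finite. TIS/IIS average z-scored constituent
signature scores; the constituent lists (e.g. nine T-cell subset
signatures for TIS) are configuration, as the canonical lists belong to
their source publications. Group comparisons reuse the Mann-Whitney
machinery with BH across scores and report direction as the sign of the
median difference, with the group order recorded in the table attributes.

## Synthetic-data generator

The generator emulates: per-feature log-normal abundances (log2 location
~ N(17, 2), scale ~ U(0.5, 1.5) — magnitudes and dispersions typical of
MS intensity panels; expression uses location N(5, 2)); multiplicative
per-(feature, block) run-day factors (2^N(0, 0.3)); per-sample dilution
~ U(0.5, 2); per-feature detection-limit censoring at a global quantile
(default 5%; real missingness rates are instrument-dependent, so this is
an exposed parameter, not a claim); planted tumor-vs-normal log2 effects;
an additive linear freeze-time trend on the log scale for a configurable
feature subset (12 by default, 0.04 log2/h over a 0–48 h range — the
simplest monotone dependence a Spearman screen detects); latent clusters
among tumors realized as Gaussian centroids of scale `cluster_sep` (in
feature-SD units) on a reserved feature block; and infiltration gradients
shifting signature genes by gain × level log2 units. Defaults mirror the
study-shaped cohort: 32 tumors, 16 normals, 728 metabolites, 16,853
genes, 4 run-day blocks, with 28 paired samples used in integrated runs.

One master seed expands into named substreams (numpy `SeedSequence`
spawn keys), one per generative stage, so adding a stage never perturbs
earlier draws and identical configs are bit-reproducible. In paired
simulations both modalities share one latent partition; each modality's
*data* reflect independently corrupted labels (rate 1 − modality_agreement,
reassignment to a uniformly random other cluster), and both the shared
partition and the per-modality labels are recorded in the ground truth.

What passing tests show — and what they do not: the generator produces
clean log-normal noise, exchangeable samples within groups, and exactly
the planted structure. Real metabolomics adds heteroscedastic
peak-integration error, correlated metabolite families, missingness that
is informative beyond a single detection threshold, and batch effects
that do not cancel by median scaling. Recovery results (PQN Spearman
≈ 0.99, consensus ARI = 1 at 4-SD separation, power 0.79 for a
log2FC = 2 effect at n = 16/16 under BH across 100 features) are
statements about this generative model, not guarantees on real data.

## Numerical choices and degenerate inputs

* Medians: midpoint of central order statistics; missing values excluded.
* Exact-vs-approximate switches: Mann-Whitney at combined n ≤ 12 (no
  ties); Spearman permutation p at n ≤ 8.
* Ties: midranks everywhere; MAD ties by feature id; cluster-ordering
  ties by size then original index; best-k ties to the smallest k.
* Degenerate inputs raise typed errors naming the offender: all-missing
  feature/block pairs, non-positive values before log/PQN, constant
  freeze-time vectors, empty contrast groups, signatures spanning the
  whole universe, k larger than the sample count.
* The pipeline driver writes each stage's outputs before the next stage
  starts, snapshots the configuration and SHA-256 checksums in a
  manifest, and reruns byte-identically (including the report figure).

## Problem sizes used in validation

Routine validation runs at reduced but structure-preserving sizes chosen
so the full suite completes in about a minute: hundreds of features,
24–60 samples, 50 consensus iterations, 200 Monte-Carlo replicates for
power/calibration estimates, 200 random instances for the Ward oracle,
and 20 seeds for COCA recovery. The acceptance script uses the same
sizes and derives every stream from its `--seed` argument.

## Known limitations

* Single-value minimum imputation understates censored-value uncertainty.
* The concordance statistic's null baseline grows with k; comparing
  concordance across k values is a heuristic, not a test.
* Two-modality COCA cannot out-perform the tie ceiling described above;
  with three or more modalities the ambiguity largely disappears.
* ssGSEA scores are convention-dependent (weighting exponent, integrated
  vs max-deviation); scores from other implementations are comparable in
  rank, not in value.
* No covariate adjustment or paired designs: all tests are unpaired
  two-group comparisons.
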
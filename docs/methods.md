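# Methods

This note documents the statistical procedures implemented in `tbvnet`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## Study design being modeled

The pipeline targets a two-group (case/control) blood transcriptome study
in which the trait of interest is total brain volume (TBV, in cc) measured
by MRI in toddlers.  Expression values are log-scale array intensities
(genes × samples).  The emulated design has ~12,208 gene probes and
87 case / 55 control male subjects aged 1–4 years, including a 253-gene
cell-cycle-like module; these are the synthetic generator's defaults, with
every analysis in the test suite run at reduced sizes chosen so the whole
suite completes in minutes on one CPU.

## Synthetic data generator

Each planted module *m* follows a single-factor block model:
`x_i = ρ_i f_m + √(1−ρ_i²) ε_i` with a per-sample latent factor
`f_m ~ N(0,1)` and iid noise.  Setting `ρ = √within_cor` makes the expected
pairwise within-module correlation equal `within_cor`; a mild linear
gradient in ρ (±10%) creates an unambiguous hub/peripheral ordering that
downstream connectivity analyses can recover.  Noise genes are independent.
Values are placed on a log-intensity scale (location 8, scale 1 by
default — arbitrary documented constants) with mild per-gene location and
scale jitter so the variance filter has realistic heterogeneous input.

The trait is `trait_mean + age_effect(age) + trait_sd·(signal + noise)`,
built from *realized expression* rather than from the factors or detected
eigengenes, so module detection and trait association are independently
testable.  Per group, each coupled module contributes through a coupled
gene subset (`coupled_fraction` of the module, default 0.3):

* hub picks (a `hub_fraction_coupled` share of the subset, taken from the
  top of the ρ order) couple through their full standardized expression,
  which is close to the shared factor — so the eigengene inherits the
  association;
* peripheral picks (the remainder, from the bottom of the ρ order) couple
  through their *idiosyncratic components* (expression minus the factor's
  share).  This plants trait relevance genuinely in the module periphery:
  peripheral genes acquire high gene significance while hubs do not, which
  is the "hub-to-periphery reorganization" phenotype the gene-level
  analyses are designed to detect.  Coupling peripheral genes through
  their raw expression would not work — the subset mean is dominated by
  the shared factor and the planted contrast all but vanishes.

Couplings are target correlations (magnitudes < 1, Σc² < 1 per group);
realized factor–trait correlations are recorded in the truth object.  Ages
are uniform on the configured range with a linear trait trend by default
(50 cc/year; any callable can be supplied).  The default TBV location/
spread (1100 ± 60 cc) is in the toddler range.  Missingness injection is
off by default.  All outputs are bit-identical under a fixed seed.

What the generator does **not** emulate: array-specific artifacts (batch,
probe effects), heavy-tailed intensity distributions, correlated
missingness, or the marginal distributions of any particular real dataset.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the factor-model idealization, not performance on real
arrays.

## Preprocessing

*Missingness filter*: genes missing in more than 50% of samples are
removed.  *Variance filter*: a gene is removed when a one-sided chi-square
test (statistic (n−1)s²/median variance, df n−1, lower tail) finds its
variance significantly *below* the median gene variance at α = 0.05 — i.e.
near-constant, uninformative genes are dropped while typical genes are
retained.  On iid equal-variance input this retains ≈ (1−α) of genes.
The filter is idempotent when the variance distribution is well separated;
with a continuum of variances a second pass can remove a few more genes
because the median shifts.

*Replicates*: technical replicate arrays are collapsed per subject either
by per-gene averaging or by keeping the designated (root) array; replicate
links are followed transitively and cycles are an error.

*Age adjustment*: TBV is residualized on age with a fixed-df natural cubic
regression spline (df = 4 basis functions, pooled across groups by
default; a per-group flag exists since pooling is a design choice).  The
spline is a deterministic, dependency-light stand-in for a generalized
additive model with the same residualization contract: residuals are
mean-zero and orthogonal to the fitted trend.  Residuals split at 0 cc
into "smaller" (< 0) and "bigger" (≥ 0; ties assigned upward, a documented
constant) brain subgroups.

## Network construction and module detection

Pearson correlation throughout; missing values must be resolved upstream.
The scale-free fit index discretizes the connectivity vector into ~10
equal-width bins and regresses log10 p(k) on log10 k̄; the R² is signed
negative when the slope is positive, since a scale-free degree
distribution must decrease.  The selected power is the lowest β ∈ [1,20]
reaching signed R² ≥ 0.90 **among powers whose mean connectivity stays
≥ 1** — without that guard, small gene sets reach the fit target only at
powers so high that the adjacency collapses and no module survives.  When
no eligible power reaches the target, the sample-size-based default for
unsigned networks is used (β = 6 for n ≥ 40 samples, 7 for 30–39, 8 for
20–29, 9 below) with a warning; chasing the argmax R² instead was measured
to destroy module recovery (ARI 0 vs 1.0) at desk scale.

Module detection clusters 1 − TOM by average linkage and cuts statically
at 0.99 × the tallest merge height (the conventional static cut; clusters
below `min_module_size` = 30 fall into the unassigned pool), then rescues
unassigned genes into the module with highest |kME| when that exceeds 0.3.
This static-cut + kME-rescue scheme replaces the hybrid dynamic branch
cut: it is deterministic, has two transparent knobs, and reproduces the
intent (minimum size, unassigned pool, membership-based rescue).  Labels
are "M1", "M2", … in decreasing size order; a color-alias table is
provided for readability.  Two planted modules driven by (nearly)
identical latent signals can legitimately merge — module identity is only
defined up to the correlation structure.

Eigengenes are the leading right singular vector of the module's
gene-standardized matrix, unit norm, sign-aligned so the correlation with
the module mean expression is non-negative; the variance-explained
fraction is recorded.  Zero-variance genes are dropped with a warning.

## Association and inference

ME–trait correlations use the Student asymptotic test (t = r√(n−2)/√(1−r²),
df = n−2, two-sided — note that printed literature values for such tests
occasionally differ from this formula by small factors attributable to
unstated sidedness conventions).  Storey q-values estimate π₀ on the λ
grid {0, 0.05, …, 0.90} via a cubic smoothing spline evaluated at the
largest λ, clipped to (0, 1]; a BH fallback (`method="bh"`) forces π₀ = 1.

Permutation p-values follow the count/(n_perm+1) convention everywhere; an
exact 0 means "< 1/(n_perm+1)" and is annotated rather than altered.  The
module permutation null scrambles the gene→module assignment (sizes
preserved) and recomputes eigengenes per iteration.  Two properties of
this scheme are worth knowing:

* under an exchangeable null (trait independent of expression, the labeled
  set no more coherent than a random set) the p-values are exactly
  uniform, which the calibration tests verify at 500 simulations × 1000
  permutations;
* when the observed module is genuinely coherent, the null draws (random
  gene sets) are *not* coherent modules, and the test is conservative —
  measured: fraction of null p < 0.05 ≈ 0.002 instead of 0.05.  This is
  inherent to the scrambling design (the hypothesis it tests is "does this
  module associate more than a random same-size gene set"), not an
  implementation artifact.

Group differences in correlation strength use zDiff = atanh(r_case) −
atanh(r_control) with a group-label-shuffling null; tests are two-sided
via |statistic| since sidedness is a reporting convention.  Bootstrap CIs
are percentile (2.5/97.5) over resampled samples; BCa was not implemented
because only a nominal 95% interval is required.  Gene-set (subnetwork)
association averages the members' standardized expression per sample and
reuses the same machinery; for a homogeneous module this average tracks
the eigengene closely (|Δr| ≤ 0.15 in tests).

## Gene-level metrics and contingency statistics

GS is the signed gene–trait correlation; GC (kWithin) the summed adjacency
to same-module genes (connectivity of unassigned genes is computed over
the unassigned pool but flagged non-comparable).  GS–GC correlations per
group are compared with the population z statistic
(atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)); no p-value accompanies it
because all module genes are measured — it is a population effect size.
Top-k rankings (k = 30, tied to the minimum module size) use |GS| by
default — relevance is a magnitude — with a signed option exposed; ties
break lexicographically by gene identifier so runs are deterministic.

Odds ratios of 2×2 tables use Haldane–Anscombe correction (+0.5 to all
four cells) if and only if a cell is zero, with Woolf CIs
exp(ln OR ± z₀.₉₇₅ √Σ1/cell) on the same (possibly corrected) table; the
Fisher exact p (two-sided, sum of hypergeometric point probabilities ≤ the
observed) is always computed on the uncorrected table and is verified
against exhaustive enumeration for small tables.  This
Haldane-plus-Woolf contract reproduces all four printed odds ratios and
confidence bounds of the motivating analysis to their printed precision.

Differential expression is a per-gene Welch t-test with a group-label
permutation p (count/(n_perm+1)); the asymptotic p uses
Welch–Satterthwaite df.

## Subgroup relevance classification

For a designated hub list (typically PPI-mapped hubs of the focal module),
the threshold is the minimum |GS| of the list in the full group ("GS-ALL";
the absolute value resolves the sign ambiguity of "lowest value" —
relevance is magnitude).  Each listed gene is *retained* in a subgroup
when its subgroup |GS| still reaches the threshold, else *lost*; candidate
genes outside the list exceeding the threshold in a subgroup are *gained*
(no additional significance filter is applied — the threshold itself is
the filter, and whether one was intended is unknowable).  The
classification is scale-invariant in the trait.  Retention counts feed the
contingency machinery above.

## Module preservation

On the gene intersection of two datasets, each reference module is scored
in the test data with a reduced battery: three density statistics (mean
within-module adjacency, eigengene variance-explained, mean |kME|) and two
connectivity statistics (correlation of reference vs test kWithin over
module genes; correlation of the vectorized within-module correlation
matrices).  Reference-side vectors are held fixed at the observed module;
the null redraws same-size gene sets from the test data (200 permutations
by default — enough for stable Z at desk scale and configurable upward).
Z = (obs − mean_null)/sd_null per statistic; Z_density and Z_connectivity
are medians of their groups, Zsummary their mean; medianRank is the median
over statistics of the module's observed-statistic rank (1 = most
preserved).  Bands: < 2 none, 2–10 moderate, > 10 high.  Holding the
reference side fixed keeps the self-preservation case (test ≡ reference)
non-degenerate: the observed connectivity correlation is 1 against a null
centered at 0.  The reduced battery reproduces the band-level behavior
(strong planted modules: Zsummary ≈ 12 on self-preservation; |Zsummary|
< 2 against independent noise) but its absolute values are not
interchangeable with other implementations' Zsummary; comparisons should
stay within one statistic set.

## Enrichment

Upper-tail hypergeometric p = P(X ≥ k) including the observed overlap,
against a fixed background universe (default 21,405 genes, the array-wide
annotated pool of the emulated design), with BH q-values across sets.
Verified against direct summation of the tail.

## Orchestration and determinism

The pipeline runs preprocessing → network → association → gene metrics →
subgroup → optional preservation and enrichment, writing every table as
TSV/JSON plus a manifest with version, parameters, global seed and the
per-stage seeds fanned out from it via a spawning seed sequence (all below
2³¹).  Reruns with identical configuration are byte-identical.  Default
permutation/bootstrap counts in the pipeline configuration are 1,000 (the
methodological reference value is 10,000; 1,000 keeps a full desk run
under a minute and the statistics stable to the precision reported).
Ranks in outputs are 1-based; internal indices 0-based.

## Known limitations

* The static-cut detector has no deep-split hierarchy; very close modules
  merge earlier than under the hybrid dynamic cut.
* The scale-free fit is unreliable below a few thousand genes; the
  mean-connectivity guard and sample-size fallback handle this, but the
  selected power on small gene sets should be read as a default, not an
  estimate.
* The label-scrambling module permutation test is conservative for
  coherent modules (see above).
* Preservation Zsummary values are battery-specific; only the bands are
  portable.
* The generator's factor model cannot represent overlapping modules or
  gene-specific trait couplings beyond the hub/peripheral mechanism.
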
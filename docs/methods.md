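# Methods

`ampliconvar` quantifies the precision of targeted 16S rRNA gene
sequencing: how much of the spread in inferred community composition is
technical (within and between sequencing runs) versus biological, and how
that spread depends on input biomass. This note documents the models, the
defaults, the numerical choices, and what the synthetic test bed does and
does not establish.

## Contaminant filtering

Reagent and extraction-kit contamination is scored per sequence variant
(SV) from negative controls:

    S_i = (reads of SV i in negative controls) / (reads of SV i in all samples)

so S_i = 0 for SVs never seen in a negative control and S_i = 1 for SVs
seen only there. SVs with `S_i > 0.1` (strictly greater — an SV exactly
at the threshold is kept) are removed before any other analysis. SVs with
zero total count score 0 and are dropped as bookkeeping rows. If a study
contains no negative controls, all scores are 0 and a warning is raised;
filtering then has no effect, which is the honest behaviour.

After filtering, a read-depth cutoff is chosen as the smallest per-sample
total of any non-negative sample such that at most
`max_negatives_retained` (default 2) negative controls lie at or above
it. This replaces an "inflection point read by eye" with its operational
consequence — essentially no negatives survive — and is reproducible and
monotone in its one parameter. A manual override is first-class for users
who want a fixed depth (e.g. a historical 10,000-read cutoff). Rarefaction to the chosen
depth uses multivariate hypergeometric subsampling (without replacement)
with an explicit seed and a single draw; the rarefied table feeds alpha
diversity only, while relative abundances feed everything else.

## Variability metrics

The coefficient of variation is reported in percent, `CV = 100 * s/m`
with the n−1 sample standard deviation. Intra-assay CV is computed
within each sequencing run; the per-taxon "mean intra-assay CV" is the
unweighted mean across run strata (runs have unequal sizes and weighting
by n would silently privilege large runs). Inter-assay CV pools all
selected samples. Undefined CVs (taxon never detected in a stratum) are
carried as NaN, never coerced to zero. Strata with fewer than two samples
are skipped with a warning, which automatically excludes runs carrying a
single control. Only undiluted mock samples enter run-stratified
variability; diluted libraries would conflate biomass effects with run
effects.

The intraclass correlation is the one-way random-effects single-measure
form ICC(1,1), from ANOVA mean squares:

    ICC = (MSB − MSW) / (MSB + (n0 − 1) MSW),
    n0 = (N − Σ n_j²/N) / (J − 1)

with the unbalanced effective group size n0. Groups of size one are
allowed (they contribute between-group degrees of freedom only). The
per-rank summary is the unweighted mean of defined per-taxon ICCs; a
single multivariate rank-level statistic would be an alternative, but the
per-taxon mean keeps the quantity interpretable taxon by taxon and
matches how single-measure ICCs are normally reported.

Levey-Jennings control charts flag observations more than `k` sample
standard deviations (default k = 2) from the per-taxon mean computed over
all selected samples (not leave-one-run-out). Note an algebraic
constraint of leave-in charts: with n observations the largest attainable
|z| is (n−1)/√n, so at k = 2 no point can ever be flagged with n ≤ 5;
flags only become possible from n = 6.

## Distances, ordination, PERMANOVA

Three dissimilarities on [0, 1]: Bray-Curtis `Σ|x−y| / Σ(x+y)` on
relative abundances, unweighted Jaccard on presence/absence (detection =
count ≥ 1), and the Jensen-Shannon distance as the square root of the JS
divergence with base-2 logarithms. The base-2 square-root form is chosen
because it is a true metric with maximum exactly 1, which makes the three
metrics directly comparable; the natural-log variant differs only by the
constant √(ln 2).

PCoA is classical metric scaling: Gower double-centering of −D²/2,
symmetric eigendecomposition, axes from positive eigenvalues in
descending order, and proportion explained relative to the sum of
positive eigenvalues. Negative eigenvalues are reported, not corrected.

PERMANOVA partitions squared distances: `SS_total = Σ_{i<j} d²/N`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`, `R² = 1 − SS_within/SS_total`, and
pseudo-F with (a−1, N−a) degrees of freedom. Significance comes from
label permutations with the +1 correction, so the smallest reportable p
at 999 permutations is 0.001. `n_permutations=None` enumerates all
distinct label arrangements and reports the exact fraction (for small
instances and for testing). When several factors are requested they are
tested sequentially, each marginally — no joint partitioning; the two
R² values answer "how much would this factor alone explain", which is
the reproducible reading when no joint model is declared. Degenerate
instances with `SS_within = 0` report infinite F and are flagged.

Distance-group comparison partitions pairs of specimen-labelled samples
into intra-run/same-specimen, inter-run/same-specimen, and
different-specimen (biological) sets, reporting both means and medians
since the two can disagree on skewed distance distributions.

## qPCR and the biomass model

The standard curve is least squares of Ct on log10(copies/reaction),
fitted on at least three distinct nonzero standards; zero-copy wells are
excluded (log undefined) and serve as no-template checks. Amplification
efficiency is `10^(−1/slope) − 1`. Quantification averages determined
replicate wells arithmetically, inverts the curve and divides by the
5 uL template volume; an all-undetermined sample gets 0 copies with a
flag.

For a sequential dilution series (each level pipetted from the previous
one), two expectations are computed per level: naive
(`stock_measured / factor`) and sequential
(`measured_{k−1} · f_{k−1} / f_k`). The sequential form absorbs a
systematic per-step over-dilution bias, which otherwise accumulates
geometrically and makes measured copies fall consistently below the
naive line.

The variance model is OLS:

    log10(CV%) = b0 + b1 · log10(copies/uL) + b2 · log10(mean RA)

Mean relative abundance enters in percent by default; the unit is stored
on the fitted model object and applied identically at prediction time, so
fit and predict cannot silently disagree — predictions are the exact
back-transform `10^(b0 + b1·log10 c + b2·log10 m)` of whatever
coefficients the model carries. An SD-of-relative-abundance response is
available behind a flag (`response='sd'`) because spread is sometimes
reported as an SD rather than a CV. Rows enter the fit only when the
taxon's mean abundance is at least 0.1 %, it is detected in at least 3
replicates of the level, and its CV is strictly positive; these cutoffs
keep every logged quantity finite and exclude presence/absence noise at
the detection limit. Per-level biomass uses the measured qPCR mean of the
level's replicates rather than the theoretical value, since measured
copies are what a user of the model will have. The default prediction
grid crosses copies/uL in {10, 10³, 10⁵} with abundance in
{1, 5, 10, 25, 50} %.

## The synthetic-study generator

Because studies of this design rarely deposit raw data, the generator is
a first-class module producing complete studies — counts, metadata, qPCR
plates, and a latent-truth record — with the structure the analyses
assume. One library is generated as:

1. **Run composition**: true proportions perturbed per taxon by
   `exp(N(0, run_effect_sd))` and renormalised — a shared multiplicative
   batch effect per run.
2. **Replicate noise**: Dirichlet with concentration
   `replicate_concentration × run composition` (standard overdispersed
   replicate model; larger concentration = tighter replicates).
3. **Contamination**: constant-load two-source mixture with weight
   `w = L/(L + c)` for a library holding `c` copies/uL against a fixed
   contaminant profile with effective load `L`. Negative controls are the
   `c = 0` limit (pure contamination); high-biomass samples are barely
   touched.
4. **Template bottleneck**: the composition is resampled through a
   multinomial pool of `(c + L) × 5 uL` molecules. This is the mechanism
   coupling noise to biomass: dilute libraries pass through a small
   molecule pool, inflating replicate-to-replicate distances, dropping
   rare taxa, and depressing observed alpha diversity — the behaviour of
   real low-input amplicon libraries.
5. **Read sampling**: multinomial at a log-normal read depth (median
   30,000, log-SD 0.35); negatives draw from a much shallower
   distribution (median 1,000, log-SD 0.6), reflecting the low yields of
   template-free libraries.

The sequential dilution run holds `stock / (factor_k · bias^k)` true
copies/uL at level k (`overdilution_bias` = 1.05 per step), and qPCR
measures truth with multiplicative log-normal error (sigma 0.1) plus
0.05-cycle Ct noise against a perfect-efficiency simulated curve
(slope −3.3219, intercept 40).

Defaults and why: the built-in mock community is 33 clinically relevant
strains at uniform proportions (configurable; a staggered geometric
variant exists for abundance-gradient questions — with a uniform truth an
abundance-variability correlation is undefined by construction, so
gradient analyses use the staggered variant). The stock is 7,520
copies/uL, placing the 1:80 level near 94 copies/uL, a realistic
lower limit for robust profiling. `run_effect_sd = 0.3` and
`replicate_concentration = 800` put intra-assay CVs of percent-level taxa
in the ~10–25 % range and inter-assay CVs in the ~15–45 % range, typical
of well-controlled mock-community monitoring; `specimen_effect_sd = 0.8`
makes biological variation between stool specimens clearly exceed the
run effect. The contaminant load of 2 copies/uL makes contamination
negligible at stock (w ≈ 3·10⁻⁴) but substantial at 1:1000 (w ≈ 0.2).
The full-scale default layout spans 19 runs with 218 mock, 29 stool and
222 negative libraries, including a 110-library dilution run (stock plus
factors 10, 20, 30, 40, 50, 60, 80, 100, 500, 1000 × 10 replicates).

All randomness flows from one study seed; per-sample generators are split
deterministically from it (`SeedSequence([seed, stream, index])`), so
studies are byte-identical under a fixed seed and independent across
seeds.

What the generator does **not** model: sequencing error, chimeras, or
read-level artefacts (denoising is assumed upstream); taxon-specific
extraction or amplification bias (the mock truth is taken at face value);
temporal drift in the contaminant profile; zero-inflation beyond what the
bottleneck induces; index hopping between libraries. Passing tests on
synthetic data therefore demonstrate the correctness and calibration of
the statistical machinery under a plausible generative model, not the
field accuracy of any particular protocol.

## Numerical choices and degenerate inputs

- Contaminant removal is idempotent at a fixed threshold and keeps
  boundary scores (`S = threshold`).
- An ICC is undefined (NaN) when all values are identical; a CV is
  undefined when the stratum mean is zero; both are flags, never zeros.
- Spearman correlations use average ranks for ties; a constant CV vector
  returns NaN with no correlation claimed.
- A positive standard-curve slope is an error, not a warning: it means
  the calibration is unusable.
- `R² = 0` is reported for a constant regression response (statsmodels
  returns −inf for the zero-total-variance case).
- Exhaustive PERMANOVA enumeration is guarded to small instances.

## Problem sizes in the test suite

The suite works at deliberately modest sizes chosen to exercise every
code path with tight Monte-Carlo bounds: oracle-equivalence checks use
randomized instances up to 50 × 50; permutation-test calibration uses 200
null studies of 10 samples at 999 permutations; regression recovery uses
100 studies of 126 rows with residual SD 0.5; qualitative pattern checks
use 20 independent full-scale synthetic studies. These sizes make the
whole suite run in well under a minute per concern while keeping the
statistical assertions sharp.

## Known limitations

- The depth-threshold rule assumes negative controls are systematically
  shallower than true samples; a contaminated high-depth negative will
  push the threshold up and can cost real samples (by design — that is
  what it should do).
- Sequential single-factor PERMANOVA does not partition shared variance
  between correlated factors; the two R² values can sum above 1.
- The variance model is a descriptive log-linear fit; it does not model
  taxon-specific dispersion or zero inflation, and extrapolation outside
  the fitted biomass/abundance range inherits all the usual risks of a
  log-log regression.
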
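# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

The input is a long-format panel of area harvested (hectares) per
(region, calendar year, commodity group). Area harvested is used as the
abundance proxy throughout. Zero and missing areas are both treated as
absence, because FAO-style sources omit crops that are not grown rather
than reporting zeros; a region-year that was observed but has nothing
grown is an *empty community*, distinguishable from a region-year outside
the data (a lookup error). A region with a truncated reporting history
(the Central-Asia pattern) is represented by absent years, never by
zero-filled years — zero-filling would fabricate diversity crashes.
Region and group labels are matched case-sensitively after whitespace
trimming; mapping errors surface as errors rather than being fuzzily
repaired.

## Tree dating and phylogenetic metrics

The crop phylogeny is a rooted newick tree (polytomies allowed) whose
node ages (My) come from a whitespace-delimited `label age` table; tips
are age 0 and branch lengths derive from age differences. Undated
internal nodes are placed by even interpolation, processed root-to-tip:
each undated node is positioned between its parent's (already final) age
and every dated endpoint reachable below it through undated nodes only,
splitting each such path evenly, and takes the oldest of these candidate
positions. On a chain between two dated nodes this is exactly the
classical even spacing of the intervening nodes; choosing the oldest
candidate guarantees ages strictly decrease root-to-tip and stay above
every fixed descendant age, which a purely per-node rule does not when
dated descendants are heterogeneous. A calibration whose age does not
exceed all dated descendants raises an error rather than being adjusted.

Pruning to a taxon set keeps the minimal subtree spanning the taxa and
the original root, retaining degree-2 pass-through nodes so age
calibrations attached to internal labels survive; branch lengths through
such nodes sum identically, so no metric is affected.

Faith's PD includes the path to the root (the common default of the
community-phylogenetics toolchain). Rao's QE uses full patristic
(tip-to-tip) distances; note that `picante::raoD` uses half that distance
(time to the most recent common ancestor), so its values are exactly half
of ours on an ultrametric tree — the package's test suite carries frozen
cross-check values from that toolchain with the factor applied.

**One-species-per-group randomization.** Groups mapping to several
species are resolved by a uniform random draw per present group,
repeated (default 100 replicates) with the median reported. Presence
metrics use the drawn species *set* (two groups drawing the same species
count it once); abundance metrics pool the areas of duplicate draws,
conserving total area. Draws are independent per year by default
(`per_year_draw=False` holds one assignment per replicate across the
series); the median over an even replicate count is the midpoint of the
two central order statistics. All randomization flows from one master
seed through deterministic per-(region, year, replicate) substreams, so
results are reproducible and parallelizable.

## Temporal models

Six mean functions for D(year), least squares throughout (Gaussian ML
for the nonlinear ones), fitted to each region × metric series:

| family     | form                                              | mean params |
|------------|---------------------------------------------------|-------------|
| linear     | a + b·year                                        | 2 |
| piecewise2 | a + b·year + c·(year−ψ₁)₊ + d·(year−ψ₂)₊          | 6 |
| quadratic  | a + b·year + c·year²                              | 3 |
| unimodal   | a·b^((year−c)²)                                   | 3 |
| asymptotic | a + b·exp(−exp(c)·(year−year₀))                   | 3 |
| logistic4  | a + (b−a)/(1 + exp((c−year)/d))                   | 4 |

The unimodal form is read as an exponentiated bump: 0 < b < 1 gives a
maximum at year c (`a·b·(year−c)²` is the other typographic reading; the
bump reading is implemented because the parameters are described as mean
value, shape, and peak year). Nonlinear fits center the year axis for
conditioning and map parameters back to calendar years; for the
asymptotic family the offset parameter b is origin-dependent and is
reported relative to a recorded origin `year₀` (the first observed year),
because mapping it to a year-0 origin overflows for calendar years
(exp(rate·1961)). c = ln(rate) is origin-invariant. Each nonlinear family
uses several data-driven starts (extremes, midpoints, endpoint ratios)
and keeps the best residual sum of squares; all-starts failure is a
convergence error.

**Breakpoint estimation.** The two-breakpoint fit uses iterative
linearization: given current ψ's, OLS on the working basis
{1, year, (year−ψ_m)₊, −I(year>ψ_m)} yields for each breakpoint a
slope-change coefficient and a gap coefficient; the update is
ψ_m ← ψ_m + gap/slope-change, iterated until the largest update is below
10⁻⁶ year or 50 iterations (reaching the cap stops the iteration; the
best-RSS comparison across starts decides). Updates are step-halved (down
to 1/16) when the full step would cross the breakpoints, exit the data
range, or leave a segment with fewer than two observations — the
admissibility rule that prevents degenerate boundary solutions; a start
fails only when even the damped step is inadmissible. Failed starts are
replaced from a decile grid of initial breakpoint pairs, and the best-RSS
admissible solution wins. When a slope-change coefficient is
numerically zero with a matching zero gap (a genuinely slope-constant
series), the breakpoint is held fixed rather than divided by zero.

**AIC.** AIC = n·ln(RSS/n) + 2k with k = mean-function parameters + 1
(error variance); the additive constant is dropped, so only within-series
comparisons are meaningful. An RSS numerically indistinguishable from
zero (below 10⁻¹² of the series' signal energy) maps to a −∞ sentinel
ordered below every finite AIC; ties — e.g. several families fitting a
noiseless line exactly — are broken in favor of fewer parameters.

**Bootstrap.** "Bootstrapping with replacement" is implemented as *case*
resampling of (year, D) pairs at the original n (robust to
heteroscedasticity, unlike residual resampling). Each replicate is refit
starting from the point-estimate breakpoints with a small quantile grid
as fallback; failures are logged and excluded, and fewer than 80%
successes is an instability error. Reported parameters, AIC, and r² are
medians over successful replicates (r² is 1 − RSS/TSS for all families,
including the nonlinear ones).

## Change indicators and cross-metric tests

From the bootstrap-summarized piecewise fit: onset = median ψ₁, duration
= median ψ₂ − median ψ₁ (reported as a positive number of years), and
post-onset rate = median b + median c. Bootstrap medians are the default
inputs to the cross-region regressions (point estimates are used only
when no bootstrap was run). Onset-versus-onset comparisons are OLS with
the usual t-based slope p-value, restricted to regions where both fits
converged (dropped regions are listed, never imputed); the 1:1 hypothesis
{intercept = 0, slope = 1} is tested jointly with
F = ((RSS₀ − RSS)/2)/(RSS/(n−2)) against F(2, n−2), where RSS₀ uses the
predictions ŷ = x. Cross-region summaries are mean ± sd by default,
median ± MAD on request.

## β-diversity

Bray-Curtis dissimilarities are computed at commodity-group granularity
— abundances are reported per group, and pushing the species
randomization into β-diversity would inject noise with no reference
procedure to calibrate against. Samples are ordered (region
lexicographic, year ascending); covered-but-empty communities are
excluded with a warning.

NMDS minimizes Kruskal stress-1 via iterative majorization (one metric
principal-coordinates start plus seeded random restarts); the reported
stress is recomputed in-package from the returned configuration using
isotonic regression with the primary (unweighted) tie treatment, so the
reported number is self-consistent by construction.

The PERMANOVA partitions G = J(−D²/2)J (J the centering matrix) with
sequential (Type-I) sums of squares in the order region, year,
region×year. Year enters as a centered numeric covariate: 54 categorical
year levels would consume most of the residual degrees of freedom, and a
1-df covariate matches the small year effects these panels show. p-values
use free permutation of sample labels with p = (exceedances + 1) /
(permutations + 1); with an exactly saturated partition (zero residual)
the pseudo-F is reported as ∞. The implementation is checked against R
vegan's `adonis2(…, by="terms")` on a frozen fixture to 8 significant
digits.

The within-year trend regresses the Bray-Curtis value of every same-year
region pair on year (pair-level data, not yearly means), reporting both
the OLS slope and the two-breakpoint fit of the same series. The response
is dissimilarity: a negative slope means homogenization.

## Synthetic data

The generator emulates the structure the analysis assumes: ~22 regions ×
54 years (1961–2014) × ~157 commodity groups, one region truncated to
1992 onward, log-normal areas (log-mean 9 ≈ 8,000 ha, log-sd 2 — heavy
tailed like real area distributions), richness trajectories following the
two-breakpoint form with onsets in 1975–1987, bursts of 1–3 groups/year
lasting 5–15 years, then levelling off, and Gaussian richness noise
(default sd 2 groups). Composition turns over through per-region
preference orderings (present groups = first k of the ordering), so
richness gains are nested and persistent, the way new commodity groups
appear once and persist in real reporting. By default 20% of groups map
to 2–5 candidate species so the randomization machinery is exercised;
the homogenization variant interpolates regional preference scores
toward a common ordering across a configurable window.

What the generator does *not* emulate: real crop identities, spatial or
temporal autocorrelation of areas beyond the richness trajectory,
country-level aggregation, trade shocks, or reporting revisions. Passing
the recovery benchmarks therefore shows the estimators work under the
assumed data-generating process, not that real panels satisfy that
process.

## Benchmark conditions

The acceptance script and end-to-end tests use: 54-point series with
noise sd = 5% of the clean range for breakpoint recovery (200 series) and
AIC selection (100 series); 100-replicate bootstraps on 100 series for
the bootstrap-agreement rate (the production default is 500 replicates;
100 keeps the confidence-interval benchmark fast at the same estimand);
2,000 simulations for the 1:1 test calibration and 1,000 (at 99
permutations, 12 samples) for the PERMANOVA calibration; and a 4-region
end-to-end pipeline run at 20 randomization replicates. The pair-count
identity is checked at the full 22 × 54 panel dimensions, where
(54−23)·C(21,2) + 23·C(22,2) = 11,823 within-year pairs over 1,157
samples.

## Known limitations

- The piecewise fitter estimates at most two breakpoints and assumes
  homoscedastic, uncorrelated errors; no autocorrelation-aware variant is
  provided.
- Only AIC is exposed for model ranking (no AICc/BIC).
- NMDS inherits the local-minimum behavior of majorization; restarts
  mitigate but do not eliminate it.
- The PERMANOVA's free permutation scheme tests each sequential term
  marginally; no restricted/reduced-model permutation is implemented.
- PD and QE magnitudes depend entirely on the user-supplied tree and age
  calibrations; with synthetic ages only relative comparisons are
  meaningful.
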
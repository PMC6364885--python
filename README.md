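# cropdiv

Regional crop-diversity time-series analysis for area-harvested panels.

Agricultural statistics such as the FAO's report, per region and calendar
year, the area harvested (ha) of each crop *commodity group*. Treating each
region-year as an ecological "community" with area harvested as the
abundance proxy, this package quantifies how the taxonomic and evolutionary
diversity of cropland has changed over the past half-century within regions
(α-diversity), when and how fast those changes happened (breakpoint
analysis), and whether regions have grown more similar to one another over
time (β-diversity / homogenization).

## What it computes

**α-diversity per region-year**

- species richness *SR* (count of commodity groups present);
- Gini-Simpson diversity *S_D* = 1 − Σᵢ pᵢ², with pᵢ the area proportion
  of group *i*;
- Faith's phylogenetic diversity *PD*: the branch-length sum (millions of
  years, My) of the minimal root-spanning subtree of the crop species
  present;
- Rao's quadratic entropy *QE_phy* = Σᵢ Σ_{j≠i} d_ij pᵢ pⱼ, with d_ij the
  patristic distance between species *i* and *j*.

Because a commodity group can map to several species while reporting one
area, *PD* and *QE_phy* resolve each group to a single randomly drawn
candidate species; values are medians over replicate draws (default 100).
The crop tree is dated from a node-age table by even interpolation of
undated nodes (branch-length adjustment, Phylocom "ages" dialect).

**Temporal change.** Each diversity series D(year) is fitted with six
candidate models — linear, two-breakpoint piecewise linear, quadratic,
unimodal, asymptotic, and four-parameter logistic — and ranked by AIC.
The piecewise family

D = a + b·year + c·(year − ψ₁)·I(year > ψ₁) + d·(year − ψ₂)·I(year > ψ₂)

is estimated by iterative linearization with a quantile grid of starting
breakpoints, then summarized by a 500-replicate case bootstrap (medians of
all parameters, AIC, and r²). Three indicators are derived per region and
metric: the onset of change (ψ₁), its duration (ψ₂ − ψ₁), and the
post-onset rate (b + c). Onsets are compared across metrics by OLS plus a
joint F-test of {intercept = 0, slope = 1} against a 1:1 line.

**β-diversity.** Bray-Curtis dissimilarity BC_jk = Σᵢ|x_ij − x_ik| /
Σᵢ(x_ij + x_ik) among all region-year communities; nonmetric
multidimensional scaling (Kruskal stress-1, best of restarts); a
permutational multivariate ANOVA partitioning the Gower-centered squared
dissimilarities by region, year (numeric), and their interaction with
sequential sums of squares; and the within-year pairwise dissimilarity
trend through time (negative slope ⇒ homogenization).

A first-class synthetic-data generator (`cropdiv.synthetic_data`) produces
panels, trees, age tables, and group→species mappings with known ground
truth, so every stage is testable without external data.

## Worked example

```python
import numpy as np
from cropdiv import ScenarioSpec, generate_panel, fit_piecewise2, select_model
from cropdiv.alpha_diversity import taxonomic_series

spec = ScenarioSpec(
    n_regions=1, noise_sd=1.0, truncated_region=False,
    trajectories=[dict(a=30.0, b=0.0, c=2.0, d=-2.0, psi1=1980.0, psi2=1990.0)],
    seed=7,
)
panel = generate_panel(spec).panel
sr, _ = taxonomic_series(panel, "region00")

best = select_model(sr).best
fit = fit_piecewise2(sr)
print(best.family, round(fit.psi1, 2), round(fit.psi2, 2),
      [round(s, 2) for s in fit.segment_slopes])
```

prints

```
piecewise2 1979.82 1990.52 [0.01, 2.0, -0.08]
```

i.e. on a region whose richness is flat at 30 groups, rises by 2
groups/year over 1980–1990, and then levels off (plus 1-group noise), the
two-breakpoint model is AIC-selected and recovers the onset at 1979.8, the
second breakpoint at 1990.5, and segment slopes of ~0, ~2, and ~0
groups/year.

The same analysis runs from the shell:

```bash
cropdiv simulate --seed 7 --out sim/
cropdiv alpha --panel sim/panel.csv --mapping sim/mapping.csv \
              --tree sim/tree.nwk --ages sim/ages.txt --seed 7 --out out/
cropdiv beta  --panel sim/panel.csv --seed 7 --out out/
```

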
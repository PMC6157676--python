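# charcomp

Compositing of sedimentary charcoal records: a tested pipeline for turning
heterogeneous lake- and peat-core charcoal series into comparable regional
biomass-burning curves, with biome-based site selection, bootstrap
confidence bands, and trend/changepoint inference.

## The problem

Charcoal that accumulates in sediments is a proxy for biomass burned, but
*absolute* charcoal quantities are incomparable across sites: basin size,
topography, vegetation productivity and laboratory protocol all set a
record's scale. Compilation studies therefore work with *relative* changes:
each record is standardized to Z-scores and many records are pooled into a
composite curve. `charcomp` implements that whole workflow:

1. **Standardization** (per record): min-max rescale to [0, 1], add a small
   positive shift, Box-Cox transform `y = (x^λ − 1)/λ` (λ fitted per record
   by profile-likelihood grid search on [−2, 2] step 0.01), then Z-score
   `z = (y − m)/s` with moments `m, s` taken from a **base period** of
   12,000–250 cal yr BP (excluding the industrial era), and finally
   averaging into regular 20-yr age bins. Every stage is strictly
   monotone, so within-record ranks survive exactly.
2. **Compositing**: binned points from all selected sites are pooled and
   smoothed with a tricube-weighted local-linear fit of fixed 250-yr
   half-window. 95% confidence bands come from a bootstrap whose
   resampling unit is the *site* (records redrawn with replacement,
   composite rebuilt per replicate, pointwise percentile envelope).
3. **Site selection**: sites are classified under named biome schemes —
   regular lon/lat grids of class codes (Esri ASCII-grid text rasters) or
   contributor-label maps — and a "grassland" subset is the sites whose
   class falls in the scheme's target set. Scheme agreement is reported as
   pairwise Jaccard fractions.
4. **Inference**: Spearman rank correlation of the composite against
   calendar time (ρ > 0 = burning increases toward the present), and exact
   penalized mean-shift segmentation
   `Σ SSE(segment)/σ̂² + penalty·(#changepoints)` solved by dynamic
   programming, with a brute-force enumeration oracle for verification.
5. **Synthetic data**: a generator that draws irregular, zero-inflated,
   lognormal charcoal records around a known burning trend, so every stage
   above is testable against ground truth without any external database.

## Worked example

Simulate 40 sites whose burning jumps by +1 Z at 4,000 cal yr BP, build a
bootstrap composite, and test it:

```bash
charcomp simulate --n-sites 40 --trend step:4000:1 --noise-sd 0.3 --seed 4 --out demo
charcomp composite --charcoal demo/charcoal.csv --sites demo/sites.csv \
    --bin-width 50 --n-boot 500 --seed 4 --out demo/composite.csv
charcomp trend --composite demo/composite.csv
charcomp changepoint --composite demo/composite.csv --max-cp 3
```

prints

```
wrote 40 records to demo
composite over 40 records (0 degenerate dropped) -> demo/composite.csv
rho=0.596 p=1.92e-24 n=240
change at 9450 cal yr BP: -0.471 -> -0.566
change at 4150 cal yr BP: -0.566 -> +0.148
change at 3900 cal yr BP: +0.148 -> +0.891
```

Reading the output: ρ = 0.596 with a tiny p-value says composite burning
increases toward the present over the 240 defined composite ages, as it
must for a positive step. The segmentation brackets the true step with
boundaries at 4,150 and 3,900 cal yr BP — the 250-yr smoothing window
turns a sharp step into a short ramp, which a mean-shift model crosses in
two hops — plus one small early-Holocene shift. The composite CSV holds
`age, mean_z, ci_low, ci_high, n_sites` per 50-yr bin.

The same analysis runs from a single YAML config (`charcomp run --config
run.yaml`) covering multiple biome schemes and subsets (all sites, a
scheme's grassland sites, its forest complement, single continents), and
writes composites, a trend table, a changepoint table, Hovmoller
site-by-time band matrices and a reproducibility manifest per run.

## Layout

- `charcomp.io` — CSV readers/writers, record canonicalization, validation
- `charcomp.biomes` — biome grids/schemes, site selection, scheme overlap
- `charcomp.transform` — the standardization chain
- `charcomp.composite` — smoothing, composites, bootstrap bands
- `charcomp.trends` — Spearman trend test, changepoint DP + oracle
- `charcomp.hovmoller` — Z-score band matrices
- `charcomp.synthetic` — the ground-truth generator
- `charcomp.experiments` — recovery/calibration experiment drivers
- `charcomp.pipeline`, `charcomp.cli` — config-driven runs and the CLI

See `docs/methods.md` for the statistical details and design rationale.
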
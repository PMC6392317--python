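# Methods

## Exposure model

The package evaluates chronic oral exposure with the point-estimate intake
equation

    ADI = Mc · IR · CF · EF · ED / (BW · ATn)        [mg/kg·day]

| symbol | meaning | unit | default |
|---|---|---|---|
| Mc | contaminant concentration in the drink | mg/kg | from panel |
| IR | ingestion rate | g/day | 78.54 |
| CF | gram→kilogram conversion inside the equation | – | 10⁻³ |
| EF | exposure frequency | day/year | 240 |
| ED | exposure duration | year | 43.65 |
| BW | body weight | kg | 60 |
| ATn | averaging time | day | 21 407 |

The defaults describe an adult consuming 2.5 × 100 mL sachets of 40% (v/v)
spirit on 5 days/week from age 15 over a 58.65-year life expectancy:
IR = 2.5 · 100 mL · 0.40 · 0.7854 g/mL = 78.54 g of ethanol per day,
ED = 58.65 − 15 = 43.65 years (15 932 days), ATn = 365 · 58.65 ≈ 21 407
days.  ED is carried in years and ATn in days deliberately — the published
parameterisation uses exactly those units and the equation is evaluated as
printed, so the dimensional asymmetry is part of the reproduced arithmetic,
not an oversight.

Metal concentrations arrive in μg/L and convert to Mc via 10⁻³ and a drink
density that defaults to 1 kg/L (μg/L ≡ μg/kg), the conventional treatment
for aqueous spirits.  The density is a real field and can be overridden.

### Ethanol conventions

Ethanol is an analyte like any other, but two conventions interact:

- **Mc convention** (`mass_fraction`, default): abv % v/v is equated with
  % w/w, Mc = abv/100 · 10⁶ mg/kg, so 40% → 400 000 mg/kg.  A `table`
  alternative (Mc = abv · 100) exists because that figure also circulates
  in print, but it is mutually inconsistent with the intake value it
  accompanies; `mass_fraction` is the convention that reproduces
  ADI = 256 mg/kg·day with the defaults above.
- **Pathway mode**: in mode `published` (default) the equation is evaluated
  verbatim with the ethanol-mass ingestion rate *and* the mass-fraction
  Mc.  Read strictly, that applies the 40% factor twice; mode `strict`
  divides the ethanol Mc by abv/100 so the ingestion rate is interpreted
  once, as drink mass, giving ≈ 2.5× larger ethanol intakes (≈ 640
  mg/kg·day at the defaults).  Default is `published` — reproducibility first,
  the physically strict reading one switch away — and the mode is recorded
  in every run manifest.

### Risk quantities

THQ = ADI/RfD per analyte; HI = Σ THQ per brand assuming additive mixture
toxicity; CR = Σ ADI · CSF over analytes with a slope factor.  Analytes
without an RfD propagate as *missing*, never as zero, and every report
lists them — "no reference value" must stay distinguishable from "no
risk".  HI bands: safe (< 1), concern (1–5), high (≥ 5).  The "1 in x"
ratio uses x = round(1/HI); published tables of this kind contain rows
whose printed ratio is inconsistent with their printed HI under any fixed
rounding, so the nearest-integer rule is fixed here and documented rather
than fitted row by row.

The shipped toxicity table uses public US EPA oral reference doses
(IRIS/PPRTV/HEAST), with two study conventions carried explicitly: ethanol
RfD 62 mg/kg·day and Pb RfD 1.5 mg/kg·day (no established oral RfD).
Slope factors: As 1.5, Cr(VI) 0.5, Pb 0.0085 (mg/kg·day)⁻¹.  Each row has
a provenance string and users can substitute their own table.

## Non-detects

Levels below the per-analyte method detection limit are flagged censored
and substituted under an explicit policy: `zero` (default), `half_mdl` or
`mdl`.  The three bracket the unknown true value; every downstream
ADI/THQ/HI value is monotone non-decreasing along that ordering, which the
suite tests end-to-end.  Zero is the default because it reproduces
summary tables in which non-detects appear as 0.0; it is the
anti-conservative bound, and sensitivity to the choice is one rerun away.
The applied policy is recorded in the panel provenance and the run
manifest.

## Descriptive layer

Quartiles use linear interpolation between order statistics at position
p(n−1) (the "inclusive" spreadsheet convention) by default; the method is
a recorded option because survey reports rarely state theirs.  SD is the
sample standard deviation (n−1).  The outlier rule is mean > 2·IQR,
strict inequality.  Composition shares are reported per brand (rows sum
to 100%) and against the grand total; all-zero brands are reported as
missing, not 0%.  Percentages are rounded only at the reporting layer.

## Cluster analysis

Risk-profile clustering operates on the row-percent-transformed THQ
matrix — the transform stops one dominant analyte (copper in artisanal
spirits) from swamping the geometry — with configurable exclusions
defaulting to Cu and ethanol for the metal-profile view.  Distances are
squared Euclidean; linkage is Ward's minimum-variance criterion via the
Lance–Williams recurrence, implemented from scratch and cross-checked in
the tests against both a brute-force greedy ΔESS oracle (all instances up
to 7 items) and scipy (whose Ward heights on Euclidean input are the
square roots of the Lance–Williams heights on squared input).

Numerical conventions:

- merge heights are the Lance–Williams distances themselves (not variance
  increments ×2); with squared Euclidean input Ward admits no inversions,
  so heights are non-decreasing;
- ties on merge cost break on the lexicographically smallest pair of
  smallest leaf indices, making runs platform-reproducible;
- `cut_tree(h)` takes connected components of merges strictly below h;
  `cut_tree_k` applies the first n−k merges, robust to tied heights;
- the cophenetic correlation is the Pearson correlation between the
  n(n−1)/2 original and cophenetic distances; it is reported as missing
  for constant distance vectors.  A tree scored against its own
  ultrametric correlates exactly 1; note that *re-agglomerating* an
  ultrametric with Ward preserves the topology but inflates the heights
  (the update strictly increases equal surrounding distances), so only
  the topology is a fixed point;
- no column standardization is applied beyond the row-percent transform.

Split-half stability follows the randomization scheme of assigning each
item a random integer in [1, 5000], sorting, and halving the order; each
half is re-clustered and compared with the full solution restricted to
that half by pairwise co-membership (Rand-style) agreement.  Each half is
cut into as many clusters as the full solution has represented within it,
so a half that happens to sample a single cluster is not forced to split.
The agreement statistic is this package's choice; the procedure it
validates only asks whether similar structures recur.

## Synthetic data generator

The generator emulates the data layout and the three structural features
the analysis keys on: (1) log-normal trace-metal marginals with locations
calibrated to published per-metal medians (σ = 0.6; metals whose median
prints as 0.0 get a near-detection-limit baseline, so they are present
but frequently censored); (2) a class of artisanal brands whose copper —
leached from copper condensation tubing — is planted directly as a share
of the brand's metal total drawn uniformly from 92–100%.  Share
conditioning, rather than a multiplicative Cu boost, is used because the
share band is the class signature: a noisy multiplicative boost cannot
guarantee copper exceeds all other metals combined in every draw, while
observed artisanal brands sit as low as 1230 μg/L Cu and still at 92%.
A multiplicative `artisanal_cu_boost` remains available (and serves as
the negative control at boost 1); (3) one outlier brand, boosted 10×
across all analytes at 20% v/v, mirroring a brand contaminated in nearly
every metal studied.  Duplicate-measurement noise is multiplicative with
CV 0.1 and per-cell SDs of CV × level; censoring applies at per-analyte
MDLs near the instrument's lowest calibration points.  Defaults: 13
industrial (one of them the outlier) + 4 artisanal brands, 20 metals +
ethanol at 40% v/v.

What it does **not** emulate: instrument drift, isobaric interference and
calibration error; correlated contamination across metals within a
production process (marginals are independent given class); brand-level
abv variation; the reference-whisky class (a Scotch control with ~76% Cu
would sit between the planted classes).  Passing planted-recovery tests
therefore shows the pipeline resolves class structure of the planted
kind and strength, not that it would resolve arbitrary real surveys.

Parameter recovery estimates each metal's log-location from the
industrial, uncensored cells only (the artisanal Cu and outlier shifts
are planted effects, not baseline) and reports bias, its standard error,
CI coverage and censoring fraction.

## Problem sizes

The test suite runs the brute-force Ward oracle over 250 random instances
of ≤ 7 items, planted-structure recovery over 100 seeded 17 × 21 panels,
and parameter recovery over 200 replicates of 50-brand panels; the whole
suite completes in well under a minute on a single core.  Sizes were
chosen to make the binomial pass criteria (≥ 95% recovery) statistically
meaningful while keeping the suite quick.

## Known limitations

- Deterministic point estimates only; no probabilistic (Monte Carlo)
  exposure assessment, and no dermal or inhalation routes.
- Additive HI ignores synergistic or antagonistic mixture effects, and
  bioaccumulation kinetics are out of scope.
- CR covers only the three analytes with slope factors; for genotoxic
  carcinogens no level is truly safe, so CR is a lower bound on concern.
- The `published` ethanol pathway intentionally reproduces a published
  double-counting; quantitative ethanol risk work should use `strict`.
- Left-censored values are substituted, not modelled; no maximum
  likelihood for censored log-normals.
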
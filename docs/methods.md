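# Methods

`crossflux` harmonizes heterogeneous literature measurements of ecosystem
carbon fluxes and cross-ecosystem material flows into one canonical unit —
gC per m² of the *recipient* ecosystem per year — and computes the
descriptive and inferential summaries that such a synthesis rests on. This
note documents the models, the conversion rules, the statistical procedures,
the synthetic-data generator, and the numerical and design choices behind
them.

## 1. Canonical units and the harmonization chain

Local fluxes (GPP, ecosystem respiration, NEP, secondary production,
decomposition flux) and spatial flows are expressed in gC m⁻² yr⁻¹;
detritus stocks in gC m⁻²; decomposition rate constants in yr⁻¹. A raw
record reaches canonical form through four multiplicative steps, applied in
order; every applied step is appended to the record's audit trail as
(step, multiplier, rule), so raw value × Π multipliers equals the output
exactly and every published number is traceable.

**Carbon conversion.** A study-reported carbon fraction takes precedence.
Otherwise the most specific factor from the (material class × mass basis)
table applies, falling back to the generic column. Shipped defaults: dry
weight 0.5 gC/g, ash-free dry weight 0.5 gC/g, wet weight 0.1 gC/g, carbon
exactly 1 — deliberately parsimonious round values, isolated in the config
so per-material factors can be dropped in without touching code.
Decomposition rates are *not* carbon-converted: a first-order loss rate is
taken to equal the carbon loss rate in whatever mass basis it was measured
(the most parsimonious assumption; anything else would need litter-specific
carbon dynamics the sources do not report).

**Volume → area.** Per-m³ values are integrated over the water column:
lake depth = volume / area (or a reported mean depth); river depth from the
hydraulic-geometry power law depth = c·Q^f with c = 0.2, f = 0.4 and Q the
discharge in m³ s⁻¹, with a 5 cm floor for catchments under 1 km²; marine
values integrate over the reported euphotic depth (e.g. Secchi-derived,
taken verbatim — no light-extinction transform) and over 100 m when only
sampling depths exist.

**Shoreline re-expression.** Lateral aquatic→terrestrial flows reported per
m² of donor waterbody are converted to per-m-shoreline — lakes: × area /
perimeter, the perimeter approximated by 2·D_L·√(area·π) when unmeasured
(D_L the shoreline development factor, defaulting to 1 = circular and
flagged in the audit as an assumption); streams: × width / 2 (two
riversides) — then spread uniformly over a recipient band along the shore,
10 m wide by default, 100 m for the conservative sensitivity run. Whole-lake
totals are first divided by lake area, reach totals by width × length. The
chain conserves carbon exactly: per-band flow × perimeter × band width =
per-donor-m² flow × donor area. Vertical pelagic→benthic flows and
terrestrial-donor flows keep their areal value (donor and recipient areas
coincide). The band width lives in the run configuration (CLI
`--band-width`) rather than on per-record geometry: the 10 vs 100 m
sensitivity contrast is a property of a run, not of a record.

**Annualization.** Per-day values scale by the climate's growing-season
length (GSL): temperate 181 d, boreal 155 d, arctic/alpine 116 d, arid
163 d, tropical 365 d. A study period shorter than the GSL is scaled up to
the GSL; between the GSL and 365 d it is taken as the annual value
unchanged; beyond 365 d it is scaled down by 365/days so totals are
conserved (the last rule is this package's choice — the convention sources
leave the >1 yr case unstated). NEP annualizes like any other flux; no
special sign rule is applied. Decomposition rates annualize by the same GSL
convention.

All steps are linear in the value, so harmonization is homogeneous
(harmonize(αx) = α·harmonize(x)) and idempotent; both are enforced as
property tests over randomized heterogeneous records.

## 2. Decomposition model

Detrital mass follows first-order decay, D_t = D_t0·e^(−k(t−t0)). The
decomposition flux over a horizon t from a stock D_M is
D_F = D_M·(1 − e^(−kt)); when a study reports detritus production D_P,
export E and the flux, the rate inverts as
k = −ln(1 − D_F/(D_P − E))/t, with E defaulting to 0 when unreported
(which can only underestimate k). Two-point litter-bag data invert as
k = −ln(D_t/D_t0)/t; complete mass loss raises an infinite-rate flag rather
than producing a number. Implementation uses `expm1`/`log1p`, keeping the
round-trip k → D_F → k accurate to 10⁻¹⁰ relative error over
k·t ∈ [10⁻⁴, 10].

Stratum-level derived fluxes: within each ecosystem × climatic-zone
combination, D_M is the median of the harmonized detritus stocks (standard
midpoint rule for even counts) and each literature rate yields one derived
flux via the decay formula with t = 1 yr — the annual canonical unit fixes
the horizon. Derived records carry provenance naming the stock median, its
sample size, and the source-rate record. Strata with rates but no stocks
are skipped with a warning.

## 3. Metabolism closure and NEP statistics

The identities NEP = GPP − R_e, NEP = NPP − R_h, NPP = GPP − R_a are closed
to a fixpoint whenever two members of an identity are known;
over-determined triplets are checked at 10⁻⁶ relative tolerance (floored at
magnitude 1) and flagged with their residual rather than silently averaged.

Per-ecosystem NEP is tested against zero with a classical two-sided
one-sample t-test (95% CI = mean ± t₀.₉₇₅,ₙ₋₁·se). The heterotrophy
probability p⁺ = Φ(mean/sd) uses the *sample standard deviation*, not the
standard error: it describes the probability that a random NEP observation
from that ecosystem type is positive under a normal fit to the data, not
the sampling uncertainty of the mean. Zero-variance samples return a
degenerate flag with p⁺ ∈ {0, ½, 1} by the sign of the mean.

Variance heterogeneity across ecosystems is documented with Bartlett's test
(groups with n < 2 excluded with a warning), which motivates the
nonparametric path: a tie-corrected Kruskal–Wallis rank test (df = groups −
1, χ² tail probability; identical samples give χ² = 0). Post-hoc pairwise
comparisons use the Siegel–Castellan critical difference on mean ranks,

|R̄ᵢ − R̄ⱼ| ≥ z₁₋α/(K(K−1)) · √( N(N+1)/12 · (1/nᵢ + 1/nⱼ) ),

at family α = 0.05, compressed to a compact letter display by the standard
insert-and-absorb algorithm (groups sharing any letter do not differ
significantly). The partition is invariant to input order; letters are
assigned in group enumeration order for reproducibility. Tests verify the
letter display directly against the hand-evaluated inequality and verify
the Kruskal–Wallis statistic against an independent brute-force ranking
implementation on all small fixtures.

## 4. Descriptive synthesis

Grouped summaries report n, median, quartiles and range per stratum;
quartiles use linear interpolation between order statistics (numpy's
default) — the convention is documented because nearest-rank quartiles can
differ by up to ~2% at n ≥ 100, which matters when comparing against
published IQRs. Values are kept at full precision; rounding to one decimal
is display-only. Ecosystems are pooled across climatic zones for reporting
(climate remains an optional grouping key, with marine climates pooled to
Cold = arctic/alpine + boreal + temperate and Warm = arid + tropical).
Spatial-versus-local comparisons report the log₁₀ ratio of medians per
(recipient ecosystem, local flux class, spatial origin), undefined-but-
retained when a median is nonpositive. Driver and interface tabulations
count spatial flows by driver category (passive: fall/wind, leaching,
currents/tides, sinking; active: foraging, migration, life cycle) and by
unordered donor–recipient domain pair (terrestrial, freshwater, pelagic,
benthic); percentages sum to 100 exactly before display rounding. The band
sensitivity analysis re-harmonizes the raw records under 10 m and 100 m
bands and pairs the per-stratum medians, splitting each stratum by whether
its records were band-routed: routed groups scale exactly by the width
ratio (all steps are linear), unrouted groups are bit-identical.

## 5. Synthetic-data generator

The generator emulates a compiled cross-ecosystem carbon dataset with known
ground truth. Positive fluxes are drawn log-normally with the stratum's
target median as log-scale median — the natural choice for flux data whose
pooled values span many orders of magnitude and are summarized by medians —
and NEP is drawn normally per ecosystem, matching the normality assumption
behind p⁺. Each drawn canonical value is then *de-harmonized*: the
generator samples a raw-unit variant (carbon vs dry vs ash-free dry mass;
per day / study period / year; per m³, per m² donor, per m shoreline, per
lake, per reach) plus the geometry needed to undo it, and inverts the
harmonization steps using the same conversion table, GSL values, and
geometry constants the harmonizer will apply. Exact inversion —
harmonize(generate(·)) equals the intended canonical value to < 10⁻⁹
relative error, record by record — is an enforced invariant, and the
log-median estimator is checked to be unbiased within Monte-Carlo error
over seeded replicates (mean log-median error < 5% at n = 200 per stratum).
A single integer seed drives all sampling; identical seeds give identical
datasets.

The default configuration plants the study conditions of the global
synthesis this package supports: 518 spatial flows and 2516 local fluxes
(3034 records); pooled spatial-flow medians of 148.7 gC m⁻² yr⁻¹ for
terrestrial plant material, 164 for macroalgae, 1.51 for invertebrates
(the typical-insect stratum median, 1.83, is set analytically so the
*mixture* of insect strata — milligram-scale deposition into forests,
lake-to-tundra flows around 124, and typical flows — pools to 1.51);
bimodal vertebrate flows (0.1–1 versus 100–1000); stream/grassland GPP
medians 55.2/611.5 with IQR-derived log spreads; NEP means and sds derived
per ecosystem from the published median/IQR where available (stream
−114.1, IQR-derived sd 281.4; ocean benthic −4.1) and from the published
95% CI otherwise (forest mean 252.5, sd 244.5 at n = 100, etc.); stratum
counts that reproduce the interface shares (66.8% terrestrial–freshwater —
518 records cannot hit 66.9% exactly — and 18.0% pelagic–benthic), the
70.5% passive-driver share, the 3.1% vertebrate share, and a Kruskal–Wallis
design of 540 NEP values over 8 ecosystems. Unit-mix proportions mirror the
compiled data (about half the records already in carbon units, 55% already
annual, ~21% of lateral flows per m² donor).

**What the generator does not emulate.** Real compiled data are skewed
beyond lognormality within categories (the synthetic spatial flows span
~6.5 orders of magnitude versus the published eight), NEP distributions are
skewed rather than normal (so a normal planting cannot match a published
mean CI and a published median simultaneously — each downstream quantity is
planted from the published number *for that quantity*), and measurements
within a study are correlated whereas the generator draws independently.
Consequently, passing tests demonstrate that the pipeline's arithmetic,
routing, and statistics are correct and that planted conditions are
recovered — not that the package reproduces the real compiled dataset,
which has no public accession. Rank-based statistics feel the lighter
tails: the synthetic Kruskal–Wallis χ² lands near 150–180 rather than the
published 275, with identical qualitative outcome (P < 0.001, df = 7).

## 6. Numerical choices and degenerate inputs

- Quantiles: linear interpolation; medians of stocks: `statistics.median`.
- Floats serialize as `%.17g`, so table round-trips are bit-exact.
- `expm1`/`log1p` guard the small-k·t decay regime.
- Degenerate statistics: zero-variance t-test → degenerate flag; identical
  KW samples → χ² = 0, p = 1; single post-hoc group → letter "a"; empty
  groups excluded with warnings, never silently.
- Validation errors name the offending row or record id; non-strict reads
  skip and report rejected rows deterministically.
- Problem sizes: the test suite runs the full 3034-record conditions where
  counts matter and proportionally scaled datasets (minimum one record per
  stratum) elsewhere; the acceptance script averages sampled statistics
  over 12 replicate generations (medians on the log scale) so reported
  values estimate the planted population quantity rather than one draw.

## 7. Known limitations

- Carbon fractions default to two-value parsimony (0.5 dry / 0.1 wet);
  per-material factors must be supplied via config for serious use.
- The euphotic-depth integration takes the reported depth verbatim.
- No distance-decay model of subsidy deposition: the recipient band is
  uniform by construction (the 100 m run bounds the sensitivity).
- No multi-pool decay models and no litter-bag time-series fitting beyond
  the two-point inversion.
- No study-level random effects: measurements pool as independent values.
- Free-text units are out of scope; inputs must be pre-mapped to the
  controlled vocabulary (see `docs/column_dictionary.md`).
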
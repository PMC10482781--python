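# Methods

## Data model

Every measurement is one record: sample id, site, sampling month (`YYYY-MM`, since
field campaigns sample by session), compartment (`soil_bearing`, `soil_free`,
`stipe`, `cap`, `sporophore`, or `fb_bulk` for published whole-body columns),
element symbol, and either a concentration in mg kg⁻¹ dry matter or a
below-detection flag with a positive detection limit. Censoring is encoded as the
literal `bdl` token in CSV value cells plus a separate detection-limit column,
mirroring how geochemical tables are printed while keeping numeric cells numeric.
The element registry defaults to the 33 ICP-OES elements of the packaged study but
is a plain tuple the caller can extend; units are fixed at mg kg⁻¹ DM for all
compartments (weight-percent display is a ×10⁴ formatting concern only).

Detection limits are published only as ranges per element group (e.g. 0.15–0.35
mg kg⁻¹ for As, P, Pb, S, Sb, Se, Sn, W). The packaged per-element limits take one
representative value inside each range (0.20, 0.06, 0.02, 0.002 for the four
groups); they are fixture choices, not measured values.

## Composition

Bulk fruiting-body concentration is the dry-mass-weighted mean of the three part
concentrations. Part weight fractions must sum to 1 within ±0.02 and are
renormalised to sum exactly to 1 before weighting; the aggregate is therefore a
convex combination (bounded by the part extremes) and scales linearly with the
parts. The published part percentages are assumed to be fractions of **dry** mass,
consistent with concentrations on a DM basis; the alternative (fresh-mass
fractions) is not supported. With a censored part the bulk is not calculable by
default; an optional policy substitutes zero and flags the result as a lower
bound.

Group summaries report the mean and sample SD (n−1 denominator; switchable via
`ddof`) over uncensored values. Censored members are omitted-with-count by
default — published tables print `bdl` in mean cells, implying omission — with
DL/2 and DL substitution available as alternatives. Single-member groups report
SD 0 with n = 1.

## Factors

BF = C_M/C_S and TF = C_upper/C_lower are plain concentration ratios on the DM
basis, reported unrounded; display rounding (two decimals) belongs to the
reporting layer. Classification thresholds are strict (> 1), so a ratio of
exactly 1 is excluder/immobile. The substrate for BF defaults to the
mushroom-bearing soil — the soil the mycelium actually draws from — with the
mushroom-free column or the pair mean selectable, since summary-level data cannot
settle which a given publication used. A censored substrate makes the factor
not-calculable (the selenium case: enriched in every fruiting body but below
detection in every soil, so no BF_Se exists); a censored mushroom value is
not-calculable by default or, in upper-bound mode, evaluated at the detection
limit and flagged as a bound.

The translocation profile is a total four-way rule on the calculable TF pair:
apical (both > 1), cap (cap/stipe > 1 ≥ spor/cap), stipe (both ≤ 1), erratic
otherwise or when a TF is not calculable.

## Paired soil statistics

Pairs are matched by sample id (one id carries both soil compartments of one
site-date collection); all sites pool by default with a per-site option, because
group sizes used by summary-level publications are not recoverable. Per-pair
depletion is (free − bearing)/free · 100. What exactly was correlated to produce
published r values of 0.97–0.999 is likewise not recoverable from a summary
table; this module correlates bearing vs free concentrations across pairs per
element — the only pairing the data support — and exposes the thresholds
(r ≥ 0.95, α = 0.01, two-sided) in the API. No multiple-testing correction is
applied by default.

Pearson's r delegates to `scipy.stats.pearsonr` (identical to the t transform
t = r√((n−2)/(1−r²)) with n−2 df) and requires n ≥ 3 with nonzero variance.

The Mann–Whitney test is implemented in-package because its exact small-sample
form with ties is the primitive the paired design needs: U = min(U_a, U_b) from
midranks; for pooled n ≤ 20 the two-sided p enumerates all C(n_a+n_b, n_a)
assignments of the observed values and counts those with
|U − n_a n_b/2| ≥ |U_obs − n_a n_b/2| (a 1e−9 float guard absorbs midrank
round-off), so tied data are exact, not approximated. Beyond n = 20 a normal
approximation with the standard tie-corrected variance and a 0.5 continuity
correction is used; the test suite checks it against the enumeration path at
8 + 8 and against `scipy.stats.mannwhitneyu` where the definitions coincide
(tie-free exact, and asymptotic with ties).

## Mass balance

Affected soil mass: π(d/2)²h·SG for the default 11 × 11 cm cylinder at
2.70 g cm⁻³ gives 2.822 kg. The published mass-balance table, however, is built
on 2.77 kg, which the stated geometry does not yield; the default configuration
therefore sets `soil_mass_override_kg = 2.77` so the table is reproducible, and
logs the geometric value whenever the two disagree. Geometry is a parameter, not
a constant: a cuboid option (d²h) demonstrates that the assumed shape shifts the
mass by only ~27 %, which cancels entirely in the depletion and uptake
percentages (both are ratios of stocks).

The chain per element is: stock = concentration × soil mass (mg); difference =
free − bearing stocks; depletion % = difference/stock_free · 100; fruiting-body
amount = concentration × 10 g DM; uptake % = fb amount/difference · 100 (not
calculable, flagged "no net depletion", when the difference is ≤ 0). All
arithmetic is unrounded internally; every result carries raw and display values.

**Reported-amounts mode.** Published stock columns are computed from unrounded
concentrations, so printed-concentration × soil-mass does not always land on the
printed stock (e.g. 0.73 × 2.77 = 2.02 against a printed 2.01), and one printed
difference (Rb: 130 vs 620 − 485) disagrees with its own stocks. When a dataset
carries reported amount columns — the packaged mass-balance fixture does — they
are treated as the authoritative stocks and differences and only the downstream
chain is recomputed; `use_reported=False` forces the fully-computed path. This is
a fidelity choice, not a numerical one: the reported columns are the
higher-precision record of the original arithmetic.

**Display rounding.** |x| < 1 → 2 significant figures, 1 ≤ |x| < 100 → 3,
|x| ≥ 100 → 2 (Python half-to-even); depletion to the integer percent, uptake
fraction to one decimal. Values taken from reported columns pass through
unchanged. This bands-by-magnitude rule reproduces the apparent conventions of
published amount columns (0.0219 → 0.022, 10.25 → 10.2, 222.45 → 220,
623.25 → 620); it is a display layer only.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
lognormal soil concentrations (positive, right-skewed — printed SDs approach the
means, so a truncated-normal would censor mass at zero), a multiplicative
depletion effect on the bearing soil, part-wise translocation gradients, and
censoring applied after noise, as a detector would.

Scenario medians parameterise the substrate (mushroom-bearing) level, matching
how soil tables are printed; the free-soil base is median/effect, free soil is
drawn lognormally around it, and bearing = free × effect × ε with ε a
**mean-one** lognormal (μ = −σ²/2). Mean-one (rather than median-one) pairing
noise makes E[bearing/free] exactly the effect, so the pipeline's mean per-pair
depletion estimator is unbiased for 100(1 − effect) by construction — the
recovery tests verify this to within Monte-Carlo error rather than assuming it.
Part concentrations derive from the bearing soil: the stipe base is
soil × bf_target/(w_s + w_c g₁ + w_sp g₁g₂), so the weight-averaged bulk targets
`bf_target` × substrate exactly in the noise-free limit, with cap = stipe × g₁
and sporophore = cap × g₂, each part carrying independent mean-one noise
(default geometric SD 1.15; pairing noise 1.05).

Default conditions mirror the field design: 3 sites × 5 sessions (July–September
2021, August–September 2022) × 1 replicate. The study-mimicking scenario reads
its parameters off the packaged tables at run time: substrate medians and
geometric SDs (gSD = e^CV clipped to [1.05, 2.0]) from the bearing-soil columns,
BF targets and gradients as cross-site means from the mushroom table,
depletion effects for Ag, Cd, K, Rb from the mass-balance concentration ratios
(0.66, 0.82, 0.78, 0.86), a mild 0.95 for Al, and 1.0 elsewhere; elements below
detection in soil get DL/2 medians so they generate censored records.

All draws derive from one `numpy.random.default_rng(seed)`; sites and elements
are iterated in sorted order so the draw sequence is independent of dict
insertion order. Reproducibility is bitwise on one platform, best-effort across
platforms.

What passing synthetic tests do **not** show about real data: the generator has
no spatial heterogeneity, no between-element correlation, no seasonal trend, and
its dispersions are back-read from printed means ± SDs, so recovery results
certify the estimators under the assumed lognormal pairing model, not the field
sampling process.

## Numerical and scale choices

Parameter-recovery runs use 200 replicates of the 3-site × 5-date single-element
scenario (15 pairs per replicate), enough for a Monte-Carlo SE below 0.1
percentage points on the depletion estimate and a ±1.4 % binomial band on the
nominal α = 0.01 false-positive rate, while keeping the whole suite fast. The
Mann–Whitney enumeration cap of 20 pooled observations bounds the oracle at
C(20,10) ≈ 1.8 × 10⁵ assignments.

## Known limitations

Per-sample factor bands (e.g. BF ranges across individual collections) and the
published correlation coefficients themselves require per-sample data that
summary tables do not carry; the package reproduces the procedures and validates
them on synthetic data instead. Indirect depletion pathways (organic-acid
exudation, metal–organic complex leaching) and redox-driven Fe/Mn mobility are
outside the model: the mass balance quantifies direct uptake only. No
health-risk indices are computed.
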
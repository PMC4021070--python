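# Methods

## Model

`pedarv` estimates the monthly cost of pediatric antiretroviral regimens
for ages 0.5–13 years in seven stages, mirroring how a costing analyst
would work by hand.

**Band costs.** WHO dosing recommendations assign each drug formulation a
dose per administration in each of seven weight bands (3–5.9, 6–9.9,
10–13.9, 14–19.9, 20–24.9, 25–34.9, 35+ kg). Monthly cost is
`average daily units × unit cost × days-per-month`, with `days-per-month`
a named, configurable constant defaulting to 30.4. Costs are carried
unrounded through the pipeline and rounded half-up to two decimals only at
render time; half-up (commercial) rounding reproduces conventional
presentation such as $34.66 from 34.656, where banker's rounding would
not. Cells marked "NR" (not recommended) or "–" (not dosed) are refused
with a named error rather than priced at zero.

**Weight-for-age.** Growth references are supplied as LMS tables (columns
source, sex, age_months, L, M, S); published WHO (<5 y) and CDC (≥5 y)
charts share this layout, and the `source` column is carried through for
provenance rather than hard-coding the split. The z-score of weight `w` is
`((w/M)^L − 1)/(L·S)` (the log form for |L| < 1e-7, the Box-Cox limit,
where the power form loses all precision to cancellation). LMS parameters
are interpolated linearly in (L, M, S) between bracketing tabulated ages —
the standard practice for LMS charts; whether the original tabulations
were interpolated or read at exact ages is not documented, so exact
reproduction of any particular published probability table is not promised
beyond roughly ±0.01 per cell.

**Population adjustment.** HIV-infected children are lighter on average
than the general population, so the reference distribution is relocated in
z-space: `z_adj = (z − Z)/k`, default `Z = −1.5`, `k = 1`. This makes the
child at reference z = −1.5 the new median while preserving the reference
shape, which is the only reading consistent with converting shifted
boundary z-scores directly to cumulative probabilities. Band probabilities
are differences of standard normal CDFs at the band lower bounds, with
each band's upper integration limit taken as the next band's lower bound
(the printed cut-point pairs 5.9/6.0 etc. otherwise leave slivers), and
the open 35+ band as `1 − Φ(z_adj(35))`. Mass below 3 kg is removed by
renormalizing over the seven bands so rows sum to exactly 1; a row with
essentially no in-band mass raises an error instead of returning silent
zeros. Male and female rows are averaged with equal weight; single-sex
charts (synthetic test charts) are used as-is.

**Age costs.** Drug cost at an age is the dot product of band costs with
band probabilities. Formulation choice within a band is resolved by one of
two strategies: `liquid_first` (syrup while recommended, then pediatric
solid, then adult tablet) or `tablet_first` (pediatric solid as soon as
recommended, falling back to syrup where the solid is NR — necessary for
LPV/r below 10 kg — then adult tablet). Probability mass in bands where a
drug has no recommended formulation contributes zero *without*
renormalization: the alternative (renormalizing over covered bands) is a
different estimand — cost conditional on being dosable — and does not
match how partial recommendations are handled in published cost tables.
EFV's "≥3 years only" condition is a per-drug minimum-age overlay
(`DRUG_MIN_AGE_YEARS`), because an age condition cannot live inside a
weight-band table; below the gate the drug is treated as having no
recommended formulation at any band.

**Regimens and scenarios.** A regimen is an anchor (LPV/r, or NVP
switching to EFV at age 3) plus a two-NRTI backbone; six common first-line
regimens ship as constants. Three availability scenarios: (1) no FDCs,
liquids until 4 years; (2) no FDCs, liquids until 6 months; (3) FDC
tablets from birth, other components as in (2). "Until age X" is strict —
the age-X row itself uses tablets — which makes scenarios 1 and 2 coincide
exactly from age 4. FDC selection is greedy by component-set inclusion:
the largest co-formulation whose components are a subset of the active
regimen is used (triple before dual), remaining components fall back to
single products; matching is exact on component sets, since only the
co-formulations in the dosing table exist. The NVP→EFV switch age and the
EFV age gate are independently configurable; a warning is logged if they
diverge, since a gap would leave children without a recommended anchor.

**Sensitivity.** For each variant adjustment the full age-cost table is
recomputed and summarized as the mean of |percentage change| over all
drug-by-age cells. The absolute mean is used because signed changes of a
shifted distribution partially cancel; the averaging set is isolated in
one function so other conventions are a one-line change. Cells undefined
at baseline (NR or zero) or under the variant are excluded from the mean
and reported as an explicit count, never silently averaged.

**Comparison.** Derived band costs are compared to an external
transaction-price table (pediatric prices quoted for ~10 kg children are
matched to the 6–9.9 and 10–13.9 kg bands; adult prices to 35+ kg), with
absolute and ratio differences; unmatched rows are flagged, not dropped.

## Reference data notes

The packaged price list carries two entries at more precision than a
two-decimal display: NVP 50 mg at $0.045/tab and the ABC/3TC 600/300 mg
low bound at $0.583/tab. Both are back-derived from the corresponding
monthly band costs ($2.74 = 2 × 0.045 × 30.4; $17.72 = 1 × 0.583 × 30.4),
which a display-rounded $0.05/$0.58 cannot reproduce; the display values
round to the conventional two decimals. The ABC/3TC 600/300 price is a
range ($0.583–$1.07), propagated as a cost range throughout.

## Synthetic growth charts

`generate_synthetic_lms` builds deterministic single-sex LMS tables: a
strictly increasing median (default linear 3→40 kg over 0.5–13 years,
roughly the span of real weight-for-age medians), constant L (default 1,
i.e. a normal weight distribution at each age) and CV ≈ 0.12 (typical of
mid-childhood weight SDs) with a small seeded log-normal jitter. These
charts exercise every property the pipeline relies on — normalization,
stochastic dominance in the z-shift, agreement with direct numerical
integration of the implied density — but they are *not* real WHO/CDC
charts: they carry no skewness (L = 1), no sex difference and no
infancy growth spurt. Tests passing on them validate the integration and
costing machinery, not the demographic accuracy of any particular
probability table; analyses of real populations should supply actual
WHO/CDC LMS files via `--lms`. The packaged band-probability table is used
for all downstream costing so that those stages are exact and
chart-independent. The published sensitivity summaries (9.7 % for z-shift
0, 4.2 %/6.4 % for halved/doubled CV) likewise depend on the real charts
and the (undocumented) averaging set, so they are documented checks for
users with chart access rather than test gates; on the synthetic default
chart the same scan yields ≈ 11.9 %, 3.6 % and 4.9 %.

## Numerical choices

- Normal CDF via `scipy.stats.norm`; no approximation.
- Band probability rows are renormalized to sum to 1 within 1e-9 (fixture
  tables printed at 3 decimals are renormalized on load).
- Trapezoid-integration cross-checks cap the open 35+ band at the weight
  whose adjusted z-score is +10, which keeps the grid fine enough for
  1e-6 agreement.
- Band label parsing is exact-string against the seven canonical labels;
  a misspelled band is an error, never a fuzzy match, because silent band
  misassignment corrupts every downstream cost.
- Currency is plain 2012 USD; no FX or inflation handling.

## Problem sizes

The default test-suite and acceptance runs use the packaged tables (30
formulations × 7 bands, 14 ages, 6 regimens × 3 scenarios) and 14-point
synthetic charts with 4001-point integration grids — the full published
problem size; nothing is scaled down.

## Limitations

- Weight-for-age only; no height/BMI, no within-child weight trajectories
  on ART, no catch-up growth.
- Doses are taken as given; no pharmacokinetic or dose-optimization
  modelling.
- Drug product costs only: no procurement, shipping, cold-chain, wastage
  or personnel costs (liquid LPV/r in particular attracts substantial
  cold-chain costs in practice).
- First-line regimens only; no sequencing, adherence or efficacy
  modelling, and no probabilistic sensitivity over prices.
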
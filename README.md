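# pedarv

Monthly antiretroviral (ARV) drug costs for HIV-infected children in
resource-limited settings, estimated from WHO weight-band dosing
recommendations.

Pediatric ART costing is awkward because doses are prescribed by *weight
band* (seven WHO bands from 3–5.9 kg to 35+ kg) while budgets and policy
work in *age*. `pedarv` implements a transparent pipeline for analysts and
program planners that:

1. loads weight-band dosing rules and unit prices (packaged 2010/2013 WHO
   dosing and a 2012 ceiling price list, or user-supplied CSVs);
2. computes monthly cost per formulation and band as
   `daily dose × unit cost × 30.4 days/month`;
3. converts weight to age with LMS (Box-Cox) growth references: for weight
   `w` with parameters (L, M, S), `z = ((w/M)^L − 1)/(L·S)`; the
   distribution is relocated for HIV-infected children by
   `z_adj = (z − Z)/k` with default shift `Z = −1.5` and CV multiplier
   `k = 1`, and band probabilities are differences of normal CDFs at the
   band bounds, renormalized over the seven bands;
4. weights band costs by those probabilities to get drug cost by age, under
   two formulation strategies (keep syrups while recommended vs adopt
   pediatric tablets as soon as recommended);
5. composes three-drug regimen costs (LPV/r- or NVP/EFV-anchored with an
   NRTI backbone) under three availability scenarios: no fixed-dose
   combinations with a liquid-to-tablet switch at 4 years (scenario 1) or
   at 6 months (scenario 2), and FDCs from birth (scenario 3);
6. quantifies sensitivity to the population adjustment (z-shifts 0 to −3,
   CV halved/doubled) and compares derived costs to an external
   transaction-price reference.

Only drug product costs are modelled — no shipping, cold-chain, personnel
or wastage costs.

## Worked example

```python
import pedarv

rules = pedarv.load_packaged_dosing()
prices = pedarv.load_packaged_prices(rules)
probs = pedarv.load_band_probability_table(
    pedarv.packaged_path("band_probs_paper.csv"))
age3 = next(r for r in probs if r.age_years == 3.0)

# ABC syrup, 3-5.9 kg: 6 ml/day x $0.06/ml x 30.4 d
costs = pedarv.band_cost_table(rules, prices)
abc = next(c for c in costs if c.formulation.key == ("ABC", "20 mg/ml")
           and c.band.label == "3-5.9 kg")
print(round(abc.monthly_cost, 2))            # 10.94

# EFV at age 3 (age gate just cleared), probability-weighted over bands
efv = pedarv.drug_cost_by_age("EFV", pedarv.FormulationStrategy.TABLET_FIRST,
                              age3, rules, prices)
print(round(efv.monthly_cost, 2))            # 3.39

# LPV/r + ZDV + 3TC, scenario 1 (no FDCs, liquids until age 4), age 3
reg = pedarv.SIX_REGIMENS[0]
row = pedarv.regimen_cost(reg, pedarv.scenario(1), age3, rules, prices)
print(round(row.monthly_cost, 2))            # 34.07
```

`$10.94` is the monthly cost of abacavir syrup for an infant in the lowest
band; `$3.39` is efavirenz at age three averaged over the weight bands a
three-year-old may occupy; `$34.07` is the full three-drug regimen cost at
age three when no co-formulations are available and syrups are kept until
age four.

The same tables are available from the shell:

```sh
pedarv-cost bands  --out band_costs.csv
pedarv-cost by-age --out age_costs.csv
pedarv-cost regimen --regimen LPV/r+ZDV+3TC --scenario 1 --out regimen.csv
pedarv-cost compare --out vs_reference.csv
```

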
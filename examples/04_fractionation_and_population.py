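"""Dose fractionation comparison and a virtual population band.

Compares Q3W DOX against a weekly fractionated regimen (matched cumulative
dose) with and without 10:1 DEX, then runs a small virtual population with
10% inter-individual variability on the TD parameters.
"""

import cardiotd as ct

frac = ct.compare_fractionation(dox_q3w_per_m2=50.0, dox_q1w_per_m2=16.67,
                                dex_ratio=10.0)
print(frac.to_string(index=False, float_format=lambda x: f"{x:12.4g}"))
print("\nAUEC in %*h; the flagged best arm preserves the most viability.")

spec = ct.PopulationSpec(n_subjects=50, iiv_cv=0.10, seed=1)
reg_dox = ct.build_regimen("DOX", 50.0, 1.8, 504.0, 1, horizon=504.0)
reg_dex = ct.build_regimen("DEX", 500.0, 1.8, 504.0, 1, horizon=504.0)
pop = ct.population_simulate(spec, reg_dox, reg_dex)
end = pop.profiles[:, -1]
print(f"\nvirtual population (n={spec.n_subjects}, 10% IIV), viability at 3 weeks:")
print(f"  5th pct {pop.quantiles[5][-1]:8.1f}%   median {pop.quantiles[50][-1]:8.1f}%"
      f"   95th pct {pop.quantiles[95][-1]:8.1f}%")
print(
    "The quantile band shows how 10% parameter variability propagates into "
    "end-of-cycle viability across subjects."
)
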
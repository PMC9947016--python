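"""Translate the cellular model to clinical dosing: DEX:DOX ratio scan.

Simulates plasma PK for DOX 50 mg/m2 Q3W x3 (15-min infusions, 1.8 m2
subject) with DEX co-administered at several dose ratios, drives the
cellular TD model with the plasma concentrations, and ranks ratios by the
AUEC-based protection metric.
"""

import cardiotd as ct

scan = ct.scan_dose_ratios(
    dox_dose_per_m2=50.0,
    ratios=(0.0, 1.0, 5.0, 10.0, 20.0, 50.0),
    n_cycles=3,
    clamp_net_kill=True,
    include_literal=True,
)

cols = ["ratio", "dex_dose_per_m2", "auec_ratio", "auec_ratio_literal"]
print(scan.table[cols].to_string(index=False,
                                 float_format=lambda x: f"{x:10.4g}"))
print(f"\nselected optimum (1% tie rule): {scan.optimum_ratio:g}:1 DEX:DOX")
print(
    "auec_ratio = AUEC(DOX+DEX)/AUEC(DOX) over 9 weeks; 1 means no "
    "protection. Protection rises steeply up to ~10:1, plateaus at 10-20:1, "
    "and declines at 50:1, where DEX's own growth inhibition outweighs the "
    "saturated anti-kill benefit. The literal (unclamped) column shows why "
    "the clamp matters when extrapolating far beyond the in vitro regime."
)
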
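"""Simulate in vitro cardiomyocyte viability under DOX, DEX, and the combination.

Builds three treatment arms at the reference parameter set, accounts for
drug loss in the culture medium, and prints viability at the assay
timepoints. The combination arm shows DEX's dose-dependent rescue of
DOX-treated cells.
"""

import numpy as np

import cardiotd as ct

p, d = ct.DEFAULT_TD, ct.DEFAULT_DEGRADATION
times = np.array([0.0, 12.0, 24.0, 48.0, 72.0])

arms = {
    "control": ct.InVitroCondition(0.0, 0.0),
    "DOX 0.5 uM": ct.InVitroCondition(0.5, 0.0),
    "DEX 100 uM": ct.InVitroCondition(0.0, 100.0),
    "DOX 0.5 + DEX 5 uM": ct.InVitroCondition(0.5, 5.0),
    "DOX 0.5 + DEX 100 uM": ct.InVitroCondition(0.5, 100.0),
}

print(f"{'condition':22s}" + "".join(f"{t:>9.0f}h" for t in times))
for name, cond in arms.items():
    v = ct.simulate_invitro(cond, p, d, out_times=times)
    print(f"{name:22s}" + "".join(f"{x:9.1f}" for x in v))

print(
    "\nViability is % of the t=0 baseline. Untreated cells grow exponentially "
    f"(kg = {p.kg}/h); 0.5 uM DOX kills most cells by 72 h after a ~{p.tau_dox:.0f} h "
    "transit delay; co-incubated DEX restores viability dose-dependently "
    "while mildly inhibiting growth on its own."
)
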
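"""Reporter normalization, apparent TE, and melting-transition detection.

Three small reducers: dual-luciferase activity normalized within genotype to
an empty control construct; apparent translation efficiency as the
protein/mRNA ratio; and the two melting temperatures of a simulated tRNA
melting curve recovered from the derivative of the FFT-smoothed trace.
"""

import numpy as np
import pandas as pd

from m2acodon import MeltingCurve, apparent_te, melting_transitions, normalize_reporter

readings = pd.DataFrame(
    [
        ("wildtype", "empty", 80.0, 20.0),
        ("wildtype", "6xCAA", 60.0, 20.0),
        ("mutant", "empty", 40.0, 10.0),
        ("mutant", "6xCAA", 10.0, 10.0),
    ],
    columns=["genotype", "construct", "firefly", "renilla"],
)
out = normalize_reporter(readings, control_construct="empty")
print("normalized reporter activity (F/R over the empty control):")
print(out.to_string(index=False))
wt = out.query("genotype=='wildtype' and construct=='6xCAA'")["normalized_activity"].iloc[0]
mut = out.query("genotype=='mutant' and construct=='6xCAA'")["normalized_activity"].iloc[0]
print(f"-> the 6xCAA reporter drops to {mut/wt:.0%} of wild type in the mutant\n")

print(f"apparent TE (protein 0.7, mRNA 1.4): {apparent_te(0.7, 1.4):.2f}\n")

rng = np.random.default_rng(3)
t = np.arange(25.0, 85.01, 0.25)
fluor = (3.0 + 1.0 / (1 + np.exp((t - 48.0) / 2.5))
         + 0.8 / (1 + np.exp((t - 68.0) / 2.5))
         + rng.normal(0, 0.01, t.size))
peaks = melting_transitions(MeltingCurve(t, fluor))
for k, (tm, prom) in enumerate(peaks, start=1):
    print(f"Tm{k} = {tm:.1f} C (prominence {prom:.3f})")
print("(Tm1 and Tm2 mark the dissolution of tertiary and secondary structure)")
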
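"""Sporulation-efficiency CFU arithmetic from a colony-count table.

Spores survive a heat kill; efficiency = (mutant post-heat-kill colonies
x dilution) / (wild-type CFU at resuspension), averaged over countable
dilutions (30-300 colonies), with the sd taken across dilutions.
"""

import pandas as pd

from sporeloc import cfp_only_fraction, sporulation_efficiency

cfu = pd.DataFrame(
    [
        ("wild_type", "resuspension", 10, 100),   # 1000 CFU/ml-equivalent
        ("mutant", "post_heat_kill", 1, 280),     # 280 spores
        ("mutant", "post_heat_kill", 10, 32),     # 320 spores
    ],
    columns=["condition", "stage", "dilution", "colonies"],
)
res = sporulation_efficiency(cfu, "mutant")
print(
    f"sporulation efficiency: {100 * res.efficiency:.0f}% +/- {100 * res.sd:.1f} "
    f"points across {res.n_dilutions} dilutions"
)

# population bookkeeping: forespores with CFP but no detectable YFP are
# tallied separately and excluded from the CFP+/YFP+ fraction
print(f"CFP-only fraction for 5 of 50 CFP+ forespores: {cfp_only_fraction(5, 45):.2f}")
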
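"""Fate of an invading killer across recombination and selfing rates.

Sweeps a small (r, s) grid at two pollen redundancy levels and tabulates the
killer's fate (increased / decreased / eliminated) in each cell.  With ample
pollen (R = 10) selfing always helps the killer; with none to spare (R = 1)
killing pollen costs fertility and selfing turns against the killer.
"""

import numpy as np

import pollenkiller as pk

for R in (10.0, 1.0):
    spec = pk.SweepSpec(
        r_grid=np.round(np.linspace(0.0, 0.1, 5), 3),
        s_grid=np.round(np.linspace(0.0, 0.9, 4), 3),
        R=R,
        init_killer_freq=0.1,
    )
    df = pk.sweep(spec)
    print(f"R = {R}: fate of the killer haplotype (rows r, columns s)")
    print(df.pivot(index="r", columns="s", values="fate").to_string())
    print()

print("At R = 10 the 'increased' region grows with s (selfing promotes the")
print("killer); at R = 1 it survives only where both r and s are small.")
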
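"""Critical recombination and selfing rates for a pollen killer to spread.

Bisection on the deterministic recursion finds (i) the largest recombination
rate r* at which a killer invading at frequency 0.1 still increases, and
(ii) the smallest selfing rate s* that lets a rare killer (frequency 0.001)
spread despite recombination r = 0.01.  Both use R = 10 and complete killing.
"""

import pollenkiller as pk

r_star = pk.find_recombination_threshold(s=1e-5, R=10, f0=0.1)
print(f"recombination threshold r* = {r_star:.4f}  (outcrossing, f0 = 0.1)")

s_star = pk.find_selfing_threshold(r=0.01, R=10, f0=0.001)
print(f"selfing threshold       s* = {s_star:.4f}  (r = 0.01, f0 = 0.001)")

f_min = pk.min_invasion_frequency(r=0.05, s=0.3, R=10)
print(f"minimum invasion freq       = {f_min:.4f}  (r = 0.05, s = 0.3)")

print()
print("Below r* the fitness gained by killing sensitive pollen outweighs the")
print("cost of forming suicide recombinants, so the killer spreads. A rare")
print("killer needs selfing above s* before it can increase at all; from a")
print("given (r, s) the minimum invasion frequency quantifies how much")
print("hybridization-scale introduction the killer requires.")
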
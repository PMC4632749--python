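"""Closed-form physiology bookkeeping on the reported group means.

Demonstrates the three leaf-physiology helpers with the magnitudes reported
for the two cultivars: the leaf length -> area allometry, leaf-area growth
percentages with sampled-leaf accounting, and intrinsic water-use efficiency
from assimilation and stomatal conductance.
"""

from vinemet import physiology

print("leaf-area allometry (Area = 0.3281 x length^2.55):")
for length in (5.0, 10.0, 15.0):
    print(f"  length {length:4.1f} cm -> {physiology.leaf_area_from_length(length):7.1f} cm^2")

print("\ngrowth accounting (percent of day-1 leaf area):")
print(f"  100 -> 154 cm^2, none sampled : {physiology.growth_percent([100], [154]):.0f}%")
print(f"  100 -> 90 cm^2 + 20 sampled   : {physiology.growth_percent([100], [90], [20]):.0f}%")

print("\nintrinsic water-use efficiency (A_N / g_s, umol CO2 / mol H2O):")
for label, a_n, g_s in [
    ("Sh 25 degC", 12.1, 0.27),
    ("Cs 25 degC", 13.1, 0.27),
    ("Sh 35 degC", 10.75, 0.34),
]:
    print(f"  {label}: A_N={a_n:5.2f}, g_s={g_s:.2f} -> WUEi {physiology.wuei(a_n, g_s):5.1f}")
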
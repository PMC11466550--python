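"""Standardizing plot ear weight to grain yield at 15 % moisture.

A harvested maize plot gives an ear weight (kg) and a grain moisture (%).
Comparable yields require putting every plot on the same basis: t/ha of
shelled grain at a standard 15 % moisture.
"""

from mettrial import grain_yield_t_ha

# a wet plot and a dry plot with the same ear weight
wet = grain_yield_t_ha(6.0, 25.0, hr_pct=15.0, shelling=0.8, npa_m2=8.0)
dry = grain_yield_t_ha(6.0, 15.0, hr_pct=15.0, shelling=0.8, npa_m2=8.0)

print(f"6.0 kg of ears at 25% moisture on 8 m^2  -> {wet:.3f} t/ha")
print(f"6.0 kg of ears at 15% moisture on 8 m^2  -> {dry:.3f} t/ha")
print(
    "The wetter plot is penalized by (100-25)/(100-15) = "
    f"{75/85:.3f}: its grain is partly water that will dry off."
)
# the shelling coefficient 0.8 says 80% of ear weight is grain; the area
# factor 100/(8*10) converts kg per 8 m^2 plot to tons per hectare
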
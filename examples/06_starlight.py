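"""How much starlight reaches schooling depth?

Beer-Lambert attenuation with k = 0.0562 m^-1 (clear ocean water, 550 nm)
and a surface starlight irradiance of 1.46e-10 W/cm^2 (0.0002 lux). Flashes
must compete only with this residual light at night.
"""

import flashschool as fs

model = fs.AttenuationModel()
print(f"k = {model.absorption_k} /m, surface = {model.surface_irradiance:.3g} W/cm^2")
for depth in (20.0, 30.0, 100.0):
    T = model.transmittance(depth)
    print(f"depth {depth:5.0f} m:  T = {T:7.4%}   irradiance = {model.irradiance(depth):.3g} W/cm^2")
print()
print("Transmittance decays exponentially; by 100 m under starlight alone,")
print("ambient light is orders of magnitude below the fishes' own flashes.")
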
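"""Stokes-Einstein diffusion of EVs through neurofluidic junction channels.

D = k_B T / (6 pi eta r) in water at 37 C; the 1-D transit-time scaling
t = L^2 / (2 D) is evaluated for the shortest (557 um) and longest (1353 um)
junction channels, and the erfc arrival fraction after 24 h for the
smallest EVs.
"""

from evsecretome import (ChannelGeometry, diffusion_coefficient,
                         diffusion_time, fraction_arrived, steady_flux)

for r in (15, 50, 500):
    d = diffusion_coefficient(r)
    print(f"r = {r:4d} nm: D = {d:.3g} m^2/s")
    for length in (557.0, 1353.0):
        t = diffusion_time(ChannelGeometry(length_um=length), d)
        print(f"    L = {length:6.0f} um: transit time {t:.3g} s = {t/3600:.2f} h")

d15 = diffusion_coefficient(15.0)
geom = ChannelGeometry(length_um=557.0)
print(f"\nfraction of 15 nm EVs past the shortest channel after 24 h: "
      f"{fraction_arrived(geom, d15, 24 * 3600):.3f}")
print(f"steady flux at dC = 1e12 particles/m^3: "
      f"{steady_flux(geom, d15, 1e12):.3g} particles/s")
print("Smaller vesicles diffuse faster (D ~ 1/r); doubling channel length")
print("quadruples the transit time (t ~ L^2).")
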
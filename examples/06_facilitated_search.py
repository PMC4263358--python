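"""Back-of-envelope facilitated-diffusion search kinetics.

Combines the Smoluchowski 3D rate with 1D sliding episodes, and evaluates
the Zwanzig roughness penalty and the electrolyte screening length used by
the force field.
"""

from bdslide import debye_length, search_rate, zwanzig_reduction

sr = search_rate(d_3d=5e-6, d_1d=5e-8, tau_1d=1e-3, tau_3d=1e-3, f=0.3)
print(f"Smoluchowski rate to a bare 3.4 A target: k_Smol = {sr.k_smol:.2e} /M/s")
print(f"mean sliding length per 1D episode: {sr.n_bar:.0f} bp")
print(f"facilitated rate: k_s = {sr.k_s:.2e} /M/s "
      f"(enhancement x{sr.k_s / sr.k_smol:.0f})")

print(f"\nsequence-roughness penalty at eps = 1.1 kBT: "
      f"x{zwanzig_reduction(1.1):.2f} on D_1D")
print(f"Debye length at 0.15 M NaCl, 298 K: {debye_length(0.15):.2f} A "
      f"(the force field's screening length)")
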
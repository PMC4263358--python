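"""Protein–DNA binding free energy by umbrella sampling + WHAM.

Pulls the protein from 90 A to 31 A along the PBP–central-PB distance in
60 harmonic windows (k = 5 kcal/mol/A^2), samples each window with the
equilibrium Metropolis sampler on the identical potential, reconstructs
the PMF with WHAM and reads off ΔG = plateau(80–90 A) − minimum.

Takes a few minutes; a DBP charge of +8 on restrained DNA gives a
non-specific binding free energy around 5–6 kcal/mol (~10 kBT).
"""

from bdslide import assemble_system, build_dna, build_protein
from bdslide.free_energy import binding_free_energy, run_umbrella, wham

system = assemble_system(build_dna(60), build_protein(a_pbp=40.0, q_dbp=8.0))
# frozen-DNA fast path: the restrained DNA's k_r=1 fluctuations shift the
# result by well under the repeat spread, at ~6x the cost when sampled
windows = run_umbrella(system, seed=1, n_equil=2000, n_prod=8000,
                       dna_fluctuates=False)
pmf = wham(windows)
bfe = binding_free_energy(pmf)

imin = pmf.free_energy.argmin()
print(f"PMF minimum at r = {pmf.r[imin]:.1f} A")
print(f"binding free energy dG = {bfe.delta_g:.2f} kcal/mol "
      f"({bfe.delta_g / 0.59248:.1f} kBT)")
# Experimental non-specific binding affinities are ~10-15 kBT; DBP charges
# of +8..+10 put the model in that regime.
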
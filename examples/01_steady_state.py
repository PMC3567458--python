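"""Construct the pre-administration hormonal steady state.

Builds the reference 70-kg body, assembles the coupled cascade with the
shipped kinetic parameters, and solves for the drug-free steady state.
The printed venous concentrations are the model's baseline hormone
levels; the published values are shown for orientation (the shipped rate
constants were identified against a different underlying physiology, so
exact agreement requires the identification step of example 03).
"""

import raasim

body = raasim.build_reference_body()
params = raasim.load_raas_parameters()
system = raasim.assemble_system(body, params)
state = raasim.solve_steady_state(system)

print(f"total plasma volume: {body.total_plasma_volume:.2f} L, "
      f"cardiac output: {body.cardiac_output:.2f} L/min")
print(f"{'species':12s} {'venous steady state':>20s} {'published':>12s}")
for sp in raasim.HORMONES:
    ref = params.species[sp].reference_plasma_conc
    print(f"{sp:12s} {state.venous_concentration(sp):17.3e} umol/L "
          f"{ref:9.2e}")
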
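"""Identify the cascade's kinetic parameters against the published
venous steady-state concentrations.

Frees the 20 'optimized' parameters of the shipped table, minimises the
relative root-mean-square deviation of the six simulated venous
steady-state concentrations from their published values with the
Nelder-Mead simplex, and prints the achieved agreement.  Budget is kept
small here for a quick demonstration; scripts/acceptance.py runs the
full-budget version.
"""

import raasim
from raasim.identification import (fit_simplex, make_raas_fit_problem,
                                   raas_steady_state_predictor)

params = raasim.load_raas_parameters()
predictor = raas_steady_state_predictor(params)
problem = make_raas_fit_problem(params, max_evaluations=1200)

result = fit_simplex(problem, predictor)
print(f"relative RMS error: {result.initial_error:.3e} -> {result.error:.3e} "
      f"({result.n_evaluations} evaluations)")

predicted = predictor(result.parameters)
print(f"{'species':12s} {'identified model':>16s} {'published':>12s}")
for sp, value in zip(raasim.HORMONES, predicted):
    ref = params.species[sp].reference_plasma_conc
    print(f"{sp:12s} {value:13.3e} umol/L {ref:9.2e}  "
          f"dev {abs(value/ref-1)*100:.2f}%")
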
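"""Cross-validate solver fluxes against saturation-kinetics predictions.

Reconstructs fluxes from kvivomax, enzyme abundance and metabolite
concentrations via v = kmax * E * P/(1+P) with P = prod (s/K)^m, then
measures log-scale Pearson agreement with a reference flux set.
"""

import numpy as np

from nidleflux.kinetics import (
    KineticSpec,
    ReactionKinetics,
    SubstrateTerm,
    predict_fluxes,
    validate_against_solution,
)

rng = np.random.default_rng(0)
n = 8
spec = KineticSpec(
    reactions={
        f"R{i}": ReactionKinetics(f"R{i}", (SubstrateTerm(f"s{i}", float(rng.uniform(0.2, 4.0)), 1),))
        for i in range(n)
    }
)
kvivomax = {f"R{i}": float(rng.lognormal(0.0, 1.0)) for i in range(n)}
gene_of = {f"R{i}": f"g{i}" for i in range(n)}


class Profile:
    abundances = {f"g{i}": float(rng.lognormal(-7.0, 0.5)) for i in range(n)}


conc = {f"s{i}": float(rng.uniform(0.1, 5.0)) for i in range(n)}
reference = predict_fluxes(kvivomax, gene_of, Profile(), spec, conc)

r, npairs = validate_against_solution(kvivomax, gene_of, Profile(), spec, conc, reference)
print(f"self-consistent fluxes:    log-Pearson r = {r:.3f} over {npairs} reactions")

shuffled = dict(zip(conc, rng.permutation(list(conc.values()))))
r2, _ = validate_against_solution(kvivomax, gene_of, Profile(), spec, shuffled, reference)
print(f"permuted concentrations:   log-Pearson r = {r2:.3f}")
print(
    "\nWhen the reference fluxes follow the assumed kinetics exactly the\n"
    "correlation is 1; scrambling the metabolite concentrations breaks the\n"
    "saturation structure and degrades the agreement."
)
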
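"""Evolve a discretization scheme (segment boundaries + alphabet size).

A mutation-only evolutionary program scores candidate schemes by the
cross-validated accuracy of 1-NN on their PLA encoding of the training set.
"""

import acetowhite as aw
from acetowhite.representations import standardize_dataset
from acetowhite.scheme_search import EPConfig, evolve_scheme

series = aw.generate_series(aw.GeneratorConfig(seed=7))
std = standardize_dataset(aw.series_to_dataset(series), 10).binarized()

config = EPConfig(population_size=10, generations=15, seed=1)
best, log = evolve_scheme(std, config=config)

print(f"generations: {config.generations}, population: {config.population_size}")
print(f"best fitness trajectory: {[round(f, 3) for _, f in log.generations[::3]]}")
print(f"evolved scheme: {best.n_segments} segments, alphabet {best.alphabet_size}")
print(f"boundaries: {best.scheme.boundaries}")
print(f"fitness (5-fold CV accuracy of 1-NN on the PLA symbols): {best.fitness:.3f}")
print(
    "\nFitness never decreases across generations (elitist selection); ties "
    "prefer fewer segments and smaller alphabets, so the search favors the "
    "most compressed scheme that classifies equally well."
)
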
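"""Isolation by distance: p-distance vs haversine km, Mantel test.

A stepping-stone chain of six localities along a lake-like arc produces
genetic distances that grow with geographic separation.
"""

import warnings

import radpop as rp
from radpop.distance import (
    average_by_locality, haversine_matrix, mantel_test, p_distance_matrix,
)

config = rp.SimulationConfig(
    seed=5, engine="beta", topology="stepping_stone", n_demes=6,
    samples_per_deme=4, n_contigs=1500, admixture_edge=None,
)
dataset, popmap, _ = rp.simulate_dataset(config)

focal = [s for s in dataset.sample_ids if not s.startswith("outgroup")]
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)  # outgroup locality dropped
    genetic = average_by_locality(
        p_distance_matrix(dataset.subset_samples(focal)), popmap
    )
coords = popmap.locality_coords().loc[genetic.labels]
geographic = haversine_matrix(list(map(tuple, coords.to_numpy())),
                              genetic.labels)

result = mantel_test(geographic, genetic, n_permutations=999, seed=3)
print(f"Mantel r = {result.r_observed:.3f}, p = {result.p_value:.3f} "
      f"({result.n_permutations} permutations, one-tailed)")
# r near 0.7-0.9 with p ~ 0.001-0.005: genetic distance increases with
# shoreline separation, the classic isolation-by-distance signature.
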
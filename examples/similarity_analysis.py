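"""Perceptual-similarity analysis on a simulated observer.

A simulated observer rates all stimulus pairs on a 5-point scale, with the
latent dissimilarity driven by closure and convexity only. The analysis
aggregates ratings into a dissimilarity matrix, embeds it by nonmetric MDS,
and measures how well topographic configurations built from cue subsets
match the perceptual configuration (Procrustes Error, normalized by the
mean Error of configurations fitted to label-scrambled ratings).
"""

import numpy as np

from contourcues import CueVector, ObserverModel, simulate_similarity
from contourcues.mds import (
    aggregate_dissimilarity,
    nonmetric_mds,
    normalized_error,
    topographic_config,
)

rng = np.random.default_rng(11)
stimuli = [CueVector(rng.uniform(0, 0.25), int(rng.integers(-6, 7)),
                     rng.uniform(-1, 1), 1, patch_id=f"s{k:02d}") for k in range(16)]

observer = ObserverModel(
    similarity_weights={"convexity": 1.0, "closure": 1.0, "symmetry": 0.0},
    noise_sd=0.3, seed=2024, observer_id="sim-obs")
trials = simulate_similarity(stimuli, observer, n_repetitions=4)
print(f"{len(trials)} rating trials "
      f"({len(stimuli) * (len(stimuli) - 1) // 2} pairs x 4 repetitions)")

d = aggregate_dissimilarity(trials)
by_id = {c.patch_id: c for c in stimuli}
ordered = [by_id[i] for i in d.ids]

for factors in (("closure", "convexity"), ("closure",), ("symmetry",)):
    dims = len(factors)
    perceptual = nonmetric_mds(d, dims=dims, seed=1, restarts=4)
    topo = topographic_config(ordered, factors)
    est = normalized_error(perceptual, topo, d, n_random=20, seed=2, restarts=4)
    print(f"\nfactors {'+'.join(factors)} ({dims}D): stress {perceptual.stress:.3f}")
    print(f"  raw Error {est.raw_error:.3f}, normalized Error "
          f"{est.normalized_error:.3f} (p = {est.p_value:.2g} vs scrambled null)")

print("\nNormalized Error < 1 means the cue configuration matches the perceptual")
print("one better than scrambled-similarity configurations do; the planted")
print("closure+convexity observer should give its factor pair the lowest value,")
print("while symmetry alone (not used by this observer) stays near 1.")
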
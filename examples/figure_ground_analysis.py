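"""Figure-ground choice-rate regression on a simulated 2AFC observer.

A simulated observer judges which side of each contour patch is the figure
(100 repetitions per patch); the probability of choosing the convex side is
a planted linear function of the cue indices with only the Closure term
nonzero. The analysis scores the answers into convex-choice rates and fits
the six-term linear model (three cues plus pairwise products).
"""

import numpy as np

from contourcues import (
    CueVector,
    ObserverModel,
    convex_choice_rate,
    mlra,
    simulate_fg,
)
from contourcues.figure_ground import TERM_NAMES
from contourcues.geometry import LocalFrame

rng = np.random.default_rng(3)
stimuli = [CueVector(rng.uniform(0, 0.25), int(rng.integers(-6, 7)),
                     rng.uniform(-1, 1), 1, patch_id=f"p{k:03d}") for k in range(40)]
frames = [LocalFrame(10.0, 0.05, np.array([0.0, 1.0])) for _ in stimuli]

planted = (0.490, 0.0, 0.0755, 0.0, 0.0, 0.0, 0.0)
observer = ObserverModel(fg_weights=planted, seed=99, observer_id="sim-obs")
responses = simulate_fg(stimuli, frames, observer, n_reps=100)
print(f"{len(responses)} trials ({len(stimuli)} patches x 100 repetitions)")

table = convex_choice_rate(responses, dict(zip([c.patch_id for c in stimuli], frames)))
result = mlra(table, stimuli)

print(f"\n{'term':<22} planted   fitted    p-value")
for term, p in zip(TERM_NAMES, planted):
    print(f"{term:<22} {p:7.4f}  {result.coefficients[term]:7.4f}  "
          f"{result.p_values[term]:.3g}")
print(f"adjusted R^2: {result.adjusted_r2:.3f}")

print("\nOnly the Closure coefficient should be significant: the observer's")
print("choices depend on how enclosed the convex side is, not on curvature or")
print("mirror symmetry. The fitted values recover the planted generator within")
print("binomial sampling error at 100 trials per patch.")
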
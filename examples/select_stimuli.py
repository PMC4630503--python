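"""Stratify a synthetic contour corpus into cue classes and pick a stimulus set.

Draws random open contour patches, screens out X-junctions, bins each patch
by convexity, closure and tangent orientation (5 x 5 x 8 = 200 classes) and
selects one patch per non-empty class, mirroring how a balanced stimulus set
is built from an over-complete natural-contour pool.
"""

from contourcues import (
    CueVector,
    closure,
    convexity,
    generate_open_curve,
    has_x_junction,
    local_frame,
    orientation_bin,
    stratified_select,
)
from contourcues.stimuli import UNBINNED, assign_class

pool = []
seed = 0
n_xjunction = 0
while len(pool) < 80 and seed < 1000:
    seed += 1
    try:
        patch = generate_open_curve(1.0, seed=seed)
        frame = local_frame(patch)
    except ValueError:  # chain too short for the 41-px curvature window
        continue
    if has_x_junction(patch):
        n_xjunction += 1
        continue
    cue = CueVector(convexity(frame), closure(patch, frame), 0.0,
                    orientation_bin(frame.tangent_deg), patch_id=f"p{seed:04d}")
    pool.append((cue.patch_id, cue))

binned = [entry for entry in pool if assign_class(entry[1]) != UNBINNED]
selected = stratified_select(binned, seed=42)

print(f"pool: {len(pool)} patches ({n_xjunction} excluded as X-junctions, "
      f"{len(pool) - len(binned)} outside the printed bin ranges)")
print(f"selected: {len(selected.members)} patches, one per non-empty class "
      f"of the 200 possible\n")
print("patch_id  convexity  closure  class (cv, cl, orient)")
for patch_id, cue, cls in selected.members[:10]:
    print(f"{patch_id}   {cue.convexity:8.4f}  {cue.closure:+7d}  "
          f"({cls.convexity_bin}, {cls.closure_bin}, {cls.orientation_bin})")
print("...")
print("\nEach row is the single random representative of its cue class; with a")
print("larger pool more of the 200 classes fill in, widening the cue coverage.")
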
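"""Tracking a bound peptide in the presenter's own reference frame.

The center of mass of the peptide is projected, frame by frame, onto the
principal inertia axes of the presenter chain.  Because the projection is
expressed in a body-fixed frame, it is invariant under any global tumbling
of the complex: a drifting trace means the peptide actually moves within
the binding groove.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from pmhcdyn import (
    Ensemble,
    SyntheticSpec,
    generate_ensemble,
    project_com_trace,
    select_chains,
    toy_complex_topology,
)

topology, mean = toy_complex_topology(10, 3, 8, charged_fraction=0.0, seed=13)
spec = SyntheticSpec(topology=topology, mean_coordinates=mean,
                     n_frames=50, noise_sigma=0.05, seed=14)
ensemble = generate_ensemble(spec)

# tumble the whole complex randomly per frame, as a freely rotating body would
rng = np.random.default_rng(15)
coords = ensemble.coordinates.copy()
for t in range(coords.shape[0]):
    r = Rotation.random(rng=rng).as_matrix()
    coords[t] = coords[t] @ r.T + rng.normal(scale=20.0, size=3)
tumbling = Ensemble(topology=topology, coordinates=coords)

body = select_chains(topology, {"A"})
probe = select_chains(topology, {"B"})
trace = project_com_trace(tumbling, body, probe)

print("peptide CoM in the presenter principal frame (first 3 frames, A):")
for t in range(3):
    print(f"  frame {t}: ({trace[t, 0]:6.2f}, {trace[t, 1]:6.2f}, {trace[t, 2]:6.2f})")
print(f"per-axis std over 50 tumbling frames: {trace.std(axis=0).round(3)} A")
print()
print("Despite arbitrary global rotation and translation of every frame the")
print("body-frame trace stays put: the peptide is not moving in the groove.")
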
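"""Regularized 3D refinement of a simulated data set.

Starting from a heavily low-pass-filtered version of the true map, the
expectation-maximization loop aligns the particles probabilistically and
rebuilds the map with the Gaussian smoothness prior each iteration.  The
printed trace shows the marginal log-likelihood rising and the estimated
resolution (the frequency where the spherically averaged SNR of the
reconstruction drops below 1).
"""

import numpy as np
from scipy import ndimage

from bayesmap import (RealVolume, RefineConfig, make_phantom, refine,
                      scenario_preset, simulate_particles, volume_from_fourier)
from bayesmap.resolution import fsc

specs, config = scenario_preset("typical_refine", seed=1)
phantom = make_phantom(specs[0], seed=1)
particles = simulate_particles([phantom], config)
initial = RealVolume(ndimage.gaussian_filter(phantom.voxels, 1.2), phantom.voxel_size)

rconfig = RefineConfig(n_classes=1, n_iterations=6, angular_step=15.0,
                       angular_step_fine=10.0, fine_from_iteration=4, seed=2)
model, history, accumulators = refine(particles, initial, rconfig)

for h in history:
    res = h["resolution"][0]
    print(f"iter {h['iteration']:2d}  logL {h['log_likelihood']:.5e}  "
          f"est. resolution {res if res else '-'} A  "
          f"map change {h['map_change']:.2e}")

final = volume_from_fourier(model.volumes[0])
cc = np.corrcoef(final.voxels.ravel(), phantom.voxels.ravel())[0, 1]
curve = fsc(final, phantom)
print(f"\nreal-space correlation with the true phantom: {cc:.3f}")
print("FSC vs truth per shell:", np.array2string(curve.values, precision=2))
print("(the estimated resolution should agree with where this FSC collapses)")
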
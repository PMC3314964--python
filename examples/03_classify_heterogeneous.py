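"""Unsupervised 3D classification of a two-structure mixture.

Simulates a 50/50 mixture of two different blob structures, seeds K = 2
classes by dividing the data into random subsets during the first
iteration, and lets expectation-maximization sort the particles.  Prints
the learned class fractions and the agreement of the dominant posterior
class with the (hidden) truth, up to label permutation.
"""

import numpy as np
from scipy import ndimage

from bayesmap import (RealVolume, RefineConfig, classify, make_phantom,
                      scenario_preset, simulate_particles)
from bayesmap.expectation import dataset_expectation

specs, config = scenario_preset("hetero_equal", seed=13)
volumes = [make_phantom(s, seed=13 + k) for k, s in enumerate(specs)]
particles = simulate_particles(volumes, config)

consensus = RealVolume(ndimage.gaussian_filter(
    np.mean([v.voxels for v in volumes], axis=0), 1.2), 3.0)
rconfig = RefineConfig(n_classes=2, n_iterations=30, angular_step=20.0,
                       seed=4, oversampling=1)
# rerun the random-subset seeding a few times; keep the best log-likelihood
model, history, _ = classify(particles, consensus, rconfig, n_attempts=3)

weights = dataset_expectation(particles, model, rconfig.grid_for(99))
dominant = np.argmax(weights.class_mass(), axis=1)
truth = particles.metadata.true_class.to_numpy()
accuracy = max(np.mean(dominant == truth), np.mean(dominant == 1 - truth))

print(f"learned class fractions: {np.round(model.class_fraction, 3)}")
print(f"dominant-class agreement with truth (up to permutation): {accuracy:.1%}")
print("(random assignment would give 50%; the classes separate because each")
print(" particle's likelihood strongly prefers the structure it came from)")
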
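"""The synthetic odor environment.

Samples a mixing matrix with equalized row sums, a stream of sparse odor
vectors, and noisy glomerular responses; prints the statistics that define
the generative model.
"""

import numpy as np

from olfbayes import glomeruli_response, make_world, sample_odors

M, N, c_o = 50, 200, 3.0 / 50
rng = np.random.default_rng(0)
world = make_world(M, N, c_o, sigma_x=1.0, rng=rng)

sums = world.W.sum(axis=1)
print(f"world: M={M} odors, N={N} glomeruli, c_o={c_o:.2f}")
print(f"row sums of W: min={sums.min():.6f} max={sums.max():.6f} (equalized)")

c = sample_odors(world.prior, rng, size=5000)
print(f"odors present per trial: mean={np.mean((c > 0).sum(axis=1)):.2f} "
      f"(c_o*M = {c_o * M:.0f}, slightly above after null-trial resampling)")
print(f"mean amplitude of present odors: {c[c > 0].mean():.3f} (unit-mean slab)")

x = glomeruli_response(world, c[0], rng)
print(f"one trial: {int((c[0] > 0).sum())} odors present, "
      f"glomerular response range [{x.min():.2f}, {x.max():.2f}]")
print()
print("Each trial mixes a few unit-mean odor amplitudes through the odor-")
print("specific affinity columns of W and adds unit-variance sensor noise;")
print("the circuit must invert this mixture without ever seeing c.")
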
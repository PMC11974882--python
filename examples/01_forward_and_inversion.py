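"""Simulate one voxel's MD-MRI signal and recover its spectrum.

A voxel holding two water pools is projected through the T1-T2-D
Fredholm kernel, observed with rician noise, and inverted back to a
non-negative spectrum, which is then collapsed to the T1-T2 correlation
map.
"""

import numpy as np

from mdmri import (InversionConfig, Spectrum, build_kernel, default_grid,
                   default_scheme, invert_signal, marginalize,
                   simulate_signal)

grid = default_grid(12)
kernel = build_kernel(grid, default_scheme())

# two pools: short-T2 myelin-like water and a free-water-like pool
weights = np.zeros(grid.n_nodes)
weights[grid.flat_index(4, 3, 4)] = 0.6
weights[grid.flat_index(10, 10, 10)] = 0.4
truth = Spectrum(grid, weights, normalized=True)

signal = simulate_signal(truth, kernel, snr=100, noise_model="rician", seed=1)
estimate = invert_signal(signal, kernel, InversionConfig(lam=1e-2))

print(f"measurements: d = {signal.values.size}, unknowns: {grid.n_nodes}")
print(f"residual ||s - K f||_2 = {estimate.meta['residual']:.4f}")


def mass_near(spec, node, radius=1):
    cube = spec.as_cube()
    sl = tuple(slice(max(i - radius, 0), i + radius + 1) for i in node)
    return cube[sl].sum()


for name, node, frac in (("myelin-like pool", (4, 3, 4), 0.6),
                         ("free-water pool", (10, 10, 10), 0.4)):
    print(f"{name}: truth fraction {frac:.2f}, recovered mass within one "
          f"grid cell = {mass_near(estimate, node):.3f}")
t1t2 = marginalize(estimate, "T1-T2")
print(f"T1-T2 map mass = {t1t2.total():.4f} "
      f"(3-D mass {estimate.total():.4f}; marginalization conserves mass)")
# both pools are found near their true grid locations; the short-T2 pool
# decays faster under the kernel, so its recovered mass is the less
# certain of the two, and a small residual means the noisy signal is
# explained almost entirely by the fitted spectrum
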
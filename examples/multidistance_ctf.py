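"""Multi-distance CTF retrieval of a weak object.

Simulates three holograms of a weak phantom (|phi| <= 0.01 rad) with the
full Fresnel propagator, then solves the per-frequency CTF least-squares
system for phase and absorption, and reports the normalized RMS phase error
for 1, 2 and 3 distances.
"""

import numpy as np

from holophase import HologramStack, ObjectMaps, ctf, fresnel_propagate, intensity

rng = np.random.default_rng(0)
n, pixel, wavelength = 256, 1e-6, 1e-10

y, x = np.mgrid[:n, :n]
phi = np.zeros((n, n))
for _ in range(8):
    cy, cx = rng.uniform(0.2 * n, 0.8 * n, 2)
    s = rng.uniform(4, 12)
    phi += rng.uniform(0.5, 1) * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * s * s))
phi = 0.01 * phi / phi.max()
phi -= phi.mean()
obj = ObjectMaps(phi=phi, b=np.zeros((n, n)), pixel=pixel)


def nrmse(est, tru):
    est = est - est.mean() + tru.mean()
    return np.sqrt(np.mean((est - tru) ** 2)) / (tru.max() - tru.min())


u0 = obj.exit_wave()
for dists in ([0.05], [0.02, 0.05], [0.02, 0.05, 0.09]):
    imgs = [intensity(fresnel_propagate(u0, wavelength, d)) for d in dists]
    stack = HologramStack(imgs, dists, pixel, wavelength)
    rec, _ = ctf(stack, alpha=1e-8)
    print(f"{len(dists)} distance(s): NRMSE(phi) = {nrmse(rec, phi):.4f}")

print("Added distances fill each other's contrast-transfer zeros, so the")
print("phase error drops as more holograms enter the least-squares solve.")
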
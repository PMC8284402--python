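"""Cone-beam geometry: magnification, effective distance, Fresnel number.

A divergent beam magnifies the sample by M = zD/z1 and, by the Fresnel
scaling theorem, behaves like a parallel beam propagated over
D = z1(zD - z1)/zD and sampled at pixel p/M.
"""

from holophase import (
    AcquisitionGeometry,
    fresnel_number,
)

# the published nano-imaging setup: 13 keV, detector 1.12 m from the focus,
# sample at 10.1 mm, 650 nm detector pixels
geo = AcquisitionGeometry(energy_kev=13.0, z1_m=10.1e-3, zd_m=1.12, pixel_m=650e-9)

print(f"magnification        M = {geo.magnification:.1f}")
print(f"effective pixel        = {geo.effective_pixel_m * 1e9:.2f} nm")
print(f"effective distance   D = {geo.effective_distance_m * 1e3:.3f} mm")

# Fresnel number of a 100 nm feature at that effective distance: F << 1
# means the image is a hologram, not an edge-enhanced radiograph
f = fresnel_number(100e-9, geo.wavelength_m, geo.effective_distance_m)
print(f"Fresnel number of a 100 nm feature: {f:.3g}")
print("F << 1: holographic regime -> CTF or iterative retrieval required.")
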
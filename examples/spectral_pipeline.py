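"""Pattern quantification of an aggregate image.

Builds a synthetic image of hexagonally packed aggregates with 1 mm
spacing (what experiments show on the plate), runs it through the
radial power-spectrum pipeline, and reports the dominant wavenumber.
For a hexagonal lattice with spacing a the first reciprocal ring sits
at 2/(sqrt(3)*a) cycles/cm, i.e. ~11.5 cycles/cm for a = 1 mm.
"""

from l1agg.spectral import (dominant_peak, power_spectrum, radial_sum,
                            smooth_radial, synthetic_pattern)

spacing = 0.1          # cm
img = synthetic_pattern(spacing_cm=spacing, spot_radius_cm=0.02,
                        lattice="hex", jitter=0.05, width_cm=1.0,
                        n_px=256, seed=0)
spec = power_spectrum(img, width_cm=1.0)
rs = smooth_radial(radial_sum(spec))
peak = dominant_peak(rs)

print(f"synthetic hexagonal pattern, spacing {spacing * 10:.0f} mm")
print(f"dominant radial-spectrum peak: {peak:.2f} cycles/cm")
print(f"expected first reciprocal ring: {2 / (3 ** 0.5 * spacing):.2f} cycles/cm")
print(f"implied pattern wavelength: {10 / peak:.2f} mm")
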
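"""Collagen fiber alignment from a second-harmonic-generation image.

Generates a fiber field oriented at 30 degrees with 15-degree angular spread,
then recovers content (mean intensity), density (masked area fraction) and
the orientation histogram's peak and dispersion from the Fourier spectrum.
"""

from tenmech import (directionality, gen_shg_image, segment_shg, shg_content,
                     shg_density)

img, truth = gen_shg_image(mean_angle_deg=30.0, angular_sd_deg=15.0,
                           fiber_count=200, seed=11)

mask = segment_shg(img)
hist = directionality(img)

print(f"collagen content (mean intensity): {shg_content(img):6.2f} a.u.")
print(f"collagen density (area fraction):  {shg_density(img, mask):6.3f}")
print(f"peak orientation: {hist.peak_angle_deg:6.2f} deg "
      f"(true {truth.mean_angle_deg})")
print(f"dispersion:       {hist.dispersion_deg:6.2f} deg "
      f"(sample sd {truth.sample_sd_deg:.2f})")
print(f"peak-fit goodness r^2: {hist.goodness:.2f}")
# Lower dispersion means better-aligned collagen; treated tendons that align
# their fibers show a measurably narrower orientation histogram.
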
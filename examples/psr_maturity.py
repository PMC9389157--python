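"""Collagen maturity scoring of a picrosirius-red polarized-light image.

Generates a birefringence image with 30% red (mature), 30% yellow
(intermediate) and 40% green (immature) fiber pixels, then classifies every
above-background pixel by its red:green intensity ratio
(>= 1.8 red, <= 1.1 green, in between yellow).
"""

from tenmech import classify_maturity, gen_psr_image, psr_content

img, truth = gen_psr_image(0.3, 0.3, 0.4, width=128, height=128, seed=1)

content = psr_content(img, method="fixed", fixed_threshold=10)
res = classify_maturity(img)

print(f"PSR-positive area fraction: {content:5.1f} %")
print(f"mature (red):        {res.pct_red:5.1f} %  (true 30)")
print(f"intermediate (yellow): {res.pct_yellow:4.1f} %  (true 30)")
print(f"immature (green):    {res.pct_green:5.1f} %  (true 40)")
print(f"classified pixels: {res.n_classified}, background: {res.n_background}")
# Percentages are taken over classified (stained) pixels; higher red fraction
# means thicker, more densely packed — i.e. more mature — collagen fibers.
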
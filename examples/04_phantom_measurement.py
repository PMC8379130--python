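"""Render a three-phase phantom and re-measure it with elliptic ROIs.

The phantom inverts a target index vector into absolute HU values (liver
background, lesion ellipse) and adds per-phase Gaussian noise.  Measuring
it the way a reader would — one lesion ROI per phase, two liver ROIs per
contrast phase — recovers the generating indices up to noise.
"""

from hccwashout import EnhancementIndices
from hccwashout.synthetic import extract_indices, generate_phantom_series

target = EnhancementIndices(cer=109.4, llc=56.3, wo_abs=46.5, wo_rel=24.3, dpar=123.2)

clean = generate_phantom_series(target, noise_sigma=0.0)
noisy = generate_phantom_series(target, noise_sigma=10.0, seed=7)

print("index    target   noise-free   sigma=10")
for name, tgt in target.rounded().items():
    c = getattr(extract_indices(clean), name)
    z = getattr(extract_indices(noisy), name)
    print(f"{name:>7}  {tgt:7.1f}  {c:10.1f}  {z:9.1f}")
# The noise-free column matches the target exactly (the ROI mean over the
# truth ellipse is the generating value); at sigma = 10 HU the indices
# scatter by a few points, the size of real inter-measurement variation.
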
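"""Wavelet speckle denoising on a piecewise-constant phantom.

Applies log-domain BayesShrink (bior3.7, level 3, soft thresholding of
the coarsest detail level) to a multiplicatively speckled image and
reports the mean squared error against the clean phantom.
"""

import numpy as np

from ceus_radiomics import DenoiseParams, denoise_frame

rng = np.random.default_rng(0)
clean = np.full((128, 128), 40.0)
clean[30:90, 40:110] = 90.0
clean[90:118, 10:50] = 15.0

# fully developed speckle: pixel-iid multiplicative exponential factor
speckle = 1.0 + 0.5 * (rng.exponential(1.0, clean.shape) - 1.0)
noisy = np.clip(clean * speckle, 0.0, None)

denoised = denoise_frame(noisy, DenoiseParams())
mse_before = np.mean((noisy - clean) ** 2)
mse_after = np.mean((denoised - clean) ** 2)
print(f"MSE vs clean phantom: {mse_before:.1f} before, {mse_after:.1f} after "
      f"({100 * (1 - mse_after / mse_before):.2f}% reduction)")
# Shrinkage is applied to the coarsest (level-3) detail coefficients
# only, so it removes the coarse-scale share of the speckle energy; the
# finer scales pass through untouched and the MSE reduction is modest.
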
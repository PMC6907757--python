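"""PSNR and SSIM on controlled distortions.

PSNR is computed on the 8-bit scale (peak 255) whatever the internal unit
storage; SSIM comes in a whole-image 'global' mode and the conventional
11x11 Gaussian-windowed mode.
"""

import numpy as np

from npgtv import NoiseModel, add_awgn, make_phantom, psnr, ssim

clean = make_phantom("texture", 64, 64, seed=3)

# a uniform 16-gray-level offset has a closed-form PSNR
offset = np.clip(clean * 0 + 0.5 + 16 / 255, 0, 1)
rep = psnr(clean * 0 + 0.5, offset)
print(f"uniform 16-level offset: MSE {rep.mse:.1f}, PSNR {rep.psnr_db:.4f} dB "
      "(closed form 10*log10(255^2/256))")

noisy = add_awgn(clean, NoiseModel(sigma=15, seed=3))
print(f"sigma=15 noise on texture: PSNR {psnr(clean, noisy).psnr_db:.2f} dB")
print(f"  SSIM windowed {ssim(clean, noisy):.4f}   SSIM global {ssim(clean, noisy, mode='global'):.4f}")
print(f"identical images: SSIM = {ssim(clean, clean):.1f}, PSNR infinite "
      f"(flag: {psnr(clean, clean).psnr_infinite})")
print()
print("PSNR measures pixelwise error on a log scale; SSIM compares local")
print("luminance, contrast and structure, tracking perceived quality better.")
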
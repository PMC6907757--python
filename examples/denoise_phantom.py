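"""End-to-end denoising of a seeded synthetic phantom.

Generates a 64x64 piecewise-constant image, adds Gaussian noise of standard
deviation 25 gray levels, denoises it with the non-local patch graph TV
method under the default noise-adaptive parameters, and compares against
the classical grid-TV baseline run through the same solver.
"""

from npgtv import (
    NoiseModel, add_awgn, baseline_grid_tv, make_phantom, npgtv_denoise, psnr, ssim,
)

clean = make_phantom("piecewise", 64, 64, num_regions=4, seed=7)
noise = NoiseModel(sigma=25, seed=7)
noisy = add_awgn(clean, noise)

result = npgtv_denoise(noisy, noise=noise)
baseline = baseline_grid_tv(noisy, noise=noise)

print(f"noisy input : PSNR {psnr(clean, noisy).psnr_db:6.2f} dB  SSIM {ssim(clean, noisy):.4f}")
print(f"NPGTV       : PSNR {psnr(clean, result.denoised).psnr_db:6.2f} dB  "
      f"SSIM {ssim(clean, result.denoised):.4f}  ({result.iterations} iterations)")
print(f"grid TV     : PSNR {psnr(clean, baseline.denoised).psnr_db:6.2f} dB  "
      f"SSIM {ssim(clean, baseline.denoised):.4f}")
print()
print("Higher PSNR/SSIM is better; the non-local patch graph preserves region")
print("boundaries that the purely local grid graph smooths away.")
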
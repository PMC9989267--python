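"""Rician noise floor: why high-b ADC is biased low, and the correction.

Simulates 10,000 voxels of magnitude data at SNR ~ 5 at b = 1500 s/mm2,
computes the ROI-style ADC from the RMS signal level, and applies power
subtraction. The floor inflates the high-b signal, biasing ADC low by a
couple of percent; the correction removes nearly all of it.
"""

import numpy as np

import breastdwi as bd

adc0, b_hi, n = 1.2e-3, 1500.0, 10_000
s_hi = float(np.exp(-b_hi * adc0))
sigma = s_hi / 5.0

rng = np.random.default_rng(0)
lo = bd.add_rician(np.ones(n), bd.NoiseModel(sigma), rng=rng)
hi = bd.add_rician(np.full(n, s_hi), bd.NoiseModel(sigma), rng=rng)

sigma_est = bd.estimate_sigma_background(
    bd.add_rician(np.zeros(n), bd.NoiseModel(sigma), rng=rng),
    np.ones(n, dtype=bool))
print(f"channel sigma: true {sigma:.4f}, estimated from background "
      f"{sigma_est:.4f} (Rayleigh-mean inversion)")

rms = lambda x: float(np.sqrt(np.mean(x**2)))
adc_raw = np.log(rms(lo) / rms(hi)) / b_hi
adc_corr = np.log(bd.noise_floor_correct(rms(lo), sigma_est)
                  / bd.noise_floor_correct(rms(hi), sigma_est)) / b_hi

print(f"true ADC                : {adc0:.4e} mm2/s")
print(f"uncorrected ADC         : {adc_raw:.4e} mm2/s "
      f"({100 * (adc_raw - adc0) / adc0:+.2f}% bias, low)")
print(f"floor-corrected ADC     : {adc_corr:.4e} mm2/s "
      f"({100 * (adc_corr - adc0) / adc0:+.2f}% bias)")
print("the uncorrected value would push a lesion toward the 'malignant' "
      "side of any ADC threshold.")
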
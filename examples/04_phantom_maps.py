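"""Synthetic phantom -> voxelwise parameter maps -> comparison to truth.

Builds the default breast phantom (fibroglandular background, lesion rim,
necrosis-like core), synthesizes a 4-b DWI volume with Rician noise at
SNR 50, computes f_IVIM / ADC0 / K / sADC / S-index maps, and summarizes
the per-region map statistics against the generating parameters.
"""

import numpy as np

import breastdwi as bd

scheme = bd.AcquisitionScheme(bd.DEFAULT_QUADRUPLE)
spec = bd.PhantomSpec(seed=42)  # default: 36x36x12 grid, sigma=2 (SNR 50)
volume = bd.make_phantom(spec)
dwi = bd.synthesize_dwi(volume, scheme, bd.NoiseModel(spec.sigma, seed=42))
mapset = bd.compute_maps(dwi, scheme, mask=volume.mask)

print(f"grid {volume.shape}, {int(volume.mask.sum())} tissue voxels, "
      f"sigma={spec.sigma} (SNR {spec.s0 / spec.sigma:.0f} at b=0)\n")
print("region        n     ADC0 est (true)          K est (true)    S-index")
for region in ("background", "lesion_rim", "lesion_core"):
    sel = volume.label_mask(region)
    adc0 = np.nanmedian(mapset.maps["adc0"][sel])
    adc0_t = np.nanmedian(volume.maps["adc0"][sel])
    k = np.nanmedian(mapset.maps["kurtosis"][sel])
    k_t = np.nanmedian(volume.maps["kurtosis"][sel])
    s = np.nanmedian(mapset.maps["s_index"][sel])
    print(f"{region:12s} {int(sel.sum()):4d}  {adc0:.3e} ({adc0_t:.3e})  "
          f"{k:5.2f} ({k_t:5.2f})    {s:5.1f}")

print("\nthe lesion rim separates from background: lower ADC0, higher K, "
      "S-index near the malignant-like anchor (100).")
flagged = int(np.sum(mapset.qc > 0))
print(f"qc-flagged voxels: {flagged} of {int(volume.mask.sum())}")
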
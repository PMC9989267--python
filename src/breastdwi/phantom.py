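"""Synthetic breast DWI phantom: parameter-map volumes and 4D data.

The phantom emulates, qualitatively, the contrast structure of breast
lesions on quantitative diffusion maps: a fibroglandular background of
relatively free diffusion, a lesion rim of densely cellular tissue (low
ADC0, high K, high perfusion fraction) and a necrosis-like lesion core
(high ADC0, low K, high perfusion fraction). Voxels outside the tissue
mask are air and contain pure noise after synthesis. The parameter ranges
are fixture conventions chosen to be physiologically plausible, not
measured values; all are configurable through :class:`PhantomSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelValidityError, ValidationError
from .noise import NoiseModel, add_rician
from .signals import (
    DEFAULT_D_BLOOD,
    DEFAULT_D_STAR,
    AcquisitionScheme,
    TissueState,
    kurtosis_attenuation,
)

__all__ = [
    "LABELS",
    "DEFAULT_PARAM_RANGES",
    "PhantomSpec",
    "ParameterMapVolume",
    "make_phantom",
    "synthesize_dwi",
]

#: Integer label codes of the phantom label map.
LABELS = {"air": 0, "background": 1, "lesion_rim": 2, "lesion_core": 3}

#: Default per-label uniform parameter ranges (adc0 in mm²/s, K and f
#: dimensionless). Rim: low adc0 / high K / high f (viable malignant
#: tissue); core: high adc0 / low K / high f (necrosis-like).
DEFAULT_PARAM_RANGES = {
    "background": {"adc0": (1.6e-3, 2.2e-3), "kurtosis": (0.4, 0.7),
                   "f_ivim": (0.02, 0.06)},
    "lesion_rim": {"adc0": (0.8e-3, 1.2e-3), "kurtosis": (0.9, 1.4),
                   "f_ivim": (0.08, 0.15)},
    "lesion_core": {"adc0": (2.2e-3, 2.8e-3), "kurtosis": (0.1, 0.3),
                    "f_ivim": (0.08, 0.15)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, parameter ranges and noise of a synthetic phantom.

    A single ellipsoidal tissue region fills most of the grid; each lesion
    is a sphere whose outer shell (``rim_thickness`` voxels) is labelled
    rim and whose interior is core. ``sigma`` is the channel noise added
    at synthesis time (default SNR 50 at b=0 for ``s0=100``).
    """

    shape: tuple[int, int, int] = (36, 36, 12)
    lesion_centers: tuple = ((14.0, 14.0, 6.0),)
    lesion_radii: tuple = (5.0,)
    rim_thickness: float = 2.0
    s0: float = 100.0
    sigma: float = 2.0
    seed: int = 0
    param_ranges: dict = field(default_factory=lambda: DEFAULT_PARAM_RANGES)
    d_star: float = DEFAULT_D_STAR
    d_blood: float = DEFAULT_D_BLOOD

    def __post_init__(self) -> None:
        if len(self.lesion_centers) != len(self.lesion_radii):
            raise ValidationError(
                "lesion_radii: need one radius per lesion center")
        shape = np.asarray(self.shape)
        for c, r in zip(self.lesion_centers, self.lesion_radii):
            c = np.asarray(c, dtype=float)
            if np.any(c - r < -0.5) or np.any(c + r > shape - 0.5):
                raise ValidationError(
                    f"lesion_centers: lesion at {tuple(c)} with radius {r} "
                    f"exceeds grid {self.shape}")
        for label, ranges in self.param_ranges.items():
            if label not in LABELS:
                raise ValidationError(f"param_ranges: unknown label {label!r}")
            for p, (lo, hi) in ranges.items():
                if not (0 <= lo <= hi):
                    raise ValidationError(
                        f"param_ranges: invalid range for {label}.{p}")


@dataclass
class ParameterMapVolume:
    """Voxel grid of tissue parameters plus mask and label map.

    ``maps`` holds 3D arrays keyed ``s0, f_ivim, adc0, kurtosis, d_star,
    d_blood`` (NaN outside the mask); ``labels`` uses :data:`LABELS`.
    """

    maps: dict
    mask: np.ndarray
    labels: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def tissue_state_at(self, idx) -> TissueState:
        if not self.mask[idx]:
            raise ValidationError(f"mask: voxel {idx} is outside the tissue mask")
        return TissueState(**{k: float(v[idx]) for k, v in self.maps.items()})

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def make_phantom(spec: PhantomSpec) -> ParameterMapVolume:
    """Build the parameter-map volume; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    center = (np.array(spec.shape) - 1) / 2.0
    semi = np.maximum((np.array(spec.shape) - 1) / 2.0 - 0.5, 0.5)
    r2 = (((ii - center[0]) / semi[0]) ** 2
          + ((jj - center[1]) / semi[1]) ** 2
          + ((kk - center[2]) / semi[2]) ** 2)
    labels = np.where(r2 <= 1.0, LABELS["background"], LABELS["air"]).astype(np.int8)

    for (cx, cy, cz), radius in zip(spec.lesion_centers, spec.lesion_radii):
        d = np.sqrt((ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2)
        inside = (d <= radius) & (labels != LABELS["air"])
        core = inside & (d <= radius - spec.rim_thickness)
        labels[inside] = LABELS["lesion_rim"]
        labels[core] = LABELS["lesion_core"]

    mask = labels != LABELS["air"]
    maps = {name: np.full(spec.shape, np.nan)
            for name in ("s0", "f_ivim", "adc0", "kurtosis", "d_star", "d_blood")}
    # fixed draw order over labels keeps realizations seed-stable
    for label in ("background", "lesion_rim", "lesion_core"):
        sel = labels == LABELS[label]
        n = int(sel.sum())
        if n == 0:
            continue
        ranges = spec.param_ranges.get(label, {})
        for param in ("adc0", "kurtosis", "f_ivim"):
            lo, hi = ranges[param]
            maps[param][sel] = rng.uniform(lo, hi, size=n)
        maps["s0"][sel] = spec.s0
        maps["d_star"][sel] = spec.d_star
        maps["d_blood"][sel] = spec.d_blood
    return ParameterMapVolume(maps=maps, mask=mask, labels=labels)


def synthesize_dwi(param_map: ParameterMapVolume,
                   scheme: AcquisitionScheme,
                   noise: NoiseModel,
                   mode: str = "assumption_matched") -> np.ndarray:
    """Voxelwise forward synthesis plus Rician noise -> 4D array (x,y,z,b).

    Masked voxels follow the IVIM-kurtosis model in the requested mode;
    air voxels are zero before noise, hence Rayleigh distributed after.
    Physical mode enforces the kurtosis-model validity limit for every
    masked voxel.
    """
    if mode not in ("physical", "assumption_matched"):
        raise ValidationError(
            f"mode: expected 'physical' or 'assumption_matched', got {mode!r}")
    mask = param_map.mask
    b = scheme.b_array
    adc0 = param_map.maps["adc0"][mask]
    k = param_map.maps["kurtosis"][mask]
    f = param_map.maps["f_ivim"][mask]
    s0 = param_map.maps["s0"][mask]

    if mode == "physical":
        with np.errstate(divide="ignore"):
            bmax = np.where(k > 0, 3.0 / (adc0 * k), np.inf)
        if np.any(b[-1] > bmax * (1 + 1e-12)):
            raise ModelValidityError(
                f"b={b[-1]:g} s/mm² exceeds the kurtosis-model turnover for "
                f"{int(np.sum(b[-1] > bmax))} voxels (min b_max = "
                f"{bmax.min():g} s/mm²); use assumption_matched mode")

    tissue_part = kurtosis_attenuation(b[None, :], adc0[:, None], k[:, None])
    if mode == "physical":
        d_fast = (param_map.maps["d_star"][mask]
                  + param_map.maps["d_blood"][mask])
        fast = np.exp(-b[None, :] * d_fast[:, None])
        sig = s0[:, None] * (f[:, None] * fast
                             + (1 - f[:, None]) * tissue_part)
    else:
        sig = s0[:, None] * (1 - f[:, None]) * tissue_part
        sig[:, 0] = s0 * (f + (1 - f) * tissue_part[:, 0])

    clean = np.zeros(param_map.shape + (len(scheme),))
    clean[mask] = sig
    return add_rician(clean, noise)
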
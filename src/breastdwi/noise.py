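"""Rician magnitude noise: simulation, sigma estimation, floor correction.

Magnitude MRI signals are Rician distributed: the modulus of a complex
Gaussian channel pair. At low SNR the magnitude never averages to zero —
the "noise floor" — which biases high-b signals upward and therefore
biases two-point ADC estimates *low*. The tools here simulate that
process, estimate the channel sigma from signal-free background (where
the magnitude is Rayleigh distributed), and correct measured magnitudes
by power subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "NoiseModel",
    "add_rician",
    "estimate_sigma_background",
    "noise_floor_correct",
    "RAYLEIGH_MEAN_FACTOR",
]

#: Mean of a Rayleigh variate with scale sigma is sigma * sqrt(pi/2).
RAYLEIGH_MEAN_FACTOR = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class NoiseModel:
    """Single-coil Gaussian channel noise of standard deviation ``sigma``.

    Identical ``seed`` gives an identical noise realization.
    """

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"sigma: must be >= 0, got {self.sigma}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def add_rician(clean, noise: NoiseModel, rng: np.random.Generator | None = None):
    """Rician magnitude of a clean signal: sqrt((S + n1)² + n2²).

    ``n1, n2`` are independent zero-mean Gaussians with ``noise.sigma``.
    With ``sigma == 0`` the input is returned unchanged. Pass ``rng`` to
    draw from an existing generator (e.g. inside a pipeline); otherwise a
    fresh generator is seeded from ``noise.seed``.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValidationError("clean: signal must be >= 0")
    if noise.sigma == 0:
        return clean.copy()
    if rng is None:
        rng = noise.rng()
    n1 = rng.normal(0.0, noise.sigma, size=clean.shape)
    n2 = rng.normal(0.0, noise.sigma, size=clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)


def estimate_sigma_background(volume, background_mask, method: str = "mean"):
    """Channel sigma from signal-free background voxels.

    In background the magnitude is Rayleigh distributed, so
    ``sigma = mean / sqrt(pi/2)`` (``method='mean'``, default) or
    ``sigma = rms / sqrt(2)`` (``method='rms'``).
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(background_mask, dtype=bool)
    vals = volume[mask]
    if vals.size == 0:
        raise ValidationError("background_mask: selects no voxels")
    if method == "mean":
        return float(vals.mean() / RAYLEIGH_MEAN_FACTOR)
    if method == "rms":
        return float(np.sqrt(np.mean(vals**2) / 2.0))
    raise ValidationError(f"method: expected 'mean' or 'rms', got {method!r}")


def noise_floor_correct(magnitude, sigma: float):
    """Power subtraction: sqrt(max(M² - 2 sigma², 0)).

    Removes the Rician floor in expectation (E[M²] = S² + 2 sigma² for
    single-coil data); magnitudes below sqrt(2) sigma map to 0.
    """
    if sigma < 0:
        raise ValidationError(f"sigma: must be >= 0, got {sigma}")
    magnitude = np.asarray(magnitude, dtype=float)
    out = np.sqrt(np.maximum(magnitude**2 - 2.0 * sigma**2, 0.0))
    return out if out.ndim else float(out)
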
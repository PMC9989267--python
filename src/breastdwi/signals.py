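"""Forward diffusion-weighted signal models.

Three nested models of the signal attenuation ``S(b)/S0`` measured with
diffusion sensitization ``b``:

* Gaussian (mono-exponential): ``exp(-b * ADC0)`` — free/hindered diffusion
  with a single diffusivity.
* IVIM bi-exponential: a fast pseudo-diffusion compartment for capillary
  blood (fraction ``f_ivim``, decay rate ``D* + D_blood``) plus the tissue
  compartment.
* IVIM-kurtosis: the tissue compartment additionally carries a quadratic
  log-signal term ``(b*ADC0)^2 * K / 6`` quantifying non-Gaussian diffusion.

Units are fixed throughout the package: b-values in s/mm², diffusivities in
mm²/s, so every exponent is dimensionless. Signal amplitudes are in
arbitrary units set by ``s0``.

Two synthesis modes are offered for the kurtosis model:

``physical``
    Evaluates the model verbatim. The quadratic exponent turns over at
    ``b = 3/(ADC0*K)``; beyond it the model predicts a (non-physical)
    rising signal, so requests past the turnover raise
    :class:`~breastdwi.errors.ModelValidityError` instead of silently
    producing garbage.

``assumption_matched``
    Mirrors the assumption under which the abbreviated 4-b estimators are
    derived: the perfusion compartment contributes fully at the smallest
    b-value of the scheme and exactly zero at every larger b. This mode
    exists so estimator algebra can be tested in isolation from
    model-mismatch bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ModelValidityError, ValidationError

__all__ = [
    "DEFAULT_D_BLOOD",
    "DEFAULT_D_STAR",
    "AcquisitionScheme",
    "TissueState",
    "SignalCurve",
    "ivim_signal",
    "ivim_kurtosis_signal",
    "validity_bmax",
    "kurtosis_attenuation",
]

#: Default water diffusion coefficient in blood, mm²/s (used for synthesis;
#: a configuration default, not a measured constant).
DEFAULT_D_BLOOD = 1.7e-3

#: Default pseudo-diffusion coefficient of the blood compartment, mm²/s.
DEFAULT_D_STAR = 10.0e-3


@dataclass(frozen=True)
class AcquisitionScheme:
    """The b-values (and optional gradient directions) of an acquisition.

    Parameters
    ----------
    b_values
        Diffusion sensitizations in s/mm², strictly ascending, all >= 0,
        at least two.
    directions
        Optional array of unit 3-vectors, one per b-value. ``None`` means
        the scheme is direction-agnostic.
    """

    b_values: tuple[float, ...]
    directions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        if b.ndim != 1 or b.size < 2:
            raise ValidationError("b_values: need at least two b-values")
        if np.any(b < 0):
            raise ValidationError("b_values: all b-values must be >= 0")
        if np.any(np.diff(b) <= 0):
            raise ValidationError(
                "b_values: must be strictly ascending with no duplicates"
            )
        if self.directions is not None:
            g = np.asarray(self.directions, dtype=float)
            if g.shape != (b.size, 3):
                raise ValidationError(
                    f"directions: expected shape ({b.size}, 3), got {g.shape}"
                )
            norms = np.linalg.norm(g, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValidationError("directions: each must have unit norm (1e-9)")
            object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return len(self.b_values)

    @property
    def b_array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def b_min(self) -> float:
        return self.b_values[0]

    def index_of(self, b: float, atol: float = 1e-6) -> int:
        """Index of a b-value in the scheme (within ``atol``)."""
        diffs = np.abs(self.b_array - b)
        i = int(np.argmin(diffs))
        if diffs[i] > atol:
            raise ValidationError(f"b_values: scheme does not contain b={b}")
        return i


@dataclass(frozen=True)
class TissueState:
    """Per-voxel ground-truth or estimated model parameters.

    Houses every symbol of the IVIM-kurtosis model: ``s0`` (unweighted
    amplitude), ``f_ivim`` (circulating-blood fraction), ``d_star`` (D*,
    pseudo-diffusion), ``d_blood`` (water diffusivity in blood), ``adc0``
    (virtual tissue diffusivity ADC0, which plays D in the pure IVIM model
    when K=0) and ``kurtosis`` (K, dimensionless).
    """

    s0: float = 1.0
    f_ivim: float = 0.0
    d_star: float = DEFAULT_D_STAR
    d_blood: float = DEFAULT_D_BLOOD
    adc0: float = 1.0e-3
    kurtosis: float = 0.0

    def __post_init__(self) -> None:
        checks = {
            "s0": self.s0,
            "d_star": self.d_star,
            "d_blood": self.d_blood,
            "adc0": self.adc0,
            "kurtosis": self.kurtosis,
            "f_ivim": self.f_ivim,
        }
        for name, v in checks.items():
            if not np.isfinite(v):
                raise ValidationError(f"{name}: must be finite, got {v}")
        if self.s0 <= 0:
            raise ValidationError(f"s0: must be > 0, got {self.s0}")
        if self.adc0 <= 0:
            raise ValidationError(f"adc0: must be > 0, got {self.adc0}")
        if not (0.0 <= self.f_ivim < 1.0):
            raise ValidationError(f"f_ivim: must lie in [0, 1), got {self.f_ivim}")
        for name in ("d_star", "d_blood", "kurtosis"):
            if checks[name] < 0:
                raise ValidationError(f"{name}: must be >= 0, got {checks[name]}")


@dataclass
class SignalCurve:
    """Signal amplitudes over a scheme (one value per b-value)."""

    scheme: AcquisitionScheme
    amplitudes: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.shape != (len(self.scheme),):
            raise ValidationError(
                f"amplitudes: expected {len(self.scheme)} values, got {amp.shape}"
            )
        if np.any(amp < 0):
            raise ValidationError("amplitudes: must be >= 0")
        self.amplitudes = amp

    def normalize(self) -> "SignalCurve":
        """Return a copy scaled so the amplitude at the smallest b equals 1."""
        a0 = self.amplitudes[0]
        if a0 <= 0:
            raise ValidationError("amplitudes: cannot normalize, amplitude at "
                                  "smallest b is not > 0")
        return SignalCurve(self.scheme, self.amplitudes / a0, normalized=True)

    def to_table(self, path) -> None:
        """Write a two-column plain-text table (b, amplitude)."""
        np.savetxt(
            path,
            np.column_stack([self.scheme.b_array, self.amplitudes]),
            header="b_s_per_mm2 amplitude",
            fmt="%.10g",
        )

    @classmethod
    def from_table(cls, path) -> "SignalCurve":
        data = np.loadtxt(path, ndmin=2)
        scheme = AcquisitionScheme(tuple(data[:, 0]))
        return cls(scheme, data[:, 1])


def kurtosis_attenuation(b, adc0, kurtosis):
    """Tissue-compartment attenuation exp(-b*ADC0 + (b*ADC0)^2 * K / 6).

    Broadcasts over arrays; no validity checking (callers decide).
    """
    b = np.asarray(b, dtype=float)
    x = b * np.asarray(adc0, dtype=float)
    return np.exp(-x + x * x * np.asarray(kurtosis, dtype=float) / 6.0)


def validity_bmax(tissue: TissueState) -> float:
    """Largest b at which the kurtosis model decays, 3/(ADC0*K).

    The quadratic log-signal term turns over at this b; beyond it the
    model predicts rising signal, which is non-physical. Returns +inf for
    K = 0 (mono-exponential, no turnover).
    """
    if tissue.adc0 <= 0:
        raise ValidationError(f"adc0: must be > 0, got {tissue.adc0}")
    if tissue.kurtosis == 0:
        return float("inf")
    return 3.0 / (tissue.adc0 * tissue.kurtosis)


def ivim_signal(scheme: AcquisitionScheme, tissue: TissueState) -> SignalCurve:
    """IVIM bi-exponential signal (kurtosis ignored, i.e. treated as 0).

    ``S(b) = s0 * { f * exp[-b (D* + D_blood)] + (1-f) * exp(-b * ADC0) }``
    """
    b = scheme.b_array
    fast = np.exp(-b * (tissue.d_star + tissue.d_blood))
    slow = np.exp(-b * tissue.adc0)
    amp = tissue.s0 * (tissue.f_ivim * fast + (1.0 - tissue.f_ivim) * slow)
    return SignalCurve(scheme, amp)


def ivim_kurtosis_signal(
    scheme: AcquisitionScheme,
    tissue: TissueState,
    mode: str = "physical",
) -> SignalCurve:
    """IVIM-kurtosis signal in ``physical`` or ``assumption_matched`` mode.

    See module docstring for the two modes. Raises
    :class:`ModelValidityError` when physical mode is asked for a b beyond
    the turnover ``3/(ADC0*K)``.
    """
    if mode not in ("physical", "assumption_matched"):
        raise ValidationError(
            f"mode: expected 'physical' or 'assumption_matched', got {mode!r}"
        )
    b = scheme.b_array
    tissue_part = kurtosis_attenuation(b, tissue.adc0, tissue.kurtosis)
    f = tissue.f_ivim
    if mode == "physical":
        bmax = validity_bmax(tissue)
        if b[-1] > bmax * (1 + 1e-12):
            raise ModelValidityError(
                f"b={b[-1]:g} s/mm² exceeds the kurtosis-model turnover "
                f"b_max = 3/(ADC0*K) = {bmax:g} s/mm²; beyond it the model "
                "predicts rising signal (use assumption_matched mode or "
                "restrict the scheme)"
            )
        fast = np.exp(-b * (tissue.d_star + tissue.d_blood))
        amp = tissue.s0 * (f * fast + (1.0 - f) * tissue_part)
    else:
        # perfusion contributes fully at the smallest b, exactly zero above
        amp = tissue.s0 * (1.0 - f) * tissue_part
        amp[0] = tissue.s0 * (f + (1.0 - f) * tissue_part[0])
    return SignalCurve(scheme, amp)
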
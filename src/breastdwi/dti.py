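"""Diffusion tensor estimation and scalar metrics (MD, FA, eigenvalues).

When diffusion is anisotropic — in the breast, around ducts in glandular
tissue — a single ADC is insufficient; the symmetric 3x3 diffusion
tensor D describes diffusivity along every direction via g'Dg. With at
least six non-collinear gradient directions plus a low-b reference the
tensor follows from a log-linear least-squares solve of

    ln S(b, g) = ln S0 - b * g' D g.

Scalar metrics:

* mean diffusivity MD = (l1 + l2 + l3)/3, the orientation-invariant ADC;
* fractional anisotropy
  FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2), 0 for
  isotropic diffusion, 1 in the single-nonzero-eigenvalue limit;
* the eigenvalue range l1 - l3.

A 3-orthogonal-direction MD shortcut is included for comparison: it
equals the full-tensor MD only when the axes coincide with the tensor's
eigenvectors (or the tensor is isotropic) and should not be used under
strong anisotropy. Because a DTI acquisition repeats b-values across
directions, this module takes plain (signals, b_values, directions)
arrays rather than an :class:`~breastdwi.signals.AcquisitionScheme`
(whose b-values are unique by contract).

Eigenvalue estimates are highly noise-sensitive (the sorting operation is
non-linear); negative eigenvalues from noisy fits are clipped to zero
with a qc flag rather than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConditioningError, ValidationError

__all__ = [
    "DiffusionTensor",
    "TensorMetrics",
    "fit_tensor",
    "tensor_metrics",
    "md_three_orthogonal",
    "tensor_signal",
    "fibonacci_directions",
    "tensor_from_eigenvalues",
]


@dataclass
class DiffusionTensor:
    """Symmetric second-order tensor with sorted eigen-decomposition."""

    matrix: np.ndarray
    s0: float = 1.0
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)  # columns e1, e2, e3
    qc_flags: frozenset = field(init=False, default=frozenset())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError(f"matrix: expected 3x3, got {m.shape}")
        m = (m + m.T) / 2.0  # exact symmetry by construction
        self.matrix = m
        vals, vecs = np.linalg.eigh(m)
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        vecs = vecs[:, order]
        flags = set()
        if np.any(vals < 0):
            flags.add("negative_eigenvalue_clipped")
            vals = np.maximum(vals, 0.0)
        self.eigenvalues = vals
        self.eigenvectors = vecs
        self.qc_flags = frozenset(flags)


@dataclass(frozen=True)
class TensorMetrics:
    md: float
    fa: float
    eigenvalues: tuple[float, float, float]
    lambda_range: float  # l1 - l3
    qc_flags: frozenset = frozenset()


def tensor_from_eigenvalues(eigenvalues, rotation=None) -> np.ndarray:
    """Construct a tensor matrix with given eigenvalues, optionally rotated."""
    lam = np.diag(np.asarray(eigenvalues, dtype=float))
    if rotation is None:
        return lam
    r = np.asarray(rotation, dtype=float)
    return r @ lam @ r.T


def tensor_signal(s0, b_values, directions, tensor_matrix) -> np.ndarray:
    """Forward DTI signal S = s0 * exp(-b * g'Dg) for each (b, g) pair."""
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(directions, dtype=float)
    quad = np.einsum("ij,jk,ik->i", g, np.asarray(tensor_matrix), g)
    return s0 * np.exp(-b * quad)


def _design_row(g):
    gx, gy, gz = g
    return np.array([gx * gx, gy * gy, gz * gz,
                     2 * gx * gy, 2 * gx * gz, 2 * gy * gz])


def fit_tensor(signals, b_values, directions) -> DiffusionTensor:
    """Log-linear least-squares tensor fit.

    Needs at least 6 directions with non-degenerate geometry plus one
    low-b measurement (7 rows total for the 7 unknowns ln S0 and the six
    tensor components). Rank deficiency raises
    :class:`~breastdwi.errors.ConditioningError`.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(directions, dtype=float)
    if s.shape != b.shape or g.shape != (b.size, 3):
        raise ValidationError(
            "signals/b_values/directions: inconsistent shapes")
    if np.any(s <= 0):
        raise ValidationError("signals: must be > 0 for the log-linear fit")
    norms = np.linalg.norm(g, axis=1)
    nonzero = b > 0
    if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
        raise ValidationError("directions: diffusion-weighted directions "
                              "must have unit norm")
    design = np.zeros((b.size, 7))
    design[:, 0] = 1.0
    for i in range(b.size):
        design[i, 1:] = -b[i] * _design_row(g[i])
    rank = np.linalg.matrix_rank(design, tol=1e-10 * max(1.0, b.max()))
    if rank < 7:
        raise ConditioningError(
            f"directions: design matrix rank {rank} < 7 — need >= 6 "
            "non-collinear, non-coplanar diffusion directions plus a low-b "
            "measurement")
    x, *_ = np.linalg.lstsq(design, np.log(s), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = x[1:]
    m = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    return DiffusionTensor(matrix=m, s0=float(np.exp(x[0])))


def tensor_metrics(tensor: DiffusionTensor) -> TensorMetrics:
    """MD, FA and eigenvalue range of a tensor.

    An all-zero tensor has undefined FA; it is reported as 0 with a
    ``zero_tensor`` qc flag.
    """
    lam = tensor.eigenvalues
    md = float(lam.mean())
    denom = float(np.sqrt(np.sum(lam**2)))
    flags = set(tensor.qc_flags)
    if denom == 0.0:
        fa = 0.0
        flags.add("zero_tensor")
    else:
        fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - md) ** 2)) / denom)
    return TensorMetrics(md=md, fa=fa,
                         eigenvalues=tuple(float(v) for v in lam),
                         lambda_range=float(lam[0] - lam[2]),
                         qc_flags=frozenset(flags))


def md_three_orthogonal(s_reference, signals_xyz, b: float,
                        axes=None, combine: str = "signal_mean") -> float:
    """MD approximation from exactly three orthogonal directions.

    Two combination conventions:

    ``signal_mean`` (default)
        The common vendor shortcut: average the three diffusion-weighted
        signals, then take one two-point ADC. By Jensen's inequality this
        *underestimates* MD whenever the three axis diffusivities differ
        (any anisotropic tensor), and matches MD exactly for isotropic
        diffusion — the reason the shortcut should not be used under
        strong anisotropy.

    ``adc_mean``
        Average the three axis-wise two-point ADCs. For a pure tensor
        signal this equals (Dxx + Dyy + Dzz)/3 = trace/3 = MD exactly in
        *any* orientation (the trace is rotation invariant), so it is
        exact noise-free; under noise it inherits per-axis log-signal
        bias.
    """
    if axes is None:
        axes = np.eye(3)
    if combine not in ("signal_mean", "adc_mean"):
        raise ValidationError(
            f"combine: expected 'signal_mean' or 'adc_mean', got {combine!r}")
    axes = np.asarray(axes, dtype=float)
    if axes.shape != (3, 3):
        raise ValidationError("axes: expected three 3-vectors (3x3)")
    gram = axes @ axes.T
    if not np.allclose(gram, np.eye(3), atol=1e-6):
        raise ValidationError("axes: the three directions must be orthonormal")
    s = np.asarray(signals_xyz, dtype=float)
    if s.shape != (3,):
        raise ValidationError("signals_xyz: expected exactly 3 signals")
    if s_reference <= 0 or np.any(s <= 0):
        raise ValidationError("signals: must be > 0")
    if b <= 0:
        raise ValidationError("b: must be > 0")
    if combine == "adc_mean":
        adcs = np.log(s_reference / s) / b
        return float(adcs.mean())
    return float(np.log(s_reference / s.mean()) / b)


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` well-spread unit vectors on the upper hemisphere (deterministic).

    A Fibonacci-lattice construction; for n >= 6 the resulting DTI design
    is full rank.
    """
    if n < 1:
        raise ValidationError(f"n: must be >= 1, got {n}")
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = (i + 0.5) / n  # upper hemisphere only (antipodes are equivalent)
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    g = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)
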
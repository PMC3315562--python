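"""Discrete and continuous B-splines and the direct/indirect spline transforms.

A centered B-spline of degree ``n`` is the (n+1)-fold self-convolution of the
unit-width indicator.  Its integer-lattice samples, after expansion by an
integer factor ``m``, form the *discrete* B-spline ``b^n_m`` — the FIR kernel
of the indirect spline transform.  This module builds those kernels (both by
direct sampling and by the moving-average convolution identity), computes
interpolation coefficients by an exact banded solve (the direct transform),
and reconstructs signals from coefficients at arbitrary integral rates (the
indirect transform).

All convolutions use whole-sample mirror extension at the boundaries unless
zero-padding is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.signal import fftconvolve

__all__ = [
    "KernelSeq",
    "SplineParams",
    "continuous_bspline",
    "discrete_bspline",
    "discrete_bspline_via_convolution",
    "direct_transform",
    "indirect_transform",
    "mirror_index",
    "extend_signal",
]

BOUNDARY_MODES = ("mirror", "zero")


@dataclass(frozen=True)
class KernelSeq:
    """A finite symmetric filter with an explicit center.

    ``taps[j]`` sits at spatial position ``(j - center_index)/m`` for an
    expansion factor ``m``; when ``half_shift`` is set the positions are
    ``(j - center_index + 1/2)/m`` and the true symmetry center lies between
    ``center_index - 1`` and ``center_index``.  The half shift occurs only
    for even expansion factors combined with even degree, where no integer
    lattice point coincides with the kernel center.
    """

    taps: np.ndarray
    center_index: int
    half_shift: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "taps", np.asarray(self.taps, dtype=float))
        if self.taps.ndim != 1 or self.taps.size == 0:
            raise ValueError("taps must be a non-empty 1-D sequence")
        if not (0 <= self.center_index < self.taps.size):
            raise ValueError("center_index must index into taps")

    @property
    def support(self) -> int:
        return int(self.taps.size)

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        t = self.taps
        if self.half_shift:
            c = self.center_index
            left = t[:c][::-1]
            right = t[c:]
            k = min(left.size, right.size)
            pad_ok = (abs(left[k:]) < tol).all() and (abs(right[k:]) < tol).all()
            return bool(pad_ok and np.allclose(left[:k], right[:k], atol=tol))
        c = self.center_index
        left = t[:c][::-1]
        right = t[c + 1:]
        k = min(left.size, right.size)
        pad_ok = (abs(left[k:]) < tol).all() and (abs(right[k:]) < tol).all()
        return bool(pad_ok and np.allclose(left[:k], right[:k], atol=tol))


@dataclass(frozen=True)
class SplineParams:
    """Spline degree, expansion/decimation factor and boundary mode.

    The polynomial *degree* is the API-level parameter; the spline *order*
    customary in the approximation literature is ``degree + 1`` (so the
    default cubic, degree 3, is a fourth-order spline).
    """

    degree: int = 3
    m: int = 1
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.m < 1:
            raise ValueError("expansion factor m must be >= 1")
        if self.boundary not in BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {BOUNDARY_MODES}")


def continuous_bspline(x, degree: int):
    """Evaluate the centered continuous B-spline ``beta^degree`` at ``x``.

    Uses the stable two-term recursion

        beta^n(x) = [ (x + (n+1)/2) beta^{n-1}(x + 1/2)
                      + ((n+1)/2 - x) beta^{n-1}(x - 1/2) ] / n

    starting from the symmetric unit indicator (value 1/2 at |x| = 1/2).
    Symmetric about 0, supported on [-(degree+1)/2, (degree+1)/2],
    non-negative, and integrates to 1.

    Accepts scalars or arrays; returns the same shape.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    xa = np.asarray(x, dtype=float)
    out = _beta_recursive(xa, int(degree))
    if np.isscalar(x) or xa.ndim == 0:
        return float(out)
    return out


def _beta_recursive(x: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        ax = np.abs(x)
        return np.where(ax < 0.5, 1.0, np.where(ax == 0.5, 0.5, 0.0))
    b_plus = _beta_recursive(x + 0.5, n - 1)
    b_minus = _beta_recursive(x - 0.5, n - 1)
    h = (n + 1) / 2.0
    return ((x + h) * b_plus + (h - x) * b_minus) / n


def discrete_bspline(degree: int, m: int) -> KernelSeq:
    """Discrete B-spline ``b^degree_m``: lattice samples of the continuous
    B-spline expanded by the integer factor ``m``.

    For odd ``m``, or odd ``degree``, the sampling lattice is ``i/m`` and the
    kernel is symmetric about an integer tap.  When both ``m`` and ``degree``
    are even the kernel center falls between lattice points; the samples are
    taken on the half-shifted lattice ``(i + 1/2)/m`` (the convention under
    which the moving-average convolution identity holds exactly) and the
    returned kernel carries ``half_shift=True``.

    The taps are non-negative and sum to ``m`` (partition of unity under
    m-fold sampling).
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if m < 1:
        raise ValueError("expansion factor m must be >= 1")
    n = int(degree)
    if m % 2 == 0 and n % 2 == 0:
        half = m * (n + 1) // 2
        i = np.arange(-half, half)
        taps = _beta_recursive((i + 0.5) / m, n)
        return KernelSeq(taps=taps, center_index=half, half_shift=True)
    edge = m * (n + 1) / 2.0
    imax = int(np.ceil(edge)) if edge != int(edge) else int(edge)
    i = np.arange(-imax, imax + 1)
    taps = _beta_recursive(i / m, n)
    nz = np.nonzero(taps)[0]
    taps = taps[nz[0]: nz[-1] + 1]
    center = imax - nz[0]
    return KernelSeq(taps=taps, center_index=int(center))


def discrete_bspline_via_convolution(degree: int, m: int) -> KernelSeq:
    """Build ``b^degree_m`` from repeated moving-average convolutions.

    Uses the identity: convolving the width-``m`` moving average with itself
    ``degree + 1`` times, then with the unit-lattice kernel ``b^degree_1``
    and dividing by ``m**degree``, reproduces the sampled discrete B-spline.
    When ``m`` is even each moving-average factor carries a half-sample
    offset; for odd ``degree`` the offsets pair up and cancel, while for even
    ``degree`` a net half-sample shift remains and the result is identified
    with the half-shifted kernel of :func:`discrete_bspline`.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if m < 1:
        raise ValueError("expansion factor m must be >= 1")
    n = int(degree)
    u = np.ones(m, dtype=float)
    taps = np.array([1.0])
    for _ in range(n + 1):
        taps = np.convolve(taps, u)
    if n > 0:
        b1 = discrete_bspline(n, 1)
        taps = np.convolve(taps, b1.taps) / float(m) ** n
    L = taps.size
    if m % 2 == 0 and n % 2 == 0:
        # net half-sample shift: length m(n+1), center between L/2-1 and L/2
        return KernelSeq(taps=taps, center_index=L // 2, half_shift=True)
    return KernelSeq(taps=taps, center_index=(L - 1) // 2)


def mirror_index(p, n: int):
    """Map extended indices onto [0, n) by whole-sample mirror reflection."""
    if n == 1:
        return np.zeros_like(np.asarray(p))
    period = 2 * n - 2
    q = np.mod(p, period)
    return np.where(q < n, q, period - q)


def extend_signal(g: np.ndarray, left: int, right: int, boundary: str = "mirror") -> np.ndarray:
    """Extend ``g`` by ``left``/``right`` samples under the boundary mode."""
    if boundary == "zero":
        return np.pad(g, (left, right))
    if g.size == 1:
        return np.full(left + 1 + right, g[0], dtype=float)
    idx = mirror_index(np.arange(-left, g.size + right), g.size)
    return g[idx]


def _interp_kernel(degree: int) -> KernelSeq:
    return discrete_bspline(degree, 1)


def direct_transform(signal, degree: int, boundary: str = "mirror"):
    """Interpolation coefficients of ``signal`` for a degree-``degree`` spline.

    Solves the banded symmetric Toeplitz system defined by the unit-lattice
    kernel ``b^degree_1`` exactly (no truncated recursive filtering), under
    the chosen boundary extension, so that the indirect transform at ``m = 1``
    reproduces the input samples to solver precision.
    """
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if boundary not in BOUNDARY_MODES:
        raise ValueError(f"boundary must be one of {BOUNDARY_MODES}")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    ker = _interp_kernel(degree)
    h = ker.center_index  # half-bandwidth
    if h == 0:
        return g.copy()
    N = g.size
    # Matrix of the m = 1 indirect transform under coefficient mirror
    # extension: sample i receives taps of coefficients i-h .. i+h, with
    # out-of-range coefficient indices reflected (period 2N - 2).  The
    # reflection makes the matrix symmetric; rows sum to 1 (partition of
    # unity), so constant signals yield constant coefficients.
    ab = np.zeros((2 * h + 1, N))
    for d in range(-h, h + 1):
        tap = ker.taps[ker.center_index + d]
        if d >= 0:
            ab[h - d, d:] = tap
        else:
            ab[h - d, : N + d] = tap
    if boundary == "mirror" and N > 1:
        for i in range(min(h, N)):
            for d in range(i + 1, h + 1):
                k = int(mirror_index(i - d, N))
                if abs(k - i) <= h:
                    ab[h + (i - k), k] += ker.taps[ker.center_index + d]
        for i in range(max(0, N - h), N):
            for d in range(N - i, h + 1):
                k = int(mirror_index(i + d, N))
                if abs(k - i) <= h:
                    ab[h + (i - k), k] += ker.taps[ker.center_index + d]
    return solve_banded((h, h), ab, g)


def synthesis_offset(m: int) -> int:
    """Integer alignment of coefficient ``k`` at signal position ``k*m + offset``.

    Chosen so that at degree 0 each coefficient governs the contiguous block
    ``[k*m, (k+1)*m)`` — the block-mean convention that fixes the phase of
    the whole least-squares pipeline.
    """
    return m // 2


def indirect_transform(coeffs, degree: int, m: int, out_length: int,
                       boundary: str = "mirror") -> np.ndarray:
    """Reconstruct a signal from spline coefficients at expansion ``m``.

    Up-samples ``coeffs`` by zero insertion, convolves with ``b^degree_m``
    and aligns coefficient ``k`` at position ``k*m + m//2``.  Under mirror
    boundary handling the coefficient sequence is first extended by
    whole-sample reflection, so constants are reproduced exactly up to the
    signal edges; the result is truncated to ``out_length``.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("coeffs must be a non-empty 1-D sequence")
    if m < 1:
        raise ValueError("expansion factor m must be >= 1")
    if out_length < 1:
        raise ValueError("out_length must be >= 1")
    if m == 1 and c.size != out_length:
        raise ValueError("at m = 1 out_length must equal the coefficient count")
    if (c.size - 1) * m + 1 > out_length + m * (degree + 1) + m:
        raise ValueError("coefficient count inconsistent with out_length and m")
    ker = discrete_bspline(degree, m)
    ext = ker.support // m + 2  # extra coefficients covering the boundary
    ce = extend_signal(c, ext, ext, boundary)
    up = np.zeros((ce.size - 1) * m + 1)
    up[::m] = ce
    if up.size * ker.support > 500_000:
        full = fftconvolve(up, ker.taps)
    else:
        full = np.convolve(up, ker.taps)
    # tap j of coefficient k lands at k*m + offset + (j - center_index);
    # the extension shifts coefficient indices by ext
    start = -ext * m + synthesis_offset(m) - ker.center_index
    lo = -start
    return full[lo: lo + out_length].copy()
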
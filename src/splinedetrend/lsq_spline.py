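"""Least-squares spline approximation on a coarse knot lattice.

The orthogonal projection of a discrete signal onto the space spanned by
B-splines of degree ``n`` on knots spaced ``m`` samples apart is computed by
a three-step filtering procedure:

1. *prefilter* — correlate the signal with the expanded kernel ``b^n_m``
   (this evaluates the inner products with every candidate basis function);
2. *decimate* — keep the correlation values at the knot positions;
3. *postfilter* — solve the banded symmetric positive-definite Gram system
   (the sampled autocorrelation of the expanded B-spline) for the expansion
   coefficients.

Coefficient ``k`` is anchored at signal position ``k*m + m//2``, so that at
degree 0 the procedure reduces exactly to block averaging.  At the signal
boundaries the basis is symmetrised by mirror reflection of the coefficient
index (period ``2M - 2``) and restricted to the signal domain — the same
convention as the indirect transform — so the fit is the exact orthogonal
projection onto that space: idempotent, energy-contracting, and identical
to the brute-force normal-equations oracle at every knot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import fftconvolve

from .bspline_core import (
    KernelSeq,
    SplineParams,
    discrete_bspline,
    extend_signal,
    indirect_transform,
    mirror_index,
    synthesis_offset,
)

__all__ = [
    "LsqModel",
    "prefilter",
    "decimate",
    "postfilter",
    "gram_kernel",
    "lsq_coefficients",
    "lsq_project",
    "brute_force_lsq",
]


@dataclass(frozen=True)
class LsqModel:
    """Result of a least-squares spline fit.

    ``coeffs`` holds the ``knots`` expansion coefficients; ``gram`` is the
    interior band of the basis autocorrelation operator whose inverse is the
    postfilter.
    """

    params: SplineParams
    knots: int
    coeffs: np.ndarray
    gram: KernelSeq

    def __post_init__(self) -> None:
        if self.coeffs.size != self.knots:
            raise ValueError("coefficient count must equal the knot count")


def _correlate(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """'valid'-mode correlation, FFT-accelerated for large problems."""
    if x.size * taps.size > 500_000:
        return fftconvolve(x, taps[::-1], mode="valid")
    return np.correlate(x, taps, mode="valid")


def _kernel_and_start(degree: int, m: int) -> tuple[KernelSeq, int]:
    ker = discrete_bspline(degree, m)
    return ker, synthesis_offset(m) - ker.center_index


def prefilter(signal, degree: int, m: int, boundary: str = "mirror") -> np.ndarray:
    """Correlate ``signal`` with ``b^degree_m`` under boundary extension.

    Output sample ``t`` is the inner product of the (extended) signal with
    the kernel anchored at ``t``; output length equals input length.
    """
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    ker = discrete_bspline(degree, m)
    c = ker.center_index
    ge = extend_signal(g, c, ker.support - 1 - c, boundary)
    return _correlate(ge, ker.taps)


def decimate(seq, m: int, phase: int = 0) -> np.ndarray:
    """Every ``m``-th sample of ``seq`` starting at ``phase``."""
    s = np.asarray(seq, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("seq must be a non-empty 1-D sequence")
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= phase < m:
        raise ValueError("phase must satisfy 0 <= phase < m")
    return s[phase::m].copy()


def gram_kernel(degree: int, m: int) -> KernelSeq:
    """Interior band of the Gram operator: the autocorrelation of ``b^degree_m``
    sampled on the knot lattice (lag step ``m``).

    Equals ``m`` times the knot samples of the degree ``2*degree + 1``
    B-spline up to lattice-sampling effects; the discrete autocorrelation is
    used because it is the exact normal-equations band.
    """
    ker = discrete_bspline(degree, m)
    t = ker.taps
    bands = [float(np.dot(t, t))]
    d = 1
    while d * m < t.size:
        bands.append(float(np.dot(t[: -d * m], t[d * m:])))
        d += 1
    taps = np.array(bands[::-1][:-1] + bands)
    return KernelSeq(taps=taps, center_index=len(bands) - 1)


def _edge_depth(degree: int, m: int) -> int:
    ker = discrete_bspline(degree, m)
    return ker.support // m + 2


def _basis_column(N: int, M: int, k: int, degree: int, m: int,
                  boundary: str) -> np.ndarray:
    """Column ``k`` of the design matrix: the degree-``degree`` basis function
    anchored at knot ``k``, with mirrored coefficient-index partners folded
    in, restricted to the signal domain ``[0, N)``."""
    ker, start_rel = _kernel_and_start(degree, m)
    col = np.zeros(N)
    E = _edge_depth(degree, m)
    if boundary == "mirror" and M > 1:
        partners = [ke for ke in range(-E, M + E)
                    if int(mirror_index(ke, M)) == k]
    else:
        partners = [k]
    for ke in partners:
        p = np.arange(ke * m + start_rel, ke * m + start_rel + ker.support)
        keep = (p >= 0) & (p < N)
        np.add.at(col, p[keep], ker.taps[keep])
    return col


def postfilter(decimated, degree: int, m: int, boundary: str = "mirror",
               signal_length: int | None = None) -> np.ndarray:
    """Apply the inverse Gram operator to a decimated correlation track.

    Solves the banded symmetric positive-definite system whose band is
    :func:`gram_kernel`.  When ``signal_length`` is given, the Gram entries
    of knots whose (boundary-symmetrised) support crosses the signal edge
    are corrected, making the solution the exact normal-equations solution.
    """
    d = np.asarray(decimated, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("decimated sequence must be non-empty")
    M = d.size
    gk = gram_kernel(degree, m)
    nb = min(gk.center_index, M - 1)  # off-diagonal bands
    ab = np.zeros((nb + 1, M))
    for j in range(nb + 1):
        ab[nb - j, j:] = gk.taps[gk.center_index + j]
    if signal_length is not None:
        E = min(_edge_depth(degree, m), M)
        edge = sorted(set(range(E)) | set(range(max(0, M - E), M)))
        cache: dict[int, np.ndarray] = {}

        def col(k: int) -> np.ndarray:
            if k not in cache:
                cache[k] = _basis_column(signal_length, M, k, degree, m, boundary)
            return cache[k]

        for k in edge:
            for l in range(max(0, k - nb), min(M, k + nb + 1)):
                r, c = (k, l) if k <= l else (l, k)
                ab[nb - (c - r), c] = float(col(k) @ col(l))
    return solveh_banded(ab, d)


def lsq_coefficients(signal, degree: int, m: int,
                     boundary: str = "mirror") -> LsqModel:
    """Least-squares spline coefficients by prefilter -> decimate -> postfilter.

    The returned coefficients minimise the residual sum of squares over the
    coarse spline space with knot spacing ``m`` (knot count
    ``M = (N-1)//m + 1``), matching the brute-force normal-equations oracle
    at every knot.
    """
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if m < 1:
        raise ValueError("m must be >= 1")
    if g.size < m:
        raise ValueError("signal must span at least one knot interval")
    N = g.size
    M = (N - 1) // m + 1
    phase = synthesis_offset(m)
    ker, start_rel = _kernel_and_start(degree, m)
    E = _edge_depth(degree, m)
    # inner products of the zero-truncated signal with every candidate basis
    # position, from knot -E to knot M - 1 + E
    lo = -E * m + start_rel
    hi = (M - 1 + E) * m + start_rel + ker.support - 1
    ge = np.zeros(hi - lo + 1)
    a, b = max(0, lo), min(N, hi + 1)
    ge[a - lo: b - lo] = g[a:b]
    track = _correlate(ge, ker.taps)  # track[t] anchors at position lo + center + t
    knot_t = (np.arange(-E, M + E) * m + phase) - (lo + ker.center_index)
    vals = track[knot_t]
    rhs = np.zeros(M)
    if boundary == "mirror" and M > 1:
        np.add.at(rhs, mirror_index(np.arange(-E, M + E), M), vals)
    else:
        rhs[:] = vals[E: E + M]
    coeffs = postfilter(rhs, degree, m, boundary, signal_length=N)
    return LsqModel(
        params=SplineParams(degree=degree, m=m, boundary=boundary),
        knots=M,
        coeffs=coeffs,
        gram=gram_kernel(degree, m),
    )


def lsq_project(signal, degree: int, m: int, boundary: str = "mirror") -> np.ndarray:
    """Orthogonal projection of ``signal`` onto the coarse spline space.

    Reconstructs the least-squares coefficients through the indirect
    transform at expansion ``m``; idempotent, with residual orthogonal to
    every basis function.
    """
    g = np.asarray(signal, dtype=float)
    model = lsq_coefficients(g, degree, m, boundary)
    return indirect_transform(model.coeffs, degree, m, g.size, boundary)


def brute_force_lsq(signal, degree: int, m: int,
                    boundary: str = "mirror") -> np.ndarray:
    """Normal-equations oracle: explicit design matrix, direct solve.

    Builds the matrix of shifted, m-expanded B-spline basis functions under
    the same boundary convention as the filtering path and solves
    ``(A^T A) c = A^T g`` densely.  Guarded to small problem sizes.
    """
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if m < 1:
        raise ValueError("m must be >= 1")
    N = g.size
    M = (N - 1) // m + 1
    if N > 10**5 or M > 10**3:
        raise ValueError("problem too large for the brute-force oracle")
    A = np.column_stack([
        _basis_column(N, M, k, degree, m, boundary) for k in range(M)
    ])
    return np.linalg.solve(A.T @ A, A.T @ g)
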
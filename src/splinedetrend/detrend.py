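"""Removal of low-frequency head-motion components from accelerometry axes.

The primary method approximates the head-motion component as a least-squares
spline on a coarse knot lattice whose knot rate is a low resampling
frequency ``f_r`` (well below the swallowing vibration band but at least
twice the head-motion band edge), and subtracts it.  Three baseline
detrenders are provided for comparison: the smoothness priors method (SPM,
a second-difference-regularised smoother applied over fixed subintervals),
piecewise polynomial fitting (PPF), and empirical mode decomposition (EMD)
with low-frequency intrinsic mode functions assigned to the trend.

Every method returns a :class:`DetrendResult` whose ``trend + residual``
reconstructs the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded

from .lsq_spline import lsq_project

__all__ = [
    "DetrendResult",
    "ResamplingChoice",
    "choose_resampling",
    "spline_detrend",
    "spm_detrend",
    "spm_lambda_for_cutoff",
    "ppf_detrend",
    "emd_detrend",
    "emd_sift",
]

METHODS = ("spline", "spm", "ppf", "emd")


@dataclass(frozen=True)
class DetrendResult:
    """Trend estimate and detrended residual for one axis.

    ``trend + residual`` equals the input signal to machine precision for
    every method; ``params_used`` records the effective method parameters.
    """

    trend: np.ndarray
    residual: np.ndarray
    method: str
    params_used: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.trend.shape != self.residual.shape:
            raise ValueError("trend and residual lengths must agree")


@dataclass(frozen=True)
class ResamplingChoice:
    """Integer decimation factor realising a requested resampling frequency.

    ``m = round(f_s / f_r)`` samples per knot interval; ``realized_fr`` is
    the frequency actually achieved, ``f_s / m``.
    """

    f_s: float
    f_r: float
    m: int
    M: int
    realized_fr: float


def choose_resampling(f_s: float, f_r: float, signal_length: int) -> ResamplingChoice:
    """Map a target resampling frequency to a knot lattice.

    The knot count is ``M = (N - 1) // m + 1`` with ``m = round(f_s / f_r)``;
    ``f_r`` must lie in ``(0, f_s / 2)`` so the knot lattice undersamples the
    signal.
    """
    if f_s <= 0:
        raise ValueError("sampling frequency must be positive")
    if not 0 < f_r < f_s / 2:
        raise ValueError("resampling frequency must satisfy 0 < f_r < f_s / 2")
    if signal_length < 2:
        raise ValueError("signal_length must be >= 2")
    m = max(2, int(round(f_s / f_r)))
    M = (signal_length - 1) // m + 1
    return ResamplingChoice(f_s=f_s, f_r=f_r, m=m, M=M, realized_fr=f_s / m)


def spline_detrend(signal, f_s: float, f_r: float, degree: int = 3) -> DetrendResult:
    """Estimate and remove the head-motion trend by least-squares splines.

    The trend is the orthogonal projection of the signal onto cubic
    (default) splines with knot rate ``f_r``; the residual keeps the
    swallowing vibrations, whose band lies far above ``f_r``.
    """
    g = np.asarray(signal, dtype=float)
    choice = choose_resampling(f_s, f_r, g.size)
    trend = lsq_project(g, degree, choice.m)
    return DetrendResult(
        trend=trend,
        residual=g - trend,
        method="spline",
        params_used={"f_s": f_s, "f_r": f_r, "degree": degree,
                     "m": choice.m, "M": choice.M,
                     "realized_fr": choice.realized_fr},
    )


def spm_lambda_for_cutoff(f_s: float, f_c: float) -> float:
    """Smoothness-priors regularisation whose -3 dB cutoff is near ``f_c``.

    The smoother's frequency response is ``1 / (1 + lam^2 (2 sin(w/2))^4)``;
    solving for half power at ``w_c = 2 pi f_c / f_s`` gives
    ``lam = 1 / (2 sin(w_c / 2))^2 ~ (f_s / (2 pi f_c))^2``.
    """
    if not 0 < f_c < f_s / 2:
        raise ValueError("cutoff must satisfy 0 < f_c < f_s / 2")
    wc = 2 * np.pi * f_c / f_s
    return 1.0 / (2 * np.sin(wc / 2)) ** 2


def _spm_block(y: np.ndarray, lam: float) -> np.ndarray:
    n = y.size
    if n < 3:
        return y.copy()
    # pentadiagonal I + lam^2 D2^T D2 in solveh_banded upper form, where D2
    # is the (n-2) x n second-difference operator with rows (1, -2, 1)
    l2 = lam * lam
    j = np.arange(n)
    diag = 1.0 + l2 * ((j <= n - 3) + 4.0 * ((j >= 1) & (j <= n - 2)) + (j >= 2))
    off1 = -2.0 * l2 * ((j - 1 <= n - 3).astype(float) + ((j >= 2) & (j - 2 <= n - 3)))
    off2 = np.full(n, l2)
    ab = np.zeros((3, n))
    ab[0, 2:] = off2[2:]
    ab[1, 1:] = off1[1:]
    ab[2] = diag
    return solveh_banded(ab, y)


def spm_detrend(signal, regularization: float,
                n_subintervals: int = 1000) -> DetrendResult:
    """Smoothness priors detrending over equal-length subintervals.

    Within each of ``n_subintervals`` contiguous blocks (the last absorbs
    the remainder), the trend solves the second-difference-regularised
    least-squares problem ``min ||y - z||^2 + lam^2 ||D2 z||^2``.  Large
    ``lam`` drives each block trend to its straight-line fit; ``lam -> 0``
    reproduces the block exactly.  Set ``n_subintervals=1`` for whole-signal
    smoothing.
    """
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if not 1 <= n_subintervals <= g.size:
        raise ValueError("n_subintervals must be in [1, signal length]")
    trend = np.empty_like(g)
    bounds = _block_bounds(g.size, n_subintervals)
    for a, b in bounds:
        trend[a:b] = _spm_block(g[a:b], regularization)
    return DetrendResult(
        trend=trend, residual=g - trend, method="spm",
        params_used={"regularization": regularization,
                     "n_subintervals": n_subintervals},
    )


def _block_bounds(N: int, n_blocks: int) -> list[tuple[int, int]]:
    """Equal-length contiguous blocks; the last absorbs the remainder."""
    size = N // n_blocks
    bounds = [(i * size, (i + 1) * size) for i in range(n_blocks)]
    a, _ = bounds[-1]
    bounds[-1] = (a, N)
    return bounds


def ppf_detrend(signal, n_subintervals: int = 5000,
                poly_degree: int = 2) -> DetrendResult:
    """Piecewise polynomial fitting: an ordinary least-squares polynomial of
    ``poly_degree`` per contiguous subinterval is taken as the trend."""
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    if poly_degree < 0:
        raise ValueError("poly_degree must be >= 0")
    if not 1 <= n_subintervals <= g.size:
        raise ValueError("n_subintervals must be in [1, signal length]")
    size = g.size // n_subintervals
    if size < poly_degree + 1:
        raise ValueError("each subinterval needs at least poly_degree + 1 samples")
    trend = np.empty_like(g)
    # all full blocks share one Vandermonde matrix: solve them as a batch
    n_full = n_subintervals - 1
    if n_full > 0:
        x = np.linspace(-1, 1, size)
        V = np.vander(x, poly_degree + 1)
        P = V @ np.linalg.pinv(V)  # hat matrix, size x size
        Y = g[: n_full * size].reshape(n_full, size).T
        trend[: n_full * size] = (P @ Y).T.ravel()
    a = n_full * size
    xl = np.linspace(-1, 1, g.size - a)
    Vl = np.vander(xl, poly_degree + 1)
    trend[a:] = Vl @ np.linalg.lstsq(Vl, g[a:], rcond=None)[0]
    return DetrendResult(
        trend=trend, residual=g - trend, method="ppf",
        params_used={"n_subintervals": n_subintervals, "poly_degree": poly_degree},
    )


# ---------------------------------------------------------------------------
# Empirical mode decomposition


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    # collapse exact plateaus so diff sign changes are well defined
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.arange(d.size)[nz]
    sv = s[nz]
    change = np.diff(sv)
    maxima = idx[1:][change == -2] + 1
    minima = idx[1:][change == 2] + 1
    return maxima, minima


def _envelope(x: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirrored end extrema."""
    n = x.size
    xs = list(ext)
    ys = list(x[ext])
    # mirror the two outermost extrema about each signal end
    head_x = [-p for p in ext[1::-1] if p > 0]          # descending -> ascending
    head_y = [x[p] for p in ext[1::-1] if p > 0]
    tail_x = [2 * (n - 1) - p for p in ext[-1:-3:-1] if p < n - 1]
    tail_y = [x[p] for p in ext[-1:-3:-1] if p < n - 1]
    xs = np.array(head_x + xs + tail_x, dtype=float)
    ys = np.array(head_y + ys + tail_y, dtype=float)
    keep = np.concatenate([[True], np.diff(xs) > 0])
    cs = CubicSpline(xs[keep], ys[keep])
    return cs(np.arange(n))


def emd_sift(signal, max_imfs: int = 12, sd_stop: float = 0.05,
             max_sifts: int = 50) -> tuple[list[np.ndarray], np.ndarray]:
    """Empirical mode decomposition by standard sifting.

    Upper/lower envelopes are cubic splines through the maxima/minima with
    the two outermost extrema mirrored past each end; sifting of one mode
    stops when the normalised successive-difference criterion drops below
    ``sd_stop`` or after ``max_sifts`` iterations.  Returns the intrinsic
    mode functions and the final residue; their sum reconstructs the input
    exactly.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("signal must be 1-D with at least 16 samples")
    imfs: list[np.ndarray] = []
    residue = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        for _ in range(max_sifts):
            mx, mn = _extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - mean_env
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_stop:
                break
        imfs.append(h)
        residue = residue - h
    return imfs, residue


def _mean_frequency(x: np.ndarray, f_s: float) -> float:
    """Zero-crossing estimate of a mode's mean frequency in Hz."""
    s = np.sign(x)
    s[s == 0] = 1
    crossings = int(np.count_nonzero(np.diff(s)))
    duration = x.size / f_s
    return crossings / (2.0 * duration)


def emd_detrend(signal, f_s: float, trend_cutoff: float) -> DetrendResult:
    """EMD-based detrending: the trend is the sifting residue plus every
    intrinsic mode function whose zero-crossing mean frequency falls below
    ``trend_cutoff``; monotone or otherwise extrema-free inputs yield
    ``trend = signal``."""
    g = np.asarray(signal, dtype=float)
    if g.ndim != 1 or g.size < 16:
        raise ValueError("signal must be 1-D with at least 16 samples")
    if trend_cutoff <= 0:
        raise ValueError("trend_cutoff must be positive")
    imfs, residue = emd_sift(g)
    trend = residue.copy()
    kept = []
    for i, imf in enumerate(imfs):
        f = _mean_frequency(imf, f_s)
        if f < trend_cutoff:
            trend = trend + imf
            kept.append(i)
    return DetrendResult(
        trend=trend, residual=g - trend, method="emd",
        params_used={"f_s": f_s, "trend_cutoff": trend_cutoff,
                     "n_imfs": len(imfs), "trend_imfs": kept},
    )
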
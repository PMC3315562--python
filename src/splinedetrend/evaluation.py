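"""Error metrics, Monte-Carlo experiments and rank-based statistics.

Two simulation studies quantify detrending accuracy on synthetic
recordings:

* the *resampling-frequency sweep* finds, per axis and noise level, the
  knot rate minimising the trend-estimation mean square error, and tests
  whether the optimum depends on SNR (Kruskal-Wallis across SNR groups);
* the *method comparison* scores the normalised MSE of the spline, SPM,
  PPF and EMD detrenders over an SNR grid, either redrawing the whole
  signal per realization or freezing trend and swallow components and
  redrawing only the noise.

NMSE is the trend-estimation MSE divided by the mean power of the true
trend, so the all-zero estimator scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .detrend import (
    emd_detrend,
    ppf_detrend,
    spline_detrend,
    spm_detrend,
    spm_lambda_for_cutoff,
)
from .synthetic import AXES, SyntheticConfig, gen_recording

__all__ = [
    "mse",
    "nmse",
    "mann_whitney",
    "kruskal_wallis",
    "SweepResult",
    "ComparisonResult",
    "fr_sweep_experiment",
    "method_comparison_experiment",
    "default_fr_grid",
]

DEFAULT_FR = {"ap": 4.0, "si": 4.0}  # calibration default: twice the 0-2 Hz band edge


def mse(true_trend, est_trend) -> float:
    """Mean squared sample-wise difference."""
    a = np.asarray(true_trend, dtype=float)
    b = np.asarray(est_trend, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    return float(np.mean((a - b) ** 2))


def nmse(true_trend, est_trend) -> float:
    """MSE normalised by the mean power of the true trend."""
    a = np.asarray(true_trend, dtype=float)
    power = float(np.mean(a * a))
    if power <= 0:
        raise ValueError("true trend must have positive energy")
    return mse(true_trend, est_trend) / power


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def kruskal_wallis(groups) -> float:
    """Kruskal-Wallis p-value (rank H statistic with tie correction)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise ValueError("need at least two non-empty groups")
    if np.ptp(np.concatenate(gs)) == 0:
        return 1.0
    return float(stats.kruskal(*gs).pvalue)


def default_fr_grid() -> np.ndarray:
    """Resampling-frequency grid for sweeps: 0.5-10 Hz in 0.25 Hz steps."""
    return np.arange(0.5, 10.0 + 1e-9, 0.25)


def _spawn_seeds(master_seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(master_seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass
class SweepResult:
    """Per-SNR distributions of the MSE-minimising resampling frequency."""

    snr_grid_db: np.ndarray
    fr_grid: np.ndarray
    best_fr: dict[str, np.ndarray]     # axis -> (n_snr, n_realizations)
    kw_p_value: dict[str, float]
    mean_fr: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis in AXES:
            for i, snr in enumerate(self.snr_grid_db):
                for r, fr in enumerate(self.best_fr[axis][i]):
                    rows.append({"axis": axis, "snr_db": float(snr),
                                 "realization": r, "best_fr_hz": float(fr)})
        return pd.DataFrame(rows)


def fr_sweep_experiment(cfg: SyntheticConfig,
                        fr_grid=None,
                        snr_grid_db=None,
                        n_realizations: int = 20,
                        master_seed: int = 0,
                        degree: int = 3) -> SweepResult:
    """Find the per-axis resampling frequency minimising trend MSE.

    For every SNR level and realization, a fresh recording is generated,
    spline-detrended at every frequency on ``fr_grid``, and the
    MSE-minimising frequency recorded.  A Kruskal-Wallis test across SNR
    groups per axis assesses whether the optimum depends on the noise level.
    """
    fr_grid = default_fr_grid() if fr_grid is None else np.asarray(fr_grid, float)
    snr_grid_db = np.arange(0.0, 31.0, 5.0) if snr_grid_db is None \
        else np.asarray(snr_grid_db, float)
    if fr_grid.size == 0 or np.any(fr_grid <= 0) or np.any(fr_grid >= cfg.f_s / 2):
        raise ValueError("fr_grid must lie in (0, f_s/2)")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rngs = _spawn_seeds(master_seed, len(snr_grid_db) * n_realizations)
    best = {axis: np.zeros((len(snr_grid_db), n_realizations)) for axis in AXES}
    for i, snr in enumerate(snr_grid_db):
        for r in range(n_realizations):
            c = SyntheticConfig(**{**cfg.__dict__, "snr_db": float(snr)})
            rec, truth = gen_recording(c, rngs[i * n_realizations + r])
            for axis in AXES:
                errs = [mse(truth.trend[axis],
                            spline_detrend(rec.channel(axis), c.f_s, fr,
                                           degree).trend)
                        for fr in fr_grid]
                best[axis][i, r] = fr_grid[int(np.argmin(errs))]
    kw, mean_fr = {}, {}
    for axis in AXES:
        groups = [best[axis][i] for i in range(len(snr_grid_db))]
        if len(groups) < 2 or n_realizations < 2:
            kw[axis] = 1.0
        else:
            kw[axis] = kruskal_wallis(groups)
        mean_fr[axis] = float(best[axis].mean())
    return SweepResult(snr_grid_db=snr_grid_db, fr_grid=fr_grid, best_fr=best,
                       kw_p_value=kw, mean_fr=mean_fr)


@dataclass
class ComparisonResult:
    """Mean and standard error of NMSE per method, axis and SNR."""

    snr_grid_db: np.ndarray
    methods: tuple[str, ...]
    condition: str
    nmse_mean: dict[tuple[str, str], np.ndarray]  # (method, axis) -> per-SNR
    nmse_se: dict[tuple[str, str], np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (method, axis), means in self.nmse_mean.items():
            ses = self.nmse_se[(method, axis)]
            for snr, mu, se in zip(self.snr_grid_db, means, ses):
                rows.append({"method": method, "axis": axis,
                             "snr_db": float(snr), "nmse_mean": float(mu),
                             "nmse_se": float(se), "condition": self.condition})
        return pd.DataFrame(rows)


def _make_detrenders(cfg: SyntheticConfig, fr: dict[str, float],
                     spm_subintervals: int, ppf_subintervals: int,
                     ppf_degree: int) -> dict[str, Callable]:
    lam = {axis: spm_lambda_for_cutoff(cfg.f_s, fr[axis]) for axis in AXES}
    return {
        "spline": lambda x, axis: spline_detrend(x, cfg.f_s, fr[axis]).trend,
        "spm": lambda x, axis: spm_detrend(x, lam[axis], spm_subintervals).trend,
        "ppf": lambda x, axis: ppf_detrend(x, ppf_subintervals, ppf_degree).trend,
        "emd": lambda x, axis: emd_detrend(x, cfg.f_s, fr[axis] / 2).trend,
    }


def method_comparison_experiment(cfg: SyntheticConfig,
                                 methods=("spline", "spm", "ppf", "emd"),
                                 snr_grid_db=None,
                                 n_realizations: int = 50,
                                 condition: str = "all_random",
                                 master_seed: int = 0,
                                 fr: dict[str, float] | None = None,
                                 spm_subintervals: int = 1000,
                                 ppf_subintervals: int = 5000,
                                 ppf_degree: int = 2) -> ComparisonResult:
    """Monte-Carlo NMSE comparison of the four detrenders over an SNR grid.

    ``condition='all_random'`` redraws trend and swallow components for
    every realization; ``'fixed_trend_new_noise'`` freezes them at the
    master seed and redraws only the additive noise.
    """
    snr_grid_db = np.arange(0.0, 31.0, 1.0) if snr_grid_db is None \
        else np.asarray(snr_grid_db, float)
    if condition not in ("all_random", "fixed_trend_new_noise"):
        raise ValueError("unknown condition")
    methods = tuple(methods)
    unknown = set(methods) - {"spline", "spm", "ppf", "emd"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    fr = dict(DEFAULT_FR) if fr is None else fr
    detrenders = _make_detrenders(cfg, fr, spm_subintervals,
                                  ppf_subintervals, ppf_degree)
    scores = {(mth, axis): np.zeros((len(snr_grid_db), n_realizations))
              for mth in methods for axis in AXES}

    if condition == "fixed_trend_new_noise":
        from .synthetic import add_noise  # local to keep module surface tidy
        base_rng = np.random.default_rng(np.random.SeedSequence(master_seed))
        frozen_cfg = SyntheticConfig(**{**cfg.__dict__, "snr_db": np.inf})
        rec0, truth0 = gen_recording(frozen_cfg, base_rng)
        noise_rngs = _spawn_seeds(master_seed + 1,
                                  len(snr_grid_db) * n_realizations)
        for i, snr in enumerate(snr_grid_db):
            for r in range(n_realizations):
                rng = noise_rngs[i * n_realizations + r]
                for axis in AXES:
                    clean = truth0.trend[axis] + truth0.swallow[axis]
                    noisy, _ = add_noise(clean, float(snr), rng)
                    for mth in methods:
                        est = detrenders[mth](noisy, axis)
                        scores[(mth, axis)][i, r] = nmse(truth0.trend[axis], est)
    else:
        rngs = _spawn_seeds(master_seed, len(snr_grid_db) * n_realizations)
        for i, snr in enumerate(snr_grid_db):
            for r in range(n_realizations):
                c = SyntheticConfig(**{**cfg.__dict__, "snr_db": float(snr)})
                rec, truth = gen_recording(c, rngs[i * n_realizations + r])
                for axis in AXES:
                    x = rec.channel(axis)
                    for mth in methods:
                        est = detrenders[mth](x, axis)
                        scores[(mth, axis)][i, r] = nmse(truth.trend[axis], est)

    means = {k: v.mean(axis=1) for k, v in scores.items()}
    ses = {k: v.std(axis=1, ddof=1) / np.sqrt(n_realizations)
           if n_realizations > 1 else np.zeros(len(snr_grid_db))
           for k, v in scores.items()}
    return ComparisonResult(snr_grid_db=snr_grid_db, methods=methods,
                            condition=condition, nmse_mean=means, nmse_se=ses)
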
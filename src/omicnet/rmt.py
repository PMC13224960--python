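"""Random-matrix-theory selection of the correlation threshold.

The nearest-neighbor spacing distribution (NNSD) of the eigenvalues of a
correlation matrix follows the Wigner surmise of the Gaussian orthogonal
ensemble, P(s) = (pi s / 2) exp(-pi s^2 / 4), while an uncorrelated
(noise-free, block-diagonal) spectrum follows the Poisson law exp(-s).
Sweeping the hard threshold t upward and hard-zeroing |r| < t, the NNSD
transitions from GOE-like to Poisson-like once the noise-level
correlations have been removed; the smallest t at which the Poisson fit
wins (for a run of consecutive grid points) is the data-driven threshold.

Eigenvalues are unfolded with the parameter-free empirical-CDF midrank
map, so the mean spacing is exactly 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from . import config

__all__ = ["RMTScan", "nnsd", "rmt_scan", "nnsd_chi2"]


@dataclass
class RMTScan:
    """Threshold-scan record: per-threshold goodness of fit and the call."""

    thresholds: np.ndarray
    chi2_poisson: np.ndarray
    chi2_goe: np.ndarray
    n_eigen: np.ndarray
    chosen: float | None
    notes: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "threshold": self.thresholds,
            "chi2_poisson": self.chi2_poisson,
            "chi2_goe": self.chi2_goe,
            "n_eigen": self.n_eigen,
        })


def nnsd(eigenvalues, degeneracy_tol: float = config.RMT_DEGENERACY_TOL) -> np.ndarray:
    """Unfolded nearest-neighbor spacings of a spectrum.

    Eigenvalues are sorted, near-degenerate values (closer than
    ``degeneracy_tol``) collapsed, and the spectrum unfolded through a
    smoothed midrank empirical CDF: a cubic smoothing spline is fitted to
    (lambda_i, (i + 0.5)/N) and each eigenvalue mapped to N * F_smooth,
    which strips the global density profile and leaves the local spacing
    fluctuations.  Spacings are renormalized so the mean is exactly 1.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if lam.size < config.RMT_MIN_EIGEN:
        raise ValueError(f"need at least {config.RMT_MIN_EIGEN} eigenvalues, got {lam.size}")
    if not np.isfinite(lam).all():
        raise ValueError("non-finite eigenvalue")
    keep = np.concatenate([[True], np.diff(lam) > degeneracy_tol])
    lam = lam[keep]
    n = lam.size
    if n < config.RMT_MIN_EIGEN:
        raise ValueError("degenerate spectrum: too few distinct eigenvalues")
    return _unfold(lam)


def _unfold(lam: np.ndarray) -> np.ndarray:
    """Spline-smoothed ECDF unfolding of a sorted, distinct spectrum.

    The outer ``config.RMT_UNFOLD_TRIM`` fraction of eigenvalues is
    trimmed at each spectral edge (edge states and isolated outliers
    distort the smooth density estimate), then a cubic spline with fixed
    smoothing ``config.RMT_SPLINE_SMOOTH`` is fitted to the midrank ECDF
    and each eigenvalue mapped through it.
    """
    n = lam.size
    k = int(config.RMT_UNFOLD_TRIM * n)
    if k and n - 2 * k >= config.RMT_MIN_EIGEN:
        lam = lam[k:n - k]
        n = lam.size
    ranks = (np.arange(n) + 0.5) / n
    spline = UnivariateSpline(lam, ranks, k=3, s=config.RMT_SPLINE_SMOOTH)
    e = n * spline(lam)
    spacings = np.diff(e)
    spacings = spacings[spacings > 0]  # a non-monotone fit wiggle is discarded
    if spacings.size == 0:
        raise ValueError("unfolding collapsed the spectrum")
    return spacings / spacings.mean()


def _wigner_pdf(s: np.ndarray) -> np.ndarray:
    return (np.pi * s / 2.0) * np.exp(-np.pi * s * s / 4.0)


def _poisson_pdf(s: np.ndarray) -> np.ndarray:
    return np.exp(-s)


def nnsd_chi2(
    spacings: np.ndarray,
    n_bins: int = config.RMT_N_BINS,
    s_max: float = config.RMT_S_MAX,
) -> tuple[float, float]:
    """Chi-square distances of an observed NNSD to the Poisson law and the
    Wigner (GOE) surmise, on ``n_bins`` equal bins over [0, s_max]."""
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(np.clip(spacings, 0, s_max - 1e-12), bins=edges)
    obs = obs / max(1, spacings.size)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    exp_p = _poisson_pdf(centers) * width
    exp_g = _wigner_pdf(centers) * width
    chi_p = float(np.sum((obs - exp_p) ** 2 / np.where(exp_p > 0, exp_p, 1.0)))
    chi_g = float(np.sum((obs - exp_g) ** 2 / np.where(exp_g > 0, exp_g, 1.0)))
    return chi_p, chi_g


def rmt_scan(
    r_matrix,
    t_min: float = config.RMT_T_MIN,
    t_max: float = config.RMT_T_MAX,
    step: float = config.RMT_T_STEP,
    n_bins: int = config.RMT_N_BINS,
    consecutive: int = config.RMT_CONSECUTIVE,
) -> RMTScan:
    """Scan hard thresholds over [t_min, t_max] and pick the GOE-to-Poisson
    transition point.

    At each t the correlation matrix is hard-thresholded (entries with
    |r| < t zeroed, unit diagonal kept), eigendecomposed, its NNSD
    computed, and chi-square distances to the Poisson and Wigner laws
    recorded.  ``chosen`` is the smallest t at which the Poisson fit beats
    the GOE fit for ``consecutive`` grid points with at least
    ``config.RMT_MIN_EIGEN`` usable eigenvalues; ``None`` if no t
    qualifies.
    """
    r = np.asarray(getattr(r_matrix, "values", r_matrix), dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("r_matrix must be square")
    if not np.allclose(r, r.T, equal_nan=True):
        raise ValueError("r_matrix must be symmetric")
    if step <= 0 or t_max <= t_min:
        raise ValueError("need t_min < t_max and step > 0")
    if not (0 <= t_min and t_max < 1):
        raise ValueError("threshold grid must lie within [0, 1)")
    r = np.nan_to_num(r, nan=0.0)

    grid = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    chi_p = np.full(grid.size, np.nan)
    chi_g = np.full(grid.size, np.nan)
    n_eig = np.zeros(grid.size, dtype=int)
    notes: list[str] = []

    for k, t in enumerate(grid):
        rt = np.where(np.abs(r) >= t, r, 0.0)
        np.fill_diagonal(rt, np.diag(r))
        lam = np.linalg.eigvalsh(rt)
        lam = np.sort(lam)
        keep = np.concatenate([[True], np.diff(lam) > config.RMT_DEGENERACY_TOL])
        lam = lam[keep]
        n_eig[k] = lam.size
        if lam.size < config.RMT_MIN_EIGEN:
            continue
        s = _unfold(lam)
        chi_p[k], chi_g[k] = nnsd_chi2(s, n_bins=n_bins)

    chosen = None
    ok = (chi_p < chi_g) & (n_eig >= config.RMT_MIN_EIGEN)
    for k in range(grid.size - consecutive + 1):
        if ok[k:k + consecutive].all():
            chosen = float(grid[k])
            break
    if chosen is None:
        notes.append("no GOE-to-Poisson transition detected on the grid")
    if (n_eig < config.RMT_MIN_EIGEN).all():
        notes.append("degenerate spectra at every threshold")
    return RMTScan(thresholds=grid, chi2_poisson=chi_p, chi2_goe=chi_g,
                   n_eigen=n_eig, chosen=chosen, notes=notes)
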
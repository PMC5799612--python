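"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Combines the biased per-window histograms into one unbiased free-energy
profile W(z) by self-consistent iteration of the standard WHAM pair of
equations (Kumar-style, single reaction coordinate):

    P(z) = Σ_i n_i(z) / Σ_i N_i · exp[(F_i − U_i(z)) / k_B T]
    F_i  = −k_B T · ln Σ_z P(z) · exp[−U_i(z) / k_B T]

with harmonic biases U_i(z) = ½ k_i (z − z_i)². Iteration starts from
F_i = 0 and stops when the largest change in any window free energy falls
below ``tolerance`` (gauge-fixed, so only F differences matter). The PMF
is W(z) = −k_B T ln P(z), shifted so its minimum is zero; bins no window
visited are masked undefined rather than zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import kt
from .sampling_io import Profile, UmbrellaDataset, UmbrellaWindow

__all__ = ["WhamResult", "run_wham", "WhamOverlapWarning"]


class WhamOverlapWarning(UserWarning):
    """Adjacent windows share no occupied histogram bins."""


@dataclass
class WhamResult:
    pmf: Profile
    window_free_energies: np.ndarray
    n_iterations: int
    converged: bool
    histogram: np.ndarray  # counts, shape (n_windows, n_bins)
    bin_centers: np.ndarray

    @property
    def density(self) -> Profile:
        """Unbiased probability density ρ(z) (Å⁻¹), integrating to 1."""
        mask = self.pmf.defined_mask
        dz = self.bin_centers[1] - self.bin_centers[0]
        p = np.where(mask, np.exp(-self.pmf.values / self._kt), 0.0)
        p /= p.sum() * dz
        p = np.where(mask, p, np.nan)
        return Profile(self.bin_centers, p, defined_mask=mask, units="Å⁻¹")

    _kt: float = 1.0  # set by run_wham


def _pool_windows(windows: list[UmbrellaWindow]) -> list[UmbrellaWindow]:
    """Concatenate series of windows sharing a center (and spring)."""
    pooled: dict[tuple[float, float], UmbrellaWindow] = {}
    out: list[UmbrellaWindow] = []
    for w in windows:
        key = (w.center_z, w.spring_k)
        if key in pooled:
            prev = pooled[key]
            merged = UmbrellaWindow(
                center_z=w.center_z,
                spring_k=w.spring_k,
                timestep=prev.timestep,
                series=np.concatenate([prev.series, w.series]),
                source_path=prev.source_path,
            )
            pooled[key] = merged
            out[out.index(prev)] = merged
        else:
            pooled[key] = w
            out.append(w)
    return out


def run_wham(
    dataset: UmbrellaDataset,
    bin_width: float = 0.2,
    tolerance: float = 1e-6,
    max_iter: int = 100_000,
    pool_duplicates: bool = False,
    f_init: np.ndarray | None = None,
) -> WhamResult:
    """Solve WHAM for ``dataset`` and return the min-anchored PMF.

    The histogram range spans [min center − 3σ, max center + 3σ] with
    σ = sqrt(k_B T / k) of the softest window, so the restrained
    distributions are fully covered. Duplicate-center windows are kept
    separate unless ``pool_duplicates``; ``f_init`` seeds the window free
    energies (default all zero).

    Per-bin PMF errors are a Poisson estimate k_B T / sqrt(n(z)) from the
    total bin count; it ignores time correlation and is a lower bound.
    """
    kT = kt(dataset.temperature)
    windows = [w for w in dataset.loaded().windows]
    if not windows:
        raise ValueError("dataset has no windows")
    for w in windows:
        if w.series.size < 2:
            raise ValueError(f"window at z={w.center_z} has fewer than 2 samples")
    if pool_duplicates:
        windows = _pool_windows(windows)

    sigma = np.sqrt(kT / min(w.spring_k for w in windows))
    lo = min(w.center_z for w in windows) - 3.0 * sigma
    hi = max(w.center_z for w in windows) + 3.0 * sigma
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.series, bins=edges)[0] for w in windows])
    n_i = counts.sum(axis=1).astype(float)  # samples actually inside range
    tot = counts.sum(axis=0).astype(float)
    occupied = tot > 0

    _warn_on_gaps(windows, counts)

    # Boltzmann factors of each bias at each bin center, in log space
    k_arr = np.array([w.spring_k for w in windows])
    c_arr = np.array([w.center_z for w in windows])
    u_bias = 0.5 * k_arr[:, None] * (centers[None, :] - c_arr[:, None]) ** 2
    log_b = -u_bias / kT  # (n_win, n_bins)

    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, dtype=float)
    log_n_i = np.log(np.where(n_i > 0, n_i, 1.0))
    converged = False
    it = 0
    with np.errstate(divide="ignore"):
        log_tot = np.where(occupied, np.log(np.where(occupied, tot, 1.0)), -np.inf)
    from scipy.special import logsumexp

    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ln N_i + (F_i + log_b*kT terms)]
        log_den = logsumexp(log_n_i[:, None] + f[:, None] / kT + log_b, axis=0)
        log_p = log_tot - log_den
        f_new = -kT * logsumexp(log_b + log_p[None, :], axis=1, b=None)
        f_new -= f_new[0]  # gauge: only differences matter
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations (max |dF| = {delta:.3g})",
            UserWarning,
        )

    w_vals = np.where(occupied, -kT * log_p, np.nan)
    w_vals -= np.nanmin(w_vals)
    errors = np.where(occupied, kT / np.sqrt(np.where(occupied, tot, 1.0)), np.nan)
    pmf = Profile(centers, w_vals, errors=errors, defined_mask=occupied, units="kcal/mol")
    res = WhamResult(
        pmf=pmf,
        window_free_energies=f,
        n_iterations=it,
        converged=converged,
        histogram=counts,
        bin_centers=centers,
    )
    res._kt = kT
    return res


def _warn_on_gaps(windows, counts) -> None:
    order = np.argsort([w.center_z for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            warnings.warn(
                "no histogram overlap between windows at "
                f"z={windows[a].center_z} and z={windows[b].center_z}",
                WhamOverlapWarning,
            )
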
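"""PMF post-processing: symmetrization, anchoring, features, partitioning.

A membrane PMF W(z) is defined up to an additive constant and, for a
symmetric bilayer, should be even in z. This module provides the standard
manipulations applied to raw WHAM output before thermodynamic quantities
are read off it:

* ``symmetrize`` — average W(z) and W(−z); the half-difference is the
  asymmetry error bar.
* ``anchor_bulk`` — shift so the bulk-water plateau (|z| ≥ 30 Å by
  default) averages to zero.
* ``extract_features`` — central peak, interfacial well, barrier height.
* ``partition_coefficient`` — Boltzmann integral of the PMF,
  K = 1/(z₂−z₁) ∫ exp(−[W(z)−W(z₁)]/k_BT) dz, and ΔG = −k_BT ln K.
* ``pka_shift_profile`` — depth-dependent pKa shift from paired
  neutral/charged PMFs, ΔpKa(z) = [ΔW_neutral(z) − ΔW_charged(z)] /
  (ln10 · k_BT).
* ``boltzmann_invert`` — −k_BT ln ρ(z) from unbiased position samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import LN10, kt
from .sampling_io import Profile

__all__ = [
    "PmfFeatures",
    "PartitionResult",
    "symmetrize",
    "anchor_bulk",
    "extract_features",
    "partition_coefficient",
    "pka_shift_profile",
    "boltzmann_invert",
    "dG_from_K",
]


@dataclass
class PmfFeatures:
    """Peak/well/barrier summary of a membrane PMF (kcal/mol, Å)."""

    w_peak: float
    z_peak: float
    w_well: float
    z_well: float
    w_barrier: float

    def __post_init__(self) -> None:
        assert self.w_barrier == self.w_peak - self.w_well


@dataclass
class PartitionResult:
    """Water→membrane partition coefficient and free energy."""

    K: float
    dG: float
    K_error: float
    dG_error: float
    z1: float
    z2: float


def dG_from_K(K: float, temperature: float) -> float:
    """ΔG = −k_B T ln K (kcal/mol). Shared by partitioning and ionization."""
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    return -kt(temperature) * float(np.log(K))


def symmetrize(pmf: Profile) -> Profile:
    """Return ½[W(z) + W(−z)] with asymmetry errors ½|W(z) − W(−z)|.

    The mirrored value is obtained by linear interpolation when −z falls
    off-grid. Points whose mirror is undefined stay undefined.
    """
    z = pmf.z_grid
    if z[0] >= 0 or z[-1] <= 0:
        raise ValueError("symmetrization needs a grid spanning both signs of z")
    mirrored = pmf.interpolate(-z)
    own = np.where(pmf.defined_mask, pmf.values, np.nan)
    both = np.isfinite(own) & np.isfinite(mirrored)
    vals = np.where(both, 0.5 * (own + mirrored), np.nan)
    errs = np.where(both, 0.5 * np.abs(own - mirrored), np.nan)
    return Profile(z, vals, errors=errs, defined_mask=both, units=pmf.units)


def anchor_bulk(pmf: Profile, bulk_min_abs_z: float = 30.0) -> Profile:
    """Shift the PMF so the mean over |z| ≥ ``bulk_min_abs_z`` is zero.

    Both bulk sides are pooled; at least one defined bulk point is
    required.
    """
    sel = (np.abs(pmf.z_grid) >= bulk_min_abs_z) & pmf.defined_mask
    if not np.any(sel):
        raise ValueError(f"no defined PMF points with |z| >= {bulk_min_abs_z}")
    shift = float(np.mean(pmf.values[sel]))
    vals = np.where(pmf.defined_mask, pmf.values - shift, np.nan)
    return Profile(
        pmf.z_grid, vals, errors=pmf.errors, defined_mask=pmf.defined_mask, units=pmf.units
    )


def extract_features(
    pmf: Profile,
    peak_search: tuple[float, float] = (0.0, 5.0),
    well_search: tuple[float, float] = (5.0, 35.0),
) -> PmfFeatures:
    """Locate the central peak and interfacial well of an anchored PMF.

    ``peak_search``/``well_search`` are |z| intervals: the peak is the
    maximum of W with |z| in [0, 5] Å, the well the minimum with
    5 < |z| ≤ 35 Å by default. The barrier is their difference.
    """
    az = np.abs(pmf.z_grid)
    pk = (az >= peak_search[0]) & (az <= peak_search[1]) & pmf.defined_mask
    wl = (az > well_search[0]) & (az <= well_search[1]) & pmf.defined_mask
    if not np.any(pk):
        raise ValueError(f"no defined PMF points in peak search |z| range {peak_search}")
    if not np.any(wl):
        raise ValueError(f"no defined PMF points in well search |z| range {well_search}")
    ip = np.flatnonzero(pk)[np.argmax(pmf.values[pk])]
    iw = np.flatnonzero(wl)[np.argmin(pmf.values[wl])]
    w_peak = float(pmf.values[ip])
    w_well = float(pmf.values[iw])
    return PmfFeatures(
        w_peak=w_peak,
        z_peak=float(pmf.z_grid[ip]),
        w_well=w_well,
        z_well=float(pmf.z_grid[iw]),
        w_barrier=w_peak - w_well,
    )


def partition_coefficient(
    pmf: Profile,
    z1: float = -40.0,
    z2: float = 40.0,
    temperature: float = 310.0,
    reference: str = "mean",
) -> PartitionResult:
    """Partition coefficient K(wat→mem) by Boltzmann integration of the PMF.

    K = 1/(z₂−z₁) ∫_{z₁}^{z₂} exp(−[W(z) − W_ref]/k_BT) dz by trapezoidal
    quadrature on the native grid (plus the exact bounds), with
    ΔG = −k_BT ln K. ``reference`` picks W_ref among the two aqueous
    endpoints: "left" (W(z₁)), "right" (W(z₂)) or "mean" of the two.

    Uncertainty: first-order propagation of the per-bin PMF errors through
    the integrand treating bins as independent (an approximation — real
    WHAM bin errors are correlated).
    """
    if not z1 < z2:
        raise ValueError("need z1 < z2")
    kT = kt(temperature)
    # evaluation grid: native points inside [z1, z2] plus the bounds
    inside = (pmf.z_grid >= z1) & (pmf.z_grid <= z2)
    zg = np.unique(np.concatenate([[z1, z2], pmf.z_grid[inside]]))
    w = pmf.interpolate(zg)
    if np.any(~np.isfinite(w)):
        gaps = zg[~np.isfinite(w)]
        raise ValueError(
            f"PMF undefined inside integration bounds near z = {gaps[:5].round(2).tolist()}"
        )
    w1, w2 = w[0], w[-1]
    w_ref = {"left": w1, "right": w2, "mean": 0.5 * (w1 + w2)}[reference]
    integrand = np.exp(-(w - w_ref) / kT)
    K = float(np.trapezoid(integrand, zg) / (z2 - z1))

    K_err = 0.0
    if pmf.errors is not None:
        err = np.interp(zg, pmf.z_grid[pmf.defined_mask], pmf.errors[pmf.defined_mask])
        # dK/dW_j = -(trapezoid weight_j / (z2-z1)) * integrand_j / kT
        wts = np.zeros_like(zg)
        wts[1:] += 0.5 * np.diff(zg)
        wts[:-1] += 0.5 * np.diff(zg)
        dK = wts * integrand / ((z2 - z1) * kT)
        K_err = float(np.sqrt(np.sum((dK * np.nan_to_num(err)) ** 2)))
    dG = dG_from_K(K, temperature)
    dG_err = kT * K_err / K if K > 0 else np.nan
    return PartitionResult(K=K, dG=dG, K_error=K_err, dG_error=dG_err, z1=z1, z2=z2)


def pka_shift_profile(
    pmf_neutral: Profile, pmf_charged: Profile, temperature: float = 310.0
) -> Profile:
    """Membrane-depth-dependent pKa shift from paired PMFs.

    ΔpKa(z) = [W_neutral(z) − W_charged(z)] / (ln10 · k_BT), both PMFs
    bulk-anchored on a common grid (the intersection of the two grids,
    linear interpolation). Negative values mean the neutral form is
    favored at that depth. Undefined wherever either PMF is undefined.
    """
    lo = max(pmf_neutral.z_grid[0], pmf_charged.z_grid[0])
    hi = min(pmf_neutral.z_grid[-1], pmf_charged.z_grid[-1])
    if lo >= hi:
        raise ValueError("PMF grids do not overlap")
    z = np.unique(np.concatenate([
        pmf_neutral.z_grid[(pmf_neutral.z_grid >= lo) & (pmf_neutral.z_grid <= hi)],
        pmf_charged.z_grid[(pmf_charged.z_grid >= lo) & (pmf_charged.z_grid <= hi)],
    ]))
    wn = pmf_neutral.interpolate(z)
    wc = pmf_charged.interpolate(z)
    ok = np.isfinite(wn) & np.isfinite(wc)
    vals = np.where(ok, (wn - wc) / (LN10 * kt(temperature)), np.nan)
    return Profile(z, vals, defined_mask=ok, units="dimensionless")


def boltzmann_invert(
    samples: np.ndarray,
    temperature: float = 310.0,
    bin_width: float = 0.5,
    z_range: tuple[float, float] | None = None,
) -> Profile:
    """Free-energy profile −k_BT ln ρ(z) from unbiased position samples.

    The samples are histogrammed at ``bin_width``, normalized to a
    probability density, and Boltzmann-inverted; the result is
    min-anchored. Bins with zero counts are masked undefined — regions a
    simulation never visited have no defined free energy.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 or np.ptp(samples) == 0:
        raise ValueError("need at least two distinct samples to invert")
    lo, hi = z_range if z_range is not None else (samples.min(), samples.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    rho = counts / (counts.sum() * bin_width)
    kT = kt(temperature)
    with np.errstate(divide="ignore"):
        w = np.where(occupied, -kT * np.log(np.where(occupied, rho, 1.0)), np.nan)
    w -= np.nanmin(w)
    errs = np.where(occupied, kT / np.sqrt(np.where(occupied, counts, 1)), np.nan)
    return Profile(centers, w, errors=errs, defined_mask=occupied, units="kcal/mol")
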
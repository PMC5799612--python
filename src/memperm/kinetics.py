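"""Position-dependent diffusion and solubility–diffusion permeability.

Diffusivity is estimated per umbrella window with Hummer's restrained-
coordinate estimator: D(z_i) = ⟨δz²⟩_i / τ_i, where τ_i is the position
autocorrelation time obtained by Laplace-transforming the autocorrelation
function Ĉ(s) = ∫ e^{−st} C(t) dt, forming τ(s) = Ĉ(s)/C(0) on a grid of
inverse times, fitting a/(s+b) and extrapolating to s → 0 (τ = a/b).

The membrane permeability is the inhomogeneous solubility–diffusion
integral P = [∫_{−L/2}^{L/2} exp(W(z)/k_BT)/D(z) dz]⁻¹, the reciprocal of
the integrated local resistance, valid in the diffusive (overdamped)
regime. The crossing time between the two membrane borders is estimated
as τ_cross = L/P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import A2_PER_PS_TO_CM2_PER_S, ANGSTROM_TO_CM, kt
from .sampling_io import Profile, UmbrellaDataset

__all__ = [
    "DiffusionEstimate",
    "PermeationSummary",
    "autocorrelation",
    "laplace_tau",
    "estimate_window_diffusion",
    "diffusion_profile",
    "permeability",
    "PAPER_S_GRID",
    "DEFAULT_FIT_RANGE",
]

#: Inverse-time grid for τ(s): 0.01…0.1, 0.2…1.0, 2.0…10.0 ps⁻¹ (28 values).
PAPER_S_GRID: np.ndarray = np.concatenate(
    [np.arange(1, 11) * 0.01, np.arange(2, 11) * 0.1, np.arange(2, 11) * 1.0]
)

#: s interval actually used in the a/(s+b) fit (ps⁻¹).
DEFAULT_FIT_RANGE: tuple[float, float] = (0.02, 1.00)


@dataclass
class DiffusionEstimate:
    """Per-window diffusivity with its autocorrelation diagnostics."""

    window_center: float
    msd_from_mean: float  # ⟨δz²⟩, Å²
    tau: float  # ps
    D: float  # Å²/ps
    fit_a: float
    fit_b: float
    fit_range: tuple[float, float]
    acf_lags: np.ndarray = field(repr=False)
    acf: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.msd_from_mean <= 0 or self.tau <= 0 or self.D <= 0:
            raise ValueError("⟨δz²⟩, τ and D must all be positive")

    @property
    def D_cm2_per_s(self) -> float:
        return self.D * A2_PER_PS_TO_CM2_PER_S


@dataclass
class PermeationSummary:
    """Permeability and crossing time from the resistance integral."""

    P: float  # cm/s
    logP: float
    half_width: float  # L/2, Å
    tau_cross: float  # s
    temperature: float

    def __post_init__(self) -> None:
        assert np.isclose(self.logP, np.log10(self.P), atol=1e-12)


def autocorrelation(series: np.ndarray, timestep: float, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation C(t) = ⟨δz(t)δz(0)⟩ of a position series.

    Uses the biased (divide-by-N) estimator computed via FFT; δz is the
    deviation from the series mean, so C(0) = ⟨δz²⟩. Returns
    ``(lags_ps, acf)`` for lags 0…max_lag.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an ACF, got {n}")
    n_lag = int(np.floor(max_lag / timestep))
    if n_lag >= n:
        raise ValueError(f"max_lag {max_lag} ps exceeds series duration {(n - 1) * timestep} ps")
    dz = series - series.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fz = np.fft.rfft(dz, nfft)
    acf_full = np.fft.irfft(fz * np.conj(fz), nfft)[: n_lag + 1] / n
    lags = timestep * np.arange(n_lag + 1)
    return lags, acf_full


def laplace_tau(
    lags: np.ndarray,
    acf: np.ndarray,
    s_grid: np.ndarray | None = None,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    truncate: bool = True,
    residual_warn: float = 0.2,
) -> tuple[float, float, float, np.ndarray]:
    """Position correlation time by Laplace transform and s → 0 extrapolation.

    Ĉ(s) is evaluated by trapezoidal quadrature over the lag grid at each
    s, τ(s) = Ĉ(s)/C(0), and a/(s+b) is least-squares fitted over
    ``fit_range``; the s → 0 limit is τ = a/b. Returns
    ``(tau, a, b, tau_of_s)`` with ``tau_of_s`` aligned to ``s_grid``.

    With ``truncate`` (default) the integral stops at the first
    zero-crossing of C(t) or 20 initial e-folding times, whichever is
    later — beyond that the ACF is statistical noise that corrupts Ĉ(s)
    at small s.
    """
    if s_grid is None:
        s_grid = PAPER_S_GRID
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    c0 = acf[0]
    if c0 <= 0:
        raise ValueError("C(0) = ⟨δz²⟩ must be positive")

    if truncate:
        n_use = _truncation_index(lags, acf)
        lags, acf = lags[:n_use], acf[:n_use]

    exps = np.exp(-np.outer(s_grid, lags))  # (n_s, n_lag)
    c_hat = np.trapezoid(exps * acf[None, :], lags, axis=1)
    tau_s = c_hat / c0

    sel = (s_grid >= fit_range[0]) & (s_grid <= fit_range[1])
    if sel.sum() < 3:
        raise ValueError("fewer than 3 s-values in the fit range")
    s_fit, t_fit = s_grid[sel], tau_s[sel]
    try:
        popt, _ = curve_fit(
            lambda s, a, b: a / (s + b),
            s_fit,
            t_fit,
            p0=(max(t_fit[-1], 1e-6), max(1.0 / max(t_fit[0], 1e-6), 1e-6)),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise ValueError(f"a/(s+b) fit failed: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    if b <= 0:
        raise ValueError("ACF not decaying: fitted b <= 0 in a/(s+b)")
    resid = np.sqrt(np.mean((a / (s_fit + b) - t_fit) ** 2)) / np.mean(np.abs(t_fit))
    if resid > residual_warn:
        warnings.warn(f"poor a/(s+b) fit: relative residual {resid:.2f}", UserWarning)
    return a / b, a, b, tau_s


def _truncation_index(lags: np.ndarray, acf: np.ndarray) -> int:
    """Lag count to keep: first zero-crossing or 20 e-folding times."""
    below = np.flatnonzero(acf <= 0)
    zero_cross = below[0] if below.size else acf.size
    # initial e-folding time from where C first drops below C(0)/e
    under_e = np.flatnonzero(acf < acf[0] / np.e)
    t_fold = lags[under_e[0]] if under_e.size else lags[-1]
    dt = lags[1] - lags[0] if lags.size > 1 else 1.0
    n_fold = int(np.ceil(20.0 * t_fold / dt)) + 1
    return min(max(zero_cross, n_fold, 2), acf.size)


def estimate_window_diffusion(
    series: np.ndarray,
    timestep: float,
    window_center: float,
    max_lag: float | None = None,
    s_grid: np.ndarray | None = None,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> DiffusionEstimate:
    """Hummer's estimator D = ⟨δz²⟩/τ for one restrained window."""
    series = np.asarray(series, dtype=float)
    if max_lag is None:
        max_lag = min(0.2 * (series.size - 1), 2000.0 / timestep) * timestep
    lags, acf = autocorrelation(series, timestep, max_lag)
    tau, a, b, _ = laplace_tau(lags, acf, s_grid=s_grid, fit_range=fit_range)
    msd = float(acf[0])
    return DiffusionEstimate(
        window_center=window_center,
        msd_from_mean=msd,
        tau=tau,
        D=msd / tau,
        fit_a=a,
        fit_b=b,
        fit_range=fit_range,
        acf_lags=lags,
        acf=acf,
    )


def diffusion_profile(
    dataset: UmbrellaDataset,
    s_grid: np.ndarray | None = None,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
) -> tuple[Profile, list[DiffusionEstimate]]:
    """D(z) at every window center; failures are masked, never fatal.

    Duplicate centers are combined by inverse-variance weighting using the
    Poisson-style variance proxy D²/n_samples (identical copies average to
    the plain mean). Returns the profile in Å²/ps plus the per-window
    estimates.
    """
    ds = dataset.loaded()
    estimates: list[DiffusionEstimate] = []
    per_center: dict[float, list[tuple[float, float]]] = {}
    for w in ds.windows:
        try:
            est = estimate_window_diffusion(w.series, w.timestep, w.center_z,
                                            s_grid=s_grid, fit_range=fit_range)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"window at z={w.center_z}: diffusion estimate failed ({exc})")
            continue
        estimates.append(est)
        var = est.D**2 / max(w.series.size, 1)
        per_center.setdefault(w.center_z, []).append((est.D, var))

    centers = np.array(sorted(set(w.center_z for w in ds.windows)))
    vals = np.full(centers.shape, np.nan)
    for i, c in enumerate(centers):
        if c in per_center:
            d_arr = np.array([d for d, _ in per_center[c]])
            w_arr = np.array([1.0 / v for _, v in per_center[c]])
            vals[i] = np.sum(d_arr * w_arr) / np.sum(w_arr)
    mask = np.isfinite(vals)
    return Profile(centers, vals, defined_mask=mask, units="Å²/ps"), estimates


def permeability(
    pmf: Profile,
    d_profile: Profile,
    half_width: float,
    temperature: float = 310.0,
    reference: str = "border",
    grid_step: float = 0.1,
) -> PermeationSummary:
    """Solubility–diffusion permeability over z ∈ [−L/2, L/2].

    Both profiles are interpolated to a common grid of spacing
    ``grid_step`` Å. With ``reference="border"`` the PMF is shifted so the
    mean of W(−L/2) and W(+L/2) is zero (on a symmetrized PMF the two
    border values coincide) — the variant appropriate for interfacially
    bound permeants, where crossing starts from the interfacial wells.
    ``reference="bulk"`` keeps the PMF's own (bulk-anchored) zero. D may
    be given in Å²/ps or cm²/s (resolved from its units tag).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    L = 2.0 * half_width
    z = np.linspace(-half_width, half_width, int(np.round(L / grid_step)) + 1)
    w = pmf.interpolate(z)
    if np.any(~np.isfinite(w)):
        raise ValueError("PMF undefined inside the integration span")
    d = d_profile.interpolate(z)
    if np.any(~np.isfinite(d)):
        raise ValueError("D(z) undefined inside the integration span")
    if "cm" in d_profile.units:
        d_cm2 = d
    else:
        d_cm2 = d * A2_PER_PS_TO_CM2_PER_S
    if np.any(d_cm2 <= 0):
        raise ValueError("D(z) must be positive on the integration span")

    if reference == "border":
        w = w - 0.5 * (w[0] + w[-1])
    elif reference != "bulk":
        raise ValueError("reference must be 'border' or 'bulk'")

    kT = kt(temperature)
    resistance = np.trapezoid(np.exp(w / kT) / d_cm2, z * ANGSTROM_TO_CM)  # s/cm
    P = 1.0 / resistance
    return PermeationSummary(
        P=P,
        logP=float(np.log10(P)),
        half_width=half_width,
        tau_cross=L * ANGSTROM_TO_CM / P,
        temperature=temperature,
    )
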
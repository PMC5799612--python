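"""Synthetic data with known ground truth: Brownian dynamics on 1-D landscapes.

Umbrella-sampling analysis methods are validated here against data whose
generating free-energy landscape W*(z) and diffusivity profile D*(z) are
known exactly. A solute's membrane-normal coordinate is propagated by
overdamped (inertialess) Langevin dynamics — the regime the downstream
estimators assume — using the Euler–Maruyama update

    z ← z + [D(z)/k_BT]·F(z)·dt + D′(z)·dt + sqrt(2·D(z)·dt)·ξ,

with F = −d(W + U_bias)/dz and ξ a standard normal. The D′(z) spurious-
drift term is required for a position-dependent diffusivity to leave the
Boltzmann distribution exp(−W_total/k_BT) stationary.

The ``membrane`` landscape mimics a drug–bilayer PMF: a Gaussian central
barrier, Gaussian interfacial wells at ±well_z, flat bulk plateaus at
zero, and a smooth (logistic) ~10-fold drop of D inside the membrane.
Defaults follow the umbrella-sampling protocol emulated throughout the
package: 81 windows from −40 to 40 Å in 1 Å steps, spring constant
2.5 kcal·mol⁻¹·Å⁻², 310 K, saved spacing 1 ps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .constants import kt
from .sampling_io import FrameSet, Profile, UmbrellaDataset, UmbrellaWindow

__all__ = [
    "LandscapeSpec",
    "BDRun",
    "simulate_window",
    "generate_dataset",
    "sample_orientations",
    "build_frames",
    "membrane_landscape",
]

_TABLE_STEP = 0.02  # Å, spacing of the tabulated W/F/D lookup


@dataclass
class LandscapeSpec:
    """Analytic reference landscape driving the generator.

    ``form``: 'flat', 'harmonic' (W = ½·harmonic_k·z²) or 'membrane'.
    The membrane form is even in z: a central Gaussian barrier of height
    ``barrier_height`` (σ = ``sigma_core``), wells of depth ``well_depth``
    (negative) at ±``well_z`` (σ = ``interface_width``), W → 0 in bulk.
    D(z) steps smoothly from ``D_bulk`` outside to ``D_core`` inside the
    membrane (logistic crossover at |z| = ``d_switch_z``).
    """

    form: str = "membrane"
    barrier_height: float = 5.4
    well_depth: float = -2.8
    well_z: float = 14.0
    sigma_core: float = 4.0
    interface_width: float = 3.0
    extent: float = 45.0
    harmonic_k: float = 1.0
    tilt: float = 0.0  # constant force along +z (kcal/mol/Å); crude stand-in
    # for a transmembrane field in unbiased runs — not an equilibrium membrane
    D_bulk: float = 0.1  # Å²/ps
    D_core: float = 0.1
    d_switch_z: float = 15.0
    d_switch_width: float = 2.0
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.form not in ("flat", "harmonic", "membrane"):
            raise ValueError(f"unknown landscape form {self.form!r}")
        if self.D_bulk <= 0 or self.D_core <= 0:
            raise ValueError("diffusivities must be positive")
        if self.extent <= 0:
            raise ValueError("extent must be positive")

    # -- analytic curves ---------------------------------------------------
    def energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            base = np.zeros_like(z)
        elif self.form == "harmonic":
            base = 0.5 * self.harmonic_k * z**2
        else:
            core = self.barrier_height * np.exp(-(z**2) / (2 * self.sigma_core**2))
            wells = self.well_depth * (
                np.exp(-((z - self.well_z) ** 2) / (2 * self.interface_width**2))
                + np.exp(-((z + self.well_z) ** 2) / (2 * self.interface_width**2))
            )
            base = core + wells
        return base - self.tilt * z

    def diffusivity(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.D_bulk == self.D_core:
            return np.full_like(z, self.D_bulk)
        # high outside |z| = d_switch_z, low inside, smooth logistic edge
        gate = 1.0 / (1.0 + np.exp(-(np.abs(z) - self.d_switch_z) / self.d_switch_width))
        return self.D_core + (self.D_bulk - self.D_core) * gate

    def truth_profiles(self, dz: float = 0.2) -> tuple[Profile, Profile]:
        """Ground-truth W*(z) and D*(z) tabulated over the extent."""
        z = np.arange(-self.extent, self.extent + dz / 2, dz)
        return (
            Profile(z, self.energy(z), units="kcal/mol"),
            Profile(z, self.diffusivity(z), units="Å²/ps"),
        )

    def _tables(self, spring_k: float = 0.0):
        """Lookup tables (z, F_landscape, D, D′, sqrt-coeff) for the stepper."""
        pad = 6.0 * np.sqrt(kt(self.temperature) / spring_k) if spring_k > 0 else 10.0
        z = np.arange(-self.extent - pad, self.extent + pad + _TABLE_STEP, _TABLE_STEP)
        w = self.energy(z)
        f = -np.gradient(w, z)
        d = self.diffusivity(z)
        dd = np.gradient(d, z)
        return z, f, d, dd

    def max_stiffness(self) -> float:
        """Largest |W''| over the extent (kcal·mol⁻¹·Å⁻²)."""
        z, f, _, _ = self._tables()
        return float(np.max(np.abs(np.gradient(-f, z))))


def membrane_landscape(**overrides) -> LandscapeSpec:
    """Membrane landscape with a 10-fold core slowdown (D_core = D_bulk/10)."""
    spec = LandscapeSpec(form="membrane", **overrides)
    if "D_core" not in overrides:
        spec.D_core = spec.D_bulk / 10.0
    return spec


@dataclass
class BDRun:
    """One Brownian-dynamics trajectory (saved points only)."""

    positions: np.ndarray
    dt: float  # spacing of the *saved* points, ps
    n_steps: int  # integration steps taken
    bias: tuple[float, float] | None  # (center, spring_k)
    seed: int

    def times(self) -> np.ndarray:
        return self.dt * (1 + np.arange(self.positions.size))


def _check_dt(landscape: LandscapeSpec, spring_k: float, dt: float) -> None:
    k_total = spring_k + landscape.max_stiffness()
    d_max = max(landscape.D_bulk, landscape.D_core)
    if k_total <= 0:
        return
    limit = 0.1 * kt(landscape.temperature) / (k_total * d_max)
    if dt >= limit:
        raise ValueError(
            f"dt={dt} ps too large for stiffness {k_total:.3g} kcal/mol/Å²; "
            f"use dt < {limit:.3g} ps"
        )


def _simulate_batch(
    landscape: LandscapeSpec,
    z0: np.ndarray,
    centers: np.ndarray | None,
    spring_k: float,
    dt: float,
    n_steps: int,
    save_stride: int,
    rng: np.random.Generator,
    burn_in: int = 0,
    spurious_drift: bool = True,
) -> np.ndarray:
    """Propagate a batch of independent walkers; returns (n_walkers, n_saved).

    ``spurious_drift=False`` drops the D′(z) term (diagnostics only): the
    stationary density then tilts to exp(−W/k_BT)/D(z).
    """
    kT = kt(landscape.temperature)
    zt, f_tab, d_tab, dd_tab = landscape._tables(spring_k)
    z = np.array(z0, dtype=float)
    n_w = z.size
    n_saved = n_steps // save_stride
    out = np.empty((n_w, n_saved))
    chunk = 8192
    total = burn_in + n_steps
    step = 0
    saved = 0
    while step < total:
        m = min(chunk, total - step)
        noise = rng.standard_normal((m, n_w))
        for j in range(m):
            d = np.interp(z, zt, d_tab)
            f = np.interp(z, zt, f_tab)
            if centers is not None:
                f = f - spring_k * (z - centers)
            drift = np.interp(z, zt, dd_tab) * dt if spurious_drift else 0.0
            z = z + (d / kT) * f * dt + drift + np.sqrt(2.0 * d * dt) * noise[j]
            step += 1
            if step > burn_in and (step - burn_in) % save_stride == 0:
                out[:, saved] = z
                saved += 1
    return out[:, :saved]


def simulate_window(
    landscape: LandscapeSpec,
    bias: tuple[float, float] | None,
    dt: float,
    n_steps: int,
    seed: int,
    save_stride: int = 20,
    burn_in: int = 0,
    z0: float | None = None,
) -> BDRun:
    """One overdamped-Langevin trajectory, optionally under a harmonic bias.

    ``bias`` is (center, spring_k) or None for an unbiased run; the walker
    starts at the bias center (or ``z0``). ``burn_in`` integration steps
    are discarded before saving every ``save_stride``-th point. Same seed
    → bit-identical series.
    """
    spring_k = bias[1] if bias is not None else 0.0
    center = bias[0] if bias is not None else 0.0
    _check_dt(landscape, spring_k, dt)
    if z0 is None:
        z0 = center if bias is not None else 0.0
    rng = np.random.default_rng(seed)
    pos = _simulate_batch(
        landscape,
        np.array([z0]),
        np.array([center]) if bias is not None else None,
        spring_k,
        dt,
        n_steps,
        save_stride,
        rng,
        burn_in=burn_in,
    )[0]
    return BDRun(positions=pos, dt=dt * save_stride, n_steps=n_steps,
                 bias=bias, seed=seed)


def generate_dataset(
    landscape: LandscapeSpec,
    centers: np.ndarray | None = None,
    spring_k: float = 2.5,
    dt: float = 0.05,
    n_steps: int = 200_000,
    base_seed: int | None = None,
    save_stride: int = 20,
    burn_in: int = 4000,
    out_dir: str | None = None,
) -> tuple[UmbrellaDataset, Profile, Profile]:
    """Full umbrella-sampling dataset on a known landscape.

    One biased trajectory per center (window i gets seed base_seed + i),
    batched through a single vectorized stepper. Default centers are the
    81-window layout −40…40 Å in 1 Å steps. Returns the loaded dataset
    plus the ground-truth W*(z) and D*(z) profiles; when ``out_dir`` is
    given, also writes metadata, per-window series and ``truth_``-prefixed
    profile files in the formats sampling_io reads.
    """
    if centers is None:
        centers = np.arange(-40.0, 41.0, 1.0)
    centers = np.asarray(centers, dtype=float)
    if np.any(np.abs(centers) > landscape.extent):
        raise ValueError("window centers fall outside the landscape extent")
    if base_seed is None:
        base_seed = landscape.seed
    _check_dt(landscape, spring_k, dt)

    # one RNG per window so each window reproduces independently of the batch
    saved = []
    n_w = centers.size
    rngs = [np.random.default_rng(base_seed + i) for i in range(n_w)]
    kT = kt(landscape.temperature)
    zt, f_tab, d_tab, dd_tab = landscape._tables(spring_k)
    z = centers.copy()
    total = burn_in + n_steps
    n_saved = n_steps // save_stride
    out = np.empty((n_w, n_saved))
    chunk = 4096
    step = 0
    saved_i = 0
    while step < total:
        m = min(chunk, total - step)
        noise = np.column_stack([r.standard_normal(m) for r in rngs])
        for j in range(m):
            d = np.interp(z, zt, d_tab)
            f = np.interp(z, zt, f_tab) - spring_k * (z - centers)
            z = z + (d / kT) * f * dt + np.interp(z, zt, dd_tab) * dt \
                + np.sqrt(2.0 * d * dt) * noise[j]
            step += 1
            if step > burn_in and (step - burn_in) % save_stride == 0:
                out[:, saved_i] = z
                saved_i += 1

    dt_saved = dt * save_stride
    windows = [
        UmbrellaWindow(center_z=c, spring_k=spring_k, timestep=dt_saved,
                       series=out[i], source_path=f"window_{i:03d}.dat")
        for i, c in enumerate(centers)
    ]
    dataset = UmbrellaDataset(windows, landscape.temperature, equilibration_discard=0.0)
    truth_w, truth_d = landscape.truth_profiles()

    if out_dir is not None:
        _write_dataset(dataset, truth_w, truth_d, out_dir)
    return dataset, truth_w, truth_d


def _write_dataset(dataset: UmbrellaDataset, truth_w: Profile, truth_d: Profile,
                   out_dir: str) -> None:
    from .sampling_io import write_profile

    os.makedirs(out_dir, exist_ok=True)
    meta_lines = [f"# temperature {dataset.temperature}"]
    for i, w in enumerate(dataset.windows):
        name = f"window_{i:03d}.dat"
        t = w.timestep * (1 + np.arange(w.series.size))
        np.savetxt(os.path.join(out_dir, name),
                   np.column_stack([t, w.series]), fmt="%.6f %.8f",
                   header="time_ps z_angstrom")
        meta_lines.append(f"{name} {w.center_z:g} {w.spring_k:g}")
    with open(os.path.join(out_dir, "metadata.dat"), "w") as fh:
        fh.write("\n".join(meta_lines) + "\n")
    write_profile(truth_w, os.path.join(out_dir, "truth_pmf.dat"))
    write_profile(truth_d, os.path.join(out_dir, "truth_diffusivity.dat"))


def sample_orientations(concentration: float, n: int, seed: int) -> np.ndarray:
    """Polar-angle samples θ from density ∝ sinθ·exp(λ·cosθ) (radians).

    λ = ``concentration``: 0 gives an isotropic distribution, large λ
    concentrates θ near 0 (alignment with +z). Inverse-CDF sampling of
    u = cosθ, which has density ∝ exp(λu) on [−1, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    r = rng.uniform(size=n)
    lam = float(concentration)
    if lam == 0.0:
        u = 2.0 * r - 1.0
    else:
        # u = 1 + ln(r + (1-r)·e^{-2λ})/λ, stable for large λ
        u = 1.0 + np.log(r + (1.0 - r) * np.exp(-2.0 * lam)) / lam
    return np.arccos(np.clip(u, -1.0, 1.0))


def build_frames(
    n_frames: int,
    n_oxygens: dict[str, int],
    planted_contacts: dict[str, int],
    box: tuple[float, float, float],
    seed: int,
    cutoff: float = 4.25,
    n_solute: int = 5,
    solute_center: tuple[float, float, float] | None = None,
) -> FrameSet:
    """Frames with an exactly known number of in-shell oxygens per class.

    A compact solute cluster sits at ``solute_center`` (box center by
    default; place it near a box edge to exercise the minimum-image
    convention). In every frame, exactly ``planted_contacts[class]``
    oxygens are placed uniformly inside the ``cutoff`` shell of a solute
    atom, and the remainder uniformly in the box but strictly outside the
    shell of *all* solute atoms.
    """
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    center = box / 2.0 if solute_center is None else np.asarray(solute_center, float)
    for name, k in planted_contacts.items():
        if k > n_oxygens.get(name, 0):
            raise ValueError(f"cannot plant {k} contacts with {n_oxygens.get(name, 0)} "
                             f"{name} oxygens")
        shell_capacity = int(4.0 / 3.0 * np.pi * cutoff**3)  # ~1 Å³ per oxygen
        if k > shell_capacity:
            raise ValueError(f"shell overfull: {k} contacts requested for {name}")

    # rigid compact cluster, same geometry every frame
    cluster = rng.normal(scale=0.8, size=(n_solute, 3))
    cluster -= cluster.mean(axis=0)
    solute = np.tile(center + cluster, (n_frames, 1, 1))

    def min_image_dist(pts: np.ndarray, refs: np.ndarray) -> np.ndarray:
        d = pts[:, None, :] - refs[None, :, :]
        d -= box * np.round(d / box)
        return np.sqrt((d**2).sum(-1)).min(axis=1)

    oxygens: dict[str, np.ndarray] = {}
    for name, n_total in n_oxygens.items():
        k_in = planted_contacts.get(name, 0)
        frames_arr = np.empty((n_frames, n_total, 3))
        for f in range(n_frames):
            placed = []
            # in-shell: uniform radius^3 in (r_lo, cutoff] around a random atom
            for _ in range(k_in):
                while True:
                    atom = cluster[rng.integers(n_solute)] + center
                    vec = rng.normal(size=3)
                    vec /= np.linalg.norm(vec)
                    r3 = rng.uniform(1.0**3, cutoff**3)
                    pos = atom + vec * r3 ** (1.0 / 3.0)
                    pos %= box
                    if min_image_dist(pos[None, :], center + cluster)[0] <= cutoff:
                        placed.append(pos)
                        break
            # out-of-shell: uniform in box, rejected out of a guarded shell
            n_out = n_total - k_in
            while n_out > 0:
                cand = rng.uniform(0, 1, size=(max(2 * n_out, 8), 3)) * box
                ok = min_image_dist(cand, center + cluster) > cutoff + 0.2
                keep = cand[ok][:n_out]
                placed.extend(keep)
                n_out -= keep.shape[0]
            frames_arr[f] = np.array(placed) if placed else np.empty((0, 3))
        oxygens[name] = frames_arr

    return FrameSet(solute=solute, oxygens=oxygens, n1_index=0,
                    s_index=min(1, n_solute - 1), box=box)
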
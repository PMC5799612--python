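"""Data model and text I/O for umbrella-sampling datasets and profiles.

The on-disk dialect follows the widely used WHAM-metadata convention: one
window per line with fields ``series-path  center_z  spring_k``, so output
from third-party umbrella-sampling drivers drops in directly. Time series
are two-column whitespace text (time ps, z Å) with ``#`` comments; profiles
are four-column text (z, value, error, defined-flag).

Conventions: the membrane center is z = 0 with the bilayer normal along +z,
lengths in Å, energies in kcal/mol, and the harmonic bias is
U(z) = ½·k·(z − z₀)² with k in kcal·mol⁻¹·Å⁻².
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "UmbrellaWindow",
    "UmbrellaDataset",
    "Profile",
    "FrameSet",
    "MetadataError",
    "read_metadata",
    "read_timeseries",
    "load_series",
    "read_profile",
    "write_profile",
    "read_frames",
    "write_frames",
]

DEFAULT_EQUILIBRATION_PS = 4000.0  # discarded from the head of every window


class MetadataError(ValueError):
    """Raised for malformed metadata or time-series files."""


@dataclass
class UmbrellaWindow:
    """One biased window: its harmonic restraint plus the sampled z series.

    ``series`` may be None for a metadata-only window (lazy loading);
    ``timestep`` is the spacing of the stored points in ps.
    """

    center_z: float
    spring_k: float
    timestep: float | None = None
    series: np.ndarray | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center_z):
            raise ValueError("window center must be finite")
        if self.spring_k <= 0:
            raise ValueError(
                f"spring constant must be positive, got {self.spring_k}"
                + (f" ({self.source_path})" if self.source_path else "")
            )
        if self.series is not None:
            self.series = np.asarray(self.series, dtype=float)
            if self.series.size < 2:
                raise ValueError("window series needs at least 2 samples")
            if not np.all(np.isfinite(self.series)):
                raise ValueError("window series contains non-finite values")
            if self.timestep is None or self.timestep <= 0:
                raise ValueError("loaded series requires a positive timestep")

    @property
    def loaded(self) -> bool:
        return self.series is not None

    @property
    def duration(self) -> float:
        """Span of the stored series in ps (0 if unloaded)."""
        if self.series is None:
            return 0.0
        return (self.series.size - 1) * float(self.timestep)


@dataclass
class UmbrellaDataset:
    """A sorted collection of umbrella windows at one temperature."""

    windows: list[UmbrellaWindow]
    temperature: float = 310.0
    equilibration_discard: float = DEFAULT_EQUILIBRATION_PS

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.equilibration_discard < 0:
            raise ValueError("equilibration discard must be nonnegative")
        self.windows = sorted(self.windows, key=lambda w: w.center_z)

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center_z for w in self.windows])

    def loaded(self) -> "UmbrellaDataset":
        """Return a copy with every window's series loaded from disk."""
        out = [
            w if w.loaded else replace(
                w, **_series_kwargs(w.source_path, self.equilibration_discard)
            )
            for w in self.windows
        ]
        return UmbrellaDataset(out, self.temperature, self.equilibration_discard)


@dataclass
class Profile:
    """A scalar curve on a strictly increasing z grid.

    ``units`` tags the values (kcal/mol, cm²/s, Å²/ps, dimensionless, Å⁻¹).
    Grid points where the quantity is not defined (e.g. unvisited PMF bins)
    carry ``defined_mask=False`` and NaN values — never a silent zero.
    """

    z_grid: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    defined_mask: np.ndarray | None = None
    units: str = "kcal/mol"

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z_grid.ndim != 1 or self.z_grid.size == 0:
            raise ValueError("profile grid must be a nonempty 1-D array")
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("profile grid must be strictly increasing")
        if self.values.shape != self.z_grid.shape:
            raise ValueError("values and grid shapes differ")
        if self.defined_mask is None:
            self.defined_mask = np.isfinite(self.values)
        else:
            self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
            if self.defined_mask.shape != self.z_grid.shape:
                raise ValueError("defined_mask and grid shapes differ")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.z_grid.shape:
                raise ValueError("errors and grid shapes differ")
            if np.any(self.errors[self.defined_mask] < 0):
                raise ValueError("errors must be nonnegative")

    def interpolate(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``z``; NaN outside the defined range.

        No extrapolation: points beyond the defined data are NaN, as are
        points falling in or beyond undefined stretches of the grid.
        """
        z = np.asarray(z, dtype=float)
        zg = self.z_grid[self.defined_mask]
        vg = self.values[self.defined_mask]
        if zg.size == 0:
            return np.full(z.shape, np.nan)
        out = np.interp(z, zg, vg, left=np.nan, right=np.nan)
        # interp bridges interior gaps; mask points surrounded by undefined bins
        if not self.defined_mask.all():
            undef_z = self.z_grid[~self.defined_mask]
            for lo, hi in _undefined_spans(zg, undef_z):
                out = np.where((z > lo) & (z < hi), np.nan, out)
        return out


def _undefined_spans(defined_z, undef_z):
    """Open intervals between defined points that contain undefined bins."""
    spans = []
    for zu in undef_z:
        i = np.searchsorted(defined_z, zu)
        if 0 < i < defined_z.size:
            spans.append((defined_z[i - 1], defined_z[i]))
    return spans


@dataclass
class FrameSet:
    """Per-frame Cartesian coordinates for solvation/orientation analysis.

    ``solute``: (n_frames, n_solute, 3) heavy-atom coordinates (Å);
    ``oxygens``: mapping class name -> (n_frames, n_class, 3);
    ``n1_index``/``s_index``: solute atom indices defining the orientation
    vector (N1 → S); ``box``: orthorhombic box lengths (Å).
    """

    solute: np.ndarray
    oxygens: dict[str, np.ndarray]
    n1_index: int
    s_index: int
    box: np.ndarray

    def __post_init__(self) -> None:
        self.solute = np.asarray(self.solute, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.solute.ndim != 3 or self.solute.shape[2] != 3:
            raise ValueError("solute coordinates must be (n_frames, n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        n_at = self.solute.shape[1]
        for idx, name in ((self.n1_index, "N1"), (self.s_index, "S")):
            if not 0 <= idx < n_at:
                raise ValueError(f"{name} index {idx} outside solute atoms")
        self.oxygens = {k: np.asarray(v, dtype=float) for k, v in self.oxygens.items()}
        for name, arr in self.oxygens.items():
            if arr.ndim != 3 or arr.shape[0] != self.n_frames or arr.shape[2] != 3:
                raise ValueError(f"oxygen class {name!r} has inconsistent shape")

    @property
    def n_frames(self) -> int:
        return self.solute.shape[0]


# ---------------------------------------------------------------------------
# readers / writers


def read_metadata(
    path: str,
    temperature: float = 310.0,
    equilibration_discard: float = DEFAULT_EQUILIBRATION_PS,
) -> UmbrellaDataset:
    """Parse a WHAM-style metadata file into an (unloaded) dataset.

    Each non-comment line: ``series-path  center_z  spring_k``. A header
    line ``# temperature <K>`` overrides the default. Relative series paths
    are resolved against the metadata file's directory. Duplicate centers
    are retained as separate windows.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    base = os.path.dirname(os.path.abspath(path))
    windows: list[UmbrellaWindow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line.lstrip("#").split()
                if len(toks) >= 2 and toks[0].lower() == "temperature":
                    temperature = float(toks[1])
                continue
            fields = line.split()
            if len(fields) < 3:
                raise MetadataError(
                    f"{path}:{lineno}: expected 'path center spring_k', got {line!r}"
                )
            series_path = fields[0]
            if not os.path.isabs(series_path):
                series_path = os.path.join(base, series_path)
            try:
                center = float(fields[1])
                spring = float(fields[2])
            except ValueError as exc:
                raise MetadataError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if spring <= 0:
                raise MetadataError(
                    f"{path}:{lineno}: spring constant must be positive, got {spring}"
                )
            windows.append(
                UmbrellaWindow(center_z=center, spring_k=spring, source_path=series_path)
            )
    if not windows:
        raise MetadataError(f"{path}: no windows")
    return UmbrellaDataset(windows, temperature, equilibration_discard)


def read_timeseries(path: str, discard: float = 0.0) -> tuple[np.ndarray, float]:
    """Read a two-column (time ps, z Å) series, dropping times ≤ ``discard``.

    Returns ``(z_values, timestep)`` with the timestep inferred from the
    first two retained rows; spacing must be uniform to 1e-6 relative.
    """
    times, zs = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 2:
                raise MetadataError(f"{path}:{lineno}: expected two columns")
            try:
                t, z = float(toks[0]), float(toks[1])
            except ValueError as exc:
                raise MetadataError(f"{path}:{lineno}: non-numeric token: {exc}") from exc
            if t > discard:
                times.append(t)
                zs.append(z)
    if len(zs) < 2:
        raise MetadataError(
            f"{path}: fewer than 2 samples remain after discarding t <= {discard} ps"
        )
    t_arr = np.asarray(times)
    dt = t_arr[1] - t_arr[0]
    if dt <= 0:
        raise MetadataError(f"{path}: non-increasing time column")
    steps = np.diff(t_arr)
    if np.any(np.abs(steps - dt) > 1e-6 * abs(dt)):
        raise MetadataError(f"{path}: nonuniform time spacing (dt0={dt})")
    return np.asarray(zs, dtype=float), float(dt)


def _series_kwargs(path: str, discard: float) -> dict:
    series, dt = read_timeseries(path, discard)
    return {"series": series, "timestep": dt}


def load_series(window: UmbrellaWindow, discard: float) -> UmbrellaWindow:
    """Return a copy of ``window`` with its series loaded from disk."""
    if window.loaded:
        return window
    return replace(window, **_series_kwargs(window.source_path, discard))


def write_profile(profile: Profile, path: str) -> None:
    """Write a profile as 4-column text: z, value, error, defined-flag."""
    if profile.z_grid.size == 0:
        raise ValueError("refusing to write an empty profile")
    err = profile.errors if profile.errors is not None else np.zeros_like(profile.values)
    try:
        with open(path, "w") as fh:
            fh.write(f"# memperm profile  units={profile.units}\n")
            fh.write("# z  value  error  defined\n")
            for z, v, e, d in zip(profile.z_grid, profile.values, err, profile.defined_mask):
                vs = f"{v:.12g}" if np.isfinite(v) else "nan"
                es = f"{e:.12g}" if np.isfinite(e) else "nan"
                fh.write(f"{z:.12g} {vs} {es} {int(d)}\n")
    except OSError as exc:
        raise OSError(f"failed writing profile to {path}: {exc}") from exc


def read_profile(path: str) -> Profile:
    """Inverse of :func:`write_profile` (round-trips to 1e-9)."""
    units = "kcal/mol"
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                if "units=" in line:
                    units = line.split("units=", 1)[1].split()[0]
                continue
            if not line:
                continue
            toks = line.split()
            if len(toks) != 4:
                raise MetadataError(f"{path}: expected 4 columns, got {line!r}")
            rows.append((float(toks[0]), float(toks[1]), float(toks[2]), bool(int(toks[3]))))
    if not rows:
        raise MetadataError(f"{path}: empty profile file")
    z, v, e, d = (np.array(col) for col in zip(*rows))
    return Profile(z, v, errors=e, defined_mask=d.astype(bool), units=units)


def write_frames(frames: FrameSet, xyz_path: str, tags_path: str) -> None:
    """Write a FrameSet as multi-frame XYZ plus a JSON tag sidecar.

    The XYZ holds solute atoms first (element C, with N1/S at their tagged
    indices) then each oxygen class (element O); the sidecar maps atom
    index ranges to classes and records the box.
    """
    import json

    order = sorted(frames.oxygens)
    n_solute = frames.solute.shape[1]
    tags = {
        "box": frames.box.tolist(),
        "n1_index": frames.n1_index,
        "s_index": frames.s_index,
        "solute": [0, n_solute],
        "classes": {},
    }
    start = n_solute
    for name in order:
        n = frames.oxygens[name].shape[1]
        tags["classes"][name] = [start, start + n]
        start += n
    with open(tags_path, "w") as fh:
        json.dump(tags, fh, indent=1)
    with open(xyz_path, "w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"{start}\n")
            fh.write(f"frame {f}\n")
            for i, xyz in enumerate(frames.solute[f]):
                el = "N" if i == frames.n1_index else ("S" if i == frames.s_index else "C")
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
            for name in order:
                for xyz in frames.oxygens[name][f]:
                    fh.write(f"O {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_frames(xyz_path: str, tags_path: str) -> FrameSet:
    """Read frames written by :func:`write_frames`.

    Uses MDAnalysis for the XYZ coordinates when available, otherwise a
    minimal text reader (the format is fixed by ``write_frames``).
    """
    import json

    with open(tags_path) as fh:
        tags = json.load(fh)
    coords = _read_xyz(xyz_path)
    s0, s1 = tags["solute"]
    oxygens = {
        name: coords[:, lo:hi, :] for name, (lo, hi) in tags["classes"].items()
    }
    return FrameSet(
        solute=coords[:, s0:s1, :],
        oxygens=oxygens,
        n1_index=tags["n1_index"],
        s_index=tags["s_index"],
        box=np.asarray(tags["box"], dtype=float),
    )


def _read_xyz(path: str) -> np.ndarray:
    try:
        import MDAnalysis as mda

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format="XYZ")
            return np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    except ImportError:
        pass
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i].split()[0])
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(x) for x in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.asarray(frames, dtype=float)
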
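"""Orientation, solvation-shell and radial-distribution analysis of frames.

The solute's orientation relative to the membrane normal (+z) is tracked
through a named intramolecular vector (N1 → S for d-sotalol); the mean
angle uses the circular mean ⟨θ⟩ = atan2(⟨sin θ⟩, ⟨cos θ⟩) and alignment
is summarized by the second-rank order parameter S = ½(3⟨cos²θ⟩ − 1)
(1: along the normal, −0.5: in-plane, 0: isotropic).

Solvation numbers follow a nearest-contact rule: an oxygen atom (water,
lipid phosphate or ester class) counts as solvating when its minimum-image
distance to *any* solute heavy atom is within the cutoff (4.25 Å by
default, the first-shell boundary read off the site–site RDFs); each
oxygen counts once per frame. Distances use the orthorhombic minimum-image
convention, delegated to MDAnalysis when it is installed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling_io import FrameSet, Profile

__all__ = [
    "OrientationStats",
    "SolvationCounts",
    "orientation_stats",
    "solvation_numbers",
    "site_rdf",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 4.25  # Å, first-shell boundary from site–site RDFs

try:
    from MDAnalysis.lib.distances import distance_array as _mda_distance_array
except ImportError:  # pragma: no cover - MDAnalysis present in normal installs
    _mda_distance_array = None


@dataclass
class OrientationStats:
    mean_theta: float  # degrees, circular mean in [0, 180]
    order_parameter: float  # ∈ [−0.5, 1]
    n_frames: int

    def __post_init__(self) -> None:
        if not -0.5 - 1e-12 <= self.order_parameter <= 1.0 + 1e-12:
            raise ValueError("order parameter outside [-0.5, 1]")


@dataclass
class SolvationCounts:
    """Per-frame, per-class solvation counts (rows = frames)."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (n_frames, n_classes) integers

    def mean(self) -> dict[str, float]:
        return {c: float(self.counts[:, i].mean()) for i, c in enumerate(self.classes)}


def _pairwise_min_image(ref: np.ndarray, conf: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(n_ref, n_conf) minimum-image distances in an orthorhombic box."""
    if _mda_distance_array is not None:
        mda_box = np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0])
        return _mda_distance_array(np.ascontiguousarray(ref), np.ascontiguousarray(conf),
                                   box=mda_box)
    d = ref[:, None, :] - conf[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt((d**2).sum(axis=-1))


def orientation_stats(frames: FrameSet) -> OrientationStats:
    """Circular-mean polar angle and order parameter of the N1→S vector."""
    vecs = frames.solute[:, frames.s_index, :] - frames.solute[:, frames.n1_index, :]
    norms = np.linalg.norm(vecs, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-length orientation vector in frame {bad[0]}")
    cos_t = vecs[:, 2] / norms
    cos_t = np.clip(cos_t, -1.0, 1.0)
    theta = np.arccos(cos_t)
    mean_theta = np.degrees(np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()))
    order = 0.5 * (3.0 * np.mean(cos_t**2) - 1.0)
    return OrientationStats(
        mean_theta=float(mean_theta),
        order_parameter=float(order),
        n_frames=frames.n_frames,
    )


def solvation_numbers(frames: FrameSet, cutoff: float = DEFAULT_CUTOFF) -> SolvationCounts:
    """Count oxygens of each class within ``cutoff`` of any solute heavy atom.

    Each oxygen is counted at most once per frame (nearest-contact rule).
    The cutoff must respect the minimum-image convention, i.e. be below
    half the smallest box length.
    """
    if cutoff > 0.5 * frames.box.min():
        raise ValueError(
            f"cutoff {cutoff} Å violates minimum image (box min {frames.box.min()} Å)"
        )
    classes = tuple(sorted(frames.oxygens))
    counts = np.zeros((frames.n_frames, len(classes)), dtype=int)
    for f in range(frames.n_frames):
        sol = frames.solute[f]
        for j, name in enumerate(classes):
            oxy = frames.oxygens[name][f]
            if oxy.shape[0] == 0:
                continue
            dmin = _pairwise_min_image(oxy, sol, frames.box).min(axis=1)
            counts[f, j] = int(np.count_nonzero(dmin <= cutoff))
    return SolvationCounts(classes=classes, counts=counts)


def site_rdf(
    frames: FrameSet,
    oxygen_class: str,
    bin_width: float = 0.1,
    r_max: float = 10.0,
    mode: str = "min",
) -> Profile:
    """Radial distribution of class oxygens around the solute.

    ``mode="min"`` (default) histograms each oxygen's minimum-image
    distance to its *nearest* solute heavy atom — the construction whose
    first minimum defines the solvation cutoff. ``mode="pair"`` is the
    conventional all-pairs site–site RDF. Both are normalized to the
    ideal-gas density of the oxygen class in the box, so g(r) → 1 for
    uniformly distributed oxygens (exactly so for a single-site solute in
    ``min`` mode).
    """
    if frames.n_frames < 1:
        raise ValueError("need at least one frame")
    if r_max > 0.5 * frames.box.min():
        raise ValueError("r_max violates the minimum-image convention")
    if oxygen_class not in frames.oxygens:
        raise ValueError(f"unknown oxygen class {oxygen_class!r}")
    oxy_all = frames.oxygens[oxygen_class]
    n_oxy = oxy_all.shape[1]
    if n_oxy == 0:
        raise ValueError(f"oxygen class {oxygen_class!r} is empty")
    if mode not in ("min", "pair"):
        raise ValueError("mode must be 'min' or 'pair'")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(edges.size - 1)
    for f in range(frames.n_frames):
        d = _pairwise_min_image(oxy_all[f], frames.solute[f], frames.box)
        r = d.min(axis=1) if mode == "min" else d.ravel()
        hist += np.histogram(r, bins=edges)[0]

    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = n_oxy / float(np.prod(frames.box))
    n_ref = 1 if mode == "min" else frames.solute.shape[1]
    g = hist / (frames.n_frames * n_ref * shell_vol * rho)
    return Profile(centers, g, defined_mask=np.ones_like(g, dtype=bool),
                   units="dimensionless")
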
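"""End-to-end permeation pipeline: windows → PMF → K, ΔG → D(z) → P, τ.

``pipeline_permeation`` chains the analysis stages the way a full
umbrella-sampling study is processed: WHAM, symmetrization, bulk
anchoring, feature extraction and the partition integral on the PMF side;
per-window diffusivity estimation and the solubility–diffusion integral
on the kinetics side. The summary mirrors the row structure of a
partitioning/permeability results table (peak, well, barrier, K, ΔG,
D in water and membrane, log P, crossing time).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from . import kinetics, pmf_analysis, wham
from .sampling_io import Profile, UmbrellaDataset, read_metadata, write_profile

__all__ = ["RunConfig", "PipelineResult", "pipeline_permeation", "load_config"]

log = logging.getLogger("memperm")


@dataclass
class RunConfig:
    """Validated knobs for one pipeline run."""

    meta_path: str = ""
    out_dir: str = ""
    temperature: float = 310.0
    bin_width: float = 0.2
    tolerance: float = 1e-6
    max_iter: int = 100_000
    equilibration_discard: float = 4000.0
    z1: float = -40.0
    z2: float = 40.0
    bulk_min_abs_z: float = 30.0
    half_width: float = 14.0
    reference: str = "border"
    pmf_only: bool = False
    pool_duplicates: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not self.z1 < self.z2:
            raise ValueError("need z1 < z2")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.reference not in ("border", "bulk"):
            raise ValueError("reference must be 'border' or 'bulk'")
        if self.equilibration_discard < 0:
            raise ValueError("equilibration_discard must be nonnegative")


def load_config(path: str, **overrides) -> RunConfig:
    """Read a TOML config; keyword overrides win over file values."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    summary: dict
    pmf: Profile
    pmf_symmetrized: Profile
    d_profile: Profile | None
    wham_result: "wham.WhamResult"


def pipeline_permeation(
    config: RunConfig, dataset: UmbrellaDataset | None = None
) -> PipelineResult:
    """Run the full permeation analysis described in the module docstring.

    ``dataset`` may be passed directly (e.g. from the synthetic
    generator); otherwise it is read from ``config.meta_path``. When
    ``config.out_dir`` is set, profiles, the JSON summary and the
    effective config are written there. Any stage failure aborts with the
    stage named; outputs of completed stages are preserved on disk.
    """
    config.validate()
    if dataset is None:
        log.info("reading metadata from %s", config.meta_path)
        dataset = read_metadata(
            config.meta_path,
            temperature=config.temperature,
            equilibration_discard=config.equilibration_discard,
        )
    out = config.out_dir
    if out:
        os.makedirs(out, exist_ok=True)
        with open(os.path.join(out, "effective_config.json"), "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=1)

    def stage(name, fn, *args, **kw):
        log.info("stage: %s", name)
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    wres = stage("wham", wham.run_wham, dataset, config.bin_width,
                 config.tolerance, config.max_iter, config.pool_duplicates)
    if out:
        write_profile(wres.pmf, os.path.join(out, "pmf_raw.dat"))
    sym = stage("symmetrize", pmf_analysis.symmetrize, wres.pmf)
    anchored = stage("anchor_bulk", pmf_analysis.anchor_bulk, sym, config.bulk_min_abs_z)
    if out:
        write_profile(anchored, os.path.join(out, "pmf.dat"))
    feats = stage("extract_features", pmf_analysis.extract_features, anchored)
    part = stage(
        "partition_coefficient", pmf_analysis.partition_coefficient,
        anchored, config.z1, config.z2, config.temperature,
    )
    summary = {
        "W_peak": feats.w_peak,
        "z_peak": feats.z_peak,
        "W_well": feats.w_well,
        "z_well": feats.z_well,
        "W_barrier": feats.w_barrier,
        "K": part.K,
        "K_error": part.K_error,
        "dG": part.dG,
        "dG_error": part.dG_error,
        "temperature": config.temperature,
    }

    d_profile = None
    if not config.pmf_only:
        d_profile, _ = stage("diffusion_profile", kinetics.diffusion_profile, dataset)
        if out:
            write_profile(d_profile, os.path.join(out, "diffusivity.dat"))
        perm = stage(
            "permeability", kinetics.permeability, anchored, d_profile,
            config.half_width, config.temperature, config.reference,
        )
        dm = d_profile.defined_mask
        az = np.abs(d_profile.z_grid)
        d_wat = float(np.mean(d_profile.values[dm & (az >= config.bulk_min_abs_z)]))
        d_mem = float(np.mean(d_profile.values[dm & (az <= 5.0)]))
        summary.update({
            "D_wat_cm2_per_s": d_wat * 1e-4,
            "D_mem_cm2_per_s": d_mem * 1e-4,
            "P_cm_per_s": perm.P,
            "logP": perm.logP,
            "tau_cross_s": perm.tau_cross,
            "half_width": config.half_width,
        })

    if out:
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
    return PipelineResult(
        summary=summary,
        pmf=wres.pmf,
        pmf_symmetrized=anchored,
        d_profile=d_profile,
        wham_result=wres,
    )
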
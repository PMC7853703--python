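"""Seeded end-to-end driver: phantoms -> maps -> lesions -> infarct -> tables.

For every sampled patient the driver rasterises a lesion matching the
patient's ground-truth volumes, simulates the noisy CTP acquisition and the
follow-up CT, runs map estimation and threshold segmentation, grows the
final infarct, and records the recovered volumes next to the generating
ones.  All randomness flows from one top-level seed through per-patient
child seeds, so a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ctpstroke import io as ctpio
from ctpstroke.cohort_stats import build_tables
from ctpstroke.infarct import RegionGrowConfig, infarct_volume, segment_infarct
from ctpstroke.lesion import ThresholdConfig, repair_config, segment_lesion
from ctpstroke.perfusion import DeconvConfig, estimate_maps
from ctpstroke.phantom import (
    AIFModel,
    CohortSpec,
    GridSpec,
    PatientRecord,
    brain_mask_for_grid,
    build_phantom,
    cohort_to_frame,
    geometry_for_volumes,
    load_preset,
    make_followup_ct,
    sample_cohort,
    scaled_spec,
)

__all__ = ["PipelineConfig", "process_patient", "recover_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; presets name the cohorts to simulate."""

    presets: tuple[str, ...] = ("covid_2020", "no_covid_2019")
    n_per_period: dict = field(default_factory=dict)  # preset -> n override
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    aif: AIFModel = field(default_factory=AIFModel.with_peak)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    region_grow: RegionGrowConfig = field(default_factory=RegionGrowConfig)
    noise_sigma: float = 2.0
    followup_base_hu: float = 32.0
    followup_delta_hu: float = 15.0
    stratified: bool = True
    output_dir: str | Path = "results/pipeline"

    def __post_init__(self) -> None:
        if int(self.seed) < 0:
            raise ValueError("seed must be a non-negative integer")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["output_dir"] = str(payload["output_dir"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _seed_mask_center(mask: np.ndarray) -> tuple[int, int, int]:
    """An interior seed voxel: the mask voxel nearest its centre of mass."""
    com = ndimage.center_of_mass(mask)
    idx = np.argwhere(mask)
    nearest = idx[np.argmin(((idx - np.asarray(com)) ** 2).sum(axis=1))]
    return tuple(int(v) for v in nearest)


def process_patient(
    record: PatientRecord,
    config: PipelineConfig,
    seed: int,
    brain: np.ndarray | None = None,
) -> PatientRecord:
    """Simulate one patient's acquisitions and fill the recovered volumes."""
    grid = config.grid
    if brain is None:
        brain = brain_mask_for_grid(grid)
    child = np.random.default_rng(seed)
    seed_ctp, seed_ct = (int(s) for s in child.integers(0, 2**31 - 1, size=2))

    geom, _ = geometry_for_volumes(
        record.total_true, record.core_true, grid, brain=brain
    )
    phantom = build_phantom(
        geom, aif=config.aif, grid=grid, noise_sigma=config.noise_sigma,
        seed=seed_ctp, brain=brain,
    )
    maps = estimate_maps(phantom, config=config.deconv)
    seg_cfg = config.thresholds
    if config.noise_sigma > 0:
        seg_cfg = repair_config(seg_cfg)
    _, volumes = segment_lesion(
        maps, brain, grid.midline_index, phantom.side, grid.spacing, seg_cfg
    )
    record.total_recovered = volumes.total_ml
    record.core_recovered = volumes.core_ml

    inf_geom, _ = geometry_for_volumes(record.infarct_true, 0.0, grid, brain=brain)
    if inf_geom is None:
        record.infarct_recovered = 0.0
    else:
        from ctpstroke.phantom import ellipsoid_mask

        inf_mask = ellipsoid_mask(grid, inf_geom.center_mm, inf_geom.penumbra_semi_mm)
        inf_mask &= brain
        if not inf_mask.any():
            record.infarct_recovered = 0.0
        else:
            ct = make_followup_ct(
                inf_mask,
                base_hu=config.followup_base_hu,
                delta_hu=config.followup_delta_hu,
                noise_sigma=config.noise_sigma,
                seed=seed_ct,
                brain=brain,
            )
            mask, _ = segment_infarct(
                ct, [_seed_mask_center(inf_mask)], brain, config.region_grow
            )
            record.infarct_recovered = infarct_volume(mask, grid.spacing)
    return record


def recover_cohort(
    spec: CohortSpec | str,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    n: int | None = None,
    with_infarct: bool = True,
) -> pd.DataFrame:
    """Sample a cohort and run every patient through the imaging chain."""
    if config is None:
        config = PipelineConfig()
    if isinstance(spec, str):
        spec = load_preset(spec)
    if n is not None:
        spec = scaled_spec(spec, n)
    master = np.random.default_rng(config.seed if seed is None else seed)
    records = sample_cohort(spec, master, stratified=config.stratified)
    brain = brain_mask_for_grid(config.grid)
    patient_seeds = master.integers(0, 2**31 - 1, size=len(records))
    for record, child_seed in zip(records, patient_seeds):
        if not with_infarct:
            record.infarct_recovered = record.infarct_true
        process_patient(record, config, int(child_seed), brain=brain)
    return cohort_to_frame(records)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full two-period study and write its outputs.

    Writes the per-patient cohort CSV, the clinical and neuroimaging
    comparison tables, and a run manifest (configuration hash, seed,
    package and numpy versions).  Returns the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    frames = []
    for preset in config.presets:
        spec = load_preset(preset)
        if preset in config.n_per_period:
            spec = scaled_spec(spec, config.n_per_period[preset])
        frame = recover_cohort(
            spec, config, seed=int(master.integers(0, 2**31 - 1))
        )
        frames.append(frame)
    cohort = pd.concat(frames, ignore_index=True)
    ctpio.save_table(out / "cohort.csv", cohort)

    clinical, neuro = build_tables(cohort)
    ctpio.save_table(out / "table_clinical.csv", clinical)
    ctpio.save_table(out / "table_neuroimaging.csv", neuro)

    import ctpstroke

    ctpio.save_json(
        out / "manifest.json",
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "presets": list(config.presets),
            "n_patients": int(len(cohort)),
            "ctpstroke_version": ctpstroke.__version__,
            "numpy_version": np.__version__,
        },
    )
    return out
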
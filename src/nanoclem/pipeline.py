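"""End-to-end run: registration -> detection -> assignment -> statistics.

``run_pipeline`` composes the stages on in-memory objects and (optionally)
writes every stage's table, the solved transform, the distribution
statistics and a run manifest into a run directory, so a run can be
re-executed from its manifest to identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .correlate import (
    CorrelationRecord,
    CorrelationSummary,
    assign_particles,
    correlation_to_df,
    usable_particle_positions,
)
from .image import RasterImage
from .particles import ParticleParams, ParticleRecord, particles_to_df, segment_particles
from .registration import AffineTransform, FiducialSet, map_points, solve_transform
from .simulate import ConfigurationError
from .spots import SpotParams, SpotRecord, detect_spots, measure_spots, spots_to_df
from .stats import DEFAULT_BINS_COUNTS, DEFAULT_BINS_FWHM, summarize_column

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters for one correlative run."""

    spot_params: SpotParams = field(default_factory=SpotParams)
    particle_params: ParticleParams = field(default_factory=ParticleParams)
    radius_factor: float = 1.0
    fwhm_bins: int = DEFAULT_BINS_FWHM
    count_bins: int = DEFAULT_BINS_COUNTS

    def __post_init__(self):
        if self.radius_factor <= 0:
            raise ConfigurationError("radius_factor: must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for key, sub in (("spot_params", SpotParams), ("particle_params", ParticleParams)):
            if key in d:
                known = {f.name for f in dataclasses.fields(sub)}
                unknown = set(d[key]) - known
                if unknown:
                    raise ConfigurationError(f"unknown {key} keys: {sorted(unknown)}")
                kwargs[key] = sub(**d.pop(key))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**kwargs, **d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    transform: AffineTransform
    spots: list[SpotRecord]
    particles: list[ParticleRecord]
    correlation: list[CorrelationRecord]
    summary: CorrelationSummary
    stats: dict


def run_pipeline(
    tirf: RasterImage,
    esem: RasterImage,
    fiducials: FiducialSet,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Register, detect, assign and summarise one TIRF/ESEM pair."""
    config = config or PipelineConfig()

    transform = _stage("registration", solve_transform, fiducials)
    logger.info("registration FRE = %.3g nm over %d fiducials",
                fiducials.fre_nm, len(fiducials))

    spots = _stage(
        "spot detection",
        lambda: measure_spots(
            tirf, detect_spots(tirf, config.spot_params), config.spot_params
        ),
    )
    particles = _stage(
        "particle segmentation", segment_particles, esem, config.particle_params
    )

    def _assign():
        xy_esem, ids = usable_particle_positions(particles)
        xy_tirf = map_points(transform, xy_esem) if len(xy_esem) else xy_esem
        return assign_particles(spots, xy_tirf, ids, config.radius_factor)

    records, summary = _stage("assignment", _assign)

    stats_out = {}
    fwhm = [s.fwhm_nm for s in spots if np.isfinite(s.fwhm_nm)]
    if len(fwhm) >= 1:
        _, _, stats_out["fwhm_nm"] = _stage(
            "FWHM statistics", summarize_column, fwhm, config.fwhm_bins
        )
    counts = [r.particle_count for r in records]
    if len(counts) >= 1:
        _, _, stats_out["particles_per_domain"] = _stage(
            "count statistics", summarize_column, counts, config.count_bins
        )

    result = PipelineResult(transform, spots, particles, records, summary, stats_out)
    if out_dir is not None:
        write_run(out_dir, result, config, fiducials)
    return result


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


# --------------------------------------------------------------------------
# run directory + manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run(
    out_dir, result: PipelineResult, config: PipelineConfig, fiducials: FiducialSet
) -> dict:
    """Write all stage outputs and a manifest with checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spots_to_df(result.spots).to_csv(out / "spots.csv", index=False)
    particles_to_df(result.particles).to_csv(out / "particles.csv", index=False)
    correlation_to_df(result.correlation).to_csv(out / "correlation.csv", index=False)
    result.transform.to_json(out / "transform.json")
    fiducials.to_csv(out / "fiducials.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "correlation": result.summary.to_dict(),
                "registration": {
                    "fre_nm": fiducials.fre_nm,
                    "n_fiducials": len(fiducials),
                    "decomposition": _jsonable(result.transform.decomposition),
                },
                "stats": result.stats,
            },
            fh,
            indent=2,
            default=_jsonable,
        )
    files = ["spots.csv", "particles.csv", "correlation.csv",
             "transform.json", "fiducials.csv", "summary.json"]
    manifest = {
        "software": {"name": "nanoclem", "version": __version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config.to_dict(),
        "outputs": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
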
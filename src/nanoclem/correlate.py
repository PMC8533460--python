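"""Assign registered gold particles to nanodomains and count them.

Once particle centroids are mapped into the fluorescence frame, each
particle is assigned to the nearest nanodomain whose acceptance disk
contains it; the default disk radius is half the spot's own measured FWHM
(scaled by ``radius_factor``), so the rule adapts to each domain's size.
Particles with no candidate domain are counted as background — the study
system genuinely has label both inside and outside nanodomains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .particles import ParticleRecord
from .particles import FLAG_OK as P_OK
from .spots import SpotRecord

logger = logging.getLogger(__name__)


@dataclass
class CorrelationRecord:
    spot_id: int
    particle_count: int
    particle_ids: list[int] = field(default_factory=list)
    assignment_radius_nm: float = np.nan


@dataclass
class CorrelationSummary:
    n_spots: int
    n_particles_total: int
    n_assigned: int
    n_background: int
    mean_count: float
    count_range: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "n_spots": self.n_spots,
            "n_particles_total": self.n_particles_total,
            "n_assigned": self.n_assigned,
            "n_background": self.n_background,
            "mean_count": self.mean_count,
            "count_range": list(self.count_range),
        }


def assign_particles(
    spots: list[SpotRecord],
    particles_xy_nm: np.ndarray,
    particle_ids=None,
    radius_factor: float = 1.0,
) -> tuple[list[CorrelationRecord], CorrelationSummary]:
    """Exclusive nearest-candidate assignment of particles to spots.

    A particle is a candidate for a spot when its distance to the spot
    center is at most ``0.5 * FWHM * radius_factor``; it is assigned to its
    nearest candidate spot, ties broken toward the lower spot id.  Spots
    without a usable FWHM are excluded (and logged).  The summary always
    satisfies ``n_assigned + n_background == n_particles_total``.
    """
    pts = np.asarray(particles_xy_nm, dtype=float).reshape(-1, 2)
    if particle_ids is None:
        particle_ids = np.arange(len(pts))
    particle_ids = np.asarray(particle_ids)

    usable = [s for s in spots if np.isfinite(s.fwhm_nm) and s.fwhm_nm > 0]
    dropped = len(spots) - len(usable)
    if dropped:
        logger.info("excluding %d spot(s) without a valid FWHM from assignment", dropped)

    records = {
        s.spot_id: CorrelationRecord(
            s.spot_id, 0, [], 0.5 * s.fwhm_nm * radius_factor
        )
        for s in usable
    }
    n_assigned = 0
    if usable and len(pts):
        # order by spot_id so argmin's first-minimum rule is the tie-break
        order = np.argsort([s.spot_id for s in usable], kind="stable")
        centers = np.array([[usable[i].x_nm, usable[i].y_nm] for i in order])
        radii = np.array([records[usable[i].spot_id].assignment_radius_nm for i in order])
        ids = np.array([usable[i].spot_id for i in order])
        d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        candidate = d <= radii[None, :]
        d_masked = np.where(candidate, d, np.inf)
        best = np.argmin(d_masked, axis=1)
        has_candidate = candidate.any(axis=1)
        for k in np.flatnonzero(has_candidate):
            rec = records[int(ids[best[k]])]
            rec.particle_ids.append(int(particle_ids[k]))
            rec.particle_count += 1
        n_assigned = int(has_candidate.sum())

    recs = sorted(records.values(), key=lambda r: r.spot_id)
    counts = [r.particle_count for r in recs]
    summary = CorrelationSummary(
        n_spots=len(recs),
        n_particles_total=len(pts),
        n_assigned=n_assigned,
        n_background=len(pts) - n_assigned,
        mean_count=float(np.mean(counts)) if counts else float("nan"),
        count_range=(int(min(counts)), int(max(counts))) if counts else (0, 0),
    )
    return recs, summary


def correlation_to_df(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_id": r.spot_id,
                "count": r.particle_count,
                "assignment_radius_nm": r.assignment_radius_nm,
                "particle_ids": ";".join(str(i) for i in r.particle_ids),
            }
            for r in records
        ],
        columns=["spot_id", "count", "assignment_radius_nm", "particle_ids"],
    )


def usable_particle_positions(
    particles: list[ParticleRecord], include_flags=(P_OK,)
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and ids of particles whose flag is in ``include_flags``."""
    keep = [p for p in particles if p.flag in include_flags]
    if not keep:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    xy = np.array([[p.x_nm, p.y_nm] for p in keep])
    ids = np.array([p.particle_id for p in keep], dtype=int)
    return xy, ids
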
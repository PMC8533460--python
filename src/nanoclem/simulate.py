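"""Synthetic paired TIRF / ESEM fields with known ground truth.

Emulates the study system: plasma-membrane nanodomains appear in a TIRF
frame (60 nm pixels) as diffraction-limited Gaussian spots whose FWHM is
unimodal around 300-500 nm, while gold-enhanced immunolabel particles
(~38 nm equivalent diameter) appear in a much finer electron image as
small disks, clustered inside nanodomains (mean about five per domain,
heavy right tail) with additional background particles outside them.
The two frames are related by a known translation + rotation +
anisotropic-scale transform, which the registration stage must recover
from fiducial pairs that satisfy it exactly.

Every stochastic choice flows from one ``numpy`` Generator seeded from
``SimulationConfig.seed``, so a fixed config yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .image import RasterImage, read_image, write_image
from .registration import AffineTransform, FiducialSet

UINT16_MAX = 65535
#: Photon baseline added under every TIRF pixel before shot noise.
TIRF_BASELINE_PHOTONS = 5.0
#: ESEM background level and particle contrast, in counts.
ESEM_BACKGROUND = 100.0
ESEM_CONTRAST = 400.0

BACKGROUND_ID = -1  # domain_id of particles outside any nanodomain


class ConfigurationError(ValueError):
    """Invalid simulation or stage configuration."""


def _default_transform() -> AffineTransform:
    # modest rotation, anisotropic scale and offset, representative of a
    # manually seated coverslip re-imaged on a second instrument
    return AffineTransform.from_params(
        rotation_rad=np.deg2rad(2.0),
        scale=(1.03, 0.97),
        translation_nm=(150.0, -80.0),
    )


@dataclass
class SimulationConfig:
    """Generator parameters; all lengths in nm, densities per µm²."""

    tirf_pixel_nm: float = 60.0
    esem_pixel_nm: float = 3.0
    field_nm: tuple[float, float] = (20000.0, 20000.0)
    n_domains: int = 50
    fwhm_mean_nm: float = 400.0
    fwhm_sd_nm: float = 80.0
    count_mean: float = 5.0
    count_dispersion: float = 2.0
    particle_diam_mean_nm: float = 38.0
    particle_diam_sd_nm: float = 11.5
    background_particle_density: float = 1.0
    transform_truth: AffineTransform = field(default_factory=_default_transform)
    noise: tuple[float, float, float] = (50.0, 2.0, 0.05)
    particle_polarity: str = "bright"
    domain_min_separation_nm: float = 1200.0
    seed: int = 0

    def __post_init__(self):
        self.field_nm = tuple(float(v) for v in self.field_nm)
        if min(self.field_nm) <= 0:
            raise ConfigurationError("field_nm: both extents must be positive")
        for key in (
            "tirf_pixel_nm",
            "esem_pixel_nm",
            "fwhm_mean_nm",
            "fwhm_sd_nm",
            "particle_diam_mean_nm",
            "particle_diam_sd_nm",
        ):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key}: must be positive")
        if self.n_domains < 0:
            raise ConfigurationError("n_domains: must be >= 0")
        if self.fwhm_mean_nm <= self.tirf_pixel_nm:
            raise ConfigurationError(
                "fwhm_mean_nm must exceed tirf_pixel_nm (spots must be resolvable)"
            )
        if self.count_mean <= 1:
            raise ConfigurationError(
                "count_mean: a >=1-truncated count distribution cannot have mean <= 1"
            )
        if self.count_dispersion <= 0:
            raise ConfigurationError("count_dispersion: must be positive")
        if self.background_particle_density < 0:
            raise ConfigurationError("background_particle_density: must be >= 0")
        if self.particle_polarity not in ("bright", "dark"):
            raise ConfigurationError("particle_polarity: must be 'bright' or 'dark'")
        if len(self.noise) != 3 or any(v < 0 for v in self.noise):
            raise ConfigurationError(
                "noise: (tirf_photon_scale, tirf_read_sd, esem_noise_frac), all >= 0"
            )
        if not isinstance(self.transform_truth, AffineTransform):
            self.transform_truth = AffineTransform.from_json(self.transform_truth)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "noise" in d:
            d["noise"] = tuple(d["noise"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transform_truth"] = self.transform_truth.to_json()
        d["field_nm"] = list(self.field_nm)
        d["noise"] = list(self.noise)
        return d


@dataclass
class GroundTruth:
    """Truth tables for one simulated pair (all coordinates in nm)."""

    domains: pd.DataFrame  # domain_id, x_nm, y_nm, fwhm_nm, count, in_esem_field
    particles: pd.DataFrame  # particle_id, x_tirf/esem_nm..., diam_nm, domain_id
    fiducials: FiducialSet
    transform: AffineTransform


# --------------------------------------------------------------------------
# truncated negative-binomial particle counts
# --------------------------------------------------------------------------

def _nb_p(mean: float, dispersion: float) -> float:
    return dispersion / (dispersion + mean)


def truncated_nb_mean(untruncated_mean: float, dispersion: float) -> float:
    """Mean of a negative binomial conditioned on being >= 1."""
    p = _nb_p(untruncated_mean, dispersion)
    return untruncated_mean / (1.0 - p**dispersion)


def calibrate_truncated_nb(target_mean: float, dispersion: float) -> float:
    """Untruncated NB mean whose >=1-truncated mean equals ``target_mean``."""
    if target_mean <= 1:
        raise ConfigurationError("truncated count mean must exceed 1")
    lo, hi = 1e-9, target_mean
    return float(
        optimize.brentq(
            lambda m: truncated_nb_mean(m, dispersion) - target_mean, lo, hi
        )
    )


def sample_truncated_nb(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    """Draw n per-domain counts from the >=1-truncated negative binomial.

    Inverse-CDF sampling: uniforms restricted to (P(X=0), 1] then pushed
    through the untruncated quantile function, so the result is exact.
    """
    m0 = calibrate_truncated_nb(mean, dispersion)
    p = _nb_p(m0, dispersion)
    p0 = p**dispersion
    u = rng.uniform(p0, 1.0, size=n)
    return stats.nbinom.ppf(u, dispersion, p).astype(int)


# --------------------------------------------------------------------------
# ground-truth sampling
# --------------------------------------------------------------------------

def _dart_throw(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_sep: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Uniform points in the box [lo, hi] with pairwise separation >= min_sep."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries > max_tries:
            raise ConfigurationError(
                f"could not place {n} domains with separation {min_sep} nm in the "
                "field; enlarge field_nm or reduce n_domains"
            )
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - q)) >= min_sep for q in pts):
            pts.append(cand)
        tries += 1
    return np.array(pts).reshape(n, 2)


def _place_hard_core(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    diam: np.ndarray,
    clearance_nm: float,
    n_candidates: int = 30,
) -> np.ndarray:
    """Uniform-in-disk placement with pairwise center separation >= sum of
    radii + clearance where geometrically possible.

    Best-candidate sampling: each particle draws ``n_candidates`` uniform
    positions and keeps the one maximising clearance to those already
    placed, so a crowded small domain degrades gracefully instead of
    failing (overlaps then become possible but stay rare).
    """
    k = len(diam)
    placed = np.empty((k, 2))
    for j in range(k):
        r = radius * np.sqrt(rng.uniform(0, 1, n_candidates))
        phi = rng.uniform(0, 2 * np.pi, n_candidates)
        cand = center + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        if j == 0:
            placed[0] = cand[0]
            continue
        required = (diam[j] + diam[:j]) / 2.0 + clearance_nm  # (j,)
        d = np.linalg.norm(cand[:, None, :] - placed[None, :j, :], axis=2)
        slack = (d - required[None, :]).min(axis=1)
        ok = np.flatnonzero(slack >= 0)
        placed[j] = cand[ok[0]] if len(ok) else cand[int(np.argmax(slack))]
    return placed


def sample_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw domains, per-domain counts, particles and fiducials."""
    w, h = config.field_nm
    margin = config.fwhm_mean_nm + 3 * config.fwhm_sd_nm
    margin = min(margin, 0.25 * min(w, h))  # keep usable area on tiny fields

    if config.n_domains > 0:
        centers = _dart_throw(
            rng,
            config.n_domains,
            np.array([margin, margin]),
            np.array([w - margin, h - margin]),
            config.domain_min_separation_nm,
        )
        fwhm = rng.normal(config.fwhm_mean_nm, config.fwhm_sd_nm, config.n_domains)
        floor = 2 * config.tirf_pixel_nm
        while np.any(fwhm < floor):  # resample unphysical (unresolvable) widths
            bad = fwhm < floor
            fwhm[bad] = rng.normal(config.fwhm_mean_nm, config.fwhm_sd_nm, bad.sum())
        counts = sample_truncated_nb(
            rng, config.n_domains, config.count_mean, config.count_dispersion
        )
    else:
        centers = np.empty((0, 2))
        fwhm = np.empty(0)
        counts = np.empty(0, dtype=int)

    # in-domain particles: uniform in the disk of radius FWHM/2, with a
    # hard-core constraint — gold-enhanced particles are solid spheres and
    # cannot interpenetrate, so centers keep at least the sum of radii
    # (plus a 6 nm clearance) apart where the disk allows it
    pos, diam, owner = [], [], []
    for i in range(config.n_domains):
        k = counts[i]
        dk = np.clip(
            rng.normal(config.particle_diam_mean_nm, config.particle_diam_sd_nm, k),
            5.0,
            None,
        )
        pk = _place_hard_core(rng, centers[i], fwhm[i] / 2.0, dk, clearance_nm=6.0)
        pos.append(pk)
        diam.append(dk)
        owner.extend([i] * k)
    # background particles: uniform over the whole field (sparse enough that
    # overlaps are negligible)
    area_um2 = (w / 1000.0) * (h / 1000.0)
    n_bg = rng.poisson(config.background_particle_density * area_um2)
    if n_bg:
        pos.append(
            np.column_stack([rng.uniform(0, w, n_bg), rng.uniform(0, h, n_bg)])
        )
        diam.append(
            np.clip(
                rng.normal(
                    config.particle_diam_mean_nm, config.particle_diam_sd_nm, n_bg
                ),
                5.0,
                None,
            )
        )
        owner.extend([BACKGROUND_ID] * n_bg)
    pos_tirf = np.vstack(pos) if pos else np.empty((0, 2))
    diam = np.concatenate(diam) if diam else np.empty(0)
    n_part = len(pos_tirf)

    inv = config.transform_truth.inverse()
    pos_esem = inv.apply(pos_tirf) if n_part else np.empty((0, 2))

    # fiducials: four target-frame points inset from the corners, sources exact
    inset = 0.1 * min(w, h)
    tgt = np.array(
        [[inset, inset], [w - inset, inset], [w - inset, h - inset], [inset, h - inset]]
    )
    fiducials = FiducialSet(inv.apply(tgt), tgt)

    centers_esem = inv.apply(centers) if config.n_domains else np.empty((0, 2))
    in_field = (
        (centers_esem[:, 0] >= 0)
        & (centers_esem[:, 0] <= w)
        & (centers_esem[:, 1] >= 0)
        & (centers_esem[:, 1] <= h)
        if config.n_domains
        else np.empty(0, dtype=bool)
    )
    if config.n_domains and not in_field.all():
        warnings.warn(
            f"{(~in_field).sum()} domain(s) map outside the ESEM field; "
            "retained in truth and flagged",
            stacklevel=2,
        )

    domains = pd.DataFrame(
        {
            "domain_id": np.arange(config.n_domains, dtype=int),
            "x_nm": centers[:, 0],
            "y_nm": centers[:, 1],
            "fwhm_nm": fwhm,
            "count": counts,
            "in_esem_field": in_field,
        }
    )
    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n_part, dtype=int),
            "x_tirf_nm": pos_tirf[:, 0] if n_part else np.empty(0),
            "y_tirf_nm": pos_tirf[:, 1] if n_part else np.empty(0),
            "x_esem_nm": pos_esem[:, 0] if n_part else np.empty(0),
            "y_esem_nm": pos_esem[:, 1] if n_part else np.empty(0),
            "diam_nm": diam,
            "domain_id": np.array(owner, dtype=int),
        }
    )
    return GroundTruth(domains, particles, fiducials, config.transform_truth)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_tirf(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> RasterImage:
    """Render nanodomain spots as 2-D Gaussians with shot + read noise."""
    px = config.tirf_pixel_nm
    shape = (int(round(config.field_nm[1] / px)), int(round(config.field_nm[0] / px)))
    photons = np.zeros(shape)
    scale, read_sd, _ = config.noise
    for row in truth.domains.itertuples():
        sigma_px = row.fwhm_nm / 2.3548200450309493 / px
        _add_gaussian(photons, row.x_nm / px, row.y_nm / px, sigma_px, scale)
    img = rng.poisson(photons + TIRF_BASELINE_PHOTONS).astype(float)
    img += rng.normal(0.0, read_sd, shape)
    img = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
    return RasterImage(img, px, "tirf")


def render_esem(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> RasterImage:
    """Render gold particles as antialiased disks over a uniform background."""
    px = config.esem_pixel_nm
    shape = (int(round(config.field_nm[1] / px)), int(round(config.field_nm[0] / px)))
    contrast = ESEM_CONTRAST if config.particle_polarity == "bright" else -ESEM_CONTRAST
    base = ESEM_BACKGROUND if config.particle_polarity == "bright" else ESEM_BACKGROUND + ESEM_CONTRAST
    img = np.full(shape, base, dtype=np.float32)
    for row in truth.particles.itertuples():
        _add_disk(img, row.x_esem_nm / px, row.y_esem_nm / px, row.diam_nm / 2 / px, contrast)
    noise_sd = config.noise[2] * ESEM_CONTRAST
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape).astype(np.float32)
    img = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
    return RasterImage(img, px, "esem")


def _add_gaussian(canvas, cx_px, cy_px, sigma_px, amplitude) -> None:
    half = int(np.ceil(4 * sigma_px)) + 1
    r0 = max(int(np.floor(cy_px)) - half, 0)
    r1 = min(int(np.ceil(cy_px)) + half + 1, canvas.shape[0])
    c0 = max(int(np.floor(cx_px)) - half, 0)
    c1 = min(int(np.ceil(cx_px)) + half + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -((cc - cx_px) ** 2 + (rr - cy_px) ** 2) / (2 * sigma_px**2)
    )


def _add_disk(canvas, cx_px, cy_px, radius_px, contrast) -> None:
    half = int(np.ceil(radius_px)) + 2
    r0 = max(int(np.floor(cy_px)) - half, 0)
    r1 = min(int(np.ceil(cy_px)) + half + 1, canvas.shape[0])
    c0 = max(int(np.floor(cx_px)) - half, 0)
    c1 = min(int(np.ceil(cx_px)) + half + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(cc - cx_px, rr - cy_px)
    coverage = np.clip(radius_px - d + 0.5, 0.0, 1.0)  # 1-px antialiased edge
    canvas[r0:r1, c0:c1] += (contrast * coverage).astype(canvas.dtype)


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------

def simulate_pair(
    config: SimulationConfig,
) -> tuple[RasterImage, RasterImage, GroundTruth]:
    """Generate one matched TIRF/ESEM pair with ground truth."""
    rng = np.random.default_rng(config.seed)
    truth = sample_truth(config, rng)
    tirf = render_tirf(truth, config, rng)
    esem = render_esem(truth, config, rng)
    return tirf, esem, truth


def simulate_tirf(config: SimulationConfig) -> tuple[RasterImage, GroundTruth]:
    """TIRF frame + truth only (for fluorescence-only studies).

    Uses the same draw order as :func:`simulate_pair`, so the truth tables
    and the TIRF raster are identical to the paired run at the same seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_truth(config, rng)
    return render_tirf(truth, config, rng), truth


def noiseless_spot_image(
    fwhm_nm: float,
    pixel_nm: float = 60.0,
    size_px: int = 101,
    center_nm: tuple[float, float] | None = None,
    amplitude: float = 1000.0,
    background: float = 0.0,
) -> RasterImage:
    """Analytic single-Gaussian-spot image with no noise (float intensities).

    The calibration reference for spot detection and FWHM measurement:
    the spot's true FWHM is exactly ``fwhm_nm``.
    """
    if center_nm is None:
        c = (size_px - 1) / 2.0 * pixel_nm
        center_nm = (c, c)
    sigma = fwhm_nm / 2.3548200450309493
    rr, cc = np.mgrid[0:size_px, 0:size_px]
    x = cc * pixel_nm
    y = rr * pixel_nm
    data = background + amplitude * np.exp(
        -((x - center_nm[0]) ** 2 + (y - center_nm[1]) ** 2) / (2 * sigma**2)
    )
    return RasterImage(data, pixel_nm, "tirf")


def simulate_disk_field(
    n_particles: int,
    diam_mean_nm: float = 38.0,
    diam_sd_nm: float = 11.5,
    pixel_nm: float = 3.0,
    gap_nm: float | None = None,
    noise_frac: float = 0.05,
    polarity: str = "bright",
    seed: int = 0,
) -> tuple[RasterImage, pd.DataFrame]:
    """ESEM-only field of guaranteed non-overlapping particles.

    Particles sit on a jittered square grid whose cell is large enough that
    disks can never touch, so segmentation accuracy can be scored particle
    by particle.  Returns the image and a truth table
    (particle_id, x_nm, y_nm, diam_nm).
    """
    rng = np.random.default_rng(seed)
    diam = np.clip(rng.normal(diam_mean_nm, diam_sd_nm, n_particles), 5.0, None)
    dmax = float(diam.max())
    cell = gap_nm if gap_nm is not None else 4.0 * dmax
    side = int(np.ceil(np.sqrt(n_particles)))
    jitter = (cell - dmax) / 2.0 - 2 * pixel_nm
    grid = np.array(
        [((i % side) + 0.5, (i // side) + 0.5) for i in range(n_particles)]
    )
    centers = grid * cell + rng.uniform(-jitter, jitter, (n_particles, 2))
    field = side * cell
    contrast = ESEM_CONTRAST if polarity == "bright" else -ESEM_CONTRAST
    base = ESEM_BACKGROUND if polarity == "bright" else ESEM_BACKGROUND + ESEM_CONTRAST
    shape = (int(round(field / pixel_nm)),) * 2
    img = np.full(shape, base, dtype=np.float32)
    for (cx, cy), d in zip(centers, diam):
        _add_disk(img, cx / pixel_nm, cy / pixel_nm, d / 2 / pixel_nm, contrast)
    if noise_frac > 0:
        img = img + rng.normal(0, noise_frac * ESEM_CONTRAST, shape).astype(np.float32)
    img = np.clip(np.rint(img), 0, UINT16_MAX).astype(np.uint16)
    table = pd.DataFrame(
        {
            "particle_id": np.arange(n_particles),
            "x_nm": centers[:, 0],
            "y_nm": centers[:, 1],
            "diam_nm": diam,
        }
    )
    return RasterImage(img, pixel_nm, "esem"), table


# --------------------------------------------------------------------------
# fixture I/O
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(
    truth: GroundTruth,
    tirf: RasterImage,
    esem: RasterImage,
    out_dir,
    config: SimulationConfig | None = None,
) -> dict:
    """Write images (16-bit TIFF), truth tables (CSV) and a manifest (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "tirf.tif", tirf)
    write_image(out / "esem.tif", esem)
    truth.domains.to_csv(out / "domains.csv", index=False)
    truth.particles.to_csv(out / "particles.csv", index=False)
    truth.fiducials.to_csv(out / "fiducials.csv")
    truth.transform.to_json(out / "transform.json")
    files = ["tirf.tif", "esem.tif", "domains.csv", "particles.csv",
             "fiducials.csv", "transform.json"]
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "pixel_size_nm": {"tirf": tirf.pixel_size_nm, "esem": esem.pixel_size_nm},
        "files": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_fixture(fixture_dir) -> tuple[RasterImage, RasterImage, GroundTruth, dict]:
    """Read back a fixture written by :func:`write_fixture`."""
    d = Path(fixture_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    px = manifest["pixel_size_nm"]
    tirf = read_image(d / "tirf.tif", tuple(px["tirf"]), "tirf")
    esem = read_image(d / "esem.tif", tuple(px["esem"]), "esem")
    truth = GroundTruth(
        pd.read_csv(d / "domains.csv"),
        pd.read_csv(d / "particles.csv"),
        FiducialSet.from_csv(d / "fiducials.csv"),
        AffineTransform.from_json(d / "transform.json"),
    )
    return tirf, esem, truth, manifest
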
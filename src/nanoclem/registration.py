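"""Fiducial-based affine registration between the ESEM and TIRF frames.

The correlative overlay needs a coordinate transform mapping electron-image
coordinates (source) into the fluorescence frame (target), solved from three
or more manually matched fiducial points.  Three-point alignment with
translation, rotation and independent scaling along two axes is, with three
point pairs, exactly the full 2-D affine transform (six constraints, six
degrees of freedom), so the solver estimates the full affine and reports the
rotation / per-axis-scale / shear decomposition; a materially non-zero shear
is flagged because the physical model expects none.

All coordinates are nanometres.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import RasterImage

logger = logging.getLogger(__name__)

#: |det| below which a linear part is treated as singular.
SINGULARITY_TOL = 1e-12
#: Fiducial triangle area below COLLINEARITY_TOL * span**2 is degenerate.
COLLINEARITY_TOL = 1e-6
#: |shear| (radians) above which the decomposition warns.
SHEAR_WARN = 0.05


class InsufficientFiducialsError(ValueError):
    """Fewer than three matched fiducial pairs."""


class DegenerateGeometryError(ValueError):
    """Collinear fiducials or a singular transform."""


@dataclass(frozen=True)
class AffineTransform:
    """y = A @ x + t mapping source-frame nm to target-frame nm.

    The decomposition convention is rotation-after-scale/shear:
    ``A = [[sx cos t, -sy sin(t + h)], [sx sin t, sy cos(t + h)]]``
    with rotation ``t``, scales ``(sx, sy)`` and shear angle ``h``.
    """

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if m.shape != (2, 2):
            raise ValueError("linear part must be 2x2")
        if abs(np.linalg.det(m)) <= SINGULARITY_TOL:
            raise DegenerateGeometryError(
                f"linear part is singular (|det| = {abs(np.linalg.det(m)):.3g})"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def from_params(
        cls,
        rotation_rad: float = 0.0,
        scale: tuple[float, float] = (1.0, 1.0),
        translation_nm: tuple[float, float] = (0.0, 0.0),
        shear_rad: float = 0.0,
    ) -> "AffineTransform":
        sx, sy = scale
        th, sh = rotation_rad, shear_rad
        m = np.array(
            [
                [sx * np.cos(th), -sy * np.sin(th + sh)],
                [sx * np.sin(th), sy * np.cos(th + sh)],
            ]
        )
        return cls(m, np.asarray(translation_nm, dtype=float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points_nm: np.ndarray) -> np.ndarray:
        """Map (n, 2) or (2,) source points into the target frame."""
        pts = np.asarray(points_nm, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform(minv, -minv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return T such that T(x) = self(other(x))."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    # -- reporting ---------------------------------------------------------
    @property
    def decomposition(self) -> dict:
        """Rotation (rad), per-axis scales, shear (rad) and translation."""
        a, b = self.matrix[0]
        c, d = self.matrix[1]
        sx = float(np.hypot(a, c))
        theta = float(np.arctan2(c, a))
        sy = float(np.hypot(b, d))
        shear = float(np.arctan2(-b, d) - theta)
        # wrap shear into (-pi, pi]
        shear = float((shear + np.pi) % (2 * np.pi) - np.pi)
        if abs(shear) > SHEAR_WARN:
            warnings.warn(
                f"transform shear {shear:.3f} rad exceeds {SHEAR_WARN}; "
                "fiducials may be misidentified",
                stacklevel=2,
            )
        return {
            "rotation_rad": theta,
            "scale": (sx, sy),
            "shear_rad": shear,
            "translation_nm": tuple(self.translation),
        }

    def to_json(self, path=None) -> dict:
        obj = {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "units": "nm",
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        return obj

    @classmethod
    def from_json(cls, source) -> "AffineTransform":
        if isinstance(source, dict):
            obj = source
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(np.asarray(obj["matrix"]), np.asarray(obj["translation"]))


@dataclass
class FiducialSet:
    """Matched (source, target) fiducial points; residuals filled by the solve."""

    source_nm: np.ndarray
    target_nm: np.ndarray
    residuals_nm: np.ndarray | None = field(default=None)
    fre_nm: float | None = field(default=None)

    def __post_init__(self):
        self.source_nm = np.atleast_2d(np.asarray(self.source_nm, dtype=float))
        self.target_nm = np.atleast_2d(np.asarray(self.target_nm, dtype=float))
        if self.source_nm.shape != self.target_nm.shape or self.source_nm.shape[1] != 2:
            raise ValueError("source and target must be matching (n, 2) arrays")
        if len(self.source_nm) < 3:
            raise InsufficientFiducialsError(
                f"need >= 3 fiducial pairs, got {len(self.source_nm)}"
            )

    def __len__(self) -> int:
        return len(self.source_nm)

    @classmethod
    def from_csv(cls, path) -> "FiducialSet":
        df = pd.read_csv(path)
        cols = ["x_src_nm", "y_src_nm", "x_tgt_nm", "y_tgt_nm"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"fiducial CSV missing columns {missing}")
        return cls(df[cols[:2]].to_numpy(), df[cols[2:]].to_numpy())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.source_nm, self.target_nm]),
            columns=["x_src_nm", "y_src_nm", "x_tgt_nm", "y_tgt_nm"],
        )
        if self.residuals_nm is not None:
            df["residual_nm"] = self.residuals_nm
        df.to_csv(path, index=False)


def _check_geometry(src: np.ndarray) -> None:
    span = float(np.ptp(src, axis=0).max())
    if span == 0:
        raise DegenerateGeometryError("all fiducial sources coincide")
    centered = src - src.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # s[0]*s[1]/2 equals the triangle area for 3 points up to a bounded factor;
    # for n>3 it is the analogous planar-spread measure.
    if s[1] * s[0] / 2.0 < COLLINEARITY_TOL * span**2:
        raise DegenerateGeometryError(
            "fiducial source points are (near-)collinear; pick a wider triangle"
        )


def solve_transform(fiducials: FiducialSet) -> AffineTransform:
    """Least-squares affine from matched fiducials (exact for three pairs).

    Fills ``fiducials.residuals_nm`` (per-pair Euclidean residual in the
    target frame) and ``fiducials.fre_nm`` (RMS fiducial registration error).
    """
    src, dst = fiducials.source_nm, fiducials.target_nm
    _check_geometry(src)
    n = len(src)
    design = np.column_stack([src, np.ones(n)])  # (n, 3)
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    transform = AffineTransform(sol[:2].T, sol[2])
    res = transform.apply(src) - dst
    fiducials.residuals_nm = np.linalg.norm(res, axis=1)
    fiducials.fre_nm = float(np.sqrt(np.mean(fiducials.residuals_nm**2)))
    return transform


def map_points(transform: AffineTransform, points_nm: np.ndarray) -> np.ndarray:
    """Apply the transform to points; thin functional alias of ``apply``."""
    pts = np.asarray(points_nm, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return transform.apply(pts)


def resample_image(
    transform: AffineTransform,
    image: RasterImage,
    target_shape: tuple[int, int],
    target_pixel_size_nm: tuple[float, float] | float,
    fill_value: float = np.nan,
) -> RasterImage:
    """Resample a source-frame image onto a target-frame grid.

    The transform maps source nm to target nm; each target pixel center is
    inverse-mapped into the source image and bilinearly interpolated.
    Target pixels falling outside the source field receive ``fill_value``.
    """
    if np.isscalar(target_pixel_size_nm):
        target_pixel_size_nm = (float(target_pixel_size_nm),) * 2
    inv = transform.inverse()
    rows, cols = np.mgrid[0 : target_shape[0], 0 : target_shape[1]]
    xy_target = np.column_stack(
        [cols.ravel() * target_pixel_size_nm[0], rows.ravel() * target_pixel_size_nm[1]]
    )
    xy_source = inv.apply(xy_target)
    coords = np.array(
        [
            xy_source[:, 1] / image.pixel_size_nm[1],  # row
            xy_source[:, 0] / image.pixel_size_nm[0],  # col
        ]
    )
    out = ndimage.map_coordinates(
        image.data.astype(float), coords, order=1, mode="constant", cval=fill_value
    ).reshape(target_shape)
    return RasterImage(out, target_pixel_size_nm, image.modality, dict(image.meta))
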
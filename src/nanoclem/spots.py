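"""Nanodomain detection and FWHM measurement in TIRF images.

Nanodomains appear as diffraction-limited fluorescent spots; their size is
quantified as the full width at half maximum (FWHM) of intensity profiles
drawn through each spot.  Detection is automated: smoothed local maxima
above a robust threshold, refined to subpixel precision with a 2-D Gaussian
fit.  Each spot's FWHM is the mean of two orthogonal (0° and 90°) profile
FWHMs, with the half-maximum level referenced to a per-profile background
estimated from the profile tails — which makes the measure invariant to
affine intensity rescaling and robust to neighbouring spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .image import RasterImage

FWHM_PER_SIGMA = 2.3548200450309493  # 2 sqrt(2 ln 2)

FLAG_OK = "ok"
FLAG_EDGE = "edge"
FLAG_SATURATED = "saturated"
FLAG_FIT_FAILED = "fit-failed"
FLAG_MULTI_PEAK = "multi-peak"


@dataclass
class SpotParams:
    """Detection and measurement parameters.

    sigma_smooth_px : pre-detection Gaussian smoothing, pixels.
    k_mad : detection threshold in robust SDs (MAD * 1.4826) above the
        image median; no threshold was published for the original
        interactive analysis, so this is an explicit, declared default.
    min_separation_nm : maxima closer than this merge to the brighter one;
        default ≈ the smallest frequent nanodomain FWHM, so a single
        domain is never split into two detections.
    refine_halfwidth_px : half-size of the Gaussian-fit refinement window.
    profile_half_length_nm : half-length of each intensity profile.
    tail_frac : outermost fraction of each profile tail used to estimate
        the local background level.
    """

    sigma_smooth_px: float = 1.0
    k_mad: float = 5.0
    min_separation_nm: float = 300.0
    refine_halfwidth_px: int = 4
    profile_half_length_nm: float = 1000.0
    tail_frac: float = 0.2


@dataclass
class SpotRecord:
    """One detected nanodomain."""

    spot_id: int
    x_nm: float
    y_nm: float
    peak: float  # background-subtracted counts
    fwhm_nm: float  # NaN until measured or on failure
    flag: str = FLAG_OK


def spots_to_df(spots: list[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "x_nm": s.x_nm,
                "y_nm": s.y_nm,
                "peak": s.peak,
                "fwhm_nm": s.fwhm_nm,
                "flag": s.flag,
            }
            for s in spots
        ],
        columns=["spot_id", "x_nm", "y_nm", "peak", "fwhm_nm", "flag"],
    )


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def detect_spots(image: RasterImage, params: SpotParams | None = None) -> list[SpotRecord]:
    """Detect spot centers (no FWHM yet).

    Local maxima of the Gaussian-smoothed image above
    ``median + k_mad * (1.4826 * MAD)``, separated by at least
    ``min_separation_nm``; centers refined by a local 2-D Gaussian fit.
    """
    params = params or SpotParams()
    if image.modality == "esem":
        warnings.warn("detect_spots called on an ESEM-tagged image", stacklevel=2)
    data = image.data.astype(float)
    if np.ptp(data) == 0:
        return []
    smoothed = ndimage.gaussian_filter(data, params.sigma_smooth_px)
    bg = np.median(smoothed)
    # noise scale from the *raw* image: smoothing shrinks the noise floor,
    # and a k-sigma cut on the smoothed scale admits smoothed-noise maxima
    mad = np.median(np.abs(data - np.median(data)))
    robust_sd = 1.4826 * mad
    threshold = bg + params.k_mad * robust_sd
    if robust_sd == 0:
        threshold = bg + 1e-9  # noiseless image: anything above background
    min_dist = max(1, int(round(params.min_separation_nm / min(image.pixel_size_nm))))
    coords = peak_local_max(
        smoothed, min_distance=min_dist, threshold_abs=threshold, exclude_border=False
    )
    sat_level = _saturation_level(image.data.dtype)
    spots: list[SpotRecord] = []
    for i, (r, c) in enumerate(coords):
        flag = FLAG_OK
        if sat_level is not None and image.data[r, c] >= sat_level:
            flag = FLAG_SATURATED
        center_px, peak, fit_ok = _refine_center(data, (r, c), params.refine_halfwidth_px)
        if not fit_ok and flag == FLAG_OK:
            flag = FLAG_FIT_FAILED
        x_nm = center_px[1] * image.pixel_size_nm[0]
        y_nm = center_px[0] * image.pixel_size_nm[1]
        spots.append(SpotRecord(i, x_nm, y_nm, peak - bg, np.nan, flag))
    return spots


def _saturation_level(dtype) -> float | None:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return None


def _gauss2d(xy, amp, x0, y0, sigma, offset):
    x, y = xy
    return offset + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2))


def _refine_center(data, rc, half):
    """Subpixel center via an isotropic 2-D Gaussian fit in a local window."""
    r, c = rc
    r0, r1 = max(r - half, 0), min(r + half + 1, data.shape[0])
    c0, c1 = max(c - half, 0), min(c + half + 1, data.shape[1])
    window = data[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    offset0 = float(window.min())
    amp0 = float(data[r, c] - offset0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (cc.ravel(), rr.ravel()),
            window.ravel(),
            p0=[max(amp0, 1e-6), c, r, max(half / 2.0, 0.5), offset0],
            bounds=(
                [0, c0 - 0.5, r0 - 0.5, 0.2, -np.inf],
                [np.inf, c1 - 0.5, r1 - 0.5, 4.0 * half, np.inf],
            ),
            maxfev=2000,
        )
        amp, x0, y0 = popt[0], popt[1], popt[2]
        return (y0, x0), float(amp + popt[4]), True
    except (RuntimeError, ValueError):
        return (float(r), float(c)), float(data[r, c]), False


# --------------------------------------------------------------------------
# profiles and FWHM
# --------------------------------------------------------------------------

def extract_profile(
    image: RasterImage,
    center_nm: tuple[float, float],
    direction_rad: float,
    half_length_nm: float,
):
    """Interpolated line profile through ``center_nm``.

    Cubic-spline samples at the pixel pitch; distances are signed and
    centred at 0.  (Bilinear sampling biases the FWHM of subpixel-centred
    spots by up to +3% at half-pixel phase; cubic interpolation keeps the
    calibration error of diffraction-sized spots below 1%.)  Samples
    falling outside the image are dropped and ``truncated`` is set.
    """
    px = min(image.pixel_size_nm)
    n = int(np.floor(half_length_nm / px))
    d = np.arange(-n, n + 1) * px
    ux, uy = np.cos(direction_rad), np.sin(direction_rad)
    x = center_nm[0] + d * ux
    y = center_nm[1] + d * uy
    rows = y / image.pixel_size_nm[1]
    cols = x / image.pixel_size_nm[0]
    inside = (
        (rows >= 0)
        & (rows <= image.data.shape[0] - 1)
        & (cols >= 0)
        & (cols <= image.data.shape[1] - 1)
    )
    truncated = not inside.all()
    rows, cols, d = rows[inside], cols[inside], d[inside]
    values = ndimage.map_coordinates(
        image.data.astype(float), np.array([rows, cols]), order=3, mode="nearest"
    )
    return d, values, truncated


def fwhm_from_profile(distance_nm: np.ndarray, intensity: np.ndarray):
    """FWHM of a single-peaked profile; returns ``(fwhm_nm, flag)``.

    Background is the median of the outer ``20%`` of samples on each tail;
    the half-maximum level is ``background + 0.5 * (peak - background)``.
    Crossings are located by linear interpolation between the bracketing
    samples, walking outward from the peak; re-crossings further out flag
    the profile as multi-peaked (the inner pair is still reported).
    """
    d = np.asarray(distance_nm, dtype=float)
    v = np.asarray(intensity, dtype=float)
    if len(d) < 5:
        return np.nan, FLAG_EDGE
    n_tail = max(1, int(round(0.2 * len(v))))
    bg = float(np.median(np.concatenate([v[:n_tail], v[-n_tail:]])))
    ipk = int(np.argmax(v))
    if ipk == 0 or ipk == len(v) - 1:
        return np.nan, FLAG_EDGE
    peak = _peak_level(d, v, ipk)
    half = bg + 0.5 * (peak - bg)
    if peak <= bg:
        return np.nan, FLAG_EDGE

    left = _crossing(d, v, ipk, half, step=-1)
    right = _crossing(d, v, ipk, half, step=+1)
    if left is None or right is None:
        return np.nan, FLAG_EDGE
    (xl, multi_l), (xr, multi_r) = left, right
    flag = FLAG_MULTI_PEAK if (multi_l or multi_r) else FLAG_OK
    return float(xr - xl), flag


def _gauss1d(x, amp, x0, sigma, offset):
    return offset + amp * np.exp(-((x - x0) ** 2) / (2 * sigma**2))


def _peak_level(d, v, ipk):
    """Peak height estimated by a 1-D Gaussian + offset fit to the profile.

    The raw maximum of a noisy profile is biased upward (max-selection over
    noise), which inflates the half-maximum level and shrinks the FWHM; a
    whole-profile fit averages the noise out, and for the quasi-Gaussian
    spots this stage measures it is an unbiased estimate of the true peak.
    Only the *level* comes from the fit — the width is still read from the
    half-max crossings of the measured samples.  Falls back to the raw
    maximum when the fit fails or wanders.
    """
    raw = float(v[ipk])
    n_tail = max(1, int(round(0.2 * len(v))))
    tails = np.concatenate([v[:n_tail], v[-n_tail:]])
    bg0 = float(np.median(tails))
    noise_sd = 1.4826 * float(np.median(np.abs(tails - bg0)))
    span = max(d[-1] - d[0], 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gauss1d,
                d,
                v,
                p0=[raw - bg0, d[ipk], 0.15 * span, bg0],
                maxfev=2000,
            )
        peak = float(popt[3] + abs(popt[0]))
    except (RuntimeError, ValueError):
        return raw
    # a fitted peak far from the raw maximum relative to the noise level
    # means the profile is not Gaussian-shaped; trust the data then
    amp = max(raw - bg0, 1e-12)
    if abs(peak - raw) > max(0.04 * amp, 4.0 * noise_sd):
        return raw
    return peak


def _crossing(d, v, ipk, half, step):
    """First half-max crossing walking outward from the peak; None if absent."""
    i = ipk
    x = None
    while 0 <= i + step < len(v):
        j = i + step
        if v[j] < half <= v[i] or (v[j] < half and x is None):
            if v[i] != v[j]:
                frac = (v[i] - half) / (v[i] - v[j])
            else:
                frac = 0.5
            x = d[i] + frac * (d[j] - d[i])
            break
        i = j
    if x is None:
        return None
    # any sample beyond the crossing rising back above half => secondary peak
    if step < 0:
        beyond = v[: max(i + step, 0) + 1]
    else:
        beyond = v[i + step :]
    multi = bool(np.any(beyond > half))
    return x, multi


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

def measure_spots(
    image: RasterImage,
    spots: list[SpotRecord],
    params: SpotParams | None = None,
) -> list[SpotRecord]:
    """Fill each spot's FWHM as the mean of the 0° and 90° profile FWHMs.

    A failure of either profile flags the spot and leaves its FWHM NaN;
    flags set at detection (saturated, fit-failed) are preserved.
    """
    params = params or SpotParams()
    out: list[SpotRecord] = []
    for s in spots:
        fwhms = []
        flag = s.flag
        truncated = False
        for direction in (0.0, np.pi / 2):
            d, v, trunc = extract_profile(
                image, (s.x_nm, s.y_nm), direction, params.profile_half_length_nm
            )
            truncated = truncated or trunc
            f, pflag = fwhm_from_profile(d, v)
            if pflag in (FLAG_EDGE,) or not np.isfinite(f):
                flag = FLAG_EDGE if flag == FLAG_OK else flag
                fwhms = []
                break
            if pflag == FLAG_MULTI_PEAK and flag == FLAG_OK:
                flag = FLAG_MULTI_PEAK
            fwhms.append(f)
        if truncated and flag == FLAG_OK:
            flag = FLAG_EDGE
        fwhm = float(np.mean(fwhms)) if len(fwhms) == 2 else np.nan
        out.append(SpotRecord(s.spot_id, s.x_nm, s.y_nm, s.peak, fwhm, flag))
    return out


def detect_and_measure(
    image: RasterImage, params: SpotParams | None = None
) -> list[SpotRecord]:
    """Convenience composition of detection and FWHM measurement."""
    params = params or SpotParams()
    return measure_spots(image, detect_spots(image, params), params)
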